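# Methods

This note documents the models and procedures implemented in
`kbcascade`, the defaults they use, and what the synthetic-data
generator does and does not emulate.

## Study design being modelled

The pipeline models a B-cell activation experiment: cells stimulated at
t = 0 and profiled at 0, 1 and 4 h. Nuclear NF-κB (RELA) rises sharply
by 1 h and largely exits again by 4 h, so RELA genome binding is
expected to peak at 1 h. The perturbation arm expresses a
degradation-resistant dominant-negative IκBα (dnIκBα) from a
tetracycline-inducible cassette in two independent clones; pre-treating
with Tet for 24 h blocks classical NF-κB nuclear translocation while
leaving basal expression largely untouched. Three cell lines are
therefore profiled: the parental line (no inducer) and two clones each
± Tet, with two replicates per condition — 30 RNA samples at the
defaults.

## Gene models and windows

Coordinates are 0-based half-open internally; GTF is converted on
read/write. Three stranded windows hang off each TSS:

| window | span (stranded) | used for |
|---|---|---|
| annotation | −1000 .. +100 | peak annotation, promoter Pol II, loop anchors |
| scan | −400 .. +100 | promoter motif prevalence |
| conservation | −1000 .. −1 | cross-species κB-site conservation |

Peak annotation is by peak midpoint with fixed priority promoter >
5′UTR > 3′UTR > exon > intron > TTS (±100 bp) > intergenic; the
priority order is stated so results are exactly reproducible. Peaks are
assigned to the gene with the nearest TSS (by midpoint) within 50 kb,
except that a midpoint inside a gene body or promoter window always
assigns to that gene; ties break to the lexicographically smaller gene
id. Distances are signed, negative upstream in the direction of
transcription.

## Replicate peak filter

"Present in both replicates" is interpreted as ≥ 1 bp overlap between
peaks that each score ≥ 100 (the score threshold is a parameter). The
emitted interval is the union of the overlapping peaks and the emitted
score the minimum of the two sides, which makes the retained genomic
regions independent of argument order. The filter is monotone in the
score threshold.

## Differential testing

The per-gene differential test is a deliberately simple, deterministic
substitute for an empirical-Bayes count model, behind a pluggable
contract (any per-gene log2FC/FDR table can be swapped in):

1. size factors by median-of-ratios against the geometric-mean
   reference (composition-robust, unlike total-count scaling — this
   matters because strong induction shifts library composition and
   would otherwise make flat genes appear to change);
2. y = log₂(count / sf + 1);
3. pooled two-sample variance per gene, shrunk toward the across-gene
   median with `prior_df = 10` pseudo-observations;
4. moderated t with residual + prior degrees of freedom, two-sided;
5. Benjamini–Hochberg FDR per contrast.

Information sharing across genes (step 3) is what makes 2–3-replicate
designs testable at all; with 2 + 2 replicates a plain t-test has 2
degrees of freedom and essentially no power. Under a global null
simulation the FDR ≤ 0.05 call rate stays at or below nominal, and
8-fold effects at n = 3 and dispersion 0.05 are recovered with recall
above 0.9 (both recomputed by the test suite and acceptance script).

Reads-per-million (each sample scaled to 10⁶) is retained as the
normalization for fold changes, trajectories and display. Fold changes
use a pseudocount of 1, so "≥ 2-fold" means |log₂FC| ≥ 1. Genes whose
mean RPM stays below 1 in every condition are excluded before
classification (floor configurable).

## Target taxonomy

A gene is **dn-reduced** when the +Tet vs −Tet contrast is significant
(FDR ≤ 0.05) with negative log2FC in *both* clones at at least one
shared time point (1 h or 4 h); **dn-increased** is the mirror image.
Requiring direction agreement at a shared time point is our reading of
"replicated in both clones" — the weakest rule that still uses both
clones as biological replication. Then:

* dn-reduced ∧ bound → **Ad**, unbound → **Ai**;
* dn-increased ∧ bound → **Rd**, unbound → **Ri**;
* qualifying in both directions (different time points) → **other**
  (kept out of both sets so the classes stay disjoint);
* no significant contrast anywhere (activation or Tet, either clone) →
  **nonfunctional_bound** if bound else **unaffected**;
* everything else (e.g. single-clone responses) → **other**.

"Bound" means ≥ 1 reproducible inducible RELA peak assigned to the
gene. The identity |Ad| + |Ai| = |dn-reduced| and |Rd| + |Ri| =
|dn-increased| holds structurally. The *robust* flag marks functional
targets changed ≥ 2-fold at 1 or 4 h in the uninduced parental line
(boundary inclusive). Pattern labels concatenate the kinetic cluster
number with the class suffix ("3Ad"); combined response groups I–IV
(dn-reduced / dn-increased / activation-up-dn-insensitive /
activation-down-dn-insensitive) partition the activation-responsive
genes.

## Kinetic clustering

k-means under correlation distance d(x, y) = 1 − Pearson(x, y), exactly
the metric a MATLAB `kmeans(..., 'Distance', 'correlation')` run uses:
rows are standardized to zero mean and unit norm, assignment maximizes
the dot product, and centroids are re-standardized member means.
Defaults: k = 6, 5 restarts, restart r seeded from `seed + r`,
k-means++ (D²) seeding per restart (also the MATLAB default
initializer), ties on total within-cluster distance to the earlier
restart, labels renumbered by descending cluster size. Clustering
operates on per-condition replicate-mean trajectories; zero-variance
trajectories must be removed beforehand (the metric is undefined for
them, and the code raises).

The silhouette uses the same distance with a permuted-membership null
(cluster sizes preserved). Note the null mean on strongly clustered
data is *negative*, not zero — a randomly relabelled gene sits far from
its assigned cluster — and approaches zero only as structure vanishes.
The elbow curve adds one warm-start candidate per k (the best k−1
solution with its farthest point split off), which makes the curve
non-increasing in k by construction rather than only in expectation.

## Loop categories

PET clusters are filtered at ≥ 2 tags and FDR ≤ 0.05. When the input
carries no FDR, a per-cluster p-value is computed under a
marginal-frequency random-ligation binomial model (expected share of an
anchor pair ∝ product of anchor marginal PET totals over the grand
total), BH-corrected — a simplified, pluggable stand-in for a full
interaction caller. A loop *involves* a gene when an anchor overlaps
the gene's promoter window or body; multi-gene calls (category IV)
additionally require the gene's *promoter* to participate, per the
promoter–promoter definition of that category. Multi-gene involvement
dominates single-gene involvement. Categories I/II (no loops) split on
reproducible promoter Pol II at 0 h. Baseline-expression differences
across categories are tested with Kruskal–Wallis. Metagene profiles
integrate the bedGraph step function exactly into n equal-width bins
from TSS to TTS, oriented 5′→3′.

## Motifs and conservation

Four κB-family position count matrices (GGGRNYYYCC-like) ship with the
package as *synthetic constructed stand-ins* in JASPAR text format so
the pipeline is self-contained offline; any real JASPAR file is
accepted by the same reader. Scoring uses log-odds with a total
pseudocount of 0.8 split evenly over bases against a uniform background
(common JASPAR practice), thresholded at relative score
(s − min)/(max − min) ≥ 0.80 on both strands; windows containing N are
skipped. Promoter prevalence counts a motif once per promoter and
selects motifs present in *more than* a 20 % fraction (strict
inequality).

Conservation uses pairwise global alignment per species rather than a
multiple alignment: for pairwise site conservation the information is
equivalent, and it keeps the aligner a small, exactly testable
component. The aligner is Needleman–Wunsch, match +1 / mismatch −1 /
gap −2 (linear), deterministic traceback diagonal > up > left. A site
is conserved against a species when the 51-bp window centred on it
(truncated at sequence ends; gaps count as mismatches; denominator =
truncated window length) keeps ≥ 40 % identity *and* the orthologous
window still contains a PWM hit at the 80 % threshold; either criterion
can be toggled, since descriptions of such analyses are ambiguous on
whether identity alone suffices. With no stated rule for combining
species, the per-gene percent is averaged across species by default
(configurable to the minimum).

## Synthetic data generator

The generator is the package's test bed and defines its study
conditions:

* **Genome.** Genes (2–10 kb, 2–4 exons, both strands) packed
  head-to-tail with 25 kb gaps on 2 chromosomes, a 60 kb head margin
  and a 1 Mb gene-free tail that hosts intergenic decoy peaks and decoy
  PET clusters (> 50 kb from any TSS, so they exercise the filters
  without touching truth recovery).
* **Classes.** Multinomial per gene: Ad 12 %, Ai 12 %, Rd 5 %, Ri 6 %,
  nonfunctional bound 15 %, unaffected 50 % — functional targets a
  minority, bound-but-inert genes common, which is the regime that
  makes the classification problem non-trivial.
* **Expression.** Negative-binomial counts (dispersion 0.05) around
  class-specific mean trajectories; baselines log-uniform over 10–1000
  counts; log-normal library-size factors (σ = 0.15) so depth
  normalization is non-trivially exercised. Six up-shapes over
  0/1/4 h (templates with nominal peak 4×, rescaled on the log scale so
  the peak equals the gene's induction fold, drawn log-uniform on
  2.5–12×); repressed genes use the reciprocal trajectory. The
  perturbation acts multiplicatively on the induced component only
  (baseline untouched), and `dn_block = 1` removes it entirely at +Tet.
  `count_noise="none"` freezes counts at rounded means with unit size
  factors — the noise-free configuration in which classification,
  loop categorization and peak assignment must reproduce the planted
  truth exactly.
* **Peaks.** Every bound gene gets a RELA peak at 1 h within 2 kb of
  its TSS (width 200–600 bp); it appears in replicate 2 with
  probability 0.85 by default, and 10 % of scores fall below the 100
  cutoff — so the replicate filter's retention is a measurable,
  planted quantity. Fractions persist at 0 h (10 %) and 4 h (20 %),
  echoing transient binding. Pol II peaks sit at promoters of loop
  categories II–IV at 0 h in both replicates.
* **Loops.** Category III genes get one intra-gene promoter-to-body
  cluster; IV genes are paired into promoter–promoter clusters (an odd
  IV count demotes the last draw to III so multi-gene loops always
  have a partner); decoys are single-count clusters removed by the
  standard filter.
* **Promoters.** 1 kb of uniform random sequence per gene; planted
  sites are PWM consensus at recorded offsets/strands (1–3 sites for
  bound genes, 30 % chance of one site otherwise). Orthologs apply
  i.i.d. substitutions at per-species rates (defaults 0.02–0.30 across
  six species), replacing uniformly over A/C/G/T, with options to spare
  or scramble the planted windows. No indels by default, so alignments
  are testable against trivial positional oracles.

What this does *not* emulate — and hence what passing tests do not
show about real data: mapping artifacts and peak-calling noise,
correlated replicate structure, GC/mappability bias, overdispersion
heterogeneity across genes, linked regulatory variation between
neighbouring genes, indel-rich promoter evolution, and real κB-motif
information content. The generator's purpose is closed-loop
correctness (planted truth in, labels out), not biological realism of
any particular dataset.

## Problem sizes and determinism

The test suite and acceptance script run fixtures of 200–1000 genes;
the acceptance script uses 500 genes for exact-recovery runs, 1000
planted peaks for the retention estimate, 600 trajectories for
clustering, 20 × 2000 genes for test calibration and ~100 planted sites
for conservation — sizes at which every quantity is stable across seeds
while a full run stays in the seconds-to-minutes range on one CPU.
Every random draw descends from a single seed (per-operation child
generators), so fixed seed means byte-identical outputs.

## Known limitations

* The differential test is a normal-theory approximation on log counts;
  it is calibrated and powerful in the simulated regimes but is not a
  substitute for a dedicated count model on real data — the contract
  accepts external results tables for that reason.
* The PET significance model ignores genomic distance and local
  background, and anchor marginals are computed by interval overlap
  within the input file only.
* Anchor-to-gene mapping uses promoter/body overlap with no distance
  tolerance beyond the promoter window.
* With three time points, correlation distance collapses trajectories
  onto one effective dimension; six planted shapes remain separable,
  but finer pattern structure would need more time points.
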