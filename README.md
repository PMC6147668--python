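# kbcascade

Classification of NF-κB/RELA target genes from kinetic genomics data.

Inducible transcription factors such as NF-κB are activated transiently:
binding and transcription must be read jointly over a time course, and
binding alone badly over-predicts function. `kbcascade` implements an
integrative pipeline for deciding, gene by gene, whether a gene is a
*direct* target of RELA (perturbation-sensitive induction plus
reproducible inducible RELA binding), an *indirect* target
(perturbation-sensitive but unbound, i.e. downstream of NF-κB-induced
factors), a *repressed* target (expression increased when NF-κB
activation is blocked), *nonfunctional bound* (RELA binds, nothing
changes), or *unaffected*. It is aimed at regulatory genomicists who
have, or want to prototype against, the standard ingredients of such a
study: replicate ChIP peak sets over a stimulation time course, RNA-seq
counts from perturbation clones (a tetracycline-inducible
dominant-negative IκBα in two independent clones), Pol II ChIA-PET
interaction files, and promoter sequences for conservation analysis.

Because real studies of this kind need many external datasets, the
package ships a first-class synthetic-data generator that emulates the
whole design with a planted, fully known truth table — every downstream
stage is testable end to end without touching external data.

## The method in brief

* **Reproducible peaks.** Peaks with score ≥ 100 present in both
  replicates (≥ 1 bp overlap; merged interval, minimum score) are kept;
  peaks are assigned to the gene with the nearest TSS within 50 kb,
  with promoter windows defined as TSS −1 kb to +100 bp.
* **Differential response.** Per-gene contrasts (activation 1 h/4 h vs
  0 h; +Tet vs −Tet per clone and time) are called with a moderated
  t-test on log₂(normalized counts + 1) at FDR ≤ 0.05
  (Benjamini–Hochberg). A gene is dn-reduced (or dn-increased) when
  both clones agree in direction at a shared time point.
* **Taxonomy.** dn-reduced ∧ bound → Ad; dn-reduced ∧ unbound → Ai;
  dn-increased analogously → Rd/Ri; never significant → nonfunctional
  bound / unaffected; |Ad| + |Ai| always equals the dn-reduced set size.
  Genes changed ≥ 2-fold without the inducer are flagged *robust*.
* **Kinetic patterns.** k-means with correlation distance
  d(x,y) = 1 − r(x,y), k = 6, best of 5 restarts, with silhouette
  against a permuted-membership null and an elbow curve.
* **Loops.** PET clusters with ≥ 2 tags and FDR ≤ 0.05 place each gene
  in category I (no promoter Pol II), II (Pol II, no loop), III
  (single-gene loop) or IV (multi-gene promoter–promoter loop).
* **κB-site conservation.** Promoters (1 kb upstream of the TSS) are
  scanned with four κB-family PWMs at ≥ 80 % relative log-odds score; a
  site is conserved in a species when the 51-bp window around it keeps
  ≥ 40 % identity through a global pairwise alignment and the ortholog
  window still contains a motif hit.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Generate a 500-gene synthetic study and run the pipeline from the shell:

```bash
kbcascade simulate --out demo --seed 3
kbcascade peaks --rep-a demo/peaks_RELA_1h_rep1.bed \
    --rep-b demo/peaks_RELA_1h_rep2.bed --gtf demo/genes.gtf \
    --out demo/peakmap.tsv
kbcascade classify --counts demo/counts.tsv --peak-map demo/peakmap.tsv \
    --out demo/taxonomy.tsv
kbcascade loops --bedpe demo/interactions_rep1.bedpe \
    --polii-a demo/peaks_POLII_0h_rep1.bed \
    --polii-b demo/peaks_POLII_0h_rep2.bed \
    --gtf demo/genes.gtf --out demo/loops.tsv
kbcascade expression --counts demo/counts.tsv --out-prefix demo/expr
```

which prints

```
wrote synthetic study (500 genes) to demo
163 reproducible peaks; map written to demo/peakmap.tsv
class
unaffected             221
Ai                      71
other                   57
nonfunctional_bound     46
Ri                      44
Ad                      42
Rd                      19
category
I      164
II     141
III    119
IV      76
k=6: within-distance 13.293, mean silhouette 0.726 (null -0.153)
```

Reading the output: of 500 simulated genes, 42 are called direct
activated targets (Ad: induction blocked by the dominant negative in
both clones, with a reproducible RELA peak within 50 kb), 71 indirect
(Ai: same response, no peak), 19 + 44 repressed (Rd/Ri), and 46 are
bound but transcriptionally inert. Under the default noise settings
(85 % replicate reproducibility, 10 % sub-threshold peak scores,
negative-binomial counts) the recovered labels track the planted truth
closely but not perfectly — exactly the ambiguity the replicate and
score filters are there to control. The loop table assigns each gene a
Pol II/loop category, and the clustering line reports the correlation
k-means fit with its silhouette against the permutation null
(0.726 vs −0.153: strong pattern structure). In the noise-free
configuration (`count_noise: none`, full reproducibility) the pipeline
reproduces the planted truth table exactly; that configuration is what
the test suite pins down.

The same operations are available as a library
(`kbcascade.filter_reproducible`, `kbcascade.classify_targets`,
`kbcascade.kmeans_patterns`, `kbcascade.conserved_site_fraction`, …) on
pandas objects.

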