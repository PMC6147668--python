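"""Synthetic data with planted ground truth for the whole pipeline.

The generator emulates the design of a B-cell NF-kB activation study:
three cell lines (parental plus two clones carrying a tetracycline-
inducible dominant-negative IkBa), stimulation time points 0/1/4 h with
replicates, replicate ChIP peak sets for RELA and Pol II, Pol II
paired-end-tag interaction (loop) files, and 1 kb ortholog promoter
sequences with planted kB sites.

Every gene carries a known truth label:

* ``Ad``/``Ai`` -- activation-induced genes whose induction is blocked by
  the dominant negative, with (Ad) or without (Ai) a planted RELA peak;
* ``Rd``/``Ri`` -- activation-repressed genes whose repression is relieved
  by the dominant negative, with/without a planted peak;
* ``nonfunctional_bound`` -- RELA-bound but transcriptionally inert;
* ``unaffected`` -- neither bound nor responsive.

Fixing ``SimulationConfig.seed`` fixes every output byte: each operation
draws from its own child generator derived from the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as kio
from .genome import GeneModels

CLASSES = ("Ad", "Ai", "Rd", "Ri", "nonfunctional_bound", "unaffected")
BOUND_CLASSES = frozenset({"Ad", "Rd", "nonfunctional_bound"})
RESPONSIVE_CLASSES = frozenset({"Ad", "Ai", "Rd", "Ri"})
LOOP_CATEGORIES = ("I", "II", "III", "IV")

#: Trajectory templates over (0, 1, 4) h.  Values are fold over baseline with
#: a nominal peak of 4x; `induction_fold` rescales them on the log scale so the
#: peak fold equals the planted fold.  Activation-repressed genes use the
#: reciprocal trajectory.  The six shapes are pairwise distinct after per-gene
#: standardization, which is what correlation-metric clustering sees.
PATTERN_SHAPES: dict[int, tuple[float, float, float]] = {
    1: (1.0, 2.0, 4.0),   # gradual riser
    2: (1.0, 3.0, 4.0),   # early riser, still climbing
    3: (1.0, 4.0, 1.0),   # transient
    4: (1.0, 1.0, 4.0),   # late riser
    5: (1.0, 4.0, 2.0),   # peak then partial decay
    6: (1.0, 2.0, 2.0),   # early plateau
}

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Knobs for the synthetic study.

    Defaults mirror the emulated design: 0/1/4 h time points, two
    replicates, two perturbation clones assayed with and without the
    inducer, and a parental line assayed without it.  Effect sizes for the
    perturbation are configuration knobs, not estimates of any dataset.
    """

    n_genes: int = 500
    seed: int = 0
    class_probs: Mapping[str, float] = field(default_factory=lambda: {
        "Ad": 0.12, "Ai": 0.12, "Rd": 0.05, "Ri": 0.06,
        "nonfunctional_bound": 0.15, "unaffected": 0.50})
    times: tuple[int, ...] = (0, 1, 4)
    n_replicates: int = 2
    # expression
    nb_dispersion: float = 0.05
    base_mean_log10_range: tuple[float, float] = (1.0, 3.0)
    induction_fold_range: tuple[float, float] = (2.5, 12.0)
    dn_block: float = 1.0            # fraction of the induced log-component removed at +Tet
    count_noise: str = "nb"          # "nb" (negative binomial) or "none" (deterministic)
    library_size_sigma: float = 0.15  # log-normal sequencing-depth factors
    # peaks
    replicate_reproducibility: float = 0.85
    peak_score_range: tuple[float, float] = (120.0, 600.0)
    subthreshold_fraction: float = 0.1  # planted peaks scored below the 100 cutoff
    peak_width_range: tuple[int, int] = (200, 600)
    peak_offset_max: int = 2000         # max |peak centre - TSS|
    rela_basal_fraction: float = 0.1    # planted RELA peaks also present at 0 h
    rela_late_fraction: float = 0.2     # planted RELA peaks persisting at 4 h
    n_decoy_peaks: int = 50
    # loops
    loop_category_probs: Mapping[str, float] = field(default_factory=lambda: {
        "I": 0.35, "II": 0.30, "III": 0.20, "IV": 0.15})
    pet_count_range: tuple[int, int] = (2, 10)
    n_decoy_clusters: int = 30
    # promoters / conservation
    divergence_per_species: Mapping[str, float] = field(default_factory=lambda: {
        "chimpanzee": 0.02, "rhesus": 0.07, "cattle": 0.18,
        "dog": 0.18, "mouse": 0.30, "rat": 0.30})
    site_fate: str = "neutral"       # "neutral" | "conserve" | "destroy"
    sites_per_bound_gene: tuple[int, int] = (1, 3)
    p_site_unbound: float = 0.3
    promoter_length: int = 1000
    # genome packing
    gene_length_range: tuple[int, int] = (2000, 10000)
    intergenic_gap: int = 25000
    n_chroms: int = 2
    chrom_length: int | None = None   # per-chromosome cap; auto-sized if None
    decoy_tail: int = 1_000_000       # gene-free tail for intergenic decoys

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("each design cell needs >= 2 replicates")
        for name, p in [("replicate_reproducibility", self.replicate_reproducibility),
                        ("subthreshold_fraction", self.subthreshold_fraction),
                        ("dn_block", self.dn_block),
                        ("p_site_unbound", self.p_site_unbound)]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for sp, d in self.divergence_per_species.items():
            if not 0.0 <= d <= 1.0:
                raise ValueError(f"divergence for {sp} must be in [0, 1]")
        if abs(sum(self.class_probs.values()) - 1.0) > 1e-9:
            raise ValueError("class_probs must sum to 1")
        if abs(sum(self.loop_category_probs.values()) - 1.0) > 1e-9:
            raise ValueError("loop_category_probs must sum to 1")
        if set(self.times) - {0, 1, 4}:
            raise ValueError("times must be drawn from {0, 1, 4}")
        if self.count_noise not in ("nb", "none"):
            raise ValueError("count_noise must be 'nb' or 'none'")
        if self.site_fate not in ("neutral", "conserve", "destroy"):
            raise ValueError("site_fate must be neutral/conserve/destroy")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def generate_gene_models(config: SimulationConfig) -> GeneModels:
    """Pack non-overlapping genes onto ``n_chroms`` chromosomes.

    Genes are laid head-to-tail with ``intergenic_gap`` bp between them and a
    60 kb margin at the chromosome start so promoter and assignment windows
    never escape the sequence.  Raises ``ValueError`` if ``chrom_length`` is
    set and too small for the requested number of genes.
    """
    rng = _rng(config, 0)
    margin = 60_000
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    genes, exons = [], []
    chrom_sizes: dict[str, int] = {}
    gid = 0
    for ci, n_here in enumerate(per_chrom):
        chrom = f"chr{ci + 1}"
        pos = margin
        for _ in range(n_here):
            length = int(rng.integers(*config.gene_length_range, endpoint=True))
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"g{gid:04d}"
            start, end = pos, pos + length
            # exon chain: equal chunks, exons at even chunk indices
            n_exons = int(rng.integers(2, 5))
            chunk = length // (2 * n_exons - 1)
            for k in range(n_exons):
                e_start = start + 2 * k * chunk
                e_end = end if k == n_exons - 1 else e_start + chunk
                exons.append({"gene_id": gene_id, "start": e_start, "end": e_end})
            utr_cap = max(2, min(300, chunk - 1))
            genes.append({
                "gene_id": gene_id, "chrom": chrom, "start": start, "end": end,
                "strand": strand,
                "utr5_len": int(rng.integers(100, utr_cap, endpoint=True)) if utr_cap > 100 else utr_cap,
                "utr3_len": int(rng.integers(100, utr_cap, endpoint=True)) if utr_cap > 100 else utr_cap,
            })
            pos = end + config.intergenic_gap
            gid += 1
        needed = pos - config.intergenic_gap + config.decoy_tail
        if config.chrom_length is not None:
            if needed > config.chrom_length:
                raise ValueError(
                    f"cannot pack {n_here} genes on {chrom}: need {needed} bp "
                    f"but chrom_length is {config.chrom_length}")
            chrom_sizes[chrom] = config.chrom_length
        else:
            chrom_sizes[chrom] = needed
    return GeneModels(pd.DataFrame(genes), pd.DataFrame(exons), chrom_sizes)


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

def make_truth(gene_models: GeneModels, config: SimulationConfig,
               pwm_widths: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Draw the per-gene truth table (class, pattern, loop category, sites).

    Multi-gene loops need at least two participating genes; an odd count of
    category-IV draws demotes the last one to category III so the planted
    truth stays exactly recoverable.
    """
    rng = _rng(config, 1)
    gene_ids = gene_models.genes["gene_id"].tolist()
    n = len(gene_ids)
    classes = rng.choice(list(config.class_probs), size=n,
                         p=list(config.class_probs.values()))
    patterns = np.where(np.isin(classes, list(RESPONSIVE_CLASSES)),
                        rng.integers(1, 7, size=n), 0)
    loop_cats = rng.choice(list(config.loop_category_probs), size=n,
                           p=list(config.loop_category_probs.values()))
    iv_idx = np.flatnonzero(loop_cats == "IV")
    if len(iv_idx) % 2 == 1:
        loop_cats[iv_idx[-1]] = "III"
    lo, hi = config.induction_fold_range
    folds = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    if pwm_widths is None:
        from .motifs import load_kb_pwms
        pwm_widths = {mid: p.width for mid, p in load_kb_pwms().items()}
    motif_ids = list(pwm_widths)
    sites_col: list[list[tuple[int, str, str]]] = []
    n_slots = config.promoter_length // 200
    for i in range(n):
        if classes[i] in BOUND_CLASSES:
            k = int(rng.integers(*config.sites_per_bound_gene, endpoint=True))
        else:
            k = int(rng.random() < config.p_site_unbound)
        slots = rng.choice(n_slots, size=min(k, n_slots), replace=False)
        sites = []
        for s in sorted(slots):
            mid = motif_ids[int(rng.integers(len(motif_ids)))]
            w = pwm_widths[mid]
            off = int(s) * 200 + int(rng.integers(20, 200 - w - 20))
            strand = "+" if rng.random() < 0.5 else "-"
            sites.append((off, strand, mid))
        sites_col.append(sites)
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "true_class": classes,
        "true_pattern": patterns,
        "true_loop_category": loop_cats,
        "induction_fold": folds,
        "planted_kappaB_sites": sites_col,
    })
    return truth


def encode_sites(sites: list[tuple[int, str, str]]) -> str:
    return ";".join(f"{off}:{strand}:{mid}" for off, strand, mid in sites)


def decode_sites(text: str) -> list[tuple[int, str, str]]:
    if not text or text != text:  # empty or NaN
        return []
    out = []
    for part in str(text).split(";"):
        off, strand, mid = part.split(":")
        out.append((int(off), strand, mid))
    return out


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def design_samples(config: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: parental without the inducer, clones with and without."""
    rows = []
    for cell_line in ("parental", "clone1", "clone2"):
        tets = ("minus",) if cell_line == "parental" else ("minus", "plus")
        for tet in tets:
            for t in config.times:
                for r in range(1, config.n_replicates + 1):
                    rows.append({"sample": f"{cell_line}.{tet}.t{t}.r{r}",
                                 "cell_line": cell_line, "tet": tet,
                                 "time": t, "replicate": r})
    return pd.DataFrame(rows).set_index("sample")


def expected_multiplier(true_class: str, pattern: int, fold: float,
                        tet: str, time_index: int, dn_block: float) -> float:
    """Planted mean trajectory as fold over baseline for one design cell."""
    if true_class in ("unaffected", "nonfunctional_bound") or pattern == 0:
        return 1.0
    shape = PATTERN_SHAPES[pattern][time_index]
    alpha = np.log(fold) / np.log(4.0)
    if true_class in ("Rd", "Ri"):
        alpha = -alpha
    if tet == "plus":
        alpha *= (1.0 - dn_block)
    return float(shape ** alpha)


def simulate_expression(gene_models: GeneModels, truth: pd.DataFrame,
                        config: SimulationConfig) -> "ExpressionMatrix":
    """Negative-binomial counts around class-specific mean trajectories.

    Baseline means are log-uniform across genes; sequencing-depth factors
    are log-normal per sample (so depth normalization is non-trivially
    exercised).  ``count_noise='none'`` freezes counts at the rounded means
    with unit depth factors, the noise-free configuration used for exact
    truth-recovery checks.
    """
    from .expression import ExpressionMatrix

    rng = _rng(config, 2)
    samples = design_samples(config)
    for (cell_line, tet, t), grp in samples.groupby(["cell_line", "tet", "time"]):
        if len(grp) < 2:
            raise ValueError(f"design cell ({cell_line}, {tet}, {t} h) has "
                             f"{len(grp)} replicates; need >= 2")
    truth = truth.set_index("gene_id", drop=False).loc[gene_models.genes["gene_id"]]
    n, m = len(truth), len(samples)
    lo, hi = config.base_mean_log10_range
    base = 10.0 ** rng.uniform(lo, hi, size=n)
    t_index = {t: i for i, t in enumerate(sorted(config.times))}
    mult = np.empty((n, m))
    for j, meta in enumerate(samples.itertuples()):
        ti = t_index[meta.time]
        for i, g in enumerate(truth.itertuples()):
            mult[i, j] = expected_multiplier(
                g.true_class, int(g.true_pattern), float(g.induction_fold),
                meta.tet, ti, config.dn_block)
    mean = base[:, None] * mult
    if config.count_noise == "none":
        counts = np.rint(mean).astype(np.int64)
    else:
        sf = np.exp(rng.normal(0.0, config.library_size_sigma, size=m))
        mu = mean * sf[None, :]
        if config.nb_dispersion <= 0:
            counts = rng.poisson(mu)
        else:
            r = 1.0 / config.nb_dispersion
            p = r / (r + mu)
            counts = rng.negative_binomial(r, p)
    counts_df = pd.DataFrame(counts, index=truth["gene_id"].values,
                             columns=samples.index)
    counts_df.index.name = "gene_id"
    return ExpressionMatrix(counts_df, samples)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

def _draw_score(rng: np.random.Generator, config: SimulationConfig) -> float:
    if rng.random() < config.subthreshold_fraction:
        return float(rng.uniform(20.0, 99.0))
    return float(rng.uniform(*config.peak_score_range))


def simulate_peaks(gene_models: GeneModels, truth: pd.DataFrame,
                   config: SimulationConfig) -> dict[tuple[str, int, int], pd.DataFrame]:
    """Replicate peak sets keyed by ``(factor, time, replicate)``.

    Every RELA-bound gene (classes Ad, Rd, nonfunctional_bound) gets one
    RELA peak at 1 h centred within ``peak_offset_max`` of its TSS; the peak
    appears in replicate 2 with probability ``replicate_reproducibility``.
    Subsets persist at 0 h / 4 h per config.  Pol II peaks sit at the
    promoters of genes with loop category II-IV at 0 h in both replicates.
    Decoy peaks land in the gene-free chromosome tails, > 50 kb from any TSS.
    """
    rng = _rng(config, 3)
    tss = gene_models.tss
    chrom_of = gene_models.genes.set_index("gene_id")["chrom"]
    truth = truth.set_index("gene_id", drop=False)
    bound = truth.loc[truth["true_class"].isin(BOUND_CLASSES), "gene_id"].tolist()

    rela: dict[int, list[dict]] = {t: [] for t in (0, 1, 4)}
    for gid in bound:
        centre = int(tss[gid]) + int(rng.integers(-config.peak_offset_max,
                                                  config.peak_offset_max + 1))
        width = int(rng.integers(*config.peak_width_range, endpoint=True))
        score = _draw_score(rng, config)
        in_b = rng.random() < config.replicate_reproducibility
        times = [1]
        if rng.random() < config.rela_basal_fraction:
            times.append(0)
        if rng.random() < config.rela_late_fraction:
            times.append(4)
        for t in times:
            jitter = int(rng.integers(-50, 51))
            rec = {"chrom": chrom_of[gid], "start": centre - width // 2,
                   "end": centre + width // 2, "score": score,
                   "name": f"RELA_{gid}_t{t}", "gene_id": gid,
                   "jitter": jitter, "in_b": in_b}
            rela[t].append(rec)

    polII_genes = truth.loc[truth["true_loop_category"].isin(["II", "III", "IV"]),
                            "gene_id"].tolist()
    pol: list[dict] = []
    for gid in polII_genes:
        score = float(rng.uniform(150.0, 500.0))
        pol.append({"chrom": chrom_of[gid], "start": int(tss[gid]) - 200,
                    "end": int(tss[gid]) + 201, "score": score,
                    "name": f"POLII_{gid}", "gene_id": gid,
                    "jitter": int(rng.integers(-30, 31)), "in_b": True})

    # decoys in the gene-free tail of each chromosome
    tails = []
    for chrom, grp in gene_models.genes.groupby("chrom"):
        lo = int(grp["end"].max()) + 60_000
        hi = gene_models.chrom_sizes.get(chrom, lo + config.decoy_tail) - 1000
        if hi > lo:
            tails.append((chrom, lo, hi))
    def decoys(n_dec, prefix):
        out = []
        for i in range(n_dec):
            chrom, lo, hi = tails[int(rng.integers(len(tails)))]
            start = int(rng.integers(lo, hi))
            width = int(rng.integers(*config.peak_width_range, endpoint=True))
            out.append({"chrom": chrom, "start": start, "end": start + width,
                        "score": _draw_score(rng, config),
                        "name": f"{prefix}_decoy{i}", "gene_id": "",
                        "jitter": int(rng.integers(-50, 51)), "in_b": True})
        return out

    result: dict[tuple[str, int, int], pd.DataFrame] = {}
    for t in (0, 1, 4):
        recs = rela[t] + (decoys(config.n_decoy_peaks, f"RELA_t{t}") if tails else [])
        result[("RELA", t, 1)] = _rep_frame(recs, rep=1)
        result[("RELA", t, 2)] = _rep_frame(recs, rep=2)
    pol_recs = pol + (decoys(config.n_decoy_peaks // 2, "POLII_t0") if tails else [])
    result[("POLII", 0, 1)] = _rep_frame(pol_recs, rep=1)
    result[("POLII", 0, 2)] = _rep_frame(pol_recs, rep=2)
    return result


def _rep_frame(records: list[dict], rep: int) -> pd.DataFrame:
    rows = []
    for rec in records:
        if rep == 2 and not rec["in_b"]:
            continue
        start, end = rec["start"], rec["end"]
        if rep == 2:
            start, end = start + rec["jitter"], end + rec["jitter"]
        rows.append({"chrom": rec["chrom"], "start": start, "end": end,
                     "name": rec["name"], "score": rec["score"], "strand": ".",
                     "gene_id": rec["gene_id"]})
    cols = ["chrom", "start", "end", "name", "score", "strand", "gene_id"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# interactions
# ---------------------------------------------------------------------------

def simulate_interactions(gene_models: GeneModels, truth: pd.DataFrame,
                          config: SimulationConfig,
                          decoys: bool = True) -> pd.DataFrame:
    """BEDPE-style PET clusters implementing the planted loop categories.

    Category III genes get one intra-gene cluster (promoter anchor to gene
    body); category IV genes are chained in pairs through promoter-promoter
    clusters.  Decoy single-count clusters (removed by the standard >= 2
    count filter) land in the chromosome tails.
    """
    rng = _rng(config, 4)
    genes = gene_models.genes.set_index("gene_id")
    tss, tts = gene_models.tss, gene_models.tts
    truth = truth.set_index("gene_id", drop=False)
    rows = []

    def promoter_anchor(gid):
        return genes.loc[gid, "chrom"], int(tss[gid]) - 200, int(tss[gid]) + 201

    for gid in truth.loc[truth["true_loop_category"] == "III", "gene_id"]:
        chrom, a_start, a_end = promoter_anchor(gid)
        body_lo = min(int(tss[gid]), int(tts[gid]))
        body_hi = max(int(tss[gid]), int(tts[gid]))
        b_centre = body_hi - 300 if genes.loc[gid, "strand"] == "+" else body_lo + 300
        b_start, b_end = b_centre - 150, b_centre + 150
        b_start, b_end = max(b_start, body_lo), min(b_end, body_hi)
        rows.append(_pet_row(chrom, a_start, a_end, chrom, b_start, b_end,
                             f"loop_{gid}", rng, config))

    iv = truth.loc[truth["true_loop_category"] == "IV", "gene_id"].tolist()
    for g1, g2 in zip(iv[0::2], iv[1::2]):
        c1, s1, e1 = promoter_anchor(g1)
        c2, s2, e2 = promoter_anchor(g2)
        rows.append(_pet_row(c1, s1, e1, c2, s2, e2, f"loop_{g1}_{g2}", rng, config))

    if decoys and config.n_decoy_clusters:
        tails = []
        for chrom, grp in gene_models.genes.groupby("chrom"):
            lo = int(grp["end"].max()) + 60_000
            hi = gene_models.chrom_sizes.get(chrom, lo + config.decoy_tail) - 10_000
            if hi > lo:
                tails.append((chrom, lo, hi))
        for i in range(config.n_decoy_clusters):
            chrom, lo, hi = tails[int(rng.integers(len(tails)))]
            s1 = int(rng.integers(lo, hi))
            s2 = s1 + int(rng.integers(2000, 8000))
            row = _pet_row(chrom, s1, s1 + 300, chrom, s2, s2 + 300,
                           f"decoy{i}", rng, config)
            row["pet_count"] = 1
            row["p"] = float(rng.uniform(0.05, 1.0))
            row["fdr"] = row["p"]
            rows.append(row)
    df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1", "chrom2",
                                     "start2", "end2", "name", "pet_count",
                                     "p", "fdr"])
    return df


def _pet_row(c1, s1, e1, c2, s2, e2, name, rng, config) -> dict:
    if (c1, s1) > (c2, s2):  # store anchors A <= B by coordinate
        c1, s1, e1, c2, s2, e2 = c2, s2, e2, c1, s1, e1
    p = float(rng.uniform(1e-8, 1e-4))
    return {"chrom1": c1, "start1": s1, "end1": e1,
            "chrom2": c2, "start2": s2, "end2": e2, "name": name,
            "pet_count": int(rng.integers(*config.pet_count_range, endpoint=True)),
            "p": p, "fdr": p}


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

def simulate_promoters(gene_models: GeneModels, truth: pd.DataFrame,
                       pwms: Mapping[str, "object"],
                       config: SimulationConfig) -> dict[str, dict[str, str]]:
    """Human promoters with planted kB consensus sites, plus diverged orthologs.

    The human promoter is ``promoter_length`` bp of random sequence (the
    kilobase upstream of the TSS); planted sites are PWM consensus at the
    recorded offsets and strands.  Each ortholog applies i.i.d. per-base
    substitutions at its species rate, replacing bases uniformly over
    A/C/G/T (so divergence 1 leaves ~25% identity).  ``site_fate`` spares
    ("conserve"), randomizes ("destroy") or ignores ("neutral") the planted
    site windows during substitution.
    """
    rng = _rng(config, 5)
    L = config.promoter_length
    tss = gene_models.tss
    for gid, pos in tss.items():
        if pos - L < 0:
            raise ValueError(f"promoter window of {gid} escapes chromosome bounds")
    truth = truth.set_index("gene_id", drop=False)
    human: dict[str, str] = {}
    site_windows: dict[str, list[tuple[int, int]]] = {}
    for g in truth.itertuples():
        seq = rng.choice(4, size=L)
        windows = []
        for off, strand, mid in g.planted_kappaB_sites:
            cons = pwms[mid].consensus
            if strand == "-":
                cons = _revcomp(cons)
            lut = {"A": 0, "C": 1, "G": 2, "T": 3}
            code = np.array([lut[b] for b in cons])
            seq[off:off + len(cons)] = code
            windows.append((off, off + len(cons)))
        human[g.gene_id] = "".join(_BASES[seq])
        site_windows[g.gene_id] = windows
    out: dict[str, dict[str, str]] = {"human": human}
    for species, rate in config.divergence_per_species.items():
        seqs = {}
        for gid, hseq in human.items():
            arr = np.frombuffer(hseq.encode(), dtype=np.uint8).copy()
            mask = rng.random(L) < rate
            repl = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=L)
            protect = np.zeros(L, dtype=bool)
            for s, e in site_windows[gid]:
                protect[s:e] = True
            if config.site_fate == "conserve":
                mask &= ~protect
            arr[mask] = repl[mask]
            if config.site_fate == "destroy":
                scram = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=L)
                arr[protect] = scram[protect]
            seqs[gid] = arr.tobytes().decode()
        out[species] = seqs
    return out


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, outdir) -> dict:
    """Generate every pipeline input under ``outdir`` and return the objects.

    Writes ``genes.gtf``, ``counts.tsv``, ``peaks_<factor>_<t>h_rep<k>.bed``,
    ``interactions_rep1.bedpe``, ``promoters_<species>.fasta`` and
    ``truth.tsv``.
    """
    from .motifs import load_kb_pwms

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pwms = load_kb_pwms()
    gm = generate_gene_models(config)
    truth = make_truth(gm, config, {mid: p.width for mid, p in pwms.items()})
    em = simulate_expression(gm, truth, config)
    peaks = simulate_peaks(gm, truth, config)
    interactions = simulate_interactions(gm, truth, config)
    promoters = simulate_promoters(gm, truth, pwms, config)

    gm.to_gtf(outdir / "genes.gtf")
    kio.write_counts(em.counts, outdir / "counts.tsv")
    for (factor, t, rep), df in peaks.items():
        kio.write_bed(df, outdir / f"peaks_{factor}_{t}h_rep{rep}.bed")
    kio.write_bedpe(interactions, outdir / "interactions_rep1.bedpe")
    for species, seqs in promoters.items():
        kio.write_fasta(seqs, outdir / f"promoters_{species}.fasta")
    t = truth.copy()
    t["planted_kappaB_sites"] = t["planted_kappaB_sites"].map(encode_sites)
    t.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return {"gene_models": gm, "truth": truth, "expression": em,
            "peaks": peaks, "interactions": interactions,
            "promoters": promoters, "pwms": pwms}
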