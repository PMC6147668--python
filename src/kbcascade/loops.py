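"""Pol II interaction (PET cluster) filtering and per-gene loop categories.

Gene promoter status in unstimulated cells is combined with filtered
paired-end-tag clusters into four categories: I = no promoter Pol II and
no loops; II = promoter Pol II without loops; III = a single-gene loop
(both anchors within one gene, one at its promoter); IV = a multi-gene
loop joining the promoters of at least two genes.  Multi-gene
involvement dominates: a gene with both single- and multi-gene loops is
category IV.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GeneModels, PROMOTER_ANNOTATION

LOOP_CATEGORIES = ("I", "II", "III", "IV")


def filter_pet_clusters(interactions: pd.DataFrame, min_count: int = 2,
                        max_fdr: float = 0.05) -> pd.DataFrame:
    """Retain clusters with >= ``min_count`` PETs and FDR <= ``max_fdr``.

    When no FDR column is present, a per-cluster p-value is computed under
    a marginal-frequency random-ligation binomial model (the expected PET
    share of an anchor pair is proportional to the product of its anchors'
    marginal PET totals over the grand total) and BH-corrected.  This is a
    simplified, pluggable stand-in for a full interaction caller.
    """
    df = interactions.copy()
    if "fdr" not in df.columns or df["fdr"].isna().any():
        df["fdr"] = _binomial_fdr(df)
    keep = (df["pet_count"] >= min_count) & (df["fdr"] <= max_fdr)
    return df[keep].reset_index(drop=True)


def _binomial_fdr(df: pd.DataFrame) -> np.ndarray:
    n = len(df)
    if n == 0:
        return np.array([])
    total = float(df["pet_count"].sum())
    anchors_a = df[["chrom1", "start1", "end1"]].values
    anchors_b = df[["chrom2", "start2", "end2"]].values
    marg_a = np.empty(n)
    marg_b = np.empty(n)
    all_anchors = np.vstack([anchors_a, anchors_b])
    all_counts = np.concatenate([df["pet_count"].values] * 2).astype(float)
    for i in range(n):
        marg_a[i] = _marginal(anchors_a[i], all_anchors, all_counts)
        marg_b[i] = _marginal(anchors_b[i], all_anchors, all_counts)
    p_exp = np.clip(marg_a * marg_b / (total * total), 1e-300, 1.0)
    p = stats.binom.sf(df["pet_count"].values - 1, int(total), p_exp)
    return multipletests(p, method="fdr_bh")[1]


def _marginal(anchor, all_anchors, counts) -> float:
    chrom, start, end = anchor
    same = all_anchors[:, 0] == chrom
    s = all_anchors[:, 1].astype(int)
    e = all_anchors[:, 2].astype(int)
    ov = same & (s < int(end)) & (int(start) < e)
    return float(counts[ov].sum())


def replicate_overlap(set_a: pd.DataFrame, set_b: pd.DataFrame) -> float:
    """Fraction of A clusters whose both anchors overlap those of a B cluster.

    Anchors are matched in order (A anchors are stored sorted), with >= 1 bp
    overlap required on each side.
    """
    if len(set_a) == 0:
        return 0.0
    hits = 0
    for a in set_a.itertuples(index=False):
        for b in set_b.itertuples(index=False):
            if (a.chrom1 == b.chrom1 and a.start1 < b.end1 and b.start1 < a.end1
                    and a.chrom2 == b.chrom2 and a.start2 < b.end2
                    and b.start2 < a.end2):
                hits += 1
                break
    return hits / len(set_a)


def promoter_polII_status(polII_peaks: pd.DataFrame,
                          gene_models: GeneModels) -> pd.Series:
    """True iff a (reproducible) Pol II peak overlaps the promoter window."""
    prom = gene_models.promoter_windows(*PROMOTER_ANNOTATION)
    status = pd.Series(False, index=prom["gene_id"].values, name="polII_at_promoter")
    for chrom, grp in prom.groupby("chrom", sort=False):
        pk = polII_peaks[polII_peaks["chrom"] == chrom]
        if pk.empty:
            continue
        ov = ((grp["start"].values[:, None] < pk["end"].values[None, :]) &
              (pk["start"].values[None, :] < grp["end"].values[:, None]))
        status.loc[grp["gene_id"].values] = ov.any(axis=1)
    return status


def _anchor_gene_sets(interactions: pd.DataFrame, gene_models: GeneModels):
    """Per interaction: genes whose promoter / promoter-or-body an anchor hits."""
    prom = gene_models.promoter_windows(*PROMOTER_ANNOTATION)
    body = gene_models.genes[["gene_id", "chrom", "start", "end"]]
    prom_sets, any_sets = [], []
    for row in interactions.itertuples(index=False):
        p, a = set(), set()
        for chrom, s, e in ((row.chrom1, row.start1, row.end1),
                            (row.chrom2, row.start2, row.end2)):
            pm = prom[(prom["chrom"] == chrom) & (prom["start"] < e) & (s < prom["end"])]
            bd = body[(body["chrom"] == chrom) & (body["start"] < e) & (s < body["end"])]
            p |= set(pm["gene_id"])
            a |= set(pm["gene_id"]) | set(bd["gene_id"])
        prom_sets.append(p)
        any_sets.append(a)
    return prom_sets, any_sets


def categorize_loops(interactions: pd.DataFrame, polII_status: pd.Series,
                     gene_models: GeneModels) -> pd.DataFrame:
    """Assign each gene its loop category from filtered interactions.

    A loop *involves* a gene when an anchor overlaps the gene's promoter
    window or body.  A gene whose promoter joins a loop involving >= 2
    distinct promoters is IV; else a gene with a loop involving only
    itself is III; else II or I by promoter Pol II status.  The result is
    invariant to the order of interaction records.
    """
    prom_sets, any_sets = _anchor_gene_sets(interactions, gene_models)
    gene_ids = gene_models.genes["gene_id"].values
    cat = {}
    for gid in gene_ids:
        is_iv = any(gid in p and len(p) >= 2 for p in prom_sets)
        if is_iv:
            cat[gid] = "IV"
            continue
        is_iii = any(a == {gid} for a in any_sets)
        if is_iii:
            cat[gid] = "III"
        else:
            cat[gid] = "II" if bool(polII_status.get(gid, False)) else "I"
    out = pd.DataFrame({"gene_id": gene_ids,
                        "polII_at_promoter": polII_status.reindex(gene_ids).fillna(False).values,
                        "category": [cat[g] for g in gene_ids]}).set_index("gene_id")
    return out


def category_kinetics(loop_status: pd.DataFrame, records: pd.DataFrame,
                      trajectories: pd.DataFrame | None = None) -> dict:
    """Cross-tabulate loop status with taxonomy classes and patterns.

    Returns a dict with ``table`` (counts of looped [III/IV] vs non-looped
    [I/II] genes per class and pattern label) and, when mean RPM
    ``trajectories`` are given, ``profiles``: mean +/- SEM trajectory per
    loop group.
    """
    joined = records.join(loop_status["category"], how="inner")
    joined["looped"] = joined["category"].isin(["III", "IV"])
    keys = ["class"] + (["pattern_label"] if "pattern_label" in joined.columns else [])
    table = (joined.groupby(keys + ["looped"]).size()
             .unstack("looped", fill_value=0)
             .rename(columns={True: "looped", False: "non_looped"}))
    for col in ("looped", "non_looped"):
        if col not in table.columns:
            table[col] = 0
    out = {"table": table[["looped", "non_looped"]]}
    if trajectories is not None:
        common = joined.index.intersection(trajectories.index)
        grp = trajectories.loc[common].groupby(joined.loc[common, "looped"])
        out["profiles"] = pd.concat({"mean": grp.mean(),
                                     "sem": grp.sem()}, axis=0)
    return out


def baseline_expression_by_category(categories: pd.Series,
                                    baseline_rpm: pd.Series) -> dict:
    """Kruskal-Wallis comparison of baseline RNA across loop categories."""
    common = categories.index.intersection(baseline_rpm.index)
    categories = categories.loc[common]
    baseline_rpm = baseline_rpm.loc[common]
    groups = {}
    for c in LOOP_CATEGORIES:
        vals = baseline_rpm[categories == c].values
        if len(vals) == 0:
            warnings.warn(f"loop category {c} is empty; excluded from the test")
            continue
        groups[c] = vals
    if len(groups) < 2:
        raise ValueError("need >= 2 nonempty categories")
    h, p = stats.kruskal(*groups.values())
    summary = pd.DataFrame({c: {"n": len(v), "median_rpm": float(np.median(v))}
                            for c, v in groups.items()}).T
    return {"H": float(h), "p": float(p), "summary": summary}


def metagene_profile(coverage: pd.DataFrame, gene_models: GeneModels,
                     n_bins: int = 100) -> np.ndarray:
    """Average coverage over gene bodies rescaled to a common length.

    Each gene's TSS-to-TTS coverage (piecewise-constant bedGraph) is
    resampled exactly into ``n_bins`` equal-width bins by integrating the
    step function, oriented 5' to 3' (minus-strand genes are reversed),
    then averaged across genes.
    """
    profiles = []
    for row in gene_models.genes.itertuples(index=False):
        length = row.end - row.start
        if length <= 0:
            raise ValueError(f"gene {row.gene_id} has zero length")
        if length < n_bins:
            raise ValueError(f"gene {row.gene_id} shorter than n_bins={n_bins}")
        cov = coverage[(coverage["chrom"] == row.chrom) &
                       (coverage["start"] < row.end) &
                       (coverage["end"] > row.start)].sort_values("start")
        # breakpoints of the step function clipped to the gene body
        xs = [row.start]
        vals = []
        pos = row.start
        for c in cov.itertuples(index=False):
            s, e = max(c.start, row.start), min(c.end, row.end)
            if s > pos:
                vals.append(0.0)
                xs.append(s)
                pos = s
            vals.append(float(c.value))
            xs.append(e)
            pos = e
        if pos < row.end:
            vals.append(0.0)
            xs.append(row.end)
        xs = np.asarray(xs, dtype=float)
        vals = np.asarray(vals, dtype=float)
        cum = np.concatenate([[0.0], np.cumsum(vals * np.diff(xs))])
        edges = np.linspace(row.start, row.end, n_bins + 1)
        cum_at = np.interp(edges, xs, cum)
        binned = np.diff(cum_at) / np.diff(edges)
        if row.strand == "-":
            binned = binned[::-1]
        profiles.append(binned)
    return np.mean(profiles, axis=0)
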