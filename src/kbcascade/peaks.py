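"""Reproducibility filtering, genomic annotation and gene assignment of
ChIP peaks.

The replicate filter keeps peaks scored at or above a threshold (default
100) in both replicates that overlap by at least one base pair; the
emitted interval is the union and the emitted score the smaller of the
two.  Peaks are annotated by midpoint with the fixed priority
promoter > 5'UTR > 3'UTR > exon > intron > TTS > intergenic, and assigned
to the gene with the nearest TSS within 50 kb (peaks inside a gene body
or promoter always go to that gene).  Distances are signed in stranded
orientation: negative means upstream of the TSS.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .genome import GeneModels, PROMOTER_ANNOTATION

ANNOTATION_PRIORITY = ("promoter", "5'UTR", "3'UTR", "exon", "intron", "TTS",
                       "intergenic")


def _check_same_condition(rep_a: pd.DataFrame, rep_b: pd.DataFrame) -> None:
    for col in ("factor", "time"):
        if col in rep_a.columns and col in rep_b.columns:
            va = set(rep_a[col].dropna().unique())
            vb = set(rep_b[col].dropna().unique())
            if va and vb and va != vb:
                raise ValueError(f"replicates disagree on {col}: {va} vs {vb}")


def filter_reproducible(rep_a: pd.DataFrame, rep_b: pd.DataFrame,
                        min_score: float = 100.0) -> pd.DataFrame:
    """Peaks scored >= ``min_score`` in A that overlap such a peak in B.

    Overlap means >= 1 bp.  The emitted interval is the union of the A peak
    with every qualifying overlapping B peak; the emitted score is
    ``min(score_A, max overlapping score_B)``, so the retained *set* is the
    same whichever replicate comes first.
    """
    _check_same_condition(rep_a, rep_b)
    a = rep_a[rep_a["score"] >= min_score]
    b = rep_b[rep_b["score"] >= min_score]
    if a.empty or b.empty:
        return a.iloc[0:0][["chrom", "start", "end", "score"]].copy()
    out = []
    for chrom, ac in a.groupby("chrom", sort=False):
        bc = b[b["chrom"] == chrom]
        if bc.empty:
            continue
        a_start = ac["start"].values[:, None]
        a_end = ac["end"].values[:, None]
        b_start = bc["start"].values[None, :]
        b_end = bc["end"].values[None, :]
        ov = (a_start < b_end) & (b_start < a_end)
        for i in np.flatnonzero(ov.any(axis=1)):
            hits = np.flatnonzero(ov[i])
            row = ac.iloc[i]
            out.append({
                "chrom": chrom,
                "start": int(min(row["start"], bc["start"].values[hits].min())),
                "end": int(max(row["end"], bc["end"].values[hits].max())),
                "score": float(min(row["score"], bc["score"].values[hits].max())),
                "name": row.get("name", ""),
            })
    if not out:
        return pd.DataFrame(columns=["chrom", "start", "end", "score", "name"])
    return pd.DataFrame(out)


def _in_any(mid: np.ndarray, chrom: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Membership of each midpoint in any interval of ``intervals``."""
    hit = np.zeros(len(mid), dtype=bool)
    for c, grp in intervals.groupby("chrom", sort=False):
        sel = np.flatnonzero(chrom == c)
        if sel.size == 0:
            continue
        m = mid[sel][:, None]
        hit[sel] = ((m >= grp["start"].values[None, :]) &
                    (m < grp["end"].values[None, :])).any(axis=1)
    return hit


def _utr_intervals(gm: GeneModels) -> tuple[pd.DataFrame, pd.DataFrame]:
    g = gm.genes
    tss, tts = gm.tss.values, gm.tts.values
    plus = g["strand"].values == "+"
    u5 = g["utr5_len"].values
    u3 = g["utr3_len"].values
    utr5 = pd.DataFrame({
        "chrom": g["chrom"].values,
        "start": np.where(plus, tss, tss - u5 + 1),
        "end": np.where(plus, tss + u5, tss + 1)})
    utr3 = pd.DataFrame({
        "chrom": g["chrom"].values,
        "start": np.where(plus, tts - u3 + 1, tts),
        "end": np.where(plus, tts + 1, tts + u3)})
    return utr5, utr3


def annotate_peaks(peaks: pd.DataFrame, gene_models: GeneModels) -> pd.Series:
    """Midpoint annotation category for each peak (fixed priority order)."""
    mid = ((peaks["start"].values + peaks["end"].values) // 2).astype(np.int64)
    chrom = peaks["chrom"].values.astype(object)
    g = gene_models.genes
    tts = gene_models.tts.values
    utr5, utr3 = _utr_intervals(gene_models)
    exons = gene_models.exons.merge(g[["gene_id", "chrom"]], on="gene_id")
    body = g[["chrom", "start", "end"]]
    tts_win = pd.DataFrame({"chrom": g["chrom"].values,
                            "start": tts - 100, "end": tts + 101})
    prom = gene_models.promoter_windows(*PROMOTER_ANNOTATION)
    category = np.full(len(peaks), "intergenic", dtype=object)
    unassigned = np.ones(len(peaks), dtype=bool)
    for name, table in [("promoter", prom), ("5'UTR", utr5), ("3'UTR", utr3),
                        ("exon", exons), ("intron", body), ("TTS", tts_win)]:
        hit = _in_any(mid, chrom, table) & unassigned
        category[hit] = name
        unassigned &= ~hit
    return pd.Series(category, index=peaks.index, name="category")


def assign_to_genes(peaks: pd.DataFrame, gene_models: GeneModels,
                    max_distance: int = 50_000) -> pd.DataFrame:
    """Peak-to-gene map: nearest TSS within ``max_distance``.

    A peak whose midpoint falls inside a gene body or its promoter window is
    assigned to that gene regardless of distance; ties (equidistant TSSs,
    or midpoint inside two overlapping windows) go to the lexicographically
    smaller gene_id.  Unassigned peaks carry an empty gene_id and NaN
    distance.  The returned frame adds ``gene_id``, ``distance`` (signed bp,
    negative upstream in stranded orientation) and ``category`` columns.
    """
    g = gene_models.genes
    tss = gene_models.tss
    prom = gene_models.promoter_windows(*PROMOTER_ANNOTATION).set_index("gene_id")
    mid = ((peaks["start"].values + peaks["end"].values) // 2).astype(np.int64)
    result_gene = np.full(len(peaks), "", dtype=object)
    result_dist = np.full(len(peaks), np.nan)
    for c, grp in g.groupby("chrom", sort=False):
        sel = np.flatnonzero(peaks["chrom"].values == c)
        if sel.size == 0:
            continue
        gids = grp["gene_id"].values
        g_tss = tss[gids].values
        sign = np.where(grp["strand"].values == "+", 1, -1)
        p_start = prom.loc[gids, "start"].values
        p_end = prom.loc[gids, "end"].values
        span_lo = np.minimum(grp["start"].values, p_start)
        span_hi = np.maximum(grp["end"].values, p_end)
        for i in sel:
            m = mid[i]
            dist = (m - g_tss) * sign
            inside = (m >= span_lo) & (m < span_hi)
            if inside.any():
                cand = np.flatnonzero(inside)
            else:
                cand = np.flatnonzero(np.abs(dist) <= max_distance)
                if cand.size == 0:
                    continue
            order = sorted(cand, key=lambda j: (abs(int(dist[j])), gids[j]))
            j = order[0]
            result_gene[i] = gids[j]
            result_dist[i] = dist[j]
    out = peaks.copy()
    out["gene_id"] = result_gene
    out["distance"] = result_dist
    out["category"] = annotate_peaks(peaks, gene_models)
    return out


def category_summary(peaks_by_time: Mapping[object, pd.DataFrame]) -> pd.DataFrame:
    """Counts per annotation category per time; rows sum to total peaks."""
    rows = {}
    for t, df in peaks_by_time.items():
        counts = df["category"].value_counts() if len(df) else pd.Series(dtype=int)
        rows[t] = counts
    out = pd.DataFrame(rows).T.reindex(columns=ANNOTATION_PRIORITY).fillna(0).astype(int)
    out.index.name = "time"
    out["total"] = out.sum(axis=1)
    return out
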