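"""Target-gene taxonomy: combining perturbation contrasts with binding.

A gene is a *direct activated* target (``Ad``) when its inducible
expression is significantly reduced by the dominant-negative IkBa in both
clones at a shared time point and it carries an inducible RELA peak;
without a peak it is *indirect* (``Ai``).  Genes whose expression the
perturbation increases are direct/indirect repressed targets
(``Rd``/``Ri``).  RELA-bound genes with no significant response anywhere
are *nonfunctional bound*; unbound unresponsive genes are *unaffected*;
everything else (single-clone or conflicting responses) is ``other``.
The classes are mutually exclusive and exhaustive over the classified
genes, so |Ad|+|Ai| always equals the size of the dn-reduced set and
|Rd|+|Ri| the dn-increased set.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, fold_change, test_differential

CLONE_CONTRASTS = [("clone1", 1), ("clone1", 4), ("clone2", 1), ("clone2", 4)]
PANEL_CONTRASTS = ["parental_1v0", "parental_4v0",
                   "clone1_tet_1", "clone1_tet_4", "clone2_tet_1", "clone2_tet_4"]


def build_contrast_panel(em: ExpressionMatrix, min_rpm: float = 1.0) -> pd.DataFrame:
    """Per-gene log2FC and FDR for the six classification contrasts.

    Parental activation (1 h and 4 h vs 0 h, no inducer) and, per clone and
    time point, +Tet vs -Tet.  Genes below the expression floor (mean RPM
    < ``min_rpm`` in every condition) are excluded before testing.
    Columns are a MultiIndex ``(contrast, field)``.
    """
    rpm = em.rpm()
    cond_means = em.condition_means(rpm)
    keep = cond_means.max(axis=1) >= min_rpm
    counts = em.counts.loc[keep]
    blocks = {}
    p0 = em.select(cell_line="parental", tet="minus", time=0)
    for t in (1, 4):
        pt = em.select(cell_line="parental", tet="minus", time=t)
        de = test_differential(counts, pt, p0)
        de["log2fc_rpm"] = fold_change(rpm.loc[keep], pt, p0)
        blocks[f"parental_{t}v0"] = de
    for clone, t in CLONE_CONTRASTS:
        plus = em.select(cell_line=clone, tet="plus", time=t)
        minus = em.select(cell_line=clone, tet="minus", time=t)
        blocks[f"{clone}_tet_{t}"] = test_differential(counts, plus, minus)
    panel = pd.concat(blocks, axis=1)
    panel.columns.names = ["contrast", "field"]
    return panel


def putative_targets(parental_de: pd.DataFrame, peak_gene_map: pd.DataFrame,
                     fc_threshold: float = 2.0) -> tuple[set, set]:
    """Inducibly bound, inducibly changed genes (the working target list).

    ``bound_up`` = genes >= ``fc_threshold``-fold up at 1 or 4 h in the
    parental line that carry an assigned inducible RELA peak; ``bound_down``
    analogously for downregulation.  ``parental_de`` needs ``log2fc``
    columns for the two activation contrasts (MultiIndex panel accepted).
    """
    rela_genes = assigned_genes(peak_gene_map)
    lfc = np.log2(fc_threshold)
    fc1 = parental_de[("parental_1v0", "log2fc")]
    fc4 = parental_de[("parental_4v0", "log2fc")]
    up = set(parental_de.index[(fc1 >= lfc) | (fc4 >= lfc)])
    down = set(parental_de.index[(fc1 <= -lfc) | (fc4 <= -lfc)])
    return up & rela_genes, down & rela_genes


def assigned_genes(peak_gene_map: pd.DataFrame) -> set:
    """Genes with at least one assigned peak in a peak-to-gene map."""
    if "gene_id" not in peak_gene_map.columns:
        raise ValueError("peak_gene_map needs a gene_id column")
    return set(peak_gene_map.loc[peak_gene_map["gene_id"] != "", "gene_id"])


def classify_targets(panel: pd.DataFrame, rela_genes: Iterable,
                     fdr: float = 0.05) -> pd.DataFrame:
    """Label every gene in the panel with its taxonomy class.

    dn-reduced requires FDR <= ``fdr`` with a negative +Tet/-Tet log2FC in
    *both* clones at at least one shared time point; dn-increased is the
    mirror image.  A gene qualifying in both directions (at different
    times) is ``other``.  Genes with every contrast non-significant are
    ``unaffected`` (``nonfunctional_bound`` if RELA-bound).
    """
    for contrast in PANEL_CONTRASTS:
        if contrast not in panel.columns.get_level_values("contrast"):
            raise ValueError(f"panel is missing contrast {contrast}")
    for contrast in PANEL_CONTRASTS:
        block = panel[contrast]
        missing = block.index[block["fdr"].isna()]
        if len(missing):
            raise ValueError(
                f"gene(s) {list(missing[:3])} missing from contrast {contrast}")
    rela_genes = set(rela_genes)
    records = []
    for gene in panel.index:
        red_times, inc_times = [], []
        for t in (1, 4):
            sig, direction = [], []
            for clone in ("clone1", "clone2"):
                row = panel.loc[gene, f"{clone}_tet_{t}"]
                sig.append(row["fdr"] <= fdr)
                direction.append(np.sign(row["log2fc"]))
            if all(sig) and direction[0] == direction[1] != 0:
                (red_times if direction[0] < 0 else inc_times).append(t)
        any_sig = any(panel.loc[gene, (c, "fdr")] <= fdr for c in PANEL_CONTRASTS)
        bound = gene in rela_genes
        if red_times and not inc_times:
            cls = "Ad" if bound else "Ai"
        elif inc_times and not red_times:
            cls = "Rd" if bound else "Ri"
        elif red_times and inc_times:
            cls = "other"
        elif not any_sig:
            cls = "nonfunctional_bound" if bound else "unaffected"
        else:
            cls = "other"
        records.append({"gene_id": gene, "class": cls, "bound": bound,
                        "reduced_times": ",".join(map(str, red_times)),
                        "increased_times": ",".join(map(str, inc_times))})
    return pd.DataFrame(records).set_index("gene_id")


def robust_flag(records: pd.DataFrame, panel: pd.DataFrame,
                threshold: float = 2.0) -> pd.DataFrame:
    """Flag target genes changed >= ``threshold``-fold in the -Tet parental line.

    Robust means |log2FC| >= log2(threshold) at 1 or 4 h (boundary
    inclusive); only functional target classes (Ad/Ai/Rd/Ri) carry the flag.
    """
    lfc = np.log2(threshold)
    fc1 = panel[("parental_1v0", "log2fc")].reindex(records.index)
    fc4 = panel[("parental_4v0", "log2fc")].reindex(records.index)
    big = (fc1.abs() >= lfc) | (fc4.abs() >= lfc)
    out = records.copy()
    out["robust"] = big.fillna(False) & out["class"].isin(["Ad", "Ai", "Rd", "Ri"])
    return out


def pattern_labels(records: pd.DataFrame,
                   class_patterns: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Attach pattern labels like ``"3Ad"`` from per-class clusterings.

    ``class_patterns`` maps a class name to the cluster assignment of its
    genes; every gene of a clustered class must appear there.
    """
    out = records.copy()
    out["pattern_label"] = ""
    for cls, clusters in class_patterns.items():
        members = out.index[out["class"] == cls]
        missing = members.difference(clusters.index)
        if len(missing):
            raise ValueError(f"unclustered {cls} gene(s): {list(missing[:3])}")
        out.loc[members, "pattern_label"] = (
            clusters.loc[members].astype(int).astype(str) + cls)
    return out


def combined_pattern_groups(records: pd.DataFrame, panel: pd.DataFrame,
                            fdr: float = 0.05) -> pd.Series:
    """Four combined response groups over the activation-responsive genes.

    I = reduced by the dominant negative; II = increased by it;
    III = activation-induced but dn-insensitive; IV = activation-repressed
    and dn-insensitive.  Responsive means a significant parental activation
    contrast; groups partition the responsive genes.
    """
    group = {}
    for gene, rec in records.iterrows():
        if rec["class"] in ("Ad", "Ai"):
            group[gene] = "I"
        elif rec["class"] in ("Rd", "Ri"):
            group[gene] = "II"
        else:
            best = None
            for c in ("parental_1v0", "parental_4v0"):
                row = panel.loc[gene, c]
                if row["fdr"] <= fdr:
                    if best is None or abs(row["log2fc"]) > abs(best):
                        best = row["log2fc"]
            if best is not None:
                group[gene] = "III" if best > 0 else "IV"
    return pd.Series(group, name="group")
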