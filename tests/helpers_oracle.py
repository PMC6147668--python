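"""Independent brute-force oracles used to cross-check the pipeline.

These are written as plain set algebra over the contrast panel, on
purpose structured differently from the package implementation: per-
contrast gene sets are materialized first and combined with set
operations.
"""

import numpy as np


def panel_sets(panel, fdr=0.05):
    """Significant gene sets per clone/time/direction from a contrast panel."""
    sets = {}
    for clone in ("clone1", "clone2"):
        for t in (1, 4):
            block = panel[f"{clone}_tet_{t}"]
            sig = block["fdr"] <= fdr
            sets[(clone, t, "down")] = set(block.index[sig & (block["log2fc"] < 0)])
            sets[(clone, t, "up")] = set(block.index[sig & (block["log2fc"] > 0)])
    return sets


def classify_oracle(panel, rela_genes, fdr=0.05):
    """Brute-force taxonomy labels as a {gene: class} dict."""
    rela = set(rela_genes)
    s = panel_sets(panel, fdr)
    reduced = ((s[("clone1", 1, "down")] & s[("clone2", 1, "down")]) |
               (s[("clone1", 4, "down")] & s[("clone2", 4, "down")]))
    increased = ((s[("clone1", 1, "up")] & s[("clone2", 1, "up")]) |
                 (s[("clone1", 4, "up")] & s[("clone2", 4, "up")]))
    sig_anywhere = set()
    for contrast in ("parental_1v0", "parental_4v0", "clone1_tet_1",
                     "clone1_tet_4", "clone2_tet_1", "clone2_tet_4"):
        block = panel[contrast]
        sig_anywhere |= set(block.index[block["fdr"] <= fdr])
    everything = set(panel.index)
    ambiguous = reduced & increased
    labels = {}
    for g in (reduced - ambiguous):
        labels[g] = "Ad" if g in rela else "Ai"
    for g in (increased - ambiguous):
        labels[g] = "Rd" if g in rela else "Ri"
    for g in ambiguous:
        labels[g] = "other"
    for g in everything - reduced - increased:
        if g in sig_anywhere:
            labels[g] = "other"
        else:
            labels[g] = "nonfunctional_bound" if g in rela else "unaffected"
    return labels


def putative_oracle(panel, rela_genes, fc_threshold=2.0):
    """Brute-force (bound_up, bound_down) putative target sets."""
    lfc = np.log2(fc_threshold)
    up = {g for g in panel.index
          if (panel.loc[g, ("parental_1v0", "log2fc")] >= lfc
              or panel.loc[g, ("parental_4v0", "log2fc")] >= lfc)}
    down = {g for g in panel.index
            if (panel.loc[g, ("parental_1v0", "log2fc")] <= -lfc
                or panel.loc[g, ("parental_4v0", "log2fc")] <= -lfc)}
    return up & set(rela_genes), down & set(rela_genes)


def robust_oracle(panel, labels, threshold=2.0):
    """Brute-force robust flags for functional target classes."""
    lfc = np.log2(threshold)
    flags = {}
    for g, cls in labels.items():
        big = (abs(panel.loc[g, ("parental_1v0", "log2fc")]) >= lfc
               or abs(panel.loc[g, ("parental_4v0", "log2fc")]) >= lfc)
        flags[g] = bool(big) and cls in ("Ad", "Ai", "Rd", "Ri")
    return flags
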