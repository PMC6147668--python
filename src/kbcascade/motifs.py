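"""PWM scanning, promoter motif prevalence and kB-site conservation.

Motif hits are reported at a *relative* log-odds score
``(score - min) / (max - min)`` thresholded at 0.80 by default.  The
log-odds matrix uses a total pseudocount of 0.8 divided evenly over the
four bases (common JASPAR practice) against a uniform background unless
one is supplied.

Cross-species conservation follows a window rule: a human site is
conserved against a species when the 51-bp window centred on it keeps at
least 40% identity through a global pairwise alignment *and* the
orthologous window still contains a motif hit at the relative-score
threshold (each criterion can be toggled).  The percent of conserved
sites per gene is the ratio of conserved to total sites, averaged over
species by default.

The global aligner is a built-in Needleman-Wunsch with linear gap
penalties (match +1, mismatch -1, gap -2) and deterministic traceback
preferring diagonal over up over left moves.

Four synthetic kB-family count matrices (GGGRNYYYCC-like) ship with the
package for self-contained runs; any JASPAR-format file is accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1}
_BASES = "ACGT"


@dataclass
class PWM:
    """Position count matrix with derived log-odds scoring."""

    motif_id: str
    counts: np.ndarray                     # 4 x width, rows A/C/G/T
    background: np.ndarray = None          # length 4
    pseudocount: float = 0.8               # total per column, split evenly

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must have 4 rows (A, C, G, T)")
        if self.background is None:
            self.background = np.full(4, 0.25)
        self.background = np.asarray(self.background, dtype=float)
        col_tot = self.counts.sum(axis=0) + self.pseudocount
        probs = (self.counts + self.pseudocount / 4.0) / col_tot
        self.pssm = np.log2(probs / self.background[:, None])
        if not np.isfinite(self.pssm).all():
            raise ValueError("log-odds matrix not finite")
        self.max_score = float(self.pssm.max(axis=0).sum())
        self.min_score = float(self.pssm.min(axis=0).sum())

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.pssm.argmax(axis=0))

    def relative(self, score: float) -> float:
        return (score - self.min_score) / (self.max_score - self.min_score)


def load_jaspar(path_or_handle) -> dict[str, PWM]:
    """Parse a JASPAR-format PWM file into ``{motif_id: PWM}``."""
    if hasattr(path_or_handle, "read"):
        parsed = bio_motifs.parse(path_or_handle, "jaspar")
    else:
        with open(path_or_handle) as fh:
            parsed = list(bio_motifs.parse(fh, "jaspar"))
    out = {}
    for m in parsed:
        counts = np.array([m.counts[b] for b in _BASES], dtype=float)
        mid = m.matrix_id or m.name
        out[mid] = PWM(motif_id=mid, counts=counts)
    return out


def load_kb_pwms() -> dict[str, PWM]:
    """The packaged synthetic kB-family matrices (stand-ins, not JASPAR data)."""
    ref = resources.files("kbcascade").joinpath("data/kb_motifs_synthetic.jaspar")
    with ref.open() as fh:
        return load_jaspar(fh)


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
    return np.array([_CODE[c] for c in seq], dtype=np.int64)


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def scan(sequence: str, pwm: PWM, rel_threshold: float = 0.80) -> pd.DataFrame:
    """Both-strand PWM scan; windows containing N are skipped.

    Offsets are forward-strand coordinates of the window start; a minus-
    strand hit means the reverse complement of the window matches the
    motif.  Returns ``offset, strand, score, rel_score, motif_id`` sorted
    by offset.
    """
    cols = ["offset", "strand", "score", "rel_score", "motif_id"]
    w = pwm.width
    if len(sequence) < w:
        warnings.warn(f"sequence shorter than motif width {w}; no scan")
        return pd.DataFrame(columns=cols)
    codes = _encode(sequence)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = (windows >= 0).all(axis=1)
    j = np.arange(w)
    safe = np.where(windows < 0, 0, windows)
    fwd = pwm.pssm[safe, j[None, :]].sum(axis=1)
    rc = pwm.pssm[3 - safe[:, ::-1], j[None, :]].sum(axis=1)
    rows = []
    for strand, scores in (("+", fwd), ("-", rc)):
        rel = (scores - pwm.min_score) / (pwm.max_score - pwm.min_score)
        hit = valid & (rel >= rel_threshold)
        for off in np.flatnonzero(hit):
            rows.append({"offset": int(off), "strand": strand,
                         "score": float(scores[off]),
                         "rel_score": float(rel[off]), "motif_id": pwm.motif_id})
    return pd.DataFrame(rows, columns=cols).sort_values(
        ["offset", "strand"]).reset_index(drop=True)


def scan_all(sequence: str, pwms: Mapping[str, PWM],
             rel_threshold: float = 0.80) -> pd.DataFrame:
    frames = [f for f in (scan(sequence, p, rel_threshold) for p in pwms.values())
              if len(f)]
    if not frames:
        return pd.DataFrame(
            columns=["offset", "strand", "score", "rel_score", "motif_id"])
    return pd.concat(frames, ignore_index=True).sort_values(
        ["offset", "strand"]).reset_index(drop=True)


def motif_prevalence(promoters: Mapping[str, str], pwms: Mapping[str, PWM],
                     rel_threshold: float = 0.80,
                     prevalence_threshold: float = 0.20) -> pd.DataFrame:
    """Fraction of promoters containing each motif at least once.

    A motif counts once per promoter regardless of site multiplicity;
    ``selected`` marks motifs present in *more than* the threshold fraction
    (strict inequality).  Raises on an empty promoter set.
    """
    if not promoters:
        raise ValueError("empty promoter set")
    rows = []
    for mid, pwm in pwms.items():
        n_with = sum(1 for seq in promoters.values()
                     if len(scan(seq, pwm, rel_threshold)) > 0)
        frac = n_with / len(promoters)
        rows.append({"motif_id": mid, "n_promoters_with_site": n_with,
                     "fraction": frac, "selected": frac > prevalence_threshold})
    return pd.DataFrame(rows).set_index("motif_id")


# ---------------------------------------------------------------------------
# pairwise global alignment
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    aligned_a: str
    aligned_b: str
    score: float

    @property
    def identity(self) -> float:
        """Matched columns over total alignment columns."""
        matches = sum(a == b and a != "-" for a, b in
                      zip(self.aligned_a, self.aligned_b))
        return matches / len(self.aligned_a)

    def a_column_of(self) -> np.ndarray:
        """Alignment column index of each position of sequence A."""
        return np.flatnonzero(np.frombuffer(self.aligned_a.encode(), dtype=np.uint8)
                              != ord("-"))


def align_pair(seq_a: str, seq_b: str, match: float = 1.0,
               mismatch: float = -1.0, gap: float = -2.0) -> Alignment:
    """Needleman-Wunsch global alignment with linear gap penalty.

    Traceback ties break deterministically diagonal > up > left (up
    consumes a base of ``seq_a``).
    """
    a, b = seq_a.upper(), seq_b.upper()
    for s in (a, b):
        if not s:
            raise ValueError("sequences must be nonempty")
        if set(s) - set("ACGTN"):
            raise ValueError(f"non-ACGTN characters: {sorted(set(s) - set('ACGTN'))}")
    ai = np.array([_CODE[c] for c in a])
    bi = np.array([_CODE[c] for c in b])
    n, m = len(ai), len(bi)
    F = np.empty((n + 1, m + 1))
    jj = np.arange(m + 1, dtype=float)
    F[0] = gap * jj
    for i in range(1, n + 1):
        sub = np.where(bi == ai[i - 1], match, mismatch)
        v = np.empty(m + 1)
        v[0] = gap * i
        v[1:] = np.maximum(F[i - 1, :-1] + sub, F[i - 1, 1:] + gap)
        # resolve left-moves in closed form: F[i,j] = max_{k<=j} v[k] + gap*(j-k)
        F[i] = gap * jj + np.maximum.accumulate(v - gap * jj)
    # traceback
    out_a, out_b = [], []
    i, j = n, m
    eps = 1e-9
    while i > 0 or j > 0:
        if i > 0 and j > 0 and abs(
                F[i, j] - (F[i - 1, j - 1] + (match if ai[i - 1] == bi[j - 1] else mismatch))) < eps:
            out_a.append(a[i - 1]); out_b.append(b[j - 1]); i -= 1; j -= 1
        elif i > 0 and abs(F[i, j] - (F[i - 1, j] + gap)) < eps:
            out_a.append(a[i - 1]); out_b.append("-"); i -= 1
        else:
            out_a.append("-"); out_b.append(b[j - 1]); j -= 1
    return Alignment("".join(reversed(out_a)), "".join(reversed(out_b)),
                     float(F[n, m]))


def window_conservation(alignment: Alignment, site_center: int,
                        window: int = 51) -> float:
    """Identity of the window centred on a human site, through the alignment.

    The window spans ``window`` human positions centred on ``site_center``,
    truncated symmetrically at the sequence ends; the denominator is the
    truncated window length.  A position counts as conserved only when the
    aligned ortholog base is identical (a gap is a mismatch).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    cols = alignment.a_column_of()
    n = len(cols)
    if not 0 <= site_center < n:
        raise ValueError("site offset outside the human sequence")
    half = window // 2
    lo, hi = max(0, site_center - half), min(n - 1, site_center + half)
    matched = sum(
        1 for p in range(lo, hi + 1)
        if alignment.aligned_a[cols[p]] == alignment.aligned_b[cols[p]] != "-")
    return matched / (hi - lo + 1)


def _ortholog_window_seq(alignment: Alignment, site_center: int,
                         window: int) -> str:
    cols = alignment.a_column_of()
    n = len(cols)
    half = window // 2
    lo, hi = max(0, site_center - half), min(n - 1, site_center + half)
    segment = alignment.aligned_b[cols[lo]:cols[hi] + 1]
    return segment.replace("-", "")


@dataclass
class ConservationResult:
    gene_id: str
    n_total_sites: int
    per_species: dict              # species -> (n_conserved, percent)
    percent_conserved: float       # combined; NaN when no sites


def conserved_site_fraction(gene_id: str, sites: pd.DataFrame,
                            alignments: Mapping[str, Alignment],
                            pwms: Mapping[str, PWM],
                            cons_cutoff: float = 0.40,
                            rel_threshold: float = 0.80,
                            window: int = 51,
                            require_identity: bool = True,
                            require_ortholog_hit: bool = True,
                            combine: str = "mean") -> ConservationResult:
    """Percent of a gene's kB sites conserved across species.

    ``sites`` comes from :func:`scan` over the upstream-kilobase promoter
    window; a site is conserved against a species when its 51-bp window
    identity meets ``cons_cutoff`` and the orthologous window retains a
    motif hit (either requirement can be toggled off).  With zero sites the
    result is flagged missing (NaN percent).
    """
    if len(sites) == 0:
        return ConservationResult(gene_id, 0, {}, float("nan"))
    per_species = {}
    for species, aln in alignments.items():
        n_cons = 0
        for site in sites.itertuples(index=False):
            pwm = pwms[site.motif_id]
            centre = int(site.offset) + pwm.width // 2
            ok = True
            if require_identity:
                ok &= window_conservation(aln, centre, window) >= cons_cutoff
            if ok and require_ortholog_hit:
                sub = _ortholog_window_seq(aln, centre, window)
                ok &= len(sub) >= pwm.width and len(scan(sub, pwm, rel_threshold)) > 0
            n_cons += bool(ok)
        per_species[species] = (n_cons, 100.0 * n_cons / len(sites))
    percents = [p for _, p in per_species.values()]
    combined = float(np.mean(percents)) if combine == "mean" else float(np.min(percents))
    return ConservationResult(gene_id, len(sites), per_species, combined)
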