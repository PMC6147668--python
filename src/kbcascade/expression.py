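"""Count normalization, differential calls, kinetic pattern discovery and
qPCR relative expression.

Kinetic patterns come from k-means with correlation distance
``d(x, y) = 1 - Pearson(x, y)``, the metric used throughout for
trajectory clustering and silhouettes.  Internally each trajectory is
standardized to zero mean and unit Euclidean norm, after which the
distance is ``1 -`` the dot product; centroids are the re-standardized
means of their members.  Clustering is the best of ``repeats`` seeded
restarts by total within-cluster distance, and labels are renumbered by
descending cluster size for determinism.

The differential test is a deliberately simple, deterministic substitute
for an empirical-Bayes count model: a moderated t-test on
log2(normalized count + 1) with a pooled-median variance floor,
Benjamini-Hochberg corrected per contrast.  Normalization for testing is
median-of-ratios (composition-robust); reads-per-million (RPM) is used
for fold changes, trajectories and display, matching how depth
normalization is conventionally reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_samples
from statsmodels.stats.multitest import multipletests

_SAMPLE_RE = re.compile(r"^(?P<cell_line>\w+?)\.(?P<tet>minus|plus)\.t(?P<time>\d+)\.r(?P<replicate>\d+)$")


class ExpressionMatrix:
    """Genes x samples counts plus the sample sheet.

    Sample names encode the design as ``<cell_line>.<tet>.t<time>.r<rep>``;
    if no sample sheet is given it is parsed from the column names.
    """

    def __init__(self, counts: pd.DataFrame, samples: pd.DataFrame | None = None):
        if (counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts
        if samples is None:
            rows = []
            for name in counts.columns:
                m = _SAMPLE_RE.match(name)
                if not m:
                    raise ValueError(f"cannot parse sample name {name!r}")
                d = m.groupdict()
                rows.append({"sample": name, "cell_line": d["cell_line"],
                             "tet": d["tet"], "time": int(d["time"]),
                             "replicate": int(d["replicate"])})
            samples = pd.DataFrame(rows).set_index("sample")
        self.samples = samples.loc[counts.columns]

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        from .io import read_counts
        return cls(read_counts(path))

    def rpm(self, per: float = 1e6) -> pd.DataFrame:
        return normalize_rpm(self.counts, per=per)

    def select(self, **criteria) -> list[str]:
        """Sample names matching the given metadata values."""
        mask = pd.Series(True, index=self.samples.index)
        for key, value in criteria.items():
            mask &= self.samples[key] == value
        return list(self.samples.index[mask])

    def condition_means(self, rpm: pd.DataFrame | None = None) -> pd.DataFrame:
        """Mean RPM per (cell_line, tet, time), columns as a MultiIndex."""
        rpm = self.rpm() if rpm is None else rpm
        keys = self.samples[["cell_line", "tet", "time"]].apply(tuple, axis=1)
        grouped = rpm.T.groupby(keys.values).mean().T
        grouped.columns = pd.MultiIndex.from_tuples(grouped.columns,
                                                    names=["cell_line", "tet", "time"])
        return grouped


def normalize_rpm(counts: pd.DataFrame, per: float = 1e6) -> pd.DataFrame:
    """Scale each sample so its total equals ``per`` (reads per million)."""
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample(s): {list(zero.index)}")
    return counts * (per / totals)


def median_ratio_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference)."""
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        totals = counts.sum(axis=0)
        return totals / totals.mean()
    log_ref = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_ref, axis=0)
    return np.exp(ratios.median(axis=0))


def fold_change(normalized: pd.DataFrame, treated: Sequence[str],
                control: Sequence[str], pseudocount: float = 1.0) -> pd.Series:
    """log2((mean treated + pc) / (mean control + pc)) per gene."""
    mt = normalized[list(treated)].mean(axis=1)
    mc = normalized[list(control)].mean(axis=1)
    return np.log2((mt + pseudocount) / (mc + pseudocount)).rename("log2fc")


def test_differential(counts: pd.DataFrame, treated: Sequence[str],
                      control: Sequence[str],
                      prior_df: float = 10.0) -> pd.DataFrame:
    """Per-gene two-sided differential test between two sample groups.

    Moderated t on log2(size-factor-normalized count + 1): the per-gene
    pooled variance is shrunk towards the across-gene median with
    ``prior_df`` pseudo-observations (empirical-Bayes style), and the
    statistic is referred to a t distribution with residual + prior
    degrees of freedom.  Information sharing across genes is what makes
    two-to-three-replicate designs testable at all; without it the
    residual df would leave no power.  Returns ``log2fc``, ``p`` and
    BH-adjusted ``fdr``; deterministic given its input.
    """
    treated, control = list(treated), list(control)
    if len(treated) < 2 or len(control) < 2:
        raise ValueError("need >= 2 replicates per arm")
    sub = counts[treated + control]
    sf = median_ratio_factors(sub)
    y = np.log2(sub / sf + 1.0)
    yt, yc = y[treated].values, y[control].values
    n1, n2 = yt.shape[1], yc.shape[1]
    diff = yt.mean(axis=1) - yc.mean(axis=1)
    ss = yt.var(axis=1, ddof=1) * (n1 - 1) + yc.var(axis=1, ddof=1) * (n2 - 1)
    df = n1 + n2 - 2
    pooled = ss / df
    s0_sq = max(float(np.median(pooled)), 1e-12)
    var_post = (prior_df * s0_sq + df * pooled) / (prior_df + df)
    se = np.sqrt(var_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / np.where(se > 0, se, 1.0),
                     np.where(diff == 0, 0.0, np.inf) * np.sign(diff))
    p = 2.0 * stats.t.sf(np.abs(t), df + prior_df)
    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"log2fc": diff, "t": t, "p": p, "fdr": fdr},
                        index=counts.index)


# ---------------------------------------------------------------------------
# correlation-metric k-means
# ---------------------------------------------------------------------------

@dataclass
class PatternAssignment:
    labels: pd.Series            # gene -> cluster in 1..k
    centroids: np.ndarray        # k x n_timepoints, standardized
    inertia: float               # total within-cluster correlation distance
    k: int
    repeats: int


def _standardize(x: np.ndarray) -> np.ndarray:
    centred = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("zero-variance trajectory: correlation distance undefined")
    return centred / norms


def _lloyd(z: np.ndarray, centroids: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    labels = np.full(len(z), -1)
    for _ in range(max_iter):
        sim = z @ centroids.T            # cosine of standardized rows
        new_labels = sim.argmax(axis=1)
        for c in range(len(centroids)):   # re-seed empty clusters
            if not (new_labels == c).any():
                d = 1.0 - sim[np.arange(len(z)), new_labels]
                new_labels[d.argmax()] = c
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(len(centroids)):
            members = z[labels == c]
            if len(members) == 0:
                continue
            m = members.mean(axis=0)
            m = m - m.mean()
            norm = np.linalg.norm(m)
            if norm > 0:
                centroids[c] = m / norm
    inertia = float((1.0 - (z * centroids[labels]).sum(axis=1)).sum())
    return labels, centroids, inertia


def _plusplus_init(z: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under correlation distance (D^2 weighting)."""
    centroids = np.empty((k, z.shape[1]))
    centroids[0] = z[rng.integers(len(z))]
    d = 1.0 - z @ centroids[0]
    for c in range(1, k):
        w = np.maximum(d, 0.0) ** 2
        total = w.sum()
        probs = w / total if total > 0 else np.full(len(z), 1.0 / len(z))
        centroids[c] = z[rng.choice(len(z), p=probs)]
        d = np.minimum(d, 1.0 - z @ centroids[c])
    return centroids


def _renumber(labels: np.ndarray, centroids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sizes = np.bincount(labels, minlength=len(centroids))
    order = sorted(range(len(centroids)), key=lambda c: (-sizes[c], c))
    remap = {old: new for new, old in enumerate(order)}
    return np.array([remap[l] for l in labels]), centroids[order]


def kmeans_patterns(trajectories: pd.DataFrame, k: int = 6, repeats: int = 5,
                    seed: int = 0, max_iter: int = 100,
                    extra_inits: Sequence[np.ndarray] = ()) -> PatternAssignment:
    """Correlation-distance k-means over per-gene trajectories.

    ``trajectories`` is genes x time points; zero-variance rows must be
    excluded beforehand (they raise).  Restart ``r`` seeds its own
    generator from ``seed + r``; ties on within-cluster distance go to the
    earlier restart.  ``extra_inits`` supplies additional warm-start
    centroid sets (used by the elbow analysis).
    """
    if len(trajectories) < k:
        raise ValueError(f"need >= k={k} trajectories, got {len(trajectories)}")
    if trajectories.shape[1] < 2:
        raise ValueError("trajectories need >= 2 time points")
    z = _standardize(trajectories.values.astype(float))
    best = None
    inits = []
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        inits.append(_plusplus_init(z, k, rng))
    inits.extend(np.asarray(ci, dtype=float).copy() for ci in extra_inits)
    for init in inits:
        labels, centroids, inertia = _lloyd(z, init.copy(), max_iter)
        if best is None or inertia < best[2] - 1e-12:
            best = (labels, centroids, inertia)
    labels, centroids, inertia = best
    labels, centroids = _renumber(labels, centroids)
    return PatternAssignment(
        labels=pd.Series(labels + 1, index=trajectories.index, name="cluster"),
        centroids=centroids, inertia=inertia, k=k, repeats=repeats)


def correlation_distance_matrix(trajectories: pd.DataFrame) -> np.ndarray:
    z = _standardize(trajectories.values.astype(float))
    d = 1.0 - z @ z.T
    np.fill_diagonal(d, 0.0)
    return np.clip(d, 0.0, 2.0)


@dataclass
class SilhouetteResult:
    s: pd.Series                 # per-gene silhouette in [-1, 1]
    observed_mean: float
    null_means: np.ndarray       # permutation-null means


def silhouette_with_null(trajectories: pd.DataFrame, labels: pd.Series,
                         n_perm: int = 100, seed: int = 0) -> SilhouetteResult:
    """Correlation-distance silhouette plus a permuted-membership null.

    The null permutes cluster memberships uniformly (preserving cluster
    sizes) ``n_perm`` times and records the mean silhouette of each draw.
    """
    labels = labels.loc[trajectories.index]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("need >= 2 clusters for a silhouette")
    if (counts == 1).all():
        raise ValueError("all clusters are singletons; silhouette undefined")
    d = correlation_distance_matrix(trajectories)
    s = silhouette_samples(d, labels.values, metric="precomputed")
    rng = np.random.default_rng(seed)
    null_means = np.empty(n_perm)
    lab = labels.values
    for i in range(n_perm):
        perm = rng.permutation(lab)
        null_means[i] = silhouette_samples(d, perm, metric="precomputed").mean()
    return SilhouetteResult(
        s=pd.Series(s, index=trajectories.index, name="silhouette"),
        observed_mean=float(s.mean()), null_means=null_means)


def elbow_curve(trajectories: pd.DataFrame, k_range: Sequence[int],
                repeats: int = 5, seed: int = 0) -> pd.DataFrame:
    """Total within-cluster distance over ``k_range`` (best of restarts).

    In addition to the random restarts, each k warm-starts from the best
    solution at the previous k with its farthest point split into a new
    centroid, which makes the curve non-increasing by construction.
    """
    ks = sorted(k_range)
    z = _standardize(trajectories.values.astype(float))
    rows = []
    prev = None
    for k in ks:
        extra = []
        if prev is not None and prev.k == k - 1:
            cent = prev.centroids
            d = 1.0 - (z * cent[prev.labels.values - 1]).sum(axis=1)
            extra = [np.vstack([cent, z[d.argmax()]])]
        pa = kmeans_patterns(trajectories, k=k, repeats=repeats, seed=seed,
                             extra_inits=extra)
        rows.append({"k": k, "within": pa.inertia})
        prev = pa
    return pd.DataFrame(rows)


def qpcr_relative_expression(ct_target, ct_reference):
    """Relative expression RE = 2^-(CT_target - CT_reference)."""
    ct_target = np.asarray(ct_target, dtype=float)
    ct_reference = np.asarray(ct_reference, dtype=float)
    if not (np.isfinite(ct_target).all() and np.isfinite(ct_reference).all()):
        raise ValueError("CT values must be finite")
    re = 2.0 ** -(ct_target - ct_reference)
    return float(re) if re.ndim == 0 else re
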