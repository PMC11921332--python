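"""Community-ecology statistics from first principles.

Rarefaction, alpha diversity (observed richness, Shannon, Simpson) with
Kruskal-Wallis and Dunn post-hoc tests, Bray-Curtis dissimilarity, principal
coordinates analysis (PCoA), a permutational multivariate ANOVA
(adonis-style PERMANOVA), and a beta-dispersion homogeneity test
(PERMDISP).  Everything operates on :class:`~fmtrack.tables.FeatureTable`
and :class:`DistanceMatrix` and is deterministic under an explicit seed.

Conventions: Shannon entropy uses the natural log (the base is an option);
ties are handled with average ranks throughout; permutation p-values use the
(exceedances + 1) / (permutations + 1) estimator so p is never zero.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
import math
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable, TableError, relative_abundance

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "rarefy",
    "alpha_diversity",
    "kruskal_wallis",
    "dunn_posthoc",
    "bray_curtis",
    "pcoa",
    "permanova",
    "permdisp",
    "read_distance_matrix",
    "write_distance_matrix",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        v = np.asarray(self.values, dtype=float).copy()
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValueError(f"distance matrix shape {v.shape} does not match {n} samples")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric within 1e-12")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, sample_ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(tuple(sample_ids), self.values[np.ix_(idx, idx)])


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(d.values, index=list(d.sample_ids), columns=list(d.sample_ids))
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column sample ids differ")
    return DistanceMatrix(tuple(df.index), df.to_numpy(dtype=float))


@dataclasses.dataclass(frozen=True)
class OrdinationResult:
    """PCoA embedding: coordinates, eigenvalues, and variance explained."""

    sample_ids: tuple[str, ...]
    coordinates: np.ndarray  # samples x retained axes
    eigenvalues: np.ndarray  # descending, positive
    proportion_explained: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


@dataclasses.dataclass(frozen=True)
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p: float
    n_permutations: int
    seed: int | None

    def __post_init__(self) -> None:
        if self.n_permutations > 0 and not (self.p >= 1.0 / (self.n_permutations + 1) - 1e-12):
            raise ValueError("permutation p-value below its attainable floor")


# ---------------------------------------------------------------------------
# rarefaction and alpha diversity
# ---------------------------------------------------------------------------


def rarefy(table: FeatureTable, depth: int, seed: int) -> FeatureTable:
    """Subsample each sample without replacement to a common depth.

    Each retained column is a multivariate-hypergeometric draw summing
    exactly to ``depth``; samples shallower than ``depth`` are dropped with
    a warning.  Deterministic under ``seed``.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be positive, got {depth}")
    rng = np.random.default_rng(seed)
    sums = table.sample_sums()
    keep = sums >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} sample(s) below rarefaction depth {depth}: "
            f"{dropped[:5]}",
            stacklevel=2,
        )
    out_ids = tuple(s for s, k in zip(table.sample_ids, keep) if k)
    cols = []
    for j, k in enumerate(keep):
        if not k:
            continue
        col = table.counts[:, j]
        if col.sum() == depth:
            cols.append(col.copy())
        else:
            cols.append(rng.multivariate_hypergeometric(col, depth))
    counts = np.column_stack(cols) if cols else np.zeros((table.n_features, 0), dtype=np.int64)
    return FeatureTable(table.feature_ids, out_ids, counts)


def alpha_diversity(table: FeatureTable) -> pd.DataFrame:
    """Observed richness, Shannon entropy (nats) and Simpson (1 - sum p^2).

    Returns a DataFrame indexed by sample with columns ``observed``,
    ``shannon``, ``simpson``.  All three are computed on proportions, so
    they are invariant to rescaling counts by a positive constant.
    """
    props = relative_abundance(table)
    observed = (table.counts > 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(props > 0, props * np.log(props), 0.0)
    shannon = -plogp.sum(axis=0)
    simpson = 1.0 - (props**2).sum(axis=0)
    return pd.DataFrame(
        {"observed": observed.astype(int), "shannon": shannon, "simpson": simpson},
        index=list(table.sample_ids),
    )


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------


def _rank_setup(values: Sequence[float], groups: Sequence[str]):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    labels = list(dict.fromkeys(groups))  # preserve first-seen order
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    ranks = stats.rankdata(values)  # average ranks for ties
    return values, groups, labels, ranks


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square (k-1 df).

    When every observation is identical the statistic is defined as H = 0
    with p = 1 (no evidence of any group difference).
    """
    values, groups, labels, ranks = _rank_setup(values, groups)
    n = len(values)
    h_raw = 0.0
    for g in labels:
        mask = groups == g
        n_g = int(mask.sum())
        if n_g == 0:
            raise ValueError(f"group {g!r} is empty")
        h_raw += ranks[mask].sum() ** 2 / n_g
    h_raw = 12.0 / (n * (n + 1)) * h_raw - 3.0 * (n + 1)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    denom = 1.0 - tie_term / (n**3 - n)
    if denom <= 0:  # all values identical
        return 0.0, 1.0
    h = h_raw / denom
    p = float(stats.chi2.sf(h, len(labels) - 1))
    return float(h), p


def dunn_posthoc(
    values: Sequence[float], groups: Sequence[str], adjust: str = "none"
) -> pd.DataFrame:
    """Dunn's pairwise z tests on the joint ranks after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p;
    ``adjust='bh'`` adds Benjamini-Hochberg q-values over the pair family.
    """
    if adjust not in ("none", "bh"):
        raise ValueError(f"adjust must be 'none' or 'bh', got {adjust!r}")
    values, groups, labels, ranks = _rank_setup(values, groups)
    n = len(values)
    mean_rank = {}
    size = {}
    for g in labels:
        mask = groups == g
        size[g] = int(mask.sum())
        if size[g] == 0:
            raise ValueError(f"group {g!r} is empty")
        mean_rank[g] = ranks[mask].mean()
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum()) / (12.0 * (n - 1))
    var_core = n * (n + 1) / 12.0 - tie_term
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        se = math.sqrt(var_core * (1.0 / size[g1] + 1.0 / size[g2]))
        z = 0.0 if se == 0 else (mean_rank[g1] - mean_rank[g2]) / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append({"group_a": g1, "group_b": g2, "z": z, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------


def bray_curtis(table: FeatureTable, use: str = "counts") -> DistanceMatrix:
    """Bray-Curtis dissimilarity: d(x, y) = 1 - 2 sum min(x, y) / sum(x + y).

    Computed on raw counts by default, or on per-sample proportions with
    ``use='proportions'``.  Values lie in [0, 1]: 0 for identical columns,
    1 for disjoint supports.
    """
    if use == "counts":
        x = table.counts.astype(float)
    elif use == "proportions":
        x = relative_abundance(table)
    else:
        raise ValueError(f"use must be 'counts' or 'proportions', got {use!r}")
    sums = x.sum(axis=0)
    if np.any(sums == 0):
        bad = table.sample_ids[int(np.nonzero(sums == 0)[0][0])]
        raise TableError(f"sample {bad!r} has zero total count")
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(x[:, i][:, None], x[:, i + 1 :]).sum(axis=0)
        d[i, i + 1 :] = 1.0 - 2.0 * shared / (sums[i] + sums[i + 1 :])
    d = d + d.T
    return DistanceMatrix(table.sample_ids, np.clip(d, 0.0, 1.0))


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis (classical metric MDS).

    Eigendecomposition of the double-centered squared-distance matrix
    B = -1/2 J D^2 J.  Axes with positive eigenvalues are retained and
    scaled by the square root of their eigenvalue; for Euclidean input the
    embedding reproduces the distances exactly (Gower).  Negative
    eigenvalues are dropped and their total magnitude logged; no
    Cailliez/Lingoes correction is applied.
    """
    n = d.n_samples
    a = -0.5 * d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = j @ a @ j
    b = (b + b.T) / 2.0
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), abs(eigval[-1]), 1.0) * 1e-12 if n else 0.0
    pos = eigval > tol
    neg_mass = float(-eigval[eigval < -tol].sum())
    if neg_mass > 0:
        logger.info("pcoa: dropped negative eigenvalue mass %.6g", neg_mass)
    lam = eigval[pos]
    coords = eigvec[:, pos] * np.sqrt(lam)[np.newaxis, :]
    total = lam.sum()
    prop = lam / total if total > 0 else np.zeros_like(lam)
    return OrdinationResult(d.sample_ids, coords, lam, prop)


def _group_codes(sample_ids: Sequence[str], groups: Sequence[str]):
    groups = list(groups)
    if len(groups) != len(sample_ids):
        raise ValueError("one group label per sample required")
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    codes = np.asarray([labels.index(g) for g in groups])
    sizes = np.bincount(codes, minlength=len(labels))
    if sizes.min() < 2:
        small = labels[int(np.argmin(sizes))]
        raise ValueError(f"group {small!r} has fewer than 2 samples")
    return labels, codes, sizes


def _permanova_f(d2: np.ndarray, codes: np.ndarray, sizes: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R^2) for one labelling; d2 is the squared distance matrix."""
    n = d2.shape[0]
    a = len(sizes)
    ss_total = d2.sum() / (2.0 * n)
    ss_within = 0.0
    for g in range(a):
        idx = np.nonzero(codes == g)[0]
        ss_within += d2[np.ix_(idx, idx)].sum() / (2.0 * sizes[g])
    ss_between = ss_total - ss_within
    f = (ss_between / (a - 1)) / (ss_within / (n - a))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return float(f), float(r2)


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaResult:
    """Permutational multivariate ANOVA (adonis-style) on a distance matrix.

    Partitions the sum of squared distances into between- and within-group
    components; pseudo-F = (SS_b / (a-1)) / (SS_w / (n-a)) and
    R^2 = SS_b / SS_total.  Significance by permuting group labels:
    p = (#{F_perm >= F_obs} + 1) / (n_permutations + 1).  Labels are
    permuted freely (no strata); with ``exhaustive=True`` all distinct
    label arrangements are enumerated instead (exact p, identity included).
    """
    labels, codes, sizes = _group_codes(d.sample_ids, groups)
    d2 = d.values**2
    f_obs, r2 = _permanova_f(d2, codes, sizes)
    n = d.n_samples
    if exhaustive:
        seen = set()
        n_ge = 0
        total = 0
        for perm in itertools.permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            f_perm, _ = _permanova_f(d2, np.asarray(perm), sizes)
            if f_perm >= f_obs - 1e-12:
                n_ge += 1
        return PermanovaResult(f_obs, r2, n_ge / total, total - 1, seed)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        f_perm, _ = _permanova_f(d2, perm, sizes)
        if f_perm >= f_obs - 1e-12:
            n_ge += 1
    p = (n_ge + 1) / (n_permutations + 1)
    return PermanovaResult(f_obs, r2, p, n_permutations, seed)


def permdisp(
    d: DistanceMatrix,
    groups: Sequence[str],
    n_permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Beta-dispersion homogeneity test (PERMDISP).

    Samples are embedded by PCoA (positive-eigenvalue axes); each sample's
    distance to its group centroid in that space is the dispersion score.
    A one-way ANOVA F on the scores measures heterogeneity; significance
    comes from permuting the scores across groups and recomputing F.
    """
    labels, codes, sizes = _group_codes(d.sample_ids, groups)
    coords = pcoa(d).coordinates
    z = np.empty(d.n_samples)
    for g in range(len(labels)):
        idx = np.nonzero(codes == g)[0]
        centroid = coords[idx].mean(axis=0)
        z[idx] = np.sqrt(((coords[idx] - centroid) ** 2).sum(axis=1))

    def anova_f(vals: np.ndarray, c: np.ndarray) -> float:
        grand = vals.mean()
        ss_b = sum(sizes[g] * (vals[c == g].mean() - grand) ** 2 for g in range(len(labels)))
        ss_w = sum(((vals[c == g] - vals[c == g].mean()) ** 2).sum() for g in range(len(labels)))
        if ss_w == 0:
            return math.inf if ss_b > 0 else 0.0
        return float((ss_b / (len(labels) - 1)) / (ss_w / (len(vals) - len(labels))))

    f_obs = anova_f(z, codes)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        f_perm = anova_f(z, rng.permutation(codes))
        if f_perm >= f_obs - 1e-12:
            n_ge += 1
    p = (n_ge + 1) / (n_permutations + 1)
    return f_obs, p
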