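"""Metabolite preprocessing and microbiome-metabolome integration.

The metabolite panel is prepared MetaboAnalyst-style: missing values (below
the limit of detection) are imputed as LOD/2, concentrations are
log-transformed, and variables are optionally autoscaled.  Group structure
is explored with a NIPALS PLS-DA whose variables are ranked by VIP
(variable importance in projection) scores; taxon-metabolite association
uses Spearman correlation with Benjamini-Hochberg FDR control; concordance
between the microbiome and metabolome ordinations is quantified by
symmetric Procrustes with a PROTEST permutation test.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import MetaboliteTable

__all__ = [
    "PlsdaResult",
    "ProcrustesResult",
    "CorrelationResult",
    "preprocess_metabolites",
    "plsda_fit",
    "vip_scores",
    "top_variables",
    "spearman_matrix",
    "procrustes_protest",
]


def preprocess_metabolites(
    table: MetaboliteTable, transform: str = "ln", scale: str = "autoscale"
) -> pd.DataFrame:
    """LOD/2 imputation, log transform, optional autoscaling.

    Missing concentrations are replaced by half the metabolite's limit of
    detection, then log-transformed (natural log by default, ``log10``
    optional).  ``scale='autoscale'`` mean-centers each metabolite and
    scales it to unit (sample) variance.  Returns samples x metabolites.
    """
    if transform not in ("ln", "log10"):
        raise ValueError(f"transform must be 'ln' or 'log10', got {transform!r}")
    if scale not in ("autoscale", "none"):
        raise ValueError(f"scale must be 'autoscale' or 'none', got {scale!r}")
    conc = table.concentrations.copy()
    missing = np.isnan(conc)
    if missing.any():
        bad_lod = np.isnan(table.lod) & missing.any(axis=1)
        if bad_lod.any():
            name = table.metabolite_ids[int(np.nonzero(bad_lod)[0][0])]
            raise ValueError(f"metabolite {name!r} has missing values but no LOD")
        conc[missing] = (table.lod[:, None] / 2.0 * np.ones_like(conc))[missing]
    if np.any(conc <= 0):
        name = table.metabolite_ids[int(np.argwhere(conc <= 0)[0][0])]
        raise ValueError(f"non-positive concentration for metabolite {name!r}; cannot log")
    x = np.log(conc) if transform == "ln" else np.log10(conc)
    x = x.T  # samples x metabolites
    if scale == "autoscale":
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            name = table.metabolite_ids[int(np.nonzero(sd == 0)[0][0])]
            raise ValueError(f"metabolite {name!r} is constant; cannot autoscale")
        x = (x - mean) / sd
    return pd.DataFrame(x, index=list(table.sample_ids), columns=list(table.metabolite_ids))


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class PlsdaResult:
    """Fitted PLS-DA model (NIPALS, one-hot response).

    ``x_weights`` are the unit-norm NIPALS weights per component (used by
    VIP), ``x_loadings`` the deflation loadings, ``y_explained_ss`` the
    response sum of squares captured by each component.
    """

    n_components: int
    group_labels: tuple[str, ...]
    scores: np.ndarray  # n x a
    x_weights: np.ndarray  # p x a, columns unit norm
    x_loadings: np.ndarray  # p x a
    y_loadings: np.ndarray  # g x a
    y_explained_ss: np.ndarray  # per component


def plsda_fit(
    x: np.ndarray | pd.DataFrame,
    groups: Sequence[str],
    n_components: int = 2,
    max_iter: int = 500,
    tol: float = 1e-12,
) -> PlsdaResult:
    """PLS-DA: NIPALS PLS2 regression of a one-hot group response on x.

    Components are extracted iteratively with X-deflation, so score vectors
    are mutually orthogonal.  ``x`` should already be preprocessed
    (autoscaled); a zero-variance column is an error.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    groups = list(groups)
    if len(groups) != n:
        raise ValueError("one group label per row of x required")
    labels = list(dict.fromkeys(groups))
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if n_components < 1 or n_components > min(n - 1, p):
        raise ValueError(
            f"n_components must be in [1, min(n-1, p)] = [1, {min(n - 1, p)}], got {n_components}"
        )
    if np.any(x.std(axis=0) == 0):
        j = int(np.nonzero(x.std(axis=0) == 0)[0][0])
        raise ValueError(f"variable column {j} has zero variance")
    y = np.zeros((n, len(labels)))
    for i, g in enumerate(groups):
        y[i, labels.index(g)] = 1.0
    y = y - y.mean(axis=0)
    xr = x - x.mean(axis=0)
    scores = np.empty((n, n_components))
    weights = np.empty((p, n_components))
    x_loadings = np.empty((p, n_components))
    y_loadings = np.empty((len(labels), n_components))
    y_ss = np.empty(n_components)
    for a in range(n_components):
        u = y[:, int(np.argmax((y**2).sum(axis=0)))].copy()
        w = np.zeros(p)
        for _ in range(max_iter):
            w_new = xr.T @ u
            norm = np.linalg.norm(w_new)
            if norm == 0:
                raise ValueError("degenerate component: zero weight vector")
            w_new /= norm
            t = xr @ w_new
            q = y.T @ t / (t @ t)
            u = y @ q / (q @ q)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new
        t = xr @ w
        p_load = xr.T @ t / (t @ t)
        q = y.T @ t / (t @ t)
        y_ss[a] = (t @ t) * (q @ q)  # response SS captured by this component
        xr = xr - np.outer(t, p_load)
        y = y - np.outer(t, q)
        scores[:, a] = t
        weights[:, a] = w
        x_loadings[:, a] = p_load
        y_loadings[:, a] = q
    return PlsdaResult(
        n_components=n_components,
        group_labels=tuple(labels),
        scores=scores,
        x_weights=weights,
        x_loadings=x_loadings,
        y_loadings=y_loadings,
        y_explained_ss=y_ss,
    )


def vip_scores(result: PlsdaResult) -> np.ndarray:
    """Variable importance in projection.

    VIP_j = sqrt(p * sum_a(SSY_a w_aj^2) / sum_a SSY_a) with unit-norm
    weight vectors, so the mean squared VIP over variables is exactly 1.
    """
    ssy = result.y_explained_ss
    total = ssy.sum()
    if total <= 0:
        raise ValueError("zero explained response sum of squares; VIP undefined")
    w2 = result.x_weights**2  # columns unit norm
    p = w2.shape[0]
    return np.sqrt(p * (w2 @ ssy) / total)


def top_variables(
    result: PlsdaResult, variable_ids: Sequence[str], k: int = 15
) -> pd.DataFrame:
    """The k variables with the highest VIP, sorted descending."""
    vip = vip_scores(result)
    if len(variable_ids) != len(vip):
        raise ValueError("variable_ids length does not match the fitted model")
    order = np.argsort(vip)[::-1][:k]
    return pd.DataFrame(
        {"variable": [variable_ids[i] for i in order], "vip": vip[order]}
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Spearman correlation matrix with FDR
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class CorrelationResult:
    """All-pairs Spearman correlations with BH-adjusted q-values.

    ``rho``, ``p`` and ``q`` are taxa x metabolites DataFrames; pairs with a
    constant variable are NaN and excluded from the FDR family.  ``mask``
    flags pairs significant at ``q < alpha``.
    """

    rho: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    mask: pd.DataFrame
    alpha: float


def spearman_matrix(
    taxa: pd.DataFrame | np.ndarray,
    metabolites: pd.DataFrame | np.ndarray,
    alpha: float = 0.01,
) -> CorrelationResult:
    """Spearman rho for every taxon x metabolite pair, BH-adjusted.

    Rho is the Pearson correlation of average-ranked columns; two-sided
    p-values use the t approximation with n-2 degrees of freedom.  The FDR
    family is all pairs tested in this call.
    """
    taxa_df = pd.DataFrame(taxa)
    met_df = pd.DataFrame(metabolites)
    if taxa_df.shape[0] != met_df.shape[0]:
        raise ValueError("taxa and metabolites must have matched sample rows")
    n = taxa_df.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for correlation")
    rt = np.apply_along_axis(stats.rankdata, 0, taxa_df.to_numpy(dtype=float))
    rm = np.apply_along_axis(stats.rankdata, 0, met_df.to_numpy(dtype=float))
    rt_sd = rt.std(axis=0)
    rm_sd = rm.std(axis=0)
    rt_c = rt - rt.mean(axis=0)
    rm_c = rm - rm.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rt_c.T @ rm_c) / n / np.outer(rt_sd, rm_sd)
    rho[np.isinf(rho)] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    t[np.isnan(rho)] = np.nan
    p = np.where(np.isclose(np.abs(rho), 1.0), 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    p[np.isnan(rho)] = np.nan
    q = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    if valid.any():
        q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    mask = np.zeros_like(p, dtype=bool)
    mask[valid] = q[valid] < alpha
    idx, cols = list(taxa_df.columns), list(met_df.columns)
    return CorrelationResult(
        rho=pd.DataFrame(rho, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        q=pd.DataFrame(q, index=idx, columns=cols),
        mask=pd.DataFrame(mask, index=idx, columns=cols),
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Procrustes / PROTEST
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ProcrustesResult:
    """Symmetric Procrustes fit between two ordinations.

    ``m_squared`` is the residual sum of squares after optimal translation,
    rotation and scaling of one unit-scaled configuration onto the other;
    ``correlation`` = sqrt(1 - m_squared).  ``p`` is the PROTEST row-
    permutation significance.
    """

    m_squared: float
    correlation: float
    p: float
    n_permutations: int
    seed: int | None

    def __post_init__(self) -> None:
        if abs(self.correlation - np.sqrt(max(0.0, 1.0 - self.m_squared))) > 1e-9:
            raise ValueError("correlation must equal sqrt(1 - m_squared)")


def _unit_configuration(coords: np.ndarray, width: int) -> np.ndarray:
    """Center, zero-pad to a common width, scale to unit sum of squares."""
    c = coords - coords.mean(axis=0)
    if c.shape[1] < width:
        c = np.hstack([c, np.zeros((c.shape[0], width - c.shape[1]))])
    ss = (c**2).sum()
    if ss == 0:
        raise ValueError("degenerate configuration: all points coincide")
    return c / np.sqrt(ss)


def _procrustes_m2(x: np.ndarray, y: np.ndarray) -> float:
    sv = np.linalg.svd(x.T @ y, compute_uv=False)
    return float(max(0.0, 1.0 - sv.sum() ** 2))


def procrustes_protest(
    x_coords: np.ndarray,
    y_coords: np.ndarray,
    n_permutations: int = 999,
    seed: int | None = None,
) -> ProcrustesResult:
    """Symmetric Procrustes m^2 with PROTEST permutation significance.

    Both configurations (rows = matched samples, columns = ordination axes)
    are centered and scaled to unit sum of squares; the optimal rotation
    comes from the SVD of the cross-product, giving
    m^2 = 1 - (sum of singular values)^2.  Significance is the fraction of
    row permutations of one configuration achieving an m^2 at least as
    small, with the (x+1)/(N+1) estimator.
    """
    x = np.asarray(x_coords, dtype=float)
    y = np.asarray(y_coords, dtype=float)
    if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("configurations must be 2-D with matched rows")
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples for Procrustes analysis")
    width = max(x.shape[1], y.shape[1])
    xu = _unit_configuration(x, width)
    yu = _unit_configuration(y, width)
    m2 = _procrustes_m2(xu, yu)
    rng = np.random.default_rng(seed)
    n_le = 0
    for _ in range(n_permutations):
        perm = rng.permutation(x.shape[0])
        if _procrustes_m2(xu[perm], yu) <= m2 + 1e-12:
            n_le += 1
    p = (n_le + 1) / (n_permutations + 1)
    return ProcrustesResult(
        m_squared=m2,
        correlation=float(np.sqrt(1.0 - m2)),
        p=p,
        n_permutations=n_permutations,
        seed=seed,
    )
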