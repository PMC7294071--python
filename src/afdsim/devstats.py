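"""Per-tract developmental statistics.

The unit of analysis is one tract x scheme AFD column over subjects.
R² is the multiple coefficient of determination of the ordinary
least-squares model afd ~ age + sex + motion.  Scheme comparisons
bootstrap the R² difference over subjects (both schemes' rows resampled
together) and report 95% bias-corrected accelerated (BCa) intervals:

    z0 = Φ⁻¹(#{θ* < θ̂} / B)
    a  = Σ(θ̄ - θ_i)³ / (6 [Σ(θ̄ - θ_i)²]^{3/2})   (jackknife)

Multiple testing uses a Bonferroni threshold over tracts x schemes.
The R² matrix is summarised by complete-linkage agglomerative
clustering under Euclidean distance (rows and columns, unscaled) and by
per-scheme column medians.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.stats import norm

__all__ = [
    "R2Result", "tract_r2", "r2_table", "r2_matrix",
    "BCaInterval", "r2_difference_bca", "bonferroni_alpha",
    "ClusterResult", "cluster_matrix", "column_median",
    "export_dendrogram_newick",
]

log = logging.getLogger(__name__)

COVARIATES = ("sex", "motion")


@dataclass(frozen=True)
class R2Result:
    tract: str
    scheme: str
    r2: float
    p_age: float
    n: int


def _subject_frame(cohort: pd.DataFrame, tract: str, scheme: str) -> pd.DataFrame:
    sub = cohort[(cohort["tract"] == tract) & (cohort["scheme"] == scheme)]
    if sub.empty:
        raise KeyError(f"no rows for tract {tract!r}, scheme {scheme!r}")
    return sub


def tract_r2(cohort: pd.DataFrame, tract: str, scheme: str,
             covariates: tuple[str, ...] = COVARIATES) -> R2Result:
    """Multiple R² of afd ~ age (+ covariates) for one tract and scheme."""
    sub = _subject_frame(cohort, tract, scheme)
    if len(sub) < 10:
        raise ValueError(f"need >= 10 subjects, got {len(sub)}")
    rhs = " + ".join(("age",) + tuple(covariates))
    design = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(float)
                               for c in ("age",) + tuple(covariates)])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"collinear design for tract {tract!r}: rank "
            f"{np.linalg.matrix_rank(design)} < {design.shape[1]}")
    res = smf.ols(f"afd ~ {rhs}", data=sub).fit()
    return R2Result(tract, scheme, float(res.rsquared),
                    float(res.pvalues["age"]), int(res.nobs))


def _design(sub: pd.DataFrame) -> np.ndarray:
    return np.column_stack([
        np.ones(len(sub)), sub["age"].to_numpy(),
        sub["sex"].to_numpy(dtype=float), sub["motion"].to_numpy(),
    ])


def _r2_ols(x: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.nan
    return 1.0 - np.sum(resid**2) / ss_tot


def r2_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """R² (and age p-value) for every tract x scheme cell of a cohort."""
    rows = []
    for (tract, scheme), sub in cohort.groupby(["tract", "scheme"], sort=False):
        r = tract_r2(cohort=sub.assign(tract=tract, scheme=scheme),
                     tract=tract, scheme=scheme)
        rows.append((tract, scheme, r.r2, r.p_age, r.n))
    return pd.DataFrame(rows, columns=["tract", "scheme", "r2", "p_age", "n"])


def r2_matrix(cohort: pd.DataFrame, fast: bool = True) -> pd.DataFrame:
    """Tract x scheme pivot of the fitted R² values.

    ``fast=True`` solves the normal equations directly (identical to the
    statsmodels route to numerical precision; cross-checked in tests),
    which matters when calibrating over hundreds of synthetic cohorts.
    """
    scheme_order = list(dict.fromkeys(cohort["scheme"]))
    tract_order = list(dict.fromkeys(cohort["tract"]))
    if fast:
        rows = [
            (tract, scheme, _r2_ols(_design(sub), sub["afd"].to_numpy()))
            for (tract, scheme), sub in cohort.groupby(["tract", "scheme"],
                                                       sort=False)
        ]
        tab = pd.DataFrame(rows, columns=["tract", "scheme", "r2"])
    else:
        tab = r2_table(cohort)
    return (tab.pivot(index="tract", columns="scheme", values="r2")
            .reindex(index=tract_order, columns=scheme_order))


# ---------------------------------------------------------------------------
# BCa bootstrap of R² differences


@dataclass(frozen=True)
class BCaInterval:
    estimate: float
    lo: float
    hi: float
    B: int
    seed: int
    n_degenerate: int = 0
    fallback: bool = False


def _batched_r2(x: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """R² of y ~ x for each row of resample indices (B, n)."""
    xb = x[idx]                      # (B, n, p)
    yb = y[idx]                      # (B, n)
    xtx = np.einsum("bnp,bnq->bpq", xb, xb)
    xty = np.einsum("bnp,bn->bp", xb, yb)
    beta = np.linalg.solve(xtx, xty[..., None])[..., 0]
    resid = yb - np.einsum("bnp,bp->bn", xb, beta)
    ss_res = np.sum(resid**2, axis=1)
    ss_tot = np.sum((yb - yb.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return 1.0 - ss_res / ss_tot


def r2_difference_bca(cohort: pd.DataFrame, tract: str, scheme_a: str,
                      scheme_b: str, B: int = 10_000,
                      seed: int = 0) -> BCaInterval:
    """95% BCa interval of R²(scheme_a) − R²(scheme_b) for one tract.

    Subjects are resampled with replacement; each resampled subject
    carries its rows for both schemes, preserving the pairing.
    Degenerate resamples (zero AFD or outcome variance) are dropped with
    a logged count.  If every bootstrap statistic falls on one side of
    the estimate, z0 is infinite and the widest interval (bootstrap min,
    max) is returned with ``fallback=True``.
    """
    sub_a = _subject_frame(cohort, tract, scheme_a).sort_values("subject_id")
    sub_b = _subject_frame(cohort, tract, scheme_b).sort_values("subject_id")
    if not np.array_equal(sub_a["subject_id"].to_numpy(),
                          sub_b["subject_id"].to_numpy()):
        raise ValueError("schemes cover different subject sets")
    n = len(sub_a)
    x = _design(sub_a)
    y_a = sub_a["afd"].to_numpy()
    y_b = sub_b["afd"].to_numpy()

    theta_hat = _r2_ols(x, y_a) - _r2_ols(x, y_b)

    rng = np.random.default_rng(seed)
    idx = rng.integers(n, size=(B, n))
    theta_star = _batched_r2(x, y_a, idx) - _batched_r2(x, y_b, idx)
    bad = ~np.isfinite(theta_star)
    n_degenerate = int(bad.sum())
    if n_degenerate:
        log.info("dropped %d degenerate bootstrap resamples", n_degenerate)
        theta_star = theta_star[~bad]
    if theta_star.size == 0 or np.ptp(theta_star) == 0:
        val = theta_hat if theta_star.size == 0 else float(theta_star[0])
        return BCaInterval(float(theta_hat), val, val, B, seed, n_degenerate)

    prop = np.mean(theta_star < theta_hat)
    if prop in (0.0, 1.0):
        log.warning("all bootstrap statistics on one side of the estimate; "
                    "falling back to the widest interval")
        return BCaInterval(float(theta_hat), float(theta_star.min()),
                           float(theta_star.max()), B, seed, n_degenerate,
                           fallback=True)
    z0 = norm.ppf(prop)

    # jackknife acceleration
    mask = ~np.eye(n, dtype=bool)
    jk_idx = np.stack([np.flatnonzero(mask[i]) for i in range(n)])
    theta_jack = _batched_r2(x, y_a, jk_idx) - _batched_r2(x, y_b, jk_idx)
    d = theta_jack.mean() - theta_jack
    denom = np.sum(d**2) ** 1.5
    a = float(np.sum(d**3) / (6 * denom)) if denom > 0 else 0.0

    lo_hi = []
    for alpha in (0.025, 0.975):
        z = z0 + norm.ppf(alpha)
        adj = norm.cdf(z0 + z / (1 - a * z))
        lo_hi.append(float(np.quantile(theta_star, adj)))
    return BCaInterval(float(theta_hat), min(lo_hi), max(lo_hi), B, seed,
                       n_degenerate)


def bonferroni_alpha(n_tracts: int, n_schemes: int,
                     family_alpha: float = 0.05) -> float:
    """Per-comparison threshold: family_alpha / (tracts x schemes)."""
    if n_tracts < 1 or n_schemes < 1:
        raise ValueError("counts must be >= 1")
    return family_alpha / (n_tracts * n_schemes)


# ---------------------------------------------------------------------------
# hierarchical clustering of the R² matrix


@dataclass(frozen=True)
class ClusterResult:
    matrix: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: tuple[str, ...]
    col_order: tuple[str, ...]

    def cut_rows(self, k: int) -> dict[str, int]:
        labels = fcluster(self.row_linkage, k, criterion="maxclust")
        return dict(zip(self.matrix.index, (int(v) for v in labels)))

    def cut_cols(self, k: int) -> dict[str, int]:
        labels = fcluster(self.col_linkage, k, criterion="maxclust")
        return dict(zip(self.matrix.columns, (int(v) for v in labels)))


def _safe_linkage(data: np.ndarray) -> np.ndarray:
    if data.shape[0] == 1:
        return np.empty((0, 4))
    return linkage(data, method="complete", metric="euclidean")


def cluster_matrix(matrix: pd.DataFrame) -> ClusterResult:
    """Complete-linkage Euclidean clustering of rows and columns (unscaled)."""
    if matrix.isna().any().any():
        raise ValueError("R² matrix contains missing entries")
    vals = matrix.to_numpy(dtype=float)
    row_link = _safe_linkage(vals)
    col_link = _safe_linkage(vals.T)
    row_order = (tuple(matrix.index[leaves_list(row_link)])
                 if row_link.size else tuple(matrix.index))
    col_order = (tuple(matrix.columns[leaves_list(col_link)])
                 if col_link.size else tuple(matrix.columns))
    return ClusterResult(matrix, row_link, col_link, row_order, col_order)


def column_median(matrix: pd.DataFrame, scheme: str) -> float:
    """Median of one scheme's column (even count: mean of central pair)."""
    if scheme not in matrix.columns:
        raise KeyError(f"no column {scheme!r}")
    return float(matrix[scheme].median())


def export_dendrogram_newick(link: np.ndarray, labels: list[str] | tuple[str, ...]) -> str:
    """Serialize a linkage matrix as Newick with branch lengths.

    Each internal node sits at half its merge height, so the path length
    between two leaves equals their cophenetic distance; a two-leaf tree
    at height h reads ``(A:h/2,B:h/2);``.
    """
    n = len(labels)
    if link.shape != (max(n - 1, 0), 4):
        raise ValueError(f"linkage shape {link.shape} inconsistent with "
                         f"{n} labels")
    heights = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return str(labels[i])
        a, b, h, _ = link[i - n]
        half = h / 2.0
        la = half - heights[int(a)]
        lb = half - heights[int(b)]
        heights[i] = half
        return f"({node(int(a))}:{la:.10g},{node(int(b))}:{lb:.10g})"

    if n == 1:
        return f"{labels[0]};"
    for i, row in enumerate(link):
        heights[n + i] = row[2] / 2.0
    heights.update({i: 0.0 for i in range(n)})
    return node(2 * n - 2) + ";"
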