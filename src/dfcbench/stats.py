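"""Benchmark statistics: metric-motion associations and pipeline comparisons.

The core quantity throughout is the QC-FC-style partial correlation between a
connectivity-derived metric (edge dispersion, node flexibility/promiscuity,
modularity Q) and subject motion, controlling for age and sex.  Unitwise
distributions are screened with Benjamini-Hochberg FDR; distance-dependence is
the correlation of the edgewise motion association with inter-node Euclidean
distance; pipelines are compared with paired t tests and Steiger's test for
two dependent correlations sharing the distance variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from scipy.spatial.distance import cdist

from .dispersion import upper_triangle
from .synthetic import NodeAtlas

__all__ = [
    "PartialCorrelation",
    "EdgeAssociationResult",
    "DistanceDependenceResult",
    "partial_correlation",
    "bh_fdr",
    "unitwise_motion_association",
    "distance_matrix",
    "distance_dependence",
    "steiger_equality",
    "paired_t",
    "scalar_motion_association",
    "subnetwork_breakdown",
]


@dataclass
class PartialCorrelation:
    r: float
    p: float
    ok: bool = True  # False when residual variance degenerated


@dataclass
class EdgeAssociationResult:
    """Unitwise (edge or node) metric-motion partial-correlation distribution."""

    r: np.ndarray
    p: np.ndarray
    fdr_mask: np.ndarray
    alpha: float = 0.05
    flagged: np.ndarray = field(default=None)  # constant-metric units

    @property
    def pct_significant_fdr(self) -> float:
        return 100.0 * float(self.fdr_mask.mean())

    @property
    def pct_significant_uncorrected(self) -> float:
        return 100.0 * float((self.p < self.alpha).mean())

    @property
    def median_abs_r(self) -> float:
        return float(np.median(np.abs(self.r)))

    @property
    def sd_r(self) -> float:
        return float(np.std(self.r, ddof=1)) if self.r.size > 1 else 0.0

    def summary(self) -> dict:
        return {
            "pct_significant_fdr": self.pct_significant_fdr,
            "pct_significant_uncorrected": self.pct_significant_uncorrected,
            "median_abs_r": self.median_abs_r,
            "sd_r": self.sd_r,
            "mean_r": float(self.r.mean()),
            "n_units": int(self.r.size),
        }


@dataclass
class DistanceDependenceResult:
    r_dd: float
    p_dd: float
    n_edges: int
    ok: bool = True


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Residual of y (n or n x k) on [1, covariates]."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    design = np.ones((n, 1))
    if covariates is not None and np.size(covariates):
        c = np.asarray(covariates, dtype=float).reshape(n, -1)
        design = np.hstack([design, c])
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _corr_p(r: np.ndarray, df: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    t = np.where(np.abs(r) >= 1.0, np.inf * np.sign(r), t)
    return 2.0 * sst.t.sf(np.abs(t), df)


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> PartialCorrelation:
    """Pearson correlation of the OLS residuals of x and y on [1, covariates].

    Two-sided p from t = r sqrt(df / (1 - r^2)) with df = n - q - 2, the
    convention for a partial correlation controlling q covariates.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    q = 0 if covariates is None else np.asarray(covariates).reshape(n, -1).shape[1]
    if n <= q + 3:
        raise ValueError("need n > q + 3 observations")
    rx = _residualize(x, covariates)
    ry = _residualize(y, covariates)
    sx, sy = rx.std(), ry.std()
    if sx < 1e-14 or sy < 1e-14:
        return PartialCorrelation(r=0.0, p=1.0, ok=False)
    r = float(np.dot(rx, ry) / (n * sx * sy))
    r = float(np.clip(r, -1.0, 1.0))
    p = float(_corr_p(np.array(r), n - q - 2))
    return PartialCorrelation(r=r, p=p)


def bh_fdr(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, int]:
    """Benjamini-Hochberg step-up: reject the k* smallest p-values where
    k* = max{k : p_(k) <= k * alpha / m}."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k_star = int(np.max(np.flatnonzero(below))) + 1
        mask[order[:k_star]] = True
    return mask, int(mask.sum())


def _covariate_matrix(covariates: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Extract (motion, [age, sex]) arrays from a covariate table."""
    required = {"mean_rel_rms", "age", "sex"}
    missing = required - set(covariates.columns)
    if missing:
        raise ValueError(f"covariate table missing columns: {sorted(missing)}")
    if covariates[sorted(required)].isna().any().any():
        raise ValueError("covariate table contains missing values")
    motion = covariates["mean_rel_rms"].to_numpy(dtype=float)
    cov = covariates[["age", "sex"]].to_numpy(dtype=float)
    return motion, cov


def unitwise_motion_association(
    metric: np.ndarray, covariates: pd.DataFrame, alpha: float = 0.05
) -> EdgeAssociationResult:
    """Per-unit partial correlation of a subjects x units metric with motion,
    controlling age and sex, with BH-FDR and uncorrected screening.

    Constant (zero-variance) units are flagged and kept with r = 0, p = 1 so
    that significance percentages are comparable across pipelines.
    """
    metric = np.atleast_2d(np.asarray(metric, dtype=float))
    motion, cov = _covariate_matrix(covariates)
    n, n_units = metric.shape
    if n != motion.size:
        raise ValueError("metric rows must match the covariate table")
    if n < 10:
        raise ValueError("need at least 10 subjects")
    rm = _residualize(motion, cov)
    rmat = _residualize(metric, cov)
    sm = rm.std()
    su = rmat.std(axis=0)
    # scale-aware degeneracy guard: constant units leave only rounding noise
    scale = np.maximum(np.abs(metric).max(axis=0), 1.0)
    flagged = su < 1e-10 * scale
    su_safe = np.where(flagged, 1.0, su)
    r = (rmat.T @ rm) / (n * su_safe * sm)
    r = np.clip(r, -1.0, 1.0)
    p = _corr_p(r, n - cov.shape[1] - 2)
    r[flagged] = 0.0
    p[flagged] = 1.0
    mask, _ = bh_fdr(p, alpha=alpha)
    return EdgeAssociationResult(r=r, p=p, fdr_mask=mask, alpha=alpha, flagged=flagged)


def distance_matrix(atlas: NodeAtlas | np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances (mm) between node centers of mass."""
    coords = atlas.coords_mm if isinstance(atlas, NodeAtlas) else np.asarray(atlas)
    return cdist(coords, coords)


def distance_dependence(
    edge_r: np.ndarray, D: np.ndarray
) -> DistanceDependenceResult:
    """Correlation of the edgewise motion association with inter-node distance.

    ``edge_r`` may be given as the upper-triangle vector or the full matrix;
    the shared row-major upper-triangle (i < j) ordering is used throughout.
    """
    d = upper_triangle(D) if D.ndim == 2 else np.asarray(D, dtype=float)
    r = np.asarray(edge_r, dtype=float)
    if r.ndim == 2:
        r = upper_triangle(r)
    if r.size != d.size:
        raise ValueError("edge vector and distance vector lengths differ")
    if r.std() < 1e-14 or d.std() < 1e-14:
        return DistanceDependenceResult(r_dd=0.0, p_dd=1.0, n_edges=r.size, ok=False)
    rr, pp = sst.pearsonr(d, r)
    return DistanceDependenceResult(r_dd=float(rr), p_dd=float(pp), n_edges=r.size)


def steiger_equality(
    r_j1: float, r_j2: float, r_12: float, n: int
) -> tuple[float, float]:
    """Steiger's Z-bar* test for two dependent correlations sharing a variable.

    r_j1 and r_j2 both involve the common variable (here: distance); r_12 is
    the correlation between the two non-shared vectors.  The two correlations
    are Fisher z-transformed and their difference scaled by the
    common-element covariance computed at the back-transformed mean
    correlation.  Returns (z, two-sided p).
    """
    if n <= 10:
        raise ValueError("need more than 10 observations")
    for v in (r_j1, r_j2, r_12):
        if not -1.0 < v < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    z1, z2 = np.arctanh(r_j1), np.arctanh(r_j2)
    rbar = np.tanh((z1 + z2) / 2.0)
    psi = r_12 * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (
        1.0 - 2.0 * rbar**2 - r_12**2
    )
    sbar = psi / (1.0 - rbar**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3.0) / (2.0 - 2.0 * sbar))
    p = 2.0 * sst.norm.sf(abs(z))
    return float(z), float(p)


def paired_t(v1: np.ndarray, v2: np.ndarray) -> tuple[float, int, float]:
    """Paired-sample t test on the elementwise differences.

    Zero-variance differences yield (inf with the sign of the mean difference,
    df, p=0) for a nonzero mean and (0, df, 1) for identical vectors.
    """
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    if v1.shape != v2.shape or v1.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    d = v1 - v2
    df = d.size - 1
    sd = d.std(ddof=1)
    if sd < 1e-14:
        if abs(d.mean()) < 1e-14:
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * np.inf), df, 0.0
    t, p = sst.ttest_rel(v1, v2)
    return float(t), df, float(p)


def scalar_motion_association(
    values: np.ndarray, covariates: pd.DataFrame
) -> PartialCorrelation:
    """Partial correlation of a per-subject scalar (e.g., mean Q, global F or
    Psi) with motion, controlling age and sex."""
    motion, cov = _covariate_matrix(covariates)
    if np.asarray(values).size < 10:
        raise ValueError("need at least 10 subjects")
    return partial_correlation(np.asarray(values, dtype=float), motion, cov)


def subnetwork_breakdown(
    significant: np.ndarray, atlas: NodeAtlas
) -> pd.Series:
    """Per-subnetwork proportion of nodes flagged significant."""
    sig = np.asarray(significant, dtype=bool)
    if sig.size != atlas.n_nodes:
        raise ValueError("mask length must equal the node count")
    return (
        pd.Series(sig, name="significant")
        .groupby(pd.Series(atlas.subnetwork, name="subnetwork"))
        .mean()
    )
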