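"""Edge dispersion: variance over windows divided by the mean, C = sigma^2 / mu.

Dispersion summarizes how strongly an edge's windowed connectivity fluctuates
across a scan, relative to its typical level.  Edges with no fluctuation are
set to 0; so are edges whose mean is numerically zero while the variance is
not (possible only when negative edges are retained), which are flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .windows import ConnectivityStack

__all__ = ["EdgeDispersionMap", "edge_dispersion", "upper_triangle"]

MEAN_GUARD = 1e-8


@dataclass
class EdgeDispersionMap:
    C: np.ndarray  # (n, n) dispersion values
    mean: np.ndarray  # (n, n) per-edge window mean
    var: np.ndarray  # (n, n) per-edge window variance
    degenerate_mean: np.ndarray = field(default=None)  # bool flags

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.C)):
            raise ValueError("dispersion values must be finite")


def edge_dispersion(stack: ConnectivityStack, ddof: int = 1) -> EdgeDispersionMap:
    """Per-edge dispersion across the T windows of a connectivity stack.

    Sample variance (denominator T-1) by default; ``ddof=0`` switches to the
    population variance.
    """
    z = stack.z_matrices
    if z.shape[0] < 2:
        raise ValueError("need at least 2 windows for dispersion")
    mu = z.mean(axis=0)
    var = z.var(axis=0, ddof=ddof)
    degenerate = (np.abs(mu) < MEAN_GUARD) & (var > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(var == 0, 0.0, var / np.where(np.abs(mu) < MEAN_GUARD, 1.0, mu))
    C[degenerate] = 0.0
    np.fill_diagonal(C, 0.0)
    return EdgeDispersionMap(C=C, mean=mu, var=var, degenerate_mean=degenerate)


def upper_triangle(matrix: np.ndarray) -> np.ndarray:
    """Row-major upper-triangle (i < j) vectorization; the shared edge order."""
    n = matrix.shape[0]
    iu = np.triu_indices(n, k=1)
    return matrix[iu]
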