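"""Sliding-window functional connectivity.

Residual node time series are divided into overlapping fixed-length windows;
within each window, edges are Pearson correlations, negative correlations are
optionally zeroed, and a Fisher z-transform is applied.  The result is a
time-ordered stack of symmetric, zero-diagonal adjacency matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["WindowScheme", "ConnectivityStack", "make_windows", "window_connectivity"]

CLIP = 1.0 - 1e-6  # |r| clip before atanh (perfect correlations diverge)


@dataclass
class WindowScheme:
    """Half-open, 0-based sliding windows; trailing partial windows dropped."""

    window_length: int
    step: int
    starts: np.ndarray

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def slices(self):
        return [slice(s, s + self.window_length) for s in self.starts]


@dataclass
class ConnectivityStack:
    """T symmetric Fisher-z adjacency matrices (zero diagonal)."""

    z_matrices: np.ndarray  # (T, n, n)
    negative_policy: str
    window_scheme: WindowScheme | None = None

    def __post_init__(self) -> None:
        z = np.asarray(self.z_matrices, dtype=float)
        if z.ndim != 3 or z.shape[1] != z.shape[2]:
            raise ValueError("z_matrices must be (T, n, n)")
        if not np.all(np.isfinite(z)):
            raise ValueError("non-finite connectivity values")
        self.z_matrices = z

    @property
    def n_windows(self) -> int:
        return self.z_matrices.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.z_matrices.shape[1]


def make_windows(
    n_frames: int, window_length: int = 20, overlap: float = 0.5
) -> WindowScheme:
    """Sliding windows of fixed length with fractional overlap.

    count = floor((n_frames - window_length) / step) + 1, with
    step = round(window_length * (1 - overlap)).  120 frames at the default
    20-frame windows with 50% overlap give 11 windows.
    """
    if window_length < 2:
        raise ValueError("window_length must be >= 2")
    if n_frames < window_length:
        raise ValueError("series shorter than one window")
    if not (0 <= overlap < 1):
        raise ValueError("overlap must be in [0, 1)")
    step = int(round(window_length * (1.0 - overlap)))
    if step < 1:
        raise ValueError("overlap too large: step would be < 1 frame")
    count = (n_frames - window_length) // step + 1
    starts = np.arange(count) * step
    return WindowScheme(window_length, step, starts)


def window_connectivity(
    signals: np.ndarray,
    scheme: WindowScheme,
    negative_policy: str = "zero",
) -> ConnectivityStack:
    """Windowed Pearson connectivity, Fisher z-transformed.

    Under ``negative_policy="zero"`` negative correlations are set to 0 before
    the transform (atanh(0)=0, so zeroing before or after is equivalent);
    under ``"retain"`` they are kept.  |r| is clipped at 1 - 1e-6 before
    atanh.  Zero-variance nodes within a window yield zero edges (warned).
    """
    if negative_policy not in ("zero", "retain"):
        raise ValueError("negative_policy must be 'zero' or 'retain'")
    x = np.asarray(signals, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("signals must be finite")
    n = x.shape[0]
    out = np.empty((scheme.n_windows, n, n))
    for t, sl in enumerate(scheme.slices()):
        seg = x[:, sl]
        sd = seg.std(axis=1)
        if np.any(sd == 0):
            warnings.warn("zero-variance node(s) in a window: edges set to 0")
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.corrcoef(seg)
        r[~np.isfinite(r)] = 0.0
        if negative_policy == "zero":
            r = np.maximum(r, 0.0)
        z = np.arctanh(np.clip(r, -CLIP, CLIP))
        np.fill_diagonal(z, 0.0)
        out[t] = (z + z.T) / 2.0  # enforce exact symmetry
    return ConnectivityStack(out, negative_policy, scheme)
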