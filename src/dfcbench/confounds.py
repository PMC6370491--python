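"""Node-level confound-regression pipelines.

Implements the regression-based de-noising strategies evaluated by the
benchmark: realignment parameters and their Friston expansion, tissue-mean
signals, local white-matter regression, global-signal regression, CompCor
components (anatomical and temporal variants), despiking, band-pass filtering
of both data and regressors, and ordinary-least-squares residualization.

Pipelines are looked up by name in :data:`PIPELINES`; ``apply_pipeline``
returns the residual node-by-frame matrix used by all downstream stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as spl
from scipy import signal as sps

from .synthetic import SubjectRecord

__all__ = [
    "RegressorSet",
    "PipelineSpec",
    "PIPELINES",
    "temporal_derivative",
    "expand_friston",
    "bandpass",
    "despike",
    "compcor",
    "select_high_variance_pool",
    "local_wm_regressor",
    "assemble_regressors",
    "apply_pipeline",
]


# registry: pipeline name -> (component list, gsr, despike)
PIPELINES: dict[str, dict] = {
    "RAW": {"components": [], "gsr": False, "despike": False},
    "2P": {"components": ["wm_mean", "csf_mean"], "gsr": False, "despike": False},
    "6P": {"components": ["rp6"], "gsr": False, "despike": False},
    "9P": {
        "components": ["rp6", "wm_mean", "csf_mean"],
        "gsr": True,
        "despike": False,
    },
    "24P": {"components": ["friston24"], "gsr": False, "despike": False},
    "36P": {"components": ["expanded36"], "gsr": True, "despike": False},
    "36P_DESPIKE": {"components": ["expanded36"], "gsr": True, "despike": True},
    "ACOMPCOR": {
        "components": ["rp6", "rp6_derivs", "acompcor"],
        "gsr": False,
        "despike": False,
    },
    "TCOMPCOR": {"components": ["tcompcor"], "gsr": False, "despike": False},
    "WMMEAN": {
        "components": ["rp6", "rp6_derivs", "wm_mean"],
        "gsr": False,
        "despike": True,
    },
    "WMLOCAL": {
        "components": ["rp6", "rp6_derivs", "wm_local"],
        "gsr": False,
        "despike": True,
    },
}


@dataclass
class PipelineSpec:
    """A named de-noising pipeline resolved from the registry.

    ``gsr`` may be switched on for any base pipeline (names like "6P+GSR");
    the 9P/36P families imply it.
    """

    name: str
    gsr: bool = False
    despike: bool = False
    components: list = field(default_factory=list)

    @classmethod
    def from_name(cls, name: str) -> "PipelineSpec":
        base, _, suffix = name.partition("+")
        if base not in PIPELINES:
            raise ValueError(f"unknown pipeline {name!r}")
        entry = PIPELINES[base]
        gsr = entry["gsr"] or suffix.upper() == "GSR"
        return cls(
            name=name,
            gsr=gsr,
            despike=entry["despike"],
            components=list(entry["components"]),
        )


@dataclass
class RegressorSet:
    """Assembled nuisance design for one subject and pipeline.

    ``node_specific`` holds an optional per-node extra column (local white
    matter); ``provenance`` records which component produced each column.
    """

    matrix: np.ndarray  # (n_frames, p)
    labels: list
    provenance: list
    node_specific: np.ndarray | None = None  # (n_nodes, n_frames)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]


def temporal_derivative(series: np.ndarray) -> np.ndarray:
    """Backward difference along the last axis; first element zero."""
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 2:
        raise ValueError("need at least 2 frames")
    out = np.zeros_like(series)
    out[..., 1:] = np.diff(series, axis=-1)
    return out


def expand_friston(rp6: np.ndarray) -> np.ndarray:
    """24-parameter expansion: [rp6, d(rp6), rp6^2, d(rp6)^2]."""
    rp6 = np.asarray(rp6, dtype=float)
    if rp6.ndim != 2 or rp6.shape[1] != 6:
        raise ValueError("expected a frames x 6 realignment matrix")
    return _expand_quadratic(rp6)


def _expand_quadratic(x: np.ndarray) -> np.ndarray:
    """Generic [X, dX, X^2, (dX)^2] column expansion."""
    d = temporal_derivative(x.T).T
    return np.hstack([x, d, x**2, d**2])


def bandpass(
    series: np.ndarray,
    tr: float,
    f_lo: float = 0.01,
    f_hi: float = 0.08,
    order: int = 1,
    axis: int = 0,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward application).

    The same filter is applied to data and regressors so confound regression
    acts on frequency-matched series.  Forward-backward filtering doubles the
    effective order and removes the DC component.
    """
    nyq = 0.5 / tr
    if not (0 < f_lo < f_hi < nyq):
        raise ValueError(
            f"passband ({f_lo}, {f_hi}) Hz must lie inside (0, {nyq}) Hz"
        )
    b, a = sps.butter(order, [f_lo / nyq, f_hi / nyq], btype="bandpass")
    return sps.filtfilt(b, a, np.asarray(series, dtype=float), axis=axis)


def despike(
    signals: np.ndarray,
    c_mad: float = 2.5,
    c_cap: float = 4.0,
    kernel: int = 7,
) -> np.ndarray:
    """Attenuate transient spikes per node by a running-median residual cap.

    Residuals from a running-median fit are compared with the node's MAD;
    samples beyond ``c_mad * MAD`` are flagged as spikes and the residual is
    saturated at ``c_cap * MAD`` (a projection, hence idempotent).  Non-outlier
    samples pass through unchanged.
    """
    x = np.atleast_2d(np.asarray(signals, dtype=float))
    if x.shape[1] < 5:
        raise ValueError("need at least 5 frames to despike")
    med = sps.medfilt(x, kernel_size=(1, kernel))
    resid = x - med
    mad = np.median(np.abs(resid), axis=1, keepdims=True)
    mad[mad == 0] = np.inf  # flat series: nothing to shrink
    cap = c_cap * mad
    keep = np.abs(resid) <= cap
    out = np.where(keep, x, med + np.clip(resid, -cap, cap))
    return out.reshape(np.asarray(signals).shape)


def compcor(noise_pool: np.ndarray, n_components: int) -> np.ndarray:
    """Orthonormal principal-component time series of a noise pool.

    Columns are standardized first; components are ordered by explained
    variance and returned as orthonormal frame-by-component series.
    """
    pool = np.asarray(noise_pool, dtype=float)
    if pool.ndim != 2:
        raise ValueError("noise pool must be frames x channels")
    q = pool.shape[1]
    if q < n_components:
        raise ValueError(f"requested {n_components} components from {q} channels")
    pool = pool - pool.mean(axis=0)
    sd = pool.std(axis=0)
    sd[sd == 0] = 1.0
    pool = pool / sd
    u, s, _ = np.linalg.svd(pool, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-10)) if s.size else 0
    if n_components > rank:
        raise ValueError(f"requested {n_components} components but rank is {rank}")
    return u[:, :n_components]


def select_high_variance_pool(
    channels: np.ndarray, fraction: float = 0.02
) -> np.ndarray:
    """Keep the top-fraction channels by temporal standard deviation.

    The retained count is ceil(fraction * q).
    """
    x = np.asarray(channels, dtype=float)
    q = x.shape[1]
    if q < 10:
        raise ValueError("need at least 10 channels")
    k = int(np.ceil(fraction * q))
    order = np.argsort(x.std(axis=0))[::-1]
    keep = np.sort(order[:k])
    return x[:, keep]


def local_wm_regressor(
    node_coord: np.ndarray,
    wm_channels: np.ndarray,
    wm_coords: np.ndarray,
    radius: float = 15.0,
) -> np.ndarray:
    """Mean of the white-matter channels within ``radius`` mm of a node.

    Falls back to the nearest channel (with a warning) when none is in range.
    """
    wm_channels = np.asarray(wm_channels, dtype=float)
    wm_coords = np.asarray(wm_coords, dtype=float)
    if wm_channels.shape[1] != wm_coords.shape[0] or wm_coords.shape[0] < 1:
        raise ValueError("need >= 1 WM channel with matching coordinates")
    d = np.linalg.norm(wm_coords - np.asarray(node_coord, dtype=float), axis=1)
    within = d <= radius
    if not within.any():
        warnings.warn(
            f"no WM channel within {radius} mm; using nearest at {d.min():.1f} mm"
        )
        within = d == d.min()
    return wm_channels[:, within].mean(axis=1)


def _csf_mean(subject: SubjectRecord) -> np.ndarray:
    return subject.nuisance.columns("csf").mean(axis=1)


def _wm_mean(subject: SubjectRecord) -> np.ndarray:
    return subject.nuisance.columns("wm").mean(axis=1)


def assemble_regressors(subject: SubjectRecord, spec: PipelineSpec) -> RegressorSet:
    """Resolve a pipeline spec into a concrete nuisance design for a subject."""
    cols: list[np.ndarray] = []
    labels: list[str] = []
    prov: list[str] = []
    node_specific = None

    def add(block: np.ndarray, names: list[str], component: str) -> None:
        block = np.atleast_2d(block.T).T if block.ndim == 1 else block
        cols.append(block)
        labels.extend(names)
        prov.extend([component] * len(names))

    rp6 = subject.motion.realign_params
    for comp in spec.components:
        if comp == "rp6":
            add(rp6, [f"rp{i}" for i in range(6)], "rp6")
        elif comp == "rp6_derivs":
            add(
                temporal_derivative(rp6.T).T,
                [f"drp{i}" for i in range(6)],
                "rp6_derivs",
            )
        elif comp == "friston24":
            add(
                expand_friston(rp6),
                [f"friston{i}" for i in range(24)],
                "friston24",
            )
        elif comp == "expanded36":
            base = np.column_stack(
                [
                    rp6,
                    _wm_mean(subject),
                    _csf_mean(subject),
                    subject.nuisance.columns("global")[:, 0],
                ]
            )
            add(
                _expand_quadratic(base),
                [f"exp36_{i}" for i in range(36)],
                "expanded36",
            )
        elif comp == "wm_mean":
            add(_wm_mean(subject)[:, None], ["wm_mean"], "wm_mean")
        elif comp == "csf_mean":
            add(_csf_mean(subject)[:, None], ["csf_mean"], "csf_mean")
        elif comp == "acompcor":
            wm_pc = compcor(subject.nuisance.columns("wm"), 5)
            csf_pc = compcor(subject.nuisance.columns("csf"), 5)
            add(wm_pc, [f"wm_pc{i}" for i in range(5)], "acompcor")
            add(csf_pc, [f"csf_pc{i}" for i in range(5)], "acompcor")
        elif comp == "tcompcor":
            pool = select_high_variance_pool(subject.nuisance.columns("pool"))
            add(compcor(pool, 6), [f"hv_pc{i}" for i in range(6)], "tcompcor")
        elif comp == "wm_local":
            wm = subject.nuisance.columns("wm")
            # per-node column: filled in by apply_pipeline using node coords
            node_specific = ("wm_local", wm, subject.nuisance.wm_coords_mm)
        else:  # pragma: no cover - registry is closed
            raise ValueError(f"unknown component {comp!r}")

    if spec.gsr and "expanded36" not in spec.components:
        add(
            subject.nuisance.columns("global"),
            ["global"],
            "gsr",
        )

    matrix = np.column_stack(cols) if cols else np.empty((rp6.shape[0], 0))
    rs = RegressorSet(matrix, labels, prov)
    if node_specific is not None:
        rs.node_specific = node_specific  # resolved per node downstream
    return rs


def _ols_residual(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Residual of each row of y on the design (intercept included by caller)."""
    beta, *_ = np.linalg.lstsq(design, y.T, rcond=None)
    return y - (design @ beta).T


def _check_rank(design: np.ndarray, label: str) -> np.ndarray:
    """Warn about (and drop) collinear columns; never fail."""
    if design.shape[1] == 0:
        return design
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # greedy column selection by QR pivoting
        _, _, piv = spl.qr(design, pivoting=True)
        keep = np.sort(piv[:rank])
        warnings.warn(
            f"{label}: dropped {design.shape[1] - rank} collinear column(s)"
        )
        return design[:, keep]
    return design


def apply_pipeline(
    subject: SubjectRecord,
    spec: PipelineSpec | str,
    tr: float = 3.0,
    signals: np.ndarray | None = None,
    node_coords_mm: np.ndarray | None = None,
) -> np.ndarray:
    """De-noise a subject's signals under a named pipeline.

    Order of operations: despike (when the pipeline demands it) -> band-pass
    the data and every regressor identically -> OLS residualization per node
    with an intercept.  Residuals are exactly orthogonal to the (band-passed)
    design.  Rank-deficient designs drop collinear columns with a warning.
    """
    if isinstance(spec, str):
        spec = PipelineSpec.from_name(spec)
    x = subject.contaminated_signals if signals is None else signals
    x = np.asarray(x, dtype=float)
    if spec.despike:
        x = despike(x)
    x = bandpass(x, tr, axis=1)

    rs = assemble_regressors(subject, spec)
    design = rs.matrix
    if design.shape[1]:
        design = bandpass(design, tr, axis=0)
    n_frames = x.shape[1]
    intercept = np.ones((n_frames, 1))

    if rs.node_specific is None:
        full = _check_rank(np.hstack([intercept, design]), spec.name)
        return _ols_residual(x, full)

    # node-specific design (local white matter)
    if node_coords_mm is None:
        raise ValueError("local-WM pipelines require node_coords_mm")
    coords = np.asarray(node_coords_mm, dtype=float)
    if coords.shape != (x.shape[0], 3):
        raise ValueError("node coordinates do not match the signal matrix")
    _, wm, wm_coords = rs.node_specific
    wm_bp = bandpass(wm, tr, axis=0)
    out = np.empty_like(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # distant-node fallbacks are expected
        local = np.column_stack(
            [local_wm_regressor(c, wm_bp, wm_coords) for c in coords]
        )
    for i in range(x.shape[0]):
        full = np.hstack([intercept, design, local[:, i : i + 1]])
        full = _check_rank(full, spec.name)
        out[i] = _ols_residual(x[i : i + 1], full)[0]
    return out
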