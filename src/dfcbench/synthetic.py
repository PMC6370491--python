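"""Synthetic cohort generator for dynamic-connectivity de-noising benchmarks.

Simulates parcel-level BOLD-like time series for a cohort of subjects:
band-limited signals with planted, window-varying community structure; head
micromovement traces with framewise-displacement spikes; motion-coupled
artifact shared across nodes with spatially decaying weight; and tissue-like
nuisance channels (global mean, CSF-like, white-matter-like with coordinates,
and a high-variance pool).  Motion is correlated with age so that covariate
adjustment in the downstream benchmarks is exercised.

The generator is the testing ground for every downstream stage: with the
artifact gain set to zero the data are null (no metric should correlate with
motion); with the default gain, short-range connectivity is preferentially
inflated in proportion to subject motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "NodeAtlas",
    "MotionProfile",
    "ArtifactModel",
    "NuisanceChannels",
    "SubjectRecord",
    "generate_atlas",
    "generate_motion_profile",
    "simulate_clean_signals",
    "inject_artifact",
    "generate_cohort",
    "covariates_table",
]

# Motion inclusion rule: subjects exceeding either bound would have been
# excluded from the study sample the generator emulates.
MAX_MEAN_REL_RMS = 0.2  # mm
SPIKE_THRESHOLD = 0.25  # mm framewise
MAX_SPIKE_FRAMES = 20

BRAIN_RADIUS_MM = 70.0


@dataclass
class NodeAtlas:
    """Node coordinates, subnetwork labels and the planted community schedule.

    ``community_schedule`` has one row per epoch; within an epoch every node
    holds a fixed ground-truth community, and a stated fraction of nodes is
    reassigned between consecutive epochs so that community structure varies
    across sliding windows.
    """

    coords_mm: np.ndarray  # (n_nodes, 3)
    subnetwork: np.ndarray  # (n_nodes,) small integer labels
    community_schedule: np.ndarray  # (n_epochs, n_nodes)

    def __post_init__(self) -> None:
        self.coords_mm = np.asarray(self.coords_mm, dtype=float)
        self.subnetwork = np.asarray(self.subnetwork, dtype=int)
        self.community_schedule = np.atleast_2d(
            np.asarray(self.community_schedule, dtype=int)
        )
        if self.coords_mm.ndim != 2 or self.coords_mm.shape[1] != 3:
            raise ValueError("coords_mm must be (n_nodes, 3)")
        if not np.all(np.isfinite(self.coords_mm)):
            raise ValueError("coordinates must be finite")
        n = self.coords_mm.shape[0]
        if self.subnetwork.shape != (n,):
            raise ValueError("subnetwork labels must match node count")
        if self.community_schedule.shape[1] != n:
            raise ValueError("community schedule must match node count")
        if np.unique(self.subnetwork).size < 2:
            raise ValueError("need at least 2 subnetworks")
        for epoch in self.community_schedule:
            if np.unique(epoch).size < 2:
                raise ValueError("each epoch needs >= 2 distinct communities")

    @property
    def n_nodes(self) -> int:
        return self.coords_mm.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.community_schedule.shape[0]


@dataclass
class MotionProfile:
    """Per-frame head displacement (mm) plus the six realignment series."""

    framewise_rel_rms: np.ndarray  # (n_frames,) mm, >= 0
    realign_params: np.ndarray  # (n_frames, 6): 3 translations mm, 3 rotations rad

    def __post_init__(self) -> None:
        self.framewise_rel_rms = np.asarray(self.framewise_rel_rms, dtype=float)
        self.realign_params = np.asarray(self.realign_params, dtype=float)
        if np.any(self.framewise_rel_rms < 0):
            raise ValueError("framewise displacement must be nonnegative")
        if self.realign_params.shape != (self.framewise_rel_rms.size, 6):
            raise ValueError("realign_params must be (n_frames, 6)")

    @property
    def mean_rel_rms(self) -> float:
        return float(self.framewise_rel_rms.mean())

    @property
    def n_frames(self) -> int:
        return self.framewise_rel_rms.size

    def passes_inclusion(self) -> bool:
        n_spikes = int(np.sum(self.framewise_rel_rms > SPIKE_THRESHOLD))
        return self.mean_rel_rms <= MAX_MEAN_REL_RMS and n_spikes <= MAX_SPIKE_FRAMES


@dataclass
class ArtifactModel:
    """Parameters of the generative contamination model.

    beta_spike      artifact gain per mm of framewise displacement
    lambda_d        spatial decay length of artifact sharing, mm
    global_drift_sd amplitude of the shared low-frequency drift in the clean
                    signal (what global-signal regression removes even in the
                    absence of motion)
    rho_in/rho_out  target within/between planted-community correlations
    ar1_coef        lag-1 coefficient of the signal innovations
    age_motion_r    target correlation between age and mean displacement
    n_sources       number of spatial artifact sources
    """

    beta_spike: float = 4.0
    lambda_d: float = 40.0
    global_drift_sd: float = 0.3
    rho_in: float = 0.4
    rho_out: float = 0.05
    ar1_coef: float = 0.3
    age_motion_r: float = -0.3
    n_sources: int = 5

    def __post_init__(self) -> None:
        if self.lambda_d <= 0:
            raise ValueError("lambda_d must be positive")
        if not (abs(self.rho_in) < 1 and abs(self.rho_out) < 1):
            raise ValueError("correlation targets must lie in (-1, 1)")
        if self.rho_in < self.rho_out:
            raise ValueError("rho_in must be >= rho_out")
        if self.rho_out < 0:
            raise ValueError("rho_out must be nonnegative (block target PSD)")
        if abs(self.age_motion_r) >= 1:
            raise ValueError("|age_motion_r| must be < 1")
        if self.n_sources < 1:
            raise ValueError("need at least one artifact source")


@dataclass
class NuisanceChannels:
    """Named nuisance-channel matrix (frames x channels).

    groups maps a channel family ("global", "csf", "wm", "pool") to its column
    names; WM channels carry spatial coordinates for local-WM regression.
    """

    data: pd.DataFrame
    wm_coords_mm: np.ndarray  # (n_wm, 3)
    groups: dict = field(default_factory=dict)

    def columns(self, group: str) -> np.ndarray:
        return self.data[self.groups[group]].to_numpy()


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    sex: int
    motion: MotionProfile
    clean_signals: np.ndarray  # (n_nodes, n_frames)
    contaminated_signals: np.ndarray  # same shape
    nuisance: NuisanceChannels

    def __post_init__(self) -> None:
        if self.clean_signals.shape != self.contaminated_signals.shape:
            raise ValueError("clean and contaminated signals must share shape")
        if not np.all(np.isfinite(self.contaminated_signals)):
            raise ValueError("signals contain non-finite values")


def _uniform_ball(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    """n points uniform in a 3-ball of given radius."""
    d = rng.standard_normal((n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    r = radius * rng.random(n) ** (1.0 / 3.0)
    return d * r[:, None]


def generate_atlas(
    n_nodes: int = 264,
    n_subnetworks: int = 11,
    n_epochs: int = 3,
    seed: int = 0,
    reassign_frac: float = 0.2,
) -> NodeAtlas:
    """Random spatially clustered atlas with a planted community schedule.

    Nodes of the same subnetwork are drawn around a common center inside a
    70 mm sphere, so short-range edges are preferentially within-system.  The
    community schedule starts at the subnetwork partition and reassigns
    ``reassign_frac`` of the nodes between consecutive epochs.
    """
    if n_subnetworks < 2:
        raise ValueError("need at least 2 subnetworks")
    if n_nodes < n_subnetworks:
        raise ValueError("need n_nodes >= n_subnetworks")
    if n_epochs < 1:
        raise ValueError("need at least one epoch")
    rng = np.random.default_rng(seed)
    centers = _uniform_ball(rng, n_subnetworks, 0.75 * BRAIN_RADIUS_MM)
    labels = np.sort(np.arange(n_nodes) % n_subnetworks)
    labels = rng.permutation(labels)
    coords = centers[labels] + rng.normal(scale=12.0, size=(n_nodes, 3))
    # clip stragglers back inside the sphere
    norm = np.linalg.norm(coords, axis=1)
    outside = norm > BRAIN_RADIUS_MM
    coords[outside] *= (BRAIN_RADIUS_MM / norm[outside])[:, None]

    schedule = np.empty((n_epochs, n_nodes), dtype=int)
    schedule[0] = labels
    n_move = int(round(reassign_frac * n_nodes))
    for e in range(1, n_epochs):
        schedule[e] = schedule[e - 1]
        movers = rng.choice(n_nodes, size=n_move, replace=False)
        for i in movers:
            others = np.delete(np.arange(n_subnetworks), schedule[e, i])
            schedule[e, i] = rng.choice(others)
    return NodeAtlas(coords, labels, schedule)


def generate_motion_profile(
    n_frames: int,
    target_mean_rms: float = 0.07,
    spike_rate: float = 0.02,
    seed: int = 0,
) -> MotionProfile:
    """Micromovement trace: lognormal baseline jitter plus occasional spikes.

    The baseline is rescaled so the mean relative RMS displacement hits the
    target; spikes (0.26-0.45 mm) are kept at their natural amplitude and
    capped at the inclusion-rule limit.  The six realignment series integrate
    the framewise displacement along a slowly wandering direction, so the
    translational difference norm reproduces framewise_rel_rms exactly.
    """
    if not (0 < target_mean_rms <= MAX_MEAN_REL_RMS):
        raise ValueError(
            f"target_mean_rms must be in (0, {MAX_MEAN_REL_RMS}] mm"
        )
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    base = np.exp(rng.normal(loc=0.0, scale=0.6, size=n_frames))
    base[0] = 0.0  # no displacement at the first frame
    spikes = np.zeros(n_frames)
    if spike_rate > 0:
        hit = np.flatnonzero(rng.random(n_frames) < spike_rate)
        hit = hit[hit > 0]
        if hit.size > MAX_SPIKE_FRAMES:
            hit = rng.choice(hit, size=MAX_SPIKE_FRAMES, replace=False)
        spikes[hit] = rng.uniform(0.26, 0.45, size=hit.size)
    spike_mean = spikes.mean()
    if spike_mean >= 0.8 * target_mean_rms:
        # pathological draw: shrink spikes so the baseline keeps some budget
        spikes *= 0.8 * target_mean_rms / spike_mean
        spike_mean = spikes.mean()
    # rescale the baseline to the remaining budget while keeping it strictly
    # below the spike threshold (only deliberate spikes may cross it)
    for _ in range(8):
        base *= (target_mean_rms - spike_mean) / base.mean()
        base = np.minimum(base, 0.9 * SPIKE_THRESHOLD)
        if abs(base.mean() + spike_mean - target_mean_rms) < 1e-4 * target_mean_rms:
            break
    fd = base + spikes

    # persistent displacement direction with frame-to-frame jitter
    u = rng.standard_normal(3)
    u /= np.linalg.norm(u)
    jitter = 0.4 * rng.standard_normal((n_frames, 3))
    dirs = u[None, :] + jitter
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    deltas = fd[:, None] * dirs
    translations = np.cumsum(deltas, axis=0)
    # small rotations: slow angular drift plus fast estimate jitter whose
    # amplitude scales with subject motion (realignment estimates are noisier
    # in movers, and the jitter shares the band of the BOLD artifact)
    fd_rot = np.exp(rng.normal(loc=0.0, scale=0.6, size=n_frames))
    fd_rot *= target_mean_rms / fd_rot.mean()
    rot_dirs = rng.standard_normal((n_frames, 3))
    rot_dirs /= np.linalg.norm(rot_dirs, axis=1, keepdims=True)
    rotations = np.cumsum(0.002 * fd_rot[:, None] * rot_dirs, axis=0)
    rotations += 0.002 * (target_mean_rms / 0.07) * rng.standard_normal(
        (n_frames, 3)
    )
    rp = np.hstack([translations, rotations])
    return MotionProfile(fd, rp)


def _bandlimited_noise(
    rng: np.random.Generator,
    shape: tuple,
    tr: float,
    ar1: float = 0.0,
    f_lo: float = 0.01,
    f_hi: float = 0.08,
) -> np.ndarray:
    """Unit-variance noise with power concentrated in [f_lo, f_hi] Hz.

    Last axis is time.  AR(1) smoothing is applied to the innovations before
    filtering; each series is standardized afterwards.
    """
    x = rng.standard_normal(shape)
    if ar1:
        x = sps.lfilter([1.0], [1.0, -ar1], x, axis=-1)
    nyq = 0.5 / tr
    b, a = sps.butter(1, [f_lo / nyq, f_hi / nyq], btype="bandpass")
    x = sps.filtfilt(b, a, x, axis=-1)
    x -= x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _epoch_of_frame(n_frames: int, n_epochs: int) -> np.ndarray:
    """Map each frame to its (contiguous, near-equal) epoch index."""
    return np.minimum((np.arange(n_frames) * n_epochs) // n_frames, n_epochs - 1)


def simulate_clean_signals(
    atlas: NodeAtlas,
    model: ArtifactModel,
    n_frames: int = 120,
    tr: float = 3.0,
    seed: int = 0,
    bandlimit: bool = True,
) -> np.ndarray:
    """Band-limited signals with planted window-varying community structure.

    Each node loads on a global factor (weight sqrt(rho_out)), on the factor
    of its current planted community (weight sqrt(rho_in - rho_out)) and on
    idiosyncratic noise, which yields within-community correlation rho_in and
    between-community correlation rho_out within each epoch.  A shared
    low-frequency drift of amplitude global_drift_sd is added (scanner /
    physiological, independent of motion).
    """
    rng = np.random.default_rng(seed)
    n = atlas.n_nodes
    labels_all = np.unique(atlas.community_schedule)
    n_comm = labels_all.max() + 1

    def make(shape):
        if bandlimit:
            return _bandlimited_noise(rng, shape, tr, ar1=model.ar1_coef)
        x = rng.standard_normal(shape)
        if model.ar1_coef:
            x = sps.lfilter([1.0], [1.0, -model.ar1_coef], x, axis=-1)
            x /= x.std(axis=-1, keepdims=True)
        return x

    g = make((n_frames,))
    h = make((n_comm, n_frames))
    eps = make((n, n_frames))

    epoch = _epoch_of_frame(n_frames, atlas.n_epochs)
    comm = atlas.community_schedule[epoch, :]  # (n_frames, n_nodes)
    h_node = h[comm.T, np.arange(n_frames)[None, :]]  # (n_nodes, n_frames)

    w_g = np.sqrt(model.rho_out)
    w_c = np.sqrt(model.rho_in - model.rho_out)
    w_e = np.sqrt(1.0 - model.rho_in)
    x = w_g * g[None, :] + w_c * h_node + w_e * eps

    if model.global_drift_sd:
        drift = np.cumsum(rng.standard_normal(n_frames))
        drift -= drift.mean()
        drift /= max(drift.std(), 1e-12)
        x = x + model.global_drift_sd * drift[None, :]
    return x


def _source_weights(
    coords: np.ndarray, sources: np.ndarray, lambda_d: float
) -> np.ndarray:
    """Spatial artifact weight per node: summed exponential kernel, mean 1."""
    d = np.linalg.norm(coords[:, None, :] - sources[None, :, :], axis=2)
    w = np.exp(-d / lambda_d).sum(axis=1)
    return w / w.mean()


def inject_artifact(
    clean: np.ndarray,
    motion: MotionProfile,
    atlas: NodeAtlas,
    model: ArtifactModel,
    seed: int = 0,
    tr: float = 3.0,
) -> tuple[np.ndarray, NuisanceChannels]:
    """Add motion-coupled artifact and build the nuisance-channel matrix.

    contaminated_i = clean_i + beta_spike * w_i * u(t)

    with spatial weight w_i (exponential kernel around randomly placed
    sources) and shared artifact series

        u(t) = FD(t) * (1 + 0.7 eta(t)) + 1.5 * <FD> * m(t)

    where FD is the framewise displacement, <FD> its mean, eta is band-limited
    noise and m is a standardized mix of the band-passed rotation estimates.
    The displacement-modulated term couples the artifact to per-frame motion;
    the rotation-mix term is exactly spanned by the realignment parameters,
    which is what makes realignment-parameter regression (6P/24P) partially
    effective — as in real data, where part of the motion artifact is linear
    in the motion estimates.  Tissue and global nuisance channels measure
    u(t) directly, so pipelines that regress them can remove the shared
    artifact essentially completely.
    """
    clean = np.asarray(clean, dtype=float)
    n_nodes, n_frames = clean.shape
    if n_frames != motion.n_frames:
        raise ValueError("signal and motion frame counts differ")
    if n_nodes != atlas.n_nodes:
        raise ValueError("signal and atlas node counts differ")
    rng = np.random.default_rng(seed)

    sources = _uniform_ball(rng, model.n_sources, BRAIN_RADIUS_MM)
    w = _source_weights(atlas.coords_mm, sources, model.lambda_d)

    fd = motion.framewise_rel_rms
    mean_fd = fd.mean()
    nyq = 0.5 / tr
    b_f, a_f = sps.butter(1, [0.01 / nyq, 0.08 / nyq], btype="bandpass")
    rot_bp = sps.filtfilt(b_f, a_f, motion.realign_params[:, 3:6], axis=0)
    rot_bp /= np.maximum(rot_bp.std(axis=0, keepdims=True), 1e-15)

    def rot_mix(weights: np.ndarray) -> np.ndarray:
        m = weights @ rot_bp.T
        m -= m.mean(axis=-1, keepdims=True)
        return m / np.maximum(m.std(axis=-1, keepdims=True), 1e-12)

    eta = _bandlimited_noise(rng, (n_frames,), tr)
    core = fd * (1.0 + 0.7 * eta) + 1.5 * mean_fd * rot_mix(
        rng.standard_normal(3)
    )

    contaminated = clean + model.beta_spike * np.outer(w, core)

    # --- nuisance channels ---------------------------------------------
    n_csf, n_wm, n_pool = 20, 30, 300
    cols, names, groups = [], [], {}

    names.append("global")
    cols.append(contaminated.mean(axis=0))
    groups["global"] = ["global"]

    csf = (
        rng.uniform(0.8, 1.6, size=(n_csf, 1)) * core[None, :]
        + 0.6 * _bandlimited_noise(rng, (n_csf, n_frames), tr)
    )
    groups["csf"] = [f"csf_{i:02d}" for i in range(n_csf)]
    names += groups["csf"]
    cols += list(csf)

    wm_coords = _uniform_ball(rng, n_wm, BRAIN_RADIUS_MM)
    w_wm = _source_weights(wm_coords, sources, model.lambda_d)
    wm = (
        0.9 * w_wm[:, None] * core[None, :]
        + 0.7 * _bandlimited_noise(rng, (n_wm, n_frames), tr)
    )
    groups["wm"] = [f"wm_{i:02d}" for i in range(n_wm)]
    names += groups["wm"]
    cols += list(wm)

    pool = _bandlimited_noise(rng, (n_pool, n_frames), tr)
    noisy = rng.choice(n_pool, size=n_pool // 10, replace=False)
    pool[noisy] += 3.0 * core[None, :]
    groups["pool"] = [f"hv_{i:03d}" for i in range(n_pool)]
    names += groups["pool"]
    cols += list(pool)

    data = pd.DataFrame(np.column_stack(cols), columns=names)
    return contaminated, NuisanceChannels(data, wm_coords, groups)


def generate_cohort(
    n_subjects: int,
    atlas: NodeAtlas | None = None,
    model: ArtifactModel | None = None,
    n_frames: int = 120,
    tr: float = 3.0,
    seed: int = 0,
) -> list[SubjectRecord]:
    """Simulate a cohort of subjects with age-correlated motion.

    Ages are uniform on [8, 22] years, sex is balanced, and per-subject motion
    targets follow a lognormal around the cohort's 0.07 mm scale, coupled to
    age through a Gaussian copula at model.age_motion_r.  All randomness flows
    from the cohort seed via per-subject derived seeds.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    if atlas is None:
        atlas = generate_atlas(seed=seed)
    if model is None:
        model = ArtifactModel()
    rng = np.random.default_rng(seed)

    r = model.age_motion_r
    z_age = rng.standard_normal(n_subjects)
    z_mot = r * z_age + np.sqrt(1 - r**2) * rng.standard_normal(n_subjects)
    from scipy.stats import norm

    ages = 8.0 + 14.0 * norm.cdf(z_age)
    targets = np.clip(0.065 * np.exp(0.5 * z_mot), 0.02, 0.18)
    sex = rng.permutation(np.arange(n_subjects) % 2)
    subj_seeds = rng.integers(0, 2**31 - 1, size=(n_subjects, 3))

    cohort = []
    for i in range(n_subjects):
        motion = generate_motion_profile(
            n_frames, target_mean_rms=float(targets[i]), seed=int(subj_seeds[i, 0])
        )
        if not motion.passes_inclusion():  # pragma: no cover - guarded by design
            warnings.warn(f"subject {i} failed inclusion; regenerating without spikes")
            motion = generate_motion_profile(
                n_frames, float(targets[i]), spike_rate=0.0, seed=int(subj_seeds[i, 0])
            )
        clean = simulate_clean_signals(
            atlas, model, n_frames=n_frames, tr=tr, seed=int(subj_seeds[i, 1])
        )
        contaminated, nuisance = inject_artifact(
            clean, motion, atlas, model, seed=int(subj_seeds[i, 2]), tr=tr
        )
        cohort.append(
            SubjectRecord(
                subject_id=f"sub-{i:04d}",
                age=float(ages[i]),
                sex=int(sex[i]),
                motion=motion,
                clean_signals=clean,
                contaminated_signals=contaminated,
                nuisance=nuisance,
            )
        )
    return cohort


def covariates_table(cohort: list[SubjectRecord]) -> pd.DataFrame:
    """Subject covariates (id, age, sex, mean relative RMS motion)."""
    return pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort],
            "age": [s.age for s in cohort],
            "sex": [s.sex for s in cohort],
            "mean_rel_rms": [s.motion.mean_rel_rms for s in cohort],
        }
    )
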