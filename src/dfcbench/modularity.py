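"""Multilayer modularity and its maximization by a generalized Louvain heuristic.

A subject's T window networks are coupled into a multilayer network by
identity edges of weight omega linking each node to itself in adjacent
windows.  Multilayer modularity is

    Q = (1/2mu) * sum_{ijlr} [ (A_ijl - gamma_l P_ijl) delta_lr
                               + delta_ij omega_jlr ] delta(g_il, g_jr)

with P the Newman-Girvan expected weight per layer, gamma the structural
resolution, and 2mu the total (intra + inter) multilayer strength.  The
heuristic operates on the flattened (n*T) x (n*T) supra-modularity matrix:
greedy single-node moves, aggregation, repeat — restarted with shuffled node
orders across iterations, exactly as practitioners run it on windowed fMRI
networks.  A brute-force enumerator over set partitions serves as an oracle
for small instances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MultilayerNetwork",
    "ModularityParams",
    "MultilayerPartition",
    "newman_girvan_null",
    "supra_modularity_matrix",
    "quality",
    "maximize",
    "brute_force_max",
    "canonicalize_labels",
]

GAIN_TOL = 1e-10


@dataclass
class MultilayerNetwork:
    """Ordered intralayer weight matrices plus the interlayer coupling weight.

    Layers must be symmetric, nonnegative, zero-diagonal.  Coupling is ordinal:
    identity edges of weight omega between the same node in adjacent layers.
    """

    layers: np.ndarray  # (T, n, n)
    omega: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.layers, dtype=float)
        if a.ndim != 3 or a.shape[1] != a.shape[2]:
            raise ValueError("layers must be (T, n, n)")
        if np.any(a < 0):
            raise ValueError("intralayer weights must be nonnegative")
        if not np.allclose(a, a.transpose(0, 2, 1)):
            raise ValueError("layers must be symmetric")
        if np.any(np.abs(np.diagonal(a, axis1=1, axis2=2)) > 0):
            raise ValueError("layers must have zero diagonal")
        if self.omega < 0:
            raise ValueError("omega must be nonnegative")
        self.layers = a

    @property
    def n_layers(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]

    def intralayer_strength(self) -> np.ndarray:
        """kappa_jl = sum_i A_ijl, shape (T, n)."""
        return self.layers.sum(axis=1)

    def interlayer_strength(self) -> np.ndarray:
        """c_jl = sum_r omega_jlr over adjacent layers, shape (T, n)."""
        T, n = self.n_layers, self.n_nodes
        c = np.zeros((T, n))
        if T > 1 and self.omega:
            c[:] = 2.0 * self.omega
            c[0] = self.omega
            c[-1] = self.omega
        return c

    def total_weight(self) -> float:
        """mu = (1/2) sum_jl (kappa_jl + c_jl), the multilayer strength total."""
        mu = 0.5 * (self.intralayer_strength().sum() + self.interlayer_strength().sum())
        if mu <= 0:
            raise ValueError("network has zero total weight")
        return float(mu)


@dataclass
class ModularityParams:
    gamma: float | np.ndarray = 1.0
    omega: float = 1.0
    n_iterations: int = 100
    seed: int = 0
    max_passes: int = 200

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.gamma) <= 0):
            raise ValueError("gamma must be positive")
        if self.n_iterations < 1:
            raise ValueError("need at least one iteration")

    def gamma_per_layer(self, n_layers: int) -> np.ndarray:
        g = np.asarray(self.gamma, dtype=float)
        return np.full(n_layers, g) if g.ndim == 0 else g


@dataclass
class MultilayerPartition:
    """Node-by-layer community labels with the associated quality value."""

    labels: np.ndarray  # (n, T), positive ints, first-appearance order
    Q: float
    iteration_index: int = 0


def canonicalize_labels(labels: np.ndarray) -> np.ndarray:
    """Relabel communities 1, 2, ... in order of first appearance (row-major)."""
    flat = np.asarray(labels).ravel()
    _, first = np.unique(flat, return_index=True)
    order = flat[np.sort(first)]
    mapping = {lab: i + 1 for i, lab in enumerate(order)}
    return np.vectorize(mapping.get)(np.asarray(labels))


def newman_girvan_null(layer: np.ndarray) -> np.ndarray:
    """Expected edge weights under the Newman-Girvan null: kappa_i kappa_j / 2m."""
    a = np.asarray(layer, dtype=float)
    k = a.sum(axis=1)
    two_m = k.sum()
    if two_m <= 0:
        warnings.warn("zero-weight layer: null model is zero")
        return np.zeros_like(a)
    return np.outer(k, k) / two_m


def supra_modularity_matrix(
    network: MultilayerNetwork, params: ModularityParams
) -> np.ndarray:
    """Flattened (n*T) x (n*T) matrix B with B[(i,l),(j,l)] = A_ijl - gamma_l P_ijl
    and B[(j,l),(j,r)] = omega for adjacent layers l, r.  Slot order is
    layer-major: slot = l * n + i.
    """
    T, n = network.n_layers, network.n_nodes
    gamma = params.gamma_per_layer(T)
    N = n * T
    B = np.zeros((N, N))
    for l in range(T):
        sl = slice(l * n, (l + 1) * n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            B[sl, sl] = network.layers[l] - gamma[l] * newman_girvan_null(
                network.layers[l]
            )
    if network.omega and T > 1:
        idx = np.arange(n * (T - 1))
        B[idx, idx + n] += network.omega
        B[idx + n, idx] += network.omega
    return B


def _as_label_matrix(labels: np.ndarray, n: int, T: int) -> np.ndarray:
    g = np.asarray(labels)
    if g.shape != (n, T):
        raise ValueError(f"labels must have shape ({n}, {T})")
    return g


def quality(
    network: MultilayerNetwork,
    labels: np.ndarray,
    params: ModularityParams | None = None,
) -> float:
    """Multilayer modularity Q of a given node-by-layer partition."""
    if params is None:
        params = ModularityParams(omega=network.omega)
    g = _as_label_matrix(labels, network.n_nodes, network.n_layers)
    B = supra_modularity_matrix(network, params)
    flat = g.T.ravel()  # layer-major, matching B's slot order
    same = flat[:, None] == flat[None, :]
    return float(B[same].sum() / (2.0 * network.total_weight()))


def _greedy_phase(B: np.ndarray, rng: np.random.Generator, max_passes: int):
    """Single-node greedy moves on the (aggregated) supra-modularity matrix.

    Returns (community labels 0..k-1, whether anything improved).  The gain of
    moving node u to community c is 2 * (s_c - s_old) where s_c sums B[u, v]
    over members v != u of c; self-loops move with u and cancel.  Among
    equal-gain moves the current community is kept; an isolated (empty)
    community is taken when every gain is negative.
    """
    n = B.shape[0]
    labels = np.arange(n)
    diag = np.diagonal(B).copy()
    improved = False
    for _ in range(max_passes):
        moved = False
        for u in rng.permutation(n):
            w = B[u]
            s = np.bincount(labels, weights=w, minlength=n)
            s[labels[u]] -= diag[u]
            cur = labels[u]
            best = int(np.argmax(s))
            best_gain = s[best] - s[cur]
            if s[best] < -GAIN_TOL:  # isolate u into an empty community
                empty = np.flatnonzero(np.bincount(labels, minlength=n) == 0)
                if empty.size and -s[cur] > GAIN_TOL:
                    labels[u] = empty[0]
                    moved = improved = True
                continue
            if best != cur and best_gain > GAIN_TOL:
                labels[u] = best
                moved = improved = True
        if not moved:
            break
    # compact labels
    _, labels = np.unique(labels, return_inverse=True)
    return labels, improved


def _aggregate(B: np.ndarray, labels: np.ndarray) -> np.ndarray:
    k = labels.max() + 1
    M = np.zeros((B.shape[0], k))
    M[np.arange(B.shape[0]), labels] = 1.0
    return M.T @ B @ M


def _louvain_once(B: np.ndarray, rng: np.random.Generator, max_passes: int):
    """One full generalized-Louvain run; returns slot labels (flat, 0-based)."""
    n = B.shape[0]
    assign = np.arange(n)
    Bcur = B
    while True:
        labels, improved = _greedy_phase(Bcur, rng, max_passes)
        assign = labels[assign]
        if not improved or labels.max() + 1 == Bcur.shape[0]:
            break
        Bcur = _aggregate(Bcur, labels)
    return assign


def maximize(
    network: MultilayerNetwork, params: ModularityParams
) -> tuple[list[MultilayerPartition], float]:
    """Run the Louvain heuristic ``n_iterations`` times; report each partition
    and the mean Q.  Iteration i is seeded from params.seed + i, so reruns are
    exactly reproducible, and each returned Q is recomputed by quality().
    """
    T, n = network.n_layers, network.n_nodes
    B = supra_modularity_matrix(network, params)
    two_mu = 2.0 * network.total_weight()
    partitions = []
    for it in range(params.n_iterations):
        rng = np.random.default_rng(params.seed + it)
        flat = _louvain_once(B, rng, params.max_passes)
        g = canonicalize_labels(flat.reshape(T, n).T)
        same = flat[:, None] == flat[None, :]
        q = float(B[same].sum() / two_mu)
        partitions.append(MultilayerPartition(labels=g, Q=q, iteration_index=it))
    mean_q = float(np.mean([p.Q for p in partitions]))
    return partitions, mean_q


def _set_partitions(n: int):
    """Yield all set partitions of range(n) as label arrays (restricted growth)."""
    g = np.zeros(n, dtype=int)
    m = np.ones(n, dtype=int)  # m[i] = 1 + max(g[:i+1])
    while True:
        yield g.copy()
        i = n - 1
        while i > 0 and g[i] == m[i - 1]:
            i -= 1
        if i == 0:
            return
        g[i] += 1
        m[i] = max(m[i - 1], g[i] + 1)
        for j in range(i + 1, n):
            g[j] = 0
            m[j] = m[i]


def brute_force_max(
    network: MultilayerNetwork, params: ModularityParams | None = None
) -> tuple[float, np.ndarray]:
    """Exhaustive maximization of Q over all set partitions of the n*T slots.

    Only feasible for n*T <= 12 (Bell numbers grow fast); the returned labels
    are canonicalized node-by-layer.
    """
    if params is None:
        params = ModularityParams(omega=network.omega)
    T, n = network.n_layers, network.n_nodes
    N = n * T
    if N > 12:
        raise ValueError("brute force limited to n * T <= 12 slots")
    B = supra_modularity_matrix(network, params)
    two_mu = 2.0 * network.total_weight()
    best_q, best_g = -np.inf, None
    for g in _set_partitions(N):
        same = g[:, None] == g[None, :]
        q = B[same].sum() / two_mu
        if q > best_q:
            best_q, best_g = q, g
    return float(best_q), canonicalize_labels(best_g.reshape(T, n).T)
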