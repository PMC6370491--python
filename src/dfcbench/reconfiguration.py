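"""Node flexibility and promiscuity from multilayer partitions.

Flexibility f_i = m / (T - 1): the fraction of between-window transitions at
which node i changes community.  Promiscuity psi_i = k_i / K: the fraction of
all communities in the partition that node i ever joins (K counts distinct
communities anywhere in the partition; a per-layer variant is exposed via
``k_total``).  Both are averaged elementwise over optimization iterations,
never over consensus labels; the global summaries F and Psi are node means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .modularity import MultilayerPartition

__all__ = [
    "ReconfigurationProfile",
    "node_flexibility",
    "node_promiscuity",
    "average_profiles",
]


@dataclass
class ReconfigurationProfile:
    flexibility: np.ndarray  # (n,)
    promiscuity: np.ndarray  # (n,)
    global_F: float
    global_Psi: float
    n_iterations_averaged: int

    def __post_init__(self) -> None:
        for v in (self.flexibility, self.promiscuity):
            if np.any((v < 0) | (v > 1)):
                raise ValueError("profile values must lie in [0, 1]")


def node_flexibility(labels: np.ndarray) -> np.ndarray:
    """Per-node fraction of community changes between consecutive windows."""
    g = np.asarray(labels)
    if g.ndim != 2 or g.shape[1] < 2:
        raise ValueError("labels must be n x T with T >= 2")
    changes = (g[:, 1:] != g[:, :-1]).sum(axis=1)
    return changes / (g.shape[1] - 1)


def node_promiscuity(labels: np.ndarray, per_layer_K: bool = False) -> np.ndarray:
    """Per-node fraction of communities visited.

    K is the number of distinct communities in the whole partition by default;
    with ``per_layer_K`` it is the mean number of communities per layer.
    """
    g = np.asarray(labels)
    if g.ndim != 2 or g.shape[1] < 1:
        raise ValueError("labels must be n x T")
    if per_layer_K:
        K = float(np.mean([np.unique(g[:, t]).size for t in range(g.shape[1])]))
    else:
        K = float(np.unique(g).size)
    k = np.array([np.unique(row).size for row in g], dtype=float)
    return np.minimum(k / K, 1.0)


def average_profiles(
    partitions: list[MultilayerPartition | np.ndarray],
) -> ReconfigurationProfile:
    """Elementwise mean of per-iteration flexibility and promiscuity vectors."""
    if not partitions:
        raise ValueError("need at least one partition")
    mats = [p.labels if isinstance(p, MultilayerPartition) else p for p in partitions]
    shape = np.asarray(mats[0]).shape
    for m in mats:
        if np.asarray(m).shape != shape:
            raise ValueError("partitions have inconsistent shapes")
    f = np.mean([node_flexibility(m) for m in mats], axis=0)
    psi = np.mean([node_promiscuity(m) for m in mats], axis=0)
    return ReconfigurationProfile(
        flexibility=f,
        promiscuity=psi,
        global_F=float(f.mean()),
        global_Psi=float(psi.mean()),
        n_iterations_averaged=len(mats),
    )
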