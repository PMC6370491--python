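"""Plain-text serialization of cohorts, connectivity stacks and partitions.

Everything is TSV or JSON so that runs are inspectable and byte-reproducible:
per-subject signal matrices (nodes x frames), the atlas table, covariates,
nuisance channels, window stacks (one TSV per window plus a JSON index) and
partition label matrices.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (
    MotionProfile,
    NodeAtlas,
    NuisanceChannels,
    SubjectRecord,
    covariates_table,
)
from .windows import ConnectivityStack, WindowScheme

__all__ = [
    "write_matrix",
    "read_matrix",
    "write_cohort",
    "read_cohort",
    "write_stack",
    "read_stack",
]

FLOAT_FMT = "%.10g"


def write_matrix(path: Path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.atleast_2d(matrix), fmt=FLOAT_FMT, delimiter="\t")


def read_matrix(path: Path) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path, delimiter="\t"))


def _write_tsv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_cohort(
    outdir: str | Path,
    cohort: list[SubjectRecord],
    atlas: NodeAtlas,
    manifest: dict | None = None,
) -> Path:
    """Serialize a cohort directory: atlas, covariates, per-subject matrices."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_tsv(
        out / "atlas.tsv",
        pd.DataFrame(
            {
                "node_id": np.arange(atlas.n_nodes),
                "x": atlas.coords_mm[:, 0],
                "y": atlas.coords_mm[:, 1],
                "z": atlas.coords_mm[:, 2],
                "subnetwork": atlas.subnetwork,
            }
        ),
    )
    write_matrix(out / "community_schedule.tsv", atlas.community_schedule)
    _write_tsv(out / "covariates.tsv", covariates_table(cohort))
    for s in cohort:
        write_matrix(out / f"{s.subject_id}_signals.tsv", s.contaminated_signals)
        write_matrix(out / f"{s.subject_id}_clean.tsv", s.clean_signals)
        motion = pd.DataFrame(
            np.column_stack([s.motion.framewise_rel_rms, s.motion.realign_params]),
            columns=["framewise_rel_rms"]
            + [f"trans_{a}" for a in "xyz"]
            + [f"rot_{a}" for a in "xyz"],
        )
        _write_tsv(out / f"{s.subject_id}_motion.tsv", motion)
        s.nuisance.data.to_csv(
            out / f"{s.subject_id}_nuisance.tsv",
            sep="\t",
            index=False,
            float_format="%.10g",
        )
    first = cohort[0]
    write_matrix(out / "wm_coords.tsv", first.nuisance.wm_coords_mm)
    meta = dict(manifest or {})
    meta["subjects"] = [s.subject_id for s in cohort]
    (out / "manifest.json").write_text(json.dumps(meta, sort_keys=True, indent=1))
    return out


def _nuisance_from_frame(data: pd.DataFrame, wm_coords: np.ndarray) -> NuisanceChannels:
    groups = {
        "global": [c for c in data.columns if c == "global"],
        "csf": [c for c in data.columns if c.startswith("csf_")],
        "wm": [c for c in data.columns if c.startswith("wm_")],
        "pool": [c for c in data.columns if c.startswith("hv_")],
    }
    return NuisanceChannels(data, wm_coords, groups)


def read_cohort(indir: str | Path) -> tuple[list[SubjectRecord], NodeAtlas]:
    """Load a cohort directory written by :func:`write_cohort`."""
    d = Path(indir)
    atlas_df = pd.read_csv(d / "atlas.tsv", sep="\t")
    schedule = read_matrix(d / "community_schedule.tsv").astype(int)
    atlas = NodeAtlas(
        atlas_df[["x", "y", "z"]].to_numpy(),
        atlas_df["subnetwork"].to_numpy(),
        schedule,
    )
    cov = pd.read_csv(d / "covariates.tsv", sep="\t")
    wm_coords = read_matrix(d / "wm_coords.tsv")
    cohort = []
    for _, row in cov.iterrows():
        sid = row["subject_id"]
        motion_df = pd.read_csv(d / f"{sid}_motion.tsv", sep="\t")
        motion = MotionProfile(
            motion_df["framewise_rel_rms"].to_numpy(),
            motion_df.iloc[:, 1:7].to_numpy(),
        )
        nuis = pd.read_csv(d / f"{sid}_nuisance.tsv", sep="\t")
        cohort.append(
            SubjectRecord(
                subject_id=sid,
                age=float(row["age"]),
                sex=int(row["sex"]),
                motion=motion,
                clean_signals=read_matrix(d / f"{sid}_clean.tsv"),
                contaminated_signals=read_matrix(d / f"{sid}_signals.tsv"),
                nuisance=_nuisance_from_frame(nuis, wm_coords),
            )
        )
    return cohort, atlas


def write_stack(outdir: str | Path, stack: ConnectivityStack, prefix: str) -> None:
    """One TSV per window plus a JSON index."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for t in range(stack.n_windows):
        write_matrix(out / f"{prefix}_window{t:03d}.tsv", stack.z_matrices[t])
    scheme = stack.window_scheme
    index = {
        "prefix": prefix,
        "n_windows": stack.n_windows,
        "negative_policy": stack.negative_policy,
        "window_length": None if scheme is None else int(scheme.window_length),
        "step": None if scheme is None else int(scheme.step),
        "starts": None if scheme is None else [int(s) for s in scheme.starts],
    }
    (out / f"{prefix}_stack.json").write_text(
        json.dumps(index, sort_keys=True, indent=1)
    )


def read_stack(indir: str | Path, prefix: str) -> ConnectivityStack:
    d = Path(indir)
    index = json.loads((d / f"{prefix}_stack.json").read_text())
    mats = np.stack(
        [
            read_matrix(d / f"{prefix}_window{t:03d}.tsv")
            for t in range(index["n_windows"])
        ]
    )
    scheme = None
    if index["window_length"] is not None:
        scheme = WindowScheme(
            index["window_length"], index["step"], np.asarray(index["starts"])
        )
    return ConnectivityStack(mats, index["negative_policy"], scheme)
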