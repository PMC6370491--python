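"""Per-pipeline benchmark report and the end-to-end runner.

For every requested de-noising pipeline the report gathers the four benchmark
families: (a) edgewise dispersion-motion partial correlations with BH-FDR
screening, (b) distance-dependence of those correlations, (c) multilayer
modularity quality Q (identifiability) and the Q-motion association, and
(d) node flexibility / promiscuity motion associations with per-subnetwork
breakdowns — plus pairwise pipeline comparisons (paired t on the edgewise
correlation distributions, Steiger tests on distance-dependence) and the
cross-benchmark correlation between pipeline mean Q and the Q-motion r.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from .confounds import PipelineSpec, apply_pipeline
from .dispersion import edge_dispersion, upper_triangle
from .io import write_cohort, write_matrix
from .modularity import ModularityParams, MultilayerNetwork, maximize
from .reconfiguration import average_profiles
from .stats import (
    distance_dependence,
    distance_matrix,
    paired_t,
    scalar_motion_association,
    steiger_equality,
    subnetwork_breakdown,
    unitwise_motion_association,
)
from .synthetic import (
    ArtifactModel,
    NodeAtlas,
    SubjectRecord,
    covariates_table,
    generate_atlas,
    generate_cohort,
)
from .windows import make_windows, window_connectivity

__all__ = [
    "BenchmarkConfig",
    "RunConfig",
    "BenchmarkReport",
    "pipeline_dispersion",
    "build_report",
    "run_all",
]

DEFAULT_PIPELINES = ("RAW", "6P", "9P", "24P", "36P")


@dataclass
class BenchmarkConfig:
    """Problem sizes and analysis parameters for one benchmark run."""

    pipelines: tuple = DEFAULT_PIPELINES
    tr: float = 3.0
    window_length: int = 20
    overlap: float = 0.5
    negative_policy: str = "zero"
    gamma: float = 1.0
    omega: float = 1.0
    n_modularity_iterations: int = 10
    modularity_max_subjects: int = 16
    modularity_seed: int = 0
    alpha: float = 0.05
    run_modularity: bool = True


@dataclass
class BenchmarkReport:
    """JSON-serializable container for per-pipeline benchmark outcomes."""

    pipelines: dict
    comparisons: dict
    cross_benchmark: dict
    config: dict

    def to_dict(self) -> dict:
        return {
            "pipelines": self.pipelines,
            "comparisons": self.comparisons,
            "cross_benchmark": self.cross_benchmark,
            "config": self.config,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1)

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkReport":
        return cls(
            pipelines=d["pipelines"],
            comparisons=d["comparisons"],
            cross_benchmark=d["cross_benchmark"],
            config=d["config"],
        )

    def ranking(self, key: str) -> list:
        """Pipelines ordered from worst (largest value) to best."""
        vals = {
            name: out[key]
            for name, out in self.pipelines.items()
            if out.get(key) is not None
        }
        return sorted(vals, key=lambda k: -abs(vals[k]))


def residualize_cohort(
    cohort: list[SubjectRecord],
    atlas: NodeAtlas,
    pipeline: str,
    tr: float = 3.0,
) -> list[np.ndarray]:
    """De-noised residual matrices for every subject under one pipeline."""
    spec = PipelineSpec.from_name(pipeline)
    return [
        apply_pipeline(s, spec, tr=tr, node_coords_mm=atlas.coords_mm)
        for s in cohort
    ]


def pipeline_dispersion(
    residuals: list[np.ndarray], config: BenchmarkConfig
) -> np.ndarray:
    """Subjects x edges matrix of dispersion values (upper-triangle order)."""
    scheme = make_windows(
        residuals[0].shape[1], config.window_length, config.overlap
    )
    rows = []
    for res in residuals:
        stack = window_connectivity(res, scheme, config.negative_policy)
        rows.append(upper_triangle(edge_dispersion(stack).C))
    return np.asarray(rows)


def _modularity_block(
    residuals: list[np.ndarray],
    covariates: pd.DataFrame,
    atlas: NodeAtlas,
    config: BenchmarkConfig,
) -> dict:
    """Q identifiability, Q-motion association and reconfiguration benchmarks.

    Modularity always operates on the zero-negative stack (intralayer weights
    must be nonnegative), on up to ``modularity_max_subjects`` subjects.
    """
    n_sub = min(len(residuals), config.modularity_max_subjects)
    scheme = make_windows(
        residuals[0].shape[1], config.window_length, config.overlap
    )
    q_means, q_sds, flex, prom = [], [], [], []
    for i in range(n_sub):
        stack = window_connectivity(residuals[i], scheme, "zero")
        net = MultilayerNetwork(stack.z_matrices, omega=config.omega)
        params = ModularityParams(
            gamma=config.gamma,
            omega=config.omega,
            n_iterations=config.n_modularity_iterations,
            seed=config.modularity_seed + 1000 * i,
        )
        partitions, mean_q = maximize(net, params)
        q_means.append(mean_q)
        q_sds.append(float(np.std([p.Q for p in partitions], ddof=0)))
        profile = average_profiles(partitions)
        flex.append(profile.flexibility)
        prom.append(profile.promiscuity)
    q_means = np.asarray(q_means)
    flex = np.asarray(flex)
    prom = np.asarray(prom)
    cov_sub = covariates.iloc[:n_sub]

    out = {
        "mean_Q": float(q_means.mean()),
        "sd_Q": float(q_means.std(ddof=1)) if n_sub > 1 else 0.0,
        "mean_within_subject_sd_Q": float(np.mean(q_sds)),
        "n_subjects_modularity": int(n_sub),
    }
    if n_sub >= 10:
        q_assoc = scalar_motion_association(q_means, cov_sub)
        out["Q_motion"] = {"r": q_assoc.r, "p": q_assoc.p}
        for label, mat in (("flexibility", flex), ("promiscuity", prom)):
            assoc = unitwise_motion_association(mat, cov_sub, alpha=config.alpha)
            g = scalar_motion_association(mat.mean(axis=1), cov_sub)
            out[f"{label}_motion"] = {
                **assoc.summary(),
                "global_r": g.r,
                "global_p": g.p,
                "subnetwork_pct_significant": (
                    100.0 * subnetwork_breakdown(assoc.p < config.alpha, atlas)
                ).to_dict(),
            }
    return out


def build_report(
    cohort: list[SubjectRecord],
    atlas: NodeAtlas,
    config: BenchmarkConfig | None = None,
) -> BenchmarkReport:
    """Run every benchmark family for every configured pipeline."""
    if config is None:
        config = BenchmarkConfig()
    covariates = covariates_table(cohort)
    D = upper_triangle(distance_matrix(atlas))

    per_pipeline: dict = {}
    edge_r_vectors: dict = {}
    for name in config.pipelines:
        try:
            residuals = residualize_cohort(cohort, atlas, name, tr=config.tr)
        except ValueError as err:  # missing inputs: mark absent, continue
            per_pipeline[name] = {"absent": True, "reason": str(err)}
            continue
        disp = pipeline_dispersion(residuals, config)
        assoc = unitwise_motion_association(disp, covariates, alpha=config.alpha)
        dd = distance_dependence(assoc.r, D)
        entry = {
            "dispersion_motion": assoc.summary(),
            "distance_dependence": {
                "r_dd": dd.r_dd,
                "p_dd": dd.p_dd,
                "n_edges": dd.n_edges,
            },
        }
        if config.run_modularity:
            entry.update(_modularity_block(residuals, covariates, atlas, config))
        per_pipeline[name] = entry
        edge_r_vectors[name] = assoc.r

    comparisons: dict = {}
    for a, b in combinations(edge_r_vectors, 2):
        ra, rb = edge_r_vectors[a], edge_r_vectors[b]
        t, df, p_t = paired_t(ra, rb)
        r12 = float(np.corrcoef(ra, rb)[0, 1]) if ra.std() and rb.std() else 0.0
        r12 = float(np.clip(r12, -0.999999, 0.999999))
        rdd_a = per_pipeline[a]["distance_dependence"]["r_dd"]
        rdd_b = per_pipeline[b]["distance_dependence"]["r_dd"]
        z, p_z = steiger_equality(rdd_a, rdd_b, r12, ra.size)
        comparisons[f"{a}|{b}"] = {
            "paired_t": t,
            "paired_t_df": df,
            "paired_t_p": p_t,
            "steiger_z": z,
            "steiger_p": p_z,
        }

    cross: dict = {}
    q_vals, qr_vals = [], []
    for name, entry in per_pipeline.items():
        if "mean_Q" in entry and "Q_motion" in entry:
            q_vals.append(entry["mean_Q"])
            qr_vals.append(entry["Q_motion"]["r"])
    if len(q_vals) >= 3 and np.std(q_vals) > 0 and np.std(qr_vals) > 0:
        r = float(np.corrcoef(q_vals, qr_vals)[0, 1])
        cross["meanQ_vs_Qmotion_r"] = r
        cross["n_pipelines"] = len(q_vals)

    return BenchmarkReport(
        pipelines=per_pipeline,
        comparisons=comparisons,
        cross_benchmark=cross,
        config=asdict(config) | {"pipelines": list(config.pipelines)},
    )


# ---------------------------------------------------------------------------
# end-to-end runner
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Cohort and benchmark parameters for a full simulate-to-report run."""

    n_subjects: int = 24
    n_nodes: int = 60
    n_subnetworks: int = 6
    n_epochs: int = 3
    n_frames: int = 120
    tr: float = 3.0
    model: ArtifactModel = field(default_factory=ArtifactModel)
    benchmark: BenchmarkConfig = field(default_factory=BenchmarkConfig)
    write_intermediates: bool = True

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        model = ArtifactModel(**d.pop("model", {}))
        bench = d.pop("benchmark", {})
        if "pipelines" in bench:
            bench["pipelines"] = tuple(bench["pipelines"])
        return cls(model=model, benchmark=BenchmarkConfig(**bench), **d)


def run_all(outdir: str | Path, seed: int = 0, config: RunConfig | None = None):
    """Chain simulate -> denoise -> network -> dispersion -> modularity ->
    reconfigure -> benchmark under one master seed, writing every stage.

    All randomness derives from ``seed``; a rerun with the same seed and
    config produces byte-identical output files.
    """
    if config is None:
        config = RunConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    atlas = generate_atlas(
        n_nodes=config.n_nodes,
        n_subnetworks=config.n_subnetworks,
        n_epochs=config.n_epochs,
        seed=seed,
    )
    cohort = generate_cohort(
        config.n_subjects,
        atlas=atlas,
        model=config.model,
        n_frames=config.n_frames,
        tr=config.tr,
        seed=seed + 1,
    )
    manifest = {
        "seed": seed,
        "n_subjects": config.n_subjects,
        "n_nodes": config.n_nodes,
        "n_frames": config.n_frames,
        "tr": config.tr,
        "model": asdict(config.model),
    }
    write_cohort(out / "cohort", cohort, atlas, manifest)

    from dataclasses import replace

    bench = replace(config.benchmark, modularity_seed=seed + 2)
    if config.write_intermediates:
        for name in bench.pipelines:
            pdir = out / "residuals" / name
            pdir.mkdir(parents=True, exist_ok=True)
            residuals = residualize_cohort(cohort, atlas, name, tr=config.tr)
            for s, res in zip(cohort, residuals):
                write_matrix(pdir / f"{s.subject_id}.tsv", res)
            disp = pipeline_dispersion(residuals, bench)
            write_matrix(out / "residuals" / f"{name}_dispersion.tsv", disp)

    report = build_report(cohort, atlas, bench)
    (out / "report.json").write_text(report.to_json())

    rows = []
    for name, entry in report.pipelines.items():
        if entry.get("absent"):
            continue
        row = {"pipeline": name}
        row.update(
            {f"disp_{k}": v for k, v in entry["dispersion_motion"].items()}
        )
        row.update(entry["distance_dependence"])
        for key in ("mean_Q", "sd_Q"):
            if key in entry:
                row[key] = entry[key]
        if "Q_motion" in entry:
            row["Q_motion_r"] = entry["Q_motion"]["r"]
            row["Q_motion_p"] = entry["Q_motion"]["p"]
        rows.append(row)
    pd.DataFrame(rows).to_csv(
        out / "benchmark_summary.tsv", sep="\t", index=False, float_format="%.10g"
    )
    return report
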