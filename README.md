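# dfcbench

Benchmarking confound-regression ("de-noising") pipelines for **dynamic**
resting-state functional connectivity and multilayer network modularity.

Head micromovements — sub-millimeter, frame-to-frame displacements that
survive subject exclusion — contaminate resting-state fMRI connectivity in a
distance-dependent way, and the field's answer is a zoo of nuisance-regression
pipelines (realignment parameters and their Friston expansion, tissue-mean
and local white-matter signals, global signal regression, CompCor components,
despiking).  For *static* connectivity these pipelines have been benchmarked
head-to-head; `dfcbench` provides the analogous evaluation machinery for
*dynamic* (sliding-window, multilayer) connectivity, together with a
synthetic cohort generator so that every stage is testable without restricted
data.

For each pipeline the benchmark computes, per subject:

- a stack of **T = 11** windowed connectivity matrices (20-TR windows, 50%
  overlap, Pearson → negatives zeroed → Fisher z);
- **edge dispersion** C = σ²/μ across windows;
- **multilayer modularity** Q = (1/2μ) Σ [(A_ijl − γP_ijl)δ_lr + δ_ij ω] δ(g_il, g_jr),
  maximized by a generalized Louvain heuristic (γ = 1, ω = 1, repeated
  restarts, Newman–Girvan null per layer);
- node **flexibility** f_i = m/(T−1) and **promiscuity** ψ_i = k/K from the
  resulting partitions;

and, across subjects, the partial correlations of each metric with mean
relative RMS displacement (controlling age and sex), BH-FDR screening,
distance-dependence of the edgewise associations, and pipeline comparisons
(paired t, Steiger's test for dependent correlations).

## Worked example

```python
import dfcbench as d

atlas = d.generate_atlas(60, 6, seed=0)          # 60 nodes, 6 subnetworks
cohort = d.generate_cohort(40, atlas=atlas, seed=1)
report = d.build_report(cohort, atlas, d.BenchmarkConfig(
    pipelines=("RAW", "6P", "36P"),
    n_modularity_iterations=5, modularity_max_subjects=12))
```

Printing the key fields (`examples/05_benchmark_report.py`) gives:

```
pipeline  median|r|   %FDR    r_dd  mean Q  Q-motion r
RAW           0.167    0.1  +0.189   0.229      -0.761
6P            0.117    0.0  +0.137   0.270      -0.557
36P           0.108    0.0  -0.021   0.401      +0.132

RAW vs 36P: paired t = -25.2 (p = 3.4e-120), Steiger z on distance-dependence = 6.4
across pipelines, mean Q vs Q-motion r: r = 1.00
```

Reading: `median|r|` is the residual edge-dispersion–motion association —
without de-noising, motion explains a median partial correlation of 0.17 per
edge; realignment-parameter regression (6P) reduces it and the fully
expanded 36-parameter pipeline with GSR brings it near the null level.
`r_dd` shows the distance-dependence of the artifact disappearing under 36P.
`mean Q` shows subnetworks become *more* identifiable as shared artifact is
removed, and the Q–motion correlation is decoupled from motion only by the
effective pipeline — the same qualitative pattern the benchmark was designed
to detect.  (At this small 40-subject example the FDR screen is already
near zero for all pipelines; the 200-subject acceptance run separates them
more sharply.)

The other example scripts walk through each capability: cohort simulation
(`01`), the pipeline registry and residual orthogonality (`02`), windowing
and dispersion (`03`), multilayer modularity with a brute-force optimality
check (`04`).

A thin CLI mirrors the stages:

```bash
dfcbench simulate --n-subjects 20 --n-nodes 60 --seed 0 --out cohort/
dfcbench denoise --pipeline 36P --cohort cohort/ --out residuals/
dfcbench benchmark --cohort cohort/ --pipelines RAW,6P,36P --out report.json
dfcbench all --seed 0 --out run/        # simulate -> ... -> report, one seed
```

`dfcbench all` is byte-reproducible: the same master seed writes identical
files on every rerun.

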