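"""Apply several confound-regression pipelines to one subject.

Shows regressor assembly (column counts match the pipeline definitions) and
the residual variance left after each pipeline; more aggressive pipelines
remove more variance.
"""

import numpy as np

import dfcbench as d

atlas = d.generate_atlas(60, 6, seed=0)
cohort = d.generate_cohort(3, atlas=atlas, seed=1)
subject = cohort[0]

print(f"{'pipeline':<12} {'columns':>7} {'residual SD':>12}")
for name in ("RAW", "2P", "6P", "9P", "24P", "36P", "36P_DESPIKE",
             "ACOMPCOR", "TCOMPCOR", "WMMEAN", "WMLOCAL"):
    spec = d.PipelineSpec.from_name(name)
    regressors = d.assemble_regressors(subject, spec)
    residual = d.apply_pipeline(subject, spec, node_coords_mm=atlas.coords_mm)
    extra = " + 1/node" if regressors.node_specific is not None else ""
    print(f"{name:<12} {regressors.n_columns:>7}{extra:<9}"
          f"{residual.std():>12.3f}")

# residuals are exactly orthogonal to the band-passed design
spec = d.PipelineSpec.from_name("36P")
residual = d.apply_pipeline(subject, spec)
design = d.bandpass(d.assemble_regressors(subject, spec).matrix, 3.0, axis=0)
design /= np.linalg.norm(design, axis=0)
rn = residual / np.linalg.norm(residual, axis=1, keepdims=True)
print(f"max |residual . regressor| after 36P: {np.abs(rn @ design).max():.2e}")
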