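# Methods

`dfcbench` evaluates participant-level confound-regression ("de-noising")
strategies for *dynamic* resting-state functional connectivity.  Because the
kind of cohort such evaluations are run on (restricted developmental rs-fMRI)
cannot be redistributed, the package pairs the full evaluation machinery with
a synthetic cohort generator that embodies the statistical assumptions the
benchmarks test.  This note documents the generative model, the analysis
pipeline, the numerical choices, and what passing the tests does and does not
establish about real data.

## The analysis pipeline

For each subject, parcel-level signals (n nodes × F frames, TR = 3 s by
default, F = 120) are de-noised by one of a registry of regression pipelines,
then:

1. **Windowing.** The series is cut into T sliding windows of 20 TRs with
   50% overlap (F = 120 → T = 11; trailing partial windows are dropped so
   window lengths are even).  Within each window edges are Pearson
   correlations; negative correlations are set to 0 by default (a `retain`
   policy is available); |r| is clipped at 1 − 10⁻⁶; a Fisher z-transform
   (atanh) is applied.  Zeroing r before or after the transform is equivalent
   because atanh(0) = 0.
2. **Edge dispersion.** Per edge, C = σ²/μ across the T windows, with the
   sample (T − 1) variance by default (a population-variance switch exists,
   since the definition is conventionally written without a denominator).
   Edges with zero variance score 0; under the `retain` policy an edge whose
   window mean is numerically zero (|μ| < 10⁻⁸) while its variance is not is
   also set to 0 and flagged, keeping the matrix shape stable.
3. **Multilayer modularity.** The T window networks are coupled by identity
   edges of weight ω between the same node in *adjacent* windows (ordinal
   coupling).  Multilayer modularity

   Q = (1/2μ) Σ_{ijlr} [(A_ijl − γ_l P_ijl) δ_lr + δ_ij ω_jlr] δ(g_il, g_jr)

   uses the Newman–Girvan null P_ijl = κ_il κ_jl / 2m_l per layer (the
   standard null for this framework; zero-weight layers contribute a zero
   null matrix rather than an error), γ = 1 and ω = 1 by default, and
   2μ = Σ_jl (intralayer strength + interlayer strength).  Maximization is a
   generalized Louvain heuristic on the flattened (nT × nT) supra-modularity
   matrix: greedy single-slot moves (gain tolerance 10⁻¹⁰; among equal-gain
   moves the current community is kept; isolation into an empty community is
   allowed), aggregation, repeat; node sweep order is reshuffled per pass.
   The heuristic is restarted `n_iterations` times (default 100, matching
   common practice for windowed fMRI), iteration i seeded by `seed + i`;
   per-subject Q is the mean over iterations, and every reported Q value is
   recomputed from the labels by the quality function.  A brute-force
   enumerator over set partitions (restricted-growth strings) serves as the
   test oracle for instances with nT ≤ 12.
4. **Reconfiguration.** Node flexibility f_i = m/(T − 1) counts community
   changes between consecutive windows; node promiscuity ψ_i = k_i/K is the
   fraction of communities the node ever joins.  K is the number of distinct
   communities in the *whole* partition (the "total number of communities" is
   ambiguous between per-layer and global counts; the global reading matches
   the promiscuity definition this measure descends from, and a per-layer
   variant is exposed).  Singleton communities are not excluded from K.  Both
   measures are averaged elementwise over the optimization iterations — never
   via a consensus partition — and the global F and Ψ are node means.
5. **Benchmarks.** (a) Per edge (or node, for flexibility/promiscuity), the
   partial correlation between the metric and mean relative RMS displacement,
   controlling age and sex (Pearson on OLS residuals; intercept included; sex
   coded 0/1; two-sided p from t = r√(df/(1 − r²)) with df = n − q − 2), with
   Benjamini–Hochberg FDR at α = 0.05 and uncorrected screening, the median
   |r| and sd(r).  Constant metric units are kept with r = 0, p = 1 and a
   flag so percentages stay comparable across pipelines.  (b) The correlation
   of the edgewise motion association with inter-node Euclidean distance
   (row-major upper-triangle ordering shared by every module).  (c) Mean and
   sd of Q and the Q–motion partial correlation.  (d) Nodewise and global
   reconfiguration–motion associations with per-subnetwork significant
   proportions.  Pipelines are compared with paired t tests on the edgewise
   correlation distributions (unadjusted, as is conventional for these
   supplementary tables; a Bonferroni flag is easy to add at call sites) and
   with Steiger's Z̄* for two dependent correlations sharing the distance
   vector, using the back-transformed mean correlation in the covariance
   term.  Two-sided tests are used throughout; the median |r| is computed
   over all units, not significant ones only.

## Confound-regression registry

| name | regressors |
|---|---|
| RAW | intercept only (demeaned, band-passed) |
| 2P | mean WM, mean CSF |
| 6P | 6 realignment parameters (3 translations, 3 rotations) |
| 9P | 6P + WM + CSF + global signal |
| 24P | [rp6, Δrp6, rp6², (Δrp6)²] |
| 36P | the 24P expansion applied to all 9 columns of 9P |
| 36P_DESPIKE | 36P with despiking before filtering |
| aCOMPCOR | rp6 + Δrp6 + 5 WM PCs + 5 CSF PCs |
| tCOMPCOR | 6 PCs of the top-2%-variance channel pool |
| wmMEAN | rp6 + Δrp6 + mean WM, despiked |
| wmLOCAL | rp6 + Δrp6 + per-node mean of WM channels within 15 mm, despiked |

Any base pipeline accepts a `+GSR` suffix.  ICA-based strategies are out of
scope: they operate on voxel data with trained component classifiers and have
no node-level analogue.

Order of operations: despike (when the pipeline demands it) → band-pass →
OLS.  The temporal derivative is a backward difference with first element 0.
The band-pass is a first-order Butterworth (0.01–0.08 Hz) applied
forward–backward for zero phase — the effective order therefore doubles —
and the *same* filter is applied to every regressor so that regression never
reintroduces out-of-band variance.  Whether despiking precedes or follows
filtering is not fixed by convention; despiking raw data first is the
default here because outlier amplitudes are defined on unfiltered intensity.
Rank-deficient designs drop collinear columns (QR with pivoting) with a
warning and never fail.

**Despiking** fits a running median (kernel 7) per node, measures residuals
against the node's MAD, flags samples beyond 2.5·MAD, and saturates residuals
at ±4·MAD.  The saturation is a hard projection (clip) rather than a smooth
tanh compression: a projection is exactly idempotent — despiking already
despiked data is a no-op — which is the defining property we want from an
outlier-attenuation operator, and both thresholds are exposed as parameters.

**CompCor.**  Channels are standardized, then orthonormal principal-component
time series are extracted by SVD and ordered by explained variance.  The
temporal variant first keeps the top ⌈0.02·q⌉ channels by temporal standard
deviation; the default high-variance pool has 300 channels so that six
components are always extractable.

## The synthetic cohort

The generator's job is to emulate, at the parcel level, exactly the features
the benchmarks are sensitive to; nothing more.

- **Atlas.**  264 nodes by default (the node count of the spherical
  whole-brain parcellation such analyses typically use; one figure source
  says 270 — 264 is followed, and the count is configurable), grouped into
  11 subnetworks whose members scatter (SD 12 mm) around centers inside a
  70 mm sphere, so short edges are preferentially within-system.  A community
  schedule starts at the subnetwork partition and reassigns 20% of nodes
  between consecutive epochs (3 epochs over the scan), giving the windows
  detectable, time-varying structure.
- **Clean signals.**  x_i(t) = √ρ_out·g(t) + √(ρ_in − ρ_out)·h_{c(i,t)}(t) +
  √(1 − ρ_in)·ε_i(t), all factors band-limited (white noise → AR(1), default
  0.3 → the same 0.01–0.08 Hz Butterworth → standardized), which yields
  within-community correlation ρ_in (default 0.4) and between-community
  correlation ρ_out (default 0.05) within each epoch.  A shared unit-variance
  drift scaled by `global_drift_sd` (default 0.3) represents slow
  scanner/physiological fluctuation; it belongs to the *clean* signal (it is
  motion-independent — it is what GSR removes even in null data).
- **Motion.**  Framewise relative RMS displacement is a lognormal baseline
  (σ = 0.6) rescaled to a per-subject target and capped below the 0.25 mm
  spike threshold, plus Bernoulli spikes of 0.26–0.45 mm (rate 0.02/frame,
  at most 20, so every simulated subject passes the inclusion rule: mean
  ≤ 0.2 mm and ≤ 20 supra-threshold frames).  Cohort targets are lognormal
  around 0.065 mm (clipped to 0.02–0.18 mm), matching the ~0.07 mm scale of
  micromovement-only samples.  Translations integrate the displacement along
  a slowly wandering direction, so ‖Δtranslation(t)‖ reproduces the stated
  framewise series exactly.  Rotations carry a slow drift plus fast estimate
  jitter whose amplitude scales with subject motion; real realignment
  estimates are noisier in movers, and this jitter is what gives the motion
  parameters in-band content.  Ages are uniform on 8–22 years, sex is
  balanced, and a Gaussian copula couples age to the motion target at
  `age_motion_r` (default −0.3: younger subjects move more), so covariate
  adjustment is genuinely exercised.
- **Artifact.**  contaminated_i = clean_i + β·w_i·u(t) with
  u(t) = FD(t)·(1 + 0.7·η(t)) + 1.5·⟨FD⟩·m(t), where η is band-limited noise
  shared across nodes and m is a standardized mix of the band-passed rotation
  estimates; w_i sums exponential kernels exp(−d/λ) around 5 random source
  locations (λ = 40 mm), normalized to mean 1, so contamination decays with
  distance from the sources and short-range edges are preferentially
  inflated.  The m-term is *exactly* spanned by the realignment parameters —
  the classic reason realignment regression is partially effective on real
  data — while the FD-modulated terms are not, so 6P/24P remove part of the
  artifact and tissue-based pipelines remove essentially all of it.  The
  default gain β = 4 per mm puts the shared artifact at roughly a sixth of
  signal SD for an average mover: strong enough that the
  contaminated/cleaned contrast is unambiguous at cohort sizes of a couple
  hundred, yet below the regime where windowed correlations saturate.
  Saturation matters: at substantially higher gains the raw data's edgewise
  motion associations compress toward a ceiling, which scrambles their
  distance structure and makes the distance-dependence comparison between
  pipelines unstable from atlas to atlas; at β = 4 both the association
  magnitudes and their distance-dependence shrink monotonically along the
  no-regression → 6P → 36P axis for essentially every seed.  β = 0 returns
  the clean signals bit-for-bit.
- **Nuisance channels** emulate measured tissue signals: the exact node-mean
  (global), 20 CSF-like channels (gain 0.8–1.6 on u plus noise), 30 WM-like
  channels with coordinates (kernel-weighted u plus noise — these make the
  15 mm local-WM rule meaningful), and a 300-channel high-variance pool in
  which a random 10% carry strong artifact (what tCOMPCOR's variance
  screening should find).
- **Seeding.**  All randomness flows from one cohort seed through derived
  per-subject seeds; the full simulate-to-report runner writes byte-identical
  output on reruns with the same master seed.

### What the generator reproduces — and what it does not

Emergent, not hard-coded, behaviors that mirror the motivating empirical
findings: GSR-bearing and tissue-based pipelines (9P/36P/2P) essentially
null the dispersion–motion association while realignment-only pipelines
(6P/24P) reduce it partially; wmLOCAL performs poorly; mean Q is lowest for
realignment-only pipelines and highest for expanded GSR pipelines; Q–motion
correlations are negative and are shrunk by effective pipelines; and the
pipelines that identify subnetworks best are the ones that decouple Q from
motion (cross-pipeline correlation ≈ 0.9).

Two directional facts deserve comment.  First, under this generator the
dispersion–motion correlation is predominantly *negative*: the shared
artifact inflates the window-mean connectivity, which is the denominator of
C = σ²/μ, and the mean channel dominates the variance channel at 20-frame
windows.  The benchmarks compare |r| magnitudes, so this sign carries no
weight in any ordering.  Second, the distance-dependence r_dd is therefore
*positive* for poorly de-noised data (short edges acquire the more negative
dispersion–motion correlations) — the same sign the real-data benchmark
reports for its weak pipelines (up to +0.18), with GSR pipelines near zero.

Not modeled: voxel-level imaging physics, hemodynamic convolution,
physiological (cardiac/respiratory) cycles, scanner drifts beyond a single
shared low-frequency component, and any coupling between head motion and
true neural state.  Passing the suite therefore shows the *machinery* is
correct and the benchmarks are calibrated (null cohorts reject at or below
nominal rates); it does not certify any pipeline's behavior on real fMRI.

## Numerical choices and degenerate inputs

- Perfect correlations are clipped at 1 − 10⁻⁶ before atanh (z ≈ 7.25).
- Zero-variance nodes in a window produce zero edges with a warning.
- Louvain convergence: no move with gain > 10⁻¹⁰; labels canonicalized by
  first appearance for reproducible serialization.
- Partial correlations with degenerate residual variance return r = 0, p = 1
  and a flag; paired t with zero-variance nonzero differences returns ±∞
  with a flag semantics of p = 0; the Steiger test requires |r| < 1 and
  n > 10.
- The Q identifiability contrast (planted vs structureless cohorts) is run at
  ρ_in = 0.6 with the drift off.  At the default ρ_in = 0.4 the Louvain
  heuristic extracts ≈ 0.30 of spurious modularity from window-estimation
  noise and the planted contribution is masked (measured 0.294 planted vs
  0.309 structureless at 60 nodes); at ρ_in = 0.6 the separation is genuine
  and grows with ρ_in.  This masking is a property of short-window modularity
  worth knowing about in its own right.

## Problem sizes

The shipped benchmark configurations are scaled for a desk run: cohorts of
100–200 subjects at 60–100 nodes for the dispersion/FDR/distance benchmarks,
6–16 subjects at 60 nodes with 3–10 Louvain restarts for the modularity
benchmarks, and 1000 Monte-Carlo draws at 500 edges for the Steiger
calibration.  `ModularityParams` itself defaults to the conventional 100
iterations; the report configuration (`BenchmarkConfig`) chooses smaller
restart counts because the Q summaries stabilize well before 100 restarts at
these network sizes.
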