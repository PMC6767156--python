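# Methods

This note records the statistical model, the synthetic-data design, the
numerical choices and the known limitations of `rvatlas`, in the spirit of
a package methods appendix. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Surface representation and coordinates

The cohort lives on a single corresponded triangulated RV-wall surface in
millimetres. Landmarks are an apex vertex and the tricuspid-annulus ring;
the ventricular long axis runs from the annulus-ring centroid (base) to the
apex. Each vertex's **base-to-apex fraction** is its scalar projection onto
this axis, clipped to [0, 1]; "distance from apex" is the axial-projection
distance (1 − fraction) × axis length, *not* a surface geodesic. The
geodesic alternative would be larger on a curved wall; the projection was
chosen because the marker location is ultimately specified on a straight
annulus–apex line in a 2D imaging plane, where a chord measurement is what
an operator would take.

Patch areas use a deterministic face-apportionment rule: a triangle
contributes its full area iff all three of its vertices are in the subset.
The same rule produces the total-area denominator (trivially, every face),
so patch fraction is internally consistent. The alternative (1/3 of each
face per member vertex) counts boundary faces partially; it was noted and
not used. Under the all-three rule a patch's reported area slightly
undercounts its nominal geodesic-disc area because boundary faces are
dropped — the planted-patch radius default below already accounts for this.

The four-chamber plane is stored as (point, unit normal). In the synthetic
mesh it is the plane containing the long axis and the freewall–septum
bisector; users with real data must supply their own. Vertices "coincide"
with the plane within a tolerance of 2 mm by default — one in-plane
acquisition voxel of the emulated imaging protocol — configurable.

## Motion decomposition

Excursion vectors (ES − ED per vertex) are decomposed in a per-vertex
orthonormal triad: longitudinal (unit base→apex direction), circumferential
(tangent to the circle about the long axis through the vertex), transverse
(radial; the cross product of the other two). Vertices on the axis (the
apex pole) get an arbitrary perpendicular and are flagged; they are
excluded from any equivariance reasoning.

Directional **composition percentages** of a region are mean *absolute*
projections over region vertices and subjects, normalised to sum to 100.
Mean absolute projection (rather than a variance share) was chosen because
the contributions are reported as positive fractions of motion magnitude;
with fixed per-vertex direction fields the two definitions order components
identically.

## Synthetic cohort generator

The generator is first-class, tested code; it defines the study conditions
under which the pipeline's operating characteristics are demonstrated.

* **Mesh** — open half prolate spheroid (apex pole to annulus rim),
  axis 70 mm, radius 25 mm (total surface ≈ 90 cm², similar to an adult
  RV-wall surface), triangulated on latitude rings; ~1000 vertices at desk
  scale, scalable toward the full-resolution surface (~11k vertices).
* **Covariates** — age ~ U(19, 72) y; sex ~ Bernoulli(0.55) (1 = female);
  BSA ~ N(1.80, 0.15²) m²; race multinomial (75% Caucasian, 12% Asian, 5%
  Afro-Caribbean, 3% African, 3% Other, 2% Chinese) — healthy-volunteer
  baseline ranges.
* **RVEF** — truncated normal, mean 57%, SD 7.4% (IQR ≈ 52–62), bounds
  [40, 73]; EDV ~ N(140, 25²) ml clipped to a physiological range, so
  RVEF·EDV/100 is a plausible stroke volume.
* **Signal patch** — geodesic disc (graph geodesics over mesh edges) of
  radius 20 mm centred on the basal freewall where the four-chamber plane
  crosses it, 43% of the way from base to apex: ≈ 7.3 cm², ≈ 8% of the
  surface, ~70 vertices at desk scale.
* **Excursion** — baseline ramps linearly from 4 mm at the apex to 10 mm at
  the base (freewall function increases apex-to-base); patch vertices add
  γ·z(RVEF) where γ = σ·ρ/√(1−ρ²) converts the configured standardised
  partial effect ρ (default 0.3) against the residual noise SD σ; age and
  sex shift all vertices (−0.4 mm/SD and +0.4 mm respectively; BSA and race
  0, so covariate-adjustment has something real to remove and the
  qualitative covariate pattern — age and sex matter, race and BSA do not —
  is reproducible); residual noise is Gaussian with a squared-exponential
  spatial kernel, SD 1.5 mm, correlation length 10 mm (the emulated study
  is silent on residual spatial correlation; 10 mm makes false-positive
  clusters realistically contiguous rather than salt-and-pepper).
* **Directions** — per-vertex unit vectors mixing the triad with L1 weights;
  inside the patch the weights are transverse 0.38 / longitudinal 0.35 /
  circumferential 0.27 (the emulated patch composition); elsewhere the
  longitudinal share ramps from 0.25 at the apex to 0.45 at the base with
  the remainder split in the patch ratio.
* **Markers** — (SPM-O, SFD-F, TAPSE-F, TAPSE, SFD) drawn jointly with the
  latent RVEF score from a Gaussian copula whose RVEF correlations are
  fixed at 0.44 / 0.43 / 0.40 / 0.24 / 0.22. Inter-marker correlations are
  plausible-by-construction (raw and fractional forms of the same measure
  0.75, same-axis pairs 0.35–0.60, SPM-O 0.40–0.50 with all), chosen once
  to make the joint matrix positive definite; the config validates
  positive-semi-definiteness before sampling. Marker scales are plausible
  healthy-adult values (e.g. TAPSE 22 ± 3.5 mm); scale does not affect any
  correlation-based analysis.
* **Repeat scans** — replicate = original + independent Gaussian noise:
  0.6 mm per-vertex excursion, 3 ml EDV, 0.7 EF points. The excursion value
  follows from requiring an emulated pointwise test–retest ICC near 0.93
  given the generator's between-subject variance; volume noise similarly
  targets ICC ≈ 0.99.
* **Seeding** — one global seed drives all sub-streams through
  `numpy.random.SeedSequence.spawn` (covariates, RVEF, markers, noise,
  volumes), so a dataset is a pure function of (config, seed).

What the generator does **not** emulate: per-subject anatomy (ED geometry is
the atlas mesh for every subject), image formation and segmentation error
beyond additive replicate noise, multi-phase trajectories (only ED→ES),
regional wall-motion abnormalities, and non-linear marker–covariate
relationships. Passing tests therefore demonstrate the pipeline's
statistical operating characteristics — error control, recovery of planted
structure, estimator correctness — not clinical performance on real CMR.

## Discovery statistics

All continuous variables are z-scored; race is dummy-coded against the
largest observed class, and dummies for levels absent from a (small) sample
are dropped with a warning. Per-vertex slopes and t-statistics are computed
through the Frisch–Waugh–Lovell decomposition (residualise the outcome and
every excursion column against the covariate block once), which is
algebraically identical to refitting the full model per vertex and is what
makes 10⁴ permutations × 10³ vertices tractable; the equivalence is pinned
by a normal-equations oracle in the tests. A vertex whose excursion is
constant has an undefined statistic: t = 0, permutation p = 1 by
convention. An exact fit (zero residual variance with nonzero slope) maps
to t = ±∞ so the extreme-case permutation p is 1/(n_perm + 1).

Permutation inference is **Freedman–Lane**: fit RVEF ~ covariates, permute
the residuals, rebuild pseudo-outcomes, recompute the excursion t per
vertex; one shared permutation sequence across vertices preserves the
spatial dependence of the null field. The scheme was chosen (over permuting
raw outcomes) because the null must respect covariates. p = (1 + #{|t*| ≥
|t|})/(1 + n_perm). BH-FDR is applied across vertices
(`statsmodels.multipletests`, pinned against a hand step-up computation in
the tests); α = 0.05.

The significant mask is reduced to connected components under mesh
adjacency; the **largest-area component** is the patch (a single distinct
contiguous region is the expected outcome and no multi-component rule is
needed; all components are reported in a sidecar). An empty mask returns an
explicit empty-patch result, not an exception.

Bootstrap CIs (percentile, 2.5–97.5) resample subjects from the
once-standardised design — standardisation is not re-estimated inside each
resample — keeping the resampled fits comparable and the procedure exactly
replayable.

## Marker derivation

PCA operates on the column-centred but **unscaled** patch matrix: columns
share units (mm) and rescaling would inflate low-variance vertices. PC1's
sign is fixed so its score correlates positively with mean patch excursion.
Only PC1 is retained, deliberately conservative and directly comparable to
single-variable markers. Reconstruction correlations are per-vertex Pearson
correlations between the rank-1 reconstruction and the original column;
constant columns are flagged NaN and excluded from selection. Marker
candidates are restricted to patch ∩ plane vertices; ties in the
reconstruction correlation break to the smaller vertex index for
determinism. The marker's fractional form divides by the subject's ED
annulus-centroid→apex chord length (the fraction is measured along this
chord, matching how an operator would place the point on a 2D view). Note
the marker measures *displacement*, not deformation: a rigid translation of
the whole ventricle registers in full.

## Validation statistics

* **Steiger test** — Z̄₁* variant for two dependent correlations sharing one
  variable: Fisher-transform both, evaluate the covariance term at the
  back-transformed mean correlation r̄,
  ψ = r_kh(1−2r̄²) − r̄²(1−2r̄²−r_kh²)/2, c = ψ/(1−r̄²)²,
  Z = (z_jk−z_jh)·√((n−3)/(2−2c)). Monte-Carlo null calibration at n = 100
  is part of the acceptance suite.
* **Variance partitioning** — last-entry incremental R² (squared
  semi-partial) per term, race as a block. Fractions are non-negative and
  their sum is bounded by 1 in practice but is not forced to equal R².
* **Model comparison** — the two covariate-adjusted models are stacked with
  a model-type indicator and a marker × indicator interaction; the OLS
  p-value of the interaction is reported. Subjects appear in both halves of
  the stack, so the test is the standard pragmatic "model type as an
  additional covariate" comparison rather than an exact inference.
* **Leave-one-out** — each subject's RVEF is predicted from a model refitted
  on the remaining subjects; covariates are included by default
  (`marker_only=False` flag available). Standardisation uses the full
  sample, keeping the loop exactly equal to the closed-form case-deletion
  (hat-matrix) formula, which the tests exploit as an oracle. Absolute
  errors are reported in EF points and converted to ml as |ΔEF|/100 × the
  subject's EDV — an EF error is dimensionless, so the ml form necessarily
  involves a volume scale, and the subject's own EDV is the natural one;
  this interpretation is a package choice and is flagged here.
* **ICC** — ICC(2,1), single-measure, two-way random effects, absolute
  agreement, from the ANOVA mean squares; zero between-subject variance
  returns 0 with a warning. The pointwise-excursion reliability of a
  surface is the **mean** of per-vertex ICCs (one number is reported for
  thousands of vertices and no aggregation is canonical; the mean was
  chosen over the median and documented here).

## Problem sizes and numerical settings

Desk-scale defaults used by the analysis scripts and the acceptance script:
300 subjects per cohort, ~1000 mesh vertices, 999 permutations, 1000
bootstrap replicates; production-scale defaults inside the library are
10,000 permutations/bootstraps, reducible everywhere. Permutation and
bootstrap loops are chunked (500 permutations / 200 resamples per block) to
bound memory at full resolution. Spatial-noise generation Cholesky-factorises
the vertex kernel once per mesh and reuses it across replicate cohorts.
Tolerances: triad orthonormality and recomposition 1e-9; oracle equivalence
in tests 1e-8–1e-12 depending on conditioning; plane membership 2 mm.

## Known limitations

* The discovery arm tests association vertex-by-vertex; no cluster-mass or
  threshold-free cluster enhancement inference is provided.
* Adjacent-vertex dependence is handled in inference (shared permutations,
  FDR) but effect sizes are not spatially smoothed or pooled.
* The end-to-end empirical claims are demonstrated on the generator's
  stated conditions only; performance under violated assumptions
  (non-linear coupling, heteroscedastic noise, regional dysfunction) is
  untested by design.
* The CLI `discover` path reads excursion tables without motion vectors, so
  directional composition is only available when motion vectors exist (the
  library path or `CohortDataset.motion`).
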