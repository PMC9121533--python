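# Methods

This note documents the models, defaults, numerical choices and limitations of
`aslquant`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Physiological calibration

Arterial oxygen content is the hemoglobin-binding plus dissolved-oxygen form
CaO₂ = 1.34·Hb·SaO₂ + 0.003·pO₂ (Hb in g/dL, saturation as a fraction, pO₂
defaulting to 100 Torr for room air). The textbook statement of the formula
pairs percent saturation with a 1/100 binding-term scale; holding saturation
as a fraction cancels both factors, which is why the implementation stores
SpO₂ internally as a fraction and rejects percent-scale inputs outright
rather than rescaling them — the single most common unit bug in this
calculation.

Blood T1 at 3 T is dominated by hematocrit (relaxation rate rises roughly
linearly with Hct) with a smaller oxygenation effect. The default calibration
is the affine relaxation-rate model

    1/T1_blood = a + b·Hct + c·(1 − SpO₂)

with c = 0.2 s⁻¹ fixed as a small positive deoxygenation term and (a, b) =
(0.40269, 0.39094) s⁻¹ solved so that two representative operating points are
interpolated exactly: an anemic subject (Hct 0.24, SpO₂ 0.97 → 1.99 s) and a
healthy one (Hct 0.41, SpO₂ 0.99 → 1.77 s). The coefficient set is a
pluggable `T1BloodCalibration`; any laboratory with its own calibration can
substitute it. Estimates outside a configurable physiological window
(default [1.3, 2.6] s) raise a calibration error rather than propagate.

Cohort-level imputation follows fixed substitution rules: missing patient
hemoglobin ← patient-group mean; missing control SpO₂ ← control-group mean;
missing control Hb/Hct ← a configurable age/sex reference table (controls may
lack blood draws entirely). Every imputed cell is flagged; observed values
are never altered.

## Signal models

Single-delay pCASL uses the consensus quantification equation and its exact
algebraic inverse as the simulation forward model, so
quantify∘forward = identity to machine precision is a tested invariant.
Negative difference signal maps to negative CBF on purpose — masking and ROI
policy live downstream, not inside the arithmetic. No correction is applied
for the proton-density scan's 4000 ms repetition time; M0 is taken as
acquired, which is a pure scaling caveat on absolute units.

The pulsed-label general kinetic model is implemented in a single unified
expression: ΔM(t) = 2·M0b·f·α·e^(−t/T1app)·e^(−k·Δt)·d·φ(k·d), where
d = clip(t−Δt, 0, τ) is the delivered bolus duration and φ(x) = (1−e^(−x))/x.
This form is continuous at both regime boundaries by construction and
degrades smoothly to the k → 0 limit (T1_blood = T1app); below |k·d| < 1e−8
the φ series 1 − x/2 + x²/6 avoids 0/0. Blood magnetisation defaults to
M0b = M0_tissue/λ (configurable). CBF crosses the unit boundary exactly once:
maps and ROI means are in mL/100g/min, the model-internal flow f = CBF/6000
in mL/g/s.

An independent oracle, `pasl_kinetic_numeric`, evaluates the same
delivery–residue–decay convolution by adaptive quadrature (box-car arterial
input α·e^(−s/T1b) on [Δt, Δt+τ), residue e^(−f·u/λ), decay e^(−u/T1t)).
Closed form and oracle agree to < 1e−6 relative error over random parameter
draws spanning tissue and venous regimes; this dual route is exercised in the
tests and the acceptance script, never collapsed onto one implementation.

Venous voxels are fitted with the same arterial kinetic model. Labelled water
in a draining vein has not necessarily exchanged with tissue, so fitted sinus
values are interpreted as relative quantities throughout; this is also why
T1_tissue defaults to 1.9 s — a blood-like value chosen for consistency with
the venous target rather than a gray-matter literature value — and is
configurable.

## Fitting

MultiTI fitting minimises Σ_TI (ΔM_obs − ΔM_model)² per voxel over (CBF, BAT)
with bounds CBF ∈ [0, 3000] mL/100g/min — wide enough for the extreme venous
apparent flows, where estimates in the low thousands are physically
meaningful readouts of shunting — and BAT ∈ [0, max TI]. The objective is
multi-modal in BAT at low SNR, so the fit is multi-started over a BAT grid
(default: every acquired TI). Each start is scored by a projected-CBF
initialisation: the data are projected onto a reference-flow template (the
curve is nearly linear in CBF; flow enters the shape only through T1app),
refined once at the projected flow. The best-scoring starts (default 2) are
polished by bounded trust-region least squares (`scipy.optimize.least_squares`,
trf, xtol = ftol = 1e−12). Because trust-region descent never increases the
cost from its starting point, the winner's RSS is bounded by every start's
initialisation RSS — a tested invariant. Ties break toward the smallest BAT
(earliest physically plausible arrival). Voxels with fewer than 3
above-noise-floor samples are not fitted (a 2-parameter model needs ≥ 3
informative points); optimizer failure at a voxel flags it non-converged and
the pipeline continues. BAT is reported only where the fit converged, and
all optimizer settings are written to the map's provenance record.

## Preprocessing

Background noise is measured in four width-5 squares at the in-plane corners
of the field of view, pooled over all slices and volumes — the corners are
where EPI ghost-free air reliably sits, and pooling is the default because
per-slice statistics at width 5 are noisy (a per-volume option exists).
Reliability requires a voxel's difference signal to be *strictly* greater
than mean + 1·SD on at least one volume; ties are excluded (the threshold
multiplier is configurable). Motion correction is out of scope (inputs are
assumed co-registered); a QC hook flags series whose volume-to-volume
centre-of-mass drift exceeds a caller-chosen limit, mirroring an
exclude-on-motion policy without re-implementing registration.

## Regions of interest

Gray/white-matter and sinus masks are inputs (anatomical segmentation and
atlas registration are external). Each anatomical mask is eroded with a
width-2 cubic box against partial-volume contamination. An even box has no
central voxel; the convention here is scipy's (offsets {−1, 0} per axis), so
a solid cube of side n erodes to side n−1 — documented because the width-2
origin is genuinely ambiguous. The high-signal sinus ROI thresholds the
*unmasked* singleTI CBF map at the 90th percentile
(linear-interpolation definition, inclusive ≥ comparison) of finite values
inside the sinus mask, and is then applied to all maps including multiTI CBF
and BAT — the singleTI map defines the ROI once per subject. Only
finite-valued voxels enter the percentile, and each ROI mean reports its
coverage (fraction of ROI voxels with finite map values), because partial
imaging coverage of the sinus is the norm in real acquisitions.

## Synthetic data

The image-level phantom is three compartments extruded along z: a white-matter
disc (radius 5 voxels) inside a gray-matter annulus (outer radius 9) and a
posterior midline sinus tube (radius 2), on a grid whose four in-plane
corner squares (width 5) are guaranteed background on every slice — so the
background-statistics stage measures exactly the planted noise. Difference
images are simulated directly from the forward models plus i.i.d. Gaussian
noise (homoscedastic per series): raw control/label pairs, background
suppression, motion, ghosting and partial-volume mixing are *not* modelled.
Passing tests therefore demonstrate correctness of the quantification,
masking, ROI and statistics machinery under the stated noise model — not
robustness to artifacts that real data contain.

The cohort level plants the statistical structure the analysis stage is
meant to detect, with defaults describing a pediatric/young-adult SCA cohort
(n = 90) versus controls (n = 40): patients have lower Hb/Hct/SpO₂ (hence
lower CaO₂ and longer T1-blood), higher CBF in all regions, shorter
gray/white-matter BAT, and longer, more variable sinus BAT. Gaussian features
carry configured mean (SD); right-skewed features (sinus CBF and BAT, SCI
burden) are lognormal with log-scale SD = ln(q3/q1)/(2·0.6745) from their
configured quartiles. Within patients, CBF is negatively coupled to CaO₂
(planted r = −0.45 in tissue, −0.40 in the sinus on the log scale; BAT
positively coupled in tissue, uncoupled in the sinus), implemented as
slope = r·σ_y/σ_x with the residual SD shrunk so marginal SDs stay at their
configured values. Cognitive scores in patients are linear in the planted
hemodynamic predictors (IQ on log sinus CBF with slope −3.94; processing
speed on white-matter CBF; tower-task scores on log sinus CBF and log
white-matter BAT) plus covariate effects and Gaussian noise whose SD is set
analytically so the marginal SDs match the configured group SDs. The
simulation noise levels were chosen so cohort summaries sit at realistic
magnitudes; they are configuration, not estimates. `CohortSpec.null()`
removes every between-group difference and coupling while keeping the noise
(a zero-noise cohort would have constant features and degenerate tests) and
is the basis of the type-I calibration checks. Each subject draws from an
independent stream seeded by (cohort seed, subject index, stage), so any
subject is reproducible in isolation and tables regenerate byte-identically.

## Statistics

Normality is assessed per group by Shapiro-Wilk at α = 0.05; the
nonparametric branch (Mann-Whitney U, rank-biserial effect size) is taken if
either group rejects, the parametric branch (Student's pooled-variance t,
Cohen's d) otherwise. Age/sex adjustment is OLS residualisation plus the
grand mean — preserving units and scale for correlation and plotting —
rather than covariates-in-model (the alternative is available through the
regression interface). Non-normal variables are natural-log-transformed
before parametric use. Benjamini-Hochberg FDR is applied independently
within each (group × parameter-map family) stratum, the families being
singleTI CBF, multiTI CBF and multiTI BAT; the implementation delegates to
`statsmodels` and is tested against a brute-force step-up oracle. Cognition
models are OLS with pre-selected covariates (age, sex, hydroxycarbamide,
chronic transfusion, SCI burden, intracranial volume, education decile),
complete cases per model, gated on an unadjusted univariate p < 0.1
(overridable; the gate decision is recorded but deliberately not itself
corrected for selection). Each term reports b, standardised β = b·σ_x/σ_y,
95% CI, p, and partial r = t/√(t² + df).

## Problem sizes

The default imaging sub-cohort in `run_pipeline` is 6 SCA + 4 control
subjects on a 32×32×8 grid, with the multiTI fit restricted to reliable
voxels inside the analysis ROIs — image-level simulation is per-voxel
expensive and a small sub-cohort exercises every stage. Study-scale
statistical validation (n = 90/40, replicate loops for CI coverage and
type-I calibration) runs on the tabular cohort generator, which is the level
at which those properties are defined. The acceptance script uses 500 noisy
voxels for fit-recovery medians, 100 replicate cohorts for regression-CI
coverage, and 200 null cohorts for the false-positive rate.

## Limitations

- Single-compartment kinetic model only; no dispersion kernel, no
  partial-volume correction, no multi-compartment exchange.
- No methemoglobin term in the T1-blood calibration.
- The simulator's clean-difference-image assumption means registration,
  ghosting and background-suppression effects are untested here.
- Absolute multiTI CBF depends on the blood-like T1_tissue choice; values in
  tissue ROIs are best read as relative, and correlation-based conclusions
  are insensitive to this scaling.
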