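# Methods

This note documents the models implemented in `hqbold`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical choices that matter for reproducing results.

## Oxygen transport model

Arterial oxygen content follows CaO₂ = φ[Hb]·SaO₂ + ε·PaO₂ with
φ = 1.34 mLO₂ g⁻¹, [Hb] = 15 g dl⁻¹ and ε = 0.0031 mLO₂ dl⁻¹ mmHg⁻¹;
saturations come from the Severinghaus empirical dissociation curve
S(p) = (23400·(p³+150p)⁻¹ + 1)⁻¹. The metabolically extracted content is
defined as CmetO₂ = OEF · CaO₂(normoxia) — the standard definition of the
extraction fraction, which reproduces SvO₂ ≈ SaO₂(1−OEF) at normoxia — and
is held fixed across gas conditions, so hyperoxia raises the venous
saturation. Venous pO₂ is solved from the content balance with the plasma
term retained (Brent's method on (0.1, 5000) mmHg, tolerance 1e-9 mmHg);
under hyperoxia the dissolved term is the driver of the venous change, so
dropping it would bias δBOLD noticeably. Capillary saturation is the
weighted sum ScO₂ = κ·SaO₂ + (1−κ)·SvO₂ with κ = 0.4 (venous-weighted).
No temperature/pH (Bohr) corrections are applied.

## Signal models

**Analytic static dephasing.** A compartment of randomly oriented vessels
with characteristic frequency δω = γ(4/3)πΔχ₀·Hct·(1−Y)·B₀ attenuates the
extravascular signal by exp(−vf·fc(δω·t)). For the ASE estimator's two-
regime structure we use the quadratic short-τ form 0.3·vf·(δω·τ)² for
τ ≤ 15 ms and the linear form vf·(δω·τ − 1) beyond, matching exactly the
model the linear system fits (hence noiseless round trips are exact). For
gradient-echo δBOLD the full isotropic-cylinder decay function fc(u) is
evaluated by 160-point Gauss–Legendre quadrature of
(1/3)∫₀¹ (2+x)√(1−x)(1−J₀(1.5ux))/x² dx, which is smooth and monotone with
the correct 0.3u² and u−1 limits; the piecewise form would introduce a
spurious jump as compartments cross the regime boundary between gas
conditions. Susceptibility uses the cgs convention in which
Δχ₀ = 0.264×10⁻⁶ per unit Hct and the cylinder field carries a 2π factor;
γ = 2.675×10⁸ rad s⁻¹ T⁻¹, B₀ = 3 T.

**Monte Carlo vascular dephasing.** Protons perform a Gaussian random walk
(D = 1.0 μm² ms⁻¹, dt = 0.1 ms) and accumulate phase from the dipole field
of randomly oriented infinite cylinders
(2πγΔχB₀·(R/ρ)²·sin²θ·cos2φ outside; uniform offset inside). Each proton
owns an independent environment: cylinders with uniform axis density inside
a sphere of radius 30R around the proton's start, added until the target
volume fraction (3%) is reached (≈ 27 cylinders). This samples the field
distribution of a dilute suspension without periodic-boundary artefacts;
the 30R cutoff loses a small fraction of the far-field dephasing, visible
as a few-percent excess in long-τ slopes against the analytic limit.
Protons that start intravascular are excluded from the signal (the qBOLD
model is extravascular; FLAIR/long TE suppress blood in the acquisitions
being modelled). Two accelerations make the 1000-state sweep cheap while
changing nothing statistically: phases are stored per unit susceptibility
(the field is strictly linear in Δχ, so one trajectory set rescales exactly
to any Hct/saturation), and log-attenuations scale linearly with volume
fraction from the simulated reference (the dilute-vessel limit). Cumulative
phases are checkpointed every 2 ms, supporting ASE τ on a 4-ms raster
(refocusing at (TE−τ)/2, TE = 80 ms) and gradient-echo TE on a 2-ms raster;
protocol times off the raster (τ step 3 ms, TE 35 ms) are linearly
interpolated, mirroring how the acquisitions are matched to the simulation
grids. Default tissue: capillaries of radius 3 μm carrying ScO₂ and volume
CBVt−DBV, venous vessels of radius 30 μm carrying SvO₂ and volume DBV —
"DBV" throughout means the venous volume. Defaults: 10 000 protons per
radius (8000 in the acceptance script, 6000 in the test fixture), seedable
and deterministic.

## Estimators

- **sqBOLD**: ordinary least squares on rows [0,0,1] (τ = 0) and
  [1, −τ, 1] (τ > 15 ms) against log-signals; τ in 3–12 ms (transition
  regime) is never fitted. R2′ from this system equals the long-τ
  log-linear fit exactly, which is why sqBOLD and hqBOLD share R2′.
- **δBOLD GLM**: the petO₂ trace is interpolated to the volume grid (TR
  1 s) and smoothed with a 10-s moving average (reflected edges,
  mean-preserving); the series is regressed on the centered regressor and
  the response is normalized by the fitted signal at the baseline plateau,
  scaled by the regressor's baseline→hyperoxia plateau difference (windows:
  volumes 1–100 baseline; 175–225 and 415–465 hyperoxia). ΔpetO₂ from the
  same windows is used as ΔPaO₂.
- **Heuristic DBV**: DBV = (A/TE+B)(C/ΔPaO₂+D)·δBOLD with A = 27 ms,
  B = 0.2, C = 245.1 mmHg, D = 0.1; output in the units of δBOLD.
- **OEF**: R2′/(k·DBV) with k evaluated at the analysis hematocrit 0.34
  regardless of the (unknown in practice) true hematocrit. Voxels are not
  clipped: negative DBV yields NaN by default, or a signed OEF when the
  noise-propagation behaviour of the quotient is itself under study.
- **TRUST**: pairwise control−tag subtraction, repeat averaging, ROI = the
  4 highest-signal voxels at eTE 0 (ties broken toward the lowest linear
  index), log-linear fit of ΔS over eTE ∈ {0,40,80,160} ms,
  T2b = 1/(1/T1b − C) with T1b = 1624 ms, and inversion of a quadratic
  1/T2b(1−Y) calibration at Hct 0.42. The default calibration coefficients
  follow the published 3 T (τ_CPMG = 10 ms) model; they are configurable,
  and every internal consistency check (round trips, phantom recovery) uses
  whatever model is configured, so results do not hinge on the defaults.

## Simulation studies

**Systematic-error sweep.** 1000 states drawn uniformly: CBVt 0–10%, DBV
0–5.7% (pairs violating DBV ≤ CBVt are redrawn), OEF 0–100%, Hct 31–43%,
PaO₂ 100–130 (normoxia) and 370–450 mmHg (hyperoxia). Noiseless ASE and
condition-level BOLD signals are generated (δBOLD from the two single
estimates), all estimators run, and estimates are regressed on truth (true
R2′ from the venous DBV and the sampled Hct), over the full range and
restricted to OEF > 30%. The analytic forward route recovers its generator
exactly (slope 1); the Monte Carlo route exhibits the diffusion-driven
DBV_sqBOLD inflation that motivates the method.

**Noise study.** At the standard state (CBVt 5%, DBV 2.3%, OEF 40%, Hct
34%, PaO₂ 110→400 mmHg) the signals are generated once and Gaussian noise
is added per repetition (20 000 repetitions): to every τ-image of the ASE
series (σ = S(τ=0)/SNR_ASE) and to the two condition-level BOLD estimates
(σ = S_norm/SNR_BOLD). No canonical SNR values exist; since symmetric noise
leaves the estimator medians essentially at their systematic values, the
defaults SNR_ASE = 30 and SNR_BOLD = 100 were calibrated to reproduce the
in-vivo voxelwise DBV interquartile ranges (≈ 5.9% for sqBOLD, ≈ 1.7% for
hqBOLD), which they match (5.7% / 1.8%). Noise is Gaussian on magnitudes
(high-SNR regime), and the OEF quotient is evaluated with signed DBV so the
inversion bias — the median OEF sliding toward zero as the DBV variance
grows — is represented faithfully.

## Synthetic phantoms

32×32×9 grids with a white-matter core and gray-matter shell, already
aligned (no motion, registration, slice-profile or FLAIR-timing effects;
those were handled by external tools in the workflow this emulates), no
CSF or partial-volume modelling. Gray matter uses the standard state.
White matter gets a *lower* venous volume (GM/WM DBV ratio 3.19) but a
*higher* effective R2′ via an explicit override (GM/WM R2′ ratio 0.78),
emulating non-heme (myelin) susceptibility sources; consequently the
phantom's qBOLD OEF in WM is unphysiologically high by construction, which
is the in-vivo WM failure mode this framework exhibits. petO₂ transitions
are first-order exponentials (τ = 10 s, the fast-transition regime of
automated gas delivery); petCO₂ is constant up to 0.2 mmHg jitter
(isocapnia). The TRUST phantom places a small sagittal-sinus blob on a
static background with the decay implied by the requested SvO₂.

Passing tests on these phantoms demonstrate estimator/model consistency
and pipeline plumbing, not robustness to motion, field inhomogeneity,
partial volume, or physiological drift — none of which are generated.

## Numerical choices

Root finds are bracketed (Brent) and deterministic; the sqBOLD system is
solved by `lstsq`/pseudo-inverse (one shared pseudo-inverse for batched
voxel/repetition fits); regressions are ordinary least squares; IQR is
Q3−Q1 with linear interpolation; group SDs use the n−1 denominator;
Tukey–Kramer p-values come from the studentized-range distribution with
the ANOVA within-group degrees of freedom. Degenerate inputs (zero-variance
groups, constant paired differences, empty masks, non-positive signals)
raise or are flagged rather than silently clipped. All stochastic
components take explicit seeds and are reproducible bit-for-bit.

## Known limitations

- The Monte Carlo kernel is a desk-scale reimplementation: two vessel
  radii, one reference volume fraction, a 30R environment cutoff, and
  dilute-limit volume scaling. It reproduces the qualitative systematic-
  error structure (R2′ slope near unity, OEF-dependent DBV_sqBOLD
  inflation, compressed OEF_sqBOLD range, full-range OEF_hqBOLD) but not
  every published regression coefficient.
- The forward model is strictly extravascular. The DBV heuristic's
  coefficients originate from a richer vascular model whose hyperoxia
  response includes intravascular and arterial contributions; with an
  extravascular-only δBOLD the heuristic under-scales DBV by roughly a
  factor ~2 at the standard state (slope ≈ 0.5 rather than ≈ 0.94 against
  true DBV for OEF > 30%), and consequently the noise-study hqBOLD OEF
  median sits above, not below, the true value. Intravascular signal
  modelling is deliberately out of scope.
- The TRUST calibration coefficients are site-configurable; the defaults
  are a published 3 T model, not a local calibration.
- Hyperoxia is modelled as isocapnic with ideal end-tidal→arterial
  equivalence (ΔpetO₂ = ΔPaO₂).
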