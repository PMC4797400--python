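# Methods

`mobydose` re-implements, as a tested pipeline, the dosimetry and
therapy-planning analysis used in preclinical radioimmunotherapy (RIT)
studies of a Lu-177-labeled antibody in mouse xenografts: biokinetic
curve fitting, cumulated activity, Monte Carlo S-factors on a voxel
mouse phantom, MIRD organ absorbed doses, activity prescription against
a bone-marrow limit, and therapy-efficacy summaries. This note records
the models, the defaults and why, the numerical choices, and the
limits of what the synthetic data can demonstrate.

## Biokinetics and cumulated activity

Each source region's decay-corrected activity is modelled as

    A(t) = A1 e^(-λ1 t) + A2 e^(-λ2 t),      t in hours, A in %IA or %IA/g,

and the cumulated activity includes the physical decay factor
analytically:

    Ã = ∫₀^∞ A(t) e^(-λ_phys t) dt = A1/(λ1+λ_phys) + A2/(λ2+λ_phys).

Fitting is least squares on decay-corrected data (well-counter data are
decay-corrected upstream, so λ_phys belongs inside the integral, not the
fit). One amplitude may be negative so the model can rise then fall, as
antibody uptake in tumors does; non-negativity is enforced on the model
value A(t) over [0, 2 × last time], not on the amplitudes.

Numerics: deterministic multi-start. Rates are initialized on a fixed
grid (0 plus 9 log-spaced values in 1e-4–1 h⁻¹); for each ordered rate
pair the amplitudes are solved linearly (variable projection); the five
best starts are refined with a trust-region least-squares optimizer
(bounds λ ≥ 0, tolerances 1e-14, ≤ 400 evaluations). Ties are broken by
lowest residual, then lowest λ1. If every unconstrained optimum dips
negative (possible on noisy uptake curves near t = 0), the fit is
retried with a hinge penalty on negativity and a small amplitude clip at
t = 0; the retry is equally deterministic. A component with negligible
amplitude is zeroed and demoted so single-exponential data report their
one real component as (A1, λ1). Curves need ≥ 4 points; all-zero curves
and non-integrable rate combinations (λi + λ_phys ≤ 0) raise typed
errors.

Red marrow is not measured directly: its concentration is taken as
0.36 × blood at every time point, the standard ratio for mice.

Unit chain: %IA·h → MBq·h per MBq administered (÷100, per-gram curves
× region mass first) → disintegrations via 3.6e9 per MBq·h.

## Nuclide data

The bundled dataset is Lu-177: half-life 6.647 d (λ_phys = ln2/159.5 h
≈ 4.345e-3 h⁻¹); beta branches with end points 497.8, 385.3, 248.6 and
176.5 keV at 78.6/9.0/0.2/12.2 % intensity, tabulated as a 1-keV-binned
density generated from the allowed spectrum shape with a
nonrelativistic Fermi function (tabulated mean 138.6 keV; published
compilations give ≈ 134 keV — the difference comes from screening and
shape corrections we deliberately omit, and is irrelevant to the
pipeline's internal consistency, which the tests check against the
table itself); photon lines 112.95 (6.17 %), 208.37 (10.36 %), 249.67
(0.20 %) and 321.32 keV (0.22 %). Conversion/Auger electrons below the
tabulation threshold are not modelled separately. The spectrum is
normalized by rectangle sum over its 1-keV bins so the sampling CDF,
total yield and mean energy are mutually exact; sampling is inverse-CDF
and requires an explicitly seeded `numpy.random.Generator`. Other
nuclides can be supplied as CSV files with the same layout.

## Voxel phantom ("MOBY-lite")

The original MOBY NURBS anatomy is not redistributable, and the
analysis only constrains organ *masses*, the tumor shape and the gland
sphere. Organs are therefore non-overlapping geometric primitives
placed at anatomically plausible positions inside a prolate-ellipsoid
body contour (axis ratio 3.75:1 along z), each primitive sized to its
target mass at 1.0 g/cm³ water-equivalent density (a config parameter;
heterogeneous densities are out of scope). Specifics:

* tumor: solid ellipsoid with axes 1:2:2, short axis along +x
  (perpendicular to the skin), attached at the right flank outside the
  body contour — semi-axis a = (3V/16π)^(1/3);
* submandibular gland: solid sphere, r = (3m/4πρ)^(1/3);
* skeleton: dorsal spine cylinder spanning 1.2 × the body semi-length,
  with red marrow as a coaxial inner cylinder (mass-apportioned radii);
* liver and GI tract: oblate ellipsoids; remaining organs: spheres.

Default grid 160 × 160 × 440 voxels at 0.25 mm (the voxel size is a
config parameter — only the grid is externally fixed); default masses
are typical for a ~25 g tumor-bearing nude mouse (liver 1.3 g, GI
2.5 g, kidneys 0.4 g, bone 1.6 g, marrow 0.25 g, submandibular 0.1 g,
tumor 0.5 g, …). Achieved voxel masses land within 5 % of target at the
default resolution (a warning is emitted if quantization breaks that,
e.g. the thin marrow annulus at 0.5 mm voxels); the sum of all region
masses reproduces the body weight within 1 %. Voxelization is pure
arithmetic: identical specs give bit-identical label arrays. Organs
lighter than one voxel raise a resolution error with a suggested voxel
size. Blood is *not* a voxel region — it enters the published
coefficient table as a compartment, and the fully simulated pipeline
reports phantom regions only.

## Monte Carlo transport

S(r_T ← r_S), the mean absorbed dose to target per disintegration in
source, is estimated by analog Monte Carlo with simplified, documented
physics (the reference analysis used a general-purpose condensed-history
code; replicating its coefficients is explicitly not a goal):

* decay sites: uniform over source-region voxels, stratified so each
  source region receives exactly its quota (`n_histories` per region);
* electrons: straight-line track of CSDA range in water (embedded
  range–energy table, log-log interpolated), energy deposited linearly
  along the track (constant stopping power E/R). Justification: Lu-177
  beta ranges are ≲ 2 mm, one or two voxels, so angular detail is
  second-order for organ-mean doses. Sub-keV electrons deposit locally;
* photons: photoelectric absorption (embedded water table, log-log
  interpolated) and incoherent scattering with the Klein-Nishina cross
  section (closed form; scattered energy sampled by Kahn's rejection
  method). Coherent scattering and bremsstrahlung are neglected (few-%
  effects at these energies). Below the cutoff (default 10 keV, valid
  range 1–100 keV) photons deposit locally. Voxels outside the animal
  are vacuum: no interaction, no range consumed;
* estimator: deposited energy per target mass; 10 equal batches give
  the fractional standard error; no variance reduction, so the
  estimator stays unbiased and the 1/√N law is testable.

Verified properties: in a region much larger than the beta range,
mass × S(self) reproduces the mean beta energy per decay within 2 %
(measured ≈ 0.6 % low, the genuine surface escape); cross-irradiation
through ≥ 10 cm of water is < 1e-3 of self-irradiation; reciprocity
m_T·S(T←S) ≈ m_S·S(S←T) holds between equal distant regions within MC
uncertainty; deposited never exceeds emitted energy; identical seeds
give identical matrices. An externally supplied S-matrix CSV can bypass
simulation entirely, which is how published coefficient tables are used
as data.

## MIRD doses, reporting and planning

D(r_T) = Σ_S Ã(r_S)·S(r_T←r_S), in Gy/MBq when Ã is per MBq
administered. Self-dose uses the diagonal entry only, so self ≤ total
always. Reporting follows the field's convention: coefficients to two
decimals, absolute doses to two significant figures; raw doubles are
kept internally and all linearity invariants are exact on the raw
values. A bundled table of published coefficients for the
Lu-177-labeled anti-hK2 antibody (both the In-111-surrogate and the
Lu-177 biokinetics variants) supports dose tables and planning without
re-running the upstream stages.

The therapy plan inverts the dose-limiting-organ constraint: activity =
limit / total coefficient of the limiting region (default red marrow,
12 Gy — a literature-based tolerance for mice, a config default rather
than a computed quantity). The reported prescription is rounded to the
nearest MBq and downstream doses use the rounded value (12/0.45 =
26.7 → 27 MBq → 27 × 4.9 = 132.3 → 132 Gy to tumor); the unrounded
activity is retained, at which the limiting organ meets its limit
exactly.

## Efficacy

Caliper volume V = ½ w² l (rotated-ellipsoid approximation, w ≤ l).
Endpoint: body-weight loss strictly greater than 20 % of baseline or
tumor diameter strictly exceeding 15 mm ("exceeding" ⇒ boundary values
do not trigger). Survival uses the Kaplan-Meier product-limit estimator
(lifelines); the median is the earliest time with S(t) ≤ 0.5 and is
reported as `None` when the curve never reaches 0.5 within the 120-day
follow-up — the convention used when nearly all animals are censored.
Percent-volume-change curves average only animals still measured at
each day (the attrition convention is recorded in the output's
`n_animals` column).

## Synthetic data: what it emulates and what it does not

The TAC generator anchors group-mean %IA/g curves to the reported
biodistribution: LNCaP tumor 22 at 72 h and 30 at 168 h; DU 145 4.9 and
pre-dosed 8.3 at 72 h; heart 6.7, liver 8.9 and submandibular 14 at
168 h (SPECT-ROI-derived; both sourcing choices are configurable);
marrow = 0.36 × blood by construction. Earlier time points and
unreported organs use plausible antibody kinetics (slow blood
clearance from ~30 %IA/g, rising gland uptake). Inter-animal noise is
multiplicative log-normal with unit mean (reported SDs are ~20–30 % of
means; default CV 0.2, n = 3/point), truncated at ±3σ, so the
noise-free limit passes exactly through the anchors.

The cohort generator is invented dynamics — the study reports outcomes,
not a growth model — calibrated once to the qualitative outcomes:

    ln V(t) = ln V0 + g t − κ·D·(1 − e^(−λ_eff t)),

with V0 = 150 mm³, g = 0.06 d⁻¹ (doubling ≈ 11.5 d, chosen so control
arms cross the 15-mm endpoint near day 40, matching the reported
control medians of 35–45 d), κ = 0.058 Gy⁻¹, λ_eff = 0.08 d⁻¹ (the
rate at which the Lu-177 dose is delivered). A tumor whose nadir falls
below 1 mm³ fully regresses; otherwise a per-animal Bernoulli flag
(defaults 1.0 / 0.4 / 0.0 for the 10/19/36 MBq arms, encoding the
reported 40 % relapse rate in the mid arm) decides regrowth versus
indolence. Arm design follows the study: 10 MBq (n=5), 19 (n=5), 36
(n=3), labeled non-specific IgG 17 MBq (n=5, zero tumor dose), saline
(n=5), unlabeled antibody (n=4). Measurements every 3 days to day 120
with CV-5 % caliper noise; weights stay near baseline except a mild
decline in the labeled-IgG arm. Under these defaults the low arm's
median lands near day 88 and the higher arms are censored throughout —
the study's reported pattern.

What passing tests therefore show: the *pipeline machinery* (fitting,
integration, transport, MIRD algebra, endpoint/KM conventions) is
correct under the statistical structure the analysis assumes. They do
not show that the simplified transport reproduces condensed-history
coefficients (our simulated tumor coefficient is ≈ 4.6 Gy/MBq against
4.9 published — agreement to ~6 % is encouraging but not a validation),
nor that real tumors follow the invented growth model.

## Problem sizes and other numerical choices

Default pipeline runs use a 80 × 80 × 220 grid at 0.5 mm with 2e4
histories per source region — enough for few-% self-dose uncertainties;
the equilibrium and scaling checks use 1e5 histories on a homogeneous
block at 1 mm voxels. The published-coefficient path is exact and
instantaneous. Closed-form cumulated activity agrees with adaptive
quadrature to 1e-6 relative over random integrable parameter sets.
Known limitations: no condensed-history electron scattering, no
coherent scattering or bremsstrahlung, homogeneous water density (bone
included), single-compartment blood handling, no NTCP/BED modelling,
no log-rank or Cox analysis.
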