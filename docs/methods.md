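# Methods

## Scope and model assumptions

The package analyses a three-patient microdose (~9.4 MBq) administration
of a ²¹²Pb-labelled PSMA ligand: whole-body clearance from external
probe counts, ligand stability from blood partitioning, projected lesion
uptake from baseline PSMA-PET SUVs, lesion detectability on γ-camera
imaging, and a first-order comparison against a ²²⁵Ac-labelled
alternative. Everything is whole-body and first-order: clearance is
monoexponential, organ kinetics, multicompartment PK and organ-level
(MIRD) dosimetry are out of scope, as are image reconstruction and
DICOM handling.

Units are hours, MBq and kBq/mL throughout; SUVs use the 1 g/mL tissue
density convention.

## Nuclear data

`data/nuclides.json` bundles rounded evaluation values (NuDat 3 /
ICRP-107 style) for the ²¹²Pb → ²⁰⁸Pb and ²²⁵Ac → ²⁰⁹Bi chains:
half-lives, branching fractions, branch-weighted mean α energies, mean
electron energies per decay (β plus conversion and Auger electrons, the
dosimetric convention) and the principal photons. ²⁰⁹Bi is treated as
stable; published evaluations differ in the third digit of some
intensities. Under this convention the chains sum to 8.68 MeV (²¹²Pb)
and 28.14 MeV (²²⁵Ac) of α+β energy per parent decay — a ratio of 3.24,
i.e. 3.2 at the customary one-decimal reporting precision. β-only means
(excluding conversion electrons) would raise the ratio to ≈ 3.27.

Bateman activities are computed per decay path with the distinct-λ
closed form; near-degenerate decay constants (|λi−λj| < 10⁻⁹·λ) are
separated by a 10⁻⁷ relative perturbation rather than a confluent limit
formula — the induced error (~10⁻⁷ relative) is far below the 0.1%
oracle tolerance the tests enforce. Ultra-short-lived members (²¹²Po,
²¹³Po) are retained exactly; tests compare against a stiff (Radau) ODE
integration relative to the initial parent activity.

## Clearance fitting

Fitting is unweighted least squares on log rates, matching straight-line
whole-body retention plots; at ~10 MBq, count statistics make Poisson
weighting a refinement rather than a necessity. The default "pooled"
scope shares one decay constant across patients with per-patient
intercepts; since it is ambiguous whether a pooled estimate of this kind
is a shared-slope fit or an average of per-patient fits, both are
provided (`scope="per_patient"` averages independent fits). The 95% CI
is the t-based slope interval pushed through the monotone map
T = −ln2/slope. Background is assumed pre-subtracted (net rates in the
input schema). Normalisation divides each patient's rates by their own
back-extrapolated t = 0 intercept and requires a measurement within
0.5 h of injection to anchor it.

## Blood partitioning

The well-counter calibration factor is defined empirically as counts per
kBq of ²¹²Pb *at daughter equilibrium* in the 55–300 keV window, so no
explicit in-growth term is needed when the protocol delay (≥ 12 h ≈ 12
²¹²Bi half-lives) is respected; a warning is raised below 7 ²¹²Bi
half-lives. The counting-window correction
e^(λ·delay)·λΔ/(1−e^(−λΔ)) converts the window-mean rate to activity at
sampling time (2.233 for the 40 min/12 h protocol). Red-cell
concentrations are reported signed — clipping negative values would
destroy the stability evidence, which is precisely that they scatter
around zero. The stability verdict is `stable` when mean A_RBC ≤ 5%
(configurable) of mean whole-blood concentration. Patient hematocrits
are not part of the public record; the synthetic default is 0.41 (s.d.
0.01), a typical adult male value, exposed in `CohortSpec`.

## Uptake conventions

The default decay correction is *physical* decay of the administered
activity to 3 h (midpoint of the day-0 SPECT session); with it, SUV_mean
45.0 / 9.0 MBq / 62 kg gives 5.37 kBq/mL and SUV_mean 6.2 / 9.6 MBq /
80 kg gives 0.61 kBq/mL. No single convention reproduces both published
example figures for patient ID03 (5.4 and 2.3 kBq/mL imply different
corrections); the package therefore tags every estimate with its
convention rather than forcing agreement. Body weights other than
ID03's 62 kg are unpublished and default to a configurable 80 kg.
Volumes come from CT dimension triples as ellipsoid (π/6·abc) or box
(abc) products, with an override mode for externally measured volumes;
the detectability rule uses box volumes and 1 cm³ where no dimensions
were recorded.

## Detectability

Hot-sphere contrast is (mean counts in sphere − background)/background.
The calibrated path bins phantom observations to the (concentration,
volume) grid, fills gaps by per-axis interpolation, and projects onto
the bimonotone cone by cyclic row/column isotonic regressions
(scikit-learn), iterated to convergence — an approximation to the exact
L2 matrix projection that guarantees the monotonicity invariant. Queries
interpolate bilinearly and clamp outside the grid; the minimum
detectable concentration is found by bisection and never reported below
the phantom floor (lowest calibrated concentration, 2 kBq/mL by
default). The default contrast threshold C* = 0.30 makes the minimum
detectable concentration approach that floor for large volumes.

Because the original phantom tables are not published, a synthetic
generator produces observations from the saturating surface
c·conc·vol/(vol + v₀) + noise with c = 0.15 (kBq/mL)⁻¹, v₀ = 1 cm³,
σ = 0.02 — parameters chosen so the surface reproduces the qualitative
behaviour (contrast rising in both axes, ~2 kBq/mL floor at large
volume). The documented fallback rule — detectable iff concentration
≥ 4 kBq/mL and volume ≥ 1.5 cm³ — is a stand-in calibrated to the same
qualitative outcomes, not a measured detection threshold; both routes
classify the same single lesion in the bundled table.

## Dose scaling

Under monoexponential clearance the time-integrated activity per unit
administered activity is T_eff/ln2, so the cross-nuclide absorbed-dose
ratio factorises into (chain energy ratio) × (T_eff ratio). The default
scenario derives T_bio = 32.2 h from the fitted 8.0 h effective / 10.64 h
physical pair and applies it to ²²⁵Ac (10 d physical → T_eff = 28.4 h).
The exact product with the bundled data is 11.5; with the energy factor
first rounded to its customary one-decimal display (3.2) the product is
11.4 — both are reported, and the computed value is never replaced by a
rounded one. This estimate ignores organ uptake, RBE/α-weighting and
daughter relocation.

## Synthetic cohort

`CohortSpec` defaults mirror the study design: 3 patients at 9.6/9.5/9.0
MBq, probe points at the protocol window midpoints (0.25, 1.5, 5,
18.5 h) plus a fifth 2.4 h point for patient 3, 5% lognormal
(mean-preserving) probe noise, blood draws at the same times
forward-simulated through the counting-window model with Poisson counts,
zero red-cell binding, lognormal lesion SUVs spanning roughly the
observed 10–77 SUV_max range. The generators capture the statistical
structure the analysis assumes — they do not emulate probe geometry
drift, background variation, patient motion, partial-volume effects or
tracer/ligand kinetic differences, so passing recovery tests demonstrate
the estimators are unbiased under the stated model, not robustness to
those real-world effects.

## Problem sizes and numerical choices

Monte-Carlo recovery checks use 200 replicates of the 3 × 4-point
design, enough to pin the mean fitted half-life to well under 1%.
Isotonic projection iterates to a 10⁻¹⁰ sup-norm change (≤ 200 sweeps);
bisection for the minimum detectable concentration runs 80 halvings.
The acceptance script's clearance target uses the same 200-replicate
design with replicate seeds spawned from the command-line seed.

## Known limitations

Absolute blood concentrations depend on an unpublished well-counter
calibration, so only ratios and the stability verdict are meaningful;
the CI of the pooled half-life depends on unpublished raw counts and is
validated only by coverage under the synthetic model; the fallback
detectability thresholds are surrogates; and the dose-scaling estimate
is a whole-body first-order bound, not dosimetry.
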