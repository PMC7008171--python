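# Methods

This note records the model equations, parameter choices, numerical
decisions and known limitations of the package, in the package's own
terms. Nothing here asserts an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and data situation

The package re-implements a mechanistic absorption analysis of a 1 mg
risperidone orodispersible film in beagle dogs. All quantitative inputs
are the published ones: the physicochemical block (MW 410.49 g/mol,
logP 3.04, diprotic base pKa 8.24/3.11, B/P 0.506, fu 0.083, solubility
0.9 mg/ml at pH 6.8, aqueous diffusion 0.64×10⁻⁵ cm²/s, precipitation
time 900 s, particle density 1.2 g/ml, radius 25 µm), the absorption
block (Peff 5.3894×10⁻⁴ cm/s, F_ut 0.15382, epithelial diffusivity
9.383×10⁻⁷, stored as printed and interpreted as cm²/s since that is the
conventional unit for a diffusivity), the three-compartment disposition
constants (Vc 0.3139 L/kg, CL 0.5903 L/h/kg, K12 16.352, K21 9.007,
K13 0.4625, K31 0.4103 h⁻¹, V2 0.56988, V3 0.35383 L/kg, first-pass
extraction 0.51), and the dosing design (1 mg, 9.0425 kg, sampling
0.167–32 h). The printed half-life (2.43 h) is derivable from the rate
constants (the smallest-magnitude eigenvalue gives 2.4269 h) and is not
stored as an input. The micro-constant convention was confirmed by the
internal consistency K12·Vc = K21·V2 = 5.133 and K13·Vc = K31·V3 = 0.145.

Raw animal-level curves and the proprietary dog physiology tables are not
public. Consequences threaded through the design:

* the gut and mouth physiology tables are **literature-plausible
  defaults that act as the calibration surface**, every entry
  overridable;
* two global mucosal scales absorb the residual unknown oral physiology
  and are estimated from the reported oral-absorption fractions;
* observed animal-level endpoint tables are treated as validation
  references, not as reproducible targets;
* all test inputs that the study did not publish are produced by the
  synthetic-data module.

## Canonical units

Hours, micrograms and liters internally (ml for luminal/saliva fluids,
cm for lengths); plasma concentrations in µg/L so simulated results read
directly against the reported tables. Printed per-kg disposition values
are kept verbatim and scaled by body weight at simulation time.
First-pass extraction is stored as the fraction 0.51.

## Dissolution

The z-factor law `dXd/dt = z (Cs − Xd/V)(Xs/X0)^(2/3) X0` is implemented
exactly as printed. (The surrounding text names a particle density, but
the printed rate law does not contain one; density is treated as absorbed
into `z`.) pH-dependent solubility for a diprotic base scales the
intrinsic solubility `S_int` — back-calculated from the 0.9 mg/ml
reference at pH 6.8, giving `S_int ≈ 0.0315 mg/ml` — by
`1 + 10^(pKa1−pH) + 10^(pKa1+pKa2−2pH)`, capped at 50 mg/ml because the
unbounded extrapolation at pH 1 is unphysical; a 1 mg dose is far below
saturation in any test medium regardless of the cap.

`z` is fitted by bounded scalar least squares on log z (positivity without
constraint handling), bracketed by a coarse log-grid scan because the
objective plateaus once `z` is fast enough to complete release before the
first sample. Only points up to the first observation ≥ 95% dissolved
enter the fit: beyond that point the model is insensitive to `z`, and
plateau noise (clipped at 100%) would bias `z` downward. The default
`z = 1.5 ml mg⁻¹ min⁻¹` was chosen once so that the film releases ≥ 95%
of its content within 2 min in 500 ml of every test medium, matching the
formulation's observed release behaviour; the synthetic generator uses it
as truth and fitting recovers it.

A note on an apparent pH-invariance: because the capped solubilities at
pH 1 and 4 are ~55× the pH 6.8 value, the z-model necessarily predicts
much *faster* (not equal) release in acid. The property the data support,
and the one tested, is that release is complete within 2 min in every
medium from pH 1 to 7.

## Disposition

The mammillary three-compartment model is simulated in closed form by
eigendecomposition (the system is linear; K12 = 16.35 h⁻¹ makes ODE
integration needlessly stiff). The terminal half-life uses the slowest
*observable* eigenvalue — one with nonzero amplitude in the central
compartment after an iv bolus — so degenerate configurations with a
disconnected peripheral compartment reduce correctly to fewer phases.

Refitting (for parameter-recovery tests) minimizes relative residuals
(1/ŷ² weighting) with 16 log-uniform multi-starts (fixed seed) around
moment-based guesses, using bounded trust-region least squares. Rate
constants are bounded so that no phase has a half-life longer than twice
the last sample time: without that bound, noisy fits can park drug in a
quasi-irreversible deep compartment that mimics elimination over the
32 h window and sends the fitted clearance to zero. **Vc is not
identifiable from the study sampling grid** — the distribution phase
(t½ ≈ 1.5 min) is over before the first sample at 10 min — so recovery
claims are made for CL (and z), not Vc.

## Gut transit and absorption

Nine sequential compartments with first-order transit. Defaults (all
overridable via the physiology table): stomach 50 ml, pH 1.5,
non-absorbing, mean residence 0.15 h; seven small-intestine segments of
15 ml, radius 0.5 cm, pH 6.2→7.4, sharing 2.0 h of transit equally;
colon 100 ml, pH 6.8, radius 1.0 cm, 12 h, absorbing with ka scaled 0.5.
Absorption of dissolved drug uses the cylindrical-lumen relation
`ka = 2 Peff/R` (7.76 h⁻¹ at the fitted Peff and R = 0.5 cm). Dissolution
uses the in-vitro-fitted `z` unchanged at the local pH solubility;
supersaturated drug precipitates toward saturation with the 900 s time
constant. Portally absorbed drug is scaled by (1 − 0.51) before entering
the central compartment. Degradation and gut-wall metabolism are carried
as ledger states fixed at zero (no rates are published).

The stomach residence deserves a word: 0.15 h reflects fast fasted-state
liquid emptying in dogs (half-time of a few minutes), appropriate here
because the dose arrives either pre-dissolved (the gavage arm dissolved
the film in water) or as a rapidly disintegrated film bolus. It is the
main knob setting the simulated Tmax scale (~0.46 h supralingually,
against a reported model prediction of 0.53 h and observed 0.62 h), and
it is part of the unpublished-physiology calibration surface, not a
measured quantity.

In the limit of instant dissolution, equal-ka segments and absorption
confined to the small intestine, the model reproduces the closed-form
compartmental-absorption-and-transit result
`Fa = 1 − (1 + ka·T/7)⁻⁷` (verified to 2%).

## Oral cavity

Six mucosal sites share one saliva pool. Defaults: total area 30 cm²
split buccal 9 / gingival 5 / palate 5 / tongue-top 5 / tongue-bottom 3 /
mouth-floor 3 cm²; epithelium 0.05 cm (non-keratinized) or 0.08 cm
(keratinized: gingival, palate, tongue top), keratinized uptake ×0.25;
saliva baseline 1 ml, secretion 0.5 ml/min during the hold, pH 6.8.
The pool grows with secretion **up to a resting mouth capacity of 3 ml**;
unbounded pooling (6 ml by a 10-min hold) is not physiological — a dog's
mouth clears fluid reflexively — and over-dilutes the late saliva, which
distorts the time course of mucosal uptake toward early saturation. With
the cap, uptake after film dissolution is near-linear in time, the shape
the reported 7.0 → 11.4 → 19.5% residence-time sequence implies.

Fluxes: saliva→tissue per site `A (D_t/h)(fu·C_sal − F_ut·C_tis)·u_i·U`;
tissue→systemic first-order at `(D_t/h²)·T`. While undissolved film
remains, the deposition sites (tongue top supralingually; tongue bottom
plus mouth floor sublingually) additionally see saturated drug at the
film surface, drawn from the solid mass and fading smoothly as it
dissolves — this is what distinguishes the two placements and produces
the early uptake burst. After the terminal swallow, drug already in the
epithelium only drains to the circulation; back-diffusion into fresh
saliva is neglected (a one-way-commitment simplification — including it
makes the two-scale calibration infeasible against the reported
anchors, see below).

`U` (uptake) and `T` (transfer) are estimated by a two-dimensional
least-squares root find in log space so the oral absorbed fraction —
cumulative drug across the saliva–epithelium interface, fixed at the end
of the hold — equals 7.0% at a 2-min hold and 19.5% at 10 min, each to
1×10⁻⁴ absolute. The two scales are jointly identifiable because `T`
controls epithelial back-pressure, hence how strongly uptake saturates at
longer residence. The 5-min fraction is then a genuine out-of-sample
prediction of the calibrated model (the acceptance suite computes it and
compares against the reported 11.4%). Structures considered and
rejected during design: a constant-volume saliva pool (uptake becomes too
convex in time; no scale pair can satisfy both anchors) and post-swallow
epithelial back-diffusion (over-convex likewise; calibration residuals
plateau near 10⁻², far above tolerance).

Mucosally absorbed drug enters the circulation without first-pass
extraction by default — mucosal venous drainage is systemic, not portal —
with `apply_fpe_to_mucosal=True` applying the 51% extraction instead.
The published exposure arithmetic is consistent with either convention to
within ~7%, and the acceptance suite checks the predicted AUC under both.

## Coupled engine

One monolithic stiff ODE (LSODA, rtol 1e-10, atol 1e-8 µg) carries
~40 states: saliva solid/dissolved, six epithelial depots, per-gut-segment
solid/dissolved, cumulative portal and mucosal inputs, fecal output,
three disposition compartments and cumulative elimination. The hold ends
with a discrete swallow event (integration restarts with the saliva
content moved to the stomach). Every flux is also accumulated, so the
mass ledger sums to the dose at machine precision; the acceptance gate is
1×10⁻⁶ relative. The output grid is log-dense from 10⁻³ h to 1 h and
quarter-hour spaced afterwards, merged with the clinical sampling times —
fine enough that trapezoidal AUC of the steep iv curve agrees with the
analytic Dose/CL identity to ~0.1%. Tmax is refined by parabolic
interpolation through the three grid points around the discrete peak.
A zero-minute hold means the intact film is swallowed at once, which is
identical to solid-input gavage (tested as a boundary-consistency
property). The shrinking-surface dissolution rate has unbounded slope at
solid exhaustion; state undershoots of order 10⁻⁶ of the dose are
tolerated as integrator artifacts (the ledger remains conserved).

## NCA, validation, sensitivity

NCA uses linear trapezoids (a log-down variant was considered and left
out: the source analysis tool's convention is unknown and linear is the
simplest defensible default), λz by best adjusted-R² log-linear
regression over terminal suffixes of ≥ 3 points excluding Tmax,
`AUC0-∞ = AUC0-t + C_last/λz`, MRT from AUMC/AUC with the matching tail
terms, CL = dose/AUC0-∞ (apparent for extravascular routes), Vd = CL/λz,
and relative F against an iv reference. Iv-bolus curves are
back-extrapolated to t = 0 log-linearly from the first two points
(standard practice; the study grid starts at 10 min, which otherwise
drops ~5% of iv AUC); extravascular curves take C(0) = 0. The fold-error
formula returns 1.0 at equality (the printed piecewise form covers only
strict inequalities). Exact arithmetic on the reference endpoint pairs
gives folds 1.1698 / 1.5451 / 1.1126; the published table prints
1.17 / 1.54 / 1.11, i.e. the middle value is truncated rather than
rounded — tests therefore compare at 0.5% relative tolerance and the
acceptance script reports the unrounded values. Sensitivity scans
evaluate a user-supplied engine over a uniform grid (11 points over the
0–10 min residence range by default) and report `(max − min)/max` per
exposure metric.

## Synthetic data

The generator emulates the study design: four dogs × four routes
(iv, intragastric, supralingual, sublingual) on the fixed sampling grid,
proportional residual error (default CV 10%, consistent with the reported
assay precision range of 1.5–11.4%) plus a 0.1 µg/L additive floor,
censoring below the 0.2 µg/L quantification limit, and optional 20%
log-normal inter-subject variability on CL and Vc (off by default — the
emulated curves are study means). Dissolution profiles are generated for
the four media (0.1 M HCl pH 1.0, acetate pH 4.0, phosphate pH 6.8,
water taken as pH 5.5 for solubility purposes) at 0.5-min intervals to
10 min, noise clipped to [0, 1]. Everything is deterministic under a
fixed seed.

What the generator does **not** emulate: real between-dog variability in
physiology (it perturbs only CL/Vc), assay-specific error structure
(heteroscedasticity beyond the proportional+additive model), period or
sequence effects of the crossover, and the actual unpublished individual
curves. Passing recovery tests therefore demonstrates that the estimation
machinery is consistent and unbiased under the stated error model at the
study's sampling design — not that it would reproduce the published
animal-level summary statistics, which depend on data that are not
public.

The recovery suite replays the study's estimation pipeline per replicate:
a triplicate dissolution run (the in-vitro test used n = 3) is averaged
and z refit; a four-dog iv arm is averaged and the disposition refit —
fits act on mean profiles, as the originals did. With 20 replicates at
10% CV the median relative bias of z and CL stays within a few percent
(the acceptance suite asserts < 5%).

## Problem sizes and runtimes

Chosen so the full analysis remains interactive on a laptop: route
simulations integrate ~40 states over 32 h (≈ 0.1–0.2 s each), the
mucosal calibration needs ~20 short oral-phase integrations (< 1 s), the
sensitivity scan 11 full simulations (~2 s), and the recovery suite
20 replicates × (3 dissolution fits + one 16-start disposition fit)
(~1–2 min). The complete test suite runs in about two minutes.

## Known limitations

* Dog gut and mouth physiology defaults are calibration surfaces, not
  measurements; Tmax/Cmax-scale conclusions inherit that uncertainty.
* No metabolite (9-OH risperidone) kinetics; the parent drug only.
* No fed state, bile-salt solubilization, transporters, enterohepatic
  recirculation, mucoadhesion kinetics or salivation feedback.
* The film route is deliberately non-superposable in dose (saturated
  film-surface flux and saliva saturation are concentration-fixed);
  dose-normalized exposure declines with dose.
* Single-dose only; no population variability in the mechanistic layer.
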