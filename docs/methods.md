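# Methods

This note records the models implemented by `specbind`, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical and design choices made where the literature leaves room.

## Quenching model and read-out convention

A titration is a set of emission spectra indexed by quencher concentration
[Q] at one temperature and excitation wavelength; the [Q] = 0 spectrum
defines F0. The Stern–Volmer fit regresses F0/F on [Q] by ordinary least
squares over all points *including* [Q] = 0, without constraining the
intercept to 1 — the reported Pearson R then measures linearity of the whole
series rather than of a forced model. `kq = Ksv/τ0` uses the conventional
unquenched biomolecular lifetime τ0 = 10⁻⁸ s unless overridden.

F and F0 are read at a **fixed wavelength**: the emission-band peak of the
zero-quencher spectrum. Quencher binding typically red-shifts the band by a
few nm; reading each spectrum at its own maximum would fold that shift into
the apparent quenching. A per-spectrum-maximum read-out and an explicit
wavelength are available as options. The band peak itself is located as the
intensity-weighted centroid of samples above 80% of the maximum: for a clean
symmetric band this equals the sampled maximum, while under per-point
instrument noise a plain argmax systematically selects the largest upward
noise excursion and biases F0 (and hence every fitted slope) high.

Mechanism classification uses the standard temperature logic: static
quenching (ground-state complex) when Ksv strictly decreases with
temperature and every kq exceeds the diffusion-limited ceiling
2.0 × 10¹⁰ L mol⁻¹ s⁻¹; dynamic when Ksv strictly increases and kq stays at
or below it; otherwise indeterminate with an explanation. Combined
static+dynamic (sphere-of-action) models are out of scope.

No dilution correction is applied by default (cumulative titrant volume in
the modelled protocol is ≤ 1.5% of the cuvette volume) and no inner-filter
correction is applied at all; both are limitations for strongly absorbing
ligands.

## Binding fits

Both linearisations use base-10 logarithms. The double-logarithmic fit
regresses lg((F0−F)/F) on lg[Q]; slope = site count n, 10^intercept = K
(L/mol). The modified Stern–Volmer fit regresses F0/(F0−F) on 1/[Q] and
reports K = 1/slope with n fixed at 1. The [Q] = 0 point is excluded from
both (log/reciprocal undefined), and nonzero-[Q] points with F ≥ F0 are
excluded with a warning. The two printed forms of these equations circulate
with typographical damage in parts of the literature; the standard forms
above are the ones consistent with single-site behaviour and are what this
package implements. When the two estimators disagree on real data both are
reported side by side; no selection criterion is imposed.

## FRET

The overlap integral J = ∫F(λ)ε(λ)λ⁴dλ / ∫F(λ)dλ is evaluated with
trapezoidal weights (second-order convergent; a plain Riemann sum differs
below reporting precision) on the intersection of the donor and acceptor
spans at a 0.5 nm default step; the denominator integrates the donor over
its full native span so emission outside the overlap region still
normalizes. Wavelengths stay in nm everywhere except the λ⁴ factor, which
is converted to cm so that J carries cm³ L mol⁻¹ and the Förster prefactor
R0⁶ = 8.8 × 10⁻²⁵·K²·Φ·n⁻⁴·J yields R0 in cm (converted to nm at the
boundary). This is the only unit regime in which those J units are
dimensionally coherent with the prefactor. Defaults K² = 2/3 (isotropic),
n = 1.336 (dilute aqueous), Φ = 0.15 (intrinsic protein emission).

Distances are flagged as plausible when r < 7 nm (practical transfer
ceiling) and 0.5 R0 < r < 1.5 R0 (the regime where efficiency is measurably
sensitive to distance). Orientation-factor modelling beyond the scalar K²
and lifetime-based efficiencies are out of scope.

A note on internal consistency of published FRET parameter blocks: for the
block this package models, substituting the printed J into the R0 expression
with the printed constants gives R0 = 3.636 nm rather than the printed
3.49 nm, and the printed (R0, E) pair reproduces the printed r only to
~0.1% (3.499 vs 3.502 nm). The package pins the independently computed
values in its regression tests and surfaces the gaps rather than forcing
agreement.

## Ellman dose–response

The inhibition ratio R = [(A3−A4)−(A1−A2)]/(A3−A4) is algebraically
invariant to shifting (A1, A2) jointly or (A3, A4) jointly — the property
the tests exercise — and is reported unclamped, with out-of-[0,1] values
flagged. IC50 comes from a two-parameter logistic in log10 concentration,
R(c) = 1/(1 + (IC50/c)^h), bottom fixed at 0 and top at 1 because the ratio
is already normalized by construction; how the original analyses derived
IC50 from such data (logistic, probit, interpolation) is generally
unstated, so this is a documented choice validated by synthetic-data
recovery. Replicates at one concentration are averaged before fitting; the
IC50 standard error comes from the fit covariance by the delta method. A
flat response is rejected as unidentifiable, and a response that never
crosses R = 0.5 inside the span yields an extrapolation warning.

pIC50 = −log10(molar IC50) requires the compound's molecular weight, which
is taken as explicit input; `implied_molecular_weight` reports the MW
consistent with a given (mass IC50, pIC50) pair (577.2 g/mol for the pair
3.478 μg/mL, 5.22).

## QSAR table evaluation

No 3D-QSAR model is trained (the upstream fragment-based CoMFA computation
is proprietary); evaluation is restricted to the printed per-compound
columns. "Success rate" is interpreted as the squared Pearson correlation
between the experimental and predicted columns per split — if published
values derived instead from leave-one-out predictions differ by more than
0.01, the computed value is surfaced alongside the ambiguity rather than
hidden. MRE is defined on the pIC50 scale. The additive diagnostic fits the
single offset c minimising the residuals of pred = c + R1 + R2 over
train+test rows; query rows (compounds without experimental values) are
excluded from all metrics and instead receive a residual under the fitted
c, which flags predictions inconsistent with the table's own additive
structure. In the packaged table the query compound's residual is ≈ −1.20
pIC50 units against a ≤ 0.017 spread for the 61 fitted rows — a diagnostic
the package reports without attempting to resolve.

## Synthetic generators

The generators reproduce the statistical structure the estimators assume,
with the governing equation embedded exactly before noise:

* **Quenching titrations** — Gaussian emission band (centre 330 nm,
  σ = 25 nm) sampled at 0.5 nm over ±4σ, red-shifting at a rate that gives
  ~4 nm across the full nine-point, 0–1.14 μM concentration ladder used as
  default. The amplitude at the *fixed* read-out wavelength follows either
  the Stern–Volmer law (with Ksv_true) or the double-log binding isotherm
  (with K_true, n_true) — one series cannot satisfy both unless n = 1 —
  and noise is multiplicative per spectral point (shot-noise proxy).
* **FRET pairs** — Gaussian donor emission and acceptor molar-absorptivity
  bands on ±5σ grids, giving overlap integrals with closed-form narrow-band
  limits. For a narrow donor against a broad acceptor J → ε(λ0)·λ0⁴; for
  two *identical* shrinking bands the Gaussian product integral gives
  J → ε_max·λ0⁴/√2, and the tests pin both limits.
* **Ellman plates** — absorbance quadruples with A2 = A4 = 0.05,
  A3 − A4 = 0.5 and A1 chosen so the ratio formula returns the logistic
  R(c) exactly; noise is additive per absorbance (plate-reader model).
  Default truth IC50 = 3.478 μg/mL, h = 2, at 2.0–9.0 μg/mL.
* **QSAR tables** — additive truth pred = c + R1 + R2 with fragment terms
  uniform on the ranges observed in the packaged table, Gaussian noise on
  the experimental column, 47/14 train/test split by default.

All generators are bit-reproducible under a fixed seed. They do **not**
emulate photobleaching, temperature drift, scattering, inner-filter
effects, baseline drift or correlated plate effects; passing recovery
tests therefore demonstrates estimator correctness under the stated noise
models, not robustness to every instrument artifact.

## Problem sizes and tolerances

Recovery tests use the nine-point titration ladder, eight-concentration
Ellman plates and the 62-row activity table; the noisy Stern–Volmer
calibration uses 200 seeded replicates at 1% multiplicative noise. The
brute-force oracles integrate at 0.01 nm (overlap) and use coarse-to-fine
grids (binding, IC50). Noiseless recovery is asserted at 10⁻⁶ relative;
oracle agreement at 0.1% (overlap) and 2–3 decimals (grid searches).

## Pipeline

Stages are independent and individually skippable; `run_study` records a
skip reason per missing input and catches per-stage errors so the remaining
stages still run, returning a versioned report with a config hash, package
version and timestamp. Reports are deterministic for a fixed config apart
from the timestamp.
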