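# specbind

Analysis toolkit for spectroscopic protein–ligand interaction studies, built
around the workflow used to characterise small-molecule inhibitors of
acetylcholinesterase (AChE) such as the plant naphthoquinone
floribundiquinone B (FB): fluorescence-quenching titrations, binding-constant
estimation, Förster resonance-energy-transfer (FRET) distances, Ellman-assay
dose–response, and external-validation metrics for a fragment-based QSAR
activity table.

## What it computes

**Stern–Volmer quenching** (`specbind.quenching`). From an emission titration
at quencher concentrations [Q],

    F0/F = 1 + kq·τ0·[Q] = 1 + Ksv·[Q]

fitted by ordinary least squares; `kq = Ksv/τ0` (τ0 = 10⁻⁸ s by default) is
compared against the diffusion ceiling 2.0 × 10¹⁰ L mol⁻¹ s⁻¹ and the
temperature trend of Ksv to classify the mechanism as static (ground-state
complex) or dynamic (collisional).

**Binding constant and sites** (`specbind.binding`). The double-logarithmic
plot

    lg[(F0 − F)/F] = lg K + n·lg[Q]

gives the association constant K and site count n; the modified Stern–Volmer
plot `F0/(F0 − F) = 1 + K⁻¹[Q]⁻¹` gives a single-site K for comparison.

**FRET distance** (`specbind.fret`). The spectral overlap of the donor
emission F(λ) and acceptor molar absorptivity ε(λ),

    J = Σ F(λ) ε(λ) λ⁴ Δλ / Σ F(λ) Δλ        [cm³ L mol⁻¹]

feeds the Förster radius `R0⁶ = 8.8 × 10⁻²⁵ K² Φ n⁻⁴ J` (K² = 2/3,
n = 1.336, Φ = 0.15 by default) and the efficiency
`E = 1 − F/F0 = R0⁶/(R0⁶ + r⁶)` is inverted to the donor–acceptor distance
`r = R0·(1/E − 1)^(1/6)`, with the r < 7 nm and 0.5 R0 < r < 1.5 R0
plausibility flags.

**Ellman inhibition** (`specbind.inhibition`). The plate-assay ratio
`R = [(A3 − A4) − (A1 − A2)]/(A3 − A4)` per concentration is fitted with a
two-parameter logistic `R(c) = 1/(1 + (IC50/c)^h)` to estimate IC50; pIC50
is derived from the molar IC50 when a molecular weight is supplied.

**QSAR parity metrics** (`specbind.qsar`). For a printed Topomer-CoMFA-style
table (experimental pIC50, predicted pIC50, fragment contributions R1, R2),
squared Pearson correlation and mean relative error per split, plus a
diagnostic fit of the additive structure `pred ≈ c + R1 + R2`. A 62-row
AChE-inhibitor table ships with the package.

All inputs can be generated with known ground truth by
`specbind.synthetic`, which is how the estimators are validated.

## Worked example

```python
from specbind import (QuenchSimConfig, simulate_quench_titration,
                      stern_volmer_fit, double_log_fit, analyze_fret,
                      simulate_fret_pair)

series = simulate_quench_titration(QuenchSimConfig(Ksv_true=22.84e6, seed=0))
sv = stern_volmer_fit(series)
print(f"Ksv = {sv.Ksv:.4g} L/mol, kq = {sv.kq:.4g} L/(mol s), R = {sv.pearson_R:.3f}")

donor, acceptor = simulate_fret_pair(eps_max=2e5)
res = analyze_fret(donor, acceptor, F0=1.0, F=0.5039)
print(f"J = {res.J_cm3_L_per_mol:.4g} cm3 L/mol, R0 = {res.R0_nm:.3f} nm, "
      f"E = {res.E:.4f}, r = {res.r_nm:.3f} nm")
```

prints

```
Ksv = 2.284e+07 L/mol, kq = 2.284e+15 L/(mol s), R = 1.000
J = 1.889e-13 cm3 L/mol, R0 = 4.165 nm, E = 0.4961, r = 4.176 nm
```

i.e. the quenching constant is recovered exactly from the noiseless
titration (kq far above the 2 × 10¹⁰ diffusion ceiling, the static-quenching
signature), and the FRET chain runs J → R0 → E → r end to end on the
synthetic band pair.

The same stages are available from the shell:

```bash
specbind sim --out bundle --seed 7      # synthetic inputs + study.yaml
specbind run --config bundle/study.yaml # consolidated report.json
specbind qsar                           # parity metrics of the packaged table
```

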