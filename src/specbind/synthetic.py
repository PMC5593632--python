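"""Synthetic instrument data with known ground truth.

Every downstream stage of the pipeline (quenching, binding, FRET, Ellman
dose-response, QSAR parity metrics) is exercised against data generated here,
because the underlying raw spectra of the study this package models are not
deposited anywhere.  Each generator embeds the governing relation exactly
before noise is added, so parameter-recovery tests can demand agreement to
numerical precision in the noiseless limit:

* fluorescence titrations obey the Stern-Volmer law F0/F = 1 + Ksv.[Q]
  (or, in ``double_log`` mode, the binding isotherm (F0-F)/F = K.[Q]^n)
  at the fixed read-out wavelength, with a Gaussian emission band that
  red-shifts with quencher concentration;
* donor-emission / acceptor-absorptivity pairs are Gaussian bands with an
  analytically known spectral overlap;
* Ellman-assay absorbance quadruples are constructed so the inhibition-ratio
  formula recovers a logistic dose-response exactly;
* QSAR tables follow an additive fragment-contribution model
  pred = c + R1 + R2.

Noise models: multiplicative Gaussian noise on fluorescence (shot-noise
proxy) and additive Gaussian noise on plate-reader absorbances.  All
generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .errors import ValidationError
from .qsar import QsarRecord, Split
from .spectra import Spectrum, SpectrumKind, TitrationSeries

__all__ = [
    "QuenchSimConfig",
    "EllmanSimConfig",
    "simulate_quench_titration",
    "simulate_fret_pair",
    "simulate_ellman_assay",
    "simulate_qsar_table",
    "PAPER_QUENCH_CONCS_M",
    "ELLMAN_CONCS_UG_ML",
]

#: Nine-point quencher-concentration ladder used throughout (mol/L):
#: 0 to 1.14e-6 M in the steps of the published titration.
PAPER_QUENCH_CONCS_M: tuple[float, ...] = tuple(
    c * 1e-6 for c in (0.0, 0.14, 0.29, 0.43, 0.57, 0.71, 0.86, 1.00, 1.14)
)

#: Eight-point inhibitor-concentration ladder for the Ellman assay (ug/mL).
ELLMAN_CONCS_UG_ML: tuple[float, ...] = (2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 9.0)

# Default red shift: ~4 nm across the full 1.14e-6 M titration range,
# matching the band movement seen for the peptide-backbone emission.
_DEFAULT_RED_SHIFT_NM_PER_M = 4.0 / 1.14e-6


@dataclass
class QuenchSimConfig:
    """Ground truth and instrument model for one quenching titration.

    ``law`` selects which relation the fixed-wavelength intensity follows
    exactly in the noiseless limit: the Stern-Volmer quenching law with
    constant ``Ksv_true``, or the double-logarithmic binding isotherm with
    constant ``K_true`` and site count ``n_true``.
    """

    Ksv_true: float = 22.84e6          # L/mol
    K_true: float = 22.47e6            # L/mol
    n_true: float = 1.02               # binding sites
    band_center_nm: float = 330.0
    band_sigma_nm: float = 25.0
    band_amplitude: float = 1000.0     # arbitrary fluorescence units
    red_shift_nm_per_M: float = _DEFAULT_RED_SHIFT_NM_PER_M
    concs_M: tuple[float, ...] = PAPER_QUENCH_CONCS_M
    noise_cv: float = 0.0              # coefficient of variation, multiplicative
    seed: int = 0
    law: Literal["stern_volmer", "double_log"] = "stern_volmer"
    grid_step_nm: float = 0.5
    grid_halfwidth_sigmas: float = 4.0

    def __post_init__(self) -> None:
        concs = np.asarray(self.concs_M, dtype=float)
        if len(concs) == 0 or concs[0] != 0.0:
            raise ValidationError("concentration ladder must start at 0")
        if np.any(np.diff(concs) <= 0):
            raise ValidationError("concentrations must increase strictly")
        if not (0.0 <= self.noise_cv < 0.2):
            raise ValidationError("noise_cv must lie in [0, 0.2)")
        for name in ("Ksv_true", "K_true", "n_true", "band_center_nm",
                     "band_sigma_nm", "band_amplitude", "grid_step_nm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


def _gaussian_band(grid: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / sigma) ** 2)


def simulate_quench_titration(
    cfg: QuenchSimConfig,
    temperature_K: float = 298.0,
    excitation_nm: float = 230.0,
    protein_conc_M: float = 5e-8,
) -> TitrationSeries:
    """Generate one emission-spectrum titration series.

    The wavelength grid is centred on the zero-quencher band centre (which
    therefore lies exactly on a grid node) and spans
    ``+/- grid_halfwidth_sigmas`` band widths.  For each quencher
    concentration the Gaussian band is red-shifted by
    ``red_shift_nm_per_M * [Q]`` and its amplitude rescaled so that the
    intensity *at the fixed zero-quencher peak wavelength* satisfies the
    configured law exactly; multiplicative noise is applied afterwards.
    """
    rng = np.random.default_rng(cfg.seed)
    half = int(round(cfg.grid_halfwidth_sigmas * cfg.band_sigma_nm / cfg.grid_step_nm))
    grid = cfg.band_center_nm + np.arange(-half, half + 1) * cfg.grid_step_nm
    lam0 = cfg.band_center_nm
    concs = np.asarray(cfg.concs_M, dtype=float)

    spectra = []
    for q in concs:
        if cfg.law == "stern_volmer":
            target = cfg.band_amplitude / (1.0 + cfg.Ksv_true * q)
        else:
            target = cfg.band_amplitude / (1.0 + cfg.K_true * q ** cfg.n_true)
        center = cfg.band_center_nm + cfg.red_shift_nm_per_M * q
        shape = _gaussian_band(grid, center, cfg.band_sigma_nm)
        at_lam0 = _gaussian_band(np.array([lam0]), center, cfg.band_sigma_nm)[0]
        values = (target / at_lam0) * shape
        if cfg.noise_cv > 0:
            values = values * rng.normal(1.0, cfg.noise_cv, size=values.shape)
            values = np.clip(values, 0.0, None)
        spectra.append(
            Spectrum(
                grid, values, SpectrumKind.EMISSION, "arb",
                {"excitation_nm": excitation_nm, "temperature_K": temperature_K,
                 "quencher_conc_M": float(q)},
            )
        )
    return TitrationSeries(
        protein_conc_M=protein_conc_M,
        quencher_concs_M=concs,
        spectra=spectra,
        temperature_K=temperature_K,
        excitation_nm=excitation_nm,
    )


def simulate_fret_pair(
    donor_center_nm: float = 330.0,
    donor_sigma_nm: float = 25.0,
    acceptor_center_nm: float = 340.0,
    acceptor_sigma_nm: float = 30.0,
    eps_max: float = 1.0e4,
    donor_amplitude: float = 1000.0,
    grid_step_nm: float = 0.25,
    halfwidth_sigmas: float = 5.0,
) -> tuple[Spectrum, Spectrum]:
    """Gaussian donor-emission / acceptor-molar-absorptivity pair.

    Both bands are sampled on their own grids (centre +/- 5 sigma); the
    acceptor peak molar absorptivity is ``eps_max`` in L mol^-1 cm^-1.
    The overlap integral of such a pair has a closed narrow-band limit
    (eps_max * lambda^4 at the shared centre), used as an oracle in tests.
    """
    if donor_sigma_nm <= 0 or acceptor_sigma_nm <= 0:
        raise ValidationError("band widths must be positive")
    if eps_max <= 0 or donor_amplitude <= 0:
        raise ValidationError("amplitudes must be positive")

    def band(center: float, sigma: float, amp: float, kind: SpectrumKind, unit: str) -> Spectrum:
        half = int(round(halfwidth_sigmas * sigma / grid_step_nm))
        grid = center + np.arange(-half, half + 1) * grid_step_nm
        # Keep wavelengths physical (positive) for extreme configurations.
        grid = grid[grid > 0]
        return Spectrum(grid, amp * _gaussian_band(grid, center, sigma), kind, unit)

    donor = band(donor_center_nm, donor_sigma_nm, donor_amplitude,
                 SpectrumKind.EMISSION, "arb")
    acceptor = band(acceptor_center_nm, acceptor_sigma_nm, eps_max,
                    SpectrumKind.MOLAR_ABSORPTIVITY, "L/(mol cm)")
    return donor, acceptor


@dataclass
class EllmanSimConfig:
    """Ground truth for a simulated Ellman-assay dose-response plate."""

    ic50_true: float = 3.478           # ug/mL
    hill: float = 2.0
    concs_ug_mL: tuple[float, ...] = ELLMAN_CONCS_UG_ML
    A3_minus_A4: float = 0.5           # absorbance span of the assay window
    baseline_abs: float = 0.05         # A2 = A4 = this constant
    noise_sd_abs: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.concs_ug_mL) <= 0):
            raise ValidationError("concentrations must be positive")
        if self.hill <= 0 or self.ic50_true <= 0 or self.A3_minus_A4 <= 0:
            raise ValidationError("ic50_true, hill and A3_minus_A4 must be positive")
        if self.noise_sd_abs < 0:
            raise ValidationError("noise_sd_abs must be >= 0")


def simulate_ellman_assay(cfg: EllmanSimConfig) -> "pd.DataFrame":
    """Absorbance quadruples (A1..A4) per inhibitor concentration.

    The true inhibition ratio follows the logistic
    ``R(c) = 1 / (1 + (IC50/c)^hill)``; absorbances are constructed as
    ``A2 = A4 = baseline``, ``A3 = baseline + span`` and
    ``A1 = A4 + (1 - R) * span`` so that the Ellman ratio
    ``[(A3-A4) - (A1-A2)] / (A3-A4)`` returns R(c) exactly before noise.
    Additive Gaussian noise of sd ``noise_sd_abs`` is applied to each
    absorbance independently.
    """
    import pandas as pd

    rng = np.random.default_rng(cfg.seed)
    rows = []
    for c in cfg.concs_ug_mL:
        r_true = 1.0 / (1.0 + (cfg.ic50_true / c) ** cfg.hill)
        a4 = cfg.baseline_abs
        a2 = cfg.baseline_abs
        a3 = a4 + cfg.A3_minus_A4
        a1 = a4 + (1.0 - r_true) * cfg.A3_minus_A4
        a = np.array([a1, a2, a3, a4])
        if cfg.noise_sd_abs > 0:
            a = np.clip(a + rng.normal(0.0, cfg.noise_sd_abs, size=4), 0.0, None)
        rows.append({"conc": c, "A1": a[0], "A2": a[1], "A3": a[2], "A4": a[3]})
    return pd.DataFrame(rows)


# Uniform ranges of the fragment-contribution columns, mirroring the spread
# observed across the evaluated inhibitor series.
_R1_RANGE = (-2.1, 1.5)
_R2_RANGE = (-0.8, 5.9)


def simulate_qsar_table(
    n_train: int = 47,
    n_test: int = 14,
    c_true: float = 5.77,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[QsarRecord]:
    """Synthetic additive fragment-contribution activity table.

    Each compound's predicted activity is ``c_true + R1 + R2`` with R1, R2
    uniform on the observed fragment ranges; the experimental activity adds
    Gaussian noise of sd ``noise_sd``.  Rows are labelled train/test.
    """
    if n_train < 2 or n_test < 2:
        raise ValidationError("need at least two rows per split")
    rng = np.random.default_rng(seed)
    records = []
    n = n_train + n_test
    r1 = rng.uniform(*_R1_RANGE, size=n)
    r2 = rng.uniform(*_R2_RANGE, size=n)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    for i in range(n):
        pred = c_true + r1[i] + r2[i]
        split = Split.TRAIN if i < n_train else Split.TEST
        records.append(
            QsarRecord(
                compound_id=f"S{i + 1}",
                exp_pic50=pred + noise[i],
                pred_pic50=pred,
                R1=float(r1[i]),
                R2=float(r2[i]),
                split=split,
            )
        )
    return records
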