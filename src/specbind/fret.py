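"""Forster resonance-energy-transfer (FRET) distance determination.

For a donor fluorophore (here the protein's intrinsic emission) and an
acceptor chromophore (the bound ligand's absorption band), non-radiative
energy transfer is governed by three quantities:

* the **spectral overlap integral**

      J = [ sum F(l) eps(l) l^4 dl ] / [ sum F(l) dl ]      (cm^3 L mol^-1)

  where F is the donor emission (arbitrary units, it cancels), eps the
  acceptor molar absorptivity in L mol^-1 cm^-1, and the wavelength enters
  as l^4 in cm^4;

* the **Forster radius** R0, the donor-acceptor separation at 50% transfer
  efficiency,

      R0^6 = 8.8e-25 * K^2 * Phi * n^-4 * J                 (cm^6)

  with orientation factor K^2 (2/3 for isotropic tumbling), donor quantum
  yield Phi, and medium refractive index n;

* the **transfer efficiency** E = 1 - F/F0 = R0^6 / (R0^6 + r^6), inverted
  to give the donor-acceptor distance r = R0 * (1/E - 1)^(1/6).

Transfer is considered plausible when r < 7 nm and 0.5*R0 < r < 1.5*R0;
both checks are reported as validity flags on the result.

Numerics: wavelengths are nm everywhere outside the integrand; the l^4
factor is converted to cm inside the sum, and the grid step cancels between
numerator and denominator so may stay in nm.  Integration uses trapezoidal
weights on the intersection of the two spectral spans (numerator) and the
donor's full native span (denominator).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataQualityWarning, ValidationError
from .spectra import Spectrum, interpolate_to_grid

__all__ = [
    "FretResult",
    "overlap_integral",
    "forster_radius",
    "transfer_efficiency",
    "donor_acceptor_distance",
    "analyze_fret",
    "DEFAULT_K2",
    "DEFAULT_REFRACTIVE_N",
    "DEFAULT_QUANTUM_YIELD",
    "MAX_TRANSFER_DISTANCE_NM",
]

#: Orientation factor for randomly oriented dipoles.
DEFAULT_K2 = 2.0 / 3.0
#: Refractive index of dilute aqueous solution.
DEFAULT_REFRACTIVE_N = 1.336
#: Donor fluorescence quantum yield used by default.
DEFAULT_QUANTUM_YIELD = 0.15
#: Distance ceiling (nm) for appreciable resonance energy transfer.
MAX_TRANSFER_DISTANCE_NM = 7.0

_NM_TO_CM = 1e-7
_CM_TO_NM = 1e7
_FORSTER_PREFACTOR = 8.8e-25  # cm^6 per (cm^3 L mol^-1), dimensionally folded


@dataclass
class FretResult:
    """Complete FRET parameter block with validity flags."""

    J_cm3_L_per_mol: float
    R0_nm: float
    E: float
    r_nm: float
    K2: float
    refractive_n: float
    phi: float
    valid_distance: bool   # r below the 7 nm transfer ceiling
    valid_ratio: bool      # 0.5*R0 < r < 1.5*R0

    def to_dict(self) -> dict:
        return {
            "J_cm3_L_per_mol": self.J_cm3_L_per_mol,
            "R0_nm": self.R0_nm,
            "E": self.E,
            "r_nm": self.r_nm,
            "K2": self.K2,
            "refractive_n": self.refractive_n,
            "phi": self.phi,
            "valid_distance": self.valid_distance,
            "valid_ratio": self.valid_ratio,
        }


def overlap_integral(
    donor_emission: Spectrum,
    acceptor_eps: Spectrum,
    grid_step_nm: float = 0.5,
) -> float:
    """Normalized spectral overlap J in cm^3 L mol^-1.

    The numerator integrates F*eps*l^4 over the intersection of the donor
    and acceptor spans at ``grid_step_nm`` resolution; the denominator
    integrates the donor emission over its full native span, so donor
    intensity outside the overlap region still normalizes J.  Disjoint
    spectra yield J = 0 with a warning.
    """
    if grid_step_nm <= 0:
        raise ValidationError("grid step must be positive")
    d_lo, d_hi = donor_emission.span_nm
    a_lo, a_hi = acceptor_eps.span_nm
    lo, hi = max(d_lo, a_lo), min(d_hi, a_hi)
    if hi <= lo:
        warnings.warn(
            "donor emission and acceptor absorption do not overlap; J = 0",
            DataQualityWarning,
            stacklevel=2,
        )
        return 0.0
    n_steps = max(int(np.ceil((hi - lo) / grid_step_nm)), 1)
    grid = np.linspace(lo, hi, n_steps + 1)
    if len(grid) < 2:
        raise ValidationError("overlap grid degenerate")
    f = interpolate_to_grid(donor_emission, grid).values
    eps = interpolate_to_grid(acceptor_eps, grid).values
    lam_cm4 = (grid * _NM_TO_CM) ** 4
    numerator = np.trapezoid(f * eps * lam_cm4, grid)
    denominator = np.trapezoid(donor_emission.values, donor_emission.wavelengths_nm)
    if denominator <= 0:
        raise ValidationError("donor emission integrates to zero")
    return float(numerator / denominator)


def forster_radius(
    J: float,
    K2: float = DEFAULT_K2,
    refractive_n: float = DEFAULT_REFRACTIVE_N,
    phi: float = DEFAULT_QUANTUM_YIELD,
) -> float:
    """Forster radius R0 in nm from the overlap integral (cm^3 L mol^-1)."""
    for name, v in (("J", J), ("K2", K2), ("refractive_n", refractive_n), ("phi", phi)):
        if v <= 0:
            raise ValidationError(f"{name} must be positive, got {v!r}")
    r0_cm6 = _FORSTER_PREFACTOR * K2 * phi * refractive_n ** -4 * J
    return float(r0_cm6 ** (1.0 / 6.0) * _CM_TO_NM)


def transfer_efficiency(F0: float, F: float) -> float:
    """E = 1 - F/F0 from intensities with and without the acceptor."""
    if F0 <= 0:
        raise ValidationError("F0 must be positive")
    if F <= 0:
        raise ValidationError("F must be positive")
    if F > F0:
        raise ValidationError("F > F0 would mean negative transfer efficiency")
    return float(1.0 - F / F0)


def donor_acceptor_distance(R0_nm: float, E: float) -> float:
    """Invert E = R0^6/(R0^6 + r^6) to the donor-acceptor distance r (nm)."""
    if R0_nm <= 0:
        raise ValidationError("R0 must be positive")
    if not (0.0 < E < 1.0):
        raise ValidationError(f"efficiency must lie in (0, 1), got {E!r}")
    return float(R0_nm * (1.0 / E - 1.0) ** (1.0 / 6.0))


def analyze_fret(
    donor_emission: Spectrum,
    acceptor_eps: Spectrum,
    F0: float,
    F: float,
    K2: float = DEFAULT_K2,
    refractive_n: float = DEFAULT_REFRACTIVE_N,
    phi: float = DEFAULT_QUANTUM_YIELD,
    grid_step_nm: float = 0.5,
) -> FretResult:
    """Full FRET chain: J -> R0 -> E -> r, with validity flags."""
    J = overlap_integral(donor_emission, acceptor_eps, grid_step_nm)
    if J <= 0:
        raise ValidationError("zero spectral overlap: FRET distance undefined")
    R0 = forster_radius(J, K2, refractive_n, phi)
    E = transfer_efficiency(F0, F)
    if E <= 0:
        raise ValidationError("no measurable quenching (E = 0): r undefined")
    r = donor_acceptor_distance(R0, E)
    return FretResult(
        J_cm3_L_per_mol=J,
        R0_nm=R0,
        E=E,
        r_nm=r,
        K2=K2,
        refractive_n=refractive_n,
        phi=phi,
        valid_distance=r < MAX_TRANSFER_DISTANCE_NM,
        valid_ratio=0.5 * R0 < r < 1.5 * R0,
    )
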