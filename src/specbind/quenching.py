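"""Stern-Volmer fluorescence-quenching analysis.

The Stern-Volmer relation ``F0/F = 1 + kq*tau0*[Q] = 1 + Ksv*[Q]`` links the
ratio of unquenched to quenched fluorescence intensity to the quencher
concentration.  The slope Ksv (L/mol) is the quenching constant; dividing it
by the unquenched fluorophore lifetime tau0 (canonically ~1e-8 s for
biomolecules) gives the apparent bimolecular quenching rate constant kq.

Mechanism classification follows the standard temperature logic: a Ksv that
*falls* as temperature rises, together with kq far above the diffusion-limited
ceiling for biomolecular collisional quenching (2.0e10 L mol^-1 s^-1),
indicates static quenching via a ground-state complex; a rising Ksv with kq
below the ceiling indicates dynamic (collisional) quenching.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError
from .spectra import TitrationSeries

__all__ = [
    "QuenchingFit",
    "Mechanism",
    "stern_volmer_fit",
    "classify_mechanism",
    "DEFAULT_TAU0_S",
    "DIFFUSION_LIMIT_KQ",
]

#: Default unquenched fluorescence lifetime of a biomolecule, seconds.
DEFAULT_TAU0_S = 1e-8

#: Maximum diffusion-limited quenching rate constant, L mol^-1 s^-1.
DIFFUSION_LIMIT_KQ = 2.0e10


@dataclass
class QuenchingFit:
    """Result of a linear Stern-Volmer fit at one temperature."""

    Ksv: float            # L/mol, slope of F0/F vs [Q]
    kq: float             # L mol^-1 s^-1, Ksv / tau0
    tau0_s: float
    intercept: float      # dimensionless, ~1 for well-behaved data
    pearson_R: float
    temperature_K: float
    n_points: int
    readout_nm: float | None = None

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise ValidationError("a quenching fit needs at least 3 points")

    @property
    def is_physical(self) -> bool:
        """Negative slopes indicate enhancement, not quenching."""
        return self.Ksv >= 0

    def to_dict(self) -> dict:
        return {
            "Ksv_L_per_mol": self.Ksv,
            "kq_L_per_mol_s": self.kq,
            "tau0_s": self.tau0_s,
            "intercept": self.intercept,
            "pearson_R": round(self.pearson_R, 3),
            "temperature_K": self.temperature_K,
            "n_points": self.n_points,
            "readout_nm": self.readout_nm,
        }


def stern_volmer_fit(
    series: TitrationSeries,
    tau0_s: float = DEFAULT_TAU0_S,
    readout: float | str = "fixed",
) -> QuenchingFit:
    """Ordinary least-squares Stern-Volmer fit of one titration.

    F0 is the intensity of the zero-quencher spectrum; F0/F is regressed
    against [Q] over all points including [Q] = 0, without forcing the
    intercept to 1 (the reported correlation then genuinely measures
    linearity).  ``readout`` selects the intensity read-out policy, see
    :meth:`TitrationSeries.readout_wavelength_nm`.
    """
    if len(series) < 3:
        raise InsufficientDataError(
            f"need >= 3 titration points, got {len(series)}"
        )
    if tau0_s <= 0:
        raise ValidationError("tau0 must be positive")
    f = series.intensities(readout)
    zero = np.flatnonzero(f <= 0)
    if zero.size:
        raise ValidationError(
            f"non-positive intensity at titration index {int(zero[0])}; "
            "cannot form F0/F"
        )
    ratios = f[0] / f
    q = series.quencher_concs_M
    res = stats.linregress(q, ratios)
    return QuenchingFit(
        Ksv=float(res.slope),
        kq=float(res.slope) / tau0_s,
        tau0_s=tau0_s,
        intercept=float(res.intercept),
        pearson_R=float(res.rvalue),
        temperature_K=series.temperature_K,
        n_points=len(series),
        readout_nm=series.readout_wavelength_nm(readout),
    )


class Mechanism(str, enum.Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"
    INDETERMINATE = "indeterminate"


def classify_mechanism(
    fits: Sequence[QuenchingFit],
    kq_threshold: float = DIFFUSION_LIMIT_KQ,
) -> tuple[Mechanism, str]:
    """Classify the quenching mechanism from fits at several temperatures.

    Static: Ksv strictly decreasing with temperature AND every kq above the
    diffusion ceiling.  Dynamic: Ksv strictly increasing AND every kq at or
    below the ceiling.  Anything else is indeterminate, with the reason
    spelled out in the returned rationale.
    """
    if len(fits) < 2:
        raise ValidationError("need fits at >= 2 temperatures")
    temps = [f.temperature_K for f in fits]
    if len(set(temps)) != len(temps):
        raise ValidationError("duplicate temperatures in mechanism analysis")
    ordered = sorted(fits, key=lambda f: f.temperature_K)
    ksv = np.array([f.Ksv for f in ordered])
    kq = np.array([f.kq for f in ordered])
    decreasing = bool(np.all(np.diff(ksv) < 0))
    increasing = bool(np.all(np.diff(ksv) > 0))
    all_above = bool(np.all(kq > kq_threshold))
    all_below = bool(np.all(kq <= kq_threshold))

    ksv_str = ", ".join(f"{f.Ksv:.4g}" for f in ordered)
    t_str = ", ".join(f"{f.temperature_K:g} K" for f in ordered)
    if decreasing and all_above:
        return Mechanism.STATIC, (
            f"Ksv falls with temperature ({ksv_str} at {t_str}) and every kq "
            f"exceeds the diffusion-limited ceiling {kq_threshold:.2g}: "
            "ground-state complex (static) quenching."
        )
    if increasing and all_below:
        return Mechanism.DYNAMIC, (
            f"Ksv rises with temperature ({ksv_str} at {t_str}) and kq stays "
            f"at or below {kq_threshold:.2g}: collisional (dynamic) quenching."
        )
    reasons = []
    if not (decreasing or increasing):
        reasons.append(f"Ksv is not monotone in temperature ({ksv_str})")
    if decreasing and not all_above:
        reasons.append("Ksv falls but some kq is below the diffusion ceiling")
    if increasing and not all_below:
        reasons.append("Ksv rises but some kq exceeds the diffusion ceiling")
    return Mechanism.INDETERMINATE, "; ".join(reasons) or "conflicting evidence"
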