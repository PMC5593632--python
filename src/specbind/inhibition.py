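"""Ellman-assay inhibition analysis: inhibition ratio, IC50, pIC50.

The colorimetric Ellman assay reads acetylcholinesterase activity as
absorbance at 405 nm.  Four plate groups are measured per inhibitor
concentration: sample (A1), sample-without-enzyme (A2), blank (A3), and
completely-inhibited (A4).  The inhibition ratio is

    R = [(A3 - A4) - (A1 - A2)] / (A3 - A4)

so R = 0 means full enzyme activity and R = 1 complete inhibition.

IC50 is estimated by least-squares fit of a two-parameter logistic in
log10 concentration, R(c) = 1 / (1 + (IC50/c)^h), with bottom fixed at 0
and top at 1 (the ratio is already normalized by construction).  pIC50 is
the negative base-10 logarithm of the *molar* IC50, so converting from a
mass concentration requires the compound's molecular weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    DataQualityWarning,
    ExtrapolationWarning,
    FitError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "EllmanRecord",
    "Ic50Result",
    "inhibition_ratio",
    "fit_ic50",
    "pic50_from_mass_ic50",
    "implied_molecular_weight",
    "read_ellman_csv",
]


@dataclass
class EllmanRecord:
    """One concentration's absorbance quadruple (all in AU)."""

    conc: float   # ug/mL
    A1: float     # sample group
    A2: float     # sample-out group (no enzyme)
    A3: float     # blank group (full activity)
    A4: float     # completely inhibited group

    def __post_init__(self) -> None:
        if self.conc <= 0:
            raise ValidationError("concentration must be positive")
        for name in ("A1", "A2", "A3", "A4"):
            if getattr(self, name) < 0:
                raise ValidationError(f"absorbance {name} must be >= 0")


@dataclass
class Ic50Result:
    ic50: float               # ug/mL
    hill: float
    se_ic50: float
    pIC50: float | None = None
    mw_g_mol: float | None = None

    def to_dict(self) -> dict:
        return {
            "ic50_ug_mL": self.ic50,
            "hill": self.hill,
            "se_ic50_ug_mL": self.se_ic50,
            "pIC50": self.pIC50,
            "mw_g_mol": self.mw_g_mol,
        }


def inhibition_ratio(rec: EllmanRecord) -> float:
    """Ellman inhibition ratio R for one record; not clamped to [0, 1]."""
    span = rec.A3 - rec.A4
    if span == 0:
        raise ZeroDivisionError(
            "A3 == A4: assay window is zero, inhibition ratio undefined"
        )
    r = (span - (rec.A1 - rec.A2)) / span
    if not (0.0 <= r <= 1.0):
        warnings.warn(
            f"inhibition ratio {r:.4g} outside [0, 1] at conc {rec.conc:g}",
            DataQualityWarning,
            stacklevel=2,
        )
    return float(r)


def _logistic_log10(log_c: np.ndarray, log_ic50: float, hill: float) -> np.ndarray:
    return 1.0 / (1.0 + 10.0 ** (hill * (log_ic50 - log_c)))


def fit_ic50(
    records: Sequence[EllmanRecord],
    mw_g_mol: float | None = None,
) -> Ic50Result:
    """Fit a two-parameter logistic dose-response and return IC50.

    Replicate records at one concentration are averaged (on the ratio scale)
    before fitting.  At least four distinct concentrations are required, and
    the measured ratios should bracket R = 0.5; if they do not, the estimate
    is an extrapolation and :class:`ExtrapolationWarning` is emitted.  The
    standard error of IC50 comes from the fit covariance via the delta
    method.  Supplying ``mw_g_mol`` adds the pIC50 conversion.
    """
    if len(records) == 0:
        raise InsufficientDataError("no Ellman records supplied")
    ratios = pd.DataFrame(
        {"conc": [r.conc for r in records],
         "R": [inhibition_ratio(r) for r in records]}
    ).groupby("conc", sort=True)["R"].mean()
    concs = ratios.index.to_numpy(dtype=float)
    r_obs = ratios.to_numpy(dtype=float)
    if len(concs) < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct concentrations, got {len(concs)}"
        )
    if r_obs.min() > 0.5 or r_obs.max() < 0.5:
        warnings.warn(
            "inhibition ratios never cross 0.5 inside the measured span; "
            "IC50 is an extrapolation",
            ExtrapolationWarning,
            stacklevel=2,
        )
    if np.ptp(r_obs) < 1e-12:
        raise FitError(
            "inhibition ratio is flat across all concentrations: "
            "dose-response parameters are unidentifiable"
        )
    log_c = np.log10(concs)
    # Start at the concentration whose ratio is closest to the midpoint.
    p0 = (float(log_c[np.argmin(np.abs(r_obs - 0.5))]), 1.0)
    lo = (log_c.min() - 6.0, 1e-3)
    hi = (log_c.max() + 6.0, 1e3)
    try:
        popt, pcov = curve_fit(
            _logistic_log10, log_c, r_obs, p0=p0, bounds=(lo, hi), maxfev=20000
        )
    except RuntimeError as exc:
        raise FitError(f"dose-response fit did not converge: {exc}") from exc
    log_ic50, hill = popt
    if not (lo[0] < log_ic50 < hi[0]):
        raise FitError("IC50 estimate pinned at parameter bound: no finite estimate")
    ic50 = float(10.0 ** log_ic50)
    var_log = float(pcov[0, 0]) if np.isfinite(pcov[0, 0]) else np.nan
    se_ic50 = float(np.log(10.0) * ic50 * np.sqrt(var_log)) if var_log == var_log else float("nan")
    pic50 = pic50_from_mass_ic50(ic50, mw_g_mol) if mw_g_mol is not None else None
    return Ic50Result(
        ic50=ic50, hill=float(hill), se_ic50=se_ic50,
        pIC50=pic50, mw_g_mol=mw_g_mol,
    )


def pic50_from_mass_ic50(ic50_ug_mL: float, mw_g_mol: float) -> float:
    """pIC50 = -log10(IC50 in mol/L), from a mass IC50 in ug/mL.

    ug/mL is mg/L, so the molar IC50 is ``ic50 * 1e-3 / mw`` mol/L.
    """
    if ic50_ug_mL <= 0 or mw_g_mol <= 0:
        raise ValidationError("ic50 and molecular weight must be positive")
    return float(-np.log10(ic50_ug_mL * 1e-3 / mw_g_mol))


def implied_molecular_weight(ic50_ug_mL: float, pic50: float) -> float:
    """Molecular weight (g/mol) consistent with a given (mass IC50, pIC50)."""
    if ic50_ug_mL <= 0:
        raise ValidationError("ic50 must be positive")
    return float(ic50_ug_mL * 1e-3 * 10.0 ** pic50)


def read_ellman_csv(path: str | Path) -> list[EllmanRecord]:
    """CSV with columns conc,A1,A2,A3,A4 (one row per concentration/replicate)."""
    df = pd.read_csv(path)
    required = {"conc", "A1", "A2", "A3", "A4"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"Ellman CSV missing columns {sorted(missing)}")
    return [
        EllmanRecord(float(r.conc), float(r.A1), float(r.A2), float(r.A3), float(r.A4))
        for r in df.itertuples()
    ]
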