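"""Binding-constant and binding-site estimation from quenching titrations.

Two standard linearisations of static-quenching data are provided, both
using base-10 logarithms:

* the double-logarithmic plot ``lg((F0-F)/F) = lg K + n * lg [Q]``, whose
  slope is the number of equivalent binding sites n and whose intercept
  gives the association constant K (L/mol);
* the modified Stern-Volmer plot ``F0/(F0-F) = 1 + (1/K) * (1/[Q])``,
  which assumes a single site and recovers K from the reciprocal slope.

For noiseless single-site data the two estimators agree exactly; when they
disagree on real data both are reported side by side rather than reconciled.
The zero-quencher point is excluded from both fits (its log/reciprocal is
undefined), and points where the intensity has not dropped below F0 are
excluded with a warning.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataQualityWarning, FitError, InsufficientDataError, ValidationError
from .spectra import TitrationSeries

__all__ = ["BindingFit", "BindingMethod", "double_log_fit", "modified_sv_fit"]


class BindingMethod(str, enum.Enum):
    DOUBLE_LOG = "double_log"
    MODIFIED_SV = "modified_sv"


@dataclass
class BindingFit:
    """Fitted association constant and site count at one temperature."""

    K: float              # L/mol
    n_sites: float        # 1.0 by construction for modified_sv
    pearson_R: float
    method: BindingMethod
    temperature_K: float
    n_points: int

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValidationError("binding constant must be positive")
        if self.n_sites <= 0:
            raise ValidationError("site count must be positive")

    def to_dict(self) -> dict:
        return {
            "K_L_per_mol": self.K,
            "n_sites": self.n_sites,
            "pearson_R": round(self.pearson_R, 3),
            "method": self.method.value,
            "temperature_K": self.temperature_K,
            "n_points": self.n_points,
        }


def _usable_points(
    series: TitrationSeries, readout: float | str
) -> tuple[np.ndarray, np.ndarray, float]:
    """Nonzero-concentration points with F strictly below F0."""
    f = series.intensities(readout)
    f0 = f[0]
    if f0 <= 0:
        raise ValidationError("zero-quencher intensity F0 must be positive")
    q = series.quencher_concs_M[1:]
    fq = f[1:]
    bad = fq >= f0
    if np.any(bad):
        idx = np.flatnonzero(bad)
        warnings.warn(
            f"excluding {idx.size} point(s) with F >= F0 at indices "
            f"{(idx + 1).tolist()} (no net quenching)",
            DataQualityWarning,
            stacklevel=3,
        )
        q, fq = q[~bad], fq[~bad]
    if np.any(fq <= 0):
        raise ValidationError("quenched intensity must be positive")
    if len(q) < 3:
        raise InsufficientDataError(
            f"need >= 3 usable nonzero-quencher points, got {len(q)}"
        )
    return q, fq, float(f0)


def double_log_fit(
    series: TitrationSeries, readout: float | str = "fixed"
) -> BindingFit:
    """OLS fit of lg((F0-F)/F) against lg [Q]: slope n, intercept lg K."""
    q, f, f0 = _usable_points(series, readout)
    y = np.log10((f0 - f) / f)
    x = np.log10(q)
    res = stats.linregress(x, y)
    return BindingFit(
        K=float(10.0 ** res.intercept),
        n_sites=float(res.slope),
        pearson_R=float(res.rvalue),
        method=BindingMethod.DOUBLE_LOG,
        temperature_K=series.temperature_K,
        n_points=len(q),
    )


def modified_sv_fit(
    series: TitrationSeries, readout: float | str = "fixed"
) -> BindingFit:
    """OLS fit of F0/(F0-F) against 1/[Q]; K is the reciprocal slope.

    Assumes a single binding site (n fixed at 1).  A slope indistinguishable
    from zero means F0/(F0-F) does not depend on 1/[Q] and K diverges; this
    degenerate case raises :class:`FitError`.
    """
    q, f, f0 = _usable_points(series, readout)
    y = f0 / (f0 - f)
    x = 1.0 / q
    res = stats.linregress(x, y)
    # Degenerate when the fitted slope is negligible against the data scale.
    scale = np.max(np.abs(y)) / np.max(x)
    if abs(res.slope) <= 1e-12 * max(scale, 1e-300):
        raise FitError(
            "modified Stern-Volmer slope ~ 0: binding constant diverges"
        )
    if res.slope < 0:
        raise FitError("negative modified Stern-Volmer slope: unphysical K")
    return BindingFit(
        K=float(1.0 / res.slope),
        n_sites=1.0,
        pearson_R=float(res.rvalue),
        method=BindingMethod.MODIFIED_SV,
        temperature_K=series.temperature_K,
        n_points=len(q),
    )
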