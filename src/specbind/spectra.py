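"""Core spectral containers and text-format I/O.

A :class:`Spectrum` is a wavelength-ordered trace of one signal — fluorescence
emission, UV-vis absorbance, molar absorptivity, or circular dichroism — with
a unit tag and free-form acquisition metadata.  A :class:`TitrationSeries`
bundles the emission spectra recorded while a quencher is titrated into a
protein solution at one temperature and excitation wavelength; its
zero-quencher entry defines the unquenched intensity F0 used by every
downstream fit.

Files are plain two-column delimited text (wavelength in nm, signal), with
``#`` comment lines; titration manifests are small YAML/JSON documents
pointing at the per-concentration spectrum files.
"""

from __future__ import annotations

import enum
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, RangeError, ValidationError

__all__ = [
    "SpectrumKind",
    "Spectrum",
    "TitrationSeries",
    "SecondaryStructureRow",
    "read_spectrum",
    "write_spectrum",
    "interpolate_to_grid",
    "intensity_at",
    "read_titration_manifest",
    "write_titration_manifest",
    "read_secondary_structure_csv",
    "validate_secondary_structure",
]


class SpectrumKind(str, enum.Enum):
    """What physical quantity a spectrum's values column holds."""

    EMISSION = "emission"
    ABSORPTION = "absorption"
    MOLAR_ABSORPTIVITY = "molar_absorptivity"
    CD = "cd"


# Kinds whose signal cannot physically be negative.
_NONNEGATIVE_KINDS = frozenset(
    {SpectrumKind.EMISSION, SpectrumKind.ABSORPTION, SpectrumKind.MOLAR_ABSORPTIVITY}
)


@dataclass
class Spectrum:
    """A single wavelength-ordered signal trace.

    Parameters
    ----------
    wavelengths_nm : array-like
        Strictly increasing wavelengths in nanometres, length >= 2.
    values : array-like
        Signal values aligned with the wavelengths.  Units depend on kind:
        arbitrary fluorescence units for emission, AU for absorbance,
        L mol^-1 cm^-1 for molar absorptivity, mdeg for CD.
    kind : SpectrumKind or str
    unit : str
        Human-readable unit tag (e.g. ``"AU"``, ``"L/(mol cm)"``).
    meta : dict
        Free-form metadata: ``excitation_nm``, ``temperature_K``, ``label``...
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: SpectrumKind
    unit: str = "arb"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.kind = SpectrumKind(self.kind)
        if self.wavelengths_nm.ndim != 1 or self.values.ndim != 1:
            raise ValidationError("wavelengths and values must be one-dimensional")
        if len(self.wavelengths_nm) != len(self.values):
            raise ValidationError(
                f"wavelengths ({len(self.wavelengths_nm)}) and values "
                f"({len(self.values)}) differ in length"
            )
        if len(self.wavelengths_nm) < 2:
            raise ValidationError("a spectrum needs at least two samples")
        dw = np.diff(self.wavelengths_nm)
        if np.any(dw == 0):
            idx = int(np.argmin(dw))
            raise ValidationError(
                f"duplicate wavelength {self.wavelengths_nm[idx]:g} nm"
            )
        if np.any(dw < 0):
            raise ValidationError("wavelengths must be strictly increasing")
        if self.kind in _NONNEGATIVE_KINDS and np.any(self.values < 0):
            raise ValidationError(f"{self.kind.value} values must be >= 0")

    # -- basic geometry -------------------------------------------------

    @property
    def span_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def peak_wavelength_nm(self) -> float:
        """Band-peak wavelength (emission-band read-out).

        Computed as the intensity-weighted centroid of the samples above 80%
        of the maximum, which coincides with the sampled maximum for clean
        symmetric bands but is robust to per-point instrument noise (a plain
        argmax systematically picks the largest upward noise excursion).
        """
        v = self.values
        w = np.clip(v - 0.8 * float(v.max()), 0.0, None)
        total = float(w.sum())
        if total <= 0:
            return float(self.wavelengths_nm[int(np.argmax(v))])
        return float(np.sum(self.wavelengths_nm * w) / total)

    def __len__(self) -> int:
        return len(self.wavelengths_nm)


def intensity_at(s: Spectrum, lambda_nm: float) -> float:
    """Linearly interpolated signal at ``lambda_nm``.

    Raises :class:`RangeError` if the wavelength lies outside the span.
    """
    lo, hi = s.span_nm
    if not (lo <= lambda_nm <= hi):
        raise RangeError(f"{lambda_nm:g} nm outside spectral span [{lo:g}, {hi:g}]")
    return float(np.interp(lambda_nm, s.wavelengths_nm, s.values))


def interpolate_to_grid(s: Spectrum, grid_nm: Sequence[float]) -> Spectrum:
    """Resample a spectrum onto ``grid_nm`` by linear interpolation.

    The grid must be strictly increasing and lie within the native span;
    native sample points are reproduced exactly.
    """
    grid = np.asarray(grid_nm, dtype=float)
    if grid.ndim != 1 or len(grid) == 0:
        raise ValidationError("grid must be a non-empty 1-D sequence")
    lo, hi = s.span_nm
    if grid[0] < lo or grid[-1] > hi:
        raise RangeError(
            f"grid [{grid[0]:g}, {grid[-1]:g}] nm exceeds spectral span "
            f"[{lo:g}, {hi:g}] nm"
        )
    vals = np.interp(grid, s.wavelengths_nm, s.values)
    return Spectrum(grid, vals, s.kind, s.unit, dict(s.meta))


# -- file I/O ------------------------------------------------------------

_DELIMS = re.compile(r"[,\s]+")


def read_spectrum(path: str | Path, kind: SpectrumKind | str, unit: str = "arb") -> Spectrum:
    """Read a two-column delimited text spectrum (wavelength nm, signal).

    Accepts whitespace, tab or comma delimiters and ``#`` comment lines.
    Rows may appear in any order; duplicated wavelengths are an error.
    """
    path = Path(path)
    wl: list[float] = []
    vals: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p for p in _DELIMS.split(line) if p]
            if len(parts) != 2:
                raise ParseError(
                    f"expected two columns, got {len(parts)}: {line!r}", lineno
                )
            try:
                wl.append(float(parts[0]))
                vals.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"non-numeric field in {line!r}", lineno) from exc
    order = np.argsort(wl, kind="stable")
    return Spectrum(
        np.asarray(wl)[order], np.asarray(vals)[order], kind, unit,
        {"source": str(path)},
    )


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a spectrum as two-column text, full double precision."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# kind: {s.kind.value}  unit: {s.unit}\n")
        for w, v in zip(s.wavelengths_nm, s.values):
            fh.write(f"{float(w)!r} {float(v)!r}\n")


# -- titration series ----------------------------------------------------


@dataclass
class TitrationSeries:
    """Emission spectra recorded across a quencher titration.

    The concentration axis must start at 0 (the unquenched reference that
    defines F0) and increase strictly; every spectrum must be an emission
    trace taken at the same excitation wavelength.
    """

    protein_conc_M: float
    quencher_concs_M: np.ndarray
    spectra: list[Spectrum]
    temperature_K: float
    excitation_nm: float

    def __post_init__(self) -> None:
        self.quencher_concs_M = np.asarray(self.quencher_concs_M, dtype=float)
        if self.protein_conc_M <= 0:
            raise ValidationError("protein concentration must be positive")
        if len(self.spectra) != len(self.quencher_concs_M):
            raise ValidationError("one spectrum required per concentration")
        if len(self.quencher_concs_M) == 0 or self.quencher_concs_M[0] != 0.0:
            raise ValidationError("first quencher concentration must be 0 (defines F0)")
        if np.any(np.diff(self.quencher_concs_M) <= 0):
            raise ValidationError("quencher concentrations must increase strictly")
        for i, s in enumerate(self.spectra):
            if s.kind is not SpectrumKind.EMISSION:
                raise ValidationError(f"spectrum {i} is {s.kind.value}, not emission")
            exc = s.meta.get("excitation_nm")
            if exc is not None and not np.isclose(exc, self.excitation_nm):
                raise ValidationError(
                    f"spectrum {i} excitation {exc} nm != series {self.excitation_nm} nm"
                )

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def f0_spectrum(self) -> Spectrum:
        return self.spectra[0]

    def readout_wavelength_nm(self, readout: float | str = "fixed") -> float | None:
        """Resolve the intensity read-out policy.

        ``"fixed"`` (default) reads every spectrum at the emission maximum of
        the zero-quencher spectrum, so a quencher-induced red shift of the
        band cannot masquerade as extra quenching.  ``"max"`` reads each
        spectrum at its own maximum.  A float reads at that wavelength.
        """
        if readout == "fixed":
            return self.f0_spectrum.peak_wavelength_nm()
        if readout == "max":
            return None
        return float(readout)

    def intensities(self, readout: float | str = "fixed") -> np.ndarray:
        """F values per concentration under the chosen read-out policy."""
        lam = self.readout_wavelength_nm(readout)
        if lam is None:
            return np.array([float(np.max(s.values)) for s in self.spectra])
        return np.array([intensity_at(s, lam) for s in self.spectra])


def read_titration_manifest(path: str | Path) -> TitrationSeries:
    """Load a titration from a YAML/JSON manifest.

    Schema::

        temperature_K: 298.0
        excitation_nm: 230.0
        protein_conc_M: 5.0e-8
        points:
          - {conc_M: 0.0, path: q000.txt}
          - {conc_M: 1.4e-7, path: q001.txt}

    Spectrum paths are resolved relative to the manifest's directory.
    """
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        points = doc["points"]
        concs = [float(p["conc_M"]) for p in points]
        spectra = [
            read_spectrum(path.parent / p["path"], SpectrumKind.EMISSION, "arb")
            for p in points
        ]
        for s in spectra:
            s.meta["excitation_nm"] = float(doc["excitation_nm"])
            s.meta["temperature_K"] = float(doc["temperature_K"])
        return TitrationSeries(
            protein_conc_M=float(doc["protein_conc_M"]),
            quencher_concs_M=np.asarray(concs),
            spectra=spectra,
            temperature_K=float(doc["temperature_K"]),
            excitation_nm=float(doc["excitation_nm"]),
        )
    except KeyError as exc:
        raise ValidationError(f"manifest {path} missing key {exc}") from exc


def write_titration_manifest(
    series: TitrationSeries, directory: str | Path, stem: str = "titration"
) -> Path:
    """Write spectrum files plus a YAML manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    points = []
    for i, (c, s) in enumerate(zip(series.quencher_concs_M, series.spectra)):
        fname = f"{stem}_q{i:02d}.txt"
        write_spectrum(s, directory / fname)
        points.append({"conc_M": float(c), "path": fname})
    doc = {
        "temperature_K": float(series.temperature_K),
        "excitation_nm": float(series.excitation_nm),
        "protein_conc_M": float(series.protein_conc_M),
        "points": points,
    }
    manifest = directory / f"{stem}.yaml"
    manifest.write_text(yaml.safe_dump(doc, sort_keys=False))
    return manifest


# -- circular-dichroism secondary-structure bookkeeping -------------------

SECONDARY_STRUCTURE_CLASSES = ("H(r)", "H(d)", "S(r)", "S(d)", "Trn", "Unrd")

#: Tolerance on the sum of secondary-structure fractions, in percentage points.
SUM_TOLERANCE_PERCENT = 0.5


@dataclass
class SecondaryStructureRow:
    """One deconvolved CD composition: regular/distorted helix and strand,
    turn, and unordered fractions, in percent."""

    label: str
    fractions_percent: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(SECONDARY_STRUCTURE_CLASSES) - set(self.fractions_percent)
        if missing:
            raise ValidationError(f"row {self.label!r} missing classes {sorted(missing)}")
        for k, v in self.fractions_percent.items():
            if not (0.0 <= v <= 100.0):
                raise ValidationError(f"{self.label!r}: {k} = {v} outside [0, 100]")

    @property
    def total_percent(self) -> float:
        return float(sum(self.fractions_percent[k] for k in SECONDARY_STRUCTURE_CLASSES))


def read_secondary_structure_csv(path: str | Path) -> list[SecondaryStructureRow]:
    """CSV with a label column plus the six composition class columns."""
    df = pd.read_csv(path)
    label_col = df.columns[0]
    return [
        SecondaryStructureRow(
            str(row[label_col]),
            {k: float(row[k]) for k in SECONDARY_STRUCTURE_CLASSES},
        )
        for _, row in df.iterrows()
    ]


def validate_secondary_structure(
    rows: Iterable[SecondaryStructureRow],
) -> pd.DataFrame:
    """Report-only consistency check of secondary-structure compositions.

    Returns one report row per input row: the fraction sum, a pass flag
    (sum within ``100 +/- SUM_TOLERANCE_PERCENT``), and per-class deltas
    relative to the preceding row (NaN for the first row).
    """
    rows = list(rows)
    if not rows:
        raise ValidationError("at least one composition row required")
    records = []
    prev: SecondaryStructureRow | None = None
    for r in rows:
        rec: dict[str, object] = {"label": r.label, "total_percent": r.total_percent}
        rec["sum_ok"] = abs(r.total_percent - 100.0) <= SUM_TOLERANCE_PERCENT
        for k in SECONDARY_STRUCTURE_CLASSES:
            rec[f"delta_{k}"] = (
                np.nan if prev is None
                else r.fractions_percent[k] - prev.fractions_percent[k]
            )
        records.append(rec)
        prev = r
    return pd.DataFrame.from_records(records)
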