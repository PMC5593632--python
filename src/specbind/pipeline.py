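"""Config-driven orchestration of the full interaction-analysis study.

A :class:`StudyConfig` names the inputs for whichever stages are available
— per-temperature titration manifests, a donor/acceptor spectrum pair with
an F0/F intensity pair, an Ellman-assay CSV, an activity table, a CD
secondary-structure table — and :func:`run_study` executes the stages in
the conventional order (quenching -> binding -> FRET -> Ellman -> QSAR ->
CD bookkeeping), skipping any stage whose inputs are absent and recording
any stage error without aborting the rest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .binding import double_log_fit, modified_sv_fit
from .errors import SpecbindError, ValidationError
from .fret import (
    DEFAULT_K2,
    DEFAULT_QUANTUM_YIELD,
    DEFAULT_REFRACTIVE_N,
    analyze_fret,
)
from .inhibition import fit_ic50, read_ellman_csv
from .qsar import evaluate_table, load_qsar_table, query_residuals
from .quenching import DEFAULT_TAU0_S, classify_mechanism, stern_volmer_fit
from .spectra import (
    SpectrumKind,
    read_secondary_structure_csv,
    read_spectrum,
    read_titration_manifest,
    validate_secondary_structure,
)

__all__ = ["StudyConfig", "StudyReport", "run_study"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class StudyConfig:
    """Inputs and physical constants for one study run.

    All paths are resolved relative to ``base_dir`` (the config file's
    directory when loaded from disk).  At least one stage's inputs must be
    present.
    """

    titration_manifests: list[str] = field(default_factory=list)
    donor_spectrum: str | None = None
    acceptor_spectrum: str | None = None
    fret_F0: float | None = None
    fret_F: float | None = None
    ellman_csv: str | None = None
    qsar_csv: str | None = None          # None + use_packaged_qsar -> fixture
    use_packaged_qsar: bool = False
    secondary_structure_csv: str | None = None
    tau0_s: float = DEFAULT_TAU0_S
    K2: float = DEFAULT_K2
    refractive_n: float = DEFAULT_REFRACTIVE_N
    phi: float = DEFAULT_QUANTUM_YIELD
    readout: float | str = "fixed"
    mw_g_mol: float | None = None
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        self.base_dir = Path(self.base_dir)
        if not (
            self.titration_manifests
            or (self.donor_spectrum and self.acceptor_spectrum)
            or self.ellman_csv
            or self.qsar_csv
            or self.use_packaged_qsar
            or self.secondary_structure_csv
        ):
            raise ValidationError("config enables no stage at all")

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        text = path.read_text()
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        doc = dict(doc or {})
        doc.setdefault("base_dir", str(path.parent))
        return cls(**doc)

    def _resolve(self, p: str | None) -> Path | None:
        return None if p is None else (self.base_dir / p)

    def content_hash(self) -> str:
        doc = {k: (str(v) if isinstance(v, Path) else v) for k, v in vars(self).items()}
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class StudyReport:
    """Per-stage results plus provenance; serializes to a single JSON file."""

    quenching: list[dict] | None = None
    mechanism: dict | None = None
    binding: list[dict] | None = None
    fret: dict | None = None
    ellman: dict | None = None
    qsar: dict | None = None
    secondary_structure: list[dict] | None = None
    skipped: dict[str, str] = field(default_factory=dict)
    errors: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "quenching": self.quenching,
            "mechanism": self.mechanism,
            "binding": self.binding,
            "fret": self.fret,
            "ellman": self.ellman,
            "qsar": self.qsar,
            "secondary_structure": self.secondary_structure,
            "skipped": self.skipped,
            "errors": self.errors,
            "provenance": self.provenance,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def run_study(config: StudyConfig) -> StudyReport:
    """Execute every stage whose inputs are configured.

    Stage failures are caught, recorded under ``report.errors`` and do not
    stop later stages; missing inputs are recorded under ``report.skipped``.
    """
    report = StudyReport()
    report.provenance = {
        "package_version": __version__,
        "config_hash": config.content_hash(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
    }

    # -- quenching + binding ------------------------------------------
    if config.titration_manifests:
        try:
            series = [
                read_titration_manifest(config._resolve(m))
                for m in config.titration_manifests
            ]
            fits = [
                stern_volmer_fit(s, tau0_s=config.tau0_s, readout=config.readout)
                for s in series
            ]
            report.quenching = [f.to_dict() for f in fits]
            if len(fits) >= 2:
                verdict, rationale = classify_mechanism(fits)
                report.mechanism = {"verdict": verdict.value, "rationale": rationale}
            binding_fits = []
            for s in series:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    binding_fits.append(double_log_fit(s, readout=config.readout))
                    try:
                        binding_fits.append(modified_sv_fit(s, readout=config.readout))
                    except SpecbindError:
                        pass  # double-log result already recorded for this T
            report.binding = [f.to_dict() for f in binding_fits]
        except (SpecbindError, OSError) as exc:
            report.errors["quenching"] = str(exc)
    else:
        report.skipped["quenching"] = "no titration manifests configured"
        report.skipped["binding"] = "no titration manifests configured"

    # -- FRET ----------------------------------------------------------
    if config.donor_spectrum and config.acceptor_spectrum:
        try:
            if config.fret_F0 is None or config.fret_F is None:
                raise ValidationError("FRET stage needs fret_F0 and fret_F")
            donor = read_spectrum(
                config._resolve(config.donor_spectrum), SpectrumKind.EMISSION
            )
            acceptor = read_spectrum(
                config._resolve(config.acceptor_spectrum),
                SpectrumKind.MOLAR_ABSORPTIVITY,
                unit="L/(mol cm)",
            )
            result = analyze_fret(
                donor, acceptor, config.fret_F0, config.fret_F,
                K2=config.K2, refractive_n=config.refractive_n, phi=config.phi,
            )
            report.fret = result.to_dict()
        except (SpecbindError, OSError) as exc:
            report.errors["fret"] = str(exc)
    else:
        report.skipped["fret"] = "donor/acceptor spectra not configured"

    # -- Ellman dose-response ------------------------------------------
    if config.ellman_csv:
        try:
            records = read_ellman_csv(config._resolve(config.ellman_csv))
            result = fit_ic50(records, mw_g_mol=config.mw_g_mol)
            report.ellman = result.to_dict()
        except (SpecbindError, OSError) as exc:
            report.errors["ellman"] = str(exc)
    else:
        report.skipped["ellman"] = "no Ellman CSV configured"

    # -- QSAR parity metrics -------------------------------------------
    if config.qsar_csv or config.use_packaged_qsar:
        try:
            records = load_qsar_table(
                config._resolve(config.qsar_csv) if config.qsar_csv else None
            )
            metrics = evaluate_table(records)
            qsar = metrics.to_dict()
            qsar["query_residuals"] = query_residuals(records, metrics.additive_offset_c)
            report.qsar = qsar
        except (SpecbindError, OSError) as exc:
            report.errors["qsar"] = str(exc)
    else:
        report.skipped["qsar"] = "no activity table configured"

    # -- CD secondary-structure bookkeeping ----------------------------
    if config.secondary_structure_csv:
        try:
            rows = read_secondary_structure_csv(
                config._resolve(config.secondary_structure_csv)
            )
            df = validate_secondary_structure(rows)
            report.secondary_structure = df.to_dict(orient="records")
        except (SpecbindError, OSError) as exc:
            report.errors["secondary_structure"] = str(exc)
    else:
        report.skipped["secondary_structure"] = "no CD composition table configured"

    return report
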