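"""Parity-metric evaluation of a fragment-based QSAR activity table.

A Topomer CoMFA model predicts pIC50 as a sum of fragment contributions
(two cut fragments R1 and R2 plus a common core term).  This module does
not train any 3D-QSAR model; it evaluates a *printed* per-compound output
table — experimental pIC50, predicted pIC50, and the two fragment
contributions — with the standard external-validation statistics:

* squared Pearson correlation r^2 between experimental and predicted
  activities per split,
* mean relative error MRE = 100 * mean(|exp - pred| / exp) on the pIC50
  scale, per split,
* an additive-structure diagnostic: the offset c that best explains
  pred = c + R1 + R2 across the train+test rows, with per-row residuals.
  Query rows (compounds predicted without an experimental value) are
  excluded from all metrics but get a residual diagnostic, which flags
  predictions inconsistent with the table's own additive structure.

A packaged activity table for a 61-compound acetylcholinesterase-inhibitor
series plus the floribundiquinone B query row ships with the module.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "Split",
    "QsarRecord",
    "QsarMetrics",
    "load_qsar_table",
    "packaged_table_path",
    "mre_percent",
    "r_squared",
    "fit_additive_offset",
    "query_residuals",
    "evaluate_table",
]


class Split(str, enum.Enum):
    TRAIN = "train"
    TEST = "test"
    QUERY = "query"


@dataclass
class QsarRecord:
    compound_id: str
    exp_pic50: float | None
    pred_pic50: float
    R1: float
    R2: float
    split: Split

    def __post_init__(self) -> None:
        self.split = Split(self.split)
        if self.split is not Split.QUERY and self.exp_pic50 is None:
            raise ValidationError(
                f"compound {self.compound_id!r}: experimental value required "
                f"for {self.split.value} rows"
            )


@dataclass
class QsarMetrics:
    r2_train: float
    r2_test: float
    mre_train_percent: float
    mre_test_percent: float
    n_train: int
    n_test: int
    additive_offset_c: float
    additive_max_abs_residual: float

    def to_dict(self) -> dict:
        return {
            "r2_train": self.r2_train,
            "r2_test": self.r2_test,
            "mre_train_percent": self.mre_train_percent,
            "mre_test_percent": self.mre_test_percent,
            "n_train": self.n_train,
            "n_test": self.n_test,
            "additive_offset_c": self.additive_offset_c,
            "additive_max_abs_residual": self.additive_max_abs_residual,
        }


def packaged_table_path() -> Path:
    """Path of the packaged acetylcholinesterase-inhibitor activity table."""
    return Path(resources.files("specbind").joinpath("data/ache_topomer_table.csv"))


def load_qsar_table(path: str | Path | None = None) -> list[QsarRecord]:
    """Load an activity table CSV; default is the packaged fixture.

    Expected header: ``compound_id,exp,pred,R1,R2,split``; ``exp`` may be
    empty only on query rows.
    """
    path = packaged_table_path() if path is None else Path(path)
    df = pd.read_csv(path, dtype={"compound_id": str})
    required = {"compound_id", "exp", "pred", "R1", "R2", "split"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"activity table missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples():
        exp = None if pd.isna(row.exp) else float(row.exp)
        records.append(
            QsarRecord(
                compound_id=str(row.compound_id),
                exp_pic50=exp,
                pred_pic50=float(row.pred),
                R1=float(row.R1),
                R2=float(row.R2),
                split=Split(row.split),
            )
        )
    return records


def _split_arrays(
    records: Sequence[QsarRecord], split: Split
) -> tuple[np.ndarray, np.ndarray]:
    sel = [r for r in records if r.split is split]
    if split is Split.QUERY:
        raise ValidationError("parity metrics are undefined for query rows")
    exp = np.array([r.exp_pic50 for r in sel], dtype=float)
    pred = np.array([r.pred_pic50 for r in sel], dtype=float)
    return exp, pred


def mre_percent(records: Sequence[QsarRecord], split: Split | str) -> float:
    """Mean relative error, percent: 100 * mean(|exp - pred| / exp)."""
    exp, pred = _split_arrays(records, Split(split))
    if len(exp) == 0:
        raise ValidationError(f"no records in split {split!r}")
    if np.any(exp == 0):
        raise ValidationError("relative error undefined for exp == 0")
    return float(100.0 * np.mean(np.abs(exp - pred) / np.abs(exp)))


def r_squared(records: Sequence[QsarRecord], split: Split | str) -> float:
    """Squared Pearson correlation between experimental and predicted."""
    exp, pred = _split_arrays(records, Split(split))
    if len(exp) < 3:
        raise ValidationError(f"need >= 3 records in split {split!r}, got {len(exp)}")
    if np.ptp(exp) == 0 or np.ptp(pred) == 0:
        raise ValidationError("correlation undefined: a column has zero variance")
    r, _ = stats.pearsonr(exp, pred)
    return float(r * r)


def fit_additive_offset(
    records: Sequence[QsarRecord],
) -> tuple[float, np.ndarray]:
    """Best constant c in pred = c + R1 + R2 over train+test rows.

    Returns the least-squares offset ``c = mean(pred - R1 - R2)`` and the
    per-row residuals ``pred - R1 - R2 - c`` in table order (train+test
    rows only).
    """
    sel = [r for r in records if r.split is not Split.QUERY]
    if len(sel) < 2:
        raise ValidationError("need >= 2 non-query rows for the additive fit")
    d = np.array([r.pred_pic50 - r.R1 - r.R2 for r in sel])
    c = float(d.mean())
    return c, d - c


def query_residuals(
    records: Sequence[QsarRecord], c: float | None = None
) -> dict[str, float]:
    """Additive-structure residual of each query row under offset ``c``.

    A query prediction that honours the table's additive structure should
    have a residual comparable to the train/test rows'; a large residual
    flags an internally inconsistent prediction.
    """
    if c is None:
        c, _ = fit_additive_offset(records)
    return {
        r.compound_id: float(r.pred_pic50 - r.R1 - r.R2 - c)
        for r in records
        if r.split is Split.QUERY
    }


def write_qsar_table(records: Sequence[QsarRecord], path: str | Path) -> None:
    """Write records in the same CSV dialect that :func:`load_qsar_table` reads."""
    df = pd.DataFrame(
        {
            "compound_id": [r.compound_id for r in records],
            "exp": [r.exp_pic50 for r in records],
            "pred": [r.pred_pic50 for r in records],
            "R1": [r.R1 for r in records],
            "R2": [r.R2 for r in records],
            "split": [r.split.value for r in records],
        }
    )
    df.to_csv(path, index=False)


def evaluate_table(records: Sequence[QsarRecord]) -> QsarMetrics:
    """All parity metrics plus the additive-structure diagnostic."""
    c, residuals = fit_additive_offset(records)
    return QsarMetrics(
        r2_train=r_squared(records, Split.TRAIN),
        r2_test=r_squared(records, Split.TEST),
        mre_train_percent=mre_percent(records, Split.TRAIN),
        mre_test_percent=mre_percent(records, Split.TEST),
        n_train=sum(r.split is Split.TRAIN for r in records),
        n_test=sum(r.split is Split.TEST for r in records),
        additive_offset_c=c,
        additive_max_abs_residual=float(np.max(np.abs(residuals))),
    )
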