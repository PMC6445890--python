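"""Median-threshold binary labelling of per-drug IC50 vectors.

A cell line is "sensitive" when its IC50 is strictly below the per-drug
median and "non_sensitive" when it is at or above it.  The median is the
usual interpolated one (mean of the middle two values for even n), so cells
tied exactly at the threshold all land in the non-sensitive class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import NON_SENSITIVE, SENSITIVE


class SingleClassError(ValueError):
    """All cell lines fall into one class; the drug is unusable."""


@dataclass
class LabelVector:
    drug: str
    cell_line_ids: list[str]
    labels: list[str]  # SENSITIVE / NON_SENSITIVE per cell line
    threshold: float  # the median IC50 used

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.cell_line_ids):
            raise ValueError("labels and cell ids misaligned")

    @property
    def y(self) -> np.ndarray:
        """Boolean array, True = sensitive (the positive / minority class)."""
        return np.array([lab == SENSITIVE for lab in self.labels])

    @property
    def n_sensitive(self) -> int:
        return int(self.y.sum())

    @property
    def n_non_sensitive(self) -> int:
        return len(self.labels) - self.n_sensitive

    def to_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.cell_line_ids, name=self.drug)


def assign_labels(ic50: pd.Series, drug: str | None = None) -> LabelVector:
    """Label each cell line by the median split of its drug's IC50 vector."""
    if ic50.isna().any():
        raise ValueError("IC50 vector must be complete (impute first)")
    if len(ic50) < 2:
        raise ValueError("need at least two cell lines")
    thr = float(np.median(ic50.to_numpy()))
    labels = [SENSITIVE if v < thr else NON_SENSITIVE for v in ic50.to_numpy()]
    lv = LabelVector(drug=drug or str(ic50.name), cell_line_ids=list(ic50.index),
                     labels=labels, threshold=thr)
    if lv.n_sensitive == 0 or lv.n_non_sensitive == 0:
        raise SingleClassError(
            f"drug {lv.drug!r}: all cells on one side of the median "
            f"(constant IC50?)")
    return lv


def imbalance_ratio(labels: LabelVector) -> float:
    """IR = |non-sensitive| / |sensitive|.

    The convention fixes non-sensitivity as the majority class; if sensitive
    cells actually dominate, IR < 1 and the imbalance machinery is bypassed.
    """
    if labels.n_sensitive == 0:
        raise SingleClassError("no sensitive cell lines")
    return labels.n_non_sensitive / labels.n_sensitive
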