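"""Growth-matrix binarization and classifier evaluation.

Experimental growth of strains on single-carbon-source media is summarized
as a strain x substrate matrix of normalized, unitless OD-derived values. A
strain is scored as metabolizing a substrate when its normalized growth is
strictly above a threshold (default 0.01). Predicted versus observed binary
growth feeds a standard 2x2 confusion tally per fiber, from which the true
positive rate TPR = TP/(TP+FN) (sensitivity/recall), the false positive
rate FPR = FP/(FP+TN) and precision TP/(TP+FP) are computed. A metric whose
denominator is zero is *undefined* — reported as NA, never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError

DEFAULT_GROWTH_THRESHOLD = 0.01


@dataclass
class GrowthMatrix:
    """Strain x substrate normalized growth values (NaN = missing)."""

    values: pd.DataFrame  # index = strains, columns = substrates

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise InputError("duplicate strain labels in growth matrix")
        if self.values.columns.duplicated().any():
            raise InputError("duplicate substrate labels in growth matrix")
        self.values = self.values.astype(float)

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    @property
    def substrates(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GrowthMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 tally; ``n_dropped`` records pairs excluded for missing data."""

    tp: int
    fp: int
    fn: int
    tn: int
    n_dropped: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricRow:
    """One fiber's evaluation row (None = undefined metric, rendered NA)."""

    fiber: str
    tpr: float | None
    fpr: float | None
    precision: float | None
    recall: float | None
    total_data: int


def binarize(
    m: GrowthMatrix, threshold: float = DEFAULT_GROWTH_THRESHOLD
) -> pd.DataFrame:
    """1 where normalized growth is strictly above ``threshold``, else 0.

    A value exactly equal to the threshold is 0 (strict "above"); missing
    values stay missing (NaN).
    """
    if threshold < 0:
        raise InputError(f"threshold must be >= 0, got {threshold}")
    v = m.values
    out = (v > threshold).astype(float)
    out[v.isna()] = np.nan
    return out


def confusion(
    pred: Sequence[float], truth: Sequence[float]
) -> ConfusionCounts:
    """Standard 2x2 tally of binary vectors, dropping missing pairs.

    ``pred`` and ``truth`` must be the same length before alignment; pairs
    where either entry is missing (NaN/None) are excluded and counted in
    ``n_dropped``.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise InputError(
            f"prediction and truth vectors differ in length: "
            f"{pred.shape} vs {truth.shape}"
        )
    keep = ~(np.isnan(pred) | np.isnan(truth))
    p, t = pred[keep].astype(bool), truth[keep].astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        fn=int(np.sum(~p & t)),
        tn=int(np.sum(~p & ~t)),
        n_dropped=int(np.sum(~keep)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts) -> MetricRow:
    """TPR, FPR, precision and recall from one confusion tally.

    Returned without a fiber label (filled by :func:`evaluate`); any
    zero-denominator metric is None.
    """
    tpr = _ratio(c.tp, c.tp + c.fn)
    return MetricRow(
        fiber="",
        tpr=tpr,
        fpr=_ratio(c.fp, c.fp + c.tn),
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=tpr,
        total_data=c.total,
    )


def round_half_up(x: float | None, ndigits: int = 2) -> float | None:
    """Decimal half-up rounding used for rendered metric tables."""
    if x is None:
        return None
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def evaluate(
    pred_table: pd.DataFrame,
    growth: GrowthMatrix,
    substrate_to_fiber: Mapping[str, str],
    threshold: float = DEFAULT_GROWTH_THRESHOLD,
) -> tuple[list[MetricRow], pd.DataFrame, list[str]]:
    """Score fiber predictions against an experimental growth matrix.

    Parameters
    ----------
    pred_table:
        strains x fibers DataFrame of 0/1 (or boolean) predictions.
    growth:
        experimental strain x substrate normalized growth values.
    substrate_to_fiber:
        maps growth-matrix substrate names onto prediction fiber names.
    threshold:
        binarization threshold for the growth values (strictly above).

    Returns
    -------
    (metric rows, long comparison table, skipped fibers)
        One :class:`MetricRow` per fiber with at least one mapped substrate;
        a long table with columns (strain, fiber, predicted, observed);
        fibers in ``pred_table`` with no mapped substrate.
    """
    binary = binarize(growth, threshold)
    fiber_to_substrates: dict[str, list[str]] = {}
    for sub, fib in substrate_to_fiber.items():
        if sub in binary.columns:
            fiber_to_substrates.setdefault(fib, []).append(sub)
    rows: list[MetricRow] = []
    long_records: list[dict] = []
    skipped: list[str] = []
    strains = [s for s in pred_table.index if s in binary.index]
    for fiber in pred_table.columns:
        subs = fiber_to_substrates.get(fiber, [])
        if not subs:
            skipped.append(fiber)
            continue
        preds: list[float] = []
        obs: list[float] = []
        for strain in strains:
            p = float(bool(pred_table.loc[strain, fiber]))
            for sub in subs:
                o = binary.loc[strain, sub]
                preds.append(p)
                obs.append(float(o) if pd.notna(o) else np.nan)
                long_records.append(
                    {
                        "strain": strain,
                        "fiber": fiber,
                        "substrate": sub,
                        "predicted": int(p),
                        "observed": int(o) if pd.notna(o) else None,
                    }
                )
        c = confusion(preds, obs)
        row = metrics(c)
        row.fiber = fiber
        rows.append(row)
    long_df = pd.DataFrame(
        long_records,
        columns=["strain", "fiber", "substrate", "predicted", "observed"],
    )
    return rows, long_df, skipped


def metric_rows_to_frame(
    rows: Sequence[MetricRow], rounded: bool = True
) -> pd.DataFrame:
    """Render metric rows as a table (half-up 2-dp like printed reports).

    Undefined metrics render as the string ``"NA"`` in the rounded table and
    NaN in the raw one.
    """
    records = []
    for r in rows:
        def fmt(x):
            if x is None:
                return "NA" if rounded else np.nan
            return round_half_up(x) if rounded else x

        records.append(
            {
                "fiber": r.fiber,
                "tpr": fmt(r.tpr),
                "fpr": fmt(r.fpr),
                "precision": fmt(r.precision),
                "recall": fmt(r.recall),
                "total_data": r.total_data,
            }
        )
    return pd.DataFrame(
        records,
        columns=["fiber", "tpr", "fpr", "precision", "recall", "total_data"],
    )
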