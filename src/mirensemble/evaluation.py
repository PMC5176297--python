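"""Confusion counting, the four accuracy metrics, and agreement analysis.

Metrics follow the classical definitions:

    SENS = TP/(TP+FN)      SPEC = TN/(TN+FP)
    ACC  = (TP+TN)/N       MCC  = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

The agreement analysis compares the *true* predictions of predictor
pairs on one class side at a time: the overlap O_ij counts samples both
predictors call correctly, the non-redundant union U_ij = T_i + T_j - O_ij
counts samples at least one calls correctly.  Unions bound what any
combiner of the pair could achieve -- the coverage ceiling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedMetricError
from .tables import ScoreTable


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class MetricSet:
    sens: float
    spec: float
    acc: float
    mcc: float

    def as_row(self) -> dict[str, str]:
        """Table-style formatting: percentages at 1 d.p., MCC at 2 d.p."""
        return {
            "SENS": f"{100 * self.sens:.1f}%",
            "SPEC": f"{100 * self.spec:.1f}%",
            "ACC": f"{100 * self.acc:.1f}%",
            "MCC": f"{self.mcc:.2f}",
        }


def confusion(labels, calls) -> ConfusionCounts:
    """Count TP/FP/TN/FN of +/-1 calls against +/-1 labels."""
    labels = np.asarray(labels, dtype=int)
    calls = np.asarray(calls, dtype=int)
    if labels.shape != calls.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {calls.shape}")
    if not (np.all(np.isin(labels, (-1, 1))) and np.all(np.isin(calls, (-1, 1)))):
        raise ValueError("labels and calls must be +1/-1")
    return ConfusionCounts(
        tp=int(np.sum((labels == 1) & (calls == 1))),
        fp=int(np.sum((labels == -1) & (calls == 1))),
        tn=int(np.sum((labels == -1) & (calls == -1))),
        fn=int(np.sum((labels == 1) & (calls == -1))),
    )


def metrics(c: ConfusionCounts) -> MetricSet:
    """SENS/SPEC/ACC/MCC from confusion counts.

    MCC is defined as 0 when any marginal sum vanishes (the standard
    convention); SENS and SPEC require at least one sample of the
    corresponding class.
    """
    if c.n == 0:
        raise UndefinedMetricError("all confusion counts are zero")
    if c.n_positive == 0 or c.n_negative == 0:
        raise UndefinedMetricError("need both classes present for SENS/SPEC")
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = 0.0 if denom == 0 else (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom)
    return MetricSet(
        sens=c.tp / c.n_positive,
        spec=c.tn / c.n_negative,
        acc=(c.tp + c.tn) / c.n,
        mcc=mcc,
    )


@dataclass
class AgreementMatrix:
    """Pairwise true-prediction overlap on one class side.

    ``true_counts[i]`` is T_i, the correct calls of predictor i among the
    ``n_samples`` samples of this side; ``overlap[(i, j)]`` is O_ij.
    """

    class_side: str
    names: list[str]
    n_samples: int
    true_counts: dict[str, int]
    overlap: dict[tuple[str, str], int]

    def _key(self, a: str, b: str) -> tuple[str, str]:
        for name in (a, b):
            if name not in self.true_counts:
                raise ValueError(f"unknown predictor {name!r}")
        return (a, b) if (a, b) in self.overlap else (b, a)

    def overlap_of(self, a: str, b: str) -> int:
        return self.overlap[self._key(a, b)]

    def union_of(self, a: str, b: str) -> int:
        """Non-redundant union U = T_a + T_b - O."""
        return self.true_counts[a] + self.true_counts[b] - self.overlap_of(a, b)

    def to_frame(self) -> pd.DataFrame:
        """Upper-triangular layout: diagonal "T/N", off-diagonal "O/U"."""
        data = {}
        for i, a in enumerate(self.names):
            row = []
            for j, b in enumerate(self.names):
                if j < i:
                    row.append("---")
                elif i == j:
                    row.append(f"({self.true_counts[a]}/{self.n_samples})")
                else:
                    row.append(f"{self.overlap_of(a, b)}/{self.union_of(a, b)}")
            data[a] = row
        return pd.DataFrame(data, index=self.names).T


def pairwise_agreement(labels, calls_by_predictor: dict[str, np.ndarray],
                       class_side: str) -> AgreementMatrix:
    """Overlap/union analysis of true predictions on one class side.

    *class_side* is ``"positive"`` or ``"negative"``; only samples of
    that class are considered.  A call is "true" when it equals the
    sample's label.
    """
    if class_side not in ("positive", "negative"):
        raise ValueError(f"class_side must be positive|negative, got {class_side!r}")
    labels = np.asarray(labels, dtype=int)
    side = 1 if class_side == "positive" else -1
    mask = labels == side
    names = list(calls_by_predictor)
    correct = {}
    for name in names:
        calls = np.asarray(calls_by_predictor[name], dtype=int)
        if calls.shape != labels.shape:
            raise ValueError(f"predictor {name!r}: calls misaligned with labels")
        correct[name] = (calls == labels)[mask]
    true_counts = {n: int(correct[n].sum()) for n in names}
    overlap = {
        (a, b): int(np.sum(correct[a] & correct[b]))
        for a, b in itertools.combinations(names, 2)
    }
    return AgreementMatrix(
        class_side=class_side,
        names=names,
        n_samples=int(mask.sum()),
        true_counts=true_counts,
        overlap=overlap,
    )


@dataclass(frozen=True)
class CoverageCeiling:
    """Upper bounds on SENS/SPEC/ACC achievable by combining a predictor set."""

    sens: float
    spec: float
    acc: float


def coverage_ceiling(u_pos: int, n_pos: int, u_neg: int, n_neg: int) -> CoverageCeiling:
    """Ceilings from union coverages: U_pos/P, U_neg/N, (U_pos+U_neg)/(P+N)."""
    if not (0 <= u_pos <= n_pos and 0 <= u_neg <= n_neg):
        raise ValueError("union counts must lie within their class sizes")
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("both class sizes must be positive")
    return CoverageCeiling(
        sens=u_pos / n_pos,
        spec=u_neg / n_neg,
        acc=(u_pos + u_neg) / (n_pos + n_neg),
    )


def pair_coverage_ceiling(pos: AgreementMatrix, neg: AgreementMatrix,
                          a: str, b: str) -> CoverageCeiling:
    """Coverage ceiling of the pair (a, b) from its positive- and
    negative-side agreement matrices (which must describe the same panel)."""
    if pos.class_side != "positive" or neg.class_side != "negative":
        raise ValueError("expected a positive-side and a negative-side matrix")
    if set(pos.names) != set(neg.names):
        raise ValueError("agreement matrices cover different predictor sets")
    return coverage_ceiling(
        pos.union_of(a, b), pos.n_samples, neg.union_of(a, b), neg.n_samples
    )


def evaluate_table(table: ScoreTable) -> dict[str, MetricSet]:
    """Per-predictor metrics of a score table's binarized calls."""
    return {
        name: metrics(confusion(table.labels, calls))
        for name, calls in table.calls().items()
    }


def metrics_frame(by_name: dict[str, MetricSet]) -> pd.DataFrame:
    """Formatted metrics table (one row per predictor)."""
    return pd.DataFrame({name: ms.as_row() for name, ms in by_name.items()}).T
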