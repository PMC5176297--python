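"""Seeded generators of labeled multi-predictor score panels.

Real panels would come from running five external tools on hairpin
sequences; these generators stand in for them by emulating each tool's
*output dialect* (token vocabulary and score ranges) while letting the
caller dial per-predictor sensitivity/specificity and cross-predictor
error correlation:

* ``generate_panel`` -- each sample gets a latent difficulty u ~ U(0,1)
  shared across predictors; predictor p calls the sample correctly with
  probability clamp(base + rho*(0.5 - u)), where base is its
  sensitivity (positive samples) or specificity (negatives).  rho = 0
  gives independent errors; larger rho makes hard samples hard for
  everyone, inducing correlated errors.
* ``generate_complementary_panel`` -- the anti-correlated regime that
  motivates meta-prediction: each of the five predictors errs on its own
  disjoint ~15% slice of positives and of negatives, so every predictor
  is ~85% accurate while any pair (and the full set) covers every sample.

Emitted cells follow the five dialects: MiPred-like positives score
uniform(50, 91) and negatives 0; MIReNA-like answer Yes/No; miRPara-like
score uniform(0.8, 1) or 0; ProMiR-like positives are log-uniform on
(0.017, 3240) and negatives a mixture of log-uniform(1e-10, 1e-2), exact
0 and NA; triplet-SVM-like answer 1/NA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import PredictorSpec, ScoreTable, default_specs

DIALECTS = ("mipred", "mirena", "mirpara", "promir", "tripletsvm")

_DEFAULT_DIALECT_BY_NAME = {
    "MiPred": "mipred",
    "MIReNA": "mirena",
    "miRPara": "mirpara",
    "ProMiR": "promir",
    "TripletSVM": "tripletsvm",
}


@dataclass(frozen=True)
class PredictorPerformance:
    """One simulated predictor: its dialect plus operating characteristics."""

    spec: PredictorSpec
    dialect: str
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        for p in (self.sensitivity, self.specificity):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probabilities must be in [0, 1], got {p}")


@dataclass
class SyntheticConfig:
    """Stated world of a simulated panel."""

    n_pos: int
    n_neg: int
    predictors: list[PredictorPerformance]
    rho: float = 0.0
    seed: int = 0
    promir_negative_weights: tuple[float, float, float] = (0.5, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.n_pos < 0 or self.n_neg < 0:
            raise ValueError("sample counts must be non-negative")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if not self.predictors:
            raise ValueError("need at least one predictor")
        if not math.isclose(sum(self.promir_negative_weights), 1.0):
            raise ValueError("ProMiR negative mixture weights must sum to 1")


def default_performances(sensitivities=None, specificities=None) -> list[PredictorPerformance]:
    """The five classic dialects with caller-supplied (or 0.9/0.9) accuracy."""
    specs = default_specs()
    sens = list(sensitivities) if sensitivities is not None else [0.9] * 5
    spec = list(specificities) if specificities is not None else [0.9] * 5
    if len(sens) != 5 or len(spec) != 5:
        raise ValueError("need one sensitivity and one specificity per predictor")
    return [
        PredictorPerformance(s, _DEFAULT_DIALECT_BY_NAME[s.name], se, sp)
        for s, se, sp in zip(specs, sens, spec)
    ]


def _loguniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _emit_cell(dialect: str, call: int, rng: np.random.Generator,
               promir_weights) -> float | str:
    positive = call == 1
    if dialect == "mipred":
        return float(rng.uniform(50.0, 91.0)) if positive else 0.0
    if dialect == "mirena":
        return "Yes" if positive else "No"
    if dialect == "mirpara":
        return float(rng.uniform(0.8, 1.0)) if positive else 0.0
    if dialect == "promir":
        if positive:
            return _loguniform(rng, 0.017, 3240.0)
        kind = rng.choice(3, p=promir_weights)
        if kind == 0:
            return _loguniform(rng, 1e-10, 1e-2)
        return 0.0 if kind == 1 else "NA"
    if dialect == "tripletsvm":
        return "1" if positive else "NA"
    raise ValueError(f"unknown dialect {dialect!r}")


def _assemble(ids, labels, performances, cells) -> ScoreTable:
    specs = [p.spec for p in performances]
    raw = pd.DataFrame(
        {s.name: [row[j] for row in cells] for j, s in enumerate(specs)},
        columns=[s.name for s in specs], dtype=object,
    )
    return ScoreTable(sample_ids=ids, labels=np.asarray(labels), predictors=specs, raw=raw)


def generate_panel(config: SyntheticConfig) -> ScoreTable:
    """Simulate a labeled score panel under the difficulty-coupling model."""
    rng = np.random.default_rng(config.seed)
    ids, labels, cells = [], [], []
    sample_plan = [(1, i) for i in range(config.n_pos)] + [
        (-1, i) for i in range(config.n_neg)
    ]
    for label, i in sample_plan:
        ids.append(f"{'pos' if label == 1 else 'neg'}_{i:05d}")
        labels.append(label)
        u = rng.uniform()
        row = []
        for perf in config.predictors:
            base = perf.sensitivity if label == 1 else perf.specificity
            p_correct = min(1.0, max(0.0, base + config.rho * (0.5 - u)))
            correct = rng.uniform() < p_correct
            call = label if correct else -label
            row.append(_emit_cell(perf.dialect, call, rng, config.promir_negative_weights))
        cells.append(row)
    return _assemble(ids, labels, config.predictors, cells)


def generate_complementary_panel(n_pos: int, n_neg: int, seed: int,
                                 error_fraction: float = 0.15) -> ScoreTable:
    """Five-predictor panel with disjoint per-predictor blind spots.

    Each predictor errs on its own slice of ~``error_fraction`` of the
    positives and of the negatives, slices disjoint across predictors,
    so individual accuracies sit near 1 - error_fraction while the union
    coverage of any pair -- and hence the coverage ceiling -- is 1.0.
    """
    if n_pos < 100 or n_neg < 100:
        raise ValueError("need at least 100 samples per class to partition blind spots")
    if not 0.0 < error_fraction <= 0.2:
        raise ValueError("error_fraction must be in (0, 0.2] so five slices stay disjoint")
    performances = default_performances()
    rng = np.random.default_rng(seed)

    def blind_spots(n: int) -> np.ndarray:
        size = int(round(error_fraction * n))
        order = rng.permutation(n)
        owner = np.full(n, -1)  # -1: no predictor errs here
        for p in range(5):
            owner[order[p * size:(p + 1) * size]] = p
        return owner

    owner_pos = blind_spots(n_pos)
    owner_neg = blind_spots(n_neg)
    ids, labels, cells = [], [], []
    for label, n, owner in ((1, n_pos, owner_pos), (-1, n_neg, owner_neg)):
        for i in range(n):
            ids.append(f"{'pos' if label == 1 else 'neg'}_{i:05d}")
            labels.append(label)
            row = []
            for p, perf in enumerate(performances):
                call = -label if owner[i] == p else label
                row.append(_emit_cell(perf.dialect, call, rng, (0.5, 0.25, 0.25)))
            cells.append(row)
    return _assemble(ids, labels, performances, cells)
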