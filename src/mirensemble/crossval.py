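"""Stratified k-fold cross-validation with a train/test/validation rotation.

The dataset is split into k class-stratified folds (per-fold class
counts within +/-1 of the ideal).  Rotation r uses fold r for
validation, fold (r+1) mod k as the early-stopping test fold, and the
remaining fold(s) for training, so k >= 3 is required.  Preprocessing
(including the PCA rotation of mode III) is fitted on the training
fold(s) only and applied frozen to the test and validation folds; the
network is freshly initialized per rotation with a seed derived from the
master seed.  Validation metrics are averaged over the k rotations and
reported with standard errors SD/sqrt(k).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .ann import AnnConfig, AnnModel, TrainHistory, classify, forward_batch, train
from .evaluation import MetricSet, confusion, metrics
from .preprocess import TransformParams, apply_transform, fit_transform
from .tables import ScoreTable, enumerate_ensembles

_METRIC_NAMES = ("sens", "spec", "acc", "mcc")


@dataclass
class FoldPlan:
    """Assignment of every sample id to one of k folds."""

    k: int
    seed: int
    assignment: dict[str, int]

    def fold_indices(self, table: ScoreTable, fold: int) -> list[int]:
        return [i for i, sid in enumerate(table.sample_ids)
                if self.assignment[sid] == fold]


def make_folds(table: ScoreTable, k: int, seed: int) -> FoldPlan:
    """Seeded stratified fold plan: shuffle within each class, then deal
    round-robin, so per-fold class counts differ from ideal by at most 1."""
    if k < 3:
        raise ValueError("k must be >= 3 (train, test and validation folds must be disjoint)")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for side in (1, -1):
        idx = np.flatnonzero(table.labels == side)
        if len(idx) < k:
            raise ValueError(
                f"class {side:+d} has {len(idx)} samples, fewer than k={k}"
            )
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            assignment[table.sample_ids[i]] = pos % k
    return FoldPlan(k=k, seed=seed, assignment=assignment)


@dataclass
class RotationResult:
    rotation: int
    metrics: MetricSet
    history: TrainHistory
    params: TransformParams
    model: AnnModel


@dataclass
class CvResult:
    """Per-rotation validation metrics plus mean and standard error."""

    k: int
    seed: int
    rotations: list[RotationResult]
    mean: dict[str, float]
    se: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {name: getattr(r.metrics, name) for name in _METRIC_NAMES}
            for r in self.rotations
        ]
        frame = pd.DataFrame(rows, index=[f"rotation {r.rotation}" for r in self.rotations])
        frame.loc["mean"] = [self.mean[n] for n in _METRIC_NAMES]
        frame.loc["se"] = [self.se[n] for n in _METRIC_NAMES]
        return frame

    def summary(self) -> str:
        lines = [f"{self.k}-fold cross-validation (seed {self.seed})"]
        for name in _METRIC_NAMES:
            if name == "mcc":
                lines.append(f"  MCC  {self.mean[name]:.2f} +/- {self.se[name]:.2f}")
            else:
                lines.append(
                    f"  {name.upper():4s} {100 * self.mean[name]:.1f}% "
                    f"+/- {100 * self.se[name]:.1f}%"
                )
        return "\n".join(lines)


def _derived_seed(seed: int, rotation: int) -> int:
    # platform-stable derivation, kept below 2**31
    return int(np.random.SeedSequence([seed, rotation]).generate_state(1)[0] % (2**31))


def fit_rotation(table: ScoreTable, train_idx: Sequence[int], test_idx: Sequence[int],
                 mode: str, ann_config: AnnConfig,
                 log_columns: Sequence[str] | None = None):
    """Fit preprocessing on the training rows only, then train the network.

    Returns (params, model, history).  Exposed separately so leakage can
    be audited: nothing outside *train_idx*/*test_idx* influences the fit.
    """
    params, train_fm = fit_transform(table.select_rows(train_idx), mode, log_columns)
    test_fm = apply_transform(params, table.select_rows(test_idx))
    model, history = train(ann_config, train_fm, test_fm)
    return params, model, history


def run_cv(table: ScoreTable, k: int, preprocess_mode: str,
           ann_config: AnnConfig | None = None,
           ensemble: Sequence[str] | None = None, seed: int = 0,
           log_columns: Sequence[str] | None = None) -> CvResult:
    """Full rotation of stratified k-fold cross-validation.

    For every rotation the validation fold is scored with the best-epoch
    model and the four metrics are recorded; means and standard errors
    over rotations are assembled into a :class:`CvResult`.
    """
    sub = table.subset(list(ensemble)) if ensemble is not None else table
    if ann_config is None:
        ann_config = AnnConfig(n_inputs=sub.n_predictors)
    if ann_config.n_inputs != sub.n_predictors:
        raise ValueError(
            f"ann_config.n_inputs={ann_config.n_inputs} but ensemble has "
            f"{sub.n_predictors} predictors"
        )
    plan = make_folds(sub, k, seed)
    rotations = []
    for r in range(k):
        val_idx = plan.fold_indices(sub, r)
        test_idx = plan.fold_indices(sub, (r + 1) % k)
        train_idx = [
            i for f in range(k) if f not in (r, (r + 1) % k)
            for i in plan.fold_indices(sub, f)
        ]
        rot_config = replace(ann_config, seed=_derived_seed(seed, r))
        params, model, history = fit_rotation(
            sub, train_idx, test_idx, preprocess_mode, rot_config, log_columns
        )
        val_fm = apply_transform(params, sub.select_rows(val_idx))
        calls = classify(forward_batch(model, val_fm.X), model.threshold)
        rotations.append(RotationResult(
            rotation=r,
            metrics=metrics(confusion(val_fm.labels, calls)),
            history=history,
            params=params,
            model=model,
        ))
    values = {
        name: np.array([getattr(r.metrics, name) for r in rotations])
        for name in _METRIC_NAMES
    }
    mean = {name: float(v.mean()) for name, v in values.items()}
    se = {name: float(v.std(ddof=1) / np.sqrt(k)) for name, v in values.items()}
    return CvResult(k=k, seed=seed, rotations=rotations, mean=mean, se=se)


def sweep_ensembles(table: ScoreTable, k: int, preprocess_mode: str,
                    ann_config: AnnConfig | None = None, seed: int = 0,
                    min_size: int = 2,
                    log_columns: Sequence[str] | None = None) -> dict[tuple, CvResult]:
    """Cross-validate every ensemble of size >= *min_size* (26 for M=5)."""
    results: dict[tuple, CvResult] = {}
    for members in enumerate_ensembles(table.predictor_names, min_size):
        cfg = (replace(ann_config, n_inputs=len(members))
               if ann_config is not None else None)
        results[members] = run_cv(
            table, k, preprocess_mode, cfg, ensemble=members, seed=seed,
            log_columns=log_columns,
        )
    return results


def best_ensemble(results: dict[tuple, CvResult]) -> tuple:
    """Ensemble with the highest mean validation ACC (lexicographic tie-break)."""
    return max(sorted(results), key=lambda e: results[e].mean["acc"])
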