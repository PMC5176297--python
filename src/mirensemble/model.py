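"""Model/Results surface tying the pipeline together.

:class:`MetaPredictor` is constructed from a :class:`ScoreTable` of
training data plus the modelling choices (ensemble, preprocessing mode,
network hyperparameters); ``fit`` runs preprocessing and training and
returns a :class:`MetaPredictorResults` carrying the fitted transform
parameters, the network weights, the training history and evaluation
helpers, in the spirit of statsmodels' model/results split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ann import AnnConfig, AnnModel, TrainHistory, classify, forward_batch, train
from .crossval import CvResult, make_folds, run_cv
from .evaluation import MetricSet, confusion, metrics, metrics_frame
from .preprocess import TransformParams, apply_transform, fit_transform
from .tables import ScoreTable, default_specs, read_score_table


class MetaPredictor:
    """Meta-classifier over a panel of base-predictor scores.

    Parameters
    ----------
    table
        Training panel (labels +1 genuine pre-miRNA, -1 pseudo-hairpin).
    ensemble
        Predictor names to combine; default all columns of *table*.
    preprocess
        ``"I"``, ``"II"`` or ``"III"`` (see :mod:`mirensemble.preprocess`).
    log_columns
        Heavy-tailed columns to log-shift in modes II/III; default: the
        numeric dialects that admit ``NA`` (ProMiR-like).
    ann
        Network hyperparameters; ``n_inputs`` is derived from the
        ensemble, other fields may be overridden via keyword arguments.
    """

    def __init__(self, table: ScoreTable, ensemble: Sequence[str] | None = None,
                 preprocess: str = "III", log_columns: Sequence[str] | None = None,
                 **ann_kwargs):
        self.table = table.subset(list(ensemble)) if ensemble is not None else table
        if preprocess not in ("I", "II", "III"):
            raise ValueError(f"unknown preprocessing mode {preprocess!r}")
        self.preprocess = preprocess
        self.log_columns = log_columns
        self.ann_kwargs = ann_kwargs

    @classmethod
    def from_tsv(cls, path, specs=None, **kwargs) -> "MetaPredictor":
        return cls(read_score_table(path, specs or default_specs()), **kwargs)

    def _config(self, seed: int) -> AnnConfig:
        kwargs = dict(self.ann_kwargs)
        kwargs.setdefault("seed", seed)
        return AnnConfig(n_inputs=self.table.n_predictors, **kwargs)

    def fit(self, test: ScoreTable | None = None, seed: int = 0) -> "MetaPredictorResults":
        """Fit transforms and train the network.

        If *test* (the early-stopping monitor set) is not given, a
        stratified third of the training table is held out for it.
        """
        if test is None:
            plan = make_folds(self.table, 3, seed)
            test_idx = plan.fold_indices(self.table, 0)
            train_idx = [i for i in range(self.table.n_samples) if i not in set(test_idx)]
            train_table = self.table.select_rows(train_idx)
            test_table = self.table.select_rows(test_idx)
        else:
            train_table = self.table
            test_table = test.subset(self.table.predictor_names)
        params, train_fm = fit_transform(train_table, self.preprocess, self.log_columns)
        test_fm = apply_transform(params, test_table)
        network, history = train(self._config(seed), train_fm, test_fm)
        return MetaPredictorResults(
            model=self, params=params, network=network, history=history,
            train_table=train_table, test_table=test_table, seed=seed,
        )

    def cross_validate(self, k: int = 5, seed: int = 0) -> CvResult:
        """Stratified k-fold train/test/validation rotation (see crossval)."""
        return run_cv(
            self.table, k, self.preprocess, ann_config=self._config(seed),
            seed=seed, log_columns=self.log_columns,
        )


@dataclass
class MetaPredictorResults:
    """Fitted meta-predictor: transforms, weights, history, diagnostics."""

    model: MetaPredictor
    params: TransformParams
    network: AnnModel
    history: TrainHistory
    train_table: ScoreTable
    test_table: ScoreTable
    seed: int
    _cache: dict = field(default_factory=dict, repr=False)

    def predict_scores(self, table: ScoreTable) -> np.ndarray:
        """Raw network outputs in (0, 1) for each row of *table*."""
        fm = apply_transform(self.params, table.subset(self.model.table.predictor_names))
        return forward_batch(self.network, fm.X)

    def predict(self, table: ScoreTable) -> np.ndarray:
        """+/-1 calls at the fitted decision threshold."""
        return classify(self.predict_scores(table), self.network.threshold)

    def evaluate(self, table: ScoreTable) -> MetricSet:
        return metrics(confusion(table.labels, self.predict(table)))

    def summary(self) -> str:
        """Human-readable fit report."""
        m = self.model
        train_ms = self.evaluate(self.train_table)
        test_ms = self.evaluate(self.test_table)
        lines = [
            "Meta-predictor fit",
            "==================",
            f"ensemble        : {', '.join(m.table.predictor_names)}",
            f"preprocess mode : {m.preprocess}",
            f"network         : {m.table.n_predictors} -> "
            f"{self.network.W1.shape[0]} -> 1 (logistic, threshold "
            f"{self.network.threshold})",
            f"training        : {self.history.n_epochs} epochs, best epoch "
            f"{self.history.best_epoch}, stopped by {self.history.stopped_reason}",
            f"seed            : {self.seed}",
            "",
            metrics_frame({"train": train_ms, "test": test_ms}).to_string(),
        ]
        return "\n".join(lines)
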