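"""Model-quality statistics: RMSE, PCC, MAE in fit / LOO / external modes.

Quality in this field is reported with Pearson's correlation coefficient
(PCC) and the root-mean-square error (RMSE), occasionally the mean absolute
error (MAE), between experimental and model ln(k_f).  Three evaluation modes
matter and must never be conflated:

* **fit** — metrics over the training records, from the fitted model;
* **loo** — leave-one-out cross-validation: each protein predicted by a
  model refit on the other n−1;
* **external** — metrics on a test set never used for fitting, the most
  stringent and the least commonly reported mode; predictions may come from
  a fitted baseline or from an ingested third-party prediction table.

An undefined correlation (constant vector, or n < 2) is raised as
:class:`UndefinedCorrelationError` and stored as ``None`` in reports — never
silently coerced to 0, which would corrupt comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy import stats

from .datasets import PredictionTable, ProteinDataset
from .model import LengthRateModel, LengthRateResults

logger = logging.getLogger(__name__)


class UndefinedCorrelationError(ValueError):
    """PCC is undefined (constant input or fewer than two points)."""


def _paired(observed, predicted) -> tuple[np.ndarray, np.ndarray]:
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("empty input")
    return obs, pred


def rmse(observed, predicted) -> float:
    """Root-mean-square error between observed and predicted values."""
    obs, pred = _paired(observed, predicted)
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def mae(observed, predicted) -> float:
    """Mean absolute error between observed and predicted values."""
    obs, pred = _paired(observed, predicted)
    return float(np.mean(np.abs(obs - pred)))


def pcc(observed, predicted) -> float:
    """Pearson product-moment correlation; raises when undefined."""
    obs, pred = _paired(observed, predicted)
    if obs.size < 2:
        raise UndefinedCorrelationError("PCC needs at least 2 points")
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        raise UndefinedCorrelationError("PCC undefined for a constant vector")
    return float(stats.pearsonr(obs, pred).statistic)


def _pcc_or_none(observed, predicted) -> Optional[float]:
    try:
        return pcc(observed, predicted)
    except UndefinedCorrelationError as exc:
        logger.warning("correlation undefined: %s", exc)
        return None


@dataclass
class EvaluationReport:
    """n, RMSE, PCC, MAE for one model on one dataset in one mode."""

    mode: str  # fit | loo | external
    n: int
    rmse: float
    pcc: Optional[float]  # None when undefined (flagged, never 0)
    mae: float
    model_name: str = ""
    dataset_name: str = ""
    min_length_filter: Optional[int] = None

    def __post_init__(self) -> None:
        if self.mode not in {"fit", "loo", "external"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.rmse < 0 or self.mae < 0 or self.rmse + 1e-12 < self.mae:
            raise ValueError("need rmse >= mae >= 0")
        if self.pcc is not None and not -1.0 - 1e-12 <= self.pcc <= 1.0 + 1e-12:
            raise ValueError("pcc out of [-1, 1]")

    def __str__(self) -> str:  # 2-decimal display, matching field convention
        pcc_s = f"{self.pcc:.3f}" if self.pcc is not None else "undef"
        return (
            f"[{self.mode}] {self.model_name} on {self.dataset_name}: "
            f"n={self.n} RMSE={self.rmse:.2f} PCC={pcc_s} MAE={self.mae:.2f}"
        )

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n": self.n,
            "rmse": self.rmse,
            "pcc": self.pcc,
            "mae": self.mae,
            "model_name": self.model_name,
            "dataset_name": self.dataset_name,
            "min_length_filter": self.min_length_filter,
        }


def _report(mode, obs, pred, model_name, dataset_name, min_length=None) -> EvaluationReport:
    return EvaluationReport(
        mode=mode,
        n=len(obs),
        rmse=rmse(obs, pred),
        pcc=_pcc_or_none(obs, pred),
        mae=mae(obs, pred),
        model_name=model_name,
        dataset_name=dataset_name,
        min_length_filter=min_length,
    )


def evaluate_fit(results: LengthRateResults, train: ProteinDataset) -> EvaluationReport:
    """Fitting-procedure metrics of *results* over *train*."""
    obs = train.ln_kf()
    pred = results.predict(train.lengths())
    return _report("fit", obs, np.atleast_1d(pred), results.training_name, train.name)


def loo_cv(train: ProteinDataset) -> EvaluationReport:
    """Leave-one-out cross-validation of the chain-length baseline on *train*.

    Each record is predicted by a model refit on the remaining n−1 records
    (explicit refits; at these dataset sizes there is nothing to optimise).
    """
    n = len(train)
    if n < 4:
        raise ValueError("LOO needs at least 4 records")
    lengths = train.lengths()
    obs = train.ln_kf()
    held_out = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        sub_L = lengths[mask]
        if np.ptp(sub_L) == 0:
            raise ValueError(
                f"degenerate design after leaving out record {i} "
                f"({train.records[i].pdb_id}): all remaining lengths equal"
            )
        x = np.log(sub_L)
        y = obs[mask]
        xbar, ybar = x.mean(), y.mean()
        a1 = float(np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2))
        a0 = ybar - a1 * xbar
        held_out[i] = a0 + a1 * np.log(lengths[i])
        mask[i] = True
    return _report("loo", obs, held_out, f"loglinear[{train.name}]", train.name)


def evaluate_external(
    model_or_predictions: Union[LengthRateResults, PredictionTable],
    test: ProteinDataset,
    min_length: Optional[int] = None,
) -> EvaluationReport:
    """External-prediction metrics on *test*; predictions are never refit.

    ``min_length`` drops records with L below the cutoff before evaluation,
    emulating servers that only predict proteins with L >= 50.
    """
    records = list(test)
    if min_length is not None:
        records = [r for r in records if r.length >= min_length]
    if not records:
        raise ValueError(f"no records of {test.name!r} pass the length filter")

    if isinstance(model_or_predictions, PredictionTable):
        table = model_or_predictions
        matched = [r for r in records if r.pdb_id in table]
        unmatched = sorted({r.pdb_id for r in records} - set(table.entries))
        if unmatched:
            logger.warning(
                "%s: no prediction for %d id(s): %s",
                table.predictor_name,
                len(unmatched),
                ", ".join(unmatched),
            )
        if len(matched) < 2:
            raise ValueError(
                f"fewer than 2 proteins of {test.name!r} matched predictions "
                f"from {table.predictor_name!r}"
            )
        obs = np.array([r.ln_kf for r in matched])
        pred = np.array([table[r.pdb_id] for r in matched])
        name = table.predictor_name
    else:
        results = model_or_predictions
        obs = np.array([r.ln_kf for r in records])
        pred = np.atleast_1d(
            results.predict(np.array([r.length for r in records], dtype=float))
        )
        name = results.training_name
    return _report("external", obs, pred, name, test.name, min_length)
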