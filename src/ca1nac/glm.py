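"""Ensemble-to-ensemble spike-count prediction in theta-cycle bins.

Each MSN's spike count per theta cycle is modeled from the simultaneously
recorded PYR population,

    MSN_j(theta) = beta_0 + sum_i beta_i PYR_i(theta) + error,

where theta indexes theta cycles (the natural time windows of assembly
expression).  The default family is Gaussian with identity link (ordinary
least squares, matching the linear-in-parameters equation); a log-link
Poisson family is available.  Model accuracy on held-out sessions is the
Pearson correlation between observed and predicted counts across cycles.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .core import SpikeTrainSet, ThetaCycles

logger = logging.getLogger(__name__)


@dataclass
class CycleCountMatrix:
    """Cycles x neurons matrix of spike counts in retained theta cycles."""

    counts: np.ndarray
    neuron_ids: list
    cycle_indices: np.ndarray  # indices into the source ThetaCycles

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be nonnegative")
        self.neuron_ids = [int(i) for i in self.neuron_ids]
        self.cycle_indices = np.asarray(self.cycle_indices, int)
        if self.counts.shape != (self.cycle_indices.size, len(self.neuron_ids)):
            raise ValueError("counts shape inconsistent with cycles/neurons")

    @property
    def n_cycles(self) -> int:
        return self.counts.shape[0]

    def column(self, nid: int) -> np.ndarray:
        return self.counts[:, self.neuron_ids.index(int(nid))]

    def submatrix(self, ids) -> np.ndarray:
        cols = [self.neuron_ids.index(int(i)) for i in ids]
        return self.counts[:, cols]


def bin_by_cycles(spikes: SpikeTrainSet, cycles: ThetaCycles) -> CycleCountMatrix:
    """Per-neuron spike count within each retained (valid) theta cycle.

    Cycles are half-open ``[start, next start)``.
    """
    keep = cycles.valid_indices
    b = cycles.boundaries
    ids = spikes.neuron_ids
    counts = np.empty((keep.size, len(ids)), dtype=int)
    for c, nid in enumerate(ids):
        t = spikes[nid]
        lo = np.searchsorted(t, b[keep])
        hi = np.searchsorted(t, b[keep + 1])
        counts[:, c] = hi - lo
    return CycleCountMatrix(counts, ids, keep)


@dataclass
class EnsembleModel:
    """Fitted cycle-count prediction model for one target neuron."""

    intercept: float
    coefficients: np.ndarray
    predictor_ids: list
    family: str = "gaussian"
    training_session: str = ""
    ridge_penalty: float = 0.0

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, float).ravel()
        if self.coefficients.size != len(self.predictor_ids):
            raise ValueError("coefficient count must equal predictor count")

    def predict(self, X: np.ndarray) -> np.ndarray:
        eta = self.intercept + np.asarray(X, float) @ self.coefficients
        if self.family == "poisson":
            return np.exp(eta)
        return eta


def fit_ensemble_model(
    target_counts,
    predictor_matrix,
    predictor_ids=None,
    family: str = "gaussian",
    training_session: str = "",
) -> EnsembleModel:
    """Fit the cycle-count model for one target neuron.

    ``family="gaussian"`` (default) is an identity-link least-squares fit;
    ``family="poisson"`` uses a log link.  Rank-deficient predictor
    matrices fall back to a small ridge penalty (logged).
    """
    y = np.asarray(target_counts, float).ravel()
    X = np.asarray(predictor_matrix, float)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("predictor matrix must be (n_cycles, n_predictors)")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("need more cycles than predictors + 1")
    if predictor_ids is None:
        predictor_ids = list(range(p))
    Xd = sm.add_constant(X, has_constant="add")
    ridge = 0.0
    if family == "gaussian":
        rank = np.linalg.matrix_rank(Xd)
        if rank < Xd.shape[1]:
            ridge = 1e-6
            logger.info("rank-deficient predictors: ridge fallback alpha=%g", ridge)
            A = Xd.T @ Xd + ridge * np.eye(Xd.shape[1])
            beta = np.linalg.solve(A, Xd.T @ y)
        else:
            beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
    elif family == "poisson":
        res = sm.GLM(y, Xd, family=sm.families.Poisson()).fit()
        beta = res.params
    else:
        raise ValueError(f"unknown family {family!r}")
    return EnsembleModel(
        intercept=float(beta[0]),
        coefficients=beta[1:],
        predictor_ids=list(predictor_ids),
        family=family,
        training_session=training_session,
        ridge_penalty=ridge,
    )


def predict_and_score(
    model: EnsembleModel,
    predictor_matrix,
    observed_counts,
) -> float:
    """Prediction accuracy: Pearson r between observed and predicted counts.

    Returns NaN (flagged undefined) when either side has zero variance.
    """
    X = np.asarray(predictor_matrix, float)
    if X.shape[1] != len(model.predictor_ids):
        raise ValueError("predictor matrix does not match the model's predictors")
    y = np.asarray(observed_counts, float).ravel()
    yhat = model.predict(X)
    if np.std(y) == 0 or np.std(yhat) == 0:
        logger.info("zero-variance observed or predicted counts: accuracy undefined")
        return float("nan")
    return float(np.corrcoef(y, yhat)[0, 1])
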