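"""Probability calibration: temperature scaling and adaptive-bin reliability.

Deep segmentation models tend to be overconfident; dividing the logit of
the natural-forest probability by a fitted temperature T > 1 softens the
probabilities without changing their ranking, so any threshold chosen on
the raw scale has an exact equivalent on the calibrated scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

_CLIP = 1e-6


@dataclass
class CalibrationModel:
    """A single positive temperature; T = 1 is the identity."""

    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


@dataclass
class ReliabilityTable:
    """Equal-count reliability bins with expected calibration error."""

    counts: np.ndarray
    mean_predicted: np.ndarray
    empirical_fraction: np.ndarray
    bin_edges: np.ndarray            # (n_bins, 2) min/max predicted prob per bin
    ece: float


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    return np.log(p) - np.log1p(-p)


def apply_temperature(p: np.ndarray | float, temperature: float) -> np.ndarray:
    """sigma(logit(p) / T); strictly increasing in p for any fixed T > 0."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    z = _logit(np.asarray(p, dtype=np.float64)) / temperature
    return 1.0 / (1.0 + np.exp(-z))


def fit_temperature(probs: np.ndarray, labels: np.ndarray) -> CalibrationModel:
    """Temperature minimizing the negative log-likelihood of binary labels.

    One-dimensional bounded minimization on log T over [log 0.1, log 10];
    deterministic. Requires n >= 100 and both label values present. A flat
    likelihood (all probabilities 0.5) returns T = 1 by convention.
    """
    probs = np.asarray(probs, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel().astype(np.float64)
    if probs.size != labels.size:
        raise ValueError("probs and labels must align")
    if probs.size < 100:
        raise ValueError("temperature fitting requires n >= 100")
    if not (labels.min() == 0.0 and labels.max() == 1.0):
        raise ValueError("labels must contain both classes (0 and 1)")
    z = _logit(probs)
    if np.allclose(z, 0.0):
        return CalibrationModel(1.0)

    def nll(log_t: float) -> float:
        zz = z / np.exp(log_t)
        # -[y*log(sigma(zz)) + (1-y)*log(1-sigma(zz))], stable form
        return float(np.mean(np.logaddexp(0.0, zz) - labels * zz))

    res = minimize_scalar(nll, bounds=(np.log(0.1), np.log(10.0)), method="bounded",
                          options={"xatol": 1e-8})
    return CalibrationModel(float(np.exp(res.x)))


def reliability(
    probs: np.ndarray,
    labels: np.ndarray,
    n_bins: int = 10,
    weights: np.ndarray | None = None,
) -> ReliabilityTable:
    """Adaptive (equal-count) reliability table.

    Observations are sorted by predicted probability and split into
    ``n_bins`` bins whose counts differ by at most one. Optional per-plot
    design weights (e.g. stratum inclusion weights) reweight the empirical
    positive fractions and bin means. The expected calibration error is the
    weight-averaged |mean predicted - empirical fraction|.
    """
    probs = np.asarray(probs, dtype=np.float64).ravel()
    labels = np.asarray(labels, dtype=np.float64).ravel()
    if probs.size < n_bins:
        raise ValueError("need at least n_bins observations")
    w = np.ones_like(probs) if weights is None else np.asarray(weights, float).ravel()
    order = np.argsort(probs, kind="stable")
    chunks = np.array_split(order, n_bins)
    counts = np.array([len(c) for c in chunks])
    mean_pred = np.empty(n_bins)
    emp = np.empty(n_bins)
    edges = np.empty((n_bins, 2))
    wsums = np.empty(n_bins)
    for i, c in enumerate(chunks):
        ww = w[c]
        wsums[i] = ww.sum()
        mean_pred[i] = np.average(probs[c], weights=ww)
        emp[i] = np.average(labels[c], weights=ww)
        edges[i] = (probs[c].min(), probs[c].max())
    ece = float(np.average(np.abs(mean_pred - emp), weights=wsums))
    return ReliabilityTable(counts, mean_pred, emp, edges, ece)
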