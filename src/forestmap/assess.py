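"""Design-based accuracy assessment against stratified validation plots.

Validation plots are 100 x 100 m; a plot is called natural forest when
strictly more than half of its 10 m pixels exceed the probability
threshold. Overall, user's and producer's accuracy are estimated with
general estimators for stratified random sampling: OA as a stratified mean
of the agreement indicator, UA/PA as combined ratio estimators of totals
with Taylor-linearized variance, all with the finite-population correction
(1 - n_h / N_h) and 95% confidence intervals of +/- 1.96 SE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import StrataSpec, ValidationPlot

log = logging.getLogger(__name__)

VALIDATION_COLUMNS = ("plot_id", "lon", "lat", "ref_label", "stratum")


@dataclass
class Estimate:
    value: float
    se: float

    @property
    def ci(self) -> tuple[float, float]:
        return (max(0.0, self.value - 1.96 * self.se), min(1.0, self.value + 1.96 * self.se))


@dataclass
class AccuracyReport:
    threshold: float | None
    oa: Estimate
    ua: Estimate | None      # None when no plot is predicted positive
    pa: Estimate | None      # None when no plot is reference positive
    n_plots: int
    strata: dict[int, dict[str, float]] = field(default_factory=dict)


@dataclass
class ThresholdCurve:
    grid: np.ndarray
    reports: list[AccuracyReport]
    t_oa: float
    t_balanced: float
    near_optimal: np.ndarray  # thresholds whose OA is within 1% of the top OA


# ---------------------------------------------------------------------------
# plot-level prediction

def plot_prediction(pixel_probs: np.ndarray, threshold: float) -> int:
    """Majority vote of thresholded pixels within one plot footprint.

    Pixels with p >= threshold count as natural; the plot is natural only
    if strictly more than 50% of pixels are (exactly half -> other).
    """
    pixel_probs = np.asarray(pixel_probs)
    if pixel_probs.size == 0:
        raise ValueError("empty plot footprint")
    return int((pixel_probs >= threshold).mean() > 0.5)


# ---------------------------------------------------------------------------
# stratified estimators

def _stratum_stats(y: np.ndarray, x: np.ndarray | None = None):
    n = y.size
    ybar = y.mean()
    s2y = y.var(ddof=1) if n > 1 else 0.0
    if x is None:
        return n, ybar, s2y
    xbar = x.mean()
    s2x = x.var(ddof=1) if n > 1 else 0.0
    sxy = np.cov(y, x, ddof=1)[0, 1] if n > 1 else 0.0
    return n, ybar, s2y, xbar, s2x, sxy


def _stratified_mean(values_by_stratum: dict[int, np.ndarray], sizes: dict[int, float]) -> Estimate:
    N = sum(sizes[h] for h in values_by_stratum)
    total = var = 0.0
    for h, y in values_by_stratum.items():
        Nh = sizes[h]
        n, ybar, s2y = _stratum_stats(y)
        total += Nh * ybar
        if n > 1:
            var += Nh**2 * (1.0 - n / Nh) * s2y / n
        else:
            log.warning("stratum %s has a single plot; its variance term is zero", h)
    return Estimate(total / N, float(np.sqrt(max(var, 0.0)) / N))


def _combined_ratio(
    pairs_by_stratum: dict[int, tuple[np.ndarray, np.ndarray]], sizes: dict[int, float]
) -> Estimate | None:
    """Ratio of stratified totals Y-hat / X-hat with Taylor variance."""
    Yhat = Xhat = 0.0
    for h, (y, x) in pairs_by_stratum.items():
        Nh = sizes[h]
        Yhat += Nh * y.mean()
        Xhat += Nh * x.mean()
    if Xhat == 0.0:
        return None
    R = Yhat / Xhat
    var = 0.0
    for h, (y, x) in pairs_by_stratum.items():
        Nh = sizes[h]
        n, _, s2y, _, s2x, sxy = _stratum_stats(y, x)
        if n > 1:
            var += Nh**2 * (1.0 - n / Nh) * (s2y + R**2 * s2x - 2.0 * R * sxy) / n
    return Estimate(R, float(np.sqrt(max(var, 0.0))) / Xhat)


def stratified_accuracy(
    predictions: np.ndarray,
    plots: list[ValidationPlot],
    strata_spec: StrataSpec,
    threshold: float | None = None,
) -> AccuracyReport:
    """OA/UA/PA with standard errors under the stratified design.

    ``predictions`` is the binary plot-level prediction aligned with
    ``plots``. Every plot's stratum must appear in ``strata_spec.sizes``
    with N_h >= n_h; strata need n_h >= 2 for a variance contribution.
    """
    strata_spec.validate()
    pred = np.asarray(predictions).astype(int)
    if pred.size != len(plots):
        raise ValueError("predictions must align with plots")
    ref = np.array([p.ref_label for p in plots], int)
    strata = np.array([p.stratum for p in plots], int)
    for h in np.unique(strata):
        if int(h) not in strata_spec.sizes:
            raise ValueError(f"stratum {h} has no population size N_h")

    agree = (pred == ref).astype(float)
    tp = ((pred == 1) & (ref == 1)).astype(float)
    ppos = (pred == 1).astype(float)
    rpos = (ref == 1).astype(float)

    by_h = {int(h): np.flatnonzero(strata == h) for h in np.unique(strata)}
    sizes = {h: strata_spec.sizes[h] for h in by_h}
    oa = _stratified_mean({h: agree[i] for h, i in by_h.items()}, sizes)
    ua = _combined_ratio({h: (tp[i], ppos[i]) for h, i in by_h.items()}, sizes)
    pa = _combined_ratio({h: (tp[i], rpos[i]) for h, i in by_h.items()}, sizes)
    strata_summary = {
        h: {"n_h": float(len(i)), "N_h": float(sizes[h]), "mean_agreement": float(agree[i].mean())}
        for h, i in by_h.items()
    }
    return AccuracyReport(threshold, oa, ua, pa, len(plots), strata_summary)


# ---------------------------------------------------------------------------
# threshold sweep

def threshold_sweep(
    plots: list[ValidationPlot],
    pixel_probs: np.ndarray,
    strata_spec: StrataSpec,
    grid: np.ndarray,
) -> ThresholdCurve:
    """Accuracy report per threshold plus the derived operating points.

    ``pixel_probs`` is (n_plots, k): the probability pixels within each
    plot footprint (k = 1 collapses to scalar plot probabilities). t_oa is
    the smallest threshold attaining the maximum OA; t_balanced the
    smallest minimizing |UA - PA|; the near-optimal band holds every
    threshold with OA >= 99% of the maximum.
    """
    grid = np.asarray(grid, float)
    if grid.min() < 0 or grid.max() > 1 or (np.diff(grid) <= 0).any():
        raise ValueError("grid must be strictly increasing within [0, 1]")
    pixel_probs = np.atleast_2d(np.asarray(pixel_probs, float))
    reports = []
    for t in grid:
        preds = np.array([plot_prediction(row, t) for row in pixel_probs])
        reports.append(stratified_accuracy(preds, plots, strata_spec, threshold=float(t)))
    oa = np.array([r.oa.value for r in reports])
    gap = np.array(
        [abs(r.ua.value - r.pa.value) if r.ua and r.pa else np.inf for r in reports]
    )
    t_oa = float(grid[int(np.argmax(oa))])           # argmax takes the first (smallest) tie
    t_balanced = float(grid[int(np.argmin(gap))])
    near = grid[oa >= 0.99 * oa.max()]
    return ThresholdCurve(grid, reports, t_oa, t_balanced, near)


def error_rates_at_extremes(
    plots: list[ValidationPlot],
    plot_probs: np.ndarray,
    t_hi: float,
    t_lo: float,
) -> dict[str, dict[str, float]]:
    """Raw commission/omission rates at high-confidence thresholds.

    Among plots with probability >= ``t_hi`` (confident natural-forest
    calls), the count and fraction whose reference is other; among plots
    with probability < ``t_lo`` (confident other calls), the count and
    fraction whose reference is natural. Unweighted counts.
    """
    if not t_lo < t_hi:
        raise ValueError("t_lo must be strictly below t_hi")
    probs = np.asarray(plot_probs, float)
    ref = np.array([p.ref_label for p in plots], int)
    hi = probs >= t_hi
    lo = probs < t_lo
    n_hi, n_lo = int(hi.sum()), int(lo.sum())
    commission = int((ref[hi] == 0).sum())
    omission = int((ref[lo] == 1).sum())
    return {
        "commission_at_high_confidence": {
            "threshold": t_hi,
            "n_predicted_natural": n_hi,
            "n_reference_other": commission,
            "rate": commission / n_hi if n_hi else 0.0,
        },
        "omission_at_high_confidence": {
            "threshold": t_lo,
            "n_predicted_other": n_lo,
            "n_reference_natural": omission,
            "rate": omission / n_lo if n_lo else 0.0,
        },
    }


# ---------------------------------------------------------------------------
# validation-table I/O

def read_validation_csv(
    path, strata_sizes: dict[int, float] | None = None
) -> tuple[list[ValidationPlot], StrataSpec]:
    """Parse the released-style validation table.

    Expects columns plot_id, lon, lat, ref_label (binary), stratum, and an
    optional region tag. When per-stratum population sizes are not
    supplied, N_h defaults to the realized sample size n_h (a
    self-weighting census), which reduces the estimators to plain
    proportions.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty validation file") from exc
    if df.empty:
        raise ValueError(f"{path}: empty validation file")
    missing = [c for c in VALIDATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    dup = df["plot_id"].duplicated()
    if dup.any():
        raise ValueError(f"{path}: duplicated plot_id at row {int(dup.idxmax())}")
    bad = ~df["ref_label"].isin((0, 1))
    if bad.any():
        raise ValueError(f"{path}: non-binary ref_label at row {int(bad.idxmax())}")
    if strata_sizes is not None:
        unknown = ~df["stratum"].isin(list(strata_sizes))
        if unknown.any():
            raise ValueError(f"{path}: unknown stratum at row {int(unknown.idxmax())}")

    plots = [
        ValidationPlot(
            plot_id=str(r.plot_id),
            lon=float(r.lon),
            lat=float(r.lat),
            ref_label=int(r.ref_label),
            stratum=int(r.stratum),
            region=str(r.region) if "region" in df.columns else None,
        )
        for r in df.itertuples()
    ]
    counts = df["stratum"].value_counts().to_dict()
    sizes = dict(strata_sizes) if strata_sizes is not None else {
        int(h): float(n) for h, n in counts.items()
    }
    spec = StrataSpec(sizes={int(h): float(n) for h, n in sizes.items()})
    spec.validate()
    log.info(
        "validation table: %d plots (%d natural, %d other), %d strata",
        len(plots), int(df.ref_label.sum()), int((1 - df.ref_label).sum()), len(counts),
    )
    return plots, spec


def regional_breakdown(
    predictions: np.ndarray,
    plots: list[ValidationPlot],
    strata_spec: StrataSpec,
    threshold: float | None = None,
) -> dict[str, AccuracyReport]:
    """Re-run the stratified estimator within each region tag."""
    pred = np.asarray(predictions)
    regions = sorted({p.region or "all" for p in plots})
    out = {}
    for reg in regions:
        idx = [i for i, p in enumerate(plots) if (p.region or "all") == reg]
        out[reg] = stratified_accuracy(
            pred[idx], [plots[i] for i in idx], strata_spec, threshold
        )
    return out
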