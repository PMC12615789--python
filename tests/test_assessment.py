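"""Design-based accuracy estimation: plot-majority aggregation, stratified
OA/UA/PA with their variances, threshold sweeps, and validation-table I/O."""

import numpy as np
import pandas as pd
import pytest

from forestmap.assess import (
    error_rates_at_extremes,
    plot_prediction,
    read_validation_csv,
    regional_breakdown,
    stratified_accuracy,
    threshold_sweep,
)
from forestmap.types import StrataSpec, ValidationPlot


def make_plots(confusions, region=None):
    """Plots from per-stratum confusion counts {h: (tp, fp, fn, tn)}.

    Returns (plots, predictions) aligned.
    """
    plots, preds = [], []
    i = 0
    for h, (tp, fp, fn, tn) in confusions.items():
        for pred, ref, n in [(1, 1, tp), (1, 0, fp), (0, 1, fn), (0, 0, tn)]:
            for _ in range(n):
                plots.append(
                    ValidationPlot(f"p{i}", 0.0, 0.0, ref, h, region=region)
                )
                preds.append(pred)
                i += 1
    return plots, np.array(preds)


def oracle_estimates(confusions, sizes):
    """Independent scalar evaluation of the stratified formulas."""
    N = sum(sizes.values())
    oa = sum(
        sizes[h] * (tp + tn) / (tp + fp + fn + tn)
        for h, (tp, fp, fn, tn) in confusions.items()
    ) / N
    Y = sum(sizes[h] * tp / sum(c) for h, c in confusions.items() for tp in [c[0]])
    X_ua = sum(sizes[h] * (c[0] + c[1]) / sum(c) for h, c in confusions.items())
    X_pa = sum(sizes[h] * (c[0] + c[2]) / sum(c) for h, c in confusions.items())
    return oa, Y / X_ua, Y / X_pa


def oracle_variance_oa(confusions, sizes):
    var = 0.0
    N = sum(sizes.values())
    for h, (tp, fp, fn, tn) in confusions.items():
        n = tp + fp + fn + tn
        y = np.array([1.0] * (tp + tn) + [0.0] * (fp + fn))
        var += sizes[h] ** 2 * (1 - n / sizes[h]) * y.var(ddof=1) / n
    return var / N**2


class TestPlotPrediction:
    def test_majority_boundary_is_strict(self):
        probs = np.zeros(100)
        probs[:51] = 0.9
        assert plot_prediction(probs, 0.5) == 1
        probs[50] = 0.1  # exactly 50 of 100
        assert plot_prediction(probs, 0.5) == 0

    def test_zero_threshold_classifies_everything_positive(self, rng):
        assert plot_prediction(rng.uniform(0.01, 1.0, 100), 0.0) == 1

    def test_empty_footprint_rejected(self):
        with pytest.raises(ValueError):
            plot_prediction(np.array([]), 0.5)


class TestStratifiedAccuracy:
    def test_census_limit_equals_raw_confusion_and_zero_se(self):
        conf = {1: (30, 10, 5, 55)}
        plots, preds = make_plots(conf)
        spec = StrataSpec(sizes={1: 100.0})  # n_h = N_h
        rep = stratified_accuracy(preds, plots, spec)
        assert rep.oa.value == pytest.approx(0.85)
        assert rep.ua.value == pytest.approx(30 / 40)
        assert rep.pa.value == pytest.approx(30 / 35)
        assert rep.oa.se == 0.0 and rep.ua.se == 0.0 and rep.pa.se == 0.0

    def test_self_weighting_design_reduces_to_plain_proportions(self):
        conf = {1: (20, 5, 5, 20), 2: (40, 10, 10, 40)}
        plots, preds = make_plots(conf)
        spec = StrataSpec(sizes={1: 5000.0, 2: 10000.0})  # N_h proportional to n_h
        rep = stratified_accuracy(preds, plots, spec)
        agree = (20 + 20 + 40 + 40) / 150
        assert rep.oa.value == pytest.approx(agree)
        assert rep.ua.value == pytest.approx((20 + 40) / (25 + 50))

    def test_two_strata_hand_case_matches_scalar_oracle(self):
        conf = {1: (60, 20, 20, 100), 2: (90, 30, 30, 150)}
        sizes = {1: 1000.0, 2: 3000.0}
        plots, preds = make_plots(conf)
        rep = stratified_accuracy(preds, plots, StrataSpec(sizes=sizes))
        oa, ua, pa = oracle_estimates(conf, sizes)
        assert rep.oa.value == pytest.approx(oa, rel=1e-12)
        assert rep.ua.value == pytest.approx(ua, rel=1e-12)
        assert rep.pa.value == pytest.approx(pa, rel=1e-12)
        assert rep.oa.se == pytest.approx(np.sqrt(oracle_variance_oa(conf, sizes)), rel=1e-9)

    def test_oa_se_matches_design_simulation(self):
        # finite populations with known per-unit agreement; the analytic SE
        # (with population variances) must match the Monte-Carlo spread
        rng = np.random.default_rng(0)
        sizes = {1: 1000, 2: 3000}
        pop_correct = {1: 700, 2: 2400}
        n = {1: 200, 2: 400}
        reps = 20_000
        est = np.zeros(reps)
        for h in sizes:
            k = rng.hypergeometric(pop_correct[h], sizes[h] - pop_correct[h], n[h], size=reps)
            est += sizes[h] * (k / n[h])
        est /= sum(sizes.values())
        analytic = 0.0
        for h in sizes:
            p = pop_correct[h] / sizes[h]
            s2 = p * (1 - p) * sizes[h] / (sizes[h] - 1)
            analytic += sizes[h] ** 2 * (1 - n[h] / sizes[h]) * s2 / n[h]
        analytic = np.sqrt(analytic) / sum(sizes.values())
        assert est.std() == pytest.approx(analytic, rel=0.05)

    def test_ua_pa_invariant_to_common_scaling_of_strata_sizes(self):
        conf = {1: (60, 20, 20, 100), 2: (90, 30, 30, 150)}
        plots, preds = make_plots(conf)
        a = stratified_accuracy(preds, plots, StrataSpec(sizes={1: 1e4, 2: 3e4}))
        b = stratified_accuracy(preds, plots, StrataSpec(sizes={1: 1e6, 2: 3e6}))
        assert a.ua.value == pytest.approx(b.ua.value, rel=1e-12)
        assert a.pa.value == pytest.approx(b.pa.value, rel=1e-12)

    def test_confusion_proportions_sum_to_one(self):
        from forestmap.assess import _stratified_mean

        conf = {1: (60, 20, 20, 100), 2: (90, 30, 30, 150)}
        plots, preds = make_plots(conf)
        ref = np.array([p.ref_label for p in plots])
        strata = np.array([p.stratum for p in plots])
        sizes = {1: 1000.0, 2: 3000.0}
        total = 0.0
        for pv, rv in [(1, 1), (1, 0), (0, 1), (0, 0)]:
            ind = ((preds == pv) & (ref == rv)).astype(float)
            total += _stratified_mean(
                {h: ind[strata == h] for h in sizes}, sizes
            ).value
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_no_predicted_positives_yields_undefined_ua(self):
        conf = {1: (0, 0, 10, 90)}
        plots, preds = make_plots(conf)
        rep = stratified_accuracy(preds, plots, StrataSpec(sizes={1: 1000.0}))
        assert rep.ua is None
        assert rep.pa is not None

    def test_unknown_stratum_rejected(self):
        plots, preds = make_plots({3: (1, 1, 1, 1)})
        with pytest.raises(ValueError, match="stratum"):
            stratified_accuracy(preds, plots, StrataSpec(sizes={1: 10.0}))

    def test_regional_breakdown_with_single_region_reproduces_whole(self):
        conf = {1: (60, 20, 20, 100), 2: (90, 30, 30, 150)}
        plots, preds = make_plots(conf, region="global")
        spec = StrataSpec(sizes={1: 1000.0, 2: 3000.0})
        whole = stratified_accuracy(preds, plots, spec)
        by_region = regional_breakdown(preds, plots, spec)
        assert set(by_region) == {"global"}
        assert by_region["global"].oa.value == whole.oa.value
        assert by_region["global"].oa.se == whole.oa.se


class TestThresholdSweep:
    @staticmethod
    def _plots_with_probs(rng, n=200):
        probs = rng.uniform(0, 1, n)
        plots = [
            ValidationPlot(f"p{i}", 0.0, 0.0, int(rng.random() < probs[i]), 1 + i % 2)
            for i in range(n)
        ]
        spec = StrataSpec(sizes={1: 4000.0, 2: 1000.0})
        return plots, probs[:, None], spec

    def test_ua_at_zero_threshold_equals_stratified_prevalence(self, rng):
        from forestmap.assess import _stratified_mean

        plots, probs, spec = self._plots_with_probs(rng)
        curve = threshold_sweep(plots, probs, spec, np.array([0.0, 0.5]))
        ref = np.array([p.ref_label for p in plots], float)
        strata = np.array([p.stratum for p in plots])
        prevalence = _stratified_mean(
            {h: ref[strata == h] for h in spec.sizes}, spec.sizes
        ).value
        assert curve.reports[0].ua.value == pytest.approx(prevalence, rel=1e-12)

    def test_predicted_positive_total_is_monotone_in_threshold(self, rng):
        plots, probs, spec = self._plots_with_probs(rng)
        grid = np.linspace(0, 1, 21)
        counts = [(probs[:, 0] >= t).sum() for t in grid]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_separable_probabilities_give_perfect_oa_between_margins(self):
        plots = []
        probs = []
        for i in range(40):
            ref = i % 2
            plots.append(ValidationPlot(f"p{i}", 0, 0, ref, 1))
            probs.append(0.9 if ref else 0.1)
        spec = StrataSpec(sizes={1: 1000.0})
        grid = np.array([0.05, 0.3, 0.5, 0.8, 0.95])
        curve = threshold_sweep(plots, np.array(probs)[:, None], spec, grid)
        oas = {t: r.oa.value for t, r in zip(curve.grid, curve.reports)}
        for t in (0.3, 0.5, 0.8):
            assert oas[t] == 1.0
        assert oas[0.05] < 1.0 and oas[0.95] < 1.0
        assert curve.t_oa == 0.3  # smallest threshold attaining max OA
        assert 0.3 <= curve.t_balanced <= 0.8
        assert set(curve.near_optimal) >= {0.3, 0.5, 0.8}

    def test_invalid_grid_rejected(self, rng):
        plots, probs, spec = self._plots_with_probs(rng)
        with pytest.raises(ValueError):
            threshold_sweep(plots, probs, spec, np.array([0.5, 0.4]))


class TestExtremeErrorRates:
    def test_worked_commission_and_omission_example(self):
        # 47 confident natural predictions, 4 wrong; 997 confident other
        # predictions, 60 wrong
        plots, probs = [], []
        for i in range(47):
            plots.append(ValidationPlot(f"hi{i}", 0, 0, int(i >= 4), 1))
            probs.append(0.97)
        for i in range(997):
            plots.append(ValidationPlot(f"lo{i}", 0, 0, int(i < 60), 1))
            probs.append(0.02)
        out = error_rates_at_extremes(plots, np.array(probs), t_hi=0.95, t_lo=0.05)
        com = out["commission_at_high_confidence"]
        omi = out["omission_at_high_confidence"]
        assert (com["n_predicted_natural"], com["n_reference_other"]) == (47, 4)
        assert round(100 * com["rate"], 1) == 8.5
        assert (omi["n_predicted_other"], omi["n_reference_natural"]) == (997, 60)
        assert round(100 * omi["rate"]) == 6

    def test_empty_selections_report_zero_counts(self):
        plots = [ValidationPlot("a", 0, 0, 1, 1), ValidationPlot("b", 0, 0, 0, 1)]
        out = error_rates_at_extremes(plots, np.array([0.5, 0.5]), 0.95, 0.05)
        assert out["commission_at_high_confidence"]["n_predicted_natural"] == 0
        assert out["commission_at_high_confidence"]["rate"] == 0.0
        assert out["omission_at_high_confidence"]["n_predicted_other"] == 0

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError):
            error_rates_at_extremes([], np.array([]), t_hi=0.1, t_lo=0.9)


class TestValidationCsv:
    @staticmethod
    def _write(tmp_path, df, name="val.csv"):
        path = tmp_path / name
        df.to_csv(path, index=False)
        return path

    @staticmethod
    def released_style_frame(n_natural=800, n_other=1272):
        n = n_natural + n_other
        return pd.DataFrame(
            {
                "plot_id": [f"plot{i}" for i in range(n)],
                "lon": np.linspace(-170, 170, n),
                "lat": np.linspace(-50, 60, n),
                "ref_label": [1] * n_natural + [0] * n_other,
                "stratum": ([1, 2, 3] * n)[:n],
                "region": (["africa", "asia", "europe"] * n)[:n],
            }
        )

    def test_released_style_composition_is_preserved(self, tmp_path):
        path = self._write(tmp_path, self.released_style_frame())
        plots, spec = read_validation_csv(path)
        assert len(plots) == 2072
        assert sum(p.ref_label for p in plots) == 800
        assert sum(1 - p.ref_label for p in plots) == 1272
        assert sum(spec.sizes.values()) == 2072

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(ValueError, match="empty"):
            read_validation_csv(path)

    def test_duplicate_plot_id_rejected(self, tmp_path):
        df = self.released_style_frame(5, 5)
        df.loc[1, "plot_id"] = df.loc[0, "plot_id"]
        with pytest.raises(ValueError, match="duplicated"):
            read_validation_csv(self._write(tmp_path, df))

    def test_missing_column_rejected(self, tmp_path):
        df = self.released_style_frame(5, 5).drop(columns=["stratum"])
        with pytest.raises(ValueError, match="stratum"):
            read_validation_csv(self._write(tmp_path, df))

    def test_non_binary_label_rejected(self, tmp_path):
        df = self.released_style_frame(5, 5)
        df.loc[2, "ref_label"] = 3
        with pytest.raises(ValueError, match="non-binary"):
            read_validation_csv(self._write(tmp_path, df))

    def test_unknown_stratum_rejected_when_sizes_supplied(self, tmp_path):
        df = self.released_style_frame(5, 5)
        path = self._write(tmp_path, df)
        with pytest.raises(ValueError, match="unknown stratum"):
            read_validation_csv(path, strata_sizes={1: 100.0, 2: 100.0})
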