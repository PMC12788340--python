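"""Agreement battery: error metrics, limits of agreement, log-ratio
Bland-Altman, Spearman magnitude bands, normality and heteroscedasticity."""

import numpy as np
import pandas as pd
import pytest

from strideval.agreement import (
    MethodComparison,
    PairedSample,
    build_report,
    heteroscedasticity_check,
    ks_normality,
    log_bland_altman,
    mae,
    magnitude_label,
    mean_bias_loa,
    rmse,
    spearman_with_magnitude,
)


def paired(device, criterion, pid=None, tid=None, variable="v", units="u"):
    return PairedSample.from_arrays(device, criterion, pid, tid, variable, units)


class TestErrorMetrics:
    def test_closed_form_3_minus4(self):
        p = paired([3.0, -4.0], [0.0, 0.0])
        assert mae(p) == pytest.approx(3.5)
        assert rmse(p) == pytest.approx(np.sqrt(12.5))

    def test_identical_pairs_zero(self):
        p = paired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert mae(p) == 0.0 and rmse(p) == 0.0

    def test_rmse_at_least_mae(self, rng):
        for _ in range(20):
            p = paired(rng.normal(size=50), rng.normal(size=50))
            assert rmse(p) >= mae(p) >= 0.0


class TestMeanBiasLoa:
    def test_zero_diffs(self):
        p = paired(np.ones(5), np.ones(5))
        r = mean_bias_loa(p)
        assert (r.mean_bias, r.loa_low, r.loa_high) == (0.0, 0.0, 0.0)

    def test_plus_minus_one_closed_form(self):
        p = paired([1.0, -1.0], [0.0, 0.0])
        r = mean_bias_loa(p)
        assert r.mean_bias == pytest.approx(0.0)
        assert r.loa_high == pytest.approx(1.96 * np.sqrt(2.0))
        assert r.loa_low == pytest.approx(-1.96 * np.sqrt(2.0))

    def test_loa_width_is_2x196_sd(self, rng):
        p = paired(rng.normal(size=200), rng.normal(size=200))
        r = mean_bias_loa(p)
        sd = np.std(p.differences, ddof=1)
        assert r.loa_high - r.loa_low == pytest.approx(2 * 1.96 * sd, abs=1e-9)
        assert r.loa_low <= r.mean_bias <= r.loa_high
        assert r.rmse >= r.mae
        assert r.rmse >= abs(r.mean_bias)

    def test_monte_carlo_recovery_of_injected_bias(self, rng):
        """n = 1e4 pairs with bias -0.5 and noise sd 0.3 recover the analytic
        bias and LoA (the construction behind the study-scale velocity row)."""
        n = 10_000
        crit = rng.uniform(6, 8, size=n)
        dev = crit - 0.5 + rng.normal(0, 0.3, size=n)
        r = mean_bias_loa(paired(dev, crit))
        assert r.mean_bias == pytest.approx(-0.5, abs=0.01)
        assert r.loa_low == pytest.approx(-1.088, abs=0.02)
        assert r.loa_high == pytest.approx(0.088, abs=0.02)

    def test_first_trial_mode_one_row_per_participant(self):
        pid = ["A", "A", "A", "B", "B", "B"]
        tid = ["T1", "T1", "T2", "T1", "T2", "T2"]
        p = paired([1.0, 2.0, 9.0, 3.0, 9.0, 9.0], [0.0] * 6, pid, tid)
        from strideval.agreement import _first_trial_rows

        rows = _first_trial_rows(p.data)
        assert len(rows) == 2
        assert set(rows["participant_id"]) == {"A", "B"}
        # participant A: mean of the two T1 rows; B: its single T1 row
        assert rows.set_index("participant_id").at["A", "device"] == pytest.approx(1.5)
        assert rows.set_index("participant_id").at["B", "device"] == pytest.approx(3.0)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            mean_bias_loa(paired([1.0], [0.0]))


class TestSpearman:
    def test_monotone_pairs_give_one(self):
        p = paired([1.0, 2.0, 5.0, 9.0], [0.1, 0.4, 0.5, 3.0])
        rho, label = spearman_with_magnitude(p)
        assert rho == pytest.approx(1.0)
        assert label == "nearly perfect"

    @pytest.mark.parametrize(
        "rho,expected",
        [
            (0.05, "trivial"),
            (0.1, "small"),
            (0.29, "small"),
            (0.3, "moderate"),
            (0.5, "large"),
            (0.69, "large"),
            (0.7, "very large"),
            (0.92, "nearly perfect"),
            (-0.92, "nearly perfect"),
        ],
    )
    def test_magnitude_bands_half_open(self, rho, expected):
        assert magnitude_label(rho) == expected

    def test_degenerate_margin_flagged(self):
        rho, label = spearman_with_magnitude(paired([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
        assert np.isnan(rho) and label == "undefined"


class TestLogBlandAltman:
    def test_exact_five_percent_offset(self):
        crit = np.linspace(1.0, 9.0, 40)
        r = log_bland_altman(paired(1.05 * crit, crit))
        assert r.percent_bias == pytest.approx(5.0, abs=1e-9)
        assert r.percent_loa_low == pytest.approx(5.0, abs=1e-9)
        assert r.percent_loa_high == pytest.approx(5.0, abs=1e-9)

    def test_identity_zero_percent(self):
        crit = np.linspace(1.0, 9.0, 40)
        r = log_bland_altman(paired(crit, crit))
        assert (r.percent_bias, r.percent_loa_low, r.percent_loa_high) == (0.0, 0.0, 0.0)

    def test_nonpositive_rows_excluded_and_counted(self):
        r = log_bland_altman(paired([1.0, -0.5, 2.0, 0.0], [1.0, 1.0, 2.0, 1.0]))
        assert r.n_excluded_nonpositive == 2
        assert r.n == 2

    def test_lognormal_ratio_simulation(self, rng):
        """Median ratio 0.93 recovers a percent bias of -7.0 (the study-scale
        instantaneous-velocity construction)."""
        n = 10_000
        crit = rng.uniform(5, 9, size=n)
        ratio = 0.93 * np.exp(rng.normal(0, 0.04, size=n))
        r = log_bland_altman(paired(ratio * crit, crit))
        assert r.percent_bias == pytest.approx(-7.0, abs=0.3)

    def test_first_order_agreement_with_linear_bias(self, rng):
        """For small relative bias, percent bias ~= 100 * bias / mean level."""
        n = 20_000
        crit = np.full(n, 8.0)
        dev = crit - 0.2 + rng.normal(0, 0.05, size=n)
        lin = mean_bias_loa(paired(dev, crit))
        lg = log_bland_altman(paired(dev, crit))
        assert abs(lg.percent_bias - 100 * lin.mean_bias / 8.0) < 0.5


class TestScreens:
    def test_heteroscedastic_by_construction(self):
        means = np.linspace(1, 10, 50)
        p = paired(means + means * 0.1, means - means * 0.1)  # |d| = 0.2*mean
        rho, pval, verdict = heteroscedasticity_check(p)
        assert rho == pytest.approx(1.0)
        assert verdict == "detected"

    def test_constant_diffs_flagged(self):
        p = paired([1.0, 2.0, 3.0], [0.5, 1.5, 2.5])
        rho, pval, verdict = heteroscedasticity_check(p)
        assert verdict == "undefined"

    def test_null_rarely_detected(self, rng):
        hits = 0
        for _ in range(50):
            crit = rng.uniform(5, 9, size=200)
            dev = crit + rng.normal(0, 0.3, size=200)
            hits += heteroscedasticity_check(paired(dev, crit))[2] == "detected"
        assert hits <= 8  # ~5% nominal false-positive rate

    def test_ks_normal_vs_exponential(self, rng):
        assert ks_normality(rng.normal(size=5000)).normal
        assert not ks_normality(rng.exponential(size=5000)).normal

    def test_ks_constant_sample_degenerate(self):
        r = ks_normality(np.full(20, 1.0))
        assert r.degenerate and not r.normal


class TestModelResults:
    @pytest.fixture()
    def fitted(self, rng):
        n = 400
        pid = np.repeat([f"P{i:02d}" for i in range(10)], n // 10)
        tid = np.tile(np.repeat(["T1", "T2"], n // 20), 10)
        crit = rng.uniform(6, 8, size=n)
        dev = crit - 0.5 + rng.normal(0, 0.3, size=n)
        model = MethodComparison.from_dataframe(
            pd.DataFrame(
                {"participant_id": pid, "trial_id": tid, "device": dev, "criterion": crit}
            ),
            variable="instantaneous_velocity",
            units="m/s",
        )
        return model.fit()

    def test_results_invariants(self, fitted):
        assert fitted.rmse >= fitted.mae >= 0
        lo, hi = fitted.loa
        assert lo <= fitted.mean_bias <= hi
        assert fitted.by_mode["first_trial"].n == 10  # one row per participant
        assert fitted.by_mode["pooled"].n == fitted.n

    def test_summary_mentions_key_fields(self, fitted):
        text = fitted.summary()
        for token in ("MAE", "RMSE", "LoA", "Spearman", "pooled", "first_trial"):
            assert token in text

    def test_bland_altman_plot_layers(self, fitted):
        ax = fitted.plot_bland_altman()
        # dashed bias line + two dotted LoA lines
        styles = [line.get_linestyle() for line in ax.lines]
        assert styles.count("--") == 1
        assert styles.count(":") == 2

    def test_report_rows_per_mode(self, fitted):
        table, _ = build_report({"instantaneous_velocity": fitted})
        assert len(table) == 2  # one row per LoA mode
        assert (table["rmse"] >= table["mae"]).all()
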