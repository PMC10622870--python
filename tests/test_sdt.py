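"""Signal detection statistics and conditional bias functions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

from biasdissect.sdt import (
    compute_rates,
    conditional_bias_function,
    exclusion_filter,
    long_minus_short,
    rank_correlation,
    reproduction_error,
    sdt_summary,
    sdt_table,
)


def _z_oracle(p: float) -> float:
    """Inverse normal CDF by root-finding — independent of scipy's ppf."""
    return brentq(lambda x: norm.cdf(x) - p, -10, 10, xtol=1e-12)


def _make_decision_trials(counts):
    """Build decision trials from (subject, direction, cat, choice, n) specs."""
    rows = []
    for subject, direction, cat, choice, n in counts:
        rows.append(pd.DataFrame({
            "subject_id": subject, "bias_source": "payoff",
            "bias_direction": direction, "true_category": cat,
            "task": "decision", "choice": choice,
            "target_px": 360.0 if cat == "long" else 340.0,
            "reproduction_px": np.nan, "rt_s": np.nan,
        }, index=range(n)))
    return pd.concat(rows, ignore_index=True)


class TestRates:
    def test_counting(self):
        trials = _make_decision_trials([
            (0, "long", "long", "long", 75), (0, "long", "long", "short", 25),
            (0, "long", "short", "long", 25), (0, "long", "short", "short", 75),
        ])
        rates = compute_rates(trials)
        assert rates.loc[0, "hit_rate"] == pytest.approx(0.75)
        assert rates.loc[0, "false_alarm_rate"] == pytest.approx(0.25)

    def test_degenerate_rate_corrected_interior(self):
        trials = _make_decision_trials([
            (0, "long", "long", "long", 100),
            (0, "long", "short", "long", 25), (0, "long", "short", "short", 75),
        ])
        rates = compute_rates(trials)
        assert 0.0 < rates.loc[0, "hit_rate"] < 1.0

    def test_missing_signal_class_is_error(self):
        trials = _make_decision_trials([(0, "long", "long", "long", 50)])
        with pytest.raises(ValueError, match="short-signal"):
            compute_rates(trials)


class TestSummary:
    def test_symmetric_rates_cancel(self):
        s = sdt_summary(0.75, 0.25)
        assert s.criterion == pytest.approx(0.0)
        assert s.d_prime > 0

    def test_equal_rates_give_zero_dprime(self):
        assert sdt_summary(0.4, 0.4).d_prime == pytest.approx(0.0)

    def test_sign_convention_higher_means_long_bias(self):
        """More 'long' responses overall must raise c (as plotted)."""
        assert sdt_summary(0.9, 0.5).criterion > 0
        assert sdt_summary(0.5, 0.1).criterion < 0

    def test_against_quantile_oracle(self):
        s = sdt_summary(0.9, 0.5)
        zh, zf = _z_oracle(0.9), _z_oracle(0.5)
        assert s.d_prime == pytest.approx(zh - zf, abs=1e-9)
        assert s.criterion == pytest.approx(0.5 * (zh + zf), abs=1e-9)

    def test_thousand_random_pairs_match_oracle(self):
        rng = np.random.default_rng(123)
        hr = rng.uniform(0.01, 0.99, 1000)
        far = rng.uniform(0.01, 0.99, 1000)
        for h, f in zip(hr, far):
            s = sdt_summary(h, f)
            zh, zf = _z_oracle(h), _z_oracle(f)
            assert abs(s.d_prime - (zh - zf)) < 1e-6
            assert abs(s.criterion - 0.5 * (zh + zf)) < 1e-6

    @given(hr=st.floats(0.01, 0.99), far=st.floats(0.01, 0.99))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_criterion_antisymmetric_under_relabeling(self, hr, far):
        """Relabeling 'long'<->'short' maps (HR, FAR) -> (1-FAR, 1-HR) and
        must negate c exactly while preserving d'."""
        a = sdt_summary(hr, far)
        b = sdt_summary(1 - far, 1 - hr)
        assert a.criterion == pytest.approx(-b.criterion, abs=1e-10)
        assert a.d_prime == pytest.approx(b.d_prime, abs=1e-10)

    def test_non_interior_rates_rejected(self):
        with pytest.raises(ValueError):
            sdt_summary(1.0, 0.2)


class TestReproductionError:
    def test_single_trial_definition(self):
        trials = pd.DataFrame({
            "subject_id": [0], "bias_source": ["muller_lyer"],
            "bias_direction": ["long"], "task": ["reproduction"],
            "target_px": [350.0], "reproduction_px": [360.0],
        })
        rep = reproduction_error(trials)
        assert rep.loc[0, "reproduction_error_px"] == pytest.approx(10.0)

    def test_empty_is_error(self):
        trials = _make_decision_trials([(0, "long", "long", "long", 5)])
        with pytest.raises(ValueError):
            reproduction_error(trials)


class TestLongMinusShort:
    def _frame(self, values):
        rows = []
        for sid, (lo, hi) in enumerate(values):
            rows += [{"subject_id": sid, "bias_direction": "short", "v": lo},
                     {"subject_id": sid, "bias_direction": "long", "v": hi}]
        return pd.DataFrame(rows)

    def test_zero_differences_give_zero_mean(self):
        eff = long_minus_short(self._frame([(1, 1), (2, 2), (0.5, 0.5)]), "v")
        assert eff.mean == 0.0
        assert eff.cohens_d is None  # sd of identical differences is 0

    def test_constant_nonzero_differences_flagged_undefined(self):
        eff = long_minus_short(self._frame([(0, 1)] * 4), "v")
        assert eff.mean == pytest.approx(1.0)
        assert eff.cohens_d is None

    def test_cohens_d_is_paired(self):
        eff = long_minus_short(self._frame([(0, 1), (0, 2), (0, 3)]), "v")
        diffs = np.array([1.0, 2.0, 3.0])
        assert eff.cohens_d == pytest.approx(diffs.mean() / diffs.std(ddof=1))

    def test_direction_swap_negates_differences(self):
        frame = self._frame([(0.1, 0.9), (0.4, 0.2), (-1.0, 2.0)])
        eff = long_minus_short(frame, "v")
        swapped = frame.replace({"bias_direction": {"long": "short", "short": "long"}})
        eff_swapped = long_minus_short(swapped, "v")
        assert np.allclose(eff.differences.values, -eff_swapped.differences.values)

    def test_subject_missing_direction_dropped(self, caplog):
        frame = self._frame([(0, 1), (0, 2)])
        frame = pd.concat([frame, pd.DataFrame(
            [{"subject_id": 9, "bias_direction": "long", "v": 5.0}])])
        eff = long_minus_short(frame, "v")
        assert 9 not in eff.differences.index


class TestExclusion:
    def _summ(self, d_primes, thresholds=None):
        n = len(d_primes)
        return pd.DataFrame({
            "subject_id": range(n), "d_prime": d_primes,
            "criterion": [0.1] * n,
            "staircase_threshold": thresholds or [30.0] * n,
            "reproduction_error_px": [1.0] * n,
        })

    def test_chance_performers_removed(self):
        kept, log = exclusion_filter(self._summ([1.2, 0.0, -0.2, 1.5]))
        assert set(kept["subject_id"]) == {0, 3}
        assert len(log) == 2
        assert all("d_prime" in r["reason"] for r in log)

    def test_outlier_beyond_four_sd_removed(self):
        # one wild staircase threshold in a 20-subject cohort: far enough
        # out to exceed 4 SD even though it inflates the sample SD itself
        rng = np.random.default_rng(0)
        thr = list(30 + rng.normal(0, 1, 19)) + [300.0]
        n = 20
        kept, log = exclusion_filter(self._summ([1.0 + 0.01 * i for i in range(n)],
                                                thresholds=thr))
        assert 19 not in set(kept["subject_id"])
        assert len(kept) == 19
        assert any("staircase_threshold" in r["reason"] for r in log)


class TestConditionalBias:
    def test_unbiased_observers_flat_at_zero(self, cbf_dc_trials):
        """With dc = z-bias = 0 every quintile's mean c is near 0."""
        unbiased = cbf_dc_trials.copy()
        # use only the structure: rebuild choices as unbiased coin given category
        rng = np.random.default_rng(0)
        p = np.where(unbiased["true_category"] == "long", 0.75, 0.25)
        unbiased["choice"] = np.where(rng.random(len(p)) < p, "long", "short")
        cbf = conditional_bias_function(unbiased)
        assert np.abs(cbf["mean_criterion"]).max() < 0.12

    def test_quintiles_are_per_subject_not_pooled(self):
        """Two subjects with disjoint RT ranges: per-subject binning uses
        each subject's own boundaries, so results differ from pooling."""
        rng = np.random.default_rng(1)
        frames = []
        for sid, rt_base in ((0, 0.3), (1, 3.0)):
            n = 200
            cat = np.where(rng.random(n) < 0.5, "long", "short")
            choice = np.where(rng.random(n) < np.where(cat == "long", 0.8, 0.3),
                              "long", "short")
            frames.append(pd.DataFrame({
                "subject_id": sid, "bias_source": "payoff",
                "bias_direction": "long", "true_category": cat, "task": "decision",
                "choice": choice, "rt_s": rt_base + rng.random(n),
            }))
        trials = pd.concat(frames, ignore_index=True)
        per_subject = conditional_bias_function(trials)
        pooled = trials.copy()
        pooled["subject_id"] = 0
        pooled_cbf = conditional_bias_function(pooled)
        merged = per_subject.merge(pooled_cbf, on="bin", suffixes=("_ps", "_pool"))
        assert not np.allclose(merged["mean_criterion_ps"],
                               merged["mean_criterion_pool"], atol=1e-6)

    def test_start_point_bias_declines_over_quintiles(self, cbf_z_trials):
        cbf = conditional_bias_function(cbf_z_trials)
        piv = cbf.pivot_table(index="bin", columns="bias_direction",
                              values="mean_criterion")
        contrast = piv["long"] - piv["short"]
        assert contrast.iloc[0] - contrast.iloc[4] > 0.3
        assert contrast.iloc[0] > contrast.iloc[2] > contrast.iloc[4]

    def test_drift_criterion_bias_is_flat(self, cbf_dc_trials):
        cbf = conditional_bias_function(cbf_dc_trials)
        piv = cbf.pivot_table(index="bin", columns="bias_direction",
                              values="mean_criterion")
        contrast = piv["long"] - piv["short"]
        assert abs(contrast.iloc[0] - contrast.iloc[4]) < 0.15
        assert contrast.min() > 0.2  # bias present in both fast and slow bins

    def test_too_few_trials_rejected(self):
        trials = _make_decision_trials([(0, "long", "long", "long", 10)])
        trials["rt_s"] = 0.5
        with pytest.raises(ValueError):
            conditional_bias_function(trials)


class TestRankCorrelation:
    def test_perfect_and_inverse(self):
        x = np.arange(10.0)
        assert rank_correlation(x, x) == pytest.approx(1.0)
        assert rank_correlation(x, -x) == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        assert rank_correlation(x, y) == pytest.approx(
            rank_correlation(np.exp(x), y))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rank_correlation(np.ones(10), np.arange(10.0))


def test_sdt_table_merges_rates_and_summaries():
    trials = _make_decision_trials([
        (0, "long", "long", "long", 80), (0, "long", "long", "short", 20),
        (0, "long", "short", "long", 30), (0, "long", "short", "short", 70),
    ])
    table = sdt_table(trials)
    assert {"d_prime", "criterion", "hit_rate"} <= set(table.columns)
    s = sdt_summary(0.8, 0.3)
    assert table.loc[0, "d_prime"] == pytest.approx(s.d_prime)
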