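"""VPD, transforms, collinearity screening, and AICc model ranking."""
import numpy as np
import pandas as pd
import pytest

from larchfire.drivers import (
    CANDIDATE_MODELS,
    aicc,
    compute_metrics,
    compute_vpd,
    count_parameters,
    fit_and_rank,
    screen_collinearity,
    tukey_transform,
)
from larchfire.types import ValidationError


class TestVpd:
    def test_saturated_air(self):
        assert compute_vpd(25.0, 100.0) == pytest.approx(0.0)

    def test_zero_exponent(self):
        assert compute_vpd(0.0, 0.0) == pytest.approx(0.6107, abs=1e-6)

    def test_worked_value(self):
        assert compute_vpd(20.0, 50.0) == pytest.approx(1.169, abs=1e-3)

    @pytest.mark.parametrize("rh", [-1.0, 101.0])
    def test_rh_bounds(self, rh):
        with pytest.raises(ValidationError):
            compute_vpd(20.0, rh)


class TestTukeyTransform:
    @pytest.mark.parametrize("lam", [0.0, 0.35, 0.45, 1.0, 2.0])
    def test_fixed_point_at_one(self, lam):
        assert tukey_transform(1.0, lam) == pytest.approx(1.0 if lam else 0.0)

    def test_identity_and_sqrt(self):
        assert tukey_transform(7.3, 1.0) == pytest.approx(7.3)
        assert tukey_transform(4.0, 0.5) == pytest.approx(2.0)

    def test_monotone(self):
        x = np.linspace(0.1, 5, 50)
        y = tukey_transform(x, 0.35)
        assert np.all(np.diff(y) > 0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            tukey_transform(0.0, 0.35)


class TestMetrics:
    def test_pool_additivity(self):
        m = compute_metrics("p", 0.5, 0.1, 0.1, 2.5, prefire_above=2.0, prefire_below=3.5)
        assert m.ct == pytest.approx(3.2)
        assert m.ca == pytest.approx(0.7)

    def test_complete_consumption(self):
        m = compute_metrics("p", 1.0, 0.5, 0.5, 3.0, prefire_above=2.0, prefire_below=3.0)
        assert m.pca == pytest.approx(1.0)
        assert m.pcb == pytest.approx(1.0)

    def test_zero_combustion(self):
        m = compute_metrics("p", 0, 0, 0, 0, prefire_above=2.0, prefire_below=3.0)
        assert (m.ca, m.cb, m.ct, m.pct) == (0, 0, 0, 0)

    def test_zero_pool_with_combustion_impossible(self):
        with pytest.raises(ValidationError):
            compute_metrics("p", 0.5, 0, 0, 0, prefire_above=0.0, prefire_below=1.0)

    def test_zero_over_zero_flagged_missing(self):
        m = compute_metrics("p", 0, 0, 0, 1.0, prefire_above=0.0, prefire_below=2.0)
        assert m.pca is None


class TestCollinearityScreen:
    def test_duplicated_column_keeps_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        retained, report = screen_collinearity(df, pd.Series(x + rng.normal(0, 0.1, 50)))
        assert sum(c in retained for c in ("a", "b")) == 1
        assert "c" in retained
        assert any(r["reason"] == "collinear" for r in report)

    def test_independent_predictors_usually_both_kept(self):
        # type-I error at alpha=0.05: both kept in >= 90% of seeds
        kept = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(200, 2)), columns=["a", "b"])
            retained, _ = screen_collinearity(df, pd.Series(rng.normal(size=200)))
            kept += retained == ["a", "b"]
        assert kept >= 27

    def test_constant_predictor_dropped_with_reason(self):
        df = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        retained, report = screen_collinearity(df)
        assert retained == ["b"]
        assert report[0]["reason"] == "constant"

    def test_single_predictor_unchanged(self):
        df = pd.DataFrame({"a": np.arange(10.0)})
        retained, report = screen_collinearity(df)
        assert retained == ["a"] and report == []


class TestAicc:
    def test_worked_value(self):
        # -2(-5) + 2*2 + 2*2*3/(10-3) = 14 + 12/7
        assert aicc(-5.0, 2, 10) == pytest.approx(15.714, abs=1e-3)

    def test_small_sample_term_vanishes_asymptotically(self):
        n = 10**6
        assert aicc(-5.0, 3, n) - (-2 * -5.0 + 2 * 3) < 1e-4

    def test_candidate_k_sequence(self):
        # 3-level moisture factor coding: the printed parameter-count ladder
        ks = {name: count_parameters(preds) for name, preds in CANDIDATE_MODELS.items()}
        assert ks == {"Null": 2, "M3": 3, "M2": 4, "M6": 5, "M1": 6, "M5": 7, "M4": 8, "Full": 9}


def _driver_frame(n=60, seed=0, signal="m1"):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "stand_age": rng.uniform(40, 140, n),
            "prefire_sol": rng.uniform(8, 20, n),
            "moisture_class": rng.integers(1, 4, n),
            "prefire_tree_biomass": rng.uniform(1, 4, n),
            "larch_proportion": rng.uniform(0.2, 1.0, n),
            "fwi": rng.uniform(10, 40, n),
        }
    )
    if signal == "m1":
        y = (
            0.02 * df["stand_age"]
            + 0.15 * df["prefire_sol"]
            + 0.3 * (df["moisture_class"] == 2)
            + rng.normal(0, 0.25, n)
        )
    else:
        y = rng.normal(size=n)
    df["y"] = y
    return df


class TestFitAndRank:
    def test_singleton_candidate_set(self):
        df = _driver_frame()
        res = fit_and_rank(df, "y", {"M3": ["fwi"]})
        assert res[0].weight == pytest.approx(1.0)
        assert res[0].delta_aicc == 0.0

    def test_weights_sum_to_one_and_best_delta_zero(self):
        res = fit_and_rank(_driver_frame(), "y")
        fitted = [r for r in res if not r.skipped]
        assert sum(r.weight for r in fitted) == pytest.approx(1.0)
        assert min(r.delta_aicc for r in fitted) == 0.0

    def test_weight_shift_invariance(self):
        # weights depend only on AICc differences, hence on logL differences
        res = fit_and_rank(_driver_frame(seed=3), "y")
        deltas = sorted(r.delta_aicc for r in res if not r.skipped)
        res2 = fit_and_rank(_driver_frame(seed=3).assign(y=lambda d: d["y"] + 10.0), "y")
        deltas2 = sorted(r.delta_aicc for r in res2 if not r.skipped)
        assert deltas == pytest.approx(deltas2)

    def test_true_model_wins_with_strong_signal(self):
        # data generated from the plot-attributes model: M1 or a superset
        # attains dAICc < 2 in >= 90% of seeds
        wins = 0
        for seed in range(20):
            res = fit_and_rank(_driver_frame(seed=seed, signal="m1"), "y")
            good = {r.name for r in res if not r.skipped and r.delta_aicc < 2.0}
            wins += bool(good & {"M1", "M4", "M5", "Full"})
        assert wins >= 18

    def test_small_n_candidates_skipped_not_dropped(self):
        df = _driver_frame(n=9)
        res = fit_and_rank(df, "y")
        skipped = {r.name for r in res if r.skipped}
        assert "Full" in skipped  # K=9 needs n > 10
        assert all(r.reason for r in res if r.skipped)
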