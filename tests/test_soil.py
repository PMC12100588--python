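"""Soil reconstruction, carbon accounting, and belowground aggregation."""
import numpy as np
import pytest

from larchfire.soil import (
    DegenerateDesignError,
    core_combustion,
    fit_arh_model,
    fit_burndepth_model,
    plot_belowground_combustion,
    prefire_soil_carbon,
    reconstruct_prefire_sol,
    residual_soil_carbon,
)
from larchfire.synthetic import generate_arh_cores
from larchfire.types import ArhModel, HorizonProfile, MeasuredHorizon, SoilCore, ValidationError


def _profile(**over):
    kw = dict(
        forest_type="larch_dense",
        scar_group="batamay",
        frac_depth={"litter": 0.5, "fibric": 0.5},
        bulk_density={"litter": 0.04, "fibric": 0.15},
        c_concentration={"litter": 400.0, "fibric": 250.0},
    )
    kw.update(over)
    return HorizonProfile(**kw)


def _core(core_id="c1", at_tree=True, sol=10.0, arh0=2.0):
    return SoilCore("p", core_id, 0.0, at_tree, sol=sol, arh0=arh0)


class TestArhModel:
    def test_noiseless_recovery_of_published_relation(self):
        cores = [
            _core(core_id=f"c{i}", sol=0.96 * a + 3.91, arh0=(0.96 * a + 3.91) - a)
            for i, a in enumerate([2.0, 5.0, 9.0, 14.0])
        ]
        model = fit_arh_model(cores)
        assert model.slope == pytest.approx(0.96, abs=1e-9)
        assert model.intercept == pytest.approx(3.91, abs=1e-9)
        assert model.r2 == pytest.approx(1.0)

    def test_noisy_recovery_over_seeds(self):
        # 1 cm Gaussian scatter, n=148: slope within +/-0.05 and intercept
        # within +/-0.5 of truth in at least 19 of 20 seeds
        hits = 0
        for seed in range(20):
            cores = generate_arh_cores(n=148, slope=1.0, intercept=3.91, resid_sd=1.0, seed=seed)
            m = fit_arh_model(cores)
            if abs(m.slope - 1.0) <= 0.05 and abs(m.intercept - 3.91) <= 0.5:
                hits += 1
        assert hits >= 19

    def test_two_points_interpolate_exactly(self):
        cores = [_core("a", sol=6.0, arh0=4.0), _core("b", sol=12.0, arh0=2.0)]
        m = fit_arh_model(cores)
        assert m.r2 == pytest.approx(1.0)
        assert m.resid_sd == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_design(self):
        cores = [_core(core_id=f"c{i}", sol=10.0, arh0=2.0) for i in range(4)]
        with pytest.raises(DegenerateDesignError):
            fit_arh_model(cores)


class TestReconstruction:
    @pytest.mark.parametrize("arh_ab,expected", [(0.0, 3.91), (10.0, 13.51)])
    def test_published_relation_substitution(self, arh_ab, expected):
        core = SoilCore("p", "c", 0.0, True, sol=arh_ab + 1.0, arh0=1.0)
        assert reconstruct_prefire_sol(core, ArhModel()) == pytest.approx(expected, abs=1e-9)

    def test_away_core_takes_plot_mean(self):
        core = SoilCore("p", "c", 7.5, False)
        assert reconstruct_prefire_sol(core, ArhModel(), plot_mean=11.0) == 11.0

    def test_away_core_without_plot_mean(self):
        with pytest.raises(ValidationError):
            reconstruct_prefire_sol(SoilCore("p", "c", 7.5, False), ArhModel())


class TestSoilCarbon:
    def test_prefire_worked_example(self):
        # 10 cm * (0.5*0.04*400 + 0.5*0.15*250) / 100 = 2.675 kg C m^-2
        assert prefire_soil_carbon(10.0, _profile()) == pytest.approx(2.675, abs=1e-9)

    def test_prefire_zero_depth_and_linearity(self):
        assert prefire_soil_carbon(0.0, _profile()) == 0.0
        assert prefire_soil_carbon(20.0, _profile()) == pytest.approx(
            2 * prefire_soil_carbon(10.0, _profile())
        )

    def test_prefire_homogeneous_in_density(self):
        doubled = _profile(bulk_density={"litter": 0.08, "fibric": 0.30})
        assert prefire_soil_carbon(10.0, doubled) == pytest.approx(2 * 2.675)

    def test_residual_fibric_worked_example(self):
        # 5 cm fibric at the unburned-plot constants: 5*0.153*258.7/100
        hz = [MeasuredHorizon("fibric", 5.0, 0.153, 258.7)]
        assert residual_soil_carbon(hz) == pytest.approx(1.979, abs=1e-3)

    def test_residual_empty_and_additive(self):
        assert residual_soil_carbon([]) == 0.0
        h1 = [MeasuredHorizon("litter", 3.0, 0.04, 400.0)]
        h2 = [MeasuredHorizon("fibric", 5.0, 0.153, 258.7)]
        assert residual_soil_carbon(h1 + h2) == pytest.approx(
            residual_soil_carbon(h1) + residual_soil_carbon(h2)
        )

    def test_residual_imputes_from_profile(self, caplog):
        hz = [MeasuredHorizon("fibric", 5.0, None, None)]
        with caplog.at_level("WARNING"):
            val = residual_soil_carbon(hz, _profile())
        assert val == pytest.approx(5.0 * 0.15 * 250.0 / 100.0)
        assert any("imput" in r.message for r in caplog.records)


class TestCoreCombustion:
    def test_difference_of_worked_examples(self):
        comb, clipped = core_combustion(2.675, 1.979)
        assert comb == pytest.approx(0.696, abs=1e-9)
        assert not clipped

    def test_negative_clipped_to_zero(self):
        comb, clipped = core_combustion(1.0, 1.2)
        assert comb == 0.0
        assert clipped

    def test_total_consumption(self):
        comb, _ = core_combustion(3.3, 0.0)
        assert comb == pytest.approx(3.3)


class TestBurnDepthModel:
    def test_noiseless_recovery(self):
        depths = np.array([2.0, 5.0, 8.0, 11.0])
        m = fit_burndepth_model(depths, 0.25 * depths)
        assert m.slope == pytest.approx(0.25, abs=1e-12)
        assert m.r2 == pytest.approx(1.0)

    def test_noise_degrades_fit(self):
        rng = np.random.default_rng(7)
        depths = rng.uniform(2, 12, 60)
        clean = fit_burndepth_model(depths, 0.3 * depths)
        noisy = fit_burndepth_model(depths, 0.3 * depths + rng.normal(0, 0.5, 60))
        assert noisy.r2 < clean.r2

    def test_degenerate_design(self):
        with pytest.raises(DegenerateDesignError):
            fit_burndepth_model([5.0, 5.0, 5.0], [1.0, 1.2, 1.4])


class TestPlotAggregation:
    def test_averaging_rule(self):
        model = fit_burndepth_model([0.0, 10.0], [0.0, 3.0])  # predicts 0.3/cm
        # outside depths predicting mean 2.4; cores mean 2.0 -> (2.0+2.4)/2
        assert plot_belowground_combustion([2.0, 2.5, 1.5], [8.0], model) == pytest.approx(2.2)

    def test_no_outside_depths_falls_back(self, caplog):
        with caplog.at_level("WARNING"):
            val = plot_belowground_combustion([2.0], [], None)
        assert val == 2.0
        assert any("outside" in r.message for r in caplog.records)

    def test_idempotent_when_means_agree(self):
        model = fit_burndepth_model([0.0, 10.0], [0.0, 3.0])
        assert plot_belowground_combustion([1.5], [5.0], model) == pytest.approx(1.5)

    def test_no_cores_is_an_error(self):
        with pytest.raises(ValidationError):
            plot_belowground_combustion([], [5.0], None)
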