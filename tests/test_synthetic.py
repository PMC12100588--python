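"""Synthetic campaign generator: determinism, truth conservation, recovery."""
import numpy as np
import pandas as pd
import pytest

from larchfire import io as lio
from larchfire import pipeline, spatial, synthetic
from larchfire.soil import fit_arh_model
from larchfire.synthetic import CampaignConfig, GenerationError, generate_campaign, generate_raster_stack


class TestDeterminism:
    def test_same_seed_byte_identical_tables(self, tmp_path):
        for sub in ("a", "b"):
            campaign, _ = generate_campaign(seed=5)
            lio.write_campaign(campaign, tmp_path / sub)
        for name in ("plots", "trees", "debris", "cores", "outside_depths", "weather"):
            assert (tmp_path / "a" / f"{name}.csv").read_bytes() == (
                tmp_path / "b" / f"{name}.csv"
            ).read_bytes()

    def test_same_seed_identical_rasters(self):
        a = generate_raster_stack(seed=3)
        b = generate_raster_stack(seed=3)
        for scar in a:
            for band in a[scar].rasters:
                assert np.array_equal(a[scar].rasters[band].values, b[scar].rasters[band].values)

    def test_different_seeds_differ(self):
        a, _ = generate_campaign(seed=1)
        b, _ = generate_campaign(seed=2)
        assert [t.diameter for t in a.trees][:20] != [t.diameter for t in b.trees][:20]


class TestTruthLedger:
    def test_conservation_exact(self, default_campaign):
        _, ledger = default_campaign
        assert ledger.check_conservation(tol=1e-9)

    def test_study_design_counts(self, default_campaign):
        campaign, _ = default_campaign
        burned = campaign.burned_plots()
        assert len(burned) == 41
        assert len(campaign.unburned_plots()) == 12
        by_type = pd.Series([p.forest_type for p in burned]).value_counts()
        assert by_type["larch_dense"] == 17
        assert by_type["larch_open"] == 20
        assert by_type["mixed"] == 4

    def test_burn_depth_ordering_across_types(self, default_campaign, pipeline_results):
        # configured contrast: dense < open < mixed mean burn depth
        campaign, _ = default_campaign
        types = {p.plot_id: p.forest_type for p in campaign.burned_plots()}
        df = pipeline_results.assign(ftype=lambda d: d["plot_id"].map(types))
        means = df.groupby("ftype")["burn_depth_mean"].mean()
        assert means["larch_dense"] < means["larch_open"] < means["mixed"]

    def test_unburned_cores_refit_configured_arh_relation(self, default_campaign):
        campaign, _ = default_campaign
        unburned = {p.plot_id for p in campaign.unburned_plots()}
        cores = [c for c in campaign.cores if c.plot_id in unburned and c.at_tree]
        model = fit_arh_model(cores)
        se_slope = model.resid_sd / (
            np.sqrt(len(cores)) * np.std([c.arh_ab for c in cores])
        )
        assert abs(model.slope - 0.96) < 3 * se_slope + 1e-9


class TestRecovery:
    def test_zero_noise_belowground_identifiability(self):
        cfg = CampaignConfig(
            arh_resid_sd=0.0, measurement_noise=0.0, burn_depth_sd=0.0,
            sol_prefire_sd=0.0, n_outside_trees=0,
        )
        campaign, ledger = generate_campaign(cfg, seed=3)
        df = pipeline.process_campaign(campaign)
        for row in df.itertuples():
            assert row.cb == pytest.approx(ledger.plots[row.plot_id]["comb_below"], abs=1e-9)

    def test_default_campaign_mean_recovery_over_seeds(self):
        # campaign-mean total combustion within 10% of ledger truth
        hits = 0
        for seed in range(10):
            campaign, ledger = generate_campaign(seed=seed)
            df = pipeline.process_campaign(campaign)
            truth = np.mean(
                [
                    v["comb_trees"] + v["comb_fwd"] + v["comb_cwd"] + v["comb_below"]
                    for v in ledger.plots.values()
                ]
            )
            hits += abs(df["ct"].mean() - truth) / truth <= 0.10
        assert hits >= 9

    def test_infeasible_burn_depth_config(self):
        cfg = CampaignConfig(burn_depth_base={"larch_dense": 20.0, "larch_open": 10.0, "mixed": 10.9})
        with pytest.raises(GenerationError, match="infeasible"):
            generate_campaign(cfg, seed=0)


class TestRasterStack:
    def test_zero_link_noise_recovers_coefficients(self, default_campaign):
        campaign, ledger = default_campaign
        stacks = generate_raster_stack(None, campaign, seed=8, ledger=ledger, link_noise_sd=0.0)
        st = stacks["Yert"]
        plots = pd.DataFrame(
            [
                {"plot_id": p.plot_id, "x": p.x, "y": p.y}
                for p in campaign.burned_plots()
                if p.scar_id == "Yert"
            ]
        )
        pred = spatial.extract_plot_predictors(st.rasters, plots)
        truth = spatial.extract_plot_predictors({"t": st.truth}, plots)
        df = pred.merge(truth, on="plot_id")
        model = spatial.select_model(df, "t", {"all": ["slope", "dnbr", "sand"]})
        for band, coef in (("slope", -0.08), ("dnbr", 0.006), ("sand", -0.01)):
            assert model.coef[band] == pytest.approx(coef, abs=1e-8)
        assert spatial.cross_validate(df, "t", model.predictors, reps=3, seed=0) == pytest.approx(1.0)

    def test_plots_inside_perimeter(self, default_campaign):
        campaign, ledger = default_campaign
        stacks = generate_raster_stack(None, campaign, seed=8, ledger=ledger)
        from shapely.geometry import Point

        for p in campaign.burned_plots():
            assert stacks[p.scar_id].perimeter.contains(Point(p.x, p.y))

    def test_dnbr_tracks_severity(self, default_campaign):
        campaign, ledger = default_campaign
        stacks = generate_raster_stack(None, campaign, seed=8, ledger=ledger)
        rows = []
        for scar, st in stacks.items():
            plots = pd.DataFrame(
                [
                    {"plot_id": p.plot_id, "x": p.x, "y": p.y}
                    for p in campaign.burned_plots()
                    if p.scar_id == scar
                ]
            )
            pred = spatial.extract_plot_predictors({"dnbr": st.rasters["dnbr"]}, plots)
            for _, r in pred.iterrows():
                rows.append((ledger.plots[r["plot_id"]]["severity"], r["dnbr"]))
        sev, dnbr = zip(*rows)
        assert np.corrcoef(sev, dnbr)[0, 1] > 0.6
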