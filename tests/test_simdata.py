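"""Synthetic-trial generator: marker panel, architecture, trial, rasters."""

import numpy as np
import pandas as pd
import pytest

from phenoflight.imaging import compute_vi, extract_plot_value, extract_canopy_height
from phenoflight.simdata import (
    SimConfig, render_band_stacks, simulate, simulate_genetic_architecture,
    simulate_marker_panel, simulate_temporal_trial,
)
from tests.conftest import SHARES_SMALL


class TestMarkerPanel:
    def test_parents_homozygous_hybrids_mendelian(self, small_trial):
        mk = small_trial.markers
        pd_ = mk.parent_dosage.to_numpy()
        assert set(np.unique(pd_)) <= {0.0, 2.0}
        for h, (p1, p2) in mk.parents.items():
            expected = (mk.parent_dosage.loc[p1].to_numpy()
                        + mk.parent_dosage.loc[p2].to_numpy()) / 2
            got = mk.dosage[mk.genotypes.index(h)]
            assert np.array_equal(got, expected)
        assert set(np.unique(mk.dosage)) <= {0.0, 1.0, 2.0}

    def test_f1_heterozygous_where_parents_differ(self, small_trial):
        mk = small_trial.markers
        h, (p1, p2) = next(iter(mk.parents.items()))
        differ = (mk.parent_dosage.loc[p1] != mk.parent_dosage.loc[p2]).to_numpy()
        got = mk.dosage[mk.genotypes.index(h)]
        assert np.all(got[differ] == 1.0)
        assert np.all(got[~differ] != 1.0)

    def test_determinism(self):
        cfg = SimConfig(n_parents=8, n_hybrids=12, n_markers=50, seed=9)
        a = simulate_marker_panel(cfg)
        b = simulate_marker_panel(cfg)
        assert a.marker_ids == b.marker_ids
        assert np.array_equal(a.dosage, b.dosage)

    def test_realized_maf_inside_range_frequency_scan(self):
        """Realized MAF after filtering lies in maf_range, verified by an
        independent allele-frequency scan over the dosage matrix."""
        cfg = SimConfig(n_parents=20, n_hybrids=60, n_markers=1000,
                        maf_range=(0.2, 0.5), seed=5)
        mk = simulate_marker_panel(cfg)
        freq = mk.dosage.sum(axis=0) / (2 * len(mk.genotypes))  # direct scan
        maf = np.minimum(freq, 1 - freq)
        assert len(maf) > 0
        assert (maf >= 0.2 - 1e-12).all() and (maf <= 0.5 + 1e-12).all()
        assert np.allclose(maf, mk.maf)

    def test_degenerate_maf_range_fails_naming_filter(self):
        # one hybrid: realized MAF is 0 or 0.5, never inside (0.05, 0.25)
        cfg = SimConfig(n_parents=2, n_hybrids=1, n_markers=5,
                        maf_range=(0.05, 0.25), seed=0)
        with pytest.raises(ValueError, match="frequency filter"):
            simulate_marker_panel(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError, match="maf_range"):
            SimConfig(maf_range=(0.0, 0.5))
        with pytest.raises(ValueError, match="sums to"):
            SimConfig(variance_shares={"X": {"flight": 0.5, "rep_in_flight": 0.1,
                                             "genotype_in_flight": 0.1, "residual": 0.1}})


class TestArchitecture:
    def test_zero_genetic_share_gives_constant_values(self):
        shares = {"V": {"flight": 0.9, "rep_in_flight": 0.05,
                        "genotype_in_flight": 0.0, "residual": 0.05}}
        cfg = SimConfig(n_parents=8, n_hybrids=15, n_markers=60, n_flights_rgb=4,
                        variance_shares=shares, seed=1)
        truth = simulate_genetic_architecture(simulate_marker_panel(cfg), cfg)
        assert np.allclose(truth.temporal_genetic_values["V"].to_numpy(), 0.0)

    def test_terminal_variance_matches_target(self):
        """Realized GY genetic variance matches h2 * phenotypic variance."""
        cfg = SimConfig(n_parents=40, n_hybrids=500, n_markers=300, seed=4,
                        n_flights_rgb=3, trait_h2={"GY": 0.5, "DTA": 0.75,
                                                   "DTS": 0.75, "PHT": 0.65})
        truth = simulate_genetic_architecture(simulate_marker_panel(cfg), cfg)
        target = 0.5 * 1.44  # h2 x GY phenotypic variance
        assert truth.genetic_values["GY"].var(ddof=1) == pytest.approx(target, rel=0.1)

    def test_perfect_across_flight_correlation_preserves_ranking(self):
        cfg = SimConfig(n_parents=10, n_hybrids=20, n_markers=80, n_flights_rgb=4,
                        effect_corr=1.0, plasticity_share=0.0, seed=2,
                        variance_shares=SHARES_SMALL)
        truth = simulate_genetic_architecture(simulate_marker_panel(cfg), cfg)
        vals = truth.temporal_genetic_values["NGRDI"]
        ranks = vals.rank(axis=0)
        for col in ranks.columns[1:]:
            assert np.array_equal(ranks[col], ranks[ranks.columns[0]])

    def test_non_psd_trait_correlation_rejected(self):
        bad = np.array([[1, 2, 0, 0], [2, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1.0]])
        cfg = SimConfig(n_parents=8, n_hybrids=12, n_markers=50, seed=0,
                        trait_corr=bad)
        with pytest.raises(ValueError, match="positive semidefinite"):
            simulate_genetic_architecture(simulate_marker_panel(cfg), cfg)


class TestTrial:
    def test_replication_structure(self, small_trial, small_config):
        counts = small_trial.phenomic.groupby(
            ["trial", "genotype", "flight_day", "trait_id"], observed=True).size()
        assert (counts == small_config.n_rep).all()

    def test_sm_genotypes_subset_of_om(self, small_trial):
        assert set(small_trial.genotypes_sm) <= set(small_trial.genotypes_om)
        assert len(small_trial.genotypes_sm) < len(small_trial.genotypes_om)

    def test_zero_residual_replicates_identical(self):
        shares = {"V": {"flight": 0.7, "rep_in_flight": 0.0,
                        "genotype_in_flight": 0.3, "residual": 0.0}}
        cfg = SimConfig(n_parents=8, n_hybrids=12, n_markers=60, n_flights_rgb=3,
                        variance_shares=shares, seed=3)
        trial = simulate(cfg)
        om = trial.phenomic[trial.phenomic.trial == "OM"]
        spread = om.groupby(["genotype", "flight_day"], observed=True).value.agg(
            lambda s: s.max() - s.min())
        assert np.allclose(spread, 0.0)

    def test_realized_components_match_targets(self, small_trial):
        for trait, shares in SHARES_SMALL.items():
            realized = small_trial.truth.realized_components[trait]
            for term, target in shares.items():
                if target > 0:
                    assert realized[term] == pytest.approx(target, rel=0.05), (trait, term)

    def test_no_gxe_means_rank_identical(self):
        noise_free = {"NGRDI": {"flight": 0.7, "rep_in_flight": 0.0,
                                "genotype_in_flight": 0.3, "residual": 0.0}}
        cfg = SimConfig(n_parents=10, n_hybrids=20, n_markers=80, n_flights_rgb=4,
                        gxe_corr=1.0, env_shift={}, seed=6,
                        variance_shares=noise_free)
        trial = simulate(cfg)
        means = trial.phenomic[trial.phenomic.trait_id == "NGRDI"].groupby(
            ["trial", "genotype"], observed=True).value.mean().unstack().T
        sm_genos = trial.genotypes_sm
        om_rank = means.loc[sm_genos, "OM"].rank()
        sm_rank = means.loc[sm_genos, "SM"].rank()
        assert (om_rank == sm_rank).all()

    def test_end_to_end_determinism(self, small_config, small_trial):
        again = simulate(small_config)
        pd.testing.assert_frame_equal(again.phenomic, small_trial.phenomic)
        pd.testing.assert_frame_equal(again.traits, small_trial.traits)
        assert np.array_equal(again.markers.dosage, small_trial.markers.dosage)

    def test_unknown_share_terms_rejected(self):
        cfg = SimConfig(n_parents=8, n_hybrids=12, n_markers=50, seed=0)
        cfg.variance_shares = {"V": {"flight": 1.0}}  # bypass __post_init__
        truth = simulate_genetic_architecture(
            simulate_marker_panel(cfg),
            SimConfig(n_parents=8, n_hybrids=12, n_markers=50, seed=0))
        with pytest.raises(ValueError, match="missing terms"):
            simulate_temporal_trial(truth, cfg)


class TestRendering:
    def test_noiseless_roundtrip(self, small_trial):
        """extract(compute_vi(stack)) equals the simulated plot VI exactly."""
        rasters = render_band_stacks(small_trial, flights=[27], pixel_noise=0.0)
        fr = rasters[0]
        vi = compute_vi(fr.stack, "NGRDI")
        table = small_trial.phenomic
        sub = table[(table.trial == "OM") & (table.flight_day == 27)
                    & (table.trait_id == "NGRDI")]
        layout = {p.plot_id: p.polygon for p in small_trial.layout}
        for _, row in sub.iterrows():
            got = extract_plot_value(vi, layout[row["plot"]])
            assert got == pytest.approx(np.clip(row.value, -1, 1), abs=1e-9)

    def test_noiseless_chm_roundtrip(self, small_trial):
        rasters = render_band_stacks(small_trial, flights=[27], pixel_noise=0.0)
        table = small_trial.phenomic
        sub = table[(table.trial == "OM") & (table.flight_day == 27)
                    & (table.trait_id == "CHM")]
        layout = {p.plot_id: p.polygon for p in small_trial.layout}
        for _, row in sub.iterrows():
            got = extract_canopy_height(rasters[0].height, layout[row["plot"]])
            assert got == pytest.approx(max(row.value, 0.0), abs=1e-9)

    def test_noisy_roundtrip_monte_carlo(self, small_trial):
        """Pixel noise sigma=0.01 over ~64 px/plot keeps 99% of plot means
        within 0.005 of the simulated value."""
        rasters = render_band_stacks(small_trial, flights=[27], pixel_noise=0.01)
        vi = compute_vi(rasters[0].stack, "NGRDI")
        table = small_trial.phenomic
        sub = table[(table.trial == "OM") & (table.flight_day == 27)
                    & (table.trait_id == "NGRDI")]
        layout = {p.plot_id: p.polygon for p in small_trial.layout}
        errors = [abs(extract_plot_value(vi, layout[row["plot"]])
                      - np.clip(row.value, -1, 1))
                  for _, row in sub.iterrows()]
        assert np.quantile(errors, 0.99) < 0.005

    def test_raster_extent_covers_layout(self, small_trial):
        rasters = render_band_stacks(small_trial, flights=[27])
        om_plots = [p for p in small_trial.layout if p.trial == "OM"]
        maxx = max(p.polygon.bounds[2] for p in om_plots)
        maxy = max(p.polygon.bounds[3] for p in om_plots)
        nrow, ncol = rasters[0].stack.shape
        assert ncol >= maxx and nrow >= maxy

    def test_overlapping_plots_rejected(self, small_trial):
        import copy
        trial = copy.copy(small_trial)
        layout = copy.deepcopy(small_trial.layout)
        layout.plots[1].polygon = layout.plots[0].polygon
        trial.layout = layout
        with pytest.raises(ValueError, match="overlapping"):
            render_band_stacks(trial, flights=[27])
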