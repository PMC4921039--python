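import numpy as np
import pandas as pd
import pytest

import canegwas as cg
from canegwas.simdata import ConfigurationError


class TestSimulatePopulation:
    def test_shape_and_binary_calls(self, default_panel):
        _, markers, _, _ = default_panel
        assert markers.calls.shape == (88, 1745)
        vals = markers.values()
        assert set(np.unique(vals)) <= {0.0, 1.0}

    def test_deterministic_under_seed(self):
        cfg = cg.SimConfig(seed=5, n_markers=100, n_genotypes=30,
                           n_families=10)
        a, _ = cg.simulate_population(cfg)
        b, _ = cg.simulate_population(cfg)
        pd.testing.assert_frame_equal(a.calls, b.calls)
        c, _ = cg.simulate_population(cg.SimConfig(seed=6, n_markers=100,
                                                   n_genotypes=30,
                                                   n_families=10))
        assert not a.calls.equals(c.calls)

    def test_realized_frequencies_track_targets(self):
        cfg = cg.SimConfig(seed=7, n_markers=2000, band_freq_range=(0.3, 0.7))
        markers, _ = cg.simulate_population(cfg)
        f = cg.presence_frequency(markers).to_numpy()
        assert np.mean((f >= 0.25) & (f <= 0.75)) >= 0.99

    def test_qtl_are_simulated_markers_and_families_cover_panel(
            self, default_panel):
        _, markers, truth, _ = default_panel
        for ids in truth.qtl_markers.values():
            assert set(ids) <= set(markers.marker_ids)
        assert list(truth.family_of.index) == list(markers.genotype_ids)

    def test_linkage_groups_round_robin(self, default_panel):
        _, markers, _, _ = default_panel
        groups = markers.metadata["linkage_group"]
        assert groups.nunique() == 107
        assert groups.iloc[0] == groups.iloc[107]

    @pytest.mark.parametrize("field,kwargs", [
        ("band_freq_range", {"band_freq_range": (0.0, 0.9)}),
        ("n_genotypes", {"n_genotypes": 0}),
        ("qtl_per_trait", {"qtl_per_trait": 20, "n_markers": 10}),
        ("n_families", {"n_families": 99}),
        ("missing_fraction", {"missing_fraction": 1.5}),
    ])
    def test_invalid_config_names_field(self, field, kwargs):
        with pytest.raises(ConfigurationError, match=field.split("_")[0]):
            cg.simulate_population(cg.SimConfig(**kwargs))


class TestSimulateTrials:
    def test_balanced_record_count(self):
        cfg = cg.SimConfig(seed=1, n_markers=20, n_linkage_groups=5,
                           n_years=1,
                           traits={"CY": cg.SimConfig().traits["CY"]})
        markers, truth = cg.simulate_population(cfg)
        ph = cg.simulate_trials(markers, truth, cfg)
        assert len(ph.records) == 88 * 2 * 3  # genotypes x locations x blocks

    def test_all_zero_variances_no_qtl_gives_constant_mu(self):
        trait = cg.TraitSim(name="Y", year_means=(5.0,), qtl_effects=(),
                            year_scale=(1.0,),
                            variance=cg.VarianceComponents(residual=0.0))
        cfg = cg.SimConfig(seed=2, n_genotypes=12, n_families=4,
                           n_markers=10, n_linkage_groups=5, qtl_per_trait=0,
                           n_locations=2, n_blocks=2, n_years=1,
                           traits={"Y": trait})
        markers, truth = cg.simulate_population(cfg)
        ph = cg.simulate_trials(markers, truth, cfg)
        assert np.allclose(ph.records["value"], 5.0)

    def test_missing_fraction_removes_records(self):
        cfg = cg.SimConfig(seed=3, n_genotypes=30, n_families=10,
                           n_markers=10, n_linkage_groups=5, n_years=1,
                           missing_fraction=0.2,
                           traits={"CY": cg.SimConfig().traits["CY"]})
        markers, truth = cg.simulate_population(cfg)
        ph = cg.simulate_trials(markers, truth, cfg)
        full = 30 * 2 * 3
        assert len(ph.records) < full
        assert len(ph.records) == pytest.approx(full * 0.8, rel=0.2)

    def test_truth_with_unknown_marker_rejected(self):
        cfg = cg.SimConfig(seed=4, n_genotypes=20, n_families=5,
                           n_markers=10, n_linkage_groups=5, n_years=1)
        markers, truth = cg.simulate_population(cfg)
        truth.qtl_markers["CY"] = ["NOPE"]
        with pytest.raises(ValueError, match="unknown markers"):
            cg.simulate_trials(markers, truth, cfg)

    def test_realized_variances_match_configuration(self):
        """Pooled draws of each random term have the configured variance."""
        vc = cg.VarianceComponents(location=2.0, block=1.0, gxe=0.5,
                                   residual=4.0, family=1.5, individual=0.8,
                                   genotype_year=0.6)
        trait = cg.TraitSim(name="Y", year_means=(0.0,), qtl_effects=(),
                            year_scale=(1.0,), variance=vc)
        cfg = cg.SimConfig(n_genotypes=24, n_families=8, n_markers=5,
                           n_linkage_groups=5, qtl_per_trait=0,
                           n_locations=6, n_blocks=4, n_years=1,
                           traits={"Y": trait})
        pools = {"location": [], "block": [], "gxe": [], "residual": []}
        shared = []
        markers, truth = cg.simulate_population(cfg)
        for rep in range(80):
            _, eff = cg.simulate_trials(markers, truth, cfg, seed=900 + rep,
                                        return_effects=True)
            e = eff[("Y", 0)]
            pools["location"].append(e["location"].ravel())
            pools["block"].append(e["block"].ravel())
            pools["gxe"].append(e["gxe"].ravel())
            pools["residual"].append(e["residual"].ravel())
            shared.append(e["shared"].to_numpy())
        for name, target in [("location", vc.location), ("block", vc.block),
                             ("gxe", vc.gxe), ("residual", vc.residual)]:
            realized = np.var(np.concatenate(pools[name]))
            assert realized == pytest.approx(target, rel=0.1), name
        # family + individual polygenic variance
        realized = np.var(np.concatenate(shared))
        assert realized == pytest.approx(vc.family + vc.individual, rel=0.1)


class TestScenarioHelpers:
    def test_heritability_config_solves_residual(self):
        cfg = cg.heritability_config(0.75, sigma2_g=3.0, n_blocks=3)
        vc = cfg.traits["Y"].variance
        # H2 = s2g / (s2g + s2e/r) = 0.75  =>  s2e = s2g
        assert vc.residual == pytest.approx(3.0)
        assert vc.individual == pytest.approx(3.0)

    def test_power_scenario_plants_requested_variance_share(self):
        markers, truth, phenos, cfg = cg.power_scenario(seed=1, r2=0.25)
        qtl = truth.qtl_markers["Y"][0]
        beta = truth.qtl_effects[("Y", 0)][0]
        x = markers.calls[qtl]
        share = beta ** 2 * x.mean() * (1 - x.mean())
        vc = cfg.traits["Y"].variance
        rest = vc.family + vc.individual + vc.residual / cfg.n_blocks
        assert share / (share + rest) == pytest.approx(0.25, abs=0.01)
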