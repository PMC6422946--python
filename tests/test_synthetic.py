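import numpy as np
import pandas as pd
import pytest

from methanonet.process import alpha_app
from methanonet.synthetic import (GeneratorConfig, NicheSpec, build_design,
                                  simulate_counts, simulate_isotopes)


class TestBuildDesign:
    def test_one_soil_nine_treatments(self):
        cfg = GeneratorConfig(soils=("I",))
        design = build_design(cfg)
        # 3 pre-incubation temps x 3 reps + 9 factorial shifts x 3 reps
        assert len(design) == 9 + 27
        assert design["sample_id"].is_unique
        assert (design[design.phase == "shift"].groupby("treatment_code").size() == 3).all()
        assert design[design.phase == "shift"]["treatment_code"].nunique() == 9

    def test_zero_soils_empty(self):
        assert len(build_design(GeneratorConfig(soils=()))) == 0

    def test_three_soils(self):
        assert len(build_design(GeneratorConfig())) == 3 * 36

    def test_empty_temps_rejected(self):
        with pytest.raises(ValueError, match="temps"):
            build_design(GeneratorConfig(temps=()))

    def test_pre_phase_has_no_inc_temp(self, experiment):
        design, _, _ = experiment
        assert design.loc[design.phase == "pre", "inc_temp"].isna().all()
        assert design.loc[design.phase == "shift", "inc_temp"].notna().all()


class TestSimulateCounts:
    def test_column_sums_equal_depth_per_domain(self, default_config, experiment):
        _, table, _ = experiment
        bact = table.domain_table("Bacteria").counts.sum(axis=0)
        arch = table.domain_table("Archaea").counts.sum(axis=0)
        assert (bact == default_config.depth_bacteria).all()
        assert (arch == default_config.depth_archaea).all()

    def test_flat_niche_gives_equal_expectation(self):
        """An infinitely wide niche responds identically at every temperature."""
        spec = {
            "OTU_B001": NicheSpec(35.0, 1e6, False, "fermenter", "Bacteria;flat"),
            "OTU_B002": NicheSpec(35.0, 1e6, False, "fermenter", "Bacteria;flat2"),
            "OTU_A001": NicheSpec(35.0, 1e6, False, "hydrogenotrophic", "Archaea;flat"),
        }
        cfg = GeneratorConfig(soils=("I",), assemblage_spec=spec, ecotype_map={}, seed=3)
        design = build_design(cfg)
        _, truth = simulate_counts(cfg, design)
        exp = truth.expected.loc["OTU_B001"]
        assert np.allclose(exp, exp.iloc[0])

    def test_hysteresis_kills_after_45(self):
        spec = {
            "OTU_B001": NicheSpec(30.0, 5.0, True, "fermenter", "Bacteria;meso"),
            "OTU_B002": NicheSpec(45.0, 3.0, False, "fermenter", "Bacteria;thermo"),
            "OTU_A001": NicheSpec(45.0, 3.0, False, "hydrogenotrophic", "Archaea;thermo"),
        }
        cfg = GeneratorConfig(soils=("I",), assemblage_spec=spec, ecotype_map={}, seed=3)
        design = build_design(cfg)
        table, truth = simulate_counts(cfg, design)
        pre45 = design.loc[design.pre_temp == 45, "sample_id"]
        assert (truth.expected.loc["OTU_B001", pre45] == 0).all()
        assert (table.counts.loc["OTU_B001", pre45] == 0).all()
        # without the 45 degC episode the mesophile is alive
        ok = design.loc[(design.pre_temp == 25) & (design.inc_temp == 25), "sample_id"]
        assert (truth.expected.loc["OTU_B001", ok] > 0).all()

    def test_monte_carlo_mean_matches_expectation(self):
        """Sampled relative abundance of a planted thermophile at 45 degC
        agrees with the analytic multinomial expectation within 3 SE."""
        spec = {
            "OTU_B001": NicheSpec(45.0, 3.0, False, "fermenter", "Bacteria;a"),
            "OTU_B002": NicheSpec(35.0, 7.0, False, "fermenter", "Bacteria;b"),
            "OTU_B003": NicheSpec(25.0, 7.0, False, "fermenter", "Bacteria;c"),
            "OTU_A001": NicheSpec(35.0, 7.0, False, "hydrogenotrophic", "Archaea;d"),
        }
        cfg = GeneratorConfig(soils=("I",), temps=(45,), n_replicates=1,
                              assemblage_spec=spec, ecotype_map={},
                              replicate_sigma=0.0, depth_bacteria=200,
                              depth_archaea=50, lognormal_sigma=0.0, seed=0)
        design = build_design(cfg)
        sample = design.sample_id.iloc[0]
        draws = []
        expected = None
        for s in range(1000):
            table, truth = simulate_counts(
                GeneratorConfig(**{**cfg.__dict__, "seed": s}), design)
            draws.append(table.counts.loc["OTU_B001", sample] / 200)
            expected = truth.expected.loc["OTU_B001", sample]
        draws = np.asarray(draws)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws.mean() - expected) < 3 * se

    def test_seed_determinism(self, default_config, experiment):
        design, table, _ = experiment
        table2, _ = simulate_counts(default_config, build_design(default_config))
        pd.testing.assert_frame_equal(table.counts, table2.counts)

    def test_negative_config_rejected(self):
        with pytest.raises(ValueError, match="depth_bacteria"):
            simulate_counts(GeneratorConfig(depth_bacteria=-5),
                            build_design(GeneratorConfig()))

    def test_ground_truth_covers_every_otu_once_per_soil(self, experiment):
        _, table, truth = experiment
        per_soil = truth.otus.groupby("soil")["otu_id"].apply(list)
        for _, otus in per_soil.items():
            assert sorted(otus) == sorted(table.otu_ids)

    def test_assemblages_partition_into_three(self, experiment):
        _, _, truth = experiment
        for soil in "IPU":
            assert set(truth.assemblage_of(soil).unique()) == {25, 35, 45}

    def test_expected_shannon_lower_after_45(self, experiment):
        """Thermophilic assemblage is smaller than the mesophilic ones, so
        the expected archaeal composition after a 45 degC pre-incubation is
        less diverse (assert on expectations pooled over soils)."""
        design, table, truth = experiment
        arch = (table.domain == "Archaea").to_numpy()
        ent = {}
        for s in truth.expected.columns:
            p = truth.expected.loc[arch, s].to_numpy()
            p = p[p > 0]
            ent[s] = -(p * np.log(p)).sum()
        ent = pd.Series(ent)
        pre = design.set_index("sample_id")["pre_temp"].loc[ent.index]
        assert ent[pre == 45].mean() < ent[pre != 45].mean()


class TestSimulateIsotopes:
    def test_alpha_identity_for_pure_hydrogenotrophic(self):
        """Noise-free, f = 1, d13CO2 = -10: d13CH4 = 990/1.08 - 1000."""
        cfg = GeneratorConfig(isotope_noise_sd=0.0, d13_co2_noise_sd=0.0, seed=5)
        design = build_design(cfg)
        _, truth = simulate_counts(cfg, design)
        iso = simulate_isotopes(cfg, design, truth)
        # U45e45: acetoclasts are hysteretic in this soil, so both the
        # pre-incubation state and the equilibrium are purely
        # hydrogenotrophic and alpha is constant at alpha_hydro
        sub = iso[iso.treatment_code == "U45e45"]
        assert truth.samples.loc[sub.sample_id.iloc[0], "f_hydro"] == 1.0
        assert np.allclose(sub.d13_ch4, 990.0 / 1.08 - 1000.0)

    def test_alpha_app_recovers_alpha_true_noise_free(self):
        cfg = GeneratorConfig(soils=("I",), isotope_noise_sd=0.0,
                              d13_co2_noise_sd=0.0, seed=5)
        design = build_design(cfg)
        _, truth = simulate_counts(cfg, design)
        iso = simulate_isotopes(cfg, design, truth)
        back = alpha_app(iso.d13_co2.to_numpy(), iso.d13_ch4.to_numpy())
        assert np.allclose(back, iso.alpha_true, atol=1e-12)

    def test_unit_fractionation_means_equal_deltas(self):
        cfg = GeneratorConfig(soils=("I",), alpha_hydro=1.0 + 1e-12,
                              alpha_mixed=1.0 + 1e-12, isotope_noise_sd=0.0,
                              d13_co2_noise_sd=0.0, seed=5)
        design = build_design(cfg)
        _, truth = simulate_counts(cfg, design)
        iso = simulate_isotopes(cfg, design, truth)
        assert np.allclose(iso.d13_ch4, iso.d13_co2, atol=1e-6)

    def test_only_shift_samples(self, isotope_series, experiment):
        design, _, _ = experiment
        shift_ids = set(design.loc[design.phase == "shift", "sample_id"])
        assert set(isotope_series.sample_id) == shift_ids


class TestSimulateAncillary:
    def test_qpcr_domain_ratio_one_order_of_magnitude(self, ancillary):
        qpcr, _ = ancillary
        logs = qpcr.assign(l=np.log10(qpcr.copies_per_g)).groupby("domain")["l"].mean()
        assert logs["Bacteria"] - logs["Archaea"] == pytest.approx(1.0, abs=0.1)

    def test_acetate_accumulates_iff_both_guilds_absent(self, experiment, ancillary):
        design, _, truth = experiment
        _, vfa = ancillary
        merged = vfa.set_index("sample_id").join(truth.samples["acetate_accumulating"])
        base = merged.loc[~merged.acetate_accumulating, "acetate_mM"]
        high = merged.loc[merged.acetate_accumulating, "acetate_mM"]
        assert len(high) > 0
        assert high.min() > 10 * base.median()
        assert base.max() < high.min()

    def test_accumulation_matches_guild_absence(self, experiment):
        """Acetate accumulates exactly where neither acetoclasts nor
        syntrophic acetate oxidizers are active; in particular in every
        45 degC-pre-incubated sample of the SAO-free soil, but never in
        the soils where SAO (I) or broad-niche acetoclasts (P) consume it."""
        design, _, truth = experiment
        st = truth.samples.join(design.set_index("sample_id")[["treatment_code", "pre_temp"]])
        inactive = (st.aceto_activity < 0.01) & (st.sao_activity < 0.01)
        assert (st.acetate_accumulating == inactive).all()
        u45 = st[(st.soil == "U") & (st.pre_temp == 45)]
        assert u45.acetate_accumulating.all()
        for code in ("I45", "I45e45", "P45", "P45e45"):
            assert not st.loc[st.treatment_code == code, "acetate_accumulating"].any()


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = GeneratorConfig(seed=7, depth_bacteria=5000)
        path = tmp_path / "gen.yaml"
        cfg.to_yaml(path)
        back = GeneratorConfig.from_yaml(path)
        assert back == cfg

    def test_validate_collects_all_violations(self):
        bad = GeneratorConfig(n_replicates=0, depth_archaea=0, alpha_hydro=0.9)
        msgs = bad.validate()
        assert len(msgs) >= 3
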