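import numpy as np
import pytest

from idirt.io import filter_psms, read_ms1
from idirt.pipeline import run_pipeline
from idirt.quant import quantify_all
from idirt.simulate import (
    NOISE_FREE,
    SimProtein,
    default_scenario,
    simulate,
    subset_scenario,
)


class TestDefaultScenario:
    def test_anchor_fractions(self):
        table = default_scenario(seed=0).fraction_table()
        for cond in ("FA0", "FA0.05", "FA0.25", "FA1.25"):
            assert table[("bait", cond)] == 1.0
            assert table[("non-specific", cond)] == 0.5
        assert table[("bulk-H3", "FA0")] == 0.90
        assert table[("bulk-H3", "FA0.05")] == 0.80

    def test_acetylated_fraction_never_above_bulk(self):
        table = default_scenario(seed=0).fraction_table()
        for cond in ("FA0", "FA0.05", "FA0.25", "FA1.25"):
            assert table[("H3K9acK14ac", cond)] <= table[("bulk-H3", cond)]
            assert table[("H4K12acK16ac", cond)] <= table[("bulk-H4", cond)]

    def test_class_sizes(self, sim_default):
        per_cond = sim_default.truth[sim_default.truth.condition == "FA0"]
        sizes = per_cond.groupby("class_label").size()
        assert sizes["bait"] >= 10
        assert sizes["bulk-H3"] >= 10
        assert sizes["non-specific"] >= 30
        assert sizes["H3K9acK14ac"] >= 2


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        scenario = default_scenario(seed=3)
        a = simulate(scenario, outdir=tmp_path / "a")
        b = simulate(scenario, outdir=tmp_path / "b")
        for name in ("truth.tsv", "groups.tsv", "FA0_psms.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name).read_bytes()
        assert (tmp_path / "a" / "FA0.mzML").read_bytes() == (
            tmp_path / "b" / "FA0.mzML").read_bytes()
        for c in scenario.conditions:
            for sa, sb in zip(a.spectra[c], b.spectra[c]):
                assert np.array_equal(sa.mz, sb.mz)
                assert np.array_equal(sa.intensity, sb.intensity)

    def test_different_seed_differs(self):
        a = simulate(default_scenario(seed=3))
        b = simulate(default_scenario(seed=4))
        assert not np.array_equal(a.spectra["FA0"][0].mz, b.spectra["FA0"][0].mz)


class TestGeneratedData:
    def test_spectra_are_valid_and_round_trip(self, sim_default, tmp_path):
        paths = sim_default.write(tmp_path)
        got = read_ms1(paths["mzml"]["FA0.05"])
        orig = sim_default.spectra["FA0.05"]
        assert len(got) == len(orig)
        for a, b in zip(got, orig):
            assert np.all(np.diff(a.mz) > 0)
            assert np.array_equal(a.mz, b.mz)
            assert np.array_equal(a.intensity, b.intensity)

    def test_bait_has_zero_injected_heavy(self, sim_default):
        bait = sim_default.truth[sim_default.truth.class_label == "bait"]
        assert (bait.I_H == 0).all()
        assert (bait.true_f == 1.0).all()

    def test_decoys_removed_and_harmless(self, sim_default):
        psms = sim_default.psms["FA0"]
        decoys = [p for p in psms if p.peptide.protein_id == "DECOY"]
        assert decoys, "scenario should emit decoy PSMs"
        kept, report = filter_psms(psms, 0.01)
        assert all(p.peptide.protein_id != "DECOY" for p in kept)
        assert report.n_q_removed >= len(decoys)
        # stripping the decoy mechanism changes no quantification result
        spectra = sim_default.spectra["FA0"]
        with_decoys, _ = quantify_all(spectra, kept)
        stripped, _ = filter_psms(
            [p for p in psms if p.peptide.protein_id != "DECOY"], 0.01)
        without_decoys, _ = quantify_all(spectra, stripped)
        assert [p.percent_light for p in with_decoys] == [
            p.percent_light for p in without_decoys]

    def test_argfree_psms_present_and_filtered(self, sim_default):
        psms = sim_default.psms["FA0"]
        argfree = [p for p in psms if "R" not in p.peptide.sequence]
        assert argfree
        _kept, report = filter_psms(psms, 0.01)
        assert report.n_unlabeled_removed == len(argfree)


class TestNoiseFreeOracle:
    def test_extracted_percent_light_equals_truth(self, sim_noise_free):
        sc = sim_noise_free.scenario
        result = run_pipeline(sim_noise_free.spectra, sim_noise_free.psms,
                              sim_noise_free.groups, list(sc.conditions))
        truth = sim_noise_free.truth.set_index(
            ["condition", "protein_id", "sequence", "modifications"])
        n = 0
        for cond, pairs in result.quants.items():
            for p in pairs:
                t = truth.loc[(cond, p.protein_id, p.sequence, p.mod_string)]
                assert abs(p.percent_light - t.true_f) <= 1e-9
                n += 1
        assert n >= 200

    def test_extracted_intensities_match_injected(self, sim_noise_free):
        """Light monoisotopic intensity equals the injected value exactly."""
        result = run_pipeline(sim_noise_free.spectra, sim_noise_free.psms,
                              sim_noise_free.groups,
                              list(sim_noise_free.scenario.conditions))
        truth = sim_noise_free.truth.set_index(
            ["condition", "protein_id", "sequence", "modifications"])
        for cond, pairs in result.quants.items():
            for p in pairs:
                t = truth.loc[(cond, p.protein_id, p.sequence, p.mod_string)]
                assert p.I_L == pytest.approx(t.I_L, rel=1e-12)


class TestRecoveryContract:
    def test_class_mean_within_two_points_of_truth(self):
        """|recovered class mean - true f| <= 0.02 under default noise."""
        failures = 0
        n_rep = 30
        for seed in range(n_rep):
            scenario = subset_scenario(
                default_scenario(seed=100 + seed),
                classes=["bulk-H3"], conditions=["FA0.05"])
            res = simulate(scenario)
            result = run_pipeline(res.spectra, res.psms, res.groups, ["FA0.05"])
            (summary,) = [s for s in result.summaries
                          if s.key.class_label == "bulk-H3"]
            assert summary.n_peptides >= 8
            if abs(summary.mean_percent_light - 0.80) > 0.02:
                failures += 1
        assert failures <= max(1, round(0.05 * n_rep))


class TestScenarioValidation:
    def test_class_without_arg_peptides_fatal(self):
        bad = SimProtein("NOARG", "GGAKGGSKGGLK", "no-arg-class")
        scenario = default_scenario(seed=0)
        from dataclasses import replace
        scenario = replace(
            scenario,
            proteins=scenario.proteins + (bad,),
            light_fraction=scenario.light_fraction + tuple(
                ("no-arg-class", c, 0.5) for c in scenario.conditions),
        )
        with pytest.raises(ValueError, match="no-arg-class"):
            simulate(scenario)

    def test_light_fraction_must_cover_all_cells(self):
        scenario = default_scenario(seed=0)
        from dataclasses import replace
        with pytest.raises(ValueError, match="no light fraction"):
            replace(scenario,
                    light_fraction=tuple(t for t in scenario.light_fraction
                                         if t[0] != "bulk-H4"))

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError, match="not in"):
            default_scenario(
                seed=0,
                light_fraction=tuple(
                    (l, c, 1.5 if l == "bulk-H3" else f)
                    for l, c, f in default_scenario(seed=0).light_fraction),
            )
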