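import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from idirt.chem import PeptideSpecies, averagine_envelope, mz_from_mass
from idirt.io import PsmRecord, SpectrumMS1
from idirt.quant import (
    PairQuant,
    QuantParams,
    collapse_peptidoforms,
    extract_pair,
    find_peak,
    overlap_correct,
    percent_light,
    quantify_all,
)

NO_CORRECTION = QuantParams(overlap_correction=False)


def spectrum(rt, peaks, scan_id="s"):
    peaks = sorted(peaks)
    return SpectrumMS1(scan_id, rt,
                       np.array([p[0] for p in peaks]),
                       np.array([p[1] for p in peaks]))


class TestFindPeak:
    SPEC = spectrum(0.0, [(500.0000, 1e5), (500.0040, 2e5)])

    def test_nearest_peak_wins(self):
        assert find_peak(self.SPEC, 500.0000, 10.0) == 1e5

    def test_distance_tie_broken_by_intensity(self):
        assert find_peak(self.SPEC, 500.0020, 10.0) == 2e5

    def test_empty_window_is_absent(self):
        assert find_peak(self.SPEC, 501.0, 10.0) is None


class TestPercentLight:
    @pytest.mark.parametrize("IL,IH,expected", [
        (100.0, 100.0, 0.5),   # the non-specific ~50:50 signature
        (100.0, 0.0, 1.0),     # pure light: the bait signature
        (90.0, 10.0, 0.9),     # ~10% exchange, the uncross-linked regime
    ])
    def test_values(self, IL, IH, expected):
        assert percent_light(IL, IH) == expected

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            percent_light(0.0, 0.0)

    intensity = st.one_of(st.just(0.0), st.floats(1e-3, 1e9))

    @given(intensity, intensity)
    @settings(max_examples=1000, deadline=None)
    def test_bounds_and_swap_symmetry(self, IL, IH):
        if IL + IH == 0:
            return
        p = percent_light(IL, IH)
        assert 0.0 <= p <= 1.0
        assert (p == 1.0) == (IH == 0.0)
        assert (p == 0.0) == (IL == 0.0)
        # exchanging the channels mirrors the statistic
        assert percent_light(IH, IL) == pytest.approx(1.0 - p, abs=1e-12)


class TestOverlapCorrect:
    ENV = averagine_envelope(2000.0, 8)

    def _env_with_ratio(self, ratio):
        rest = 1.0 - 0.5 * (1 + ratio)
        from idirt.chem import IsotopeEnvelope
        return IsotopeEnvelope((0.5, rest, 0.5 * ratio))

    def test_subtracts_light_contribution(self):
        env = self._env_with_ratio(0.01)
        corrected, clamped = overlap_correct(500.0, 1000.0, env, 2)
        assert corrected == pytest.approx(490.0)
        assert not clamped

    def test_clamps_at_zero(self):
        env = self._env_with_ratio(0.01)
        corrected, clamped = overlap_correct(5.0, 1000.0, env, 2)
        assert corrected == 0.0 and clamped

    def test_zero_ratio_identity(self):
        env = self._env_with_ratio(0.0)
        corrected, clamped = overlap_correct(500.0, 1000.0, env, 2)
        assert corrected == 500.0 and not clamped

    def test_short_envelope_rejected(self):
        with pytest.raises(ValueError, match="envelope"):
            overlap_correct(500.0, 1000.0, self.ENV, 12)


def make_psm(sequence="GQEILSR", charge=2, rt=100.0, psm_id="p1", mods=()):
    return PsmRecord(psm_id, PeptideSpecies(sequence, mods, charge, "P1", 1), rt, 0.005)


def pair_spectrum(psm, I_L, I_H, rt=100.0, scan_id="s"):
    pep = psm.peptide
    light = pep.mz
    heavy = light + 6.020129 * pep.n_label_residues / pep.charge
    peaks = []
    if I_L:
        peaks.append((light, I_L))
    if I_H:
        peaks.append((heavy, I_H))
    return spectrum(rt, peaks, scan_id)


class TestExtractPair:
    def test_direct_ratio(self):
        psm = make_psm()
        spec = pair_spectrum(psm, 8e4, 2e4)
        pair, reason = extract_pair([spec], psm, NO_CORRECTION)
        assert reason is None
        assert (pair.I_L, pair.I_H) == (8e4, 2e4)
        assert pair.percent_light == pytest.approx(0.8)

    def test_heavy_missing_is_pure_light_with_flag(self):
        psm = make_psm()
        pair, _ = extract_pair([pair_spectrum(psm, 8e4, 0)], psm, NO_CORRECTION)
        assert pair.percent_light == 1.0
        assert "heavy_missing" in pair.flags

    def test_light_missing_is_pure_heavy_with_flag(self):
        psm = make_psm()
        pair, _ = extract_pair([pair_spectrum(psm, 0, 8e4)], psm, NO_CORRECTION)
        assert pair.percent_light == 0.0
        assert "light_missing" in pair.flags

    def test_both_missing_excluded(self):
        psm = make_psm()
        empty = spectrum(100.0, [(123.0, 1.0)])
        pair, reason = extract_pair([empty], psm, NO_CORRECTION)
        assert pair is None and "missing" in reason

    def test_no_scans_in_window_excluded(self):
        psm = make_psm(rt=1000.0)
        pair, reason = extract_pair([pair_spectrum(psm, 1e4, 1e4, rt=0.0)], psm)
        assert pair is None and "no MS1 scans" in reason

    def test_apex_scan_selected_and_same_scan_ratio(self):
        psm = make_psm()
        scans = [
            pair_spectrum(psm, 1e4, 1e3, rt=98.0, scan_id="a"),
            pair_spectrum(psm, 5e4, 2e3, rt=100.0, scan_id="b"),
            pair_spectrum(psm, 3e4, 9e3, rt=102.0, scan_id="c"),
        ]
        pair, _ = extract_pair(scans, psm, NO_CORRECTION)
        assert (pair.I_L, pair.I_H) == (5e4, 2e3)

    def test_summed_mode_integrates_all_scans(self):
        psm = make_psm()
        scans = [
            pair_spectrum(psm, 1e4, 1e3, rt=98.0),
            pair_spectrum(psm, 5e4, 2e3, rt=100.0),
        ]
        params = QuantParams(xic_mode="summed", overlap_correction=False)
        pair, _ = extract_pair(scans, psm, params)
        assert (pair.I_L, pair.I_H) == (6e4, 3e3)

    def test_unlabeled_peptide_unquantifiable(self):
        psm = make_psm("GQEILSK")
        pair, reason = extract_pair([pair_spectrum(psm, 1e4, 0)], psm)
        assert pair is None and "no labeled residue" in reason

    def test_scale_invariance(self):
        psm = make_psm()
        base = pair_spectrum(psm, 8e4, 2e4)
        scaled = SpectrumMS1("s", 100.0, base.mz, base.intensity * 37.5)
        p1, _ = extract_pair([base], psm)
        p2, _ = extract_pair([scaled], psm)
        assert p1.percent_light == pytest.approx(p2.percent_light, abs=1e-12)


class TestCollapse:
    def _pair(self, I_L, I_H, mods="", charge=2, n=1):
        return PairQuant("P1", "GQEILSR", mods, 1, (charge,), I_L, I_H,
                         percent_light(I_L, I_H), n_psms=n)

    def test_intensity_weighted_pooling(self):
        collapsed = collapse_peptidoforms([self._pair(100, 0), self._pair(300, 100, charge=3)])
        assert len(collapsed) == 1
        assert collapsed[0].percent_light == pytest.approx(0.8)
        assert collapsed[0].charges == (2, 3)
        assert collapsed[0].n_psms == 2

    def test_distinct_modifications_not_collapsed(self):
        collapsed = collapse_peptidoforms(
            [self._pair(100, 100), self._pair(100, 0, mods="1:acetyl")]
        )
        assert len(collapsed) == 2

    def test_single_psm_identity(self):
        (got,) = collapse_peptidoforms([self._pair(100, 50)])
        assert (got.I_L, got.I_H, got.n_psms) == (100, 50, 1)

    def test_label_swap_symmetry(self, rng):
        pairs = [self._pair(a, b) for a, b in rng.uniform(1, 1e6, (50, 2))]
        swapped = [self._pair(p.I_H, p.I_L) for p in pairs]
        a = collapse_peptidoforms(pairs)[0].percent_light
        b = collapse_peptidoforms(swapped)[0].percent_light
        assert a == pytest.approx(1.0 - b, abs=1e-12)


class TestQuantifyAll:
    def test_report_accounts_for_every_psm(self):
        good = make_psm()
        far = make_psm(rt=1e6, psm_id="p2")
        spec = pair_spectrum(good, 1e4, 1e4)
        pairs, report = quantify_all([spec], [good, far])
        assert report.n_psms == 2
        assert report.n_quantified == len(pairs) == 1
        assert report.n_excluded_no_scans == 1
        assert len(report.excluded) == 1
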