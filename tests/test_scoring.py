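"""Cascade scores: oxonium triage, envelope similarity, fragment matching,
decoys and FDR estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nglyq.chem import GlycanComposition, Glycopeptide, PeptideBackbone
from nglyq.isotopes import IsotopePattern, predict_pattern
from nglyq.scoring import (
    DEFAULT_OXONIUM_TABLE,
    FragmentSet,
    OxoniumIon,
    estimate_fdr,
    fit_mscore_threshold,
    generate_fragments,
    glycan_ladder,
    m_score,
    make_decoy,
    match_score,
    s_score,
    y_score,
)
from nglyq.spectra import Ms2Spectrum

GP = Glycopeptide(PeptideBackbone("ENGTISR", 2, "P1"),
                  GlycanComposition(5, 4, 0, 2))


def spec(mz, intensity, mode="HCD"):
    return Ms2Spectrum(np.array(mz, float), np.array(intensity, float),
                       1000.0, 3, 5.0, mode, "s")


class TestMScore:
    def test_default_table_has_fifteen_ions(self):
        assert len(DEFAULT_OXONIUM_TABLE) == 15
        assert all(ion.mz < 700 for ion in DEFAULT_OXONIUM_TABLE)
        assert all(ion.weight > 0 for ion in DEFAULT_OXONIUM_TABLE)

    def test_no_oxonium_match_scores_zero(self):
        assert m_score(spec([500.0, 600.0], [10.0, 20.0])) == 0.0

    def test_single_base_peak_match(self):
        """A matched HexNAc ion that is the sub-700 base peak, weight 1 and
        zero mass error contributes exactly its weighted relative
        intensity."""
        table = (OxoniumIon(204.087, 1.0, "HexNAc"),)
        s = spec([204.087, 800.0], [500.0, 1e9])
        assert m_score(s, table) == pytest.approx(1.0)

    def test_two_ion_weighted_sum(self):
        table = (OxoniumIon(204.087, 1.0, "a"), OxoniumIon(366.140, 0.8, "b"))
        s = spec([204.087, 366.140], [1000.0, 500.0])
        assert m_score(s, table) == pytest.approx(1.0 + 0.8 * 0.5)

    def test_mass_error_damps_contribution(self):
        table = (OxoniumIon(204.087, 1.0, "a"),)
        off = 204.087 * (1 + 10e-6)  # 10 ppm off
        s = spec([off], [100.0])
        expected = 1.0 / (abs(off - 204.087) + 1.0)
        assert m_score(s, table) == pytest.approx(expected)

    def test_empty_spectrum_zero(self):
        assert m_score(spec([], [])) == 0.0

    def test_intensity_scale_invariance(self):
        s1 = spec([138.055, 204.087, 366.14, 500.0], [5.0, 50.0, 20.0, 30.0])
        s2 = spec([138.055, 204.087, 366.14, 500.0],
                  [500.0, 5000.0, 2000.0, 3000.0])
        assert m_score(s1) == pytest.approx(m_score(s2))


class TestMScoreThreshold:
    def test_null_mode_gives_mu_plus_three_sigma(self):
        rng = np.random.default_rng(0)
        t = fit_mscore_threshold(rng.normal(0.3, 0.1, 2000), floor=0.1)
        assert t == pytest.approx(0.6, abs=0.05)

    def test_bimodal_separation_retains_glycopeptides(self):
        rng = np.random.default_rng(5)
        null = rng.normal(0.3, 0.1, 900)
        glyco = rng.normal(2.0, 0.3, 100)
        t = fit_mscore_threshold(np.concatenate([null, glyco]), floor=0.1)
        assert 0.5 < t < 1.5
        assert (glyco >= t).mean() > 0.99

    def test_constant_scores_fall_back_to_floor(self):
        t = fit_mscore_threshold(np.full(200, 0.7), floor=0.5)
        assert t == 0.5

    def test_requires_enough_scores(self):
        with pytest.raises(ValueError):
            fit_mscore_threshold(np.ones(50))


class TestSScore:
    @pytest.fixture()
    def pattern(self):
        return predict_pattern(GP.formula, charge=3)

    def test_perfect_match_scores_100(self, pattern):
        obs = np.zeros(8)
        n = min(8, len(pattern.rel_intensity))
        obs[:n] = pattern.rel_intensity[:n]
        assert s_score(obs, pattern, 10.0) == pytest.approx(100.0, abs=1e-9)

    def test_mass_errors_cap_score_at_ten(self, pattern):
        """With every peak off in mass by at least the tolerance, the 9:1
        weighting caps the score at the intensity share."""
        n = min(8, len(pattern.rel_intensity))
        obs = np.zeros(8)
        obs[:n] = pattern.rel_intensity[:n]
        bad_mz = pattern.mz[:8] * (1 + 50e-6)  # 50 ppm off everywhere
        assert s_score(obs, pattern, 10.0, observed_mz=bad_mz) <= 10.0

    def test_all_zero_envelope_zero(self, pattern):
        assert s_score(np.zeros(8), pattern, 10.0) == 0.0

    def test_scale_invariance(self, pattern):
        obs = np.zeros(8)
        n = min(8, len(pattern.rel_intensity))
        obs[:n] = pattern.rel_intensity[:n]
        assert s_score(obs * 7.3, pattern, 10.0) == pytest.approx(
            s_score(obs, pattern, 10.0))


class TestFragments:
    def test_hexnac_b_ion(self):
        frags = generate_fragments(GP, 3, "CID")
        b = [mz for mz, lab in zip(frags.mz, frags.labels)
             if lab == "B_0100"]
        assert len(b) == 1
        assert b[0] == pytest.approx(204.0867, abs=1e-3)

    def test_bare_peptide_y0_always_present(self):
        for code in ("5402", "9200", "4413"):
            gp = Glycopeptide(PeptideBackbone("ENGTISR", 2),
                              GlycanComposition(*(int(c) for c in code)))
            frags = generate_fragments(gp, 3, "CID")
            assert "Y_0000^1+" in frags.labels

    def test_cid_charge_states_for_triply_charged_precursor(self):
        frags = generate_fragments(GP, 3, "CID")
        charges = {lab.split("^")[1] for lab in frags.labels
                   if lab.startswith("Y_")}
        assert charges == {"1+", "2+"}
        assert any(lab.startswith("B_") for lab in frags.labels)

    def test_hcd_has_only_singly_charged_y_plus_peptide_ions(self):
        frags = generate_fragments(GP, 3, "HCD")
        y_charges = {lab.split("^")[1] for lab in frags.labels
                     if lab.startswith("Y_")}
        assert y_charges == {"1+"}
        assert any(lab.startswith("b") for lab in frags.labels)
        assert any(lab.startswith("y") for lab in frags.labels)
        assert any(lab.startswith("oxonium") for lab in frags.labels)

    @given(st.tuples(st.integers(0, 8), st.integers(2, 7),
                     st.integers(0, 3), st.integers(0, 4)))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_ladder_states_bounded_by_parent(self, counts):
        g = GlycanComposition(*counts)
        states = glycan_ladder(g)
        assert g.as_tuple() in states
        assert (0, 0, 0, 0) in states
        for h, n, f, s in states:
            assert 0 <= h <= g.hex and 0 <= n <= g.hexnac
            assert 0 <= f <= g.fuc and 0 <= s <= g.neuac


class TestMatchScore:
    def test_all_matched_scores_100(self):
        frags = FragmentSet(np.array([300.0, 500.0]), ["a", "b"])
        assert match_score(spec([300.0, 500.0], [5.0, 10.0]), frags) == 100.0

    def test_nothing_matched_scores_0(self):
        frags = FragmentSet(np.array([300.0]), ["a"])
        assert match_score(spec([800.0], [5.0]), frags) == 0.0

    def test_half_intensity_matched(self):
        frags = FragmentSet(np.array([500.0]), ["a"])
        assert match_score(spec([500.0, 900.0], [10.0, 10.0]), frags) == 50.0

    def test_denoising_keeps_top_peaks(self):
        mz = np.concatenate([[500.0], np.linspace(600, 1500, 300)])
        inten = np.concatenate([[1000.0], np.full(300, 1.0)])
        frags = FragmentSet(np.array([500.0]), ["a"])
        score = match_score(spec(mz, inten), frags, denoise_top=200)
        assert score == pytest.approx(100 * 1000 / (1000 + 199), rel=1e-6)

    def test_scale_invariance(self):
        frags = FragmentSet(np.array([300.0, 700.0]), ["a", "b"])
        s1 = match_score(spec([300.0, 900.0], [4.0, 6.0]), frags)
        s2 = match_score(spec([300.0, 900.0], [400.0, 600.0]), frags)
        assert s1 == pytest.approx(s2)


class TestYScore:
    @pytest.mark.parametrize("cid,hcd,expected", [
        (80.0, 80.0, 80.0),
        (100.0, 0.0, 70.0),
        (0.0, 100.0, 30.0),
    ])
    def test_seven_three_weighting(self, cid, hcd, expected):
        assert y_score(cid, hcd) == pytest.approx(expected)

    def test_single_mode_fallback(self):
        assert y_score(None, 60.0) == 60.0
        assert y_score(60.0, None) == 60.0
        with pytest.raises(ValueError):
            y_score(None, None)


class TestDecoy:
    def test_glycan_class_swap(self):
        gp = Glycopeptide(PeptideBackbone("CANLVPVPITNATLDQITGK", 11),
                          GlycanComposition(6, 5, 0, 3))
        d = make_decoy(gp)
        assert d.glycan.as_tuple() == (5, 6, 3, 0)

    def test_sequence_reversed_with_mirrored_site(self):
        d = make_decoy(GP)
        assert d.backbone.sequence == "RSITGNE"
        assert d.backbone.glycosite == len("ENGTISR") - 2 + 1

    def test_swap_fixed_point_still_distinct_by_reversal(self):
        gp = Glycopeptide(PeptideBackbone("ENGTISR", 2),
                          GlycanComposition(4, 4, 2, 2))
        d = make_decoy(gp)
        assert d.glycan == gp.glycan
        assert d.backbone.sequence != gp.backbone.sequence

    @given(st.tuples(st.integers(0, 9), st.integers(0, 9),
                     st.integers(0, 9), st.integers(0, 9)))
    @settings(max_examples=50, derandomize=True)
    def test_glycan_swap_is_involution(self, counts):
        g = GlycanComposition(*counts)
        swapped = GlycanComposition(g.hexnac, g.hex, g.neuac, g.fuc)
        back = GlycanComposition(swapped.hexnac, swapped.hex,
                                 swapped.neuac, swapped.fuc)
        assert back == g

    def test_decoy_preserves_peptide_mass(self):
        d = make_decoy(GP)
        from nglyq.chem import peptide_mass

        assert peptide_mass(d.backbone.sequence) == pytest.approx(
            peptide_mass(GP.backbone.sequence), abs=1e-9)


class TestFdr:
    def test_one_decoy_over_hundred_targets(self):
        q, thr = estimate_fdr([10.0] * 100, [10.0])
        assert np.allclose(q, 0.01)
        assert thr == 10.0

    def test_no_decoys_above_targets_accepts_all(self):
        q, thr = estimate_fdr([50.0, 60.0, 70.0], [10.0, 20.0])
        assert np.allclose(q, 0.0)
        assert thr == 50.0

    def test_empty_decoys_warns_and_accepts(self):
        q, thr = estimate_fdr([5.0, 6.0], [])
        assert np.allclose(q, 0.0)
        assert thr == 5.0

    def test_q_values_monotone_in_score(self):
        rng = np.random.default_rng(1)
        targets = rng.uniform(0, 100, 500)
        decoys = rng.uniform(0, 60, 300)
        q, _ = estimate_fdr(targets, decoys)
        order = np.argsort(targets)
        assert np.all(np.diff(q[order]) <= 1e-12)

    def test_simulated_calibration_within_twofold(self):
        """Reported FDR at threshold tracks the planted false fraction."""
        rng = np.random.default_rng(7)
        true_scores = rng.normal(80, 5, 200)
        false_scores = rng.normal(30, 10, 800)
        false_decoys = rng.normal(30, 10, 800)
        targets = np.concatenate([true_scores, false_scores])
        q, thr = estimate_fdr(targets, false_decoys, fdr=0.05)
        accepted = targets >= thr
        realized = (false_scores >= thr).sum() / max(accepted.sum(), 1)
        assert realized <= 2 * 0.05
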