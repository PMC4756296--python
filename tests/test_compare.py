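"""Cross-run comparison: match-between-runs gating, replicate aggregation,
charge merging, normalization, roll-up and volcano statistics."""

import numpy as np
import pandas as pd
import pytest

from nglyq.chem import GlycanComposition, Glycopeptide, PeptideBackbone
from nglyq.compare import (
    MasterRow,
    aggregate_replicates,
    build_master_table,
    compare_groups,
    match_between_runs,
    merge_charges,
    normalize_global,
    rollup_and_volcano,
)
from nglyq.config import RunConfig
from nglyq.db import GlycopeptideRecord
from nglyq.isotopes import IsotopePattern, predict_pattern
from nglyq.simulate import SimConfig, SimSpecies, pick_species, simulate_two_group
from nglyq.spectra import MsRun


def _record(code="5402", seq="ENGTISR", site=2):
    gp = Glycopeptide(PeptideBackbone(seq, site, "P1"),
                      GlycanComposition(*(int(c) for c in code)))
    return GlycopeptideRecord(gp, predict_pattern(gp.formula))


def _clean_run(record, charge=3, abundance=1e6, rt=5.0):
    sp = SimSpecies(record, charge, abundance, rt)
    from nglyq.simulate import simulate_run

    run, _ = simulate_run(SimConfig(
        species=[sp], run_length=10.0, ppm_jitter=0.0, ms1_noise_peaks=0,
        ms2_noise_peaks=0, poisson=False, seed=0))
    return run


class TestMatchBetweenRuns:
    def test_matching_envelope_within_rt_window_quantified(self):
        rec = _record()
        run = _clean_run(rec, rt=5.0)
        row = MasterRow(rec, 3, rt_ref=5.0 + 4.0)  # 4 min off, within 5
        cfg = RunConfig(mbr_rt_window_min=5.0)
        res = match_between_runs(run, row, cfg)
        assert res is not None
        assert res.method == "MBR-3TIQ"
        assert res.abundance > 0

    def test_rt_gap_beyond_window_absent(self):
        rec = _record()
        run = _clean_run(rec, rt=2.0)
        row = MasterRow(rec, 3, rt_ref=2.0 + 6.0)  # 6 min off, beyond 5
        assert match_between_runs(run, row, RunConfig()) is None

    def test_pattern_below_gate_absent(self):
        """A reference whose isotope pattern disagrees with the run's
        envelope scores below the S gate and is not transferred."""
        rec = _record()
        run = _clean_run(rec, rt=5.0)
        distorted = IsotopePattern(
            mz=rec.pattern.mz,
            rel_intensity=rec.pattern.rel_intensity[::-1].copy(),
            charge=1, monoisotopic_index=rec.pattern.monoisotopic_index)
        bad = GlycopeptideRecord(rec.glycopeptide, distorted)
        row = MasterRow(bad, 3, rt_ref=5.0)
        assert match_between_runs(run, row, RunConfig()) is None

    def test_direct_takes_precedence_over_mbr(self):
        rec = _record()
        key = (rec.glycopeptide.backbone.sequence,
               rec.glycopeptide.glycan.code,
               rec.glycopeptide.backbone.glycosite)
        run = _clean_run(rec, rt=5.0)

        class Psm:
            pass

        psm = Psm()
        psm.key, psm.charge, psm.rt = key, 3, 5.0
        master = build_master_table({"r1": run}, {"r1": [psm]}, {key: rec})
        assert master.loc[0, "r1__method"] == "direct-3TIQ"


class TestAggregateReplicates:
    @pytest.mark.parametrize("values,expected_mean,expected_cv", [
        ((100.0, 100.0, 100.0), 100.0, 0.0),
        ((100.0, 110.0, 160.0), 123.3333, 0.2606),
    ])
    def test_kept_with_mean_and_cv(self, values, expected_mean, expected_cv):
        mean, cv = aggregate_replicates(values)
        assert mean == pytest.approx(expected_mean, abs=1e-3)
        assert cv == pytest.approx(expected_cv, abs=1e-3)

    def test_high_cv_excluded(self):
        assert aggregate_replicates((50.0, 100.0, 150.0)) is None  # CV 50%

    def test_single_observation_excluded(self):
        assert aggregate_replicates((100.0, None, np.nan)) is None

    def test_two_observations_suffice(self):
        mean, _ = aggregate_replicates((100.0, 110.0, None))
        assert mean == pytest.approx(105.0)


class TestMergeCharges:
    def test_abundances_summed_across_charges(self):
        table = pd.DataFrame([
            {"peptide": "ENGTISR", "glycan": "5402", "glycosite": 2,
             "protein": "P1", "charge": 2, "r1": 100.0, "r2": 80.0},
            {"peptide": "ENGTISR", "glycan": "5402", "glycosite": 2,
             "protein": "P1", "charge": 3, "r1": 50.0, "r2": np.nan},
        ])
        merged = merge_charges(table, ["r1", "r2"])
        assert len(merged) == 1
        assert merged.loc[0, "r1"] == 150.0
        assert merged.loc[0, "r2"] == 80.0  # absent charge contributes zero
        assert merged.loc[0, "charges"] == "2,3"

    def test_single_charge_unchanged(self):
        table = pd.DataFrame([
            {"peptide": "ENGTISR", "glycan": "5402", "glycosite": 2,
             "protein": "P1", "charge": 2, "r1": 100.0},
        ])
        merged = merge_charges(table, ["r1"])
        assert merged.loc[0, "r1"] == 100.0


class TestNormalization:
    def test_identical_runs_unit_factors(self):
        t = pd.DataFrame({"r1": [10.0, 20.0], "r2": [10.0, 20.0]})
        _, factors = normalize_global(t, ["r1", "r2"])
        assert factors == {"r1": 1.0, "r2": 1.0}

    def test_doubled_run_rescaled_to_match(self):
        t = pd.DataFrame({"r1": [10.0, 20.0], "r2": [20.0, 40.0]})
        out, _ = normalize_global(t, ["r1", "r2"])
        np.testing.assert_allclose(out["r1"], out["r2"])

    def test_idempotent(self):
        t = pd.DataFrame({"r1": [10.0, 20.0], "r2": [14.0, 55.0],
                          "r3": [7.0, 90.0]})
        once, _ = normalize_global(t, ["r1", "r2", "r3"])
        twice, _ = normalize_global(once, ["r1", "r2", "r3"])
        pd.testing.assert_frame_equal(once, twice)

    def test_all_zero_run_excluded(self):
        t = pd.DataFrame({"r1": [10.0], "r2": [0.0]})
        _, factors = normalize_global(t, ["r1", "r2"])
        assert "r2" not in factors


class TestRollupVolcano:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_identical_groups_fold_change_one(self):
        t = self._table([
            {"peptide": "ENGTISR", "glycan": "5402", "glycosite": 2,
             "protein": "P1", "a1": 10.0, "a2": 10.0, "b1": 10.0,
             "b2": 10.0},
        ])
        pep, prot = rollup_and_volcano(t, ["a1", "a2"], ["b1", "b2"])
        assert pep.loc[0, "log2_fc"] == 0.0
        assert not pep.loc[0, "flagged"]
        assert prot.loc[0, "log2_fc"] == 0.0

    def test_protein_abundance_is_sum_of_glycopeptides(self):
        t = self._table([
            {"peptide": "A" * 3, "glycan": "5402", "glycosite": 1,
             "protein": "P1", "a1": 10.0, "a2": 10.0, "b1": 10.0, "b2": 10.0},
            {"peptide": "B", "glycan": "5401", "glycosite": 1,
             "protein": "P1", "a1": 20.0, "a2": 20.0, "b1": 20.0, "b2": 20.0},
            {"peptide": "C", "glycan": "5400", "glycosite": 1,
             "protein": "P1", "a1": 30.0, "a2": 30.0, "b1": 30.0, "b2": 30.0},
        ])
        _, prot = rollup_and_volcano(t, ["a1", "a2"], ["b1", "b2"])
        assert prot.loc[0, "mean_a"] == 60.0

    def test_zero_denominator_infinite_fold_change(self):
        t = self._table([
            {"peptide": "ENGTISR", "glycan": "5402", "glycosite": 2,
             "protein": "P1", "a1": 0.0, "a2": 0.0, "b1": 10.0, "b2": 10.0},
        ])
        pep, _ = rollup_and_volcano(t, ["a1", "a2"], ["b1", "b2"])
        assert pep.loc[0, "infinite_fc"]
        assert pep.loc[0, "log2_fc"] == np.inf

    def test_sitewise_change_masked_at_protein_level(self):
        """A 2-fold change on one glycoform vanishes in the protein roll-up
        when the protein's other glycoforms dominate and stay constant."""
        rows = [
            {"peptide": "ENGTISR", "glycan": "5402", "glycosite": 2,
             "protein": "P1", "a1": 10.0, "a2": 10.0, "b1": 20.0, "b2": 20.0},
        ]
        for i, code in enumerate(["5401", "6503", "5300", "9200"]):
            rows.append({"peptide": "ENGTISR", "glycan": code, "glycosite": 2,
                         "protein": "P1", "a1": 100.0, "a2": 100.0,
                         "b1": 100.0, "b2": 100.0})
        t = self._table(rows)
        pep, prot = rollup_and_volcano(t, ["a1", "a2"], ["b1", "b2"])
        assert pep.loc[0, "flagged"]  # glycopeptide level sees the change
        assert not prot.loc[0, "flagged"]  # protein level does not
        assert abs(prot.loc[0, "log2_fc"]) < 0.1

    def test_requires_two_replicates_per_group(self):
        t = self._table([
            {"peptide": "ENGTISR", "glycan": "5402", "glycosite": 2,
             "protein": "P1", "a1": 1.0, "b1": 2.0, "b2": 2.0},
        ])
        with pytest.raises(ValueError):
            rollup_and_volcano(t, ["a1"], ["b1", "b2"])


@pytest.fixture(scope="module")
def two_group(glyco_db):
    species = pick_species(glyco_db, 30, seed=11)
    keys = [(sp.record.glycopeptide.backbone.sequence,
             sp.record.glycopeptide.glycan.code,
             sp.record.glycopeptide.backbone.glycosite)
            for sp in species]
    fold_map = {k: 4.0 for k in keys[:3]}
    base = SimConfig(species=species, n_noise_ms2=30, seed=11)
    runs, truths, ga, gb = simulate_two_group(base, fold_map)
    records = {}
    for sp in species:
        gp = sp.record.glycopeptide
        records[(gp.backbone.sequence, gp.glycan.code,
                 gp.backbone.glycosite)] = sp.record
    return runs, ga, gb, records, fold_map, species


class TestTwoGroupPipeline:
    def test_planted_fold_changes_flagged(self, glyco_db, two_group):
        from nglyq.identify import identify

        runs, ga, gb, records, fold_map, _ = two_group
        idents = {name: identify(run, glyco_db)[0] for name, run in runs.items()}
        master = build_master_table(runs, idents, records)
        _, pep, _ = compare_groups(master, ga, gb)
        flagged = set(zip(pep[pep.flagged].peptide, pep[pep.flagged].glycan,
                          pep[pep.flagged].glycosite))
        all_keys = set(zip(pep.peptide, pep.glycan, pep.glycosite))
        planted = set(fold_map)
        assert len(flagged & planted) >= 0.9 * len(planted & all_keys)
        background = all_keys - planted
        assert len(flagged - planted) <= max(1, 0.05 * len(background))

    def test_exact_recovery_with_zero_replicate_noise(self, two_group):
        _, _, _, records, fold_map, species = two_group
        base = SimConfig(species=species, n_noise_ms2=0, ppm_jitter=0.0,
                         ms1_noise_peaks=0, ms2_noise_peaks=0, poisson=False,
                         seed=11)
        runs, truths, ga, gb = simulate_two_group(base, fold_map,
                                                  replicate_sigma=0.0)
        for name in gb:
            t = truths[name].set_index(["peptide", "glycan", "glycosite"])
            ref = truths[ga[0]].set_index(["peptide", "glycan", "glycosite"])
            for key, fold in fold_map.items():
                assert t.loc[key, "abundance"] == pytest.approx(
                    ref.loc[key, "abundance"] * fold, rel=1e-12)
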