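"""Conditioning rules: mass closure, species screening, imputation, U matrix."""

import numpy as np
import pandas as pd
import pytest

from pmfsa.preprocessing import (
    BDL,
    MEASURED,
    MISSING,
    build_matrices,
    exclude_species,
    exclude_unclosed_samples,
    preprocess,
    signal_to_noise,
)
from pmfsa.synthetic import GroundTruth, generate

from conftest import make_dataset


class TestMassClosure:
    def test_exact_closure_kept_and_gross_violation_removed(self):
        ds = make_dataset([[10.0, 4.0, 6.0], [10.0, 2.0, 2.9]])
        out = exclude_unclosed_samples(ds)
        # |10 - 10|/10 = 0 kept; |10 - 4.9|/10 = 0.51 > 0.50 removed
        assert out.sample_ids == ["S001"]
        assert [(e[0], e[1]) for e in out.exclusion_log] == [("S002", "mass-closure")]

    def test_nonpositive_mass_gets_its_own_rule(self):
        ds = make_dataset([[0.0, 1.0, 1.0], [10.0, 5.0, 5.0]])
        out = exclude_unclosed_samples(ds)
        assert out.n_samples == 1
        assert out.exclusion_log[0][1] == "nonpositive-or-missing-mass"

    def test_bdl_counts_at_half_mdl_in_the_sum(self):
        flags = [[MEASURED, BDL, MEASURED]]
        # species sum = 0.05 + 9.0; mass 10 -> rel diff 0.095, kept
        ds = make_dataset([[10.0, np.nan, 9.0]], flags=flags,
                          mdl=[0.5, 0.1, 0.1])
        assert exclude_unclosed_samples(ds).n_samples == 1

    def test_idempotent(self):
        ds = make_dataset([[10.0, 4.0, 6.0], [10.0, 2.0, 2.9],
                           [5.0, 2.0, 2.5]])
        once = exclude_unclosed_samples(ds)
        twice = exclude_unclosed_samples(once)
        assert twice.sample_ids == once.sample_ids
        np.testing.assert_array_equal(twice.conc, once.conc)


class TestSpeciesExclusion:
    def test_ninety_percent_rule(self):
        n = 73
        conc = np.ones((n, 3))
        flags = np.full((n, 3), MEASURED, dtype=object)
        flags[:67, 1] = BDL  # 67/73 = 91.8% >= 90% -> dropped
        conc[:67, 1] = np.nan
        ds = make_dataset(conc, flags=flags)
        out = exclude_species(ds)
        assert out.species_names == ["PM2.5", "S2"]
        assert out.exclusion_log[0][:2] == ("S1", "bdl-missing-fraction")

    def test_clean_species_kept(self):
        ds = make_dataset(np.ones((10, 3)))
        assert exclude_species(ds).n_species == 3

    def test_drop_list_removes_exactly_the_listed_columns(self):
        ds = make_dataset(np.ones((5, 6)),
                          species=["PM2.5", "Sn", "Cu", "F-", "Zn", "Pb"])
        out = exclude_species(ds, drop_list={"Sn", "Cu", "F-"})
        assert out.species_names == ["PM2.5", "Zn", "Pb"]
        assert {e[0] for e in out.exclusion_log} == {"Sn", "Cu", "F-"}

    def test_dropping_mass_column_is_an_error(self):
        ds = make_dataset(np.ones((5, 3)))
        with pytest.raises(ValueError, match="mass"):
            exclude_species(ds, drop_list={"PM2.5"})


class TestSignalToNoise:
    def test_all_below_mdl_gives_zero(self):
        flags = np.full((4, 2), MEASURED, dtype=object)
        flags[:, 1] = BDL
        conc = np.column_stack([np.full(4, 10.0), np.full(4, np.nan)])
        ds = make_dataset(conc, flags=flags, mdl=[0.5, 0.1],
                          species=["PM2.5", "X"])
        assert signal_to_noise(ds)["X"] == 0.0

    def test_single_sample_three_times_mdl(self):
        ds = make_dataset([[10.0, 0.3]], mdl=[0.5, 0.1],
                          species=["PM2.5", "X"])
        assert signal_to_noise(ds)["X"] == pytest.approx(2.0)

    def test_all_missing_reported_as_nan(self):
        flags = np.asarray([[MEASURED, MISSING]] * 3, dtype=object)
        conc = np.column_stack([np.full(3, 10.0), np.full(3, np.nan)])
        ds = make_dataset(conc, flags=flags, species=["PM2.5", "X"])
        assert np.isnan(signal_to_noise(ds)["X"])

    def test_mostly_quantified_species_has_high_ratio(self):
        # mimics a crustal element quantified well above a 0.006 ug/m3 MDL
        rng = np.random.default_rng(42)
        vals = rng.lognormal(np.log(0.22), 0.8, size=73)
        conc = np.column_stack([np.full(73, 18.0), vals])
        ds = make_dataset(conc, mdl=[0.5, 0.006], species=["PM2.5", "Al"])
        ratio = signal_to_noise(ds)["Al"]
        assert 5.0 < ratio < 100.0  # order of magnitude of a strong signal


class TestBuildMatrices:
    def test_measured_cell_uncertainty_formula(self):
        ds = make_dataset([[10.0, 1.0]], mdl=[0.5, 0.1])
        cm = build_matrices(ds)
        assert cm.U[0, 1] == pytest.approx(np.sqrt(0.01 + 0.0025))
        assert cm.X[0, 1] == 1.0

    def test_bdl_cell_rules(self):
        flags = [[MEASURED, BDL]]
        ds = make_dataset([[10.0, np.nan]], flags=flags, mdl=[0.5, 0.12])
        cm = build_matrices(ds)
        assert cm.X[0, 1] == pytest.approx(0.06)
        assert cm.U[0, 1] == pytest.approx(0.10)

    def test_measured_zero_treated_as_bdl(self):
        ds = make_dataset([[10.0, 0.0]], mdl=[0.5, 0.12])
        cm = build_matrices(ds)
        assert cm.X[0, 1] == pytest.approx(0.06)
        assert cm.U[0, 1] == pytest.approx(0.10)

    def test_missing_cell_geometric_mean_imputation(self):
        flags = np.asarray([[MEASURED, MEASURED], [MEASURED, MEASURED],
                            [MEASURED, MISSING]], dtype=object)
        conc = [[10.0, 1.0], [10.0, 10.0], [10.0, np.nan]]
        ds = make_dataset(conc, flags=flags, mdl=[0.5, 0.1])
        cm = build_matrices(ds)
        assert cm.X[2, 1] == pytest.approx(np.sqrt(10.0))
        assert cm.U[2, 1] == pytest.approx(4.0 * np.sqrt(10.0))

    def test_mass_column_uncertainty_is_four_times_value(self):
        ds = make_dataset([[17.8298, 5.0]], mdl=[0.5, 0.1])
        cm = build_matrices(ds)
        assert cm.U[0, 0] == pytest.approx(71.3192)

    def test_species_with_no_measured_positive_values_errors(self):
        flags = np.asarray([[MEASURED, MISSING]] * 2, dtype=object)
        conc = np.column_stack([np.full(2, 10.0), np.full(2, np.nan)])
        ds = make_dataset(conc, flags=flags)
        with pytest.raises(ValueError, match="no measured positive"):
            build_matrices(ds)

    def test_fully_measured_table_left_identical(self):
        rng = np.random.default_rng(0)
        conc = rng.uniform(0.5, 5.0, size=(8, 5))
        conc[:, 0] = conc[:, 1:].sum(axis=1)  # perfect closure
        ds = make_dataset(conc)
        cm = build_matrices(ds)
        np.testing.assert_array_equal(cm.X, ds.conc)

    def test_monotone_censoring(self):
        """Raising an MDL never decreases the BDL-cell uncertainty."""
        flags = [[MEASURED, BDL]]
        for lo, hi in [(0.1, 0.2), (0.05, 0.5), (1.0, 1.5)]:
            lo_u = build_matrices(
                make_dataset([[10.0, np.nan]], flags=flags, mdl=[0.5, lo])
            ).U[0, 1]
            hi_u = build_matrices(
                make_dataset([[10.0, np.nan]], flags=flags, mdl=[0.5, hi])
            ).U[0, 1]
            assert hi_u >= lo_u


class TestFullChain:
    def test_randomized_tables_give_positive_u_and_consistent_shapes(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n, m = rng.integers(5, 15), rng.integers(3, 8)
            conc = rng.uniform(0.01, 3.0, size=(n, m))
            conc[:, 0] = conc[:, 1:].sum(axis=1) * rng.uniform(0.6, 1.4, n)
            flags = np.full((n, m), MEASURED, dtype=object)
            censor = rng.random((n, m)) < 0.1
            censor[:, 0] = False
            flags[censor] = rng.choice([BDL, MISSING], size=int(censor.sum()))
            conc[censor] = np.nan
            ds = make_dataset(conc, flags=flags,
                              mdl=rng.uniform(0.001, 0.1, m))
            cm = preprocess(ds)
            assert np.all(cm.U > 0)
            sample_rules = {"mass-closure", "nonpositive-or-missing-mass"}
            n_samp_excl = sum(1 for e in cm.exclusion_log
                              if e[1] in sample_rules)
            n_spec_excl = sum(1 for e in cm.exclusion_log
                              if e[1] not in sample_rules)
            assert cm.X.shape[0] + n_samp_excl == n
            assert cm.X.shape[1] + n_spec_excl == m

    def test_study_scale_preset_conditions_to_73_by_25(self):
        ds, _, _ = generate(GroundTruth.study_scale(seed=0))
        assert ds.conc.shape == (74, 30)
        cm = preprocess(ds, drop_list=("Sn", "Cu", "F-"))
        assert cm.X.shape == (73, 25)
        # every excluded entity appears exactly once in the log
        entities = [e[0] for e in cm.exclusion_log]
        assert len(entities) == len(set(entities))
        rules = {e[0]: e[1] for e in cm.exclusion_log}
        assert rules["Sn"] == rules["Cu"] == rules["F-"] == "drop-list"
        assert rules["Ba"] == rules["PO4_3-"] == "bdl-missing-fraction"
        assert sum(r == "mass-closure" for r in rules.values()) == 1
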