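import itertools

import numpy as np
import pytest

from gutmr.harmonize import (
    build_instrument_set,
    complement_alleles,
    harmonize_pair,
    is_palindromic,
)
from gutmr.simulate import SimulationConfig, simulate_two_sample

from conftest import make_table


class TestAlleleAlgebra:
    @pytest.mark.parametrize("base,comp", [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")])
    def test_complement(self, base, comp):
        assert complement_alleles(base) == comp
        assert complement_alleles(complement_alleles(base)) == base

    def test_invalid_base_rejected(self):
        with pytest.raises(ValueError):
            complement_alleles("N")

    def test_palindromic_matches_set_definition(self):
        for ea, oa in itertools.permutations("ACGT", 2):
            expected = {ea, oa} in ({"A", "T"}, {"C", "G"})
            assert is_palindromic(ea, oa) is expected


class TestHarmonizePair:
    def test_swapped_alleles_negate_beta_and_mirror_eaf(self):
        exposure = make_table(nrows=1, effect_allele=["A"], other_allele=["G"], beta=[0.1])
        outcome = make_table(nrows=1, trait_type="outcome", effect_allele=["G"],
                             other_allele=["A"], beta=[-0.05], eaf=[0.7])
        hset = harmonize_pair(exposure, outcome)
        row = hset.df.iloc[0]
        assert row["action"] == "swapped"
        assert row["Gamma"] == pytest.approx(0.05)
        assert row["eaf_outcome"] == pytest.approx(0.3)

    def test_strand_flip_resolved(self):
        exposure = make_table(nrows=1, effect_allele=["A"], other_allele=["G"], beta=[0.1])
        outcome = make_table(nrows=1, trait_type="outcome", effect_allele=["T"],
                             other_allele=["C"], beta=[0.05], eaf=[0.3])
        hset = harmonize_pair(exposure, outcome)
        assert hset.df.iloc[0]["action"] == "strand_flipped"
        assert hset.df.iloc[0]["Gamma"] == pytest.approx(0.05)

    def test_palindromic_same_side_kept_as_is(self):
        exposure = make_table(nrows=1, effect_allele=["A"], other_allele=["T"], eaf=[0.20])
        outcome = make_table(nrows=1, trait_type="outcome", effect_allele=["A"],
                             other_allele=["T"], beta=[0.04], eaf=[0.21])
        hset = harmonize_pair(exposure, outcome)
        assert hset.df.iloc[0]["action"] == "as_is"
        assert hset.df.iloc[0]["Gamma"] == pytest.approx(0.04)

    def test_palindromic_opposite_sides_flipped(self):
        exposure = make_table(nrows=1, effect_allele=["C"], other_allele=["G"], eaf=[0.20])
        outcome = make_table(nrows=1, trait_type="outcome", effect_allele=["C"],
                             other_allele=["G"], beta=[0.04], eaf=[0.80])
        hset = harmonize_pair(exposure, outcome)
        assert hset.df.iloc[0]["action"] == "palindromic_inferred"
        assert hset.df.iloc[0]["Gamma"] == pytest.approx(-0.04)
        assert hset.df.iloc[0]["eaf_outcome"] == pytest.approx(0.20)

    def test_palindromic_near_half_dropped_ambiguous(self):
        exposure = make_table(nrows=1, effect_allele=["C"], other_allele=["G"], eaf=[0.30])
        outcome = make_table(nrows=1, trait_type="outcome", effect_allele=["C"],
                             other_allele=["G"], eaf=[0.50])
        hset = harmonize_pair(exposure, outcome)
        assert hset.nsnp == 0
        assert hset.dropped == [("rs0", "ambiguous")]

    def test_incompatible_allele_sets_dropped(self):
        exposure = make_table(nrows=1, effect_allele=["A"], other_allele=["G"])
        outcome = make_table(nrows=1, trait_type="outcome", effect_allele=["A"],
                             other_allele=["C"])
        hset = harmonize_pair(exposure, outcome)
        assert hset.dropped == [("rs0", "incompatible")]

    def test_conflicting_positions_dropped(self):
        exposure = make_table(nrows=1, pos=[1000])
        outcome = make_table(nrows=1, trait_type="outcome", pos=[9999])
        hset = harmonize_pair(exposure, outcome)
        assert hset.dropped == [("rs0", "incompatible")]

    def test_records_and_dropped_partition_matched_set(self):
        cfg = SimulationConfig(n_variants=300, n_instruments=0, seed=6,
                               palindromic_fraction=0.3, allele_swap_fraction=0.5,
                               strand_flip_fraction=0.2)
        data = simulate_two_sample(cfg)
        hset = harmonize_pair(data.exposure, data.outcome)
        kept = set(hset.df["variant_id"])
        dropped = {v for v, _ in hset.dropped}
        assert kept | dropped == set(data.exposure.df["variant_id"])
        assert not kept & dropped


class TestHarmonizationInvariants:
    def test_self_harmonization_identity(self):
        cfg = SimulationConfig(n_variants=200, n_instruments=10, seed=5,
                               palindromic_fraction=0.2)
        data = simulate_two_sample(cfg)
        table = data.exposure
        hset = harmonize_pair(table.subset(np.ones(len(table.df), bool)), table)
        np.testing.assert_allclose(hset.gamma, hset.Gamma)

    def test_idempotence_on_aligned_tables(self):
        cfg = SimulationConfig(n_variants=100, n_instruments=10, seed=12,
                               allele_swap_fraction=0.5)
        data = simulate_two_sample(cfg)
        first = harmonize_pair(data.exposure, data.outcome)
        # re-express the outcome in the exposure's allele frame
        aligned = data.exposure.df.set_index("variant_id").loc[first.df["variant_id"]]
        realigned = data.outcome.subset(
            data.outcome.df["variant_id"].isin(first.df["variant_id"]).to_numpy())
        order = {v: i for i, v in enumerate(first.df["variant_id"])}
        realigned.df = realigned.df.sort_values(
            "variant_id", key=lambda s: s.map(order)).reset_index(drop=True)
        realigned.df["effect_allele"] = aligned["effect_allele"].to_numpy()
        realigned.df["other_allele"] = aligned["other_allele"].to_numpy()
        realigned.df["beta"] = first.df["Gamma"].to_numpy()
        realigned.df["eaf"] = first.df["eaf_outcome"].to_numpy()
        second = harmonize_pair(data.exposure, realigned)
        m = second.df["variant_id"].isin(first.df["variant_id"])
        np.testing.assert_allclose(second.df.loc[m, "Gamma"], first.df["Gamma"])

    def test_outcome_encoding_invariance(self):
        # negating a record's alleles+beta+eaf leaves the harmonized Gamma unchanged
        exposure = make_table(nrows=1, effect_allele=["A"], other_allele=["G"], beta=[0.1])
        outcome1 = make_table(nrows=1, trait_type="outcome", effect_allele=["A"],
                              other_allele=["G"], beta=[0.05], eaf=[0.3])
        outcome2 = make_table(nrows=1, trait_type="outcome", effect_allele=["G"],
                              other_allele=["A"], beta=[-0.05], eaf=[0.7])
        g1 = harmonize_pair(exposure, outcome1).df.iloc[0]["Gamma"]
        g2 = harmonize_pair(exposure, outcome2).df.iloc[0]["Gamma"]
        assert g1 == pytest.approx(g2)

    def test_recovered_strand_flip_fraction(self):
        cfg = SimulationConfig(n_variants=1000, n_instruments=0, seed=30,
                               palindromic_fraction=0.0, allele_swap_fraction=0.0,
                               strand_flip_fraction=0.2)
        data = simulate_two_sample(cfg)
        hset = harmonize_pair(data.exposure, data.outcome)
        frac = (hset.df["action"] == "strand_flipped").mean()
        assert 0.15 < frac < 0.25  # binomial 99% bounds around 0.2 at n=1000


class TestBuildInstrumentSet:
    def test_all_present_aligned(self):
        exposure = make_table(nrows=5, variant_id=[f"rs{i}" for i in range(5)],
                              pos=list(range(1000, 6000, 1000)))
        outcome = make_table(nrows=5, trait_type="outcome",
                             variant_id=[f"rs{i}" for i in range(5)],
                             pos=list(range(1000, 6000, 1000)), beta=[0.05] * 5)
        hset = build_instrument_set(exposure, outcome)
        assert hset.nsnp == 5 and not hset.dropped
        assert "f_stat" in hset.df.columns

    def test_missing_variant_logged_and_dropped(self):
        exposure = make_table(nrows=5, variant_id=[f"rs{i}" for i in range(5)],
                              pos=list(range(1000, 6000, 1000)))
        outcome = make_table(nrows=4, trait_type="outcome",
                             variant_id=[f"rs{i}" for i in range(4)],
                             pos=list(range(1000, 5000, 1000)))
        hset = build_instrument_set(exposure, outcome)
        assert hset.nsnp == 4
        assert ("rs4", "missing_in_outcome") in hset.dropped
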