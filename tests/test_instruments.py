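"""Instrument selection: significance filter, clumping, F, Steiger, pooling."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrmediate.exceptions import ConfigurationError, DataError
from mrmediate.instruments import (clump, combine_instruments_mvmr,
                                   f_statistic, filter_genomewide,
                                   naive_variance_explained, steiger_filter,
                                   variance_explained)
from mrmediate.simulate import simulate_ld_block
from mrmediate.sumstats import HarmonizedPair, LDReference, VariantAssociation

from conftest import make_table


def row(snp, bp, p, chrom="1", beta=0.1, se=0.01, eaf=0.3):
    return (snp, chrom, bp, "A", "G", eaf, beta, se, p, 1000)


class TestFilter:
    def test_fixture_row_retained_at_default_threshold(self, ocn_eldjarn):
        kept = filter_genomewide(ocn_eldjarn)
        assert "rs1831272" in kept  # p = 6.71e-9 < 5e-8

    def test_boundary_exactly_at_threshold_excluded(self):
        t = make_table("x", "continuous", [row("rs1", 1, 5e-8), row("rs2", 2, 4.9e-8)])
        kept = filter_genomewide(t)
        assert kept.ids == ["rs2"]

    def test_empty_table_stays_empty(self):
        t = make_table("x", "continuous", [row("rs1", 1, 0.5)])
        assert len(filter_genomewide(t)) == 0


class TestClump:
    def test_strongest_variant_dominates_correlated_region(self):
        t = make_table("x", "continuous", [
            row("rs1", 100, 1e-20), row("rs2", 200, 1e-10), row("rs3", 300, 1e-9)])
        ld = LDReference(positions={"rs1": 100, "rs2": 200, "rs3": 300})
        for a, b in [("rs1", "rs2"), ("rs1", "rs3"), ("rs2", "rs3")]:
            ld.set_r2(a, b, 0.5)
        assert clump(t, ld).ids == ["rs1"]

    def test_pairs_outside_window_both_kept(self):
        t = make_table("x", "continuous", [
            row("rs1", 1_000_000, 1e-20), row("rs2", 13_000_000, 1e-10)])
        ld = LDReference(positions={"rs1": 1_000_000, "rs2": 13_000_000})
        ld.set_r2("rs1", "rs2", 0.9)
        assert set(clump(t, ld).ids) == {"rs1", "rs2"}

    def test_low_r2_neighbours_both_kept(self):
        t = make_table("x", "continuous", [
            row("rs1", 1_000_000, 1e-20), row("rs2", 2_000_000, 1e-10)])
        ld = LDReference(positions={"rs1": 1_000_000, "rs2": 2_000_000})
        ld.set_r2("rs1", "rs2", 0.005)
        assert set(clump(t, ld).ids) == {"rs1", "rs2"}

    def test_different_chromosomes_never_clumped(self):
        t = make_table("x", "continuous", [
            row("rs1", 100, 1e-20, chrom="1"), row("rs2", 150, 1e-10, chrom="2")])
        ld = LDReference(positions={"rs1": 100, "rs2": 150})
        ld.set_r2("rs1", "rs2", 1.0)
        assert set(clump(t, ld).ids) == {"rs1", "rs2"}

    def test_result_independent_of_row_order(self):
        rng = np.random.default_rng(7)
        rows = [row(f"rs{i}", 1_000_000 + i * 50_000, float(rng.uniform(1e-30, 1e-8)))
                for i in range(12)]
        ld = simulate_ld_block([(r[0], r[2]) for r in rows], decay=0.6)
        baseline = clump(make_table("x", "continuous", rows), ld).ids
        for _ in range(5):
            shuffled = [rows[i] for i in rng.permutation(len(rows))]
            assert clump(make_table("x", "continuous", shuffled), ld).ids == baseline

    def test_no_retained_pair_violates_thresholds(self):
        rng = np.random.default_rng(3)
        rows = [row(f"rs{i}", 1_000_000 + i * 500_000, float(rng.uniform(1e-30, 1e-8)))
                for i in range(15)]
        ld = simulate_ld_block([(r[0], r[2]) for r in rows], decay=0.8)
        kept = clump(make_table("x", "continuous", rows), ld)
        ids, pos = kept.ids, dict((r[0], r[2]) for r in rows)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                if abs(pos[a] - pos[b]) <= 10_000_000:
                    assert ld.r2(a, b) < 0.01

    def test_variant_missing_from_ld_treated_independent(self):
        t = make_table("x", "continuous", [row("rs1", 100, 1e-20), row("rs2", 200, 1e-10)])
        assert set(clump(t, LDReference()).ids) == {"rs1", "rs2"}


class TestFStatistic:
    def test_arithmetic(self):
        assert f_statistic(0.1, 0.05) == pytest.approx(4.0)
        assert f_statistic(0.2, 0.2) == pytest.approx(1.0)

    def test_printed_values_give_formula_not_published_f(self):
        # (0.168/0.031)^2 from rounded printed values
        assert f_statistic(0.168, 0.031) == pytest.approx(29.37, abs=0.005)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(DataError):
            f_statistic(0.1, 0.0)

    @given(beta=st.floats(-5, 5, allow_nan=False), se=st.floats(0.001, 2))
    def test_sign_invariance(self, beta, se):
        assert f_statistic(beta, se) == f_statistic(-beta, se)


class TestVarianceExplained:
    def _assoc(self, eaf, beta):
        return VariantAssociation(snp_id="rs1", chromosome="1", base_position=1,
                                  effect_allele="A", other_allele="G", eaf=eaf,
                                  beta=beta, se=0.01, p_value=1e-9, n=100)

    def test_continuous(self):
        assert variance_explained(self._assoc(0.5, 0.1), "continuous") == pytest.approx(0.005)

    def test_zero_effect(self):
        assert variance_explained(self._assoc(0.5, 0.0), "continuous") == 0.0
        assert variance_explained(self._assoc(0.5, 0.0), "binary") == 0.0

    def test_binary_latent_scale(self):
        # 0.005 / (0.005 + pi^2/3)
        expect = 0.005 / (0.005 + math.pi ** 2 / 3)
        assert variance_explained(self._assoc(0.5, 0.1), "binary") == pytest.approx(expect)
        assert expect == pytest.approx(0.001518, abs=2e-6)

    def test_naive_scale_option(self):
        assert naive_variance_explained(self._assoc(0.5, 0.1)) == pytest.approx(0.005)

    def test_missing_eaf_rejected(self):
        a = VariantAssociation(snp_id="rs1", chromosome="1", base_position=1,
                               effect_allele="A", other_allele="G", eaf=None,
                               beta=0.1, se=0.01, p_value=1e-9, n=100)
        with pytest.raises(DataError):
            variance_explained(a, "continuous")


def _pair(snp, bx, by, eaf_x=0.5, eaf_y=0.5):
    return HarmonizedPair(snp_id=snp, effect_allele="A", other_allele="G",
                          beta_exposure=bx, se_exposure=0.01, eaf_exposure=eaf_x,
                          beta_outcome=by, se_outcome=0.01, eaf_outcome=eaf_y,
                          action="kept")


class TestSteiger:
    def test_more_exposure_variance_retained(self):
        kept, recs = steiger_filter([_pair("rs1", 0.1, 0.001)], "continuous", "continuous")
        assert [p.snp_id for p in kept] == ["rs1"] and recs[0].retained

    def test_equal_variance_dropped_strict(self):
        kept, recs = steiger_filter([_pair("rs1", 0.1, 0.1)], "continuous", "continuous")
        assert kept == [] and not recs[0].retained

    def test_null_outcome_effect_always_retained(self):
        kept, _ = steiger_filter([_pair("rs1", 0.1, 0.0)], "continuous", "binary")
        assert len(kept) == 1

    def test_rerun_is_noop(self, small_study):
        from mrmediate.sumstats import harmonize
        pairs = harmonize(small_study.exposure, small_study.outcome).retained
        once, _ = steiger_filter(pairs, "continuous", "binary")
        twice, _ = steiger_filter(once, "continuous", "binary")
        assert [p.snp_id for p in twice] == [p.snp_id for p in once]

    def test_outcome_eaf_falls_back_to_exposure(self):
        p = HarmonizedPair(snp_id="rs1", effect_allele="A", other_allele="G",
                           beta_exposure=0.1, se_exposure=0.01, eaf_exposure=0.5,
                           beta_outcome=0.01, se_outcome=0.01, eaf_outcome=None,
                           action="kept")
        kept, recs = steiger_filter([p], "continuous", "continuous")
        assert len(kept) == 1 and recs[0].r2_outcome > 0


class TestCombineInstruments:
    def _tables(self):
        exp1 = make_table("x1", "continuous", [
            row("rs1", 1_000_000, 1e-20), row("rs2", 30_000_000, 1e-10),
            row("rs3", 60_000_000, 0.5)])
        exp2 = make_table("x2", "continuous", [
            row("rs1", 1_000_000, 1e-9), row("rs3", 60_000_000, 1e-12),
            row("rs2", 30_000_000, 0.5)])
        out = make_table("y", "binary", [
            row("rs1", 1_000_000, 0.5), row("rs2", 30_000_000, 0.5),
            row("rs3", 60_000_000, 0.5)])
        return exp1, exp2, out

    def test_disjoint_significant_sets_all_retained(self):
        exp1, exp2, out = self._tables()
        iset = combine_instruments_mvmr([exp1, exp2], out)
        assert set(iset.ids) == {"rs1", "rs2", "rs3"}
        assert iset.exposures == ["x1", "x2"]

    def test_shared_variant_scored_by_min_p_appears_once(self):
        exp1, exp2, out = self._tables()
        iset = combine_instruments_mvmr([exp1, exp2], out)
        assert iset.ids.count("rs1") == 1

    def test_variant_missing_everywhere_without_proxy_dropped(self):
        exp1, exp2, out = self._tables()
        exp2_missing = make_table("x2", "continuous", [
            row("rs3", 60_000_000, 1e-12)])  # rs1/rs2 absent entirely
        iset = combine_instruments_mvmr([exp1, exp2_missing], out)
        assert set(iset.ids) == {"rs3"}
        assert set(iset.dropped) == {"rs1", "rs2"}

    def test_proxy_substitution_with_complete_ld(self):
        exp1, exp2, out = self._tables()
        # rs2 missing from exp2; rs2b is in complete LD and present everywhere
        extra = row("rs2b", 30_000_500, 1e-4)
        exp1b = make_table("x1", "continuous", [
            row("rs1", 1_000_000, 1e-20), row("rs2", 30_000_000, 1e-10), extra])
        exp2b = make_table("x2", "continuous", [row("rs1", 1_000_000, 1e-9), extra])
        outb = make_table("y", "binary", [
            row("rs1", 1_000_000, 0.5), row("rs2b", 30_000_500, 0.5)])
        ld = LDReference(positions={"rs2": 30_000_000, "rs2b": 30_000_500})
        ld.set_r2("rs2", "rs2b", 1.0)
        iset = combine_instruments_mvmr([exp1b, exp2b], outb, ld)
        assert "rs2b" in iset.ids and "rs2" not in iset.ids

    def test_single_exposure_rejected(self):
        exp1, _, out = self._tables()
        with pytest.raises(ConfigurationError):
            combine_instruments_mvmr([exp1], out)

    def test_no_significant_variants_is_data_error(self):
        weak = make_table("x1", "continuous", [row("rs1", 1, 0.5)])
        weak2 = make_table("x2", "continuous", [row("rs1", 1, 0.5)])
        out = make_table("y", "binary", [row("rs1", 1, 0.5)])
        with pytest.raises(DataError):
            combine_instruments_mvmr([weak, weak2], out)
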