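"""Instrument construction: QC, imputation, clumping, scores, LD."""

import numpy as np
import pandas as pd
import pytest

from vdrmr.giv import (AlleleMismatchError, ClumpParams, EmptyPanelError,
                       QcThresholds, VariantWeight, clump, compute_giv_25ohd,
                       compute_giv_vdr, ld_r2, mean_impute, qc_filter)

from conftest import make_cohort


class TestQcFilter:
    def test_low_info_dropped(self):
        cohort = make_cohort({"a": [0, 1, 2, 1], "b": [1, 1, 0, 2]},
                             info={"a": 0.79, "b": 0.95})
        out = qc_filter(cohort, QcThresholds())
        assert list(out.dosages.columns) == ["b"]

    def test_maf_exactly_at_threshold_dropped(self):
        # eaf 0.05 -> maf 0.05, strict '>' excludes it
        d = {"rare": [1.0] + [0.0] * 9, "common": [1, 0, 1, 2, 0, 1, 0, 1, 2, 0]}
        out = qc_filter(make_cohort(d), QcThresholds())
        assert list(out.dosages.columns) == ["common"]

    def test_vacuous_thresholds_identity(self):
        cohort = make_cohort({"a": [0, 1, 2, 1], "b": [1, 1, 0, 2]})
        out = qc_filter(cohort, QcThresholds(min_info=0.0,
                                             max_snp_missing=1.0,
                                             max_sample_missing=1.0,
                                             min_maf=0.0))
        pd.testing.assert_frame_equal(out.dosages, cohort.dosages)

    def test_snp_missingness(self):
        d = {"gappy": [np.nan, np.nan, 1, 1, 0, 1, 1, 0, 1, 1],
             "full": [1, 0, 1, 2, 0, 1, 0, 1, 2, 0]}
        out = qc_filter(make_cohort(d), QcThresholds())
        assert list(out.dosages.columns) == ["full"]

    def test_sample_missingness_drops_individuals(self):
        d = {"a": [np.nan, 1, 1, 0, 1, 1, 1, 0, 1, 1],
             "b": [np.nan, 0, 1, 2, 0, 1, 0, 1, 2, 0]}
        out = qc_filter(make_cohort(d, status=[1, 0] * 5),
                        QcThresholds(max_snp_missing=0.2))
        assert len(out.dosages) == 9  # the all-missing individual is gone

    def test_empty_panel_raises(self):
        cohort = make_cohort({"a": [0, 1, 2, 1]}, info=0.1)
        with pytest.raises(EmptyPanelError):
            qc_filter(cohort, QcThresholds())


class TestMeanImpute:
    def test_fills_with_twice_allele_frequency(self):
        cohort = make_cohort({"a": [0, 1, 1, 2, np.nan]})
        out = mean_impute(cohort)
        assert out.dosages["a"].iloc[4] == pytest.approx(1.0)  # 2 * 4/8

    def test_no_missing_is_identity(self):
        cohort = make_cohort({"a": [0, 1, 2, 1]})
        pd.testing.assert_frame_equal(mean_impute(cohort).dosages,
                                      cohort.dosages)

    def test_all_zero_variant(self):
        cohort = make_cohort({"a": [0, 0, 0, np.nan]})
        assert mean_impute(cohort).dosages["a"].iloc[3] == 0.0

    def test_unobserved_variant_raises(self):
        cohort = make_cohort({"a": [np.nan, np.nan, np.nan, np.nan]})
        with pytest.raises(ValueError):
            mean_impute(cohort)


def w(rsid, p, chrom="1", pos=0, beta=0.1):
    return VariantWeight(rsID=rsid, effect_allele="A", beta=beta, p_value=p,
                         chrom=chrom, pos=pos)


def greedy_oracle(weights, ld, params):
    """Independent restatement of the clumping rule, variant by variant."""
    accepted = []
    for cand in sorted(weights,
                       key=lambda x: (x.p_value, x.chrom, x.pos, x.rsID)):
        if cand.p_value >= params.p_threshold:
            continue
        if all(a.chrom != cand.chrom
               or abs(a.pos - cand.pos) > params.window_kb * 1000
               or ld[frozenset((a.rsID, cand.rsID))] < params.r2_threshold
               for a in accepted):
            accepted.append(cand)
    return [a.rsID for a in accepted]


class TestClump:
    def test_perfectly_linked_pair_keeps_smaller_p(self):
        a, b = w("a", 1e-10, pos=100), w("b", 1e-9, pos=200)
        out = clump([b, a], {("a", "b"): 1.0}, ClumpParams())
        assert [x.rsID for x in out] == ["a"]

    def test_different_chromosomes_never_exclude(self):
        a, b = w("a", 1e-10, chrom="1"), w("b", 1e-9, chrom="2")
        out = clump([a, b], lambda *_: 1.0, ClumpParams())
        assert {x.rsID for x in out} == {"a", "b"}

    def test_p_threshold_excludes(self):
        out = clump([w("a", 1e-7)], {}, ClumpParams(p_threshold=1e-8))
        assert out == []

    def test_five_variant_matrix_matches_oracle(self):
        variants = [w("v1", 1e-12, pos=1000), w("v2", 1e-11, pos=2000),
                    w("v3", 1e-10, pos=3000), w("v4", 1e-9, pos=4000),
                    w("v5", 5e-9, pos=5_500_000)]
        rng = np.random.default_rng(1)
        ld = {}
        names = [v.rsID for v in variants]
        for i in range(5):
            for j in range(i + 1, 5):
                ld[frozenset((names[i], names[j]))] = float(rng.random() * 0.01)
        ld[frozenset(("v1", "v2"))] = 0.9  # force one exclusion
        params = ClumpParams(window_kb=5000, r2_threshold=0.001)
        lookup = {tuple(sorted(k)): v for k, v in ld.items()}
        got = [x.rsID for x in clump(variants, lookup, params)]
        assert got == greedy_oracle(variants, ld, params)
        # window: v5 sits > 5000 kb from the rest, so LD cannot exclude it
        assert "v5" in got

    def test_output_subset_and_pairwise_compatible(self):
        rng = np.random.default_rng(3)
        variants = [w(f"x{i}", float(rng.uniform(1e-12, 1e-7)),
                      pos=int(rng.integers(1, 10**7))) for i in range(12)]
        ld = {}
        for i in range(12):
            for j in range(i + 1, 12):
                ld[(f"x{i}", f"x{j}")] = float(rng.random() * 0.02)
        params = ClumpParams(p_threshold=1e-8)
        out = clump(variants, ld, params)
        names = {v.rsID for v in out}
        assert all(v.p_value < params.p_threshold for v in out)
        lookup = {tuple(sorted(k)): v for k, v in ld.items()}
        for a in out:
            for b in out:
                if a.rsID < b.rsID and a.chrom == b.chrom \
                        and abs(a.pos - b.pos) <= params.window_kb * 1000:
                    assert lookup[(a.rsID, b.rsID)] < params.r2_threshold


class TestScores:
    def test_formula_and_zero_dosage(self):
        cohort = make_cohort({"a": [0, 2, 1]})
        s = compute_giv_vdr(cohort, VariantWeight("a", "A", beta=0.5))
        assert list(s) == [0.0, 1.0, 0.5]

    def test_allele_flip(self):
        # cohort stores A as effect allele; a weight on G flips dosage 2 -> 0
        cohort = make_cohort({"a": [2.0, 0.0, 1.0]})
        s = compute_giv_vdr(cohort, VariantWeight("a", "G", beta=0.5,
                                                  other_allele="A"))
        assert list(s) == [0.0, 1.0, 0.5]

    def test_flip_involution_preserves_association(self):
        cohort = make_cohort({"a": [0, 1, 2, 1, 0]})
        fwd = compute_giv_vdr(cohort, VariantWeight("a", "A", beta=0.5))
        # flipping both the counted allele and the sign of beta shifts the
        # score by a constant (2*beta) without changing its spread
        rev = compute_giv_vdr(cohort, VariantWeight("a", "G", beta=-0.5,
                                                    other_allele="A"))
        assert np.allclose(rev - fwd, rev.iloc[0] - fwd.iloc[0])

    def test_ambiguous_pair_refuses_flip(self):
        cohort = make_cohort({"a": [0, 1, 2]})
        cohort.variant_meta.loc["a", ["effect_allele", "other_allele"]] = \
            ["A", "T"]
        with pytest.raises(AlleleMismatchError, match="ambiguous"):
            compute_giv_vdr(cohort, VariantWeight("a", "T", other_allele="A",
                                                  beta=0.5))

    def test_no_matching_allele_raises(self):
        cohort = make_cohort({"a": [0, 1, 2]})
        with pytest.raises(AlleleMismatchError):
            compute_giv_vdr(cohort, VariantWeight("a", "C", beta=0.5))

    def test_absent_variant_raises(self):
        cohort = make_cohort({"a": [0, 1, 2]})
        with pytest.raises(KeyError):
            compute_giv_vdr(cohort, VariantWeight("zzz", "A", beta=0.5))
        with pytest.raises(KeyError):
            compute_giv_25ohd(cohort, [VariantWeight("zzz", "A", beta=0.5)])

    def test_multi_snp_hand_summation(self):
        rng = np.random.default_rng(0)
        dos = {f"g{k}": rng.integers(0, 3, 6).astype(float) for k in range(8)}
        cohort = make_cohort(dos)
        weights = [VariantWeight(f"g{k}", "A", beta=0.05 * (k + 1))
                   for k in range(8)]
        out = compute_giv_25ohd(cohort, weights)
        expected = sum(dos[f"g{k}"] * 0.05 * (k + 1) for k in range(8))
        assert np.allclose(out["score"].to_numpy(), expected)
        assert (out["n_variants_used"] == 8).all()

    def test_single_snp_reduces_to_vdr_score(self):
        cohort = make_cohort({"a": [0, 1, 2, 2]})
        weight = VariantWeight("a", "A", beta=0.3)
        multi = compute_giv_25ohd(cohort, [weight])["score"]
        single = compute_giv_vdr(cohort, weight)
        assert np.allclose(multi.to_numpy(), single.to_numpy())

    def test_linearity_over_disjoint_weight_sets(self):
        rng = np.random.default_rng(2)
        dos = {f"g{k}": rng.integers(0, 3, 10).astype(float)
               for k in range(6)}
        cohort = make_cohort(dos)
        ws = [VariantWeight(f"g{k}", "A", beta=float(rng.normal()))
              for k in range(6)]
        whole = compute_giv_25ohd(cohort, ws)["score"]
        parts = (compute_giv_25ohd(cohort, ws[:3])["score"]
                 + compute_giv_25ohd(cohort, ws[3:])["score"])
        assert np.allclose(whole.to_numpy(), parts.to_numpy())

    def test_zero_betas_zero_scores(self):
        cohort = make_cohort({"a": [0, 1, 2], "b": [2, 1, 0]})
        out = compute_giv_25ohd(cohort, [VariantWeight("a", "A", 0.0),
                                         VariantWeight("b", "A", 0.0)])
        assert (out["score"] == 0).all()


class TestLdR2:
    def test_identical_vectors(self):
        assert ld_r2([0, 1, 2, 0], [0, 1, 2, 0]) == pytest.approx(1.0)

    def test_perfect_negative_correlation(self):
        assert ld_r2([0, 1, 2, 0], [2, 1, 0, 2]) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # r = 1.8 / 2.8 -> r2 = 81/196
        assert ld_r2([0, 1, 2, 1, 0], [0, 0, 2, 1, 1]) == pytest.approx(
            81 / 196, abs=1e-12)

    def test_constant_vector_raises(self):
        with pytest.raises(ValueError):
            ld_r2([1, 1, 1, 1], [0, 1, 2, 0])

    def test_qc_then_impute_leaves_clean_panel(self):
        rng = np.random.default_rng(5)
        dos = {}
        for k in range(6):
            col = rng.integers(0, 3, 60).astype(float)
            col[rng.random(60) < 0.02] = np.nan
            dos[f"g{k}"] = col
        cohort = mean_impute(qc_filter(make_cohort(dos), QcThresholds()))
        d = cohort.dosages
        assert not d.isna().any().any()
        maf = np.minimum(d.mean() / 2, 1 - d.mean() / 2)
        assert (maf > 0.05).all()
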