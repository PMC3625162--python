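"""Quantification stack: cut-off, card-median correction, ΔΔCt, Ntarget, geNorm."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import zygoct as z
from zygoct.errors import DegenerateCardError, NormalizationError, ParameterError

from conftest import make_ct, random_ct


class TestCutoff:
    @pytest.mark.parametrize(
        "ct_value,cutoff,detected",
        [
            (36.2, 35.0, False),  # late Ct discarded at the cell-line cut-off
            (34.9, 35.0, True),
            (36.5, 37.0, True),  # retained under the tumor-series cut-off
            (35.0, 35.0, True),  # boundary: cut-off itself is kept
        ],
    )
    def test_cutoff_rule(self, ct_value, cutoff, detected):
        ct = make_ct({"s1": {"g1": ct_value}})
        out = z.apply_ct_cutoff(ct, cutoff)
        assert bool(out.detect_mask.at["g1", "s1"]) is detected
        if detected:
            assert out.values.at["g1", "s1"] == ct_value

    def test_input_not_mutated(self):
        ct = make_ct({"s1": {"g1": 36.0}})
        z.apply_ct_cutoff(ct, 35.0)
        assert ct.values.at["g1", "s1"] == 36.0

    def test_nonpositive_cutoff_rejected(self):
        ct = make_ct({"s1": {"g1": 20.0}})
        with pytest.raises(ParameterError):
            z.apply_ct_cutoff(ct, 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), lo=st.floats(20, 30), delta=st.floats(0.1, 10))
    def test_raising_cutoff_is_monotone(self, seed, lo, delta):
        ct = random_ct(np.random.default_rng(seed))
        n_low = z.apply_ct_cutoff(ct, lo).n_detected()
        n_high = z.apply_ct_cutoff(ct, min(lo + delta, 50.0)).n_detected()
        assert n_high >= n_low


class TestCardMedianCorrection:
    def test_worked_example_two_cards(self, two_card_ct):
        # card A median 22, card B median 23, target = median of medians = 22.5
        out, factors = z.card_median_correction(two_card_ct)
        assert factors.target == pytest.approx(22.5)
        assert factors.offsets["A"] == pytest.approx(0.5)
        assert factors.offsets["B"] == pytest.approx(-0.5)
        assert out.values["s1"].median() == pytest.approx(22.5, abs=1e-12)
        assert out.values["s2"].median() == pytest.approx(22.5, abs=1e-12)

    def test_identity_when_median_matches_target(self):
        ct = make_ct({"s1": {"g1": 20.0, "g2": 22.0, "g3": 24.0}})
        out, factors = z.card_median_correction(ct, target=22.0)
        assert factors.offsets["card1"] == 0.0
        pd.testing.assert_frame_equal(out.values, ct.values)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), n_cards=st.integers(1, 4))
    def test_all_card_medians_hit_target(self, seed, n_cards):
        ct = random_ct(np.random.default_rng(seed), n_cards=n_cards)
        out, factors = z.card_median_correction(ct)
        for card in out.cards:
            block = out.values[out.samples_of_card(card)].to_numpy()
            med = np.median(block[~np.isnan(block)])
            assert abs(med - factors.target) < 1e-9

    def test_nondetects_untouched(self):
        ct = make_ct({"s1": {"g1": 20.0, "g2": np.nan, "g3": 24.0}})
        out, _ = z.card_median_correction(ct, target=30.0)
        assert np.isnan(out.values.at["g2", "s1"])

    def test_degenerate_card_named(self):
        ct = make_ct(
            {"s1": {"g1": 20.0}, "s2": {"g1": np.nan}},
            cards={"s1": "A", "s2": "B"},
        )
        with pytest.raises(DegenerateCardError, match="B"):
            z.card_median_correction(ct)


class TestDeltaCt:
    def test_card_median_worked_example(self):
        # single card, median of {24, 22, 23, 22} = 22.5; gene at 24 -> ΔCt 1.5
        ct = make_ct({"s1": {"g1": 24.0, "g2": 22.0, "g3": 23.0, "g4": 22.0}})
        dct = z.delta_ct(ct)
        assert dct.dct.at["g1", "s1"] == pytest.approx(24.0 - 22.5)

    def test_gene_at_median_gives_zero(self):
        ct = make_ct({"s1": {"g1": 22.0, "g2": 20.0, "g3": 24.0}})
        dct = z.delta_ct(ct)
        assert dct.dct.at["g1", "s1"] == pytest.approx(0.0)

    def test_per_card_median_of_dct_is_zero(self, rng):
        ct = random_ct(rng, n_cards=3)
        dct = z.delta_ct(ct)
        for card in ct.cards:
            block = dct.dct[ct.samples_of_card(card)].to_numpy()
            assert abs(np.median(block[~np.isnan(block)])) < 1e-9

    def test_reference_gene_mode(self):
        ct = make_ct({"s1": {"g1": 25.0, "ref": 25.0}, "s2": {"g1": 27.0, "ref": 25.0}})
        dct = z.delta_ct(ct, centering="reference_gene", reference="ref")
        assert dct.dct.at["g1", "s1"] == 0.0
        assert dct.dct.at["g1", "s2"] == 2.0

    def test_reference_nondetect_masks_sample_with_warning(self):
        ct = make_ct({"s1": {"g1": 25.0, "ref": np.nan}, "s2": {"g1": 26.0, "ref": 25.0}})
        with pytest.warns(UserWarning, match="s1"):
            dct = z.delta_ct(ct, centering="reference_gene", reference="ref")
        assert np.isnan(dct.dct.at["g1", "s1"])
        assert dct.dct.at["g1", "s2"] == 1.0

    def test_correction_then_delta_commutes(self, rng):
        # correcting cards first, then centering on the shared target, equals
        # centering directly on each card's own median
        ct = random_ct(rng, n_cards=3)
        direct = z.delta_ct(ct).dct
        corrected, factors = z.card_median_correction(ct)
        via = corrected.values - factors.target
        both = ~np.isnan(direct.to_numpy())
        assert np.allclose(
            direct.to_numpy()[both], via.to_numpy()[both], atol=1e-9
        )


class TestDeltaDeltaCt:
    def test_worked_example_mean_reference(self):
        ct = make_ct(
            {"s1": {"g1": 23.5, "pad1": 20.0, "pad2": 25.0},
             "s2": {"g1": 24.5, "pad1": 20.0, "pad2": 25.0},
             "s3": {"g1": 25.5, "pad1": 20.0, "pad2": 25.0}}
        )
        dct = z.DeltaCtMatrix(
            pd.DataFrame({"s1": {"g1": 1.0}, "s2": {"g1": 2.0}, "s3": {"g1": 3.0}}),
            "card_median",
        )
        rq = z.delta_delta_ct(dct)
        assert rq.rq.loc["g1"].tolist() == pytest.approx([2.0, 1.0, 0.5])

    def test_constant_assay_gives_unit_rq(self):
        dct = z.DeltaCtMatrix(
            pd.DataFrame({"s1": {"g1": 1.7}, "s2": {"g1": 1.7}}), "card_median"
        )
        rq = z.delta_delta_ct(dct)
        assert rq.rq.loc["g1"].tolist() == pytest.approx([1.0, 1.0])

    def test_reference_sample_mode_unit_rq_in_reference(self, rng):
        ct = random_ct(rng, nondetect_rate=0.0)
        rq = z.delta_delta_ct(z.delta_ct(ct), reference="S0")
        assert np.allclose(rq.rq["S0"].to_numpy(), 1.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 100_000))
    def test_geometric_mean_one_law(self, seed):
        # the virtual-housekeeping invariant: per-assay geometric mean of
        # present RQ equals 1 under mean-of-all-samples centering
        ct = random_ct(np.random.default_rng(seed))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rq = z.delta_delta_ct(z.delta_ct(ct))
        assert rq.reference_mode == "virtual_housekeeping"
        for _, row in rq.rq.iterrows():
            present = row.dropna().to_numpy()
            gm = np.exp2(np.mean(np.log2(present)))
            assert abs(gm - 1.0) < 1e-9

    def test_all_masked_assay_dropped_with_warning(self):
        dct = z.DeltaCtMatrix(
            pd.DataFrame({"s1": {"g1": 1.0, "g2": np.nan}, "s2": {"g1": 2.0, "g2": np.nan}}),
            "card_median",
        )
        with pytest.warns(UserWarning, match="g2"):
            rq = z.delta_delta_ct(dct)
        assert list(rq.rq.index) == ["g1"]


class TestNtarget:
    @pytest.mark.parametrize(
        "ct_ref,ct_target,expected",
        [(20.0, 20.0, 1.0), (20.0, 18.0, 4.0), (20.0, 23.0, 0.125)],
    )
    def test_worked_values(self, ct_ref, ct_target, expected):
        ct = make_ct({"s1": {"tgt": ct_target, "ref": ct_ref}})
        rq = z.ntarget_reference_gene(ct, "tgt", "ref")
        assert rq.rq.at["tgt", "s1"] == pytest.approx(expected)

    def test_nondetect_masks_cell(self):
        ct = make_ct({"s1": {"tgt": np.nan, "ref": 20.0}, "s2": {"tgt": 18.0, "ref": 20.0}})
        rq = z.ntarget_reference_gene(ct, "tgt", "ref")
        assert np.isnan(rq.rq.at["tgt", "s1"])
        assert rq.rq.at["tgt", "s2"] == pytest.approx(4.0)


class TestTumorCorrectingFactors:
    def test_worked_example(self):
        ct = make_ct(
            {"t1": {"ETV6": 24.0, "g1": 30.0}, "t2": {"ETV6": 26.0, "g1": 30.0}},
            cards={"t1": "c1", "t2": "c2"},
        )
        out, factors = z.tumor_correcting_factors(ct, "ETV6")
        assert factors.grand_mean == pytest.approx(25.0)
        assert factors.offsets["t1"] == pytest.approx(1.0)
        assert factors.offsets["t2"] == pytest.approx(-1.0)
        assert out.values.loc["ETV6"].tolist() == pytest.approx([25.0, 25.0])
        assert out.values.loc["g1"].tolist() == pytest.approx([31.0, 29.0])

    def test_single_tumor_identity(self):
        ct = make_ct({"t1": {"ETV6": 24.0, "g1": 30.0}})
        out, factors = z.tumor_correcting_factors(ct, "ETV6")
        assert factors.offsets["t1"] == 0.0
        pd.testing.assert_frame_equal(out.values, ct.values)

    def test_reference_sd_zero_after_correction(self, rng):
        ct = random_ct(rng, nondetect_rate=0.0)
        out, _ = z.tumor_correcting_factors(ct, "A0")
        assert out.values.loc["A0"].std(ddof=0) < 1e-9

    def test_missing_reference_names_tumor(self):
        ct = make_ct({"t1": {"ETV6": np.nan, "g1": 30.0}, "t2": {"ETV6": 25.0, "g1": 30.0}})
        with pytest.raises(NormalizationError, match="t1"):
            z.tumor_correcting_factors(ct, "ETV6")


class TestFoldVsBaseline:
    def test_worked_example(self):
        rq = z.RQMatrix(pd.DataFrame({"b1": {"g1": 1.0}, "b2": {"g1": 4.0}, "t": {"g1": 4.0}}))
        groups = pd.Series({"b1": "WT", "b2": "WT", "t": "mut"})
        folds = z.fold_vs_baseline_group(rq, groups, "WT")
        assert folds.rq.at["g1", "t"] == pytest.approx(2.0)  # geo-mean baseline = 2

    def test_baseline_geometric_mean_fold_is_one(self, rng):
        vals = pd.DataFrame(
            rng.lognormal(0, 1, (4, 6)),
            index=list("abcd"),
            columns=[f"s{i}" for i in range(6)],
        )
        groups = pd.Series({f"s{i}": ("WT" if i < 3 else "mut") for i in range(6)})
        folds = z.fold_vs_baseline_group(z.RQMatrix(vals), groups, "WT")
        gm = np.exp2(np.log2(folds.rq[["s0", "s1", "s2"]]).mean(axis=1))
        assert np.allclose(gm, 1.0)

    def test_scale_invariance(self, simple_rq):
        groups = pd.Series({"s1": "WT", "s2": "mut"})
        f1 = z.fold_vs_baseline_group(simple_rq, groups, "WT")
        doubled = z.RQMatrix(simple_rq.rq * 2.0)
        f2 = z.fold_vs_baseline_group(doubled, groups, "WT")
        pd.testing.assert_frame_equal(f1.rq, f2.rq)

    def test_empty_baseline_assay_masked(self):
        rq = z.RQMatrix(pd.DataFrame({"b": {"g1": np.nan, "g2": 1.0}, "t": {"g1": 2.0, "g2": 2.0}}))
        groups = pd.Series({"b": "WT", "t": "mut"})
        folds = z.fold_vs_baseline_group(rq, groups, "WT")
        assert folds.rq.loc["g1"].isna().all()
        assert folds.rq.at["g2", "t"] == pytest.approx(2.0)


class TestGenormStability:
    def test_m_matches_direct_formula(self, rng):
        ct_vals = pd.DataFrame(
            rng.uniform(20, 30, (4, 8)),
            index=list("abcd"),
            columns=[f"s{i}" for i in range(8)],
        )
        rank = z.genorm_stability(ct_vals, scale="ct", iterate=False)
        # independent direct computation of M for gene 'a'
        x = -ct_vals.to_numpy()
        sds = [np.std(x[0] - x[k], ddof=1) for k in range(1, 4)]
        assert rank.m["a"] == pytest.approx(np.mean(sds))
        assert (rank.m.to_numpy() >= 0).all()
        assert list(rank.m.index) == rank.ranking
        assert sorted(rank.m.tolist()) == rank.m.tolist()

    def test_constant_ratio_pair_has_zero_pairwise_sd(self):
        # two genes at constant offset plus an unstable third: the stable
        # pair's M comes entirely from the third gene
        vals = pd.DataFrame(
            {
                "s1": {"a": 20.0, "b": 22.0, "c": 25.0},
                "s2": {"a": 21.0, "b": 23.0, "c": 29.0},
                "s3": {"a": 22.0, "b": 24.0, "c": 24.0},
            }
        )
        rank = z.genorm_stability(vals, scale="ct", iterate=False)
        sd_ac = np.std((-vals.loc["a"]) - (-vals.loc["c"]), ddof=1)
        assert rank.m["a"] == pytest.approx(sd_ac / 2)  # mean of {0, sd_ac}
        assert rank.ranking[-1] == "c"

    def test_sample_permutation_invariance(self, rng):
        vals = pd.DataFrame(
            rng.uniform(20, 30, (5, 7)),
            index=list("abcde"),
            columns=[f"s{i}" for i in range(7)],
        )
        r1 = z.genorm_stability(vals)
        perm = list(rng.permutation(vals.columns))
        r2 = z.genorm_stability(vals[perm])
        pd.testing.assert_series_equal(r1.m, r2.m)
        assert r1.exclusion_order == r2.exclusion_order

    def test_planted_stable_genes_rank_first(self, rng):
        n = 10
        rows = {}
        for g in ["st1", "st2", "st3", "st4"]:
            rows[g] = 25.0 + rng.normal(0, 0.05, n)
        for g in ["un1", "un2"]:
            rows[g] = 25.0 + rng.normal(0, 1.0, n)
        vals = pd.DataFrame(rows).T
        vals.columns = [f"s{i}" for i in range(n)]
        rank = z.genorm_stability(vals)
        assert set(rank.ranking[:4]) == {"st1", "st2", "st3", "st4"}
        assert set(rank.exclusion_order) >= {"un1", "un2"} or set(
            rank.exclusion_order[:2]
        ) == {"un1", "un2"}

    def test_masked_cells_rejected(self):
        vals = pd.DataFrame(np.ones((3, 3)) * 25.0, index=list("abc"))
        vals.iloc[0, 0] = np.nan
        with pytest.raises(ParameterError, match="masked"):
            z.genorm_stability(vals)
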