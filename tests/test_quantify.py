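"""Reporter ratios, replicate slopes, internal-error cutoff, t-test."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coldmem import quantify as qt
from coldmem.quantify import CutoffParams


class TestPeptideRatios:
    def test_direct_division(self):
        assert qt.peptide_ratios(100, 140, 70) == pytest.approx((1.4, 0.7))

    def test_identity(self):
        assert qt.peptide_ratios(50, 50, 50) == (1.0, 1.0)

    def test_zero_reference_unquantifiable(self):
        with pytest.raises(ValueError, match="unquantifiable"):
            qt.peptide_ratios(0, 10, 10)


class TestProteinRatio:
    def test_equal_weights_mean(self):
        assert qt.protein_ratio([1.0, 2.0], [1.0, 1.0]) == pytest.approx(1.5)

    def test_single_peptide_identity(self):
        assert qt.protein_ratio([0.7]) == pytest.approx(0.7)

    def test_weighted_mean(self):
        assert qt.protein_ratio([2.0, 1.0], [3.0, 1.0]) == pytest.approx(1.75)

    def test_bounded_by_inputs_and_invariances(self):
        rng = np.random.default_rng(11)
        r = rng.uniform(0.2, 5.0, 20)
        w = rng.uniform(0.1, 10.0, 20)
        v = qt.protein_ratio(r, w)
        assert r.min() <= v <= r.max()
        perm = rng.permutation(20)
        assert qt.protein_ratio(r[perm], w[perm]) == pytest.approx(v)
        assert qt.protein_ratio(r, 7.3 * w) == pytest.approx(v)

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            qt.protein_ratio([])


class TestReplicateSlope:
    def test_identity_line(self):
        x = np.array([-1.0, 0.0, 1.0, 2.0])
        assert qt.replicate_slope(x, x).slope == pytest.approx(1.0)

    def test_half_slope(self):
        x = np.array([-2.0, 0.0, 1.0, 3.0])
        assert qt.replicate_slope(x, 0.5 * x).slope == pytest.approx(0.5)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0, 1, 50)
        y = 0.9 * x + rng.normal(0, 0.2, 50)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert qt.replicate_slope(x, y).slope == pytest.approx(expected, abs=1e-12)

    def test_insufficient_data(self):
        assert qt.replicate_slope([0.0, 1.0], [0.0, 1.0]) is None


class TestInternalErrorCutoff:
    def test_published_conversion(self):
        # Two aligned sets differing by exactly 0.48 log2 units everywhere.
        sets = [np.zeros(10), np.full(10, 0.48)]
        cut = qt.internal_error_cutoff(sets)
        assert cut.d_log2 == pytest.approx(0.48)
        assert cut.fold_cutoff == pytest.approx(2.0 ** 0.48)
        assert math.log2(cut.fold_cutoff) == pytest.approx(cut.d_log2, abs=1e-12)

    def test_identical_replicates_zero(self):
        x = np.random.default_rng(1).normal(size=(3, 20))
        cut = qt.internal_error_cutoff([x[0], x[0], x[0]])
        assert cut.d_log2 == 0.0
        assert cut.fold_cutoff == 1.0

    def test_hand_computed_average(self):
        # Per-pair per-protein errors average 0.4 for every set pair.
        sets = [[0.0, 0.0], [0.2, 0.6], [0.6, 0.2]]
        cut = qt.internal_error_cutoff(sets)
        assert cut.d_log2 == pytest.approx(0.4)
        assert cut.fold_cutoff == pytest.approx(2.0 ** 0.4)

    def test_permutation_and_shift_invariance(self):
        rng = np.random.default_rng(3)
        sets = rng.normal(size=(3, 30))
        d = qt.internal_error_cutoff(sets).d_log2
        assert qt.internal_error_cutoff(sets[[2, 0, 1]]).d_log2 == pytest.approx(d)
        assert qt.internal_error_cutoff(sets + 1.7).d_log2 == pytest.approx(d)

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            qt.internal_error_cutoff([np.zeros(10)])


class TestDifferentialTest:
    def test_identical_groups(self):
        assert qt.differential_test([1.0, 1.1, 0.9], [1.0, 1.1, 0.9]) == pytest.approx(
            stats.ttest_ind([1.0, 1.1, 0.9], [1.0, 1.1, 0.9]).pvalue
        )
        assert qt.differential_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_textbook_closed_form(self):
        ctrl, trt = [0.0, 0.0, 0.0], [1.0, 1.1, 0.9]
        # Pooled-variance Student t with df = 4, computed independently.
        s2 = np.var(trt, ddof=1)
        sp2 = (0.0 + 2 * s2) / 4
        t = (np.mean(trt) - 0.0) / math.sqrt(sp2 * (2 / 3))
        expected = 2 * stats.t.sf(abs(t), df=4)
        assert qt.differential_test(ctrl, trt) == pytest.approx(expected, rel=1e-10)

    def test_degenerate_zero_variance_unequal_means(self):
        assert qt.differential_test([0.0, 0.0], [1.0, 1.0]) == 0.0

    def test_insufficient_group_size(self):
        with pytest.raises(ValueError):
            qt.differential_test([0.0], [1.0, 2.0, 3.0])


class TestCutoffParams:
    def test_default_is_published_fold_criterion(self):
        cut = CutoffParams()
        assert cut.fold_cutoff == pytest.approx(1.4, abs=1e-12)
        assert cut.down_cutoff == pytest.approx(1 / 1.4, abs=1e-12)
        assert cut.p_threshold == 0.05

    def test_fold_round_trips_through_log2(self):
        for d in (0.0, 0.3, 0.48, 1.0):
            cut = CutoffParams(d_log2=d)
            assert math.log2(cut.fold_cutoff) == pytest.approx(d, abs=1e-12)


class TestQuantTable:
    def test_rollup_and_pvalues(self, small_quant_a):
        q = small_quant_a
        assert (q["r115"] > 0).all() and (q["r116"] > 0).all()
        assert (q["n_peptides"] >= 2).all()
        complete = q.groupby("protein_id")["replicate_set"].nunique() == 3
        with_p = q.dropna(subset=["p_3h"])
        assert set(with_p["protein_id"]) == set(complete.index[complete])
        assert ((with_p["p_3h"] >= 0) & (with_p["p_3h"] <= 1)).all()

    def test_weighted_rollup_matches_manual(self):
        psms = pd.DataFrame(
            {
                "peptide": ["AK", "BK".replace("B", "G"), "AK"],
                "protein_id": "P1",
                "genotype": "A",
                "replicate_set": "set1",
                "i114": [100.0, 200.0, 50.0],
                "i115": [140.0, 240.0, 80.0],
                "i116": [70.0, 180.0, 40.0],
            }
        )
        out = qt.protein_quant_table(psms)
        w = psms[["i114", "i115", "i116"]].sum(axis=1)
        r115 = np.average(psms["i115"] / psms["i114"], weights=w)
        assert out["r115"].iloc[0] == pytest.approx(r115)
        assert out["n_peptides"].iloc[0] == 2

    def test_null_false_positive_control(self, small_study, small_quant_a):
        """On proteins with no planted effect, the joint DAMP criterion
        (p <= 0.05 and |log2 fold| >= log2 1.4) fires on <= 5%."""
        _, truths, _ = small_study
        null_ids = {t.protein_id for t in truths["A"] if t.log2_effect_3h == 0}
        q = small_quant_a.dropna(subset=["p_3h"])
        q = q[q["protein_id"].isin(null_ids)]
        per_protein = q.groupby("protein_id").agg(
            fold=("r115", "mean"), p=("p_3h", "first")
        )
        hits = (per_protein["p"] <= 0.05) & (
            np.abs(np.log2(per_protein["fold"])) >= math.log2(1.4)
        )
        assert hits.mean() <= 0.05
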