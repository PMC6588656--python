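"""Tests for resampling designs, accuracy metrics and significance tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from traingp import evalcv, simdata
from traingp.evalcv import (
    TrainingDesign,
    accuracy,
    classify_relatedness,
    crosses_by_lines_grid,
    increment_ttest,
    leave_one_cross_out,
    mask_training_fraction,
    relatedness_designs,
    tenfold_by_cross,
    tenfold_random,
    top_fraction_accuracy,
    wald_significance,
)


@pytest.fixture(scope="module")
def reference_design():
    return simdata.design_crosses(27, seed=0)


class TestAccuracy:
    def test_perfect_and_inverted(self):
        b = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert accuracy(b, b, grouping="across-all") == pytest.approx(1.0)
        assert accuracy(b, -b, grouping="across-all") == pytest.approx(-1.0)

    def test_hand_pearson(self):
        b = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        p = pd.Series([1.0, 3.0, 2.0, 4.0], index=list("abcd"))
        assert accuracy(b, p, grouping="across-all") == pytest.approx(0.8)

    def test_zero_variance_missing(self):
        b = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        p = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        assert np.isnan(accuracy(b, p, grouping="across-all"))

    def test_by_cross_grouping(self):
        b = pd.Series([1.0, 2.0, 5.0, 4.0], index=list("abcd"))
        p = pd.Series([1.1, 2.2, 4.0, 5.0], index=list("abcd"))
        cross_of = {"a": "X1", "b": "X1", "c": "X2", "d": "X2"}
        r = accuracy(b, p, cross_of)
        assert r["X1"] == pytest.approx(1.0)
        assert r["X2"] == pytest.approx(-1.0)


class TestWald:
    def test_null_center(self):
        assert wald_significance(0.0, 30) == pytest.approx(0.5)

    def test_large_family_significant(self):
        # independent computation of the one-sided t tail
        r, n = 0.45, 68
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert wald_significance(r, n) == pytest.approx(float(stats.t.sf(t, n - 2)))
        assert wald_significance(r, n) < 0.05

    def test_wrong_direction(self):
        assert wald_significance(-0.20, 68) > 0.5

    def test_perfect_correlation(self):
        assert wald_significance(1.0, 10) == 0.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            wald_significance(0.5, 3)


class TestIncrementTtest:
    def test_identical_pairs_p_one(self):
        assert increment_ttest([0.1, 0.2, 0.3], [0.1, 0.2, 0.3]) == 1.0

    def test_formula_oracle(self):
        d = np.array([0.01, 0.02, 0.015, 0.012])
        base = np.zeros(4)
        t = d.mean() / (d.std(ddof=1) / 2.0)
        expected = 2 * stats.t.sf(abs(t), 3)
        assert increment_ttest(base, d) == pytest.approx(expected)

    def test_symmetry(self):
        a = [0.1, 0.15, 0.2, 0.12]
        b = [0.12, 0.18, 0.19, 0.16]
        assert increment_ttest(a, b) == pytest.approx(increment_ttest(b, a))

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            increment_ttest([0.1], [0.2])


class TestTopFraction:
    def test_no_truncation_equals_full(self):
        rng = np.random.default_rng(0)
        b = pd.Series(rng.normal(0, 1, 20), index=[f"l{i}" for i in range(20)])
        p = b + rng.normal(0, 1, 20)
        cross_of = {l: "X1" for l in b.index}
        full = accuracy(b, p, cross_of)["X1"]
        assert top_fraction_accuracy(b, p, cross_of, k=20)["X1"] == pytest.approx(full)

    def test_perfect_predictions_survive_truncation(self):
        b = pd.Series(np.arange(30.0), index=[f"l{i}" for i in range(30)])
        cross_of = {l: "X1" for l in b.index}
        assert top_fraction_accuracy(b, b, cross_of, k=15)["X1"] == pytest.approx(1.0)

    def test_k_too_large(self):
        b = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="fewer than k"):
            top_fraction_accuracy(b, b, {"a": "X", "b": "X"}, k=15)


class TestTenfoldByCross(object):
    def test_fold_sizes_44_crosses(self, reference_design):
        designs = list(tenfold_by_cross(reference_design, k=10, reps=1, seed=0))
        assert len(designs) == 10
        folds = [set(d.descriptors["validation_crosses"]) for d in designs]
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {4, 5} and sum(sizes) == 44
        assert set().union(*folds) == set(reference_design.cross_ids)
        for a, b in itertools.combinations(folds, 2):
            assert not a & b

    def test_whole_cross_confinement(self, reference_design):
        cross_of = reference_design.cross_of()
        for d in itertools.islice(tenfold_by_cross(reference_design, reps=1, seed=1), 3):
            val_crosses = {cross_of[l] for l in d.validation}
            train_crosses = {cross_of[l] for l in d.training}
            assert not val_crosses & train_crosses

    def test_k_equals_crosses_is_loco(self, reference_design):
        designs = list(tenfold_by_cross(reference_design, k=44, reps=1, seed=0))
        loco = list(leave_one_cross_out(reference_design))
        assert {frozenset(d.validation) for d in designs} == {
            frozenset(d.validation) for d in loco
        }

    def test_deterministic(self, reference_design):
        a = [d.validation for d in tenfold_by_cross(reference_design, reps=2, seed=5)]
        b = [d.validation for d in tenfold_by_cross(reference_design, reps=2, seed=5)]
        assert a == b

    def test_k_too_large(self, reference_design):
        with pytest.raises(ValueError, match="exceeds"):
            list(tenfold_by_cross(reference_design, k=45))


class TestLeaveOneCrossOut:
    def test_44_designs_with_2924_training(self, reference_design):
        designs = list(leave_one_cross_out(reference_design))
        assert len(designs) == 44
        assert all(len(d.training) == 2992 - 68 == 2924 for d in designs)
        assert all(len(d.validation) == 68 for d in designs)

    def test_two_crosses_complementary(self):
        d2 = simdata.design_crosses(
            2, (simdata.UsageBucket(2, 1, 1),), n_bi=1, n_tri=0, lines_per_cross=3, seed=0
        )
        with pytest.raises(ValueError):
            list(leave_one_cross_out(d2))
        d3 = simdata.design_crosses(
            3,
            (simdata.UsageBucket(1, 2, 2), simdata.UsageBucket(2, 1, 1)),
            n_bi=2, n_tri=0, lines_per_cross=3, seed=0,
        )
        designs = list(leave_one_cross_out(d3))
        assert len(designs) == 2
        assert set(designs[0].training) == set(designs[1].validation)


class TestMasking:
    def _base(self, reference_design):
        return next(leave_one_cross_out(reference_design))

    def test_half_leaves_1462(self, reference_design):
        base = self._base(reference_design)
        designs = list(mask_training_fraction(base, fractions=(0.5,), reps=2, seed=0))
        assert all(len(d.training) == 1462 for d in designs)

    def test_ninety_percent_removed_still_disjoint(self, reference_design):
        base = self._base(reference_design)
        for d in mask_training_fraction(base, fractions=(0.9,), reps=3, seed=0):
            assert len(d.training) == 2924 - round(0.9 * 2924)
            assert not set(d.training) & set(d.validation)

    def test_repetitions_differ_but_reproduce(self, reference_design):
        base = self._base(reference_design)
        a = [d.training for d in mask_training_fraction(base, (0.5,), reps=3, seed=1)]
        b = [d.training for d in mask_training_fraction(base, (0.5,), reps=3, seed=1)]
        assert a == b
        assert len({frozenset(t) for t in a}) == 3

    def test_bad_fraction(self, reference_design):
        base = self._base(reference_design)
        with pytest.raises(ValueError, match="outside"):
            list(mask_training_fraction(base, fractions=(1.5,), reps=1, seed=0))


class TestGrid:
    def test_cell_products(self, reference_design):
        designs = list(
            crosses_by_lines_grid(
                reference_design, n_crosses_list=(10, 40), n_lines_list=(10, 40),
                reps=1, seed=0, validation_crosses=[reference_design.cross_ids[0]],
            )
        )
        sizes = {
            (d.descriptors["n_training_crosses"], d.descriptors["lines_per_cross"]): len(d.training)
            for d in designs
        }
        assert sizes[(10, 40)] == 400
        assert sizes[(40, 10)] == 400

    def test_validation_lines_never_sampled(self, reference_design):
        vcid = reference_design.cross_ids[3]
        val_lines = set(reference_design.lines_of(vcid))
        for d in crosses_by_lines_grid(
            reference_design, n_crosses_list=(5,), n_lines_list=(20,), reps=2, seed=1,
            validation_crosses=[vcid],
        ):
            assert not val_lines & set(d.training)

    def test_infeasible_cells_skipped(self, reference_design):
        designs = list(
            crosses_by_lines_grid(
                reference_design, n_crosses_list=(100,), n_lines_list=(10,), reps=1, seed=0
            )
        )
        assert designs == []


class TestRelatedness:
    def test_shared_parent_classification(self):
        d = simdata.CrossDesign(
            ("A", "B", "C", "D"),
            (
                simdata.Cross("X1", ("A", "B"), 4),
                simdata.Cross("X2", ("A", "C"), 4),
                simdata.Cross("X3", ("C", "D"), 4),
            ),
        )
        rel = classify_relatedness(d, "X1")
        assert rel == {"X2": "related", "X3": "unrelated"}

    def test_triparental_shared_third_parent(self):
        d = simdata.CrossDesign(
            ("A", "B", "C", "D"),
            (
                simdata.Cross("X1", ("A", "B", "C"), 4),
                simdata.Cross("X2", ("C", "D"), 4),
            ),
        )
        assert classify_relatedness(d, "X1")["X2"] == "related"

    def test_unknown_cross(self, reference_design):
        with pytest.raises(KeyError):
            classify_relatedness(reference_design, "nope")

    def test_quarter_arithmetic_68_lines(self, trend_bundle, reference_design):
        vcid = reference_design.cross_ids[0]
        designs = [
            d
            for d in relatedness_designs(
                reference_design, vcid, "one-parent", n_combinations=1,
                quarters_in_training=(3,), n_crosses_list=(1,), reps=1, seed=0,
            )
        ]
        assert designs
        for d in designs:
            in_train_val_lines = set(d.training) & set(reference_design.lines_of(vcid))
            assert len(in_train_val_lines) == 51
            assert len(d.validation) == 17

    def test_mixed_composition(self, trend_bundle):
        design = trend_bundle["design"]
        vcid = trend_bundle["design"].cross_ids[0]
        rel = classify_relatedness(design, vcid)
        designs = list(
            relatedness_designs(
                design, vcid, "mixed", n_combinations=2, quarters_in_training=(0,),
                n_crosses_list=(6,), reps=1, seed=0,
            )
        )
        assert designs
        for d in designs:
            kinds = [rel[c] for c in d.descriptors["crosses"]]
            assert kinds.count("related") == 3 and kinds.count("unrelated") == 3

    def test_zero_quarters_keeps_validation_clean(self, reference_design):
        vcid = reference_design.cross_ids[1]
        val_lines = set(reference_design.lines_of(vcid))
        for d in relatedness_designs(
            reference_design, vcid, "one-parent", n_combinations=2, quarters_in_training=(0,),
            n_crosses_list=(2,), reps=1, seed=3,
        ):
            assert not val_lines & set(d.training)

    def test_unknown_set_type(self, reference_design):
        with pytest.raises(ValueError, match="set_type"):
            list(relatedness_designs(reference_design, reference_design.cross_ids[0], "cousins"))


class TestTopFractionAttenuation:
    def test_low_accuracy_regime_top15_near_zero(self):
        # at reference-scale by-cross accuracy (~0.13) the top-15-of-68 subset is
        # range-restricted enough that its accuracy collapses toward zero
        from conftest import _build_population
        from traingp.gblup import fit_aireml, predict_lines

        bundle = _build_population(
            seed=23, n_parents=10,
            buckets=[[2, 3, None], [2, 2, 2], [6, 1, 1]],
            n_bi=9, n_tri=1, lines_per_cross=68,
            n_chrom=6, markers_per_chrom=80, n_qtl=300, line_h2=0.25,
        )
        design = bundle["design"]
        designs = list(
            crosses_by_lines_grid(
                design, n_crosses_list=(2,), n_lines_list=(30,), reps=20, seed=23,
                validation_crosses=[design.cross_ids[0]],
            )
        )
        full_acc, top_acc = [], []
        for d in designs:
            y = bundle["blues"].loc[list(d.training)]
            vc = fit_aireml(y, bundle["grm"])
            preds = predict_lines(vc, y, bundle["grm"]).set_index("line")["ghat"]
            val = pd.Index(d.validation)
            full_acc.append(
                accuracy(bundle["blues"].loc[val], preds.loc[val], bundle["cross_of"]).iloc[0]
            )
            top_acc.append(
                top_fraction_accuracy(
                    bundle["blues"].loc[val], preds.loc[val], bundle["cross_of"], k=15
                ).iloc[0]
            )
        assert 0.05 < np.mean(full_acc) < 0.30  # the intended low-accuracy regime
        assert abs(np.mean(top_acc)) < 0.1


class TestEvaluateDesigns:
    def test_tidy_output_and_refit_per_design(self, small_bundle):
        designs = list(leave_one_cross_out(small_bundle["design"]))[:3]
        res = evalcv.evaluate_designs(
            designs, small_bundle["blues"], small_bundle["grm"], small_bundle["cross_of"]
        )
        per_cross = res.loc[res["validation_cross"] != "__all__"]
        assert len(per_cross) == 3
        assert per_cross["accuracy"].between(-1, 1).all()
        assert (per_cross["n_validation_lines"] == 12).all()
        # pooled rows exist and variance components vary across designs
        assert (res["validation_cross"] == "__all__").sum() == 3
        assert res["sigma_g2"].nunique() > 1


class TestDesignInvariants:
    def test_all_generators_emit_disjoint_sets(self, reference_design):
        streams = [
            itertools.islice(tenfold_by_cross(reference_design, reps=1, seed=0), 10),
            itertools.islice(tenfold_random(reference_design, reps=1, seed=0), 10),
            itertools.islice(leave_one_cross_out(reference_design), 5),
            itertools.islice(
                crosses_by_lines_grid(
                    reference_design, (5,), (20,), reps=2, seed=0,
                    validation_crosses=reference_design.cross_ids[:2],
                ),
                8,
            ),
            itertools.islice(
                relatedness_designs(
                    reference_design, reference_design.cross_ids[0], "one-parent",
                    quarters_in_training=(0, 2), n_crosses_list=(2,), reps=1, seed=0,
                ),
                16,
            ),
        ]
        for stream in streams:
            for d in stream:
                assert not set(d.training) & set(d.validation)
                assert d.validation

    def test_training_design_rejects_overlap(self):
        with pytest.raises(ValueError, match="overlap"):
            TrainingDesign("bad", 0, ("a", "b"), ("b", "c"))
        with pytest.raises(ValueError, match="non-empty"):
            TrainingDesign("bad", 0, ("a",), ())
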