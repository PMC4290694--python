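import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from progsig.classifiers import make_trainer
from progsig.evaluation import (
    CVResult,
    FoldPlan,
    categorize_patients,
    class_specific_error,
    make_fold_plan,
    method_comparison_report,
    overall_error,
    patient_accuracy,
    run_cv,
    stability,
)
from progsig.io_data import AlignedDataset
from progsig.synthetic_data import SimulationConfig, simulate_dataset

from ._oracles import oracle_pairwise_overlap
from .conftest import make_expr, make_pheno


def labels_mixed(n_gp, n_pp):
    return np.array(["GP"] * n_gp + ["PP"] * n_pp, dtype=object)


class TestFoldPlan:
    def test_equal_folds(self):
        plan = make_fold_plan(labels_mixed(5, 5), K=5, R=3, seed=0)
        for folds in plan.assignment:
            assert sorted(len(f) for f in folds) == [2, 2, 2, 2, 2]

    def test_same_seed_identical(self):
        y = labels_mixed(12, 9)
        assert make_fold_plan(y, K=5, R=4, seed=3) == make_fold_plan(y, K=5, R=4, seed=3)
        assert make_fold_plan(y, K=5, R=4, seed=3) != make_fold_plan(y, K=5, R=4, seed=4)

    def test_melanoma_cohort_fold_sizes(self):
        plan = make_fold_plan(labels_mixed(25, 22), K=5, R=10, seed=1)
        for folds in plan.assignment:
            assert sorted(len(f) for f in folds) == [9, 9, 9, 10, 10]

    def test_stratification_balances_class_mix(self):
        y = labels_mixed(25, 22)
        plan = make_fold_plan(y, K=5, R=20, seed=2)
        for folds in plan.assignment:
            for f in folds:
                n_gp = int(np.sum(y[f] == "GP"))
                assert 4 <= n_gp <= 6  # 25/5 = 5 +- rounding

    def test_small_class_falls_back_unstratified(self):
        y = labels_mixed(8, 3)
        with pytest.warns(UserWarning, match="unstratified"):
            plan = make_fold_plan(y, K=5, R=2, seed=0)
        assert plan.R == 2

    def test_coverage_validated(self):
        with pytest.raises(ValueError, match="partition"):
            FoldPlan(K=2, R=1, seed=0, assignment=[[np.array([0]), np.array([0])]], n_samples=2)


def two_class_dataset(n_gp=10, n_pp=10, n_genes=30, sep=0.0, seed=0):
    rng = np.random.default_rng(seed)
    values = rng.normal(size=(n_genes, n_gp + n_pp))
    values[:5, n_gp:] += sep
    expr = make_expr(values, genes=[f"g{i:02d}" for i in range(n_genes)])
    pheno = make_pheno(["GP"] * n_gp + ["PP"] * n_pp, samples=list(expr.sample_ids))
    return AlignedDataset(expr, pheno)


class _ConstantTrainer:
    """Test stub: always predicts one class."""

    kind = "const"

    def __init__(self, label):
        self.label = label

    def train(self, X, y):
        from progsig.classifiers import TrainedClassifier

        return TrainedClassifier(
            "const", X.feature_ids, lambda Xt: [self.label] * len(Xt.sample_ids)
        )


class TestRunCV:
    def test_constant_classifier_errors(self):
        data = two_class_dataset(seed=1)
        plan = make_fold_plan(data.labels, K=5, R=2, seed=0)
        res = run_cv(data, "mod_t", _ConstantTrainer("PP"), plan, n_features=5)
        ce = class_specific_error(res)
        assert ce["PP"] == 0.0
        assert ce["GP"] == 1.0
        assert overall_error(res) == pytest.approx(0.5)

    def test_every_sample_tested_once_per_round(self):
        data = two_class_dataset(seed=2)
        plan = make_fold_plan(data.labels, K=5, R=3, seed=1)
        res = run_cv(data, "mod_t", make_trainer("dlda"), plan, n_features=5)
        assert not np.any(res.predictions == None)  # noqa: E711

    def test_deterministic(self):
        data = two_class_dataset(seed=3, sep=1.0)
        plan = make_fold_plan(data.labels, K=5, R=2, seed=2)
        a = run_cv(data, "mod_t", make_trainer("dlda"), plan, n_features=5)
        b = run_cv(data, "mod_t", make_trainer("dlda"), plan, n_features=5)
        assert np.array_equal(a.predictions, b.predictions)
        assert a.selections == b.selections

    def test_strong_signal_low_error(self):
        data = two_class_dataset(sep=3.0, seed=4)
        plan = make_fold_plan(data.labels, K=5, R=3, seed=3)
        res = run_cv(data, "mod_t", make_trainer("dlda"), plan, n_features=5)
        assert overall_error(res) <= 0.05

    def test_no_leakage_from_test_labels(self):
        """Corrupting the labels of one fold's test samples must not change
        that fold's selected features or predictions."""
        data = two_class_dataset(sep=1.0, seed=5)
        plan = make_fold_plan(data.labels, K=2, R=1, seed=4)
        test_idx = plan.assignment[0][0]
        flipped = data.phenotype.classes.copy()
        for i in test_idx:
            flipped[i] = "GP" if flipped[i] == "PP" else "PP"
        corrupted = AlignedDataset(
            data.expression,
            make_pheno(list(flipped), samples=list(data.expression.sample_ids)),
            data.network,
        )
        res_a = run_cv(data, "mod_t", make_trainer("dlda"), plan, n_features=5)
        res_b = run_cv(corrupted, "mod_t", make_trainer("dlda"), plan, n_features=5)
        assert res_a.selections[0][0] == res_b.selections[0][0]
        assert np.array_equal(
            res_a.predictions[0, test_idx], res_b.predictions[0, test_idx]
        )

    def test_wrong_plan_size_rejected(self):
        data = two_class_dataset(seed=6)
        plan = make_fold_plan(labels_mixed(6, 6), K=3, R=1, seed=0)
        with pytest.raises(ValueError, match="different number of samples"):
            run_cv(data, "mod_t", make_trainer("dlda"), plan)

    def test_unknown_method_rejected(self):
        data = two_class_dataset(seed=7)
        plan = make_fold_plan(data.labels, K=5, R=1, seed=0)
        with pytest.raises(ValueError, match="unknown method"):
            run_cv(data, "gsea", make_trainer("dlda"), plan)


def toy_result(preds_by_round, labels, method="m", clf="dlda", plan=None, lists=None):
    labels = np.asarray(labels, dtype=object)
    preds = np.asarray(preds_by_round, dtype=object)
    R, n = preds.shape
    if plan is None:
        plan = make_fold_plan(labels, K=min(5, n), R=R, seed=0)
    sel = lists or [[tuple("abc")] * plan.K for _ in range(R)]
    return CVResult(
        method=method,
        classifier_kind=clf,
        sample_ids=tuple(f"s{i}" for i in range(n)),
        labels=labels,
        predictions=preds,
        selections=sel,
        plan=plan,
    )


class TestErrorIdentities:
    def test_all_correct_and_all_wrong(self):
        y = labels_mixed(2, 2)
        res = toy_result([list(y)] * 3, y)
        assert overall_error(res) == 0.0
        flipped = ["PP" if l == "GP" else "GP" for l in y]
        res2 = toy_result([flipped] * 3, y)
        assert overall_error(res2) == 1.0

    def test_conservation_identities_on_seeded_run(self):
        data = two_class_dataset(n_gp=12, n_pp=9, sep=0.8, seed=8)
        plan = make_fold_plan(data.labels, K=5, R=4, seed=5)
        res = run_cv(data, "mod_t", make_trainer("dlda"), plan, n_features=5)
        err = overall_error(res)
        ce = class_specific_error(res)
        n_gp, n_pp = 12, 9
        assert n_gp * ce["GP"] + n_pp * ce["PP"] == pytest.approx(21 * err, abs=1e-12)
        acc = patient_accuracy(res)
        assert 1 - acc.counts.mean() / res.R == pytest.approx(err, abs=1e-12)

    def test_patient_counts_extremes(self):
        y = labels_mixed(1, 1)
        preds = [["GP", "GP"], ["GP", "GP"], ["GP", "GP"]]  # s1 (PP) never correct
        plan = make_fold_plan(y, K=2, R=3, seed=0)
        res = toy_result(preds, y, plan=plan)
        acc = patient_accuracy(res)
        assert acc.counts.tolist() == [3, 0]
        cats = categorize_patients(acc)
        assert cats["s0"] == "easy" and cats["s1"] == "hard"


class TestStability:
    def test_identical_lists(self):
        lists = [tuple(f"f{i}" for i in range(50))] * 10
        prof = stability(lists)
        for n in (20, 30, 40, 50):
            assert prof.overlap[n] == n
            assert prof.fraction[n] == 1.0

    def test_disjoint_lists(self):
        lists = [tuple(f"a{i}" for i in range(50)), tuple(f"b{i}" for i in range(50))]
        prof = stability(lists)
        assert all(v == 0.0 for v in prof.overlap.values())

    def test_three_list_enumeration(self):
        lists = [tuple("12345"), tuple("12345"), tuple("45678")]
        prof = stability(lists, top_ns=(5,))
        assert prof.overlap[5] == pytest.approx(3.0)

    def test_short_lists_flagged(self):
        lists = [tuple("abc"), tuple("abd")]
        with pytest.warns(UserWarning, match="shorter"):
            prof = stability(lists, top_ns=(5,))
        assert prof.overlap[5] == pytest.approx(2.0)

    def test_fewer_than_two_lists_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            stability([tuple("abc")])

    @settings(max_examples=30, deadline=None)
    @given(
        st.lists(
            st.lists(st.integers(0, 20), min_size=1, max_size=10, unique=True),
            min_size=2,
            max_size=8,
        ),
        st.integers(1, 10),
    )
    def test_matches_pairwise_enumeration(self, lists, n):
        lists = [tuple(map(str, l)) for l in lists]
        prof = stability(lists, top_ns=(n,))
        assert prof.overlap[n] == pytest.approx(oracle_pairwise_overlap(lists, n))
        assert 0 <= prof.overlap[n] <= n


class TestComparisonReport:
    def test_identical_methods_identical_rows(self):
        y = labels_mixed(3, 3)
        plan = make_fold_plan(y, K=3, R=2, seed=0)
        preds = [list(y), ["GP"] * 6]
        res_a = toy_result(preds, y, method="A", plan=plan)
        res_b = toy_result(preds, y, method="B", plan=plan)
        tables = method_comparison_report([res_a, res_b])
        errs = tables["errors"]["error"].tolist()
        assert errs[0] == errs[1]
        # identical methods: every sample has identical per-method fractions
        pm = tables["patient_matrix"]
        assert pm.iloc[0, 2:].tolist() == pm.iloc[1, 2:].tolist()

    def test_complementary_methods_all_differential(self):
        y = labels_mixed(2, 2)
        plan = make_fold_plan(y, K=2, R=2, seed=0)
        right = [list(y)] * 2
        wrong = [["PP", "PP", "GP", "GP"]] * 2
        res_a = toy_result(right, y, method="A", plan=plan)
        res_b = toy_result(wrong, y, method="B", plan=plan)
        tables = method_comparison_report([res_a, res_b])
        assert (tables["patients_categorized"]["category"] == "differential").all()

    def test_differing_plans_rejected(self):
        y = labels_mixed(3, 3)
        res_a = toy_result([list(y)], y, plan=make_fold_plan(y, K=3, R=1, seed=0))
        res_b = toy_result([list(y)], y, plan=make_fold_plan(y, K=3, R=1, seed=99))
        with pytest.raises(ValueError, match="share one fold plan"):
            method_comparison_report([res_a, res_b])

    def test_csv_outputs_written(self, tmp_path):
        y = labels_mixed(3, 3)
        plan = make_fold_plan(y, K=3, R=1, seed=0)
        res = toy_result([list(y)], y, plan=plan)
        method_comparison_report([res], out_dir=tmp_path)
        for name in (
            "errors",
            "class_errors",
            "stability",
            "patient_matrix",
            "patients_categorized",
        ):
            assert (tmp_path / f"{name}.csv").exists()


def test_null_data_error_near_half():
    """Label-permuted null data: error inside a wide chance band."""
    rng = np.random.default_rng(0)
    data = two_class_dataset(n_gp=12, n_pp=12, sep=0.0, seed=9)
    plan = make_fold_plan(data.labels, K=4, R=5, seed=6)
    res = run_cv(data, "mod_t", make_trainer("dlda"), plan, n_features=5)
    assert 0.35 <= overall_error(res) <= 0.65
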