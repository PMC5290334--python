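"""CALF greedy selection, scoring, AUC and ROC contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirisk.calf import (
    ClassifierModel,
    apply_to_groups,
    auc,
    greedy_calf,
    roc_curve,
    score_samples,
    two_sample_t_pvalue,
)


def pooled_t_pvalue_oracle(x, y):
    """Textbook pooled-variance two-sided Student t-test."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    return 2 * stats.t.sf(abs(t), n1 + n2 - 2)


def brute_force_auc(scores, labels):
    pos = scores[labels]
    neg = scores[~labels]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestTwoSampleT:
    def test_identical_samples_give_p_one(self):
        with pytest.warns(UserWarning):
            assert two_sample_t_pvalue([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_extreme_separation(self):
        assert two_sample_t_pvalue([0, 0, 0.0001], [10, 10, 10.0001]) < 1e-6

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 3], [2, 3, 4]),
            ([0.5, 1.1, 0.9, 1.4], [2.0, 2.2]),
            ([-1, 0, 1, 2, 3], [0, 0, 1]),
        ],
    )
    def test_matches_textbook_formula(self, x, y):
        assert two_sample_t_pvalue(x, y) == pytest.approx(pooled_t_pvalue_oracle(x, y))

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=12), rng.normal(0.5, 1, size=9)
        assert two_sample_t_pvalue(x, y) == pytest.approx(
            stats.ttest_ind(x, y, equal_var=True).pvalue
        )


class TestGreedyCalf:
    def test_perfect_marker_selected_alone(self, rng):
        z = rng.normal(size=(10, 20))
        labels = np.arange(20) >= 10
        z[4] = np.where(labels, 10.0, -10.0) + rng.normal(0, 0.01, 20)
        model = greedy_calf(pd.DataFrame(z, index=[f"m{i}" for i in range(10)]), labels)
        assert model.terms[0] == ("m4", 1)
        assert model.final_auc == 1.0

    def test_first_pick_is_global_argmin_pvalue(self, rng):
        """Exhaustive oracle: iteration 1 must select the miRNA whose
        individual t-test p-value is smallest, over random instances."""
        for _ in range(25):
            z = rng.normal(size=(20, 16))
            labels = np.arange(16) >= 8
            z[rng.integers(20), labels] += rng.uniform(0.5, 1.5)
            pvals = [
                pooled_t_pvalue_oracle(z[i, ~labels], z[i, labels]) for i in range(20)
            ]
            model = greedy_calf(z, labels, max_markers=1)
            assert int(model.terms[0][0]) == int(np.argmin(pvals))
            assert model.metric_trace[0] == pytest.approx(min(pvals))

    def test_first_marker_oriented_towards_risk(self, rng):
        z = rng.normal(size=(5, 30))
        labels = np.arange(30) >= 15
        z[2, labels] -= 2.0  # downregulated in the positive class
        model = greedy_calf(z, labels, max_markers=1)
        assert model.terms[0] == ("2", -1)
        scores = score_samples(model, z).to_numpy()
        assert scores[labels].mean() > scores[~labels].mean()

    def test_trace_strictly_decreases_and_no_better_candidate(self, normalized):
        z, _, labels, samples = normalized
        model = greedy_calf(z[samples], labels, max_markers=6)
        trace = model.metric_trace
        assert all(b < a for a, b in zip(trace, trace[1:]))
        # exhaustive re-check: no rejected candidate would improve the metric
        scores = score_samples(model, z[samples]).to_numpy()
        used = {m for m, _ in model.terms}
        best_p = trace[-1]
        for m in z.index:
            if m in used:
                continue
            for sign in (+1, -1):
                cand = scores + sign * z.loc[m, samples].to_numpy()
                p = pooled_t_pvalue_oracle(cand[~labels], cand[labels])
                assert not p < best_p or len(model.terms) == 6

    def test_marker_limit_respected(self, normalized):
        z, _, labels, samples = normalized
        for k in (1, 3, 6):
            assert len(greedy_calf(z[samples], labels, max_markers=k).terms) <= k

    def test_unlimited_run_terminates(self, normalized):
        z, _, labels, samples = normalized
        model = greedy_calf(z[samples], labels, max_markers=10**6)
        assert len(model.terms) < len(z.index)

    def test_precondition_errors(self, rng):
        z = rng.normal(size=(4, 6))
        with pytest.raises(ValueError):
            greedy_calf(z, [True] * 5 + [False], max_markers=2)
        with pytest.raises(ValueError):
            greedy_calf(z, [True, False, False, False, False, False], max_markers=2)


class TestScoreSamples:
    def test_empty_model_scores_zero(self, rng):
        z = pd.DataFrame(rng.normal(size=(3, 5)), index=["a", "b", "c"])
        assert (score_samples(ClassifierModel(terms=[]), z) == 0).all()

    def test_signed_sum_arithmetic(self):
        z = pd.DataFrame({"s": [1.5, 0.5]}, index=["A", "B"])
        model = ClassifierModel(terms=[("A", 1), ("B", -1)])
        assert score_samples(model, z)["s"] == pytest.approx(1.0)

    def test_missing_mirna_named(self, rng):
        z = pd.DataFrame(rng.normal(size=(2, 3)), index=["A", "B"])
        with pytest.raises(KeyError, match="C"):
            score_samples(ClassifierModel(terms=[("C", 1)]), z)

    def test_weight_negation_flips_auc(self, normalized):
        z, _, labels, samples = normalized
        model = greedy_calf(z[samples], labels, max_markers=3)
        flipped = ClassifierModel(terms=[(m, -w) for m, w in model.terms])
        a = auc(score_samples(model, z[samples]).to_numpy(), labels)
        b = auc(score_samples(flipped, z[samples]).to_numpy(), labels)
        assert a + b == pytest.approx(1.0)


class TestAuc:
    def test_perfect_separation(self):
        assert auc(np.array([3, 4, 1, 2]), np.array([True, True, False, False])) == 1.0

    def test_all_ties_give_half(self):
        assert auc(np.zeros(6), np.array([True] * 3 + [False] * 3)) == 0.5

    def test_pair_counting_example(self):
        scores = np.array([3, 1, 2, 0], dtype=float)
        labels = np.array([True, True, False, False])
        assert auc(scores, labels) == 0.75

    def test_matches_brute_force_with_ties(self, rng):
        for _ in range(20):
            scores = rng.integers(0, 5, size=14).astype(float)
            labels = rng.random(14) < 0.5
            if labels.all() or not labels.any():
                continue
            assert auc(scores, labels) == pytest.approx(brute_force_auc(scores, labels))

    def test_complement_identity(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)


class TestRocCurve:
    def test_trapezoid_area_equals_auc(self, rng):
        scores = rng.normal(size=40)
        labels = rng.random(40) < 0.5
        roc = roc_curve(scores, labels, bootstrap_n=0)
        assert np.trapezoid(roc.tpr, roc.fpr) == pytest.approx(roc.auc, abs=1e-12)

    def test_monotone_from_origin_to_corner(self, rng):
        scores = rng.normal(size=25)
        labels = np.arange(25) % 2 == 0
        roc = roc_curve(scores, labels, bootstrap_n=0)
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert (np.diff(roc.fpr) >= 0).all() and (np.diff(roc.tpr) >= 0).all()

    def test_null_band_covers_chance_diagonal(self, rng):
        """With random scores the 95% bootstrap band should cover the
        chance AUC in nearly all seeds."""
        covered = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            scores = r.normal(size=200)
            labels = np.arange(200) < 100
            roc = roc_curve(scores, labels, bootstrap_n=300, seed=seed)
            lo = np.trapezoid(roc.band_lo, roc.band_fpr)
            hi = np.trapezoid(roc.band_hi, roc.band_fpr)
            covered += lo <= 0.5 <= hi
        assert covered >= 9


class TestApplyToGroups:
    def test_positive_class_orientation(self, normalized):
        z, meta, labels, samples = normalized
        model = greedy_calf(z[samples], labels, max_markers=3)
        a = apply_to_groups(model, z, meta, "nonprogressed", "progressed")
        assert a == pytest.approx(model.final_auc)

    def test_intermediate_group_scores_between(self, normalized):
        """The unaffected group sits between the two planted classes, so
        separating it from progressed is easier than chance but harder
        than the trained contrast."""
        z, meta, labels, samples = normalized
        model = greedy_calf(z[samples], labels, max_markers=4)
        auc_np = apply_to_groups(model, z, meta, "nonprogressed", "progressed")
        auc_un = apply_to_groups(model, z, meta, "unaffected", "progressed")
        assert 0.5 < auc_un < auc_np

    def test_unknown_group_rejected(self, normalized):
        z, meta, labels, samples = normalized
        model = greedy_calf(z[samples], labels, max_markers=2)
        with pytest.raises(ValueError, match="martian"):
            apply_to_groups(model, z, meta, "martian", "progressed")


class TestModelSerialization:
    def test_json_roundtrip(self, tmp_path):
        model = ClassifierModel(
            terms=[("hsa-miR-941", 1), ("hsa-miR-31-5p", -1)],
            metric_trace=[0.005, 0.0002],
            final_auc=0.86,
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ClassifierModel.from_json(path)
        assert back.terms == model.terms
        assert back.metric_trace == model.metric_trace
        assert back.final_auc == model.final_auc

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError):
            ClassifierModel(terms=[("a", 2)])
        with pytest.raises(ValueError):
            ClassifierModel(terms=[("a", 1), ("a", -1)])
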