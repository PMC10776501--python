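import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cfmotif.cohort import SampleMeta
from cfmotif.errors import EvaluationError
from cfmotif.evaluation import (
    ConfusionMetrics,
    anova_scores,
    auc_ci_bootstrap,
    auc_ci_delong,
    confusion_metrics,
    delong_variance,
    heatmap_order,
    motif_group_tests,
    roc_curve,
    subgroup_roc,
    wilcoxon_rank_sum,
    youden_threshold,
)


def brute_force_auc(pos, neg):
    """Pairwise U-statistic: wins count 1, ties count 1/2."""
    total = 0.0
    for x in pos:
        for y in neg:
            total += 1.0 if x > y else (0.5 if x == y else 0.0)
    return total / (len(pos) * len(neg))


def random_instance(seed, n_max=50, discrete=False):
    rng = np.random.default_rng(seed)
    n_pos = rng.integers(2, n_max // 2 + 1)
    n_neg = rng.integers(2, n_max // 2 + 1)
    if discrete:  # forces ties
        scores = rng.integers(0, 5, n_pos + n_neg).astype(float)
    else:
        scores = rng.random(n_pos + n_neg)
    labels = ["cancer"] * int(n_pos) + ["healthy"] * int(n_neg)
    return scores, labels, int(n_pos)


class TestROC:
    def test_perfect_separation(self):
        roc = roc_curve([0.9, 0.8, 0.2, 0.1], ["cancer", "cancer", "healthy", "healthy"])
        assert roc.auc == 1.0

    def test_all_tied_scores(self):
        roc = roc_curve([0.5] * 6, ["cancer"] * 3 + ["healthy"] * 3)
        assert roc.auc == 0.5

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("discrete", [False, True])
    def test_auc_equals_pairwise_enumeration(self, seed, discrete):
        scores, labels, n_pos = random_instance(seed, discrete=discrete)
        roc = roc_curve(scores, labels)
        expected = brute_force_auc(scores[:n_pos], scores[n_pos:])
        assert roc.auc == pytest.approx(expected, abs=1e-12)

    def test_sensitivity_non_increasing_in_threshold(self):
        scores, labels, _ = random_instance(3)
        roc = roc_curve(scores, labels)
        assert (np.diff(roc.thresholds) > 0).all()
        assert (np.diff(roc.sensitivity) <= 0).all()

    def test_monotone_transform_invariance(self):
        scores, labels, _ = random_instance(5)
        base = roc_curve(scores, labels).auc
        assert roc_curve(2 * scores + 1, labels).auc == pytest.approx(base)
        assert roc_curve(np.exp(scores), labels).auc == pytest.approx(base)

    def test_label_reversal_maps_auc_to_complement(self):
        scores, labels, _ = random_instance(7)
        flipped = ["healthy" if l == "cancer" else "cancer" for l in labels]
        a = roc_curve(scores, labels, positive_label="cancer").auc
        b = roc_curve(scores, flipped, positive_label="cancer").auc
        assert a + b == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_curve([0.1, 0.2], ["cancer", "cancer"])


class TestDeLong:
    @pytest.mark.parametrize("seed", range(10))
    def test_variance_matches_component_enumeration(self, seed):
        """DeLong variance equals the O(n^2) structural-component oracle."""
        scores, labels, n_pos = random_instance(seed, n_max=20, discrete=(seed % 2 == 0))
        pos, neg = scores[:n_pos], scores[n_pos:]
        psi = np.zeros((len(pos), len(neg)))
        for i, x in enumerate(pos):
            for j, y in enumerate(neg):
                psi[i, j] = 1.0 if x > y else (0.5 if x == y else 0.0)
        v10 = psi.mean(axis=1)
        v01 = psi.mean(axis=0)
        expected = v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg)
        auc, var = delong_variance(scores, labels)
        assert auc == pytest.approx(psi.mean(), abs=1e-12)
        assert var == pytest.approx(expected, abs=1e-12)

    def test_degenerate_separation_gives_zero_width_ci(self):
        scores = [0.9, 0.8, 0.7, 0.2, 0.15, 0.1]
        labels = ["cancer"] * 3 + ["healthy"] * 3
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = auc_ci_delong(scores, labels)
        assert (lo, hi) == (1.0, 1.0)

    def test_ci_contains_auc_and_is_clamped(self):
        scores, labels, _ = random_instance(11)
        auc, _ = delong_variance(scores, labels)
        lo, hi = auc_ci_delong(scores, labels)
        assert 0 <= lo <= auc <= hi <= 1

    def test_too_small_class_rejected(self):
        with pytest.raises(EvaluationError):
            auc_ci_delong([0.1, 0.5, 0.9], ["cancer", "healthy", "healthy"])

    def test_bootstrap_ci_brackets_auc(self):
        scores, labels, _ = random_instance(13)
        auc, _ = delong_variance(scores, labels)
        lo, hi = auc_ci_bootstrap(scores, labels, n_resamples=500, seed=0)
        assert lo <= auc <= hi


class TestYouden:
    def brute_force(self, scores, labels):
        roc = roc_curve(scores, labels)
        best = None
        for t, sens, spec in zip(roc.thresholds, roc.sensitivity, roc.specificity):
            key = (sens + spec - 1, spec)
            if best is None or key > best[0]:
                best = (key, t)
        return best[1]

    def test_perfect_separation_operating_point(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = ["cancer", "cancer", "healthy", "healthy"]
        roc = roc_curve(scores, labels)
        t = youden_threshold(roc)
        cm = confusion_metrics(scores, labels, t)
        assert cm.sensitivity == 1.0 and cm.specificity == 1.0

    def test_all_tied_scores_predict_all_negative(self):
        roc = roc_curve([0.5] * 6, ["cancer"] * 3 + ["healthy"] * 3)
        t = youden_threshold(roc)
        assert math.isinf(t) and t > 0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_scan(self, seed):
        scores, labels, _ = random_instance(seed, n_max=30, discrete=(seed % 2 == 0))
        roc = roc_curve(scores, labels)
        assert youden_threshold(roc) == self.brute_force(scores, labels)


class TestConfusionMetrics:
    def test_printed_formula_example(self):
        cm = ConfusionMetrics(tp=3, fn=1, tn=4, fp=0, threshold=0.5)
        assert cm.sensitivity == 0.75
        assert cm.specificity == 1.0
        assert cm.ppv == 1.0
        assert cm.npv == 0.8
        assert cm.accuracy == 0.875

    def test_no_predicted_positives_gives_nan_ppv(self):
        cm = confusion_metrics([0.1, 0.2], ["cancer", "healthy"], threshold=0.9)
        assert math.isnan(cm.ppv)
        assert cm.tp == 0 and cm.fp == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_naive_recount(self, seed):
        scores, labels, _ = random_instance(seed, discrete=True)
        threshold = float(np.median(scores))
        cm = confusion_metrics(scores, labels, threshold)
        tp = fn = tn = fp = 0
        for s, l in zip(scores, labels):
            predicted_positive = s >= threshold
            if l == "cancer":
                tp += predicted_positive
                fn += not predicted_positive
            else:
                fp += predicted_positive
                tn += not predicted_positive
        assert (cm.tp, cm.fn, cm.tn, cm.fp) == (tp, fn, tn, fp)

    @given(
        tp=st.integers(0, 50), fn=st.integers(0, 50),
        tn=st.integers(0, 50), fp=st.integers(0, 50),
    )
    def test_metric_identities_for_all_tables(self, tp, fn, tn, fp):
        cm = ConfusionMetrics(tp=tp, fn=fn, tn=tn, fp=fp, threshold=0.5)
        if tp + fn:
            assert cm.sensitivity == tp / (tp + fn)
        else:
            assert math.isnan(cm.sensitivity)
        if tn + fp:
            assert cm.specificity == tn / (tn + fp)
        if tp + fp + tn + fn:
            assert cm.accuracy == (tp + tn) / (tp + fp + tn + fn)
            for value in (cm.sensitivity, cm.specificity, cm.ppv, cm.npv, cm.accuracy):
                assert math.isnan(value) or 0 <= value <= 1


class TestSubgroupROC:
    def build(self, rng):
        metas, scores = [], {}
        for i in range(20):  # strong subgroup
            sid = f"lung{i}"
            metas.append(SampleMeta(sid, "cancer", "lung", "IV"))
            scores[sid] = 0.8 + 0.1 * rng.random()
        for i in range(20):  # weak subgroup
            sid = f"gi{i}"
            metas.append(SampleMeta(sid, "cancer", "gastrointestinal", "II"))
            scores[sid] = 0.45 + 0.2 * rng.random()
        for i in range(30):
            sid = f"h{i}"
            metas.append(SampleMeta(sid, "healthy"))
            scores[sid] = 0.35 + 0.2 * rng.random()
        return metas, pd.Series(scores)

    def test_whole_cancer_subgroup_equals_global_roc(self):
        rng = np.random.default_rng(0)
        metas, scores = self.build(rng)
        metas = [
            SampleMeta(m.sample_id, m.label, "lung" if m.label == "cancer" else None,
                       m.stage) for m in metas
        ]
        labels = [m.label for m in metas]
        global_auc = roc_curve(scores, labels).auc
        sub = subgroup_roc(scores, metas, "cancer_type")
        assert list(sub) == ["lung"]
        assert sub["lung"].auc == pytest.approx(global_auc)

    def test_stronger_subgroup_has_higher_auc(self):
        rng = np.random.default_rng(1)
        metas, scores = self.build(rng)
        labels = [m.label for m in metas]
        global_auc = roc_curve(scores, labels).auc
        sub = subgroup_roc(scores, metas, "cancer_type")
        assert sub["lung"].auc >= global_auc >= sub["gastrointestinal"].auc

    def test_subgroups_share_all_controls(self):
        rng = np.random.default_rng(2)
        metas, scores = self.build(rng)
        sub = subgroup_roc(scores, metas, "cancer_type")
        assert sub["lung"].n_neg == 30 and sub["gastrointestinal"].n_neg == 30
        assert sub["lung"].n_pos == 20

    def test_stage_pooling(self):
        rng = np.random.default_rng(3)
        metas, scores = self.build(rng)
        sub = subgroup_roc(scores, metas, "stage")
        assert set(sub) == {"II-III", "IV"}
        assert sub["II-III"].n_pos == 20  # the stage-II subgroup


def wilcoxon_exact_enumeration(x, y):
    """Exact two-sided p by enumerating all group assignments of the pooled
    sample (valid without ties)."""
    pooled = list(x) + list(y)
    m = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    u_all = []
    for combo in itertools.combinations(range(len(pooled)), m):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u_all.append(sum(1 for xi in xs for yj in ys if xi > yj))
    u_all = np.array(u_all)
    mean_u = len(x) * len(y) / 2
    extreme = np.abs(u_all - mean_u) >= abs(u_obs - mean_u) - 1e-12
    return extreme.mean()


class TestWilcoxon:
    def test_identical_singletons(self):
        _, p = wilcoxon_rank_sum([5.0], [5.0])
        assert p == pytest.approx(1.0)

    def test_fully_separated_triples_exact(self):
        u, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 9, 2)
        pooled = rng.permutation(20)[: n1 + n2].astype(float)  # tie-free
        x, y = pooled[:n1], pooled[n1:]
        _, p = wilcoxon_rank_sum(x, y)
        assert p == pytest.approx(wilcoxon_exact_enumeration(x, y), abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(EvaluationError):
            wilcoxon_rank_sum([], [1.0])

    def test_motif_group_tests_flag_planted_motifs(self, small_cohort):
        matrix, metas = small_cohort
        labels = [m.label for m in metas]
        table = motif_group_tests(matrix, labels, motifs=["AAAA", "AAGG", "TTTT"])
        assert set(table.columns) >= {"motif", "statistic", "p_value", "p_bh", "direction"}
        planted = table.set_index("motif")
        assert planted.loc["AAAA", "p_value"] < 0.01
        assert planted.loc["AAAA", "direction"] == "up"
        assert planted.loc["AAGG", "direction"] == "down"


class TestAnova:
    def test_identical_strata_give_zero_f(self):
        scores = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        strata = ["a", "a", "a", "b", "b", "b"]
        f, p = anova_scores(scores, strata)
        assert f == pytest.approx(0.0, abs=1e-12)

    def test_two_strata_f_equals_squared_t(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(8), rng.random(10) + 0.3
        f, p_f = anova_scores(np.concatenate([a, b]), ["a"] * 8 + ["b"] * 10)
        t, p_t = stats.ttest_ind(a, b)
        assert f == pytest.approx(t**2)
        assert p_f == pytest.approx(p_t)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(6)
        groups = [rng.random(5), rng.random(7) + 0.2, rng.random(6) - 0.1]
        scores = np.concatenate(groups)
        strata = ["a"] * 5 + ["b"] * 7 + ["c"] * 6
        grand = scores.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        df_b, df_w = 2, len(scores) - 3
        expected_f = (ss_between / df_b) / (ss_within / df_w)
        f, _ = anova_scores(scores, strata)
        assert f == pytest.approx(expected_f)

    def test_degenerate_strata_rejected(self):
        with pytest.raises(EvaluationError):
            anova_scores([1.0, 2.0], ["a", "a"])
        with pytest.raises(EvaluationError):
            anova_scores([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestHeatmapOrder:
    def block_matrix(self):
        rng = np.random.default_rng(7)
        block = np.vstack(
            [rng.normal(0, 0.05, (10, 6)) + [1, 1, 1, 0, 0, 0],
             rng.normal(0, 0.05, (10, 6)) + [0, 0, 0, 1, 1, 1]]
        )
        return pd.DataFrame(
            block,
            index=[f"c{i}" for i in range(10)] + [f"h{i}" for i in range(10)],
            columns=[f"m{j}" for j in range(6)],
        )

    def test_identical_samples_are_adjacent_leaves(self):
        m = self.block_matrix()
        m.iloc[5] = m.iloc[3]  # duplicate row -> distance 0
        row_order, _, _ = heatmap_order(m)
        positions = {m.index[i]: rank for rank, i in enumerate(row_order)}
        assert abs(positions["c3"] - positions["c5"]) == 1

    def test_planted_blocks_separate_into_contiguous_groups(self):
        row_order, col_order, scaled = heatmap_order(self.block_matrix())
        leaf_labels = ["c" if i < 10 else "h" for i in row_order]
        switches = sum(a != b for a, b in zip(leaf_labels, leaf_labels[1:]))
        assert switches == 1  # one contiguous block per class

    def test_z_scaling_contract(self):
        _, _, scaled = heatmap_order(self.block_matrix())
        np.testing.assert_allclose(scaled.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(scaled.std(axis=0, ddof=0), 1, atol=1e-9)

    def test_zero_variance_column_scaled_to_zero_with_warning(self):
        m = self.block_matrix()
        m["flat"] = 0.5
        with pytest.warns(UserWarning, match="zero-variance"):
            _, _, scaled = heatmap_order(m)
        assert (scaled["flat"] == 0).all()
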