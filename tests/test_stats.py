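import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from richdom.genomic import ExpressionMatrix
from richdom.stats import (
    compare_domain_gene_expression,
    correlate,
    ora_fisher,
    rank_sum_test,
    roc_analysis,
    signature_score,
    split_by_driver,
)


def ranksum_enumeration_p(x, y, alternative):
    """Exact rank-sum p by enumerating every assignment of pooled values."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        return sum(1 for a in xs for b in ys if a > b) + 0.5 * sum(
            1 for a in xs for b in ys if a == b
        )

    u_obs = u_stat(x, y)
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in combo]
        ys = [pooled[i] for i in range(len(pooled)) if i not in combo]
        us.append(u_stat(xs, ys))
    us = np.array(us)
    if alternative == "less":
        return (us <= u_obs).mean()
    if alternative == "greater":
        return (us >= u_obs).mean()
    return min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))


class TestRankSum:
    def test_small_exact_example(self):
        res = rank_sum_test([1, 2], [3, 4], "two_sided")
        assert res.statistic == 0
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_samples(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3], "two_sided")
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    @pytest.mark.parametrize("alternative", ["less", "greater", "two_sided"])
    def test_exact_matches_enumeration(self, alternative):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n1, n2 = int(rng.integers(2, 8)), int(rng.integers(2, 8))
            # distinct values so the exact method applies
            vals = rng.choice(10_000, size=n1 + n2, replace=False).astype(float)
            x, y = vals[:n1], vals[n1:]
            res = rank_sum_test(x, y, alternative)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(
                ranksum_enumeration_p(x, y, alternative), rel=1e-10
            )

    def test_ties_fall_back_to_normal_approx(self):
        x = [1.0, 2.0, 2.0, 5.0]
        y = [2.0, 3.0, 4.0, 6.0]
        res = rank_sum_test(x, y, "two_sided")
        assert res.method == "normal_approx"
        assert 0 < res.p_value <= 1

    def test_large_shifted_normals_direction(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 200)
        y = rng.normal(1, 1, 200)
        res = rank_sum_test(x, y, "less")
        assert res.p_value < 1e-10


class TestRepressionComparison:
    def make_expr(self, delta, seed=0, n_genes=60, n_samples=8):
        rng = np.random.default_rng(seed)
        mat = rng.normal(5, 1, (n_genes, n_samples))
        mat[:20] += delta
        genes = [f"g{i:03d}" for i in range(n_genes)]
        return (
            ExpressionMatrix(
                pd.DataFrame(mat, index=genes, columns=[f"s{j}" for j in range(n_samples)])
            ),
            genes[:20],
        )

    def test_planted_repression_detected(self):
        expr, domain_genes = self.make_expr(delta=-2.0, seed=1)
        res = compare_domain_gene_expression(domain_genes, expr)
        assert res.alternative == "less"
        assert res.p_value < 1e-6
        assert res.median1 < res.median2

    def test_extreme_separation(self):
        mat = np.vstack([np.zeros((5, 4)), np.full((10, 4), 8.0)])
        genes = [f"g{i}" for i in range(15)]
        expr = ExpressionMatrix(
            pd.DataFrame(mat, index=genes, columns=list("abcd"))
        )
        res = compare_domain_gene_expression(genes[:5], expr)
        # U = 0: the smallest one-sided p attainable at these group sizes
        assert res.statistic == 0
        assert res.p_value < 1e-3

    def test_too_few_genes(self):
        expr, _ = self.make_expr(0)
        with pytest.raises(ValueError, match="3 genes"):
            compare_domain_gene_expression(["g000", "g001"], expr)


class TestCorrelate:
    def test_perfect_negative(self):
        x = np.arange(10.0)
        res = correlate(x, -x)
        assert res.pearson_r == pytest.approx(-1.0)
        assert res.spearman_rho == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-1.0)
        assert res.intercept == pytest.approx(0.0)

    def test_monotone_nonlinear(self):
        x = np.linspace(0, 5, 30)
        res = correlate(x, np.exp(-x))
        assert res.spearman_rho == pytest.approx(-1.0)
        assert -1.0 < res.pearson_r < -0.5

    def test_zero_variance_named(self):
        with pytest.raises(ValueError, match="zero variance in y"):
            correlate([1.0, 2.0, 3.0], [4.0, 4.0, 4.0])

    def test_requires_three_pairs(self):
        with pytest.raises(ValueError):
            correlate([1.0, 2.0], [2.0, 1.0])


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([5, 6, 7, 1, 2, 3], [1, 1, 1, 0, 0, 0])
        assert res.auc == 1.0
        assert res.sensitivity_at_cutoff == 1.0
        assert res.specificity_at_cutoff == 1.0

    def test_hand_counted_auc(self):
        # pos {4,2}, neg {3,1}: concordant pairs 4>3, 4>1, 2>1 -> 3/4
        res = roc_analysis([4, 2, 3, 1], [1, 1, 0, 0])
        assert res.auc == 0.75

    def test_matches_sklearn_on_small_inputs(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(23)
        for _ in range(30):
            n = int(rng.integers(4, 30))
            labels = np.zeros(n, int)
            labels[: int(rng.integers(1, n))] = 1
            rng.shuffle(labels)
            if labels.sum() in (0, n):
                continue
            scores = rng.integers(0, 6, n).astype(float)  # many ties
            res = roc_analysis(scores, labels)
            assert res.auc == pytest.approx(
                sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(0, 1, 100)
        labels = (rng.random(100) < 0.4).astype(int)
        a = roc_analysis(scores, labels)
        b = roc_analysis(np.exp(scores), labels)
        assert a.auc == pytest.approx(b.auc)
        assert a.sensitivity_at_cutoff == pytest.approx(b.sensitivity_at_cutoff)
        assert a.specificity_at_cutoff == pytest.approx(b.specificity_at_cutoff)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(77)
        aucs = [
            roc_analysis(rng.normal(0, 1, 200), np.repeat([0, 1], 100)).auc
            for _ in range(20)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_one_class_absent(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], [1, 1])

    def test_curve_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(4)
        res = roc_analysis(rng.normal(0, 1, 60), (rng.random(60) < 0.5).astype(int))
        assert res.fpr[0] == 0 and res.tpr[0] == 0
        assert res.fpr[-1] == 1 and res.tpr[-1] == 1
        assert (np.diff(res.fpr) >= 0).all() and (np.diff(res.tpr) >= 0).all()


class TestOra:
    def test_closed_form_full_overlap(self):
        universe = [f"g{i}" for i in range(10)]
        res = ora_fisher(universe[:5], {"set": universe[:5]}, universe)
        assert res.results[0].p_value == pytest.approx(1 / math.comb(10, 5))

    def test_disjoint_set_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        res = ora_fisher(universe[:5], {"other": universe[10:15]}, universe)
        assert res.results[0].p_value == 1.0
        assert res.results[0].overlap == 0

    def test_bh_step_up_by_hand(self):
        # sets engineered to give raw p ascending; BH of (p1,p2,p3) follows
        # the step-up rule: adjusted_i = min over j>=i of p_j * m / j
        universe = [f"g{i}" for i in range(40)]
        hits = universe[:10]
        sets = {
            "a": universe[:10],  # perfect overlap, tiny p
            "b": universe[5:15],
            "c": universe[30:40],  # no overlap, p = 1
        }
        res = ora_fisher(hits, sets, universe)
        raw = [r.p_value for r in res.results]
        adj = [r.p_adjusted for r in res.results]
        m = len(raw)
        expected = [
            min(min(raw[j] * m / (j + 1) for j in range(i, m)), 1.0) for i in range(m)
        ]
        assert adj == pytest.approx(expected)
        assert all(a >= p for a, p in zip(adj, raw))

    def test_sets_intersected_with_universe(self):
        universe = [f"g{i}" for i in range(10)]
        res = ora_fisher(universe[:3], {"s": universe[:3] + ["outside1", "outside2"]}, universe)
        assert res.results[0].set_size == 3

    def test_empty_inputs_raise(self):
        with pytest.raises(ValueError):
            ora_fisher([], {"s": ["g1"]}, ["g1"])
        with pytest.raises(ValueError):
            ora_fisher(["g1"], {"s": ["g1"]}, [])


class TestGroupSplit:
    def make_expr(self, values, samples):
        return ExpressionMatrix(
            pd.DataFrame([values], index=["EZH2"], columns=samples)
        )

    def test_exact_partition(self):
        samples = [f"s{i:02d}" for i in range(40)]
        expr = self.make_expr(list(range(40)), samples)
        split = split_by_driver(expr, "EZH2", 20)
        assert set(split.high_samples) == set(samples[20:])
        assert set(split.low_samples) == set(samples[:20])
        assert not set(split.high_samples) & set(split.low_samples)

    def test_tie_break_lexicographic(self):
        expr = self.make_expr([1.0, 1.0, 1.0, 1.0], ["d", "c", "b", "a"])
        split = split_by_driver(expr, "EZH2", 2)
        assert split.low_samples == ("a", "b")
        assert split.high_samples == ("c", "d")

    def test_too_few_samples(self):
        expr = self.make_expr([1.0, 2.0], ["a", "b"])
        with pytest.raises(ValueError):
            split_by_driver(expr, "EZH2", 20)

    def test_missing_driver(self):
        expr = self.make_expr([1.0, 2.0], ["a", "b"])
        with pytest.raises(KeyError):
            split_by_driver(expr, "MYC", 1)


class TestSignatureScore:
    def test_hand_z_scores_single_gene(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[2.0, 4.0, 6.0]], index=["g1"], columns=list("abc"))
        )
        scores = signature_score(expr, ["g1"])
        np.testing.assert_allclose(scores.to_numpy(), [-1.0, 0.0, 1.0])

    def test_zero_variance_gene_named(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[3.0, 3.0, 3.0]], index=["flat"], columns=list("abc"))
        )
        with pytest.raises(ValueError, match="flat"):
            signature_score(expr, ["flat"])

    def test_missing_genes_warn_but_score(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["g1"], columns=list("abc"))
        )
        with pytest.warns(UserWarning, match="absent"):
            scores = signature_score(expr, ["g1", "nope"])
        assert len(scores) == 3

    def test_entirely_absent_signature(self):
        expr = ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=list("ab"))
        )
        with pytest.raises(ValueError, match="entirely absent"):
            signature_score(expr, ["x", "y"])

    def test_planted_repressed_signature_direction(self):
        rng = np.random.default_rng(9)
        n_genes, n_samples = 30, 24
        mat = rng.normal(5, 1, (n_genes, n_samples))
        mat[:10, :12] -= 1.0  # signature repressed in the first half
        expr = ExpressionMatrix(
            pd.DataFrame(
                mat,
                index=[f"g{i}" for i in range(n_genes)],
                columns=[f"s{j:02d}" for j in range(n_samples)],
            )
        )
        scores = signature_score(expr, [f"g{i}" for i in range(10)])
        assert scores.iloc[:12].mean() < scores.iloc[12:].mean()
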