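"""Statistics layer: t-tests, ROC/Youden/DeLong, ICC, correlations."""

import subprocess

import numpy as np
import pytest
from scipy import stats as sps

from dkisim.stats import (
    agreement_band,
    correlate,
    correlation_category,
    ddct_fold_change,
    delong_compare,
    empirical_auc,
    icc,
    roc_analysis,
    t_test_groups,
)


def auc_all_pairs(scores, labels):
    """Brute-force Mann-Whitney AUC: count all positive/negative pairs,
    half credit for ties."""
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else 0.5 if p == q else 0.0
    return total / (len(pos) * len(neg))


def youden_exhaustive(scores, labels, direction):
    """Reference threshold scan: loop over all observed values, compute
    sens/spec, maximise Youden; ties -> higher sens, then lower value."""
    pos, neg = scores[labels], scores[~labels]
    best = None
    for t in sorted(set(scores)):
        if direction == "greater":
            sens = np.mean(pos > t)
            spec = np.mean(neg <= t)
        else:
            sens = np.mean(pos <= t)
            spec = np.mean(neg > t)
        key = (sens + spec - 1, sens, -t)
        if best is None or key > best[0]:
            best = (key, t, sens, spec)
    return best[1], best[2], best[3]


class TestTTest:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = t_test_groups(a, a.copy())
        assert res.t_stat == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_summary_input_matches_closed_form(self):
        # pooled two-sample t from printed summaries (rounded inputs)
        res = t_test_groups((485.64, 74.05, 10), (469.59, 44.29, 10))
        sp2 = (74.05**2 + 44.29**2) / 2
        t_oracle = (485.64 - 469.59) / np.sqrt(sp2 * 2 / 10)
        assert res.t_stat == pytest.approx(t_oracle, abs=1e-10)
        assert res.t_stat == pytest.approx(0.588, abs=0.005)
        assert res.p_value == pytest.approx(2 * sps.t.sf(t_oracle, 18), abs=1e-10)
        assert res.p_value == pytest.approx(0.56, abs=0.01)

    def test_separation_limit(self):
        a = np.array([1.0, 1.0 + 1e-9, 1.0 - 1e-9])
        res = t_test_groups(a, a + 10.0)
        assert res.p_value < 1e-12

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            t_test_groups(np.ones(5), np.ones(5))

    def test_welch_flag(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 3, 10)
        t_w, p_w = sps.ttest_ind(a, b, equal_var=False)
        res = t_test_groups(a, b, welch=True)
        assert res.t_stat == pytest.approx(t_w)
        assert res.p_value == pytest.approx(p_w)


class TestRoc:
    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("tied", [False, True])
    def test_auc_equals_all_pairs_oracle(self, seed, tied):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 50)
        m = rng.integers(10, 50)
        labels = np.concatenate([np.zeros(n, bool), np.ones(m, bool)])
        if tied:
            scores = rng.integers(0, 8, size=n + m).astype(float)
        else:
            scores = np.concatenate([rng.normal(0, 1, n), rng.normal(0.8, 1, m)])
        assert empirical_auc(scores, labels) == pytest.approx(
            auc_all_pairs(scores, labels), abs=1e-12
        )

    @pytest.mark.parametrize("direction", ["greater", "less"])
    @pytest.mark.parametrize("seed", range(4))
    def test_threshold_equals_exhaustive_scan(self, seed, direction):
        rng = np.random.default_rng(100 + seed)
        labels = np.concatenate([np.zeros(15, bool), np.ones(15, bool)])
        scores = np.round(rng.normal(labels.astype(float), 1.0), 1)
        res = roc_analysis(scores, labels, positive_direction=direction)
        t, sens, spec = youden_exhaustive(scores, labels, direction)
        assert res.threshold == pytest.approx(t)
        assert res.sensitivity == pytest.approx(sens)
        assert res.specificity == pytest.approx(spec)

    def test_perfect_separation(self):
        labels = np.array([0, 0, 0, 1, 1, 1], bool)
        res = roc_analysis(np.array([1.0, 2, 3, 10, 11, 12]), labels)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.p_vs_half < 1e-6

    def test_null_scores_give_half(self):
        rng = np.random.default_rng(7)
        labels = rng.random(4000) < 0.5
        scores = rng.normal(size=4000)
        assert empirical_auc(scores, labels) == pytest.approx(0.5, abs=0.03)

    def test_direction_symmetry(self):
        rng = np.random.default_rng(3)
        labels = np.concatenate([np.zeros(20, bool), np.ones(20, bool)])
        scores = rng.normal(labels.astype(float), 1.0)
        a = empirical_auc(scores, labels, "greater")
        b = empirical_auc(-scores, labels, "less")
        assert a == pytest.approx(b, abs=1e-12)

    def test_binormal_closed_form_agreement(self):
        # large-n empirical AUC vs Phi(|mu1-mu2|/sqrt(s1^2+s2^2))
        rng = np.random.default_rng(2024)
        n = 100_000
        cases = [
            ((0.54, 0.06), (0.46, 0.02), "less"),
            ((1.22, 0.14), (1.53, 0.13), "greater"),
        ]
        for (m0, s0), (m1, s1), direction in cases:
            scores = np.concatenate(
                [rng.normal(m0, s0, n), rng.normal(m1, s1, n)]
            )
            labels = np.concatenate([np.zeros(n, bool), np.ones(n, bool)])
            closed = sps.norm.cdf(abs(m1 - m0) / np.hypot(s0, s1))
            emp = empirical_auc(scores, labels, direction)
            assert emp == pytest.approx(closed, abs=0.005)

    def test_sens_spec_cis_are_clopper_pearson(self):
        labels = np.array([0] * 10 + [1] * 10, bool)
        scores = np.concatenate([np.arange(10), np.arange(10) + 8.0])
        res = roc_analysis(scores, labels)
        k = int(round(res.sensitivity * 10))
        lo = sps.beta.ppf(0.025, k, 10 - k + 1) if k > 0 else 0.0
        hi = sps.beta.ppf(0.975, k + 1, 10 - k) if k < 10 else 1.0
        assert res.sensitivity_ci_95 == pytest.approx((lo, hi))

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(5.0), np.ones(5, bool))


class TestDeLong:
    def test_identical_markers(self):
        rng = np.random.default_rng(1)
        labels = np.array([0] * 10 + [1] * 10, bool)
        x = rng.normal(labels.astype(float), 1.0)
        res = delong_compare(x, x.copy(), labels)
        assert res.auc_difference == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(4)
        labels = np.array([0] * 12 + [1] * 12, bool)
        x = rng.normal(labels.astype(float), 1.0)
        y = rng.normal(0.5 * labels.astype(float), 1.0)
        a = delong_compare(x, y, labels)
        b = delong_compare(y, x, labels)
        assert a.auc_difference == pytest.approx(-b.auc_difference)
        assert a.p_value == pytest.approx(b.p_value)

    def test_matches_proc_reference(self):
        # independent oracle: R pROC's DeLong variance and paired test
        rng = np.random.default_rng(12)
        n = 12
        labels = np.array([0] * n + [1] * n, bool)
        x = np.concatenate([rng.normal(0, 1, n), rng.normal(1, 1, n)])
        y = np.concatenate([rng.normal(0, 1, n), rng.normal(0.5, 1, n)])
        res = roc_analysis(x, labels)
        cmp = delong_compare(x, y, labels)
        rcode = (
            "suppressMessages(library(pROC));"
            f"x <- c({','.join(map(str, x))});"
            f"y <- c({','.join(map(str, y))});"
            f"lab <- c({','.join(map(str, labels.astype(int)))});"
            'rx <- roc(lab, x, quiet=TRUE, direction="<");'
            'ry <- roc(lab, y, quiet=TRUE, direction="<");'
            'cat(auc(rx), var(rx), roc.test(rx, ry, method="delong")$p.value)'
        )
        out = subprocess.run(
            ["Rscript", "-e", rcode], capture_output=True, text=True, check=True
        )
        auc_r, var_r, p_r = map(float, out.stdout.split())
        assert res.auc == pytest.approx(auc_r, abs=1e-6)
        assert res.auc_se**2 == pytest.approx(var_r, rel=1e-6)
        assert cmp.p_value == pytest.approx(p_r, rel=1e-6)

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_compare(np.arange(4.0), np.arange(5.0), np.array([0, 0, 1, 1], bool))


def icc21_anova(y):
    """Hand ANOVA oracle for ICC(2,1): two-way random effects, absolute
    agreement, single measurement."""
    y = np.asarray(y, float)
    n, k = y.shape
    grand = y.mean()
    msr = k * np.sum((y.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((y.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = np.sum((y - grand) ** 2) - (n - 1) * msr / k * k - (k - 1) * msc / n * n
    sst = np.sum((y - grand) ** 2)
    ssr = (n - 1) * msr
    ssc = (k - 1) * msc
    mse = (sst - ssr - ssc) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestIcc:
    def test_duplicate_columns_give_one(self):
        y = np.column_stack([np.arange(5.0), np.arange(5.0)])
        res = icc(y)
        assert res.icc == 1.0
        assert res.agreement_band == "excellent"

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(10)
        res = icc(rng.normal(size=(500, 2)))
        assert abs(res.icc) < 0.1

    def test_matches_hand_anova_oracle(self):
        y = np.array([[9.0, 2.0], [1.0, 10.0], [8.0, 8.0]])
        res = icc(y)
        assert res.icc == pytest.approx(icc21_anova(y), abs=1e-10)
        rng = np.random.default_rng(5)
        y2 = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1)) * 2
        assert icc(y2).icc == pytest.approx(icc21_anova(y2), abs=1e-10)

    def test_average_measures_not_below_single(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            y = rng.normal(size=(10, 2)) + rng.normal(size=(10, 1))
            single = icc(y, "ICC2").icc
            average = icc(y, "ICC2k").icc
            assert average >= single - 1e-12

    def test_agreement_bands(self):
        assert agreement_band(0.95) == "excellent"
        assert agreement_band(0.7) == "substantial"
        assert agreement_band(0.5) == "lower"

    def test_incomplete_layout_rejected(self):
        y = np.array([[1.0, 2.0], [np.nan, 3.0]])
        with pytest.raises(ValueError):
            icc(y)


class TestCorrelate:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert correlate(x, x).r == pytest.approx(1.0)
        assert correlate(x, x).category == "good/excellent"
        assert correlate(x, -x).r == pytest.approx(-1.0)

    def test_affine_invariance_pearson(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r1 = correlate(x, y).r
        r2 = correlate(3.5 * x - 2, y * 0.1 + 7).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1 = correlate(x, y, "spearman").r
        r2 = correlate(np.exp(x), y**3, "spearman").r  # monotone transforms
        assert r1 == pytest.approx(correlate(np.exp(x), y, "spearman").r)
        assert correlate(x, y, "spearman").r == pytest.approx(
            correlate(x, y**3, "spearman").r
        )

    @pytest.mark.parametrize(
        "r,cat",
        [(0.1, "little/none"), (-0.24, "little/none"), (0.3, "fair"),
         (-0.49, "fair"), (0.6, "moderate/good"), (0.74, "moderate/good"),
         (0.75, "good/excellent"), (-1.0, "good/excellent")],
    )
    def test_category_bands(self, r, cat):
        assert correlation_category(r) == cat

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(5), np.arange(5.0))


class TestFoldChange:
    @pytest.mark.parametrize("ddct,expected", [(0, 1.0), (-1, 2.0)])
    def test_examples(self, ddct, expected):
        assert ddct_fold_change(ddct) == expected

    def test_inverse_identity(self):
        assert ddct_fold_change(-np.log2(33.9)) == pytest.approx(33.9)
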