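"""IQR outlier rule, EM mixture fit, and the closed-form intersection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.stats import norm

from abratio.mixture import (
    MixtureFit,
    NoIntersectionError,
    ThresholdMethod,
    ThresholdResult,
    classify_plasmatic,
    fit_gmm_em,
    gaussian_intersection,
    iqr_fences,
    remove_outliers_iqr,
)


class TestIqrOutliers:
    def test_hand_worked_example(self):
        # linear-interpolation quartiles of [1,2,3,4,100]: q25=2, q75=4,
        # fences (-1, 7) -> only 100 is excluded
        kept, removed = remove_outliers_iqr([1, 2, 3, 4, 100])
        assert kept.tolist() == [1, 2, 3, 4]
        assert removed.tolist() == [100]

    def test_all_equal_keeps_everything(self):
        kept, removed = remove_outliers_iqr([5.0] * 10)
        assert removed.size == 0 and kept.size == 10

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            remove_outliers_iqr([1.0, 2.0, 3.0])

    def test_planted_extremes_are_exactly_the_removed_set(self, rng):
        """357 plausible ratios plus 8 planted far outside the fences.

        The core is bounded (uniform) so its own Tukey fences can never
        flag a core value, making the expected removal set exact."""
        core = rng.uniform(0.04, 0.06, size=357)
        planted = np.array([0.12, 0.15, 0.2, 0.25, 0.001, 0.002, 0.11, 0.3])
        values = np.concatenate([core, planted])
        rng.shuffle(values)
        lo, hi = np.quantile(values, 0.25), np.quantile(values, 0.75)
        lo, hi = lo - 1.5 * (hi - lo), hi + 1.5 * (hi - lo)
        assert np.all((planted < lo) | (planted > hi))  # genuinely extreme
        assert np.all((core > lo) & (core < hi))
        kept, removed = remove_outliers_iqr(values)
        assert sorted(removed) == sorted(planted)
        assert kept.size == 357

    @given(
        st.lists(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=4, max_size=60)
    )
    @settings(max_examples=100, deadline=None)
    def test_partition_property(self, values):
        kept, removed = remove_outliers_iqr(values)
        assert sorted(np.concatenate([kept, removed])) == sorted(values)
        lo, hi = iqr_fences(values)
        assert np.all((kept >= lo) & (kept <= hi))


class TestEmFit:
    def test_separated_point_masses(self, rng):
        x = np.concatenate([rng.normal(0.03, 1e-5, 50), rng.normal(0.06, 1e-5, 50)])
        fit = fit_gmm_em(x, seed=0)
        assert fit.converged
        assert fit.means[0] == pytest.approx(0.03, abs=1e-4)
        assert fit.means[1] == pytest.approx(0.06, abs=1e-4)
        assert fit.weights[0] == pytest.approx(0.5, abs=0.01)

    def test_loglik_monotone_every_iteration(self, rng):
        for _ in range(5):
            x = np.concatenate(
                [rng.normal(0.042, 0.004, 150), rng.normal(0.052, 0.005, 250)]
            )
            fit = fit_gmm_em(x, seed=3)
            diffs = np.diff(fit.loglik_trace)
            assert np.all(diffs >= -1e-9)

    def test_single_gaussian_input_total_variation(self, rng):
        """A one-component sample is re-expressed without distortion."""
        mu, sd = 0.05, 0.004
        x = rng.normal(mu, sd, 5000)
        fit = fit_gmm_em(x, seed=1)
        tv = 0.5 * quad(
            lambda t: abs(fit.pdf(t) - norm.pdf(t, x.mean(), x.std())),
            mu - 8 * sd,
            mu + 8 * sd,
            limit=200,
        )[0]
        assert tv < 0.02

    def test_likelihood_at_least_sklearn(self, rng):
        """Our EM is a proper maximum-likelihood contender: its best restart
        matches or beats scikit-learn's best-of-10 on the same data."""
        sklearn = pytest.importorskip("sklearn.mixture")
        x = np.concatenate([rng.normal(0.039, 0.004, 140), rng.normal(0.058, 0.005, 260)])
        fit = fit_gmm_em(x, seed=2)
        gm = sklearn.GaussianMixture(2, n_init=10, random_state=0, tol=1e-8, max_iter=1000)
        gm.fit(x[:, None])
        assert fit.loglik >= gm.score(x[:, None]) * x.size - 1e-3
        order = np.argsort(gm.means_.ravel())
        np.testing.assert_allclose(fit.means, gm.means_.ravel()[order], atol=5e-4)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            fit_gmm_em(np.arange(5, dtype=float))

    def test_component_ordering_and_weight_sum(self, rng):
        x = np.concatenate([rng.normal(0.06, 0.003, 100), rng.normal(0.04, 0.003, 100)])
        fit = fit_gmm_em(x, seed=0)
        assert fit.means[0] < fit.means[1]
        assert fit.weights[0] + fit.weights[1] == pytest.approx(1.0, abs=1e-12)


def _bisect_intersection(w, m, s):
    """Independent oracle: bisection on the weighted log-density difference."""
    f = lambda x: (
        math.log(w[0]) + norm.logpdf(x, m[0], s[0]) - math.log(w[1]) - norm.logpdf(x, m[1], s[1])
    )
    return brentq(f, m[0] + 1e-12, m[1] - 1e-12, xtol=1e-15, rtol=1e-15)


def _fit(w, m, s):
    return MixtureFit(weights=w, means=m, sds=s, loglik=0.0, n_iter=1, converged=True)


class TestIntersection:
    def test_symmetric_case_is_midpoint(self):
        thr = gaussian_intersection(_fit((0.5, 0.5), (0.0, 2.0), (1.0, 1.0)))
        assert thr.value == pytest.approx(1.0, abs=1e-14)
        assert thr.method is ThresholdMethod.GMM

    def test_unequal_variance_matches_bisection(self):
        w, m, s = (0.5, 0.5), (0.0, 3.0), (1.0, 2.0)
        assert gaussian_intersection(_fit(w, m, s)).value == pytest.approx(
            _bisect_intersection(w, m, s), abs=1e-10
        )

    def test_ratio_scale_case_matches_bisection(self):
        w, m, s = (0.3, 0.7), (0.042, 0.052), (0.004, 0.005)
        assert gaussian_intersection(_fit(w, m, s)).value == pytest.approx(
            _bisect_intersection(w, m, s), abs=1e-12
        )

    def test_unweighted_option_ignores_weights(self):
        w, m, s = (0.2, 0.8), (0.04, 0.06), (0.004, 0.005)
        unw = gaussian_intersection(_fit(w, m, s), weighted=False).value
        ref = gaussian_intersection(_fit((0.5, 0.5), m, s), weighted=True).value
        assert unw == pytest.approx(ref, abs=1e-14)

    def test_extreme_weights_raise_with_roots(self):
        with pytest.raises(NoIntersectionError) as exc:
            gaussian_intersection(_fit((1e-12, 1.0 - 1e-12), (0.0, 1.0), (1.0, 1.0)))
        assert len(exc.value.roots) >= 1

    @given(
        mu1=st.floats(0.02, 0.05),
        gap=st.floats(0.005, 0.04),
        s1=st.floats(0.002, 0.01),
        s2=st.floats(0.002, 0.01),
        w1=st.floats(0.15, 0.85),
    )
    @settings(max_examples=150, deadline=None)
    def test_root_satisfies_density_equality(self, mu1, gap, s1, s2, w1):
        """The returned cutoff equates the weighted component densities and
        lies strictly between the means, whichever component is heavier."""
        w, m, s = (w1, 1 - w1), (mu1, mu1 + gap), (s1, s2)
        try:
            x = gaussian_intersection(_fit(w, m, s)).value
        except NoIntersectionError:
            return
        assert m[0] < x < m[1]
        d1 = math.log(w[0]) + norm.logpdf(x, m[0], s[0])
        d2 = math.log(w[1]) + norm.logpdf(x, m[1], s[1])
        assert d1 == pytest.approx(d2, abs=1e-7)


class TestClassification:
    def test_tie_is_positive(self):
        thr = ThresholdResult(value=0.0472, method=ThresholdMethod.GMM)
        assert classify_plasmatic([0.0472], thr).tolist() == ["positive"]
        assert classify_plasmatic([0.0473], thr).tolist() == ["negative"]

    def test_empty_input(self):
        thr = ThresholdResult(value=0.05, method=ThresholdMethod.GMM)
        assert classify_plasmatic([], thr).size == 0
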