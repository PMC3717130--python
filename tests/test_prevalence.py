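"""Prevalence weighting: transforms, independent and copula forms, Kish size."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import multivariate_normal

from mapel import (
    AxesWeightSolution,
    PrevalenceWeights,
    UnconstrainedVector,
    bivariate_rectangle_probability,
    compute_axis_binning,
    effective_sample_size,
    from_unconstrained,
    to_unconstrained,
    weights_independent,
    weights_with_copula,
)
from mapel.errors import AllMassLostError, MapelError

from conftest import make_cohort


def brute_force_weights(cohort, sol):
    """VP-by-VP, axis-by-axis re-implementation of the weighting rule."""
    med = {a: float(np.median(cohort.axes[a])) for a in cohort.axis_names}
    paired = {n for k, l, _ in sol.correlations for n in (k, l)}
    u = []
    for vp in cohort.vp_ids:
        f = 1.0
        for axis in cohort.axis_names:
            if axis in paired:
                continue
            p = sol.p_of(axis)
            f *= p if cohort.axes.loc[vp, axis] > med[axis] else 1.0 - p
        for k, l, rho in sol.correlations:
            f *= _mvn_rectangle(
                cohort.axes.loc[vp, k] > med[k],
                cohort.axes.loc[vp, l] > med[l],
                sol.p_of(k),
                sol.p_of(l),
                rho,
            )
        u.append(f)
    u = np.array(u)
    return u / u.sum()


def _mvn_rectangle(upper_k, upper_l, p_k, p_l, rho):
    """Independent rectangle oracle via scipy's bivariate normal CDF."""
    from scipy.special import ndtri

    zk = ndtri(1 - p_k) if 0 < p_k < 1 else (np.inf if p_k == 0 else -np.inf)
    zl = ndtri(1 - p_l) if 0 < p_l < 1 else (np.inf if p_l == 0 else -np.inf)
    lo = [zk if upper_k else -np.inf, zl if upper_l else -np.inf]
    hi = [np.inf if upper_k else zk, np.inf if upper_l else zl]
    dist = multivariate_normal(mean=[0, 0], cov=[[1, rho], [rho, 1]])
    return float(dist.cdf(np.array(hi), lower_limit=np.array(lo)))


class TestHypersphericalTransform:
    def test_symmetry_point(self):
        sol = AxesWeightSolution(p=[0.5], axis_names=["a"])
        assert to_unconstrained(sol).values[0] == pytest.approx(math.pi / 4)

    def test_boundaries(self):
        sol = AxesWeightSolution(p=[0.0, 1.0], axis_names=["a", "b"])
        np.testing.assert_allclose(to_unconstrained(sol).values, [0.0, math.pi / 2])
        back = from_unconstrained(to_unconstrained(sol))
        np.testing.assert_allclose(back.p, [0.0, 1.0], atol=1e-12)

    def test_correlation_maps_through_atanh(self):
        sol = AxesWeightSolution(
            p=[0.5, 0.5], axis_names=["a", "b"],
            correlations=[("a", "b", 0.46211715726000974)],
        )
        vec = to_unconstrained(sol)
        assert vec.values[-1] == pytest.approx(0.5, abs=1e-11)
        back = from_unconstrained(vec)
        assert back.correlations[0][2] == pytest.approx(0.46211715726000974, abs=1e-12)

    def test_any_real_vector_maps_into_domain(self):
        vec = UnconstrainedVector(values=[10.0, -3.2, 7.0], axis_names=["a", "b"], pairs=[("a", "b")])
        sol = from_unconstrained(vec)
        assert 0 <= sol.p[0] <= 1 and 0 <= sol.p[1] <= 1
        assert sol.p[0] == pytest.approx(math.sin(10.0) ** 2)
        assert abs(sol.correlations[0][2]) < 1

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8),
        st.floats(-0.999, 0.999),
    )
    def test_round_trip_property(self, p, rho):
        names = [f"a{i}" for i in range(len(p))]
        correlations = [(names[0], "extra", rho)] if len(p) >= 1 else []
        sol = AxesWeightSolution(
            p=list(p) + [0.5], axis_names=names + ["extra"], correlations=correlations
        )
        back = from_unconstrained(to_unconstrained(sol))
        np.testing.assert_allclose(back.p, sol.p, atol=1e-12)
        assert back.correlations[0][2] == pytest.approx(rho, abs=1e-12)


class TestIndependentWeights:
    def test_uniform_at_half(self, quadrant_cohort):
        binning = compute_axis_binning(quadrant_cohort)
        sol = AxesWeightSolution.from_cohort(quadrant_cohort, [0.5, 0.5])
        w = weights_independent(quadrant_cohort, binning, sol)
        np.testing.assert_allclose(w.w, 0.25)

    def test_mass_confined_to_upper(self):
        cohort = make_cohort({"a": [1, 1, 2, 2]}, {("rtx", 6.0): [0, 0, 0, 0]})
        binning = compute_axis_binning(cohort)
        sol = AxesWeightSolution.from_cohort(cohort, [1.0])
        w = weights_independent(cohort, binning, sol)
        np.testing.assert_allclose(w.w, [0, 0, 0.5, 0.5])

    def test_hand_product_over_bin_patterns(self, quadrant_cohort):
        binning = compute_axis_binning(quadrant_cohort)
        sol = AxesWeightSolution.from_cohort(quadrant_cohort, [0.7, 0.2])
        w = weights_independent(quadrant_cohort, binning, sol)
        np.testing.assert_allclose(w.w, [0.24, 0.06, 0.56, 0.14], atol=1e-15)

    def test_all_mass_lost(self):
        cohort = make_cohort(
            {"a": [1, 1, 2], "b": [1, 2, 1]}, {("rtx", 6.0): [0, 0, 0]}
        )
        binning = compute_axis_binning(cohort)
        sol = AxesWeightSolution.from_cohort(cohort, [1.0, 1.0])
        with pytest.raises(AllMassLostError):
            weights_independent(cohort, binning, sol)

    @pytest.mark.parametrize("seed", range(4))
    def test_uniformity_and_monotonicity(self, random_cohort_factory, seed):
        cohort = random_cohort_factory(15, 3, seed)
        binning = compute_axis_binning(cohort)
        w_half = weights_independent(
            cohort, binning, AxesWeightSolution.from_cohort(cohort, [0.5] * 3)
        )
        np.testing.assert_allclose(w_half.w, 1 / 15, atol=1e-14)
        # raising p_0 weakly raises the upper-bin mass of axis 0
        upper0 = binning.upper[cohort.axis_names[0]].to_numpy()
        prev = -1.0
        for p0 in (0.1, 0.3, 0.5, 0.7, 0.9):
            w = weights_independent(
                cohort, binning, AxesWeightSolution.from_cohort(cohort, [p0, 0.4, 0.6])
            )
            mass = float(w.w[upper0].sum())
            assert mass >= prev - 1e-12
            prev = mass


class TestRectangleProbability:
    def test_independence_product(self):
        for uk in (False, True):
            for ul in (False, True):
                pk, pl = 0.3, 0.65
                expect = (pk if uk else 1 - pk) * (pl if ul else 1 - pl)
                got = bivariate_rectangle_probability(uk, ul, pk, pl, 0.0)
                assert got == pytest.approx(expect, abs=1e-12)

    def test_orthant_closed_form(self):
        # P(U,U) at p = 1/2 is 1/4 + arcsin(rho) / (2 pi)
        got = bivariate_rectangle_probability(True, True, 0.5, 0.5, 0.5)
        assert got == pytest.approx(1 / 3, abs=1e-9)
        for rho in (-0.8, -0.3, 0.2, 0.9):
            got = bivariate_rectangle_probability(True, True, 0.5, 0.5, rho)
            assert got == pytest.approx(0.25 + math.asin(rho) / (2 * math.pi), abs=1e-9)

    def test_centered_symmetry(self):
        for rho in (-0.7, 0.0, 0.4):
            ll = bivariate_rectangle_probability(False, False, 0.5, 0.5, rho)
            uu = bivariate_rectangle_probability(True, True, 0.5, 0.5, rho)
            assert ll == pytest.approx(uu, abs=1e-10)

    def test_domain_error_on_rho(self):
        with pytest.raises(MapelError):
            bivariate_rectangle_probability(True, True, 0.5, 0.5, 1.0)

    @pytest.mark.parametrize("rho", [-0.9, -0.4, 0.3, 0.75])
    @pytest.mark.parametrize("pk,pl", [(0.2, 0.7), (0.5, 0.9), (0.05, 0.5)])
    def test_against_scipy_bivariate_cdf(self, rho, pk, pl):
        total = 0.0
        for uk in (False, True):
            for ul in (False, True):
                got = bivariate_rectangle_probability(uk, ul, pk, pl, rho)
                oracle = _mvn_rectangle(uk, ul, pk, pl, rho)
                assert got == pytest.approx(oracle, abs=1e-6)
                total += got
        assert total == pytest.approx(1.0, abs=1e-8)


class TestCopulaWeights:
    def test_rho_zero_reduces_to_independent(self, random_cohort_factory):
        for seed in range(3):
            cohort = random_cohort_factory(20, 4, seed)
            binning = compute_axis_binning(cohort)
            p = np.random.default_rng(seed).uniform(0, 1, 4)
            pair = [(cohort.axis_names[0], cohort.axis_names[2], 0.0)]
            w_cop = weights_with_copula(
                cohort, binning, AxesWeightSolution.from_cohort(cohort, p, pair)
            )
            w_ind = weights_independent(
                cohort, binning, AxesWeightSolution.from_cohort(cohort, p)
            )
            np.testing.assert_allclose(w_cop.w, w_ind.w, atol=1e-8)

    def test_orthant_weights(self, quadrant_cohort):
        binning = compute_axis_binning(quadrant_cohort)
        sol = AxesWeightSolution.from_cohort(
            quadrant_cohort, [0.5, 0.5], [("a1", "a2", 0.5)]
        )
        w = weights_with_copula(quadrant_cohort, binning, sol)
        np.testing.assert_allclose(w.w, [1 / 3, 1 / 6, 1 / 6, 1 / 3], atol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_brute_force_oracle(self, random_cohort_factory, seed):
        cohort = random_cohort_factory(16, 4, seed)
        binning = compute_axis_binning(cohort)
        rng = np.random.default_rng(100 + seed)
        sol = AxesWeightSolution.from_cohort(
            cohort,
            rng.uniform(0.05, 0.95, 4),
            [(cohort.axis_names[1], cohort.axis_names[3], float(rng.uniform(-0.8, 0.8)))],
        )
        w = weights_with_copula(cohort, binning, sol)
        np.testing.assert_allclose(w.w, brute_force_weights(cohort, sol), atol=1e-6)


class TestEffectiveSampleSize:
    def test_known_values(self):
        ids3 = ["a", "b", "c"]
        assert effective_sample_size(
            PrevalenceWeights(vp_ids=[f"v{i}" for i in range(100)], w=np.full(100, 0.01))
        ) == pytest.approx(100.0)
        assert effective_sample_size(
            PrevalenceWeights(vp_ids=ids3, w=np.array([1.0, 0.0, 0.0]))
        ) == pytest.approx(1.0)
        assert effective_sample_size(
            PrevalenceWeights(vp_ids=ids3, w=np.array([0.5, 0.25, 0.25]))
        ) == pytest.approx(1 / 0.375)

    def test_normalization_enforced(self):
        with pytest.raises(MapelError):
            PrevalenceWeights(vp_ids=["a", "b"], w=np.array([0.5, 0.6]))
        with pytest.raises(MapelError):
            PrevalenceWeights(vp_ids=["a", "b"], w=np.array([1.5, -0.5]))
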