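"""Closed-form theory: frozen spot values, identities, and limit behavior."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, optimize

import neutralclone as nc
from neutralclone import BranchingParams, EstimatorConfig
from neutralclone.exceptions import DomainError, InvalidParameterError

P072 = BranchingParams(b=0.25, d=0.18, u=0.015)
P099 = BranchingParams.from_delta(0.99, u=0.015)
P0 = BranchingParams(b=0.25, d=0.0, u=0.015)

deltas = st.floats(min_value=0.01, max_value=0.995)
fractions = st.floats(min_value=1e-4, max_value=1 - 1e-4)


class TestFixationProbability:
    @pytest.mark.parametrize(
        "k, params, expected, tol",
        [
            (1, P099, 0.6, 0.005),  # slow growth: first mutation usually fixes
            (5, P099, 0.08, 0.005),
            (1, P072, 0.04, 0.005),
            (1, BranchingParams.from_delta(0.96), 0.27, 0.005),
            (1, P0, 0.0, 0.0),  # pure birth: founder immortal, nothing fixes
        ],
    )
    def test_printed_values(self, k, params, expected, tol):
        assert nc.fixation_probability(k, params) == pytest.approx(expected, abs=tol)

    def test_decreasing_in_k_increasing_in_delta_and_u(self):
        rhos = [nc.fixation_probability(k, P099) for k in range(1, 8)]
        assert all(a > b for a, b in zip(rhos, rhos[1:]))
        grid_d = [nc.fixation_probability(1, BranchingParams.from_delta(d)) for d in (0.3, 0.6, 0.9, 0.99)]
        assert all(a < b for a, b in zip(grid_d, grid_d[1:]))
        grid_u = [nc.fixation_probability(1, BranchingParams.from_delta(0.9, u=u)) for u in (0.001, 0.01, 0.1)]
        assert all(a < b for a, b in zip(grid_u, grid_u[1:]))

    @pytest.mark.parametrize("delta", [0.5, 0.72, 0.96, 0.99])
    @pytest.mark.parametrize("k", [1, 2, 3, 4, 5])
    def test_quadrature_representation_agrees(self, delta, k):
        p = BranchingParams.from_delta(delta, u=0.015)
        assert nc.fixation_probability_integral(k, p) == pytest.approx(
            nc.fixation_probability(k, p), abs=1e-8
        )

    def test_integral_vanishes_without_death(self):
        assert nc.fixation_probability_integral(2, P0) == 0.0

    @pytest.mark.parametrize("k", [0, -1])
    def test_k_must_be_positive(self, k):
        with pytest.raises(DomainError):
            nc.fixation_probability(k, P099)


class TestFrequencyCdf:
    def test_vanishes_at_zero(self):
        assert nc.frequency_cdf(1, 1e-12, P072) == pytest.approx(0.0, abs=1e-9)

    def test_frozen_value(self):
        # direct high-precision evaluation of the closed form
        assert nc.frequency_cdf(1, 0.05, P072) == pytest.approx(0.4845170287, abs=1e-9)

    @given(k=st.integers(min_value=1, max_value=10), delta=deltas)
    def test_upper_limit_complements_fixation(self, k, delta):
        p = BranchingParams.from_delta(delta, u=0.015)
        assert 1 - nc.frequency_cdf(k, 1 - 1e-12, p) == pytest.approx(
            nc.fixation_probability(k, p), abs=1e-9
        )

    @given(k=st.integers(min_value=1, max_value=5), delta=deltas)
    def test_nondecreasing(self, k, delta):
        p = BranchingParams.from_delta(delta, u=0.015)
        grid = np.linspace(0.01, 0.99, 50)
        vals = nc.frequency_cdf(k, grid, p)
        assert np.all(np.diff(vals) >= -1e-12)

    def test_pdf_is_cdf_derivative(self):
        eps = 1e-7
        for k in (1, 3):
            for a in (0.1, 0.5, 0.9):
                num = (nc.frequency_cdf(k, a + eps, P072) - nc.frequency_cdf(k, a - eps, P072)) / (2 * eps)
                assert nc.frequency_pdf(k, a, P072) == pytest.approx(num, rel=1e-5)

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.3])
    def test_domain(self, alpha):
        with pytest.raises(DomainError):
            nc.frequency_cdf(1, alpha, P072)


class TestMedianFrequency:
    def test_fixation_mass_forces_median_one(self):
        # rho_1(0.99) ~ 0.6 > 1/2, so the median sits at fixation
        assert nc.median_frequency(1, P099) == 1.0

    @pytest.mark.parametrize("k, params", [(1, P072), (3, P099), (2, P072)])
    def test_inverts_the_cdf(self, k, params):
        med = nc.median_frequency(k, params)
        if med < 1:
            root = optimize.brentq(
                lambda a: nc.frequency_cdf(k, a, params) - 0.5, 1e-9, 1 - 1e-9, xtol=1e-12
            )
            assert med == pytest.approx(root, abs=1e-9)

    def test_frozen_values(self):
        assert nc.median_frequency(1, P072) == pytest.approx(0.05317164, abs=1e-6)
        assert nc.median_frequency(3, P099) == pytest.approx(0.389, abs=5e-4)


class TestConditionalFrequencyLaw:
    @pytest.mark.parametrize(
        "z, delta, expected",
        [(100, 0.99, 0.63), (100, 0.0, 1 / 101), (0, 0.7, 1.0)],
    )
    def test_expected_frequency_printed_values(self, z, delta, expected):
        p = BranchingParams.from_delta(delta, u=0.015)
        assert nc.expected_frequency_given_z(z, p) == pytest.approx(expected, abs=0.005)

    @given(z=st.integers(min_value=1, max_value=300), delta=deltas)
    def test_mean_reproduced_by_quadrature(self, z, delta):
        p = BranchingParams.from_delta(delta, u=0.015)
        mean_quad = p.delta**z + integrate.quad(
            lambda a: a * nc.frequency_law_given_z(z, a, p)[1], 0, 1, epsabs=1e-12, limit=200
        )[0]
        assert nc.expected_frequency_given_z(z, p) == pytest.approx(mean_quad, abs=1e-8)

    @pytest.mark.parametrize("z", [1, 10, 100])
    def test_pdf_mass_is_subclonal_probability(self, z):
        for p in (P072, P099):
            mass = integrate.quad(
                lambda a: nc.frequency_law_given_z(z, a, p)[1], 0, 1, epsabs=1e-12, limit=200
            )[0]
            assert mass == pytest.approx(1 - p.delta**z, abs=1e-9)

    def test_uniform_when_single_competitor_no_death(self):
        for a in (0.1, 0.5, 0.9):
            assert nc.frequency_law_given_z(1, a, P0)[1] == pytest.approx(1.0)

    def test_cdf_endpoint(self):
        cdf, _ = nc.frequency_law_given_z(100, 0.5, P099)
        assert cdf == pytest.approx(1 - 0.995**100, abs=1e-12)


class TestOriginSizeEstimators:
    @pytest.mark.parametrize(
        "alpha, delta, expected, tol",
        [
            (0.1, 0.99, 1000, 1),  # printed "as many as 1000 cells"
            (0.5, 0.99, 200, 1),
            (0.1, 0.0, 9.4912, 1e-3),
            (0.5, 0.0, 1.4427, 1e-3),
        ],
    )
    def test_ml_values(self, alpha, delta, expected, tol):
        p = BranchingParams.from_delta(delta)
        assert nc.zhat_ml(alpha, p) == pytest.approx(expected, abs=tol)

    @given(delta=deltas)
    def test_ml_increasing_in_delta(self, delta):
        lo = BranchingParams.from_delta(delta * 0.5)
        hi = BranchingParams.from_delta(delta)
        assert nc.zhat_ml(0.2, hi) > nc.zhat_ml(0.2, lo)

    def test_map_matches_ml_for_tiny_prior(self):
        ml = nc.zhat_ml(0.1, P099)
        mp = nc.zhat_map(0.1, P099, EstimatorConfig(v=1e-9))
        assert abs(mp - ml) / ml < 1e-5

    def test_map_frozen_value(self):
        assert nc.zhat_map(0.5, P0, EstimatorConfig(v=0.5)) == pytest.approx(0.72135, abs=1e-4)

    @pytest.mark.parametrize("alpha", [0.0, 1.0])
    def test_domain(self, alpha):
        with pytest.raises(DomainError):
            nc.zhat_ml(alpha, P099)


class TestMutationCounts:
    @pytest.mark.parametrize(
        "alpha, delta, expected",
        [
            (0.01, 0.99, 148.5),
            (0.001, 0.72, 53.5),
            (0.001, 0.999, 14985.0),
            (0.1, 0.96, 3.37),
            (1.0, 0.5, 0.0),
        ],
    )
    def test_subclonal_table_values(self, alpha, delta, expected):
        p = BranchingParams.from_delta(delta, u=0.015)
        assert nc.expected_subclonal(alpha, p) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize(
        "delta, expected", [(0.0, 0.0), (0.99, 1.485), (0.999, 14.985), (0.72, 0.0386)]
    )
    def test_clonal_values(self, delta, expected):
        p = BranchingParams.from_delta(delta, u=0.015)
        assert nc.expected_clonal(p) == pytest.approx(expected, abs=5e-3)

    def test_total_surviving(self):
        assert nc.expected_total_surviving_mutations(1e9, 0.015) == pytest.approx(1.5e7)
        assert nc.expected_total_surviving_mutations(5, 0.0) == 0.0
        assert nc.expected_total_surviving_mutations(1, 0.3) == pytest.approx(0.3)

    @given(delta=deltas, alpha=st.floats(min_value=1e-3, max_value=0.25))
    def test_window_count_consistent_with_spectrum(self, delta, alpha):
        p = BranchingParams.from_delta(delta, u=0.015)
        direct = nc.allele_count_in_window(alpha, p)
        via_spectrum = nc.expected_subclonal(2 * alpha, p) - nc.expected_subclonal(0.5, p)
        assert direct == pytest.approx(via_spectrum, abs=1e-12)

    def test_window_count_vanishes_at_cutoff(self):
        assert nc.allele_count_in_window(0.25, P072) == 0.0

    def test_window_count_published_fit_amplitude(self):
        # amplitude 1.23 is a published single-sample fit; the curve at 0.12
        # then predicts 1.23 * (1/0.12 - 4) mutations
        p = BranchingParams.from_delta(1 - 0.015 / (2 * 1.23), u=0.015)
        assert nc.allele_count_in_window(0.12, p) == pytest.approx(1.23 * (1 / 0.12 - 4), rel=1e-9)

    @given(delta=deltas)
    def test_monotonicities(self, delta):
        p = BranchingParams.from_delta(delta, u=0.015)
        subs = [nc.expected_subclonal(a, p) for a in (0.001, 0.01, 0.1, 0.5)]
        assert all(a > b for a, b in zip(subs, subs[1:]))

    def test_table1_reproduces_printed_rows(self):
        tab = nc.analytic.table1().set_index("delta")
        assert tab.loc[0.99, ">0.01"] == pytest.approx(148.5)
        assert tab.loc[0.72, ">0.001"] == pytest.approx(53.5, abs=0.05)
        assert tab.loc[0.0, "clonal"] == 0.0

    @pytest.mark.parametrize("alpha", [0.0, -0.1, 0.3])
    def test_window_domain(self, alpha):
        with pytest.raises(DomainError):
            nc.allele_count_in_window(alpha, P072)


def test_delta_at_or_above_one_rejected_everywhere():
    with pytest.raises(InvalidParameterError):
        BranchingParams.from_delta(1.0)
    with pytest.raises(InvalidParameterError):
        BranchingParams(b=0.25, d=0.26)
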