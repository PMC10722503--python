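"""Core clade-size birth-death model: beta, likelihood, grid MLE, bounds."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from depauperon.birthdeath_core import (
    BirthDeathParams,
    GridSpec,
    beta,
    bounds_from_beta,
    clade_size_bounds,
    grid_mle,
    loglik,
    profile_ci,
)


class TestParams:
    def test_derived_quantities(self):
        p = BirthDeathParams(r=0.05, lam=0.5)
        assert p.mu == pytest.approx(0.45)
        assert p.eps == pytest.approx(0.9)

    def test_from_r_eps_round_trip(self):
        p = BirthDeathParams.from_r_eps(0.05, 0.9)
        assert p.lam == pytest.approx(0.5)
        assert p.eps == pytest.approx(0.9)

    @pytest.mark.parametrize("r,lam", [(0.0, 1.0), (-0.1, 1.0), (0.2, 0.1), (0.1, 0.0)])
    def test_invalid_rates_rejected(self, r, lam):
        with pytest.raises(ValueError):
            BirthDeathParams(r, lam)


class TestBeta:
    def test_pure_birth_closed_form(self):
        p = BirthDeathParams.from_r_eps(0.1, 0.0)
        assert beta(p, 10.0) == pytest.approx(1 - math.exp(-1), abs=1e-15)

    def test_with_extinction_closed_form(self):
        p = BirthDeathParams.from_r_eps(0.1, 0.5)
        assert beta(p, 10.0) == pytest.approx((math.e - 1) / (math.e - 0.5), abs=1e-12)

    def test_matches_pure_birth_identity_everywhere(self):
        rng = np.random.default_rng(0)
        for r, t in zip(rng.uniform(1e-4, 0.2, 50), rng.uniform(0.1, 300, 50)):
            p = BirthDeathParams.from_r_eps(r, 0.0)
            assert abs(beta(p, t) - (1 - math.exp(-r * t))) < 1e-12

    def test_vanishes_as_t_to_zero(self):
        p = BirthDeathParams.from_r_eps(0.1, 0.5)
        assert beta(p, 1e-12) < 1e-10

    def test_saturates_for_old_clades(self):
        p = BirthDeathParams.from_r_eps(0.1, 0.5)
        assert beta(p, 1e4) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_age_rejected(self):
        p = BirthDeathParams.from_r_eps(0.1, 0.0)
        with pytest.raises(ValueError):
            beta(p, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        r=st.floats(1e-4, 0.2),
        eps=st.floats(0.0, 0.99),
        t1=st.floats(0.1, 200.0),
        dt=st.floats(0.1, 100.0),
    )
    def test_monotone_in_age_and_extinction(self, r, eps, t1, dt):
        p = BirthDeathParams.from_r_eps(r, eps)
        assert beta(p, t1 + dt) >= beta(p, t1)
        p_hi = BirthDeathParams.from_r_eps(r, min(eps + 0.005, 0.995))
        assert beta(p_hi, t1) >= beta(p, t1)


class TestLoglik:
    def test_single_species_clade_is_log_one_minus_beta(self, t_half):
        p = BirthDeathParams.from_r_eps(0.1, 0.0)
        assert loglik(p, [(1, t_half)]) == pytest.approx(math.log(0.5), rel=1e-12)

    def test_geometric_mass_at_n_four(self, t_half):
        # beta = 0.5: ln(1-b) + 3 ln b = 4 ln(1/2)
        p = BirthDeathParams.from_r_eps(0.1, 0.0)
        assert loglik(p, [(4, t_half)]) == pytest.approx(4 * math.log(0.5), rel=1e-12)

    def test_additive_over_clades(self):
        p = BirthDeathParams.from_r_eps(0.07, 0.3)
        clades = [(3, 50.0), (17, 80.0)]
        assert loglik(p, clades) == pytest.approx(
            sum(loglik(p, [c]) for c in clades), rel=1e-12
        )

    def test_matches_naive_per_clade_loop(self):
        rng = np.random.default_rng(3)
        p = BirthDeathParams.from_r_eps(0.05, 0.8)
        clades = [(int(n), float(t)) for n, t in zip(rng.integers(1, 500, 40), rng.uniform(5, 150, 40))]
        naive = sum(
            math.log(1 - beta(p, t)) + (n - 1) * math.log(beta(p, t)) for n, t in clades
        )
        assert loglik(p, clades) == pytest.approx(naive, abs=1e-9)

    def test_geometric_pmf_normalizes(self):
        for b in (0.1, 0.5, 0.9, 0.99):
            n = np.arange(1, 5000)
            partial = np.sum((1 - b) * b ** (n - 1))
            assert partial == pytest.approx(1 - b ** 5000, abs=1e-14)

    def test_empty_clade_set_rejected(self):
        with pytest.raises(ValueError):
            loglik(BirthDeathParams.from_r_eps(0.1, 0.0), [])


def brute_force_mle(clades, spec):
    """Oracle: naive loop over every grid point."""
    best = (-np.inf, None, None)
    for r in spec.r_values():
        for lam in spec.lam_values():
            if lam < r:
                continue
            ll = loglik(BirthDeathParams(float(r), float(lam)), clades)
            if ll > best[0]:
                best = (ll, float(r), float(lam))
    return best


class TestGridMLE:
    COARSE = GridSpec(0.01, 0.1, 0.01, 0.1, 2.0, 0.1)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            clades = [
                (int(n), float(t))
                for n, t in zip(rng.integers(1, 200, 15), rng.uniform(10, 120, 15))
            ]
            fit = grid_mle(clades, self.COARSE)
            ll, r, lam = brute_force_mle(clades, self.COARSE)
            assert fit.params_hat.r == pytest.approx(r)
            assert fit.params_hat.lam == pytest.approx(lam)
            assert fit.loglik_max == pytest.approx(ll, abs=1e-9)

    def test_single_monotypic_clade_drives_rate_to_grid_minimum(self):
        # With n = 1 the likelihood ln(1 - beta) decreases in beta, hence in r and lam
        spec = GridSpec(0.001, 0.05, 0.001, 0.1, 1.0, 0.05)
        fit = grid_mle([(1, 100.0)], spec)
        assert fit.params_hat.r == pytest.approx(spec.r_min)
        assert fit.params_hat.lam == pytest.approx(spec.lam_min)

    def test_profile_ci_brackets_the_mle(self):
        rng = np.random.default_rng(5)
        clades = [
            (int(n), float(t)) for n, t in zip(rng.integers(1, 300, 30), rng.uniform(20, 120, 30))
        ]
        fit = grid_mle(clades, self.COARSE)
        ci = profile_ci(fit)
        p = fit.params_hat
        for name, value in [("r", p.r), ("lam", p.lam), ("mu", p.mu), ("eps", p.eps)]:
            lo, hi = ci[name]
            assert lo - 1e-12 <= value <= hi + 1e-12

    def test_more_clades_shrink_the_interval(self):
        from depauperon.synthetic_data import sample_geometric

        spec = GridSpec(1e-3, 0.2, 1e-3, 0.1, 2.0, 0.02)
        p = BirthDeathParams.from_r_eps(0.06, 0.5)
        widths = []
        for size in (40, 640):
            deltas = []
            for seed in range(3):
                rng = np.random.default_rng(100 + seed)
                t = rng.uniform(30, 120, size)
                n = [int(sample_geometric(float(beta(p, tt)), rng)[0]) for tt in t]
                fit = grid_mle(list(zip(n, t)), spec)
                lo, hi = fit.profile_ci["r"]
                deltas.append(hi - lo)
            widths.append(np.mean(deltas))
        assert widths[1] < widths[0]

    def test_empty_clades_rejected(self):
        with pytest.raises(ValueError):
            grid_mle([], self.COARSE)


class TestCladeSizeBounds:
    def test_printed_formulas_at_beta_half(self):
        k_lo, k_hi = bounds_from_beta(0.5)
        assert k_lo == pytest.approx(math.log(0.975) / math.log(0.5) + 1, abs=1e-12)
        assert k_hi == pytest.approx(math.log(0.025) / math.log(0.5) + 1, abs=1e-12)
        assert k_lo == pytest.approx(1.0365, abs=5e-5)
        assert k_hi == pytest.approx(6.3219, abs=5e-5)

    def test_upper_bound_monotone_in_beta(self):
        betas = np.linspace(0.05, 0.995, 40)
        uppers = [bounds_from_beta(b)[1] for b in betas]
        assert all(b2 > b1 for b1, b2 in itertools.pairwise(uppers))

    def test_ordering_and_degenerate_beta(self):
        for b in (0.0, 0.2, 0.9, 0.9999):
            k_lo, k_hi = bounds_from_beta(b)
            assert k_lo <= k_hi
        assert bounds_from_beta(0.0) == (1.0, 1.0)

    def test_invalid_beta_rejected(self):
        for b in (-0.1, 1.0, float("nan")):
            with pytest.raises(ValueError):
                bounds_from_beta(b)

    def test_from_params(self, t_half):
        p = BirthDeathParams.from_r_eps(0.1, 0.0)
        k_lo, k_hi = clade_size_bounds(p, t_half)
        assert (k_lo, k_hi) == pytest.approx((1.0365, 6.3219), abs=5e-5)
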