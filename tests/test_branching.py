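"""Constant-p branching solver: closed-form cubic, approximations, threshold."""

import numpy as np
import pytest
from scipy.optimize import fsolve

from sdturnover.branching import (
    dynamics_matrix,
    leading_eigenvalue,
    phi_constant_p,
    phi_negative_approx,
    phi_small_r,
    residuals,
    threshold_r,
)
from sdturnover.model import MutationRates, SelectionParams, alpha, beta, case2_swap

from conftest import BALANCING, NEGATIVE, make_config


def random_config(rng):
    sel = SelectionParams(
        s_m=rng.uniform(0.001, 0.05),
        s_f=-rng.uniform(0.001, 0.05),
        h_m=rng.uniform(),
        h_f=rng.uniform(),
    )
    return make_config(
        sel,
        r=rng.uniform(0, 0.02),
        mut=MutationRates(rng.uniform(0, 1e-5), rng.uniform(0, 1e-5)),
    )


class TestDynamicsMatrix:
    def test_decoupled_limit_is_diagonal(self):
        cfg = make_config(BALANCING, r=0.0, mut=MutationRates(0, 0))
        m = dynamics_matrix(0.3, cfg)
        assert m[0, 1] == 0.0 and m[1, 0] == 0.0
        assert m[0, 0] == alpha(0.3, BALANCING)
        assert m[1, 1] == beta(0.3, BALANCING)

    def test_off_diagonals_at_fixed_B(self):
        cfg = make_config(BALANCING, r=0.01, mut=MutationRates(0, 0))
        m = dynamics_matrix(1.0, cfg)
        assert m[0, 1] == pytest.approx(0.01)  # p r + v
        assert m[1, 0] == 0.0  # (1-p) r + u

    def test_leading_eigenvalue_balancing(self):
        cfg = make_config(BALANCING, r=0.0, mut=MutationRates(0, 0))
        assert leading_eigenvalue(0.5, cfg) == pytest.approx(0.005)


class TestConstantP:
    def test_neutral_process_cannot_escape(self):
        cfg = make_config(SelectionParams(0, 0, 0.5, 0.5))
        est = phi_constant_p(0.4, cfg)
        assert est.phi_B == 0.0 and est.phi_b == 0.0

    def test_decoupled_limit_equals_twice_alpha(self):
        cfg = make_config(
            SelectionParams(0.02, -0.02, 1.0, 1.0), r=0.0, mut=MutationRates(0, 0)
        )
        for p in (0.05, 0.1, 0.3, 0.5, 0.9):
            est = phi_constant_p(p, cfg)
            assert est.phi_B == pytest.approx(2 * alpha(p, cfg.selection), abs=1e-10)
            assert est.phi_b == 0.0

    def test_recessive_equalizing_symmetric_with_peak_at_half(self):
        cfg = make_config(SelectionParams(0.02, -0.02, 0.0, 0.0), r=0.0)
        ps = np.linspace(0.05, 0.95, 19)
        vals = np.array([phi_constant_p(p, cfg).phi_B for p in ps])
        assert np.argmax(vals) == len(ps) // 2
        # symmetry is exact up to the tiny mutation terms in the coupling
        assert vals == pytest.approx(vals[::-1], rel=1e-3, abs=1e-8)

    def test_dominant_equalizing_decreasing_in_p(self):
        cfg = make_config(SelectionParams(0.02, -0.02, 1.0, 1.0), r=0.0)
        ps = np.linspace(0.02, 0.98, 40)
        vals = [phi_constant_p(p, cfg).phi_B for p in ps]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_residuals_on_random_grid(self):
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 1000:
            cfg = random_config(rng)
            p = rng.uniform(0.01, 0.99)
            if leading_eigenvalue(p, cfg) <= 0:
                continue
            est = phi_constant_p(p, cfg)
            r1, r2 = residuals(est.phi_B, est.phi_b, p, cfg)
            assert max(abs(r1), abs(r2)) < 1e-10
            assert 0.0 <= est.phi_b <= est.phi_B <= 1.0
            checked += 1

    def test_matches_generic_numeric_solver(self):
        """Independent multi-start solve of the two coupled quadratics."""
        rng = np.random.default_rng(21)
        checked = 0
        while checked < 200:
            cfg = random_config(rng)
            p = rng.uniform(0.05, 0.95)
            if leading_eigenvalue(p, cfg) <= 1e-6:
                continue
            est = phi_constant_p(p, cfg)
            if est.phi_B < 1e-6:
                continue
            best = None
            for guess in [(2 * alpha(p, cfg.selection), 1e-4), (0.05, 0.01), (0.2, 0.05)]:
                x, info, ier, _ = fsolve(
                    lambda z: residuals(z[0], z[1], p, cfg),
                    guess,
                    full_output=True,
                    xtol=1e-13,
                )
                if ier == 1 and 1e-12 < x[0] <= 1 and -1e-9 <= x[1] <= 1:
                    if best is None or x[0] > best:
                        best = x[0]
            if best is None:
                continue
            assert est.phi_B == pytest.approx(best, rel=1e-8)
            checked += 1

    def test_weighted_consistency(self):
        est = phi_constant_p(0.3, make_config(BALANCING))
        assert est.weighted == pytest.approx(
            0.3 * est.phi_B + 0.7 * est.phi_b, abs=1e-15
        )

    def test_weak_selection_linearity(self):
        """Scaling all rates by c scales the probabilities by ~c."""
        base = dict(s=0.02, r=0.002, u=1e-6, v=1e-6)
        vals = {}
        for c in (1.0, 0.25):
            sel = SelectionParams(c * base["s"], -c * base["s"], 1.0, 1.0)
            cfg = make_config(
                sel,
                r=c * base["r"],
                mut=MutationRates(c * base["u"], c * base["v"]),
            )
            vals[c] = phi_constant_p(0.3, cfg)
        assert vals[0.25].phi_B == pytest.approx(0.25 * vals[1.0].phi_B, rel=5e-3)


class TestBranchingMonteCarlo:
    def test_cubic_matches_direct_branching_simulation(self):
        """Stochastic oracle for the closed form: simulate the two-type
        branching process itself (Poisson offspring with the dynamics-
        matrix means) and compare the escape frequency with the cubic.
        Unlike the Wright-Fisher simulator this has no finite-N feedback
        on p, so it isolates the cubic's correctness."""
        cfg = make_config(BALANCING, N=10_000, r=0.0)
        p = 0.5
        est = phi_constant_p(p, cfg)
        m = dynamics_matrix(p, cfg)
        a, c = m[0]
        b, d = m[1]
        rng = np.random.default_rng(99)
        n_lineages = 200_000
        nB = np.ones(n_lineages, dtype=np.int64)
        nb = np.zeros(n_lineages, dtype=np.int64)
        alive = np.ones(n_lineages, dtype=bool)
        escaped = np.zeros(n_lineages, dtype=bool)
        for _ in range(4000):
            idx = np.nonzero(alive)[0]
            if idx.size == 0:
                break
            new_B = rng.poisson((1 + a) * nB[idx] + c * nb[idx])
            new_b = rng.poisson(b * nB[idx] + (1 + d) * nb[idx])
            nB[idx], nb[idx] = new_B, new_b
            tot = new_B + new_b
            esc = tot >= 5_000
            escaped[idx[esc]] = True
            alive[idx] = ~esc & (tot > 0)
        phi_mc = escaped.mean()
        se = np.sqrt(phi_mc * (1 - phi_mc) / n_lineages)
        assert abs(phi_mc - est.phi_B) < 3 * se + 1e-4


class TestSmallR:
    def test_r_zero_limit(self):
        cfg = make_config(BALANCING, r=0.0)
        est = phi_small_r(0.3, cfg)
        assert est.phi_B == pytest.approx(2 * alpha(0.3, BALANCING))
        assert est.phi_b == 0.0
        assert est.method == "small_r"

    def test_printed_arithmetic(self):
        sel = SelectionParams(0.02, -0.02, 1.0, 1.0)
        cfg = make_config(sel, r=0.002)
        assert phi_small_r(0.5, cfg).phi_B == pytest.approx(0.008)

    def test_agrees_with_cubic_for_tight_linkage(self):
        sel = SelectionParams(0.02, -0.02, 1.0, 1.0)
        for p in (0.1, 0.3, 0.5, 0.7):
            a = alpha(p, sel)
            cfg = make_config(sel, r=0.1 * a)
            approx = phi_small_r(p, cfg).phi_B
            exact = phi_constant_p(p, cfg).phi_B
            assert approx == pytest.approx(exact, rel=0.1)


class TestNegativeApproximation:
    def test_above_threshold_vanishes(self):
        cfg = make_config(NEGATIVE, r=0.02)
        est = phi_negative_approx(cfg)
        assert est.phi_B == 0.0 and est.phi_b == 0.0
        assert est.drift_dominated

    def test_below_threshold_value(self):
        cfg = make_config(NEGATIVE, r=0.0)
        assert phi_negative_approx(cfg).phi_B == pytest.approx(0.02)

    def test_exactly_at_threshold(self):
        cfg = make_config(NEGATIVE, r=0.01)
        assert phi_negative_approx(cfg).phi_B == 0.0

    def test_warns_outside_negative_mode(self):
        cfg = make_config(BALANCING, r=0.0)
        with pytest.warns(UserWarning, match="negative-selection"):
            phi_negative_approx(cfg)


class TestThreshold:
    def test_reference_value(self):
        assert threshold_r(make_config(NEGATIVE)) == pytest.approx(0.01)

    def test_additive_allele_has_zero_threshold(self):
        sel = SelectionParams(0.02, -0.04, 0.0, 0.5)
        assert threshold_r(make_config(sel)) == 0.0

    def test_case2_uses_female_parameters(self):
        sel = SelectionParams(s_m=-0.04, s_f=0.02, h_m=0.5, h_f=0.5)
        assert threshold_r(make_config(sel, case=2)) == pytest.approx(0.01)


class TestCase2Equivalence:
    def test_phi_surface_matches_swapped_case1(self):
        sel2 = SelectionParams(s_m=-0.02, s_f=0.02, h_m=0.0, h_f=1.0)
        cfg2 = make_config(sel2, r=0.005, case=2)
        cfg1 = make_config(case2_swap(sel2), r=0.005, case=1)
        for p in (0.1, 0.4, 0.8):
            e2 = phi_constant_p(p, cfg2)
            e1 = phi_constant_p(p, cfg1)
            assert e2.phi_B == e1.phi_B and e2.phi_b == e1.phi_b
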