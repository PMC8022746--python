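"""Fitness scheme, selection functions, equilibria, and mode classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sdturnover.model import (
    ModelConfig,
    MutationRates,
    SelectionMode,
    SelectionParams,
    alpha,
    beta,
    case2_swap,
    classify_mode,
    equilibrium_p,
    mean_change,
)

from conftest import BALANCING, MUT, NEGATIVE, make_config

sel_draw = st.builds(
    SelectionParams,
    s_m=st.floats(-0.2, 0.2),
    s_f=st.floats(-0.2, 0.2),
    h_m=st.floats(0.0, 1.0),
    h_f=st.floats(0.0, 1.0),
)


class TestSelectionFunctions:
    @pytest.mark.parametrize(
        "p, h_m, expected",
        [
            (0.0, 1.0, 0.02),  # alpha(0) = h_m s_m
            (0.0, 0.3, 0.006),
            (0.5, 1.0, 0.005),
            (0.5, 0.0, 0.005),  # h=0: alpha = s p (1-p)
        ],
    )
    def test_alpha_values(self, p, h_m, expected):
        sel = SelectionParams(0.02, -0.02, h_m, 0.5)
        assert alpha(p, sel, case=1) == pytest.approx(expected, abs=1e-15)

    def test_alpha_recessive_symmetry(self):
        """With h_m = 0 the A-B growth rate reduces to s p (1-p), symmetric
        about p = 1/2."""
        sel = SelectionParams(0.02, -0.02, 0.0, 0.0)
        for p in np.linspace(0.0, 1.0, 21):
            assert alpha(p, sel) == pytest.approx(alpha(1.0 - p, sel), abs=1e-16)
            assert alpha(p, sel) == pytest.approx(0.02 * p * (1 - p), abs=1e-16)

    @pytest.mark.parametrize(
        "p, h_m, expected",
        [(0.0, 0.7, 0.0), (1.0, 0.5, -0.01), (0.5, 1.0, -0.005)],
    )
    def test_beta_values(self, p, h_m, expected):
        sel = SelectionParams(0.02, -0.02, h_m, 0.5)
        assert beta(p, sel, case=1) == pytest.approx(expected, abs=1e-15)

    @given(sel=sel_draw)
    @settings(max_examples=200, derandomize=True)
    def test_boundary_identities(self, sel):
        assert alpha(0.0, sel) == pytest.approx(sel.h_m * sel.s_m, abs=1e-16)
        assert beta(0.0, sel) == 0.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            alpha(1.2, BALANCING)
        with pytest.raises(ValueError):
            beta(-0.1, BALANCING)

    def test_case2_uses_female_coefficients(self):
        sel = SelectionParams(s_m=-0.02, s_f=0.03, h_m=0.1, h_f=0.7)
        assert alpha(0.3, sel, case=2) == alpha(0.3, case2_swap(sel), case=1)
        assert beta(0.3, sel, case=2) == beta(0.3, case2_swap(sel), case=1)


class TestMeanChange:
    def test_balanced_scheme_vanishes_at_half(self):
        assert mean_change(0.5, BALANCING, MutationRates(1e-6, 1e-6)) == pytest.approx(
            0.0, abs=1e-18
        )

    def test_boundary_mutation_terms(self):
        sel = NEGATIVE
        assert mean_change(0.0, sel, MutationRates(0.0, 3e-6)) == 3e-6
        assert mean_change(1.0, sel, MutationRates(7e-7, 0.0)) == -7e-7

    def test_mutation_only(self):
        sel = SelectionParams(0, 0, 0.5, 0.5)
        assert mean_change(0.25, sel, MutationRates(1e-6, 1e-6)) == pytest.approx(
            5e-7, rel=1e-12
        )

    @given(
        p=st.floats(0.0, 1.0),
        u=st.floats(0.0, 1e-3),
        v=st.floats(0.0, 1e-3),
        h=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_neutral_reduces_to_mutation_pressure(self, p, u, v, h):
        sel = SelectionParams(0.0, 0.0, h, h)
        assert mean_change(p, sel, MutationRates(u, v)) == -u * p + v * (1 - p)


class TestEquilibrium:
    def test_balanced_polymorphism_at_half(self):
        res = equilibrium_p(BALANCING, MUT)
        assert res.p_star == pytest.approx(0.5, abs=1e-12)
        assert not res.multistable

    def test_mutation_balance(self):
        res = equilibrium_p(SelectionParams(0, 0, 0.5, 0.5), MUT)
        assert res.p_star == pytest.approx(0.5, abs=1e-9)

    def test_negative_selection_root_matches_grid_scan(self):
        """Stable root for directional selection against B agrees with a
        brute-force dense sign-change scan of M_p."""
        res = equilibrium_p(NEGATIVE, MUT)
        # oracle: first sign change on a very dense low-end grid
        dense = np.linspace(1e-8, 1e-3, 200_001)
        dv = np.array([mean_change(p, NEGATIVE, MUT) for p in dense])
        i = int(np.nonzero(np.diff(np.sign(dv)))[0][0])
        assert dense[i] <= res.p_star <= dense[i + 1]
        assert res.p_star == pytest.approx(2.0e-4, rel=2e-2)

    def test_root_quality(self):
        res = equilibrium_p(NEGATIVE, MUT)
        assert abs(mean_change(res.p_star, NEGATIVE, MUT)) < 1e-12
        step = 1e-6
        deriv = (
            mean_change(res.p_star + step, NEGATIVE, MUT)
            - mean_change(res.p_star - step, NEGATIVE, MUT)
        ) / (2 * step)
        assert deriv < 0

    def test_multistability_flagged(self):
        # average underdominance: interior root at 1/2 unstable, boundaries
        # held off only by mutation
        sel = SelectionParams(0.02, -0.02, 0.0, 1.0)
        res = equilibrium_p(sel, MUT)
        assert res.multistable
        assert any(not s for s in res.stable)

    def test_no_root_error_names_direction(self):
        sel = SelectionParams(0.02, -0.01, 0.5, 0.5)  # positive selection
        with pytest.raises(ValueError, match="absorbed"):
            equilibrium_p(sel, MutationRates(0.0, 1e-6))


class TestClassifyMode:
    @pytest.mark.parametrize(
        "sel, expected",
        [
            (SelectionParams(0.02, -0.02, 1.0, 0.0), SelectionMode.BALANCING),
            (SelectionParams(0.02, -0.025, 0.5, 0.5), SelectionMode.NEGATIVE),
            (SelectionParams(0.02, -0.01, 0.5, 0.5), SelectionMode.POSITIVE),
            (SelectionParams(0.02, -0.02, 0.5, 0.5), SelectionMode.EQUALIZING),
            (SelectionParams(0.02, -0.02, 0.0, 1.0), SelectionMode.UNCLASSIFIED),
        ],
    )
    def test_reference_schemes(self, sel, expected):
        assert classify_mode(sel) is expected

    def test_agrees_with_bruteforce_ordering(self):
        rng = np.random.default_rng(12345)
        tol = 1e-12
        for _ in range(10_000):
            sel = SelectionParams(
                s_m=rng.uniform(-0.5, 0.5),
                s_f=rng.uniform(-0.5, 0.5),
                h_m=rng.uniform(),
                h_f=rng.uniform(),
            )
            w_bb, w_Bb, w_BB = sel.sex_averaged_fitness()
            mode = classify_mode(sel)
            if abs(w_bb - w_Bb) <= tol and abs(w_Bb - w_BB) <= tol:
                assert mode is SelectionMode.EQUALIZING
            elif w_Bb > w_bb + tol and w_Bb > w_BB + tol:
                assert mode is SelectionMode.BALANCING
            elif w_bb - tol > w_Bb > w_BB + tol:
                assert mode is SelectionMode.NEGATIVE
            elif w_bb + tol < w_Bb < w_BB - tol:
                assert mode is SelectionMode.POSITIVE


class TestCaseSwap:
    def test_involution(self):
        sel = SelectionParams(-0.02, 0.02, 0.1, 0.9)
        assert case2_swap(case2_swap(sel)) == sel

    def test_roles_exchanged(self):
        sel = SelectionParams(s_m=-0.02, s_f=0.02, h_m=0.0, h_f=1.0)
        swapped = case2_swap(sel)
        assert (swapped.s_m, swapped.h_m) == (0.02, 1.0)
        assert (swapped.s_f, swapped.h_f) == (-0.02, 0.0)


class TestValidation:
    def test_config_sign_rules(self):
        with pytest.raises(ValueError, match="case 1"):
            make_config(SelectionParams(-0.01, 0.02, 0.5, 0.5), case=1)
        with pytest.raises(ValueError, match="case 2"):
            make_config(SelectionParams(0.01, -0.02, 0.5, 0.5), case=2)
        # neutral scheme allowed in either case
        make_config(SelectionParams(0, 0, 0.5, 0.5), case=1)

    def test_parameter_ranges(self):
        with pytest.raises(ValueError):
            SelectionParams(0.02, -0.02, 1.5, 0.5)
        with pytest.raises(ValueError):
            SelectionParams(-1.5, 0.0, 0.5, 0.5)  # negative fitness
        with pytest.raises(ValueError):
            MutationRates(1.0, 0.0)
        with pytest.raises(ValueError):
            make_config(BALANCING, N=1)
        with pytest.raises(ValueError):
            make_config(BALANCING, r=0.6)

    def test_mutation_rate_warning(self):
        with pytest.warns(UserWarning, match="second-order"):
            MutationRates(5e-3, 1e-6)

    def test_config_dict_round_trip(self):
        cfg = make_config(BALANCING, N=1234, r=0.01)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg
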