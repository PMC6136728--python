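"""Unit and property tests for the deterministic 1:1 binding heat model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itcfit import (
    ExperimentDesign,
    InvalidDesignError,
    ParameterState,
    R_GAS,
    association_constant,
    complex_concentration,
    mgedta_design,
    model_heats,
)


class TestAssociationConstant:
    def test_zero_free_energy_gives_unity(self):
        assert association_constant(0.0, 298.15) == 1.0

    def test_matches_independent_scalar_arithmetic(self):
        # independent evaluation of exp(10 / (R T))
        expected = math.exp(10.0 / (1.9872e-3 * 298.15))
        assert association_constant(-10.0, 298.15) == pytest.approx(
            expected, rel=1e-12
        )

    def test_inverse_identity_recovers_target_constant(self):
        dG = -R_GAS * 298.15 * math.log(1e6)
        assert association_constant(dG, 298.15) == pytest.approx(1e6, rel=1e-9)

    def test_decreasing_in_free_energy(self):
        ka = [association_constant(dg, 300.0) for dg in (-12.0, -10.0, -8.0)]
        assert ka[0] > ka[1] > ka[2] > 0

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(InvalidDesignError):
            association_constant(-10.0, 0.0)


def _fixed_point_complex(Rtot, Ltot, Ka):
    """Independent oracle: bisection on the mass-action fixed point.

    The root of f(x) = Ka (Rtot-x)(Ltot-x) - x on [0, min(Rtot, Ltot)]
    (f >= 0 at the left end, f <= 0 at the right end, single sign change).
    """
    lo, hi = 0.0, min(Rtot, Ltot)
    f = lambda x: Ka * (Rtot - x) * (Ltot - x) - x
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(mid) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestComplexConcentration:
    @pytest.mark.parametrize("Rtot,Ltot", [(1e-4, 0.0), (0.0, 1e-3)])
    def test_missing_species_gives_zero(self, Rtot, Ltot):
        assert complex_concentration(Rtot, Ltot, 1e6) == 0.0

    def test_matches_fixed_point_oracle_at_reference_point(self):
        rl = complex_concentration(1e-4, 1e-4, 1e6)
        assert rl == pytest.approx(_fixed_point_complex(1e-4, 1e-4, 1e6), rel=1e-10)

    def test_matches_fixed_point_oracle_on_random_triples(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            Rtot = 10.0 ** rng.uniform(-6, -2)
            Ltot = 10.0 ** rng.uniform(-6, -2)
            Ka = 10.0 ** rng.uniform(2, 9)
            assert complex_concentration(Rtot, Ltot, Ka) == pytest.approx(
                _fixed_point_complex(Rtot, Ltot, Ka), rel=1e-10, abs=1e-20
            )

    def test_bounded_and_monotone_in_affinity(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            Rtot = 10.0 ** rng.uniform(-7, -2)
            Ltot = 10.0 ** rng.uniform(-7, -2)
            Ka = 10.0 ** rng.uniform(1, 10)
            lo = complex_concentration(Rtot, Ltot, Ka)
            hi = complex_concentration(Rtot, Ltot, Ka * 10)
            assert 0.0 <= lo <= min(Rtot, Ltot)
            assert hi >= lo

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            complex_concentration(-1e-5, 1e-4, 1e6)


def _oracle_heats(state, design):
    """Independent step-by-step mass balance in moles, plain Python floats."""
    V0 = design.cell_volume
    Ka = math.exp(-state.dG / (R_GAS * design.temperature))
    d = 1.0
    c_prev = 0.0
    heats = []
    for v in design.injection_volumes:
        d *= 1.0 - v / V0
        Rtot = state.R0 * d
        Ltot = state.Ls * (1.0 - d)
        s = Rtot + Ltot + 1.0 / Ka
        c = 0.5 * (s - math.sqrt(s * s - 4.0 * Rtot * Ltot))
        heats.append(V0 * state.dH * 1e3 * (c - c_prev * (1.0 - v / V0)) + state.dH0)
        c_prev = c
    return np.array(heats)


class TestModelHeats:
    def test_zero_enthalpy_gives_zero_heats(self, design):
        state = ParameterState(dG=-10, dH=0.0, dH0=0.0, Ls=1e-3, R0=1e-4, sigma=1e-6)
        assert np.all(model_heats(state, design) == 0.0)

    def test_vanishing_titrant_leaves_only_offset(self, design):
        state = ParameterState(
            dG=-10, dH=-5.0, dH0=0.5e-6, Ls=1e-30, R0=1e-4, sigma=1e-6
        )
        assert np.allclose(model_heats(state, design), 0.5e-6, atol=1e-9)

    def test_matches_independent_mass_balance_oracle(self, design):
        state = ParameterState(
            dG=-10.0, dH=-5.0, dH0=0.5e-6, Ls=1e-3, R0=1e-4, sigma=1e-6
        )
        q = model_heats(state, design)
        assert q == pytest.approx(_oracle_heats(state, design), rel=1e-10)

    def test_oracle_agreement_on_random_parameter_draws(self, design):
        rng = np.random.default_rng(99)
        for _ in range(100):
            state = ParameterState(
                dG=rng.uniform(-14, -5),
                dH=rng.uniform(-20, 20),
                dH0=rng.uniform(-5e-6, 5e-6),
                Ls=10.0 ** rng.uniform(-4, -2),
                R0=10.0 ** rng.uniform(-5, -3),
                sigma=1e-6,
            )
            assert model_heats(state, design) == pytest.approx(
                _oracle_heats(state, design), rel=1e-10, abs=1e-18
            )

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(dH=st.floats(-50, 50), scale=st.floats(0.1, 10))
    def test_reaction_heat_linear_in_enthalpy(self, design, dH, scale):
        base = ParameterState(dG=-10, dH=1.0, dH0=0.3e-6, Ls=1e-3, R0=1e-4, sigma=1e-6)
        q1 = model_heats(base, design) - base.dH0
        state = ParameterState(
            dG=-10, dH=dH * scale, dH0=0.3e-6, Ls=1e-3, R0=1e-4, sigma=1e-6
        )
        q2 = model_heats(state, design) - state.dH0
        assert np.allclose(q2, q1 * dH * scale, rtol=1e-9, atol=1e-20)

    def test_tight_binding_total_heat_matches_equivalents(self):
        # huge titrant excess: essentially all receptor binds in injection 1,
        # so the total evolved heat is dH times the receptor equivalents
        # (the only loss is the sliver of unbound receptor displaced during
        # the first injection itself, ~v1/V0)
        design = mgedta_design(
            first_injection=0.5e-6, stated_titrand=5e-5, stated_titrant=0.2
        )
        dG = -R_GAS * design.temperature * math.log(1e15)
        state = ParameterState(dG=dG, dH=-5.0, dH0=0.0, Ls=0.2, R0=5e-5, sigma=1e-6)
        total = float(np.sum(model_heats(state, design)))
        expected = design.cell_volume * state.dH * 1e3 * state.R0
        assert total == pytest.approx(expected, rel=1e-3)

    def test_injection_as_large_as_cell_rejected(self):
        with pytest.raises(InvalidDesignError):
            ExperimentDesign(
                cell_volume=1e-5,
                injection_volumes=[2e-5],
                temperature=298.15,
                stated_titrand=1e-4,
                stated_titrant=1e-3,
            )

    def test_exponential_dilution_convention_differs(self, design):
        alt = mgedta_design(dilution_model="exponential")
        state = ParameterState(dG=-10, dH=-5.0, dH0=0.0, Ls=1e-3, R0=1e-4, sigma=1e-6)
        q_disp = model_heats(state, design)
        q_exp = model_heats(state, alt)
        assert not np.allclose(q_disp, q_exp)
        # conventions nearly agree where heats are appreciable (v << V0)
        assert np.allclose(q_disp[:10], q_exp[:10], rtol=0.02)
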