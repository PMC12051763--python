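"""Decay-chain arithmetic against independent numerical oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from alphapk import decay
from alphapk.decay import (
    DecayChain,
    bateman_activities,
    biologic_half_life,
    counting_window_correction,
    decay_factor,
    effective_half_life,
    total_emitted_energy,
)


def ode_activities(chain: DecayChain, t: float) -> dict[str, float]:
    """Stiff ODE oracle for the Bateman solution (atom balance, Radau)."""
    members = chain.members
    index = {n.name: i for i, n in enumerate(members)}
    lam = np.array([n.decay_constant for n in members])
    feed = np.zeros((len(members), len(members)))
    for n in members:
        for dname, frac in n.daughters:
            feed[index[dname], index[n.name]] = frac

    def rhs(_, y):
        decays = lam * y
        return -decays + feed @ decays

    y0 = np.zeros(len(members))
    parent = index[chain.parent]
    y0[parent] = chain.initial_activity_MBq / lam[parent]
    sol = solve_ivp(rhs, (0, t), y0, method="Radau", rtol=1e-10, atol=1e-14)
    return {n.name: lam[i] * sol.y[i, -1] for i, n in enumerate(members)}


class TestDecayFactor:
    @pytest.mark.parametrize(
        "half_life, dt, expected",
        [
            (10.64, 10.64, 0.5),  # one physical half-life of Pb-212
            (10.64, 0.0, 1.0),
            (8.0, 40.0, 0.03125),  # five effective half-lives: ~3% retained
        ],
    )
    def test_known_values(self, half_life, dt, expected):
        assert decay_factor(half_life, dt) == pytest.approx(expected)

    def test_rejects_bad_parameters(self):
        with pytest.raises(ValueError):
            decay_factor(0.0, 1.0)
        with pytest.raises(ValueError):
            decay_factor(10.0, -1.0)

    @given(
        st.floats(0.5, 100), st.floats(0, 50), st.floats(0, 50)
    )
    @settings(max_examples=50, deadline=None)
    def test_composes_multiplicatively(self, half_life, a, b):
        assert decay_factor(half_life, a + b) == pytest.approx(
            decay_factor(half_life, a) * decay_factor(half_life, b), rel=1e-12
        )


class TestBateman:
    def test_initial_condition(self):
        acts = bateman_activities(DecayChain("Pb-212", 5.0), 0.0)
        assert acts["Pb-212"] == pytest.approx(5.0)
        assert all(v == 0 for k, v in acts.items() if k != "Pb-212")

    @pytest.mark.parametrize("parent", ["Pb-212", "Ac-225"])
    @pytest.mark.parametrize("n_half_lives", [0.1, 1.0, 5.0, 10.0])
    def test_matches_ode_oracle(self, parent, n_half_lives):
        """Closed form within 0.1% of a stiff ODE integration, relative to
        the initial parent activity."""
        chain = DecayChain(parent, 1.0)
        t = n_half_lives * decay.nuclide(parent).half_life_h
        closed = bateman_activities(chain, t)
        oracle = ode_activities(chain, t)
        for name in closed:
            assert closed[name] == pytest.approx(oracle[name], abs=1e-3)

    def test_transient_equilibrium_ratio(self):
        """A(Bi-212)/A(Pb-212) → λ_Bi/(λ_Bi−λ_Pb) ≈ 1.105 at late times."""
        chain = DecayChain("Pb-212", 1.0)
        lam_pb = decay.nuclide("Pb-212").decay_constant
        lam_bi = decay.nuclide("Bi-212").decay_constant
        expected = lam_bi / (lam_bi - lam_pb)
        acts = bateman_activities(chain, 60.0)
        assert acts["Bi-212"] / acts["Pb-212"] == pytest.approx(expected, rel=1e-4)
        assert expected == pytest.approx(1.105, abs=0.001)

    def test_parent_decays_conserve_atoms(self):
        """∫λ·A dt over all time equals the initial number of parent atoms."""
        nuc = decay.nuclide("Pb-212")
        a0 = 1.0
        n0 = a0 / nuc.decay_constant
        integral, _ = quad(
            lambda t: a0 * math.exp(-nuc.decay_constant * t), 0, np.inf
        )
        assert integral == pytest.approx(n0, rel=1e-9)

    def test_activities_nonnegative(self):
        for t in (0.0, 0.5, 3.0, 25.0, 100.0):
            assert all(v >= 0 for v in bateman_activities(DecayChain("Ac-225"), t).values())


class TestCountingWindow:
    def window_oracle(self, delay, duration, half_life):
        """Numerical integration of activity over the counting window."""
        lam = decay.LN2 / half_life
        avg, _ = quad(lambda t: math.exp(-lam * t), delay, delay + duration)
        return duration / avg

    @pytest.mark.parametrize(
        "delay, duration",
        [(12.0, 2.0 / 3.0), (0.0, 1.0), (24.0, 0.5), (5.0, 3.0)],
    )
    def test_matches_quadrature_oracle(self, delay, duration):
        assert counting_window_correction(delay, duration, 10.64) == pytest.approx(
            self.window_oracle(delay, duration, 10.64), rel=1e-6
        )

    def test_protocol_window_value(self):
        """40 min acquisition 12 h after sampling needs a ≈2.23 correction."""
        assert counting_window_correction(12.0, 2.0 / 3.0, 10.64) == pytest.approx(
            2.233, abs=0.001
        )

    def test_limits_and_monotonicity(self):
        assert counting_window_correction(0.0, 1e-9, 10.64) == pytest.approx(1.0)
        delays = np.linspace(0, 30, 40)
        factors = [counting_window_correction(d, 0.5, 10.64) for d in delays]
        assert all(np.diff(factors) > 0)
        durations = np.linspace(0.01, 10, 40)
        factors = [counting_window_correction(1.0, d, 10.64) for d in durations]
        assert all(np.diff(factors) > 0)

    def test_delay_factor_is_exponential(self):
        lam = decay.LN2 / 10.64
        f1 = counting_window_correction(6.0, 0.5, 10.64)
        f2 = counting_window_correction(12.0, 0.5, 10.64)
        assert f2 / f1 == pytest.approx(math.exp(lam * 6.0), rel=1e-12)


class TestEmittedEnergy:
    def test_empty_kind_set(self):
        assert total_emitted_energy(DecayChain("Pb-212"), ()) == 0.0

    def test_alpha_budget_hand_sum(self):
        """One α per ²¹²Pb decay: 0.36·6.06 + 0.64·8.785 ≈ 7.8 MeV."""
        expected = 0.3594 * 6.060 + 0.6406 * 8.785
        got = total_emitted_energy(DecayChain("Pb-212"), ("alpha",))
        assert got == pytest.approx(expected, rel=1e-6)
        assert got == pytest.approx(7.8, abs=0.05)

    def test_chain_energy_ratio(self):
        """²²⁵Ac chain emits ≈3.2× the α+β energy of the ²¹²Pb chain."""
        ratio = total_emitted_energy(DecayChain("Ac-225")) / total_emitted_energy(
            DecayChain("Pb-212")
        )
        assert round(ratio, 1) == 3.2

    def test_unknown_nuclide_is_named(self):
        with pytest.raises(decay.NuclideDataError, match="Xx-999"):
            decay.nuclide("Xx-999")


class TestHalfLifeAlgebra:
    def test_rate_addition_identity(self):
        t_eff = effective_half_life(10.64, 32.2)
        assert 1 / t_eff == pytest.approx(1 / 10.64 + 1 / 32.2, rel=1e-12)

    def test_inverse_round_trip(self):
        t_bio = biologic_half_life(8.0, 10.64)
        assert t_bio == pytest.approx(32.2, abs=0.1)
        assert effective_half_life(10.64, t_bio) == pytest.approx(8.0, rel=1e-12)

    def test_ac225_effective_half_life(self):
        """10 d physical with the fitted 32.2 h biologic gives ≈28.4 h."""
        assert effective_half_life(240.0, biologic_half_life(8.0, 10.64)) == pytest.approx(
            28.4, abs=0.05
        )

    def test_infinite_biologic_limit(self):
        assert effective_half_life(10.64, 1e12) == pytest.approx(10.64, rel=1e-9)

    def test_inverse_requires_teff_below_tphys(self):
        with pytest.raises(ValueError):
            biologic_half_life(10.64, 10.64)
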