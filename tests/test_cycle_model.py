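"""Cycle-level physics: rate laws, thermodynamic consistency, steady states,
fluxes, velocity, stall and occupancy crossovers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from myo1c import (CycleParameters, Conditions, ParameterError, RateSet,
                   NoCrossingError, force_factor, transition_rates, rates_at,
                   gibbs_free_energy, balance_atp_release, steady_state,
                   steady_state_nullspace, excess_flux, cycle_flux,
                   effective_velocity, stall_force,
                   occupancy_summaries, dominance_crossings,
                   dominance_crossing_force)

from conftest import random_rateset, random_balanced_system

EDGES = ((1, 2), (2, 3), (3, 4), (4, 5), (5, 1))


def equilibrium_conditions(params, actin=100.0, adp=1000.0):
    """Concentrations with [ADP][Pi]/[ATP] = Keq: zero free energy."""
    atp = 1.0
    pi = params.keq_uM * atp / adp
    return Conditions(atp=atp, adp=adp, pi=pi, actin=actin, force=0.0)


# ---------------------------------------------------------------------------
# g(F)

def test_force_factor_reference_points(table1):
    assert force_factor(table1, 0.0) == pytest.approx(1.0, abs=1e-15)
    assert force_factor(table1, 1e4) == pytest.approx(table1.omega_off,
                                                      rel=1e-12)
    # direct arithmetic at F = kBT/xi (exponent exactly 1)
    f_char = table1.kBT / table1.xi
    expected = 2.0 * (1.0 - 0.001) / (1.0 + np.e) + 0.001
    assert force_factor(table1, f_char) == pytest.approx(expected, rel=1e-14)


def test_force_factor_monotone_and_bounded(table1):
    F = np.linspace(-6.0, 6.0, 1201)
    g = force_factor(table1, F)
    assert np.all(np.diff(g) < 0)
    wide = force_factor(table1, np.linspace(-40.0, 40.0, 4001))
    assert np.all(wide > table1.omega_off - 1e-15)
    assert np.all(wide < 2.0 - table1.omega_off + 1e-15)
    # assisting loads are not clipped
    assert force_factor(table1, -30.0) > 1.9


@settings(derandomize=True, max_examples=60, deadline=None)
@given(f=st.floats(-6.0, 6.0), step=st.floats(0.01, 6.0))
def test_force_factor_strictly_decreasing_property(f, step):
    params = CycleParameters()
    assert force_factor(params, f + step) < force_factor(params, f)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(c=st.floats(1.1, 50.0))
def test_gibbs_log_additivity_property(c):
    """Scaling [ATP] by c adds exactly kBT ln c to the free energy."""
    params = CycleParameters()
    base = Conditions(atp=800.0, adp=15.0, pi=900.0)
    more = Conditions(atp=c * 800.0, adp=15.0, pi=900.0)
    assert gibbs_free_energy(params, more) - gibbs_free_energy(
        params, base) == pytest.approx(params.kBT * np.log(c), rel=1e-10)


# ---------------------------------------------------------------------------
# transition rates

def test_rates_match_scalar_formulas(table1, phys):
    """Each rate equals an independent scalar evaluation of its law at 2 pN."""
    p, F = table1, 2.0
    r = transition_rates(p, phys.with_force(F))
    kBT = p.kBT
    g = 2 * (1 - p.omega_off) / (1 + np.exp(p.xi * F / kBT)) + p.omega_off
    assert r.w23 == pytest.approx(
        p.w23_0 * np.exp(-p.delta1 * F * p.dx1 / kBT), rel=1e-14)
    assert r.w32 == pytest.approx(
        p.w32_hat * phys.pi * np.exp((1 - p.delta1) * F * p.dx1 / kBT),
        rel=1e-14)
    assert r.w34 == pytest.approx(
        p.w34_0 * np.exp(-p.delta2 * F * p.dx2 / kBT), rel=1e-14)
    assert r.w43 == pytest.approx(
        p.w43_hat * phys.adp * np.exp((1 - p.delta2) * F * p.dx2 / kBT),
        rel=1e-14)
    assert r.w45 == pytest.approx(p.w45_hat * phys.atp, rel=1e-14)
    assert r.w51 == pytest.approx(g * p.w51_0, rel=1e-14)
    assert r.w54 == pytest.approx(g * p.w54_0, rel=1e-14)
    assert r.w12 == pytest.approx(p.w12_hat * phys.actin, rel=1e-14)
    assert r.w15 == pytest.approx(p.w15_hat * phys.actin, rel=1e-14)
    assert r.w21 == p.w21


def test_adp_binding_detailed_balance_point(table1):
    """At [ADP] = K_ADP = 1.8 uM and F = 0, ADP binding balances release."""
    r = transition_rates(table1, Conditions(adp=1.8, force=0.0))
    assert r.w43 == pytest.approx(table1.w34_0, rel=0.01)


def test_rates_linear_in_concentrations(table1):
    r = transition_rates(table1, Conditions(atp=0, adp=0, pi=0, actin=0))
    assert r.w32 == r.w43 == r.w45 == r.w12 == r.w15 == 0.0
    assert r.w21 == table1.w21 and r.w23 == table1.w23_0


# ---------------------------------------------------------------------------
# free energy, balance and the thermodynamic identity

def test_gibbs_free_energy_values(table1, phys):
    eq = equilibrium_conditions(table1)
    assert gibbs_free_energy(table1, eq) == pytest.approx(0.0, abs=1e-9)
    # physiological: kBT ln(4.9e10)
    assert gibbs_free_energy(table1, phys) == pytest.approx(
        table1.kBT * np.log(4.9e10), rel=1e-12)
    doubled = Conditions(atp=2 * phys.atp, adp=phys.adp, pi=phys.pi)
    assert gibbs_free_energy(table1, doubled) - gibbs_free_energy(
        table1, phys) == pytest.approx(table1.kBT * np.log(2), rel=1e-12)


def test_gibbs_rejects_zero_concentrations(table1):
    with pytest.raises(ParameterError):
        gibbs_free_energy(table1, Conditions(atp=0.0))


def test_balance_rate_from_branch_probability(table1):
    """With the actin-binding ratio pi2/(1-pi2) = 499 the balance gives
    the literature ATP-release rate 3.04 1/s."""
    p = CycleParameters().replace(w12_hat=499.0 * 0.0015)
    assert balance_atp_release(p) == pytest.approx(3.04, rel=0.02)


def test_balance_homogeneity(table1):
    base = balance_atp_release(table1)
    assert balance_atp_release(
        table1.replace(w23_0=3 * table1.w23_0)) == pytest.approx(
        3 * base, rel=1e-12)
    # scaling all forward and all reverse constants by c scales by c
    c = 2.0
    scaled = table1.replace(
        w12_hat=c * table1.w12_hat, w23_0=c * table1.w23_0,
        w34_0=c * table1.w34_0, w45_hat=c * table1.w45_hat,
        w51_0=c * table1.w51_0, w21=c * table1.w21,
        w32_hat=c * table1.w32_hat, w43_hat=c * table1.w43_hat,
        w15_hat=c * table1.w15_hat)
    assert balance_atp_release(scaled) == pytest.approx(c * base, rel=1e-12)


def cycle_ratio(r: RateSet) -> float:
    fwd = r.w12 * r.w23 * r.w34 * r.w45 * r.w51
    rev = r.w21 * r.w32 * r.w43 * r.w54 * r.w15
    return fwd / rev


def test_thermodynamic_identity_random_systems(table1):
    """Forward/backward cycle-rate ratio equals exp((dmu - F dx)/kBT)
    for 100 random balanced parameter/condition draws."""
    rng = np.random.default_rng(2024)
    for _ in range(100):
        params, cond = random_balanced_system(rng)
        r = transition_rates(params, cond)
        dmu = gibbs_free_energy(params, cond)
        expected = np.exp((dmu - (params.dx1 + params.dx2) * cond.force)
                          / params.kBT)
        assert cycle_ratio(r) == pytest.approx(expected, rel=1e-8)


def test_identity_exact_at_single_force(table1, phys):
    r = transition_rates(table1, phys.with_force(1.7))
    dmu = gibbs_free_energy(table1, phys)
    expected = np.exp((dmu - (table1.dx1 + table1.dx2) * 1.7) / table1.kBT)
    assert cycle_ratio(r) == pytest.approx(expected, rel=1e-10)


# ---------------------------------------------------------------------------
# steady state

def test_uniform_for_symmetric_chain():
    r = RateSet(**{n: 2.5 for n in
                   ("w12", "w15", "w21", "w23", "w32",
                    "w34", "w43", "w45", "w51", "w54")})
    assert steady_state(r).p == pytest.approx(np.full(5, 0.2), abs=1e-14)


def test_closed_form_matches_nullspace_and_master_equation():
    rng = np.random.default_rng(7)
    for _ in range(100):
        r = random_rateset(rng)
        dist = steady_state(r)
        alt = steady_state_nullspace(r)
        assert dist.p == pytest.approx(alt.p, abs=1e-9)
        # stationary master equation residual
        residual = dist.p @ r.generator()
        assert np.max(np.abs(residual)) < 1e-10 * max(
            float(np.max(r.generator())), 1.0)
        assert dist.p.sum() == pytest.approx(1.0, abs=1e-12)


def test_degenerate_chain_masses_on_detached_state(table1):
    dist = steady_state(transition_rates(table1, Conditions(actin=0.0)))
    assert dist.degenerate
    assert dist.p == pytest.approx([1, 0, 0, 0, 0], abs=1e-15)


def test_adp_and_atp_state_crossover_near_printed_force(table1, phys):
    dist = steady_state(rates_at(table1, phys, 1.5))
    # ADP (3) and ATP (5) occupancies cross close to 1.5 pN
    assert dist[3] == pytest.approx(dist[5], rel=0.1)


# ---------------------------------------------------------------------------
# fluxes and velocity

def test_fluxes_vanish_at_equilibrium(table1):
    eq = equilibrium_conditions(table1)
    r = transition_rates(table1, eq)
    dist = steady_state(r)
    scale = max(dist[i] * r.rate(i, j) for i, j in EDGES)
    for edge in EDGES:
        assert abs(excess_flux(dist, r, edge)) < 1e-10 * scale


def test_single_loop_flux_equality(table1, phys):
    r = transition_rates(table1, phys.with_force(1.0))
    dist = steady_state(r)
    fluxes = [excess_flux(dist, r, e) for e in EDGES]
    assert fluxes == pytest.approx([fluxes[0]] * 5, rel=1e-9)
    assert fluxes[0] > 0  # forward cycling under physiological drive


def test_velocity_consistent_with_cycle_flux(table1, phys):
    r = transition_rates(table1, phys)
    j = cycle_flux(steady_state(r), r)
    assert effective_velocity(table1, phys) == pytest.approx(
        (table1.dx1 + table1.dx2) * j, rel=1e-12)


def test_velocity_zero_at_stall_and_equilibrium(table1, phys):
    fs = stall_force(table1, phys)
    v_scale = abs(effective_velocity(table1, phys))
    assert abs(effective_velocity(table1, phys.with_force(fs))) \
        < 1e-10 * v_scale
    # sign change around stall
    assert effective_velocity(table1, phys.with_force(fs - 0.1)) > 0
    assert effective_velocity(table1, phys.with_force(fs + 0.1)) < 0
    eq = equilibrium_conditions(table1)
    assert abs(effective_velocity(table1, eq)) < 1e-12 * v_scale


def test_velocity_monotone_and_saturating_in_actin(table1):
    actins = np.array([10.0, 100.0, 1000.0, 10000.0])
    v = np.array([effective_velocity(
        table1, Conditions.physiological(actin=a)) for a in actins])
    assert np.all(np.diff(v) > 0)
    # saturation above ~1 mM: a further tenfold actin gains <15%
    assert (v[3] - v[2]) / v[2] < 0.15


def test_stall_force_values(table1, phys):
    dmu = gibbs_free_energy(table1, phys)
    fs = stall_force(table1, phys)
    assert fs == pytest.approx(dmu / 7.8, rel=1e-12)
    assert fs == pytest.approx(12.6, rel=0.01)
    wide = table1.replace(dx1=2 * table1.dx1, dx2=2 * table1.dx2)
    assert stall_force(wide, phys) == pytest.approx(fs / 2, rel=1e-12)
    # reversed chemistry warns and returns non-positive stall
    rev = Conditions(atp=1e-6, adp=1e6, pi=1e6)
    with pytest.warns(UserWarning):
        assert stall_force(table1, rev) <= 0


# ---------------------------------------------------------------------------
# occupancy summaries and dominance crossings

def test_occupancy_summaries_basics():
    from myo1c import StateDistribution
    assert occupancy_summaries(StateDistribution(
        np.array([1.0, 0, 0, 0, 0]))) == (0.0, 0.0)
    p_sb, p_on = occupancy_summaries(StateDistribution(np.full(5, 0.2)))
    assert (p_sb, p_on) == (pytest.approx(0.6), pytest.approx(0.8))


def test_high_actin_saturates_attachment_not_strong_binding(table1):
    cond = Conditions.physiological(actin=10000.0).with_force(1.0)
    p_sb, p_on = occupancy_summaries(steady_state(transition_rates(
        table1, cond)))
    assert p_on > 0.98
    assert p_sb < 0.9
    assert p_on >= p_sb
    # attachment approaches unity with yet more actin; strong binding
    # stays limited by phosphate release
    richer = Conditions.physiological(actin=100000.0).with_force(1.0)
    p_sb2, p_on2 = occupancy_summaries(steady_state(transition_rates(
        table1, richer)))
    assert p_on2 > 0.995
    assert p_sb2 < 0.9


def test_dominance_crossing_location(table1, phys):
    root = dominance_crossing_force(table1, phys)
    assert 1.0 < root < 2.0
    dist = steady_state(rates_at(table1, phys, root))
    assert dist[3] == pytest.approx(dist[5], rel=1e-2)


def test_elevated_adp_gives_two_crossings(table1):
    cond = Conditions(atp=1000.0, adp=250.0, pi=1000.0, actin=100.0)
    roots = dominance_crossings(table1, cond)
    assert len(roots) == 2
    assert roots[0] < 3.0 < roots[1] < 6.0


def test_no_crossing_without_atp_binding(table1, phys):
    p = table1.replace(w45_hat=0.0)
    with pytest.raises(NoCrossingError):
        dominance_crossing_force(p, phys)
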