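"""Absorbing-state attachment statistics: entry probabilities, strong-state
unbinding, weak-state time, filament detachment — against independent
first-passage oracles and invariance properties."""

import numpy as np
import pytest

from myo1c import (Conditions, RateSet, entry_probabilities,
                   strong_unbinding_rate, weak_time, filament_unbinding_rate,
                   first_passage_summary, unbinding_curve, transition_rates,
                   steady_state, occupancy_summaries)
from myo1c.first_passage import (tsb_inv_from_rates, koff_from_rates,
                                 tsb_inv_closed_form, koff_closed_form,
                                 mean_absorption_time, _pi2, _pi3)

from conftest import random_rateset


def strong_subchain_generator(r: RateSet) -> np.ndarray:
    """Sub-generator over the transient strong states (3, 4, 5); the
    absorbing routes are 3->2 (w32) and 5->1 (w51)."""
    return np.array([
        [-(r.w32 + r.w34), r.w34, 0.0],
        [r.w43, -(r.w43 + r.w45), r.w45],
        [0.0, r.w54, -(r.w54 + r.w51)],
    ], dtype=float)


def attached_subchain_generator(r: RateSet) -> np.ndarray:
    """Sub-generator over the attached states (2..5); absorption is 2->1
    (w21) and 5->1 (w51)."""
    return np.array([
        [-(r.w21 + r.w23), r.w23, 0.0, 0.0],
        [r.w32, -(r.w32 + r.w34), r.w34, 0.0],
        [0.0, r.w43, -(r.w43 + r.w45), r.w45],
        [0.0, 0.0, r.w54, -(r.w54 + r.w51)],
    ], dtype=float)


# ---------------------------------------------------------------------------
# entry probabilities

def test_pi2_values(table1, phys):
    pi2, _ = entry_probabilities(table1, phys)
    assert pi2 == pytest.approx(0.76 / 0.7615, rel=1e-12)
    assert pi2 == pytest.approx(0.998, abs=5e-4)
    even = table1.replace(w12_hat=0.3, w15_hat=0.3)
    assert entry_probabilities(even, phys)[0] == pytest.approx(0.5)


def test_pi3_zero_without_phosphate_release(table1, phys):
    _, pi3 = entry_probabilities(table1.replace(w23_0=0.0), phys)
    assert pi3 == 0.0


# ---------------------------------------------------------------------------
# strong-state unbinding rate

def test_no_exit_gives_zero_rate():
    r = random_rateset(np.random.default_rng(1))
    r0 = RateSet(**{**{n: getattr(r, n) for n in r.__dataclass_fields__},
                    "w32": 0.0, "w51": 0.0, "w54": 0.0})
    assert tsb_inv_from_rates(r0, pi3=0.7) == 0.0


def test_irreversible_limit_matches_sequential_formula():
    """With instant ATP-state exit and no re-entry routes the strong-state
    lifetime reduces to (w34 + w43 + w45)/(w34 w45)."""
    w34, w43, w45 = 3.9, 21.7, 260.0
    r = RateSet(w12=1.0, w15=0.0, w21=164.0, w23=1.5, w32=0.0,
                w34=w34, w43=w43, w45=w45, w51=1e6, w54=0.0)
    rate = tsb_inv_from_rates(r, pi3=1.0)
    assert rate == pytest.approx(w34 * w45 / (w34 + w43 + w45), rel=0.01)


def test_closed_diagram_equals_printed_form_and_oracle():
    """Closed-diagram solve == printed closed form == inverse mean
    absorption time from the fundamental matrix, on 200 random rate sets."""
    rng = np.random.default_rng(11)
    for _ in range(200):
        r = random_rateset(rng)
        dist = steady_state(r)
        pi3 = float(_pi3(r))
        by_solve = tsb_inv_from_rates(r, pi3)
        by_form = float(tsb_inv_closed_form(r))
        start = np.array([pi3, 0.0, 1.0 - pi3])
        by_oracle = 1.0 / mean_absorption_time(
            strong_subchain_generator(r), start)
        assert by_solve == pytest.approx(by_form, rel=1e-8)
        assert by_solve == pytest.approx(by_oracle, rel=1e-8)


def test_strong_unbinding_invariant_to_actin_and_binding_scale(table1, phys):
    base = strong_unbinding_rate(table1, phys)
    rich = Conditions.physiological(actin=10000.0)
    assert strong_unbinding_rate(table1, rich) == pytest.approx(
        base, rel=1e-10)
    # only the ratio of the actin-binding constants matters
    scaled = table1.replace(w12_hat=50 * table1.w12_hat,
                            w15_hat=50 * table1.w15_hat)
    assert strong_unbinding_rate(scaled, phys) == pytest.approx(
        base, rel=1e-10)


def test_catch_bond_shape_of_unbinding_curve(table1):
    """Plateau near zero force, then a drop into the catch regime."""
    cond = Conditions(atp=5000.0, adp=0.1, pi=0.1, actin=100.0)
    F = np.array([0.0, 0.25, 2.0, 4.0])
    rate = unbinding_curve(table1, cond, F, quantity="tsb")
    assert rate[1] / rate[0] > 0.9          # plateau
    assert rate[2] < 0.5 * rate[0]          # catch-bond drop by 2 pN
    assert rate[3] < rate[2]


# ---------------------------------------------------------------------------
# weak/detached time

def test_weak_time_consistent_with_occupancy(table1, phys):
    """t_sb/(t_sb + t_wb) equals the strong-state occupancy P_sb."""
    for F in (0.0, 1.0, 3.0):
        cond = phys.with_force(F)
        t_sb = 1.0 / strong_unbinding_rate(table1, cond)
        t_wb = weak_time(table1, cond)
        p_sb, _ = occupancy_summaries(steady_state(transition_rates(
            table1, cond)))
        assert t_sb / (t_sb + t_wb) == pytest.approx(p_sb, abs=1e-10)


def test_weak_time_infinite_without_strong_binding(table1, phys):
    blocked = table1.replace(w23_0=0.0, w15_hat=0.0)
    assert weak_time(blocked, phys) == np.inf


# ---------------------------------------------------------------------------
# filament detachment rate

def test_koff_matches_printed_form_and_oracle():
    rng = np.random.default_rng(13)
    for _ in range(200):
        r = random_rateset(rng)
        pi2 = float(_pi2(r))
        by_solve = koff_from_rates(r, pi2)
        by_form = float(koff_closed_form(r))
        start = np.array([pi2, 0.0, 0.0, 1.0 - pi2])
        by_oracle = 1.0 / mean_absorption_time(
            attached_subchain_generator(r), start)
        assert by_solve == pytest.approx(by_form, rel=1e-8)
        assert by_solve == pytest.approx(by_oracle, rel=1e-8)


def test_koff_invariant_to_actin(table1):
    lean = Conditions.physiological(actin=1.0).with_force(1.5)
    rich = Conditions.physiological(actin=10000.0).with_force(1.5)
    assert filament_unbinding_rate(table1, lean) == pytest.approx(
        filament_unbinding_rate(table1, rich), rel=1e-12)


def test_attachment_renewal_identity(table1):
    """P_on = k_on/(k_on + k_off): mean on/off times against the full-cycle
    steady state."""
    for actin, F in ((100.0, 0.0), (1000.0, 2.0), (50.0, 4.0)):
        cond = Conditions.physiological(actin=actin).with_force(F)
        k_on = (table1.w12_hat + table1.w15_hat) * actin
        k_off = filament_unbinding_rate(table1, cond)
        _, p_on = occupancy_summaries(steady_state(transition_rates(
            table1, cond)))
        assert k_on / (k_on + k_off) == pytest.approx(p_on, abs=1e-10)


def test_first_passage_summary_is_consistent(table1, phys):
    res = first_passage_summary(table1, phys.with_force(2.0))
    cond = phys.with_force(2.0)
    assert res.t_sb_inv == pytest.approx(
        strong_unbinding_rate(table1, cond), rel=1e-12)
    assert res.k_off == pytest.approx(
        filament_unbinding_rate(table1, cond), rel=1e-12)
    assert res.t_wb == pytest.approx(weak_time(table1, cond), rel=1e-12)
    assert res.p_strong.sum() == pytest.approx(1.0, abs=1e-12)
    assert res.s_attached.sum() == pytest.approx(1.0, abs=1e-12)
    assert 0.0 <= res.pi3 <= 1.0


# ---------------------------------------------------------------------------
# stochastic cross-check

def test_simulated_dwells_match_strong_state_lifetime(table1,
                                                      single_head_clamp):
    """Mean strongly-bound sojourn of a clamped single-head simulation
    agrees with the analytic 1/t_sb_inv within 3 standard errors."""
    cond, _, dwells = single_head_clamp
    assert dwells.size > 9000
    model = 1.0 / strong_unbinding_rate(table1, cond)
    se = dwells.std(ddof=1) / np.sqrt(dwells.size)
    assert abs(dwells.mean() - model) < 3.0 * se
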