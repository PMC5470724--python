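"""Steady-state analysis of the five-state myosin Ic cross-bridge cycle.

The cycle is a single-loop continuous-time Markov chain over a detached
state (1), a weakly bound ADP·Pi state (2), and three strongly bound
states: ADP (3), nucleotide-free (4) and ATP (5).  Transition rates carry
the force dependence of the two power strokes (through force-distribution
factors ``delta1``/``delta2``), the catch-bond force factor ``g(F)`` of
the ATP-state exits, and linear dependencies on nucleotide and actin
concentrations.  Thermodynamic consistency ties the ATP-release rate to
the remaining constants, so a full forward cycle dissipates exactly
``Δμ − (Δx1+Δx2)F``.

All functions broadcast over numpy arrays of force, which keeps force
sweeps (crossing searches, unbinding curves, fits) vectorised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .parameters import (CycleParameters, Conditions, ParameterError,
                         balanced_atp_release_rate)

__all__ = [
    "RateSet",
    "StateDistribution",
    "force_factor",
    "transition_rates",
    "gibbs_free_energy",
    "balance_atp_release",
    "steady_state",
    "steady_state_nullspace",
    "excess_flux",
    "cycle_flux",
    "effective_velocity",
    "stall_force",
    "occupancy_summaries",
    "dominance_crossings",
    "dominance_crossing_force",
    "NoCrossingError",
]

#: largest magnitude allowed in exponents of the force laws; beyond this
#: the strain is capped to keep every rate finite.
_EXP_CAP = 500.0

_EDGES = ((1, 2), (1, 5), (2, 1), (2, 3), (3, 2),
          (3, 4), (4, 3), (4, 5), (5, 1), (5, 4))


def _capped_exp(x):
    return np.exp(np.clip(x, -_EXP_CAP, _EXP_CAP))


def force_factor(params: CycleParameters, force) -> np.ndarray | float:
    """Catch-bond force factor ``g(F)`` of the ATP-state exit rates.

    ``g(F) = 2(1 − ω_off)/(1 + exp(ξF/kBT)) + ω_off``: equal to 1 at zero
    force, monotonically decreasing, saturating at ``ω_off`` for large
    resisting load and at ``2 − ω_off`` for strong assisting load.
    """
    x = _capped_exp(np.asarray(force, dtype=float) * params.xi / params.kBT)
    g = 2.0 * (1.0 - params.omega_off) / (1.0 + x) + params.omega_off
    return float(g) if np.ndim(force) == 0 else g


@dataclass(frozen=True)
class RateSet:
    """The ten pairwise transition rates of the cycle, in 1/s.

    Fields may be scalars or broadcast-compatible numpy arrays (a force
    sweep evaluates all ten rates on the grid at once).
    """

    w12: float | np.ndarray
    w15: float | np.ndarray
    w21: float | np.ndarray
    w23: float | np.ndarray
    w32: float | np.ndarray
    w34: float | np.ndarray
    w43: float | np.ndarray
    w45: float | np.ndarray
    w51: float | np.ndarray
    w54: float | np.ndarray

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            value = np.asarray(getattr(self, name))
            if np.any(value < 0) or not np.all(np.isfinite(value)):
                raise ParameterError(f"rate {name} must be finite and >= 0")

    def rate(self, i: int, j: int):
        """Rate of the i -> j transition (zero for non-adjacent states)."""
        return getattr(self, f"w{i}{j}") if (i, j) in _EDGES else 0.0

    def generator(self) -> np.ndarray:
        """5x5 generator matrix Q with ``Q[i, j]`` the rate (i+1) -> (j+1).

        Scalar rates only; rows sum to zero.
        """
        Q = np.zeros((5, 5))
        for (i, j) in _EDGES:
            Q[i - 1, j - 1] = float(self.rate(i, j))
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q


def transition_rates(params: CycleParameters, cond: Conditions) -> RateSet:
    """Evaluate all ten transition rates at the given force and chemistry.

    The stroke-coupled pairs split the work ``F·dx`` between forward and
    reverse rates via the force-distribution factors; nucleotide- and
    actin-binding rates are linear in the respective concentrations; the
    ATP-state exits (5→1 and 5→4) share the catch-bond factor ``g(F)``.
    """
    return rates_at(params, cond, cond.force)


def rates_at(params: CycleParameters, cond: Conditions, force) -> RateSet:
    """Like :func:`transition_rates` but with force overridden (broadcasts)."""
    F = np.asarray(force, dtype=float)
    if F.ndim == 0:
        F = float(F)
    kBT = params.kBT
    g = force_factor(params, F)
    return RateSet(
        w12=params.w12_hat * cond.actin,
        w15=params.w15_hat * cond.actin,
        w21=params.w21,
        w23=params.w23_0 * _capped_exp(-params.delta1 * F * params.dx1 / kBT),
        w32=params.w32_hat * cond.pi
        * _capped_exp((1.0 - params.delta1) * F * params.dx1 / kBT),
        w34=params.w34_0 * _capped_exp(-params.delta2 * F * params.dx2 / kBT),
        w43=params.w43_hat * cond.adp
        * _capped_exp((1.0 - params.delta2) * F * params.dx2 / kBT),
        w45=params.w45_hat * cond.atp,
        w51=g * params.w51_0,
        w54=g * params.w54_0,
    )


def gibbs_free_energy(params: CycleParameters, cond: Conditions) -> float:
    """Free energy Δμ of ATP hydrolysis at the given concentrations, pN·nm.

    ``Δμ = kBT·ln([ATP]·Keq / ([ADP][Pi]))`` with all concentrations in μM
    and ``Keq`` converted to μM.  Vanishes exactly at chemical equilibrium.
    """
    if cond.atp <= 0 or cond.adp <= 0 or cond.pi <= 0:
        raise ParameterError(
            "gibbs_free_energy requires strictly positive ATP, ADP and Pi "
            f"concentrations (got {cond.atp}, {cond.adp}, {cond.pi} μM)")
    return params.kBT * np.log(cond.atp * params.keq_uM / (cond.adp * cond.pi))


def balance_atp_release(params: CycleParameters,
                        cond: Conditions | None = None) -> float:
    """Force-free ATP-release rate implied by thermodynamic consistency.

    Independent of every concentration (the actin-binding rates enter only
    as a ratio), hence the unused ``cond`` argument kept for interface
    symmetry.
    """
    return balanced_atp_release_rate(params)


@dataclass(frozen=True)
class StateDistribution:
    """Steady-state probabilities P1..P5 of the cycle states.

    ``p`` has shape (5,) or (5, ...) for vectorised force sweeps.
    ``degenerate`` marks a reducible chain (no route off state 1), in
    which case all mass sits on state 1.
    """

    p: np.ndarray
    degenerate: bool = False

    def __post_init__(self):
        object.__setattr__(self, "p", np.asarray(self.p, dtype=float))
        if self.p.shape[0] != 5:
            raise ParameterError("state distribution must have 5 entries")
        total = self.p.sum(axis=0)
        if np.any(np.abs(total - 1.0) > 1e-9) or np.any(self.p < -1e-12):
            raise ParameterError("state probabilities must be normalised")

    def __getitem__(self, state: int):
        """Probability of state ``state`` (1-based, as in the cycle diagram)."""
        return self.p[state - 1]


def _spanning_tree_weights(r: RateSet) -> np.ndarray:
    """Unnormalised stationary weights (matrix-tree sums) for each state."""
    w12, w15, w21, w23, w32 = r.w12, r.w15, r.w21, r.w23, r.w32
    w34, w43, w45, w51, w54 = r.w34, r.w43, r.w45, r.w51, r.w54
    n1 = w23 * w34 * w45 * w51 + w21 * (
        w34 * w45 * w51 + w32 * (w43 + w45) * w51 + w32 * w43 * w54)
    n2 = w12 * (w34 * w45 + w32 * (w43 + w45)) * w51 \
        + (w12 + w15) * w32 * w43 * w54
    n3 = w15 * (w21 + w23) * w43 * w54 \
        + w12 * w23 * (w45 * w51 + w43 * (w51 + w54))
    n4 = w15 * (w23 * w34 + w21 * (w32 + w34)) * w54 \
        + w12 * w23 * w34 * (w51 + w54)
    n5 = w12 * w23 * w34 * w45 + w15 * (
        w21 * w32 * w43 + w23 * w34 * w45 + w21 * (w32 + w34) * w45)
    return np.array(np.broadcast_arrays(n1, n2, n3, n4, n5))


def steady_state(rates: RateSet) -> StateDistribution:
    """Stationary distribution of the cycle from the closed-form solution.

    Uses the spanning-tree (King–Altman) numerators with the shared
    normalisation.  If the chain cannot leave state 1 (``w12 + w15 = 0``)
    it is reducible; the distribution degenerates to all mass on state 1.
    """
    weights = _spanning_tree_weights(rates)
    norm = weights.sum(axis=0)
    if np.all(np.asarray(rates.w12) + np.asarray(rates.w15) == 0.0) \
            and not np.any(norm == 0):
        # actin-free chain: state 1 is absorbing; the spanning-tree form
        # still lands all mass there, but the chain is reducible
        return StateDistribution(p=weights / norm, degenerate=True)
    if np.any(norm == 0):
        # reducible chain (typically actin = 0): park all mass on state 1
        p = np.zeros_like(weights)
        p[0] = 1.0
        if np.ndim(norm) > 0:
            mask = norm > 0
            p[:, mask] = weights[:, mask] / norm[mask]
        return StateDistribution(p=p, degenerate=True)
    return StateDistribution(p=weights / norm)


def steady_state_nullspace(rates: RateSet) -> StateDistribution:
    """Stationary distribution via a rank-revealing null-space solve.

    Independent cross-check of :func:`steady_state`: the one-dimensional
    kernel of the transposed generator, normalised to unit sum.  Scalar
    rates only.
    """
    Q = rates.generator()
    _, s, vt = np.linalg.svd(Q.T)
    if s[-2] < 1e-12 * max(s[0], 1.0):
        raise ParameterError("rate matrix kernel is not one-dimensional")
    p = vt[-1]
    p = p / p.sum()
    if np.any(p < -1e-10):
        raise ParameterError("null-space solution is not a distribution")
    return StateDistribution(p=np.clip(p, 0.0, None) / np.clip(p, 0.0, None).sum())


def excess_flux(dist: StateDistribution, rates: RateSet,
                edge: tuple[int, int]):
    """Net probability flux ``ΔJij = Pi·ωij − Pj·ωji`` along an edge."""
    i, j = edge
    return dist[i] * rates.rate(i, j) - dist[j] * rates.rate(j, i)


def cycle_flux(dist: StateDistribution, rates: RateSet):
    """Common loop flux at stationarity (evaluated on the 2→3 edge)."""
    return excess_flux(dist, rates, (2, 3))


def effective_velocity(params: CycleParameters, cond: Conditions):
    """Mean power-stroke displacement per unit time, nm/s.

    ``v = Δx1·ΔJ23 + Δx2·ΔJ34``; at stationarity all loop fluxes coincide
    so this equals ``(Δx1+Δx2)·J``.  Zero exactly at the stall force and
    at chemical equilibrium.
    """
    rates = transition_rates(params, cond)
    dist = steady_state(rates)
    return (params.dx1 * excess_flux(dist, rates, (2, 3))
            + params.dx2 * excess_flux(dist, rates, (3, 4)))


def velocity_vs_force(params: CycleParameters, cond: Conditions, forces):
    """Vectorised effective velocity over an array of forces."""
    rates = rates_at(params, cond, np.asarray(forces, dtype=float))
    dist = steady_state(rates)
    return (params.dx1 * excess_flux(dist, rates, (2, 3))
            + params.dx2 * excess_flux(dist, rates, (3, 4)))


def stall_force(params: CycleParameters, cond: Conditions) -> float:
    """Force at which the mean cycle flux, hence the velocity, vanishes.

    ``Fs = Δμ/(Δx1+Δx2)``, a direct consequence of tight chemomechanical
    coupling.  A warning is emitted when Δμ ≤ 0 (the returned stall is
    then non-positive: the cycle runs backwards even without load).
    """
    dmu = gibbs_free_energy(params, cond)
    fs = dmu / (params.dx1 + params.dx2)
    if dmu <= 0:
        warnings.warn("Δμ <= 0: no positive stall force (cycle is driven "
                      "backwards by the chemistry)", stacklevel=2)
    return fs


def occupancy_summaries(dist: StateDistribution):
    """Strong-binding and attachment probabilities ``(P_sb, P_on)``.

    ``P_sb = P3+P4+P5`` (time fraction in the strongly bound states) and
    ``P_on = P2+P3+P4+P5`` (time fraction attached to the filament);
    ``P_on >= P_sb`` always.
    """
    p_sb = dist.p[2:5].sum(axis=0)
    p_on = dist.p[1:5].sum(axis=0)
    return p_sb, p_on


class NoCrossingError(RuntimeError):
    """The searched force interval contains no occupancy crossing."""


def _p3_minus_p5(params: CycleParameters, cond: Conditions, forces):
    dist = steady_state(rates_at(params, cond, np.asarray(forces, float)))
    return dist.p[2] - dist.p[4]


def dominance_crossings(params: CycleParameters, cond: Conditions,
                        f_range: tuple[float, float] = (0.0, 6.0),
                        n_grid: int = 241, xtol: float = 1e-3) -> list[float]:
    """All forces in ``f_range`` where the ADP-state occupancy P3 equals
    the ATP-state occupancy P5.

    A grid scan brackets every sign change of ``P3 − P5``; each bracket is
    refined by bisection to ``xtol`` (pN).
    """
    lo, hi = f_range
    grid = np.linspace(lo, hi, n_grid)
    h = _p3_minus_p5(params, cond, grid)
    roots = []
    for k in range(n_grid - 1):
        a, b, ha, hb = grid[k], grid[k + 1], h[k], h[k + 1]
        if ha == 0.0:
            roots.append(float(a))
            continue
        if ha * hb < 0:
            while b - a > xtol:
                m = 0.5 * (a + b)
                hm = float(_p3_minus_p5(params, cond, m))
                if ha * hm <= 0:
                    b = m
                else:
                    a, ha = m, hm
            roots.append(0.5 * (a + b))
    if h[-1] == 0.0:
        roots.append(float(grid[-1]))
    return roots


def dominance_crossing_force(params: CycleParameters, cond: Conditions,
                             f_range: tuple[float, float] = (0.0, 6.0),
                             xtol: float = 1e-3) -> float:
    """The lowest force at which the ATP state overtakes the ADP state.

    Raises
    ------
    NoCrossingError
        If ``P3 − P5`` does not change sign on the interval (for example
        when ATP binding is switched off and state 5 is unreachable).
    """
    roots = dominance_crossings(params, cond, f_range=f_range, xtol=xtol)
    if not roots:
        raise NoCrossingError(
            f"no P3 = P5 crossing in force range {f_range} pN")
    return roots[0]
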