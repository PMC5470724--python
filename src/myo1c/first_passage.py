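"""Attachment-time observables via absorbing-state (closed-diagram) analysis.

Three quantities summarise how long a single myosin Ic head stays engaged:

* ``t_sb^-1`` — the effective unbinding rate from the strongly bound
  states (3)–(5), the quantity measured in isometric optical-clamp
  recordings of attachment lifetimes;
* ``t_wb`` — the mean time per cycle spent weakly bound or detached;
* ``k_off`` — the rate of full detachment from the filament, which
  feeds the ensemble birth–death description.

Each rate is the stationary probability current of a closed diagram in
which absorbing transitions are redirected to the entry states weighted
with their entry probabilities (Hill's ensemble-average construction);
equivalently, the inverse of the mean first-passage time to absorption
from the entry distribution.  Both routes are implemented — the closed
diagram as the primary path, the fundamental-matrix mean-absorption time
as an independent oracle for tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import CycleParameters, Conditions, ParameterError
from .cycle_model import RateSet, rates_at, transition_rates, steady_state

__all__ = [
    "FirstPassageResult",
    "entry_probabilities",
    "strong_unbinding_rate",
    "weak_time",
    "filament_unbinding_rate",
    "first_passage_summary",
    "tsb_inv_from_rates",
    "koff_from_rates",
    "tsb_inv_closed_form",
    "koff_closed_form",
    "mean_absorption_time",
    "unbinding_curve",
]


@dataclass(frozen=True)
class FirstPassageResult:
    """Bundle of attachment statistics at one force/condition point."""

    t_sb_inv: float      # unbinding rate from the strongly bound states, 1/s
    t_wb: float          # mean weakly-bound/detached time per cycle, s
    k_off: float         # detachment rate from the filament, 1/s
    pi2: float           # probability of binding into state (2)
    pi3: float           # probability of entering the strong states at (3)
    p_strong: np.ndarray    # closed-diagram occupancies (p3, p4, p5)
    s_attached: np.ndarray  # closed-diagram occupancies (s2, s3, s4, s5)


def entry_probabilities(params: CycleParameters,
                        cond: Conditions) -> tuple[float, float]:
    """Entry probabilities ``(π2, π3)``.

    ``π2 = ω12/(ω12+ω15)`` is the probability that a binding event lands
    in the weakly bound state (2); the actin concentration cancels, so it
    reduces to ``ŵ12/(ŵ12+ŵ15)``.  ``π3`` is the probability that an
    entry into the strongly bound states occurs at state (3) rather than
    (5), given by the relative stationary current ``ω23·P2`` versus
    ``ω15·P1`` of the full cycle.
    """
    rates = transition_rates(params, cond)
    return _pi2(rates), _pi3(rates)


def _pi2(rates: RateSet):
    tot = rates.w12 + rates.w15
    if np.any(np.asarray(tot) == 0):
        raise ParameterError("π2 undefined: both actin-binding rates are zero")
    return rates.w12 / tot


def _pi3(rates: RateSet):
    dist = steady_state(rates)
    num = rates.w23 * dist[2]
    den = num + rates.w15 * dist[1]
    return np.where(np.asarray(den) == 0, 0.0, num / np.where(den == 0, 1.0, den)) \
        if np.ndim(den) else (0.0 if den == 0 else num / den)


# ---------------------------------------------------------------------------
# strongly bound states: closed diagram over (3, 4, 5)

def tsb_inv_from_rates(rates: RateSet, pi3: float) -> float:
    """Unbinding rate from the strong states by solving the closed diagram.

    States (1) and (2) are made absorbing; transitions into them are
    redirected back to the entry states (3) (weight ``π3``) and (5)
    (weight ``1 − π3``), self-loops dropped.  The stationary current into
    the absorbing states, ``ω32·p3 + ω51·p5``, is the unbinding rate.
    Scalar rates only; use :func:`tsb_inv_closed_form` for force sweeps.
    """
    w32, w34, w43 = float(rates.w32), float(rates.w34), float(rates.w43)
    w45, w51, w54 = float(rates.w45), float(rates.w51), float(rates.w54)
    if w32 == 0.0 and w51 == 0.0:
        return 0.0  # no exit from the strong states
    A = np.array([
        [-((1 - pi3) * w32 + w34), w43, pi3 * w51],
        [w34, -(w43 + w45), w54],
        [(1 - pi3) * w32, w45, -(w54 + pi3 * w51)],
    ])
    p = _stationary_of(A)
    return w32 * p[0] + w51 * p[2]


def tsb_inv_closed_form(rates: RateSet):
    """Printed closed form of the strong-state unbinding rate.

    Algebraically identical to the closed-diagram solve (the entry weight
    π3 has been eliminated in favour of the full-cycle rates), but pure
    arithmetic, so it broadcasts over force arrays; used both as the
    cross-check in tests and as the fast path in curve fitting.
    """
    w12, w15, w21, w23, w32 = rates.w12, rates.w15, rates.w21, rates.w23, rates.w32
    w34, w43, w45, w51, w54 = rates.w34, rates.w43, rates.w45, rates.w51, rates.w54
    num = (((w15 * w21 + w12 * w23) * w32 * w43
            + (w12 * w23 * (w32 + w34)
               + w15 * (w21 * w32 + (w21 + w23) * w34)) * w45) * w51
           + (w15 * w21 + (w12 + w15) * w23) * w32 * w43 * w54)
    den = (w15 * (w21 * (w32 * (w43 + w45) + w34 * w45) + w23 * w34 * w45
                  + (w23 * (w34 + w43) + w21 * (w32 + w34 + w43)) * w54)
           + w12 * w23 * ((w43 + w45) * w51 + w43 * w54
                          + w34 * (w45 + w51 + w54)))
    return num / den


def strong_unbinding_rate(params: CycleParameters, cond: Conditions) -> float:
    """Effective unbinding rate ``t_sb^-1`` from the strongly bound states.

    Independent of the actin concentration and of the magnitude of ω15
    (only the ratio ω12/ω15 enters, through the entry weight π3): binding
    rates set how often the head engages, not how long it stays engaged.
    """
    rates = transition_rates(params, cond)
    return tsb_inv_from_rates(rates, float(_pi3(rates)))


def weak_time(params: CycleParameters, cond: Conditions) -> float:
    """Mean time per cycle in the weakly bound and detached states, s.

    ``t_wb = t_sb·(1/P_sb − 1)``, so that ``t_sb/(t_sb+t_wb) = P_sb``
    exactly.  Infinite when the strong states are never reached.
    """
    rates = transition_rates(params, cond)
    p_sb = float(steady_state(rates).p[2:5].sum())
    if p_sb <= 0.0:
        return np.inf
    tsb_inv = tsb_inv_from_rates(rates, float(_pi3(rates)))
    if tsb_inv == 0.0:
        return np.inf
    return (1.0 / tsb_inv) * (1.0 / p_sb - 1.0)


# ---------------------------------------------------------------------------
# attached states: closed diagram over (2, 3, 4, 5)

def koff_from_rates(rates: RateSet, pi2: float) -> float:
    """Filament detachment rate by solving the attached closed diagram.

    State (1) is made absorbing; the 2→1 current is redirected to state
    (5) with weight ``1 − π2`` and the 5→1 current to state (2) with
    weight ``π2``.  Returns ``ω21·s2 + ω51·s5``.
    """
    w21, w23, w32, w34 = (float(rates.w21), float(rates.w23),
                          float(rates.w32), float(rates.w34))
    w43, w45, w51, w54 = (float(rates.w43), float(rates.w45),
                          float(rates.w51), float(rates.w54))
    if w21 == 0.0 and w51 == 0.0:
        return 0.0
    A = np.array([
        [-(w23 + (1 - pi2) * w21), w32, 0.0, pi2 * w51],
        [w23, -(w32 + w34), w43, 0.0],
        [0.0, w34, -(w43 + w45), w54],
        [(1 - pi2) * w21, 0.0, w45, -(w54 + pi2 * w51)],
    ])
    s = _stationary_of(A)
    return w21 * s[0] + w51 * s[3]


def koff_closed_form(rates: RateSet):
    """Printed closed form of the detachment rate (broadcasts over force).

    Depends on the actin-binding rates only through ``π2 = ω12/(ω12+ω15)``
    and is therefore invariant to the actin concentration.
    """
    w12, w15, w21, w23, w32 = rates.w12, rates.w15, rates.w21, rates.w23, rates.w32
    w34, w43, w45, w51, w54 = rates.w34, rates.w43, rates.w45, rates.w51, rates.w54
    pi2 = w12 / (w12 + w15)
    num = (w23 * w34 * w45 + w21 * (w34 * w45 + w32 * (w43 + w45))) * w51 \
        + w21 * w32 * w43 * w54
    A = pi2 * (w34 * w45 + w32 * (w43 + w45)) * w51 + w32 * w43 * w54
    B = (1 - pi2) * w21 * (w34 * w45 + (w34 + w43) * w54
                           + w32 * (w43 + w45 + w54))
    C = w23 * (pi2 * (w43 + w45) * w51 + w43 * w54
               + w34 * (w45 + pi2 * w51 + w54))
    return num / (A + B + C)


def filament_unbinding_rate(params: CycleParameters, cond: Conditions) -> float:
    """Detachment rate ``k_off`` of the head from the actin filament, 1/s."""
    rates = transition_rates(params, cond)
    return koff_from_rates(rates, float(_pi2(rates)))


def first_passage_summary(params: CycleParameters,
                          cond: Conditions) -> FirstPassageResult:
    """All attachment statistics at one operating point."""
    rates = transition_rates(params, cond)
    pi2 = float(_pi2(rates))
    pi3 = float(_pi3(rates))
    p_strong = _strong_occupancy(rates, pi3)
    s_attached = _attached_occupancy(rates, pi2)
    t_sb_inv = float(rates.w32) * p_strong[0] + float(rates.w51) * p_strong[2]
    k_off = float(rates.w21) * s_attached[0] + float(rates.w51) * s_attached[3]
    p_sb = float(steady_state(rates).p[2:5].sum())
    t_wb = np.inf if (p_sb <= 0 or t_sb_inv == 0) \
        else (1.0 / t_sb_inv) * (1.0 / p_sb - 1.0)
    return FirstPassageResult(t_sb_inv=t_sb_inv, t_wb=t_wb, k_off=k_off,
                              pi2=pi2, pi3=pi3, p_strong=p_strong,
                              s_attached=s_attached)


def unbinding_curve(params: CycleParameters, cond: Conditions, forces,
                    quantity: str = "tsb"):
    """Vectorised force sweep of ``tsb`` (t_sb^-1), ``koff`` or ``twb``."""
    F = np.asarray(forces, dtype=float)
    rates = rates_at(params, cond, F)
    if quantity == "tsb":
        return tsb_inv_closed_form(rates)
    if quantity == "koff":
        return koff_closed_form(rates)
    if quantity == "twb":
        p_sb = steady_state(rates).p[2:5].sum(axis=0)
        tsb_inv = tsb_inv_closed_form(rates)
        with np.errstate(divide="ignore"):
            return np.where((p_sb > 0) & (tsb_inv > 0),
                            (1.0 / tsb_inv) * (1.0 / p_sb - 1.0), np.inf)
    raise ValueError(f"unknown quantity {quantity!r}")


# ---------------------------------------------------------------------------
# helpers and the independent first-passage oracle

def _stationary_of(A: np.ndarray) -> np.ndarray:
    """Normalised kernel of a small closed-diagram generator (columns sum 0)."""
    n = A.shape[0]
    M = np.vstack([A, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    sol, residuals, rank, _ = np.linalg.lstsq(M, b, rcond=None)
    if rank < n:
        raise ParameterError("closed-diagram system is singular "
                             "(degenerate rate set)")
    return sol


def _strong_occupancy(rates: RateSet, pi3: float) -> np.ndarray:
    w32, w34, w43 = float(rates.w32), float(rates.w34), float(rates.w43)
    w45, w51, w54 = float(rates.w45), float(rates.w51), float(rates.w54)
    A = np.array([
        [-((1 - pi3) * w32 + w34), w43, pi3 * w51],
        [w34, -(w43 + w45), w54],
        [(1 - pi3) * w32, w45, -(w54 + pi3 * w51)],
    ])
    return _stationary_of(A)


def _attached_occupancy(rates: RateSet, pi2: float) -> np.ndarray:
    w21, w23, w32, w34 = (float(rates.w21), float(rates.w23),
                          float(rates.w32), float(rates.w34))
    w43, w45, w51, w54 = (float(rates.w43), float(rates.w45),
                          float(rates.w51), float(rates.w54))
    A = np.array([
        [-(w23 + (1 - pi2) * w21), w32, 0.0, pi2 * w51],
        [w23, -(w32 + w34), w43, 0.0],
        [0.0, w34, -(w43 + w45), w54],
        [(1 - pi2) * w21, 0.0, w45, -(w54 + pi2 * w51)],
    ])
    return _stationary_of(A)


def mean_absorption_time(sub_generator: np.ndarray,
                         start: np.ndarray) -> float:
    """Mean time to absorption of a transient sub-chain (oracle).

    ``sub_generator`` is the restriction of the full generator to the
    transient states (rows = from-state, including the loss terms to the
    absorbing states on the diagonal); ``start`` is the entry
    distribution.  The standard fundamental-matrix construction:
    ``t = (−Q_T)^{-1}·1`` and the mean is ``start·t``.
    """
    t = np.linalg.solve(-sub_generator, np.ones(sub_generator.shape[0]))
    return float(np.asarray(start) @ t)
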