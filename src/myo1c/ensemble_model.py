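"""Birth–death description of an ensemble of myosin Ic heads under load.

The number ``n`` of actin-bound heads in a cluster of ``N`` performs a
birth–death Markov chain with attachment rate ``(N−n)·k_on`` and
detachment rate ``n·k_off(f)``, where ``f`` is the force borne per bound
head.  Load sharing comes in three flavours:

* ``cooperative`` — the external force is split over the currently bound
  heads, ``f = F/n``: detachment of one head raises the load on the rest,
  which for a catch bond *stabilises* them;
* ``fixed`` — independent heads at ``f = F/N``;
* ``selfconsistent`` — independent heads at ``f = F/⟨ñ⟩`` with ``⟨ñ⟩``
  solved self-consistently.

From the mean bound number follow the ensemble's elastic extension
``x = F/(⟨n⟩κ)`` and the mechanical release predicted when Ca²⁺ lowers
the binding rate (factor ``β``) and/or the per-head stiffness
(``κ → κ_Ca``), the candidate mechanism for fast adaptation in hair
cells.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Literal

import numpy as np

from .parameters import CycleParameters, Conditions, ParameterError, KAPPA_HEAD
from .cycle_model import rates_at
from .first_passage import koff_closed_form

__all__ = [
    "EnsembleSpec",
    "EnsembleResult",
    "ensemble_from_cycle",
    "stationary_bound_distribution",
    "mean_bound",
    "force_extension",
    "calcium_release",
    "EnsembleDetachedError",
]

Sharing = Literal["cooperative", "fixed", "selfconsistent"]


class EnsembleDetachedError(RuntimeError):
    """The ensemble carries load with no bound head (infinite extension)."""


@dataclass(frozen=True)
class EnsembleSpec:
    """An ensemble of ``N`` identical heads under total external force ``F``.

    ``k_on`` is the per-head attachment rate (ω12 + ω15 at the working
    actin concentration, 1/s) and ``koff_of_f`` maps a per-head force (pN,
    clamped at ≥ 0: the ensemble treats only resisting loads) to the
    detachment rate (1/s).  ``beta ≥ 1`` is the Ca²⁺ binding-reduction
    factor and ``kappa_ca`` the post-Ca²⁺ per-head stiffness.
    """

    N: int
    F: float
    k_on: float
    koff_of_f: Callable[[float], float]
    sharing: Sharing = "cooperative"
    beta: float = 1.0
    kappa: float = KAPPA_HEAD
    kappa_ca: float | None = None

    def __post_init__(self):
        if self.N < 1:
            raise ParameterError(f"N must be >= 1, got {self.N}")
        if self.beta < 1.0:
            raise ParameterError(f"beta must be >= 1, got {self.beta}")
        if self.kappa <= 0 or (self.kappa_ca is not None and self.kappa_ca <= 0):
            raise ParameterError("stiffnesses must be > 0")
        if self.k_on < 0:
            raise ParameterError("k_on must be >= 0")
        if self.sharing not in ("cooperative", "fixed", "selfconsistent"):
            raise ParameterError(f"unknown sharing rule {self.sharing!r}")

    def koff(self, f: float) -> float:
        """Per-head detachment rate at per-head force f (clamped at f >= 0)."""
        return float(self.koff_of_f(max(float(f), 0.0)))

    def replace(self, **changes) -> "EnsembleSpec":
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class EnsembleResult:
    """Stationary summary of the bound-head chain."""

    S: np.ndarray          # stationary distribution over n = 0..N
    mean_n: float          # mean number of bound heads
    extension: float       # ensemble extension x = F/(mean_n * kappa), nm
    absorbed_at_N: bool = False   # koff vanished along the ladder


def ensemble_from_cycle(params: CycleParameters, cond: Conditions, N: int,
                        F: float, sharing: Sharing = "cooperative",
                        beta: float = 1.0,
                        kappa: float | None = None,
                        kappa_ca: float | None = None) -> EnsembleSpec:
    """Build an :class:`EnsembleSpec` from the single-head cycle.

    ``k_on = (ŵ12 + ŵ15)·[actin]`` and ``k_off(f)`` is the filament
    detachment rate of the cycle evaluated at per-head force ``f`` under
    the given nucleotide conditions.
    """
    k_on = (params.w12_hat + params.w15_hat) * cond.actin

    def koff_of_f(f: float) -> float:
        return float(koff_closed_form(rates_at(params, cond, float(f))))

    return EnsembleSpec(N=N, F=F, k_on=k_on, koff_of_f=koff_of_f,
                        sharing=sharing, beta=beta,
                        kappa=params.kappa if kappa is None else kappa,
                        kappa_ca=kappa_ca)


def _log_ratios(spec: EnsembleSpec) -> tuple[np.ndarray, bool]:
    """log(k_on^i / k_off^{i+1}) for i = 0..N-1, and an absorption flag."""
    N = spec.N
    logr = np.empty(N)
    absorbed = False
    for i in range(N):
        n_next = i + 1
        f = spec.F / n_next if spec.sharing == "cooperative" else spec.F / N
        koff = spec.koff(f)
        kon_i = (N - i) * spec.k_on
        if koff <= 0.0:
            absorbed = True
            logr[i:] = np.inf
            break
        logr[i] = np.log(kon_i) - np.log(n_next * koff) if kon_i > 0 else -np.inf
    return logr, absorbed


def stationary_bound_distribution(spec: EnsembleSpec) -> EnsembleResult:
    """Stationary distribution ``S_n`` of the number of bound heads.

    Product-form solution of the birth–death chain, accumulated in log
    space and renormalised after exponentiation, so ensembles of a few
    hundred heads remain well-conditioned.  If ``k_off`` vanishes at some
    rung the chain absorbs at ``n = N``.
    """
    if spec.k_on == 0.0:
        S = np.zeros(spec.N + 1)
        S[0] = 1.0
        return _result(spec, S)
    logr, absorbed = _log_ratios(spec)
    if absorbed:
        S = np.zeros(spec.N + 1)
        S[-1] = 1.0
        return _result(spec, S, absorbed_at_N=True)
    logS = np.concatenate([[0.0], np.cumsum(logr)])
    logS -= logS.max()
    S = np.exp(logS)
    S /= S.sum()
    return _result(spec, S)


def _result(spec: EnsembleSpec, S: np.ndarray,
            absorbed_at_N: bool = False) -> EnsembleResult:
    mean_n = float(np.arange(spec.N + 1) @ S)
    if mean_n > 0:
        x = spec.F / (mean_n * spec.kappa)
    elif spec.F == 0:
        x = 0.0
    else:
        x = np.inf
    return EnsembleResult(S=S, mean_n=mean_n, extension=x,
                          absorbed_at_N=absorbed_at_N)


def _independent_mean(spec: EnsembleSpec, f: float) -> float:
    """N·P_on(f) for independent heads: N·k_on/(k_on + k_off(f))."""
    koff = spec.koff(f)
    if spec.k_on == 0.0 and koff == 0.0:
        raise ParameterError("both k_on and k_off vanish; occupancy undefined")
    return spec.N * spec.k_on / (spec.k_on + koff)


def mean_bound(spec: EnsembleSpec) -> float:
    """Mean number of bound heads under the configured load-sharing rule.

    * cooperative — ``Σ n·S_n`` over the product-form distribution;
    * fixed — ``N·P_on(F/N)``;
    * selfconsistent — the root of ``m = N·P_on(F/m)``, found by damped
      fixed-point iteration with a bisection fallback.
    """
    if spec.sharing == "cooperative":
        return stationary_bound_distribution(spec).mean_n
    if spec.sharing == "fixed":
        return _independent_mean(spec, spec.F / spec.N)
    # self-consistent force sharing
    m = max(_independent_mean(spec, spec.F / spec.N), 1e-9)
    for _ in range(1000):
        target = _independent_mean(spec, spec.F / max(m, 1e-12))
        m_new = 0.5 * m + 0.5 * target
        if abs(m_new - m) < 1e-8 * max(1.0, m):
            return m_new
        m = m_new
    # bisection fallback on h(m) = m - N*P_on(F/m)
    lo, hi = 1e-9, float(spec.N)
    h = lambda m: m - _independent_mean(spec, spec.F / m)
    if h(lo) * h(hi) > 0:
        raise ParameterError("self-consistent occupancy did not converge")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if h(lo) * h(mid) <= 0:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def force_extension(spec: EnsembleSpec) -> float:
    """Ensemble extension ``x = F/(⟨n⟩·κ)`` in nm.

    Raises :class:`EnsembleDetachedError` when the ensemble bears load
    with (on average) no bound head.
    """
    if spec.F == 0.0:
        return 0.0
    n = mean_bound(spec)
    if n <= 0.0:
        raise EnsembleDetachedError(
            "no bound heads under load: extension diverges (detachment)")
    return spec.F / (n * spec.kappa)


def calcium_release(spec: EnsembleSpec) -> float:
    """Mechanical release Δx (nm) caused by the Ca²⁺ modulation.

    ``Δx = F·(1/(κ_Ca·⟨n⟩_Ca) − 1/(κ·⟨n⟩))`` where ``⟨n⟩`` uses
    ``(k_on, κ)`` and ``⟨n⟩_Ca`` uses ``(k_on/β, κ_Ca)``; ``κ_Ca = κ``
    when only the binding probability is modulated.
    """
    kappa_ca = spec.kappa if spec.kappa_ca is None else spec.kappa_ca
    n_before = mean_bound(spec)
    n_after = mean_bound(spec.replace(k_on=spec.k_on / spec.beta, beta=1.0,
                                      kappa=kappa_ca, kappa_ca=None))
    if n_before <= 0.0:
        raise EnsembleDetachedError("pre-Ca²⁺ ensemble is detached")
    if n_after <= 0.0:
        raise EnsembleDetachedError(
            "post-Ca²⁺ ensemble fully detaches: release unbounded")
    return spec.F * (1.0 / (kappa_ca * n_after) - 1.0 / (spec.kappa * n_before))
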