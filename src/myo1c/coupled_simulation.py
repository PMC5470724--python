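"""Event-driven Monte Carlo simulation of elastically coupled myosin heads.

``N`` heads each follow the five-state chemomechanical cycle.  Every head
is attached through its own linear spring (stiffness ``κ``) to a rigid
common backbone.  Mechanics are quasi-static: after every chemical event
the backbone position ``X`` re-equilibrates instantly from force balance,

    ``Σ_bound κ(a_i − X) = F``,

where ``a_i`` is the anchor coordinate of bound head ``i`` and ``F`` the
external load (positive opposes the power strokes).  The signed per-head
force ``f_i = κ(a_i − X)`` feeds back into that head's force-dependent
rates — assisting (negative) strains use the same rate laws, with
``g(f) > 1`` permitted.  A head binds without tension (``a_i = X`` at the
moment of binding); the 2→3 power stroke advances its anchor by ``Δx1``
and the 3→4 stroke by ``Δx2``, reverse strokes move it back symmetrically.

The simulation is an exact Gillespie algorithm; under a fixed integer
seed trajectories are bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .parameters import CycleParameters, Conditions, ParameterError
from .ensemble_model import EnsembleDetachedError

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "mechanical_equilibrium",
    "gillespie_run",
    "motility_velocity",
    "strongly_bound_dwells",
]

#: cap on the magnitude of exponents in the strained rate laws
_EXP_CAP = 500.0


@dataclass(frozen=True)
class SimulationConfig:
    """Configuration of a coupled-ensemble run.

    ``mode`` is either ``"force_clamp"`` (fixed external load ``force`` on
    the backbone) or ``"motility"`` (zero load, free backbone whose drift
    is the ensemble velocity).  ``t_max`` is the simulated time span and
    ``burn_in`` the initial span discarded from summaries.
    """

    N: int
    params: CycleParameters
    conditions: Conditions
    mode: Literal["force_clamp", "motility"] = "force_clamp"
    coupling_kappa: float | None = None      # defaults to params.kappa
    t_max: float = 10.0
    burn_in: float = 0.0
    seed: int = 0
    terminate_on_detach: bool = False
    max_events: int = 50_000_000

    def __post_init__(self):
        if self.N < 1:
            raise ParameterError("N must be >= 1")
        if not self.t_max > self.burn_in >= 0:
            raise ParameterError("need t_max > burn_in >= 0")
        if self.mode not in ("force_clamp", "motility"):
            raise ParameterError(f"unknown mode {self.mode!r}")

    @property
    def kappa(self) -> float:
        return self.params.kappa if self.coupling_kappa is None \
            else self.coupling_kappa

    @property
    def force(self) -> float:
        return self.conditions.force if self.mode == "force_clamp" else 0.0


@dataclass
class Trajectory:
    """Event log and summaries of a coupled-ensemble run.

    Events are (time, head, from-state, to-state) with states in 1..5;
    a head is bound to actin in states 2–5.  ``X`` is the backbone
    position after each event.  ``mean_n`` is the time-averaged bound
    count after burn-in and ``detached_fraction`` the fraction of
    post-burn-in time with zero bound heads.
    """

    times: np.ndarray
    head: np.ndarray
    s_from: np.ndarray
    s_to: np.ndarray
    X: np.ndarray
    mean_n: float
    detached_fraction: float
    t_end: float
    seed: int
    config: SimulationConfig = field(repr=False)

    @property
    def n_events(self) -> int:
        return len(self.times)

    def bound_count(self) -> np.ndarray:
        """Number of bound heads after each event (all heads start detached)."""
        delta = ((self.s_from == 1).astype(int)
                 - (self.s_to == 1).astype(int))
        return np.cumsum(delta)


def mechanical_equilibrium(anchors, force: float, kappa: float) -> float:
    """Backbone position balancing the bound-head springs against the load.

    Solves ``Σ κ(a_i − X) = F`` over the bound anchors: ``X = mean(a) −
    F/(nκ)``.  The per-head force is then ``f_i = κ(a_i − X)``; with
    equal anchors every head carries ``F/n``.
    """
    a = np.asarray(anchors, dtype=float)
    if a.size == 0:
        if force != 0.0:
            raise EnsembleDetachedError(
                "no bound head can balance a nonzero load")
        return 0.0
    return float(a.mean() - force / (a.size * kappa))


# channel targets: for each state (1..5) the destination of channel A and B
_TARGET_A = np.array([0, 2, 1, 2, 3, 1])   # index by state
_TARGET_B = np.array([0, 5, 3, 4, 5, 4])


class _EventLog:
    """Growable typed event storage (amortised append)."""

    def __init__(self):
        self._cap = 1024
        self.n = 0
        self.t = np.empty(self._cap)
        self.head = np.empty(self._cap, dtype=np.int32)
        self.s_from = np.empty(self._cap, dtype=np.int8)
        self.s_to = np.empty(self._cap, dtype=np.int8)
        self.X = np.empty(self._cap)

    def append(self, t, head, s_from, s_to, X):
        if self.n == self._cap:
            self._cap *= 2
            for name in ("t", "head", "s_from", "s_to", "X"):
                arr = getattr(self, name)
                grown = np.empty(self._cap, dtype=arr.dtype)
                grown[:self.n] = arr
                setattr(self, name, grown)
        i = self.n
        self.t[i] = t
        self.head[i] = head
        self.s_from[i] = s_from
        self.s_to[i] = s_to
        self.X[i] = X
        self.n = i + 1


class _Averager:
    """Time averages of bound count and detached time after burn-in."""

    def __init__(self, burn_in: float, t_max: float):
        self.burn_in, self.t_max = burn_in, t_max
        self.n_dt = 0.0
        self.detached_dt = 0.0
        self.T = 0.0

    def add(self, t: float, dt: float, n_bound: int):
        lo = t if t > self.burn_in else self.burn_in
        hi = t + dt
        if hi > self.t_max:
            hi = self.t_max
        if hi > lo:
            self.T += hi - lo
            self.n_dt += n_bound * (hi - lo)
            if n_bound == 0:
                self.detached_dt += hi - lo


def gillespie_run(config: SimulationConfig) -> Trajectory:
    """Exact stochastic simulation of the coupled ensemble.

    All heads start detached (state 1).  After every event the backbone
    position, per-head forces and all force-dependent rates are updated.
    If the ensemble detaches completely under load, a warning is recorded
    (once) and the backbone holds its last position until a head rebinds
    (tension-free), unless ``terminate_on_detach`` is set.

    A single head under force clamp is a time-homogeneous chain (its
    spring force equals the clamped load whenever it is bound), so that
    case runs through a dedicated scalar fast path; the result is an
    exact simulation either way.
    """
    if config.N == 1 and config.mode == "force_clamp":
        return _run_single_clamped(config)
    return _run_vectorised(config)


def _run_single_clamped(config: SimulationConfig) -> Trajectory:
    p, cond = config.params, config.conditions
    F = config.force
    rng = np.random.default_rng(config.seed)

    from .cycle_model import rates_at
    if abs(F * p.xi / p.kBT) > _EXP_CAP or \
            abs(F * p.dx1 / p.kBT) > _EXP_CAP:
        warnings.warn("extreme clamp force: rate-law exponent capped",
                      stacklevel=3)
    r = rates_at(p, cond, F)
    # per-state (channel-A rate, channel-B rate, total)
    table = {
        1: (float(r.w12), float(r.w15)),
        2: (float(r.w21), float(r.w23)),
        3: (float(r.w32), float(r.w34)),
        4: (float(r.w43), float(r.w45)),
        5: (float(r.w51), float(r.w54)),
    }
    totals = {s: a + b for s, (a, b) in table.items()}
    kappa = config.kappa
    exp = rng.exponential
    uni = rng.random

    state = 1
    X = 0.0
    a = 0.0
    t = 0.0
    log = _EventLog()
    avg = _Averager(config.burn_in, config.t_max)
    while t < config.t_max and log.n < config.max_events:
        tot = totals[state]
        if tot <= 0.0:
            avg.add(t, config.t_max - t, int(state > 1))
            t = config.t_max
            break
        dt = exp(1.0 / tot)
        avg.add(t, dt, int(state > 1))
        t += dt
        if t >= config.t_max:
            break
        ra, rb = table[state]
        s_new = int(_TARGET_A[state]) if uni() * tot < ra \
            else int(_TARGET_B[state])
        if state == 1:
            a = X
        elif state == 2 and s_new == 3:
            a += p.dx1
        elif state == 3 and s_new == 2:
            a -= p.dx1
        elif state == 3 and s_new == 4:
            a += p.dx2
        elif state == 4 and s_new == 3:
            a -= p.dx2
        s_old, state = state, s_new
        if state > 1:
            X = a - F / kappa
        log.append(t, 0, s_old, s_new, X)
        if state == 1 and F != 0.0 and config.terminate_on_detach:
            break
    return _finish(config, log, avg, t)


def _finish(config: SimulationConfig, log: _EventLog, avg: _Averager,
            t: float) -> Trajectory:
    mean_n = avg.n_dt / avg.T if avg.T > 0 else 0.0
    detached = avg.detached_dt / avg.T if avg.T > 0 else 1.0
    n = log.n
    return Trajectory(
        times=log.t[:n].copy(), head=log.head[:n].copy(),
        s_from=log.s_from[:n].copy(), s_to=log.s_to[:n].copy(),
        X=log.X[:n].copy(), mean_n=mean_n, detached_fraction=detached,
        t_end=min(t, config.t_max), seed=config.seed, config=config)


def _run_vectorised(config: SimulationConfig) -> Trajectory:
    p, cond = config.params, config.conditions
    N, kappa, F_ext = config.N, config.kappa, config.force
    rng = np.random.default_rng(config.seed)

    # precomputed rate-law constants
    w12c = p.w12_hat * cond.actin
    w15c = p.w15_hat * cond.actin
    w32c = p.w32_hat * cond.pi
    w43c = p.w43_hat * cond.adp
    w45c = p.w45_hat * cond.atp
    c23 = p.delta1 * p.dx1 / p.kBT
    c32 = (1.0 - p.delta1) * p.dx1 / p.kBT
    c34 = p.delta2 * p.dx2 / p.kBT
    c43 = (1.0 - p.delta2) * p.dx2 / p.kBT
    cxi = p.xi / p.kBT

    state = np.ones(N, dtype=np.int64)
    anchors = np.zeros(N)
    X = 0.0
    t = 0.0

    log = _EventLog()
    avg = _Averager(config.burn_in, config.t_max)
    strain_warned = False
    detach_warned = False

    while t < config.t_max and log.n < config.max_events:
        bound = state > 1
        n_bound = int(bound.sum())
        f = np.zeros(N)
        f[bound] = kappa * (anchors[bound] - X)
        arg = f * cxi
        if not strain_warned and np.any(np.abs(arg) > _EXP_CAP):
            warnings.warn("extreme spring strain: rate-law exponent capped",
                          stacklevel=2)
            strain_warned = True
        g = 2.0 * (1.0 - p.omega_off) \
            / (1.0 + np.exp(np.clip(arg, -_EXP_CAP, _EXP_CAP))) + p.omega_off

        rate_a = np.empty(N)
        rate_b = np.empty(N)
        m = state == 1
        rate_a[m] = w12c
        rate_b[m] = w15c
        m = state == 2
        rate_a[m] = p.w21
        rate_b[m] = p.w23_0 * np.exp(np.clip(-c23 * f[m], -_EXP_CAP, _EXP_CAP))
        m = state == 3
        rate_a[m] = w32c * np.exp(np.clip(c32 * f[m], -_EXP_CAP, _EXP_CAP))
        rate_b[m] = p.w34_0 * np.exp(np.clip(-c34 * f[m], -_EXP_CAP, _EXP_CAP))
        m = state == 4
        rate_a[m] = w43c * np.exp(np.clip(c43 * f[m], -_EXP_CAP, _EXP_CAP))
        rate_b[m] = w45c
        m = state == 5
        rate_a[m] = p.w51_0 * g[m]
        rate_b[m] = p.w54_0 * g[m]

        flat = np.concatenate([rate_a, rate_b])
        total = flat.sum()
        if total <= 0.0:
            # frozen system (e.g. actin = 0 and everything detached)
            avg.add(t, config.t_max - t, n_bound)
            t = config.t_max
            break
        dt = rng.exponential(1.0 / total)
        avg.add(t, dt, n_bound)
        t += dt
        if t >= config.t_max:
            break

        u = rng.random() * total
        idx = int(np.searchsorted(np.cumsum(flat), u))
        idx = min(idx, 2 * N - 1)
        head = idx % N
        s = int(state[head])
        s_new = int(_TARGET_A[s]) if idx < N else int(_TARGET_B[s])

        if s == 1:                       # binding: tension-free anchor
            anchors[head] = X
        elif s == 2 and s_new == 3:
            anchors[head] += p.dx1
        elif s == 3 and s_new == 2:
            anchors[head] -= p.dx1
        elif s == 3 and s_new == 4:
            anchors[head] += p.dx2
        elif s == 4 and s_new == 3:
            anchors[head] -= p.dx2
        state[head] = s_new

        bound = state > 1
        if bound.any():
            X = mechanical_equilibrium(anchors[bound], F_ext, kappa)
        else:
            if F_ext != 0.0:
                if not detach_warned:
                    warnings.warn("ensemble fully detached under load",
                                  stacklevel=2)
                    detach_warned = True
                if config.terminate_on_detach:
                    log.append(t, head, s, s_new, X)
                    break
            # backbone holds its last position until a head rebinds

        log.append(t, head, s, s_new, X)

    return _finish(config, log, avg, t)


def strongly_bound_dwells(traj: Trajectory, head: int | None = None) -> np.ndarray:
    """Durations of completed strongly-bound sojourns (states 3–5), s.

    A sojourn starts on a 2→3 or 1→5 transition and ends on the next
    3→2 or 5→1 transition of the same head; incomplete sojourns at the
    end of the run are discarded.
    """
    dwells = []
    heads = [head] if head is not None else range(traj.config.N)
    for h in heads:
        sel = traj.head == h
        t = traj.times[sel]
        s_from, s_to = traj.s_from[sel], traj.s_to[sel]
        # entries: 2->3 or 1->5; exits: 3->2 or 5->1.  Per head these
        # strictly alternate (a head must leave the strong states before
        # re-entering), so order pairing suffices.
        enter = ((s_from == 2) & (s_to == 3)) | ((s_from == 1) & (s_to == 5))
        leave = ((s_from == 3) & (s_to == 2)) | ((s_from == 5) & (s_to == 1))
        t_in, t_out = t[enter], t[leave]
        m = min(t_in.size, t_out.size)
        if m:
            dwells.append(t_out[:m] - t_in[:m])
    if not dwells:
        return np.empty(0)
    return np.concatenate(dwells)


def motility_velocity(config: SimulationConfig,
                      n_segments: int = 10) -> tuple[float, float, Trajectory]:
    """Ensemble gliding velocity from a zero-load run, nm/s.

    Least-squares slope of the backbone position ``X(t)`` after burn-in,
    with a standard error from slopes of ``n_segments`` contiguous
    trajectory segments.  Returns ``(velocity, stderr, trajectory)``.  A
    warning is attached when the ensemble was fully detached for more
    than 10% of the analysed time.
    """
    if config.mode != "motility":
        raise ParameterError("motility_velocity requires mode='motility'")
    traj = gillespie_run(config)
    mask = traj.times >= config.burn_in
    t, x = traj.times[mask], traj.X[mask]
    if t.size < 10:
        raise ParameterError("too few events after burn-in for a slope")
    slope = float(np.polyfit(t, x, 1)[0])
    edges = np.linspace(t[0], t[-1], n_segments + 1)
    seg_slopes = []
    for a, b in zip(edges[:-1], edges[1:]):
        m = (t >= a) & (t <= b)
        if m.sum() >= 3:
            seg_slopes.append(np.polyfit(t[m], x[m], 1)[0])
    se = float(np.std(seg_slopes, ddof=1) / np.sqrt(len(seg_slopes))) \
        if len(seg_slopes) > 1 else np.inf
    if traj.detached_fraction > 0.10:
        warnings.warn("ensemble detached for >10% of the run: "
                      "velocity estimate unreliable", stacklevel=2)
    return slope, se, traj
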