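"""Calibration of the cycle from single-molecule attachment data.

The pipeline mirrors how the model parameters are determined in practice:

1. :func:`derived_parameters` — a chain of identities fixes several rate
   constants from literature values (duty ratio, strong-bound lifetime,
   ADP equilibrium constant, the free-energy drop of the main power
   stroke, the binding-branch probability π2) and the thermodynamic
   balance fixes the ATP-release constant.
2. :func:`bin_events` — isometric-clamp attachment events (force,
   duration) are binned in 1-pN force bins; each bin's unbinding-rate
   estimate is the inverse mean duration with exponential-lifetime χ²
   confidence intervals.
3. :func:`joint_fit` — the remaining free parameters {ω21, ω51⁰, δ1, δ2,
   ξ, ω_off} are found by weighted nonlinear least squares on the binned
   unbinding-rate curves of two nucleotide conditions simultaneously
   (weights: half the CI width), with multiple seeded starts.  The
   strong-state unbinding rate is independent of ω15 and of the actin
   concentration, so ω15 is pinned to an arbitrary 1 1/s during this fit.
4. :func:`fit_binding_rate` — ω15 (hence ŵ15) is then recovered
   separately by matching the weak/detached time ``t_wb`` at 100 μM actin.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .parameters import CycleParameters, Conditions, ParameterError, KEQ_M
from .cycle_model import RateSet, _capped_exp
from .first_passage import tsb_inv_closed_form, weak_time

__all__ = [
    "CalibrationInputs",
    "derived_parameters",
    "bin_events",
    "FitResult",
    "joint_fit",
    "fit_binding_rate",
    "DEFAULT_FIT_CONDITIONS",
]

#: the two nucleotide conditions of the isometric-clamp data sets:
#: saturating ATP, and reduced ATP with added ADP, both with trace
#: contamination levels for the unreported species.
DEFAULT_FIT_CONDITIONS: dict[str, Conditions] = {
    "atp5000": Conditions(atp=5000.0, adp=0.1, pi=0.1, actin=100.0),
    "atp1000_adp50": Conditions(atp=1000.0, adp=50.0, pi=0.1, actin=100.0),
}


@dataclass(frozen=True)
class CalibrationInputs:
    """Literature constants entering the derived-parameter chain."""

    duty_ratio: float = 0.11        # fraction of cycle spent strongly bound
    t_sb: float = 0.213             # force-free strong-bound lifetime, s
    K_ADP: float = 1.8              # ADP-release equilibrium constant, μM
    dG23: float = -15.0             # power-stroke free-energy drop, kBT units
    pi2: float = 0.998              # probability of binding into state (2)
    muscle_pi: float = 1000.0       # [Pi] assumed for the dG23 source, μM
    Keq: float = KEQ_M              # hydrolysis equilibrium constant, M

    def __post_init__(self):
        if not 0.0 < self.duty_ratio < 1.0:
            raise ParameterError("duty ratio must lie in (0, 1)")
        if self.K_ADP <= 0 or self.t_sb <= 0:
            raise ParameterError("t_sb and K_ADP must be > 0")
        if not 0.0 < self.pi2 < 1.0:
            raise ParameterError("pi2 must lie in (0, 1)")

    @property
    def t_wb(self) -> float:
        """Weak/detached time implied by the duty ratio: t_sb(1−r)/r."""
        return self.t_sb * (1.0 - self.duty_ratio) / self.duty_ratio


def derived_parameters(cal: CalibrationInputs,
                       params: CycleParameters | None = None
                       ) -> CycleParameters:
    """Fill in the rate constants fixed by the calibration identities.

    * ``ŵ43 = ω34⁰ / K_ADP`` (ADP binding from the release equilibrium);
    * ``ŵ32 = (ω23⁰/[Pi]) · exp(ΔG23/kBT)`` (Pi binding from the
      power-stroke free energy, at the source's assumed 1 mM Pi);
    * ``ŵ12 = π2·ŵ15/(1 − π2)`` (binding branch ratio);
    * ``ω54⁰`` from the thermodynamic balance condition.
    """
    base = CycleParameters() if params is None else params
    w43_hat = base.w34_0 / cal.K_ADP
    w32_hat = (base.w23_0 / cal.muscle_pi) * float(np.exp(cal.dG23))
    w12_hat = cal.pi2 * base.w15_hat / (1.0 - cal.pi2)
    filled = dataclasses.replace(base, w43_hat=w43_hat, w32_hat=w32_hat,
                                 w12_hat=w12_hat, Keq=cal.Keq,
                                 balanced=False)
    return filled.rebalanced()


def bin_events(events: pd.DataFrame, bin_width: float = 1.0,
               alpha: float = 0.05, f_max: float = 6.0) -> pd.DataFrame:
    """Bin attachment events by force and estimate per-bin unbinding rates.

    Parameters
    ----------
    events :
        Table with columns ``condition``, ``force_pN``, ``duration_s``.
    bin_width :
        Force bin width in pN; edges sit at integer multiples.
    alpha :
        CI level: 1−α two-sided intervals from the exponential-lifetime
        χ² formulas (upper bound ``rate·χ²_{1−α/2,2n}/(2n)``, lower bound
        ``rate·χ²_{α/2,2n}/(2n)``).
    f_max :
        Events at larger forces are excluded (power strokes are only
        characterised below this load).

    Returns
    -------
    DataFrame with one row per non-empty (condition, bin): columns
    ``condition, force, n, rate, lo, hi, alpha``.
    """
    required = {"condition", "force_pN", "duration_s"}
    if not required.issubset(events.columns):
        raise ParameterError(f"event table must have columns {sorted(required)}")
    if len(events) == 0:
        raise ParameterError("no events to bin")
    if (events["duration_s"] <= 0).any():
        raise ParameterError("durations must be > 0")
    kept = events[events["force_pN"] <= f_max].copy()
    kept["bin"] = np.floor(kept["force_pN"] / bin_width).astype(int)
    rows = []
    for (label, b), grp in kept.groupby(["condition", "bin"], sort=True):
        n = len(grp)
        rate = 1.0 / grp["duration_s"].mean()
        lo = rate * stats.chi2.ppf(alpha / 2, 2 * n) / (2 * n)
        hi = rate * stats.chi2.ppf(1 - alpha / 2, 2 * n) / (2 * n)
        rows.append({"condition": label, "force": (b + 0.5) * bin_width,
                     "f_lo": b * bin_width, "f_hi": (b + 1) * bin_width,
                     "n": n, "rate": rate, "lo": lo, "hi": hi,
                     "alpha": alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# joint weighted least-squares fit

_FREE = ("w21", "w51_0", "delta1", "delta2", "xi", "omega_off")


def _model_rates(theta: np.ndarray, base: CycleParameters, cond: Conditions,
                 forces: np.ndarray, w12_over_w15: float) -> RateSet:
    """Rate set on a force grid with the free parameters taken from theta.

    ω15 is pinned at 1 1/s (the strong-state unbinding rate depends on the
    actin-binding rates only through their ratio, held at the calibrated
    π2/(1−π2)); ω54⁰ is recomputed from the balance condition at every
    evaluation so thermodynamic consistency holds throughout the fit.
    """
    w21, w51_0, delta1, delta2, xi, omega_off = theta
    kBT = base.kBT
    F = np.asarray(forces, dtype=float)
    g = 2.0 * (1.0 - omega_off) / (1.0 + _capped_exp(xi * F / kBT)) + omega_off
    w54_0 = (w12_over_w15 * base.w23_0 * base.w34_0 * base.w45_hat * w51_0
             / (w21 * base.w32_hat * base.w43_hat * base.keq_uM))
    return RateSet(
        w12=w12_over_w15, w15=1.0, w21=w21,
        w23=base.w23_0 * _capped_exp(-delta1 * F * base.dx1 / kBT),
        w32=base.w32_hat * cond.pi
        * _capped_exp((1.0 - delta1) * F * base.dx1 / kBT),
        w34=base.w34_0 * _capped_exp(-delta2 * F * base.dx2 / kBT),
        w43=base.w43_hat * cond.adp
        * _capped_exp((1.0 - delta2) * F * base.dx2 / kBT),
        w45=base.w45_hat * cond.atp,
        w51=g * w51_0, w54=g * w54_0)


@dataclass(frozen=True)
class FitResult:
    """Outcome of the joint unbinding-curve fit."""

    params: CycleParameters
    theta: dict[str, float]
    objective: float
    n_starts: int
    start_objectives: np.ndarray = field(repr=False)
    success: bool = True


def joint_fit(binned: pd.DataFrame, conditions: dict[str, Conditions],
              base: CycleParameters | None = None, n_starts: int = 20,
              seed: int = 0, symmetric_weights: bool = True) -> FitResult:
    """Fit {ω21, ω51⁰, δ1, δ2, ξ, ω_off} to binned unbinding-rate curves.

    Minimises ``Σ ((model − estimate)/w)²`` over all bins of all
    conditions jointly, with ``w`` half the confidence-interval width
    (or the asymmetric distances when ``symmetric_weights=False``).
    Rates and ξ are optimised in log space under bounds δ ∈ [0,1] and
    ω_off ∈ (0,1]; ``n_starts`` seeded random starts guard against local
    minima and the best objective is returned.
    """
    base = CycleParameters() if base is None else base
    missing = set(binned["condition"]) - set(conditions)
    if missing:
        raise ParameterError(f"no Conditions supplied for {sorted(missing)}")
    ratio = base.w12_hat / base.w15_hat
    # The per-bin estimate 1/mean(duration) converges to the *harmonic*
    # average of the rate over the bin's force span, so the model value
    # compared against it is the harmonic bin average on a sub-grid —
    # evaluating at the bin centre would bias the fit wherever the curve
    # is steep on the 1-pN bin scale.
    n_sub = 9
    groups = []
    for label, grp in binned.groupby("condition"):
        w = 0.5 * (grp["hi"].to_numpy() - grp["lo"].to_numpy())
        if symmetric_weights:
            w_lo = w_hi = w
        else:
            w_lo = grp["rate"].to_numpy() - grp["lo"].to_numpy()
            w_hi = grp["hi"].to_numpy() - grp["rate"].to_numpy()
        if {"f_lo", "f_hi"}.issubset(grp.columns):
            f_lo, f_hi = grp["f_lo"].to_numpy(), grp["f_hi"].to_numpy()
        else:  # fall back to centre +- half a unit bin
            f_lo, f_hi = grp["force"].to_numpy() - 0.5, \
                grp["force"].to_numpy() + 0.5
        offsets = (np.arange(n_sub) + 0.5) / n_sub
        F_grid = f_lo[:, None] + offsets[None, :] * (f_hi - f_lo)[:, None]
        groups.append((conditions[label], F_grid,
                       grp["rate"].to_numpy(), w_lo, w_hi))

    def residuals(x: np.ndarray) -> np.ndarray:
        theta = np.array([np.exp(x[0]), np.exp(x[1]), x[2], x[3],
                          np.exp(x[4]), np.exp(x[5])])
        res = []
        for cond, F_grid, est, w_lo, w_hi in groups:
            rate_grid = tsb_inv_closed_form(
                _model_rates(theta, base, cond, F_grid, ratio))
            model = 1.0 / np.mean(1.0 / rate_grid, axis=1)
            diff = model - est
            w = np.where(diff >= 0, w_hi, w_lo)
            res.append(diff / w)
        return np.concatenate(res)

    lb = np.array([np.log(1e-2), np.log(1e-2), 0.0, 0.0,
                   np.log(1e-2), np.log(1e-6)])
    ub = np.array([np.log(1e5), np.log(1e5), 1.0, 1.0,
                   np.log(1e3), 0.0])
    rng = np.random.default_rng(seed)
    best = None
    start_objs = []
    for _ in range(n_starts):
        x0 = rng.uniform(lb, ub)
        try:
            sol = optimize.least_squares(residuals, x0, bounds=(lb, ub),
                                         method="trf", xtol=1e-12,
                                         ftol=1e-12, gtol=1e-12)
        except Exception:
            start_objs.append(np.inf)
            continue
        obj = 2.0 * sol.cost
        start_objs.append(obj)
        if best is None or obj < best[0]:
            best = (obj, sol)
    if best is None:
        raise RuntimeError(
            "joint_fit: no start converged; objectives: " + repr(start_objs))
    obj, sol = best
    x = sol.x
    theta = {"w21": float(np.exp(x[0])), "w51_0": float(np.exp(x[1])),
             "delta1": float(x[2]), "delta2": float(x[3]),
             "xi": float(np.exp(x[4])), "omega_off": float(np.exp(x[5]))}
    fitted = base.replace(**theta).rebalanced()
    return FitResult(params=fitted, theta=theta, objective=float(obj),
                     n_starts=n_starts,
                     start_objectives=np.asarray(start_objs),
                     success=bool(sol.success))


def fit_binding_rate(params: CycleParameters, target_twb: float,
                     actin: float = 100.0,
                     cond: Conditions | None = None) -> float:
    """Recover the actin-binding constant ŵ15 from the weak/detached time.

    Solves ``t_wb(ω15) = target`` at the given actin concentration by a
    bracketed root search over ω15 ∈ (1e-6, 1e3) 1/s, with the binding
    branch ratio ω12/ω15 held at the calibrated value, and returns
    ``ŵ15 = ω15/[actin]``.
    """
    if target_twb <= 0:
        raise ParameterError("target t_wb must be > 0")
    if cond is None:
        cond = DEFAULT_FIT_CONDITIONS["atp5000"]
    cond = dataclasses.replace(cond, actin=actin)
    ratio = params.w12_hat / params.w15_hat

    def twb_of(log_w15: float) -> float:
        w15 = float(np.exp(log_w15))
        p = params.replace(w15_hat=w15 / actin,
                           w12_hat=ratio * w15 / actin).rebalanced()
        return weak_time(p, cond) - target_twb

    lo, hi = np.log(1e-6), np.log(1e3)
    f_lo, f_hi = twb_of(lo), twb_of(hi)
    if not np.isfinite(f_lo) or f_lo * f_hi > 0:
        raise ParameterError(
            f"no ω15 in (1e-6, 1e3) 1/s reaches t_wb = {target_twb} s "
            f"(bracket values {f_lo:.3g}, {f_hi:.3g})")
    log_w15 = optimize.brentq(twb_of, lo, hi, xtol=1e-12, rtol=1e-12)
    return float(np.exp(log_w15)) / actin
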