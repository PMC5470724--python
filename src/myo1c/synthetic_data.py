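"""Synthetic isometric-clamp attachment-event datasets.

The single-molecule recordings the calibration rests on are not publicly
deposited, so this module emulates the measurement: a dual-trap clamp
holds one myosin Ic head at a near-constant force while the durations of
its strongly bound attachments are recorded, at two nucleotide
conditions and forces spanning 0–6 pN.  Event durations are drawn either
from the model's exponential strong-state lifetime at the clamped force
(the statistical structure the binned analysis assumes) or, in
``full_cycle`` mode, harvested from strongly-bound sojourns of an actual
single-head Gillespie simulation — a cross-check that the exponential
shortcut matches the stochastic cycle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import CycleParameters, Conditions, ParameterError
from .cycle_model import rates_at
from .first_passage import tsb_inv_closed_form
from .coupled_simulation import (SimulationConfig, gillespie_run,
                                 strongly_bound_dwells)
from .inference import DEFAULT_FIT_CONDITIONS

__all__ = ["ExperimentDesign", "generate_events"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Layout of a simulated isometric-clamp experiment.

    ``conditions`` maps a label to the nucleotide/actin conditions of one
    recording series (the force field is ignored; each event carries its
    own clamped force).  ``force_law`` is ``"uniform"`` over ``f_range``
    or ``"clustered"`` (a mixture of narrow normal clusters mimicking
    trap-style force clustering).  Durations below ``dead_time`` (s) are
    censored, emulating finite temporal resolution.
    """

    conditions: dict[str, Conditions] = field(
        default_factory=lambda: dict(DEFAULT_FIT_CONDITIONS))
    events_per_condition: int = 500
    f_range: tuple[float, float] = (0.0, 6.0)
    force_law: str = "uniform"
    dead_time: float = 0.0
    mode: str = "exponential"           # or "full_cycle"

    def __post_init__(self):
        if self.events_per_condition < 1:
            raise ParameterError("need at least one event per condition")
        lo, hi = self.f_range
        if not (0.0 <= lo < hi <= 6.0):
            raise ParameterError("force range must lie within [0, 6] pN")
        if self.force_law not in ("uniform", "clustered"):
            raise ParameterError(f"unknown force law {self.force_law!r}")
        if self.mode not in ("exponential", "full_cycle"):
            raise ParameterError(f"unknown mode {self.mode!r}")


def _draw_forces(design: ExperimentDesign, rng: np.random.Generator,
                 n: int) -> np.ndarray:
    lo, hi = design.f_range
    if design.force_law == "uniform":
        return rng.uniform(lo, hi, size=n)
    centers = rng.uniform(lo, hi, size=max(4, n // 60))
    picks = rng.integers(0, len(centers), size=n)
    f = rng.normal(centers[picks], 0.15 * (hi - lo) / len(centers))
    return np.clip(f, lo, hi)


def _full_cycle_duration(params: CycleParameters, cond: Conditions,
                         force: float, seed: int) -> float:
    """First completed strongly-bound sojourn of a clamped single head."""
    # expected cycle period sets the simulated horizon
    rate = float(tsb_inv_closed_form(rates_at(params, cond, force)))
    horizon = max(50.0 / max(rate, 1e-3), 50.0)
    cfg = SimulationConfig(N=1, params=params,
                           conditions=cond.with_force(force),
                           mode="force_clamp", t_max=horizon, seed=seed)
    for _ in range(20):
        dwells = strongly_bound_dwells(gillespie_run(cfg))
        if dwells.size:
            return float(dwells[0])
        cfg = dataclasses.replace(cfg, t_max=cfg.t_max * 4,
                                  seed=cfg.seed + 104729)
    raise RuntimeError("no strongly-bound sojourn observed; "
                       "conditions may forbid strong binding")


def generate_events(design: ExperimentDesign, params: CycleParameters,
                    seed: int = 0) -> pd.DataFrame:
    """Simulate an attachment-event table.

    Returns a DataFrame with columns ``condition``, ``force_pN``,
    ``duration_s`` — the schema the inference module consumes.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for label, cond in design.conditions.items():
        n = design.events_per_condition
        forces = _draw_forces(design, rng, n)
        if design.mode == "exponential":
            rates = tsb_inv_closed_form(rates_at(params, cond, forces))
            if np.any(rates <= 0):
                raise ParameterError(
                    "strong-state unbinding rate vanished at some force")
            durations = rng.exponential(1.0 / rates)
        else:
            sub_seeds = rng.integers(0, 2**31 - 1, size=n)
            durations = np.array([
                _full_cycle_duration(params, cond, float(f), int(s))
                for f, s in zip(forces, sub_seeds)])
        frame = pd.DataFrame({"condition": label, "force_pN": forces,
                              "duration_s": durations})
        if design.dead_time > 0:
            frame = frame[frame["duration_s"] >= design.dead_time]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
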