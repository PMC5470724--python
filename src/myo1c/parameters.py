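"""Parameter and condition containers for the myosin Ic cross-bridge cycle.

Internal unit system: piconewtons (pN), nanometres (nm), seconds (s) and
micromolar (μM).  Thermal energy defaults to ``kBT = 4 pN·nm`` (4 zJ, room
temperature), so ``F * dx / kBT`` is dimensionless with numbers of order one.
The ATP-hydrolysis equilibrium constant ``Keq`` is stored in molar and
converted to μM where it meets concentration ratios.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

__all__ = [
    "CycleParameters",
    "Conditions",
    "table1_parameters",
    "load_parameters",
    "save_parameters",
    "load_conditions",
    "save_conditions",
]

#: thermal energy at room temperature, pN·nm (= zJ)
KBT_ROOM = 4.0

#: ATP hydrolysis equilibrium constant, molar
KEQ_M = 4.9e5

#: single-head spring stiffness, pN/nm (= 500 μN/m)
KAPPA_HEAD = 0.5


class ParameterError(ValueError):
    """Raised when a parameter or condition set violates its invariants."""


@dataclass(frozen=True)
class CycleParameters:
    """Rate constants and mechanical parameters of the five-state cycle.

    The cycle has one detached state (1) and four actin-bound states:
    the weakly bound ADP·Pi state (2), the strongly bound ADP state (3),
    nucleotide-free state (4) and ATP state (5).  Rates ``w{ij}_0`` are
    force-free first-order rates in 1/s; ``w{ij}_hat`` are second-order
    constants in 1/(s·μM) that multiply a concentration.

    Parameters
    ----------
    dx1, dx2 :
        Power-stroke distances (nm): the main 5.8-nm stroke on Pi release
        and the 2-nm stroke on ADP release.
    delta1, delta2 :
        Force-distribution factors in [0, 1]: the fraction of the stroke
        work ``F·dx`` loaded on the forward rate of each stroke.
    xi :
        Characteristic length (nm) of the force sensitivity of the exit
        from the ATP state (the catch-bond length scale).
    omega_off :
        Dimensionless high-force offset of the ATP-state force factor
        ``g(F)``; ``g`` saturates at ``omega_off`` for large resisting load.
    w23_0, w34_0 :
        Force-free Pi-release and ADP-release rates (1/s).
    w32_hat, w43_hat, w45_hat :
        Pi-, ADP- and ATP-binding rate constants (1/(s·μM)).
    w51_0, w54_0 :
        Force-free detachment from the ATP state and ATP-release rate
        (1/s); both are modulated by ``g(F)`` under load.  ``w54_0`` is not
        a free parameter: thermodynamic consistency fixes it in terms of
        the other constants (see :func:`balanced_atp_release_rate`).
    w21 :
        Detachment rate from the weakly bound state (1/s).
    w12_hat, w15_hat :
        Actin-binding rate constants into states (2) and (5) (1/(s·μM)).
    Keq :
        ATP-hydrolysis equilibrium constant, in molar.
    kBT :
        Thermal energy, pN·nm.
    kappa :
        Single-head spring stiffness, pN/nm.
    balanced :
        If True (default for the packaged parameter set), ``w54_0`` was
        computed from the balance condition rather than taken as input.
    """

    dx1: float = 5.8
    dx2: float = 2.0
    delta1: float = 0.12
    delta2: float = 0.0
    xi: float = 13.45
    omega_off: float = 0.001
    w23_0: float = 1.5
    w32_hat: float = 4.5e-10
    w34_0: float = 3.9
    w43_hat: float = 2.17
    w45_hat: float = 0.26
    w51_0: float = 314.0
    w54_0: float = 3.04
    w21: float = 164.0
    w12_hat: float = 0.76
    w15_hat: float = 0.0015
    Keq: float = KEQ_M
    kBT: float = KBT_ROOM
    kappa: float = KAPPA_HEAD
    balanced: bool = False

    def __post_init__(self) -> None:
        positive = {"dx1": self.dx1, "dx2": self.dx2, "xi": self.xi,
                    "kBT": self.kBT, "kappa": self.kappa, "Keq": self.Keq}
        for name, value in positive.items():
            if not value > 0:
                raise ParameterError(f"{name} must be > 0, got {value!r}")
        nonneg = {"w23_0": self.w23_0, "w32_hat": self.w32_hat,
                  "w34_0": self.w34_0, "w43_hat": self.w43_hat,
                  "w45_hat": self.w45_hat, "w51_0": self.w51_0,
                  "w54_0": self.w54_0, "w21": self.w21,
                  "w12_hat": self.w12_hat, "w15_hat": self.w15_hat}
        for name, value in nonneg.items():
            if value < 0:
                raise ParameterError(f"{name} must be >= 0, got {value!r}")
        for name, value in (("delta1", self.delta1), ("delta2", self.delta2)):
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")
        if not 0.0 < self.omega_off <= 1.0:
            raise ParameterError(
                f"omega_off must lie in (0, 1], got {self.omega_off!r}")
        if self.balanced:
            target = balanced_atp_release_rate(self)
            if not math.isclose(self.w54_0, target, rel_tol=1e-10):
                raise ParameterError(
                    "parameters flagged balanced but w54_0="
                    f"{self.w54_0!r} != balance value {target!r}")

    @property
    def keq_uM(self) -> float:
        """Equilibrium constant converted to μM."""
        return self.Keq * 1e6

    def replace(self, **changes: Any) -> "CycleParameters":
        """Return a copy with the given fields replaced.

        Any change to a rate constant clears the ``balanced`` flag unless
        ``w54_0`` is part of the change or ``balanced`` is set explicitly.
        """
        if changes and "balanced" not in changes:
            changes["balanced"] = False
        return dataclasses.replace(self, **changes)

    def rebalanced(self) -> "CycleParameters":
        """Return a copy with ``w54_0`` recomputed from the balance condition."""
        return dataclasses.replace(
            self, w54_0=balanced_atp_release_rate(self), balanced=True)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "CycleParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)


def balanced_atp_release_rate(params: CycleParameters) -> float:
    """Force-free ATP-release rate ``w54_0`` implied by thermodynamic balance.

    Requiring that the product of forward over reverse rates around the
    cycle equal ``exp((Δμ − (Δx1+Δx2)F)/kBT)`` at every force and every
    set of concentrations fixes

        ``w54_0 = (ŵ12/ŵ15) · w23_0 · w34_0 · ŵ45 · w51_0
                  / (w21 · ŵ32 · ŵ43 · Keq)``

    with ``Keq`` expressed in μM.  The actin-binding constants enter only
    through their ratio, so the result is independent of all
    concentrations; the ``g(F)`` factors of the ATP-state rates cancel,
    leaving ``w54 = g(F)·w54_0``.
    """
    denom = params.w21 * params.w32_hat * params.w43_hat * params.w15_hat \
        * params.keq_uM
    if denom == 0:
        raise ParameterError(
            "balance condition undefined: a reverse rate constant is zero")
    num = (params.w12_hat * params.w23_0 * params.w34_0 * params.w45_hat
           * params.w51_0)
    return num / denom


def table1_parameters(balanced: bool = True) -> CycleParameters:
    """The packaged default parameter set for myosin Ic.

    With ``balanced=True`` (default) the ATP-release constant ``w54_0`` is
    recomputed from the thermodynamic balance condition (3.08 1/s with the
    packaged actin-binding ratio 0.76/0.0015; the rounded literature value
    is 3.04 1/s, within 2%).  With ``balanced=False`` the rounded value
    3.04 1/s is kept as-is.
    """
    base = CycleParameters()
    return base.rebalanced() if balanced else base


@dataclass(frozen=True)
class Conditions:
    """Experimental conditions: concentrations (μM) and external force (pN).

    A positive force opposes the power stroke (resisting load); negative
    (assisting) forces are allowed.
    """

    atp: float = 1000.0
    adp: float = 10.0
    pi: float = 1000.0
    actin: float = 100.0
    force: float = 0.0

    def __post_init__(self) -> None:
        for name in ("atp", "adp", "pi", "actin"):
            value = getattr(self, name)
            if value < 0:
                raise ParameterError(
                    f"concentration {name} must be >= 0, got {value!r}")
        if not math.isfinite(self.force):
            raise ParameterError(f"force must be finite, got {self.force!r}")

    @classmethod
    def physiological(cls, force: float = 0.0, actin: float = 100.0) -> "Conditions":
        """In-vivo-like nucleotides: 1 mM ATP, 10 μM ADP, 1 mM Pi."""
        return cls(atp=1000.0, adp=10.0, pi=1000.0, actin=actin, force=force)

    def with_force(self, force: float) -> "Conditions":
        return dataclasses.replace(self, force=force)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Conditions":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown condition keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# flat JSON-compatible parameter/condition files

def load_parameters(path: str | Path) -> CycleParameters:
    """Load a :class:`CycleParameters` from a flat JSON document."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: expected a JSON object")
    return CycleParameters.from_dict(data)


def save_parameters(params: CycleParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(params.to_dict(), fh, indent=1)
        fh.write("\n")


def load_conditions(path: str | Path) -> Conditions:
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ParameterError(f"{path}: expected a JSON object")
    return Conditions.from_dict(data)


def save_conditions(cond: Conditions, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(cond.to_dict(), fh, indent=1)
        fh.write("\n")
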