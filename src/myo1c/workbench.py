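"""Thin command-line interface over the library.

Every subcommand is a pure function of its inputs and ``--seed``:
deterministic paths give identical output for identical inputs, and all
stochastic outputs embed the seed they were produced with.  Tabular
output is comma-separated with a header naming columns and units.
"""

from __future__ import annotations

import hashlib
import json
import sys

import click
import numpy as np
import pandas as pd

from . import __version__
from .parameters import (CycleParameters, Conditions, table1_parameters,
                         load_parameters, load_conditions, save_parameters)
from .cycle_model import (rates_at, steady_state, velocity_vs_force,
                          dominance_crossings)
from .first_passage import unbinding_curve
from .ensemble_model import ensemble_from_cycle, mean_bound, force_extension, \
    calcium_release
from .coupled_simulation import SimulationConfig, gillespie_run, \
    motility_velocity
from .inference import bin_events, joint_fit, DEFAULT_FIT_CONDITIONS
from .synthetic_data import ExperimentDesign, generate_events


def _params_from(path: str | None) -> CycleParameters:
    return table1_parameters() if path is None else load_parameters(path)


def _cond_from(path: str | None) -> Conditions:
    return Conditions.physiological() if path is None else load_conditions(path)


def _params_hash(params: CycleParameters) -> str:
    payload = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _emit(df: pd.DataFrame, out: str | None) -> None:
    target = sys.stdout if out is None else open(out, "w")
    df.to_csv(target, index=False, float_format="%.10g")
    if out is not None:
        target.close()


def _manifest(command: str, params: CycleParameters, seed: int | None = None
              ) -> None:
    note = f"# myo1c {__version__} | {command} | params {_params_hash(params)}"
    if seed is not None:
        note += f" | seed {seed}"
    click.echo(note, err=True)


@click.group()
@click.version_option(__version__)
def main() -> None:
    """Myosin Ic chemomechanical-cycle workbench."""


_params_opt = click.option("--params", "params_file", type=click.Path(
    exists=True, dir_okay=False), default=None,
    help="JSON parameter file (default: packaged values).")
_cond_opt = click.option("--cond", "cond_file", type=click.Path(
    exists=True, dir_okay=False), default=None,
    help="JSON condition file (default: physiological, 100 uM actin).")
_grid_opt = click.option("--force-grid", nargs=3, type=float, default=None,
                         metavar="LO HI N", help="Force grid in pN.")
_out_opt = click.option("--out", type=click.Path(dir_okay=False), default=None,
                        help="Output CSV (default: stdout).")


def _forces(force: float | None, grid) -> np.ndarray:
    if grid is not None:
        lo, hi, n = grid
        return np.linspace(lo, hi, int(n))
    return np.asarray([0.0 if force is None else force])


@main.command()
@_params_opt
@_cond_opt
@click.option("--force", type=float, default=None, help="Force in pN.")
@_grid_opt
@_out_opt
def rates(params_file, cond_file, force, force_grid, out):
    """Tabulate the ten transition rates versus force."""
    params, cond = _params_from(params_file), _cond_from(cond_file)
    F = _forces(force, force_grid)
    rs = rates_at(params, cond, F)
    cols = {"force_pN": F}
    for name in ("w12", "w15", "w21", "w23", "w32",
                 "w34", "w43", "w45", "w51", "w54"):
        cols[f"{name}_per_s"] = np.broadcast_to(getattr(rs, name), F.shape)
    _manifest("rates", params)
    _emit(pd.DataFrame(cols), out)


@main.command()
@_params_opt
@_cond_opt
@click.option("--force", type=float, default=None)
@_grid_opt
@_out_opt
def steady(params_file, cond_file, force, force_grid, out):
    """Steady-state probabilities P1..P5 and occupancy summaries."""
    params, cond = _params_from(params_file), _cond_from(cond_file)
    F = _forces(force, force_grid)
    dist = steady_state(rates_at(params, cond, F))
    p = np.atleast_2d(dist.p.T).reshape(len(F), 5)
    df = pd.DataFrame(p, columns=[f"P{i}" for i in range(1, 6)])
    df.insert(0, "force_pN", F)
    df["P_sb"] = df[["P3", "P4", "P5"]].sum(axis=1)
    df["P_on"] = df[["P2", "P3", "P4", "P5"]].sum(axis=1)
    _manifest("steady", params)
    _emit(df, out)


@main.command()
@_params_opt
@_cond_opt
@click.option("--force", type=float, default=None)
@_grid_opt
@_out_opt
def velocity(params_file, cond_file, force, force_grid, out):
    """Effective power-stroke velocity (nm/s) versus force."""
    params, cond = _params_from(params_file), _cond_from(cond_file)
    F = _forces(force, force_grid)
    v = velocity_vs_force(params, cond, F)
    _manifest("velocity", params)
    _emit(pd.DataFrame({"force_pN": F, "velocity_nm_per_s": v}), out)


@main.command()
@_params_opt
@_cond_opt
@_out_opt
def crossing(params_file, cond_file, out):
    """Forces where ADP- and ATP-state occupancies cross (0-6 pN)."""
    params, cond = _params_from(params_file), _cond_from(cond_file)
    roots = dominance_crossings(params, cond)
    _manifest("crossing", params)
    if not roots:
        click.echo("no P3 = P5 crossing in [0, 6] pN", err=True)
    _emit(pd.DataFrame({"crossing_force_pN": roots}), out)


@main.command("unbinding-curve")
@_params_opt
@_cond_opt
@click.option("--force-grid", nargs=3, type=float, default=(0.0, 6.0, 61),
              show_default=True)
@click.option("--quantity", type=click.Choice(["tsb", "koff", "twb"]),
              default="tsb", show_default=True,
              help="tsb: strong-state unbinding rate; koff: filament "
                   "detachment rate; twb: weak/detached time.")
@_out_opt
def unbinding_curve_cmd(params_file, cond_file, force_grid, quantity, out):
    """Attachment-statistic force sweeps from the absorbing-state analysis."""
    params, cond = _params_from(params_file), _cond_from(cond_file)
    lo, hi, n = force_grid
    F = np.linspace(lo, hi, int(n))
    y = unbinding_curve(params, cond, F, quantity=quantity)
    unit = "s" if quantity == "twb" else "per_s"
    _manifest("unbinding-curve", params)
    _emit(pd.DataFrame({"force_pN": F, f"{quantity}_{unit}": y}), out)


@main.command()
@_params_opt
@_cond_opt
@click.option("--n-heads", "-N", "n_heads", type=int, default=30,
              show_default=True)
@click.option("--force-grid", nargs=3, type=float, default=(0.0, 20.0, 21),
              show_default=True)
@click.option("--sharing", type=click.Choice(
    ["cooperative", "fixed", "selfconsistent"]), default="cooperative",
    show_default=True)
@click.option("--beta", type=float, default=1.0, show_default=True,
              help="Ca2+ binding-reduction factor.")
@click.option("--kappa-ca", type=float, default=None,
              help="Post-Ca2+ per-head stiffness, pN/nm (default: kappa).")
@_out_opt
def ensemble(params_file, cond_file, n_heads, force_grid, sharing, beta,
             kappa_ca, out):
    """Mean bound number, extension and Ca2+ release versus force."""
    params, cond = _params_from(params_file), _cond_from(cond_file)
    lo, hi, n = force_grid
    rows = []
    for F in np.linspace(lo, hi, int(n)):
        spec = ensemble_from_cycle(params, cond, N=n_heads, F=float(F),
                                   sharing=sharing, beta=beta,
                                   kappa_ca=kappa_ca)
        nbar = mean_bound(spec)
        rows.append({
            "force_pN": F, "mean_bound": nbar,
            "extension_nm": force_extension(spec) if nbar > 0 else np.inf,
            "release_nm": calcium_release(spec) if beta > 1 or kappa_ca
            else 0.0})
    _manifest("ensemble", params)
    _emit(pd.DataFrame(rows), out)


@main.command()
@click.option("--config", "config_file", type=click.Path(exists=True,
              dir_okay=False), required=True,
              help="JSON simulation config (keys of SimulationConfig; "
                   "params/conditions as nested objects or file paths).")
@click.option("--out", "out_prefix", type=str, required=True,
              help="Output prefix: writes PREFIX_events.csv and "
                   "PREFIX_summary.json.")
@click.option("--seed", type=int, default=None, help="Override config seed.")
def simulate(config_file, out_prefix, seed):
    """Run the coupled-ensemble Gillespie simulation."""
    with open(config_file) as fh:
        raw = json.load(fh)
    params = CycleParameters.from_dict(raw.pop("params", {})) \
        if isinstance(raw.get("params"), dict) \
        else _params_from(raw.pop("params", None))
    cond = Conditions.from_dict(raw.pop("conditions", {})) \
        if isinstance(raw.get("conditions"), dict) \
        else _cond_from(raw.pop("conditions", None))
    if seed is not None:
        raw["seed"] = seed
    cfg = SimulationConfig(params=params, conditions=cond, **raw)
    if cfg.mode == "motility":
        v, se, traj = motility_velocity(cfg)
    else:
        traj = gillespie_run(cfg)
        v = se = None
    events = pd.DataFrame({"time_s": traj.times, "head": traj.head,
                           "from_state": traj.s_from, "to_state": traj.s_to,
                           "backbone_nm": traj.X})
    events.to_csv(f"{out_prefix}_events.csv", index=False,
                  float_format="%.10g")
    summary = {"mean_bound": traj.mean_n,
               "detached_fraction": traj.detached_fraction,
               "n_events": traj.n_events, "t_end_s": traj.t_end,
               "seed": traj.seed, "params_hash": _params_hash(params)}
    if v is not None:
        summary["velocity_nm_per_s"] = v
        summary["velocity_se_nm_per_s"] = se
    with open(f"{out_prefix}_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    click.echo(json.dumps(summary, indent=1))


@main.command()
@click.option("--params", "params_file", type=click.Path(exists=True,
              dir_okay=False), default=None)
@click.option("--events", "events_n", type=int, default=500,
              show_default=True, help="Events per condition.")
@click.option("--mode", type=click.Choice(["exponential", "full_cycle"]),
              default="exponential", show_default=True)
@click.option("--dead-time", type=float, default=0.0, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@_out_opt
def synth(params_file, events_n, mode, dead_time, seed, out):
    """Generate a synthetic isometric-clamp attachment-event table."""
    params = _params_from(params_file)
    design = ExperimentDesign(events_per_condition=events_n, mode=mode,
                              dead_time=dead_time)
    table = generate_events(design, params, seed=seed)
    _manifest("synth", params, seed=seed)
    _emit(table, out)


@main.command()
@click.option("--events", "events_file", type=click.Path(exists=True,
              dir_okay=False), required=True,
              help="CSV with columns condition, force_pN, duration_s.")
@click.option("--fixed-params", "params_file", type=click.Path(exists=True,
              dir_okay=False), default=None)
@click.option("--alpha", type=float, default=0.05, show_default=True)
@click.option("--bin-width", type=float, default=1.0, show_default=True)
@click.option("--starts", type=int, default=20, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", type=click.Path(dir_okay=False), default=None,
              help="Write fitted parameters as JSON.")
def fit(events_file, params_file, alpha, bin_width, starts, seed, out):
    """Joint weighted fit of the unbinding-rate curves, then binding rate."""
    params = _params_from(params_file)
    events = pd.read_csv(events_file)
    binned = bin_events(events, bin_width=bin_width, alpha=alpha)
    labels = set(binned["condition"])
    unknown = labels - set(DEFAULT_FIT_CONDITIONS)
    if unknown:
        raise click.ClickException(
            f"unknown condition labels {sorted(unknown)}; expected "
            f"{sorted(DEFAULT_FIT_CONDITIONS)}")
    result = joint_fit(binned, DEFAULT_FIT_CONDITIONS, base=params,
                       n_starts=starts, seed=seed)
    report = {"theta": result.theta, "objective": result.objective,
              "n_starts": result.n_starts, "seed": seed,
              "params_hash": _params_hash(params)}
    click.echo(json.dumps(report, indent=1))
    if out:
        save_parameters(result.params, out)


@main.command()
@_params_opt
@click.option("--seed", type=int, default=0, show_default=True)
def reproduce(params_file, seed):
    """Recompute the headline model predictions and compare to references.

    Deterministic quantities only (the long stochastic motility run is
    available through `myo1c simulate`).
    """
    from .targets import evaluate_targets, REFERENCES

    params = _params_from(params_file)
    rows = []
    values = evaluate_targets(params=params, seed=seed)
    for key, ref in REFERENCES.items():
        got = values[key]["value"]
        tol = ref["rel_tol"] * abs(ref["value"])
        ok = got <= ref["value"] if ref["cmp"] == "le" \
            else abs(got - ref["value"]) <= tol
        rows.append({"target": key, "computed": got,
                     "reference": ref["value"], "cmp": ref["cmp"],
                     "pass": ok})
    df = pd.DataFrame(rows)
    _manifest("reproduce", params, seed=seed)
    _emit(df, None)
    if not df["pass"].all():
        raise SystemExit(1)


if __name__ == "__main__":
    main()
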