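"""Run drivers tying the pipeline together, with tabular outputs.

These are the computational entry points behind the command-line
interface: each takes plain configuration values, runs the relevant
pipeline stage (sampling, classification, continuation, time-domain
simulation) and returns tidy :class:`pandas.DataFrame` tables ready for
CSV export.  ``run_dir`` helpers persist (config, log, results) together
so every result is replayable from its config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .continuation import (
    continue_parameter,
    default_fold_grid,
    robustness_profiles,
)
from .ensemble import sample_constrained, sample_unconstrained
from .errors import ConfigurationError
from .fixtures import FIXTURE_NAMES, get_fixture
from .network import MetabolicNetwork, load_model
from .simulate import batch_run, fed_batch, productive_fraction

logger = logging.getLogger("emra")

DEFAULT_N = 1000
DEFAULT_REPLICATES = 3
DEFAULT_SEED = 20160310


@dataclass
class RunConfig:
    """Fully serializable description of one command invocation."""

    command: str
    system: str
    n: int = DEFAULT_N
    seed: int = DEFAULT_SEED
    replicates: int = DEFAULT_REPLICATES
    targets: list[str] = field(default_factory=list)
    fold_min: float = 0.1
    fold_max: float = 10.0
    fold_points: int = 41
    scheme: str = "default"
    batch_multiplier: float = 200.0
    feed_schedule: list = field(default_factory=list)
    out: str = "."

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def resolve_system(system: str) -> MetabolicNetwork:
    """Fixture name or path to a model file."""
    if system in FIXTURE_NAMES:
        return get_fixture(system)
    path = Path(system)
    if path.exists():
        return load_model(path)
    raise ConfigurationError(
        f"{system!r} is neither a fixture ({', '.join(FIXTURE_NAMES)}) "
        "nor a model file"
    )


def _replicate_seeds(seed: int, replicates: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(replicates)]


def intrinsic_summary(
    systems: list[str],
    n: int = DEFAULT_N,
    seed: int = DEFAULT_SEED,
    replicates: int = DEFAULT_REPLICATES,
    scheme: str = "default",
    measures: tuple[str, ...] = ("productive_unconstrained", "stable_constrained"),
) -> pd.DataFrame:
    """Both intrinsic-stability measures, replicated, as percent +/- SD.

    ``productive_unconstrained``: fraction of fully random parameter sets
    that reach a non-trivial productive steady state in time domain.
    ``stable_constrained``: fraction of reference-constrained draws whose
    fixed point is stable.  Replicates use independent child seeds of the
    root seed; the SD column is the across-replicate standard deviation in
    percentage points.
    """
    rows = []
    for system in systems:
        net = resolve_system(system)
        for measure in measures:
            fracs = []
            for rep_seed in _replicate_seeds(seed, replicates):
                if measure == "productive_unconstrained":
                    ens = sample_unconstrained(net, n, rep_seed, scheme=scheme)
                    frac = productive_fraction(net, ens)
                elif measure == "stable_constrained":
                    frac = sample_constrained(net, n, rep_seed).stable_fraction
                else:
                    raise ConfigurationError(f"unknown measure {measure!r}")
                fracs.append(100.0 * frac)
                logger.info("%s %s replicate: %.1f%%", system, measure, fracs[-1])
            rows.append(
                {
                    "system": system,
                    "measure": measure,
                    "percent": float(np.mean(fracs)),
                    "sd": float(np.std(fracs, ddof=1)) if len(fracs) > 1 else 0.0,
                    "replicates": replicates,
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def robustness_table(
    system: str,
    targets: list[str] | None = None,
    n: int = DEFAULT_N,
    seed: int = DEFAULT_SEED,
    fold_min: float = 0.1,
    fold_max: float = 10.0,
    fold_points: int = 41,
) -> pd.DataFrame:
    """Ensemble stability profiles for the requested enzyme targets.

    ``targets=None`` profiles every enzymatic reaction (group members are
    replaced by their group) plus the feed rate of each input exchange.
    """
    net = resolve_system(system)
    if targets is None:
        grouped = {r for members in net.groups.values() for r in members}
        targets = list(net.groups) + [
            r
            for r, k in zip(net.reaction_ids, net.kind)
            if r not in grouped and k != "output_exchange"
        ]
    grid = default_fold_grid(fold_min, fold_max, fold_points)
    ens = sample_constrained(net, n, seed)
    logger.info(
        "%s: constrained ensemble n=%d (%d draws)", system, n, ens.n_draws
    )
    return robustness_profiles(net, ens, targets, grid=grid)


def select_bifurcating_member(
    net: MetabolicNetwork,
    target: str,
    fold_lo: float,
    fold_hi: float,
    seed: int = DEFAULT_SEED,
    max_members: int = 50,
):
    """First constrained member whose upward bifurcation lands in a window.

    Mirrors the workflow of picking a representative parameter set whose
    productive branch vanishes at a known fold before running batch
    simulations.  Returns ``(member, profile)`` or raises if none found.
    """
    ens = sample_constrained(net, max_members, seed)
    for p in ens.members:
        prof = continue_parameter(net, p, target)
        if (
            prof.bifurcation_fold_up is not None
            and fold_lo <= prof.bifurcation_fold_up <= fold_hi
        ):
            return p, prof
    raise ConfigurationError(
        f"no member of {max_members} bifurcates upward in "
        f"[{fold_lo}, {fold_hi}] for target {target!r}"
    )


def batch_table(
    system: str,
    target: str,
    folds: list[float],
    substrate: str,
    multiplier: float = 200.0,
    seed: int = DEFAULT_SEED,
    member=None,
    t_end: float = 1e4,
):
    """Batch time-domain runs across enzyme folds for one parameter set.

    Returns ``(trajectories, summary)``: per-fold :class:`Trajectory`
    objects and a final-titer summary table.  If ``member`` is omitted the
    first member of a constrained ensemble is used.
    """
    net = resolve_system(system)
    if member is None:
        member = sample_constrained(net, 1, seed).members[0]
    from .continuation import _target_reactions

    rxns = _target_reactions(net, target)
    trajectories, rows = {}, []
    for fold in folds:
        vmax = dict(member.vmax)
        for r in rxns:
            vmax[r] *= fold
        p_fold = member.with_vmax(vmax)
        traj = batch_run(net, p_fold, substrate, multiplier, t_end=t_end)
        trajectories[fold] = traj
        rows.append(
            {
                "system": net.name,
                "target": target,
                "fold": fold,
                "final_titer": float(traj.product_amount[-1]),
                "t_final": float(traj.t[-1]),
            }
        )
    return trajectories, pd.DataFrame(rows)


def trajectory_frame(traj) -> pd.DataFrame:
    """Tidy (time, variable, value) export of a trajectory."""
    frames = [
        pd.DataFrame(
            {"time": traj.t, "variable": met, "value": traj.xbar_t[:, i]}
        )
        for i, met in enumerate(traj.net.metabolite_ids)
    ]
    frames.append(
        pd.DataFrame(
            {
                "time": traj.t,
                "variable": "production_rate",
                "value": traj.production_rate,
            }
        )
    )
    frames.append(
        pd.DataFrame(
            {
                "time": traj.t,
                "variable": "product_amount",
                "value": traj.product_amount,
            }
        )
    )
    return pd.concat(frames, ignore_index=True)


def fed_batch_table(
    system: str,
    feed_multipliers: list[float],
    seed: int = DEFAULT_SEED,
    member=None,
    t_end: float = 100.0,
    diagnostics: tuple[str, ...] = (),
):
    """Fed-batch runs at several constant feed rates for one member."""
    net = resolve_system(system)
    if member is None:
        member = sample_constrained(net, 1, seed).members[0]
    trajectories, rows = {}, []
    for mult in feed_multipliers:
        traj = fed_batch(net, member, mult, t_end=t_end)
        trajectories[mult] = traj
        row = {
            "system": net.name,
            "feed_multiplier": mult,
            "final_product": float(traj.product_amount[-1]),
        }
        for met in diagnostics:
            row[f"final_{met}"] = float(traj.series(met)[-1])
        rows.append(row)
    return trajectories, pd.DataFrame(rows)


def write_run(out_dir, config: RunConfig, results: dict[str, pd.DataFrame]):
    """Persist config + results atomically (write tmp, then rename)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in results.items():
        tmp = out / f".{name}.csv.tmp"
        frame.to_csv(tmp, index=False)
        tmp.replace(out / f"{name}.csv")
    tmp = out / ".config.json.tmp"
    tmp.write_text(config.to_json() + "\n")
    tmp.replace(out / "config.json")
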