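"""Enzyme-amount continuation: fold-change grids, bifurcation detection.

The continuation is a warm-started walk: starting from the reference fixed
point at fold 1, the target Vmax (an enzyme, a reaction group perturbed
jointly, or the feed rate ``IN``) is multiplied along a fold grid outward
in both directions; at each fold the steady state is re-solved from the
previous fold's state and its Jacobian re-classified.  When stability is
lost (or the steady state can no longer be located — typically past a
saddle-node where the productive branch has vanished), the branch is
terminated and the bifurcation fold is refined by bisection.  Unstable
branches are not tracked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .ensemble import Ensemble, sample_constrained
from .kinetics import PackedKinetics, ParameterSet
from .network import MetabolicNetwork
from .stability import packed_find_steady_state

STABLE, UNSTABLE, LOST = "stable", "unstable", "lost"


def default_fold_grid(
    fold_min: float = 0.1, fold_max: float = 10.0, n: int = 41
) -> np.ndarray:
    """Log-spaced fold multipliers containing 1.0 exactly."""
    grid = 10.0 ** np.linspace(np.log10(fold_min), np.log10(fold_max), n)
    grid = np.union1d(np.round(grid, 12), [1.0])
    return grid


@dataclass
class ContinuationProfile:
    """Stability status and output flux along one enzyme's fold grid."""

    target: str
    folds: np.ndarray
    status: list[str]
    flux_out: np.ndarray
    bifurcation_fold_up: float | None
    bifurcation_fold_down: float | None

    def stable_mask(self) -> np.ndarray:
        return np.array([s == STABLE for s in self.status])


def _target_reactions(net: MetabolicNetwork, target: str) -> list[str]:
    if target in net.groups:
        return list(net.groups[target])
    if target in net.reaction_ids:
        return [target]
    raise ConfigurationError(
        f"unknown continuation target {target!r}; expected a reaction or "
        f"group of {net.name}"
    )


def _output_flux(net: MetabolicNetwork, v: np.ndarray) -> float:
    mask = np.array([k == "output_exchange" for k in net.kind])
    return float(v[mask].sum())


def continue_parameter(
    net: MetabolicNetwork,
    p: ParameterSet,
    target: str,
    grid: np.ndarray | None = None,
    refine: bool = True,
    bisect_tol: float = 1e-3,
) -> ContinuationProfile:
    """Track the steady state of one member along a fold grid for ``target``.

    Returns per-fold status (``stable``/``unstable``/``lost``) and output
    flux; with ``refine=True`` the first stability loss in each direction
    is bisected to ``bisect_tol`` in the fold coordinate.
    """
    rxns = _target_reactions(net, target)
    grid = default_fold_grid() if grid is None else np.asarray(grid, dtype=float)
    pk0 = PackedKinetics(net, p)
    i_ref = int(np.argmin(np.abs(grid - 1.0)))

    def solve_at(fold: float, x_start: np.ndarray):
        pk = pk0.copy()
        pk.scale_vmax(rxns, fold)
        return packed_find_steady_state(pk, x_start)

    n = grid.shape[0]
    status = [LOST] * n
    flux = np.full(n, np.nan)
    bif = {+1: None, -1: None}
    x_ref = np.ones(net.n_metabolites)

    for direction in (+1, -1):
        x_prev = x_ref
        last_stable_fold = 1.0
        alive = True
        idx = range(i_ref, n) if direction > 0 else range(i_ref, -1, -1)
        for i in idx:
            if direction < 0 and i == i_ref:
                continue  # fold 1 handled on the way up
            if not alive:
                status[i] = LOST
                continue
            rec = solve_at(grid[i], x_prev)
            if rec.converged and rec.stable:
                status[i] = STABLE
                flux[i] = _output_flux(net, rec.v)
                x_prev = rec.xbar
                last_stable_fold = grid[i]
            else:
                status[i] = UNSTABLE if rec.converged else LOST
                if rec.converged:
                    flux[i] = _output_flux(net, rec.v)
                alive = False
                if refine:
                    bif[direction] = _bisect_bifurcation(
                        solve_at, last_stable_fold, grid[i], x_prev, bisect_tol
                    )
                else:
                    bif[direction] = grid[i]
    return ContinuationProfile(
        target=target,
        folds=grid,
        status=status,
        flux_out=flux,
        bifurcation_fold_up=bif[+1],
        bifurcation_fold_down=bif[-1],
    )


def _bisect_bifurcation(solve_at, fold_ok, fold_bad, x_ok, tol):
    """Refine the stability boundary between a good and a failed fold."""
    x_start = x_ok
    while abs(fold_bad - fold_ok) > tol:
        mid = 0.5 * (fold_ok + fold_bad)
        rec = solve_at(mid, x_start)
        if rec.converged and rec.stable:
            fold_ok = mid
            x_start = rec.xbar
        else:
            fold_bad = mid
    return 0.5 * (fold_ok + fold_bad)


def robustness_profile(
    net: MetabolicNetwork,
    ens: Ensemble,
    target: str,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fraction of ensemble members stable at each fold of ``target``.

    Long-format table with one row per (target, fold): columns ``system``,
    ``target``, ``fold``, ``fraction_stable``, ``n``.  Members come from a
    constrained ensemble, so the fraction at fold 1 is exactly 1.
    """
    if ens.mode != "constrained":
        raise ConfigurationError("robustness profiles need a constrained ensemble")
    grid = default_fold_grid() if grid is None else np.asarray(grid, dtype=float)
    counts = np.zeros(grid.shape[0])
    for p in ens.members:
        prof = continue_parameter(net, p, target, grid=grid, refine=False)
        counts += prof.stable_mask()
    return pd.DataFrame(
        {
            "system": net.name,
            "target": target,
            "fold": grid,
            "fraction_stable": counts / max(len(ens.members), 1),
            "n": len(ens.members),
        }
    )


def robustness_profiles(
    net: MetabolicNetwork,
    ens: Ensemble,
    targets: list[str],
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Concatenated :func:`robustness_profile` over several targets."""
    return pd.concat(
        [robustness_profile(net, ens, t, grid=grid) for t in targets],
        ignore_index=True,
    )


def compare_regulation(
    net_unreg: MetabolicNetwork,
    net_reg: MetabolicNetwork,
    n: int,
    targets: list[str],
    seed: int = 0,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Paired stability profiles for a regulated/unregulated network pair.

    Both ensembles are drawn with the same root seed, so on identical
    networks the curves coincide and any difference is attributable to the
    regulation term.  Returns the long-format profile table with a
    ``variant`` column plus, per (target, fold), the regulated-minus-
    unregulated difference in ``delta_fraction``.
    """
    missing = [t for t in targets if t not in net_reg.reaction_ids
               and t not in net_reg.groups]
    shared = set(net_unreg.reaction_ids) == set(net_reg.reaction_ids)
    if missing or not shared:
        raise ConfigurationError(
            "regulated and unregulated networks must share reaction naming"
        )
    frames = []
    for variant, net in (("unregulated", net_unreg), ("regulated", net_reg)):
        ens = sample_constrained(net, n, seed)
        tab = robustness_profiles(net, ens, targets, grid=grid)
        tab.insert(0, "variant", variant)
        frames.append(tab)
    out = pd.concat(frames, ignore_index=True)
    wide = out.pivot_table(
        index=["target", "fold"], columns="variant", values="fraction_stable"
    )
    delta = (wide["regulated"] - wide["unregulated"]).rename("delta_fraction")
    return out.merge(delta.reset_index(), on=["target", "fold"], how="left")
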