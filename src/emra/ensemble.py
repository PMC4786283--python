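"""Parameter-ensemble sampling: reference-constrained and fully random.

Two sampling modes mirror the two intrinsic-stability measures:

* ``constrained``: scaled affinities K̄ ~ U(0.1, 10), driving-force ratios
  ρ ~ U(0, 1) and inhibition constants K̄i ~ U(0.1, 10) are drawn, Vmax is
  *solved* so x̄ = 1 is a fixed point, and the draw is kept only if that
  fixed point is stable.  Unstable draws are discarded but counted, so the
  stable fraction (stable draws / total draws) is a by-product of building
  the ensemble rather than a separate run.

* ``unconstrained``: Vmax is itself random — log-uniform over a 100-fold
  range centered on the reference flux (Vref * 10^U(-1,1)) under the
  default scheme — and no fixed-point constraint is imposed.  Whether such
  a draw reaches a productive steady state is decided later by time-domain
  integration (see :mod:`emra.simulate`).

Reaction groups (e.g. the two phosphoketolase activities at weights
1/4 : 3/4) receive a *single* random magnitude split across members by
weight, so total group activity is one random variable.

Reproducibility: one root seed; each draw gets its own child stream from
``numpy.random.SeedSequence.spawn``, recorded in ``seed_info``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, SamplingError
from .kinetics import PackedKinetics, ParameterSet, solve_vmax
from .network import MetabolicNetwork
from .stability import classify_stability, n_structural_zeros, packed_jacobian

SCHEMES = ("default", "all-uniform", "all-log-uniform")

KBAR_LO, KBAR_HI = 0.1, 10.0


@dataclass
class Ensemble:
    """A collection of sampled parameter sets plus draw accounting."""

    members: list[ParameterSet]
    n_requested: int
    n_stable: int
    n_draws: int
    mode: str  # "constrained" | "unconstrained"
    distribution_config: str
    seed: int
    network: str = ""

    @property
    def stable_fraction(self) -> float:
        """Stable draws over total draws (the constrained-mode measure)."""
        return self.n_stable / self.n_draws if self.n_draws else float("nan")

    def to_dict(self) -> dict:
        return {
            "network": self.network,
            "mode": self.mode,
            "distribution_config": self.distribution_config,
            "seed": self.seed,
            "n_requested": self.n_requested,
            "n_stable": self.n_stable,
            "n_draws": self.n_draws,
            "members": [_params_to_dict(m) for m in self.members],
        }


def _params_to_dict(p: ParameterSet) -> dict:
    return {
        "kbar": {f"{r}::{m}": v for (r, m), v in p.kbar.items()},
        "rho": dict(p.rho),
        "kibar": {f"{r}::{m}": v for (r, m), v in p.kibar.items()},
        "vmax": dict(p.vmax or {}),
        "seed_info": dict(p.seed_info),
    }


def _kbar_slots(net: MetabolicNetwork):
    """All (reaction, metabolite) pairs that need a scaled affinity."""
    slots = []
    for j, rxn in enumerate(net.reaction_ids):
        kind = net.kind[j]
        if kind == "input_exchange":
            continue
        for met, _n in net.substrates(rxn):
            slots.append((rxn, met))
        if kind == "enzymatic" and net.reversible[j]:
            for met, _n in net.products(rxn):
                slots.append((rxn, met))
    return slots


def _draw_kbar(rng, scheme):
    if scheme == "all-log-uniform":
        return 10.0 ** rng.uniform(-1.0, 1.0)
    return rng.uniform(KBAR_LO, KBAR_HI)


def draw_parameters(
    net: MetabolicNetwork, rng: np.random.Generator, scheme: str = "default"
) -> ParameterSet:
    """Draw the non-Vmax parameters (K̄, ρ, K̄i) for one member.

    Each parameter class uses its own child stream, so networks differing
    only in regulation draw identical K̄ and ρ under the same seed —
    regulated-vs-unregulated comparisons are then driven purely by the
    inhibition term.
    """
    rng_k, rng_rho, rng_ki = rng.spawn(3)
    kbar = {slot: _draw_kbar(rng_k, scheme) for slot in _kbar_slots(net)}
    rho = {
        rxn: rng_rho.uniform(0.0, 1.0)
        for j, rxn in enumerate(net.reaction_ids)
        if net.kind[j] == "enzymatic" and net.reversible[j]
    }
    kibar = {
        (reg.reaction, reg.metabolite): _draw_kbar(rng_ki, scheme)
        for reg in net.regulators
    }
    return ParameterSet(kbar=kbar, rho=rho, kibar=kibar)


def _draw_vmax_factor(rng, scheme):
    if scheme == "all-uniform":
        return rng.uniform(KBAR_LO, KBAR_HI)
    return 10.0 ** rng.uniform(-1.0, 1.0)


def _grouped_reactions(net):
    out = {}
    for gname, members in net.groups.items():
        for rxn, w in members.items():
            out[rxn] = (gname, w)
    return out


def sample_constrained(net: MetabolicNetwork, n: int, seed: int) -> Ensemble:
    """Collect ``n`` stable reference-constrained members.

    Sampling continues until ``n`` stable members are found; the ratio of
    stable draws to total draws is the constrained intrinsic-stability
    fraction.  Raises :class:`SamplingError` if fewer than 1% of draws are
    stable after 100 * n attempts.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    root = np.random.SeedSequence(seed)
    members: list[ParameterSet] = []
    n_draws = 0
    while len(members) < n:
        if n_draws >= 100 * n and len(members) < n_draws / 100:
            raise SamplingError(
                f"{net.name}: only {len(members)}/{n_draws} draws stable; "
                "acceptance below 1% — inspect the model"
            )
        (child,) = root.spawn(1)
        rng = np.random.default_rng(child)
        p = draw_parameters(net, rng)
        p = solve_vmax(net, p)
        p.seed_info = {"root_seed": seed, "draw_index": n_draws}
        n_draws += 1
        pk = PackedKinetics(net, p)
        J = packed_jacobian(pk, np.ones(net.n_metabolites))
        _lead, stable = classify_stability(J, n_structural_zeros(pk))
        if stable:
            members.append(p)
    return Ensemble(
        members=members,
        n_requested=n,
        n_stable=len(members),
        n_draws=n_draws,
        mode="constrained",
        distribution_config="default",
        seed=seed,
        network=net.name,
    )


def sample_unconstrained(
    net: MetabolicNetwork, n: int, seed: int, scheme: str = "default"
) -> Ensemble:
    """Draw ``n`` fully random members (no fixed-point constraint).

    Vmax ranges over a 100-fold band centered on the reference flux;
    grouped reactions share one Vmax magnitude split by group weight.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if scheme not in SCHEMES:
        raise ConfigurationError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    root = np.random.SeedSequence(seed)
    grouped = _grouped_reactions(net)
    group_vref = {
        g: sum(net.vref[net.reaction_index(r)] for r in members)
        for g, members in net.groups.items()
    }
    members: list[ParameterSet] = []
    for i in range(n):
        (child,) = root.spawn(1)
        rng_params, rng_vmax = np.random.default_rng(child).spawn(2)
        p = draw_parameters(net, rng_params, scheme)
        vmax = {}
        group_total: dict[str, float] = {}
        for j, rxn in enumerate(net.reaction_ids):
            if rxn in grouped:
                gname, weight = grouped[rxn]
                if gname not in group_total:
                    group_total[gname] = group_vref[gname] * _draw_vmax_factor(
                        rng_vmax, scheme
                    )
                vmax[rxn] = weight * group_total[gname]
            else:
                vmax[rxn] = float(net.vref[j]) * _draw_vmax_factor(rng_vmax, scheme)
        p = p.with_vmax(vmax)
        p.seed_info = {"root_seed": seed, "draw_index": i}
        members.append(p)
    return Ensemble(
        members=members,
        n_requested=n,
        n_stable=0,
        n_draws=n,
        mode="unconstrained",
        distribution_config=scheme,
        seed=seed,
        network=net.name,
    )


def group_vmax_assignment(
    net: MetabolicNetwork,
    p: ParameterSet,
    group: str,
    magnitude: float | None = None,
    rng: np.random.Generator | None = None,
) -> ParameterSet:
    """Assign one Vmax magnitude to a group, split by the group's weights.

    ``magnitude`` is the total group activity; if omitted it is drawn
    log-uniformly over the 100-fold band centered on the group's total
    reference flux using ``rng``.
    """
    if group not in net.groups:
        raise ConfigurationError(
            f"unknown group {group!r}; available: {sorted(net.groups)}"
        )
    if magnitude is None:
        if rng is None:
            raise ConfigurationError("provide either magnitude or rng")
        total_vref = sum(
            net.vref[net.reaction_index(r)] for r in net.groups[group]
        )
        magnitude = total_vref * 10.0 ** rng.uniform(-1.0, 1.0)
    vmax = dict(p.vmax or {})
    for rxn, weight in net.groups[group].items():
        vmax[rxn] = weight * magnitude
    return p.with_vmax(vmax)
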