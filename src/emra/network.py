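"""Enzymatic network representation: stoichiometry, reversibility, exchanges.

A :class:`MetabolicNetwork` is the static description of a cell-free
enzymatic system in normalized coordinates: metabolite concentrations are
expressed relative to a reference steady state (so the reference state is
the all-ones vector) and the reference flux distribution ``vref`` must be a
right null vector of the stoichiometric matrix ``S`` (every balanced
metabolite has zero net production at reference).

Conventions
-----------
* All reference fluxes are positive; reaction direction lives in the sign
  pattern of the ``S`` column, never in the flux sign.
* ``input_exchange`` reactions are constant-rate sources feeding exactly one
  metabolite (+1 column); ``output_exchange`` reactions are irreversible
  saturable sinks draining exactly one metabolite (-1 column).
* Reaction groups tie several activities (e.g. the two phosphoketolase
  activities Fpk and Xpk) to a single controllable amount via fixed weights.

Model files are a small JSON dialect; ``save_model`` emits a canonical form
(sorted keys, fixed indentation) so save -> load -> save is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import sympy

from .errors import FluxImbalanceError, ModelFormatError

KINDS = ("enzymatic", "input_exchange", "output_exchange")

#: Max tolerated |S @ vref| for a model to count as flux-balanced.
FLUX_BALANCE_TOL = 1e-9


@dataclass(frozen=True)
class Regulator:
    """A competitive-inhibition edge: ``metabolite`` inhibits ``reaction``."""

    reaction: str
    metabolite: str
    mode: str = "competitive_inhibition"


@dataclass
class MetabolicNetwork:
    """Stoichiometry, reversibilities, exchanges and reference flux.

    Parameters
    ----------
    metabolite_ids, reaction_ids
        Names, in the row/column order of ``S``.
    S
        Integer stoichiometric matrix, metabolites x reactions.
    reversible
        Per-reaction flag; affects only the rate-law form, not directions.
    kind
        Per-reaction tag among ``{"enzymatic", "input_exchange",
        "output_exchange"}``.
    vref
        Strictly positive reference flux per reaction (normalized units).
    regulators
        Competitive-inhibition edges.
    groups
        ``name -> {reaction: weight}`` with weights summing to 1; a group is
        perturbed as one variable, split across members by weight.
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    reversible: np.ndarray
    kind: list[str]
    vref: np.ndarray
    regulators: list[Regulator] = field(default_factory=list)
    groups: dict[str, dict[str, float]] = field(default_factory=dict)
    name: str = "unnamed"
    provenance: str = "user"
    #: closed equilibrium toys (no exchanges) cannot balance a positive
    #: reference flux; set False to skip only the S @ vref check.
    check_balance: bool = True

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        self.vref = np.asarray(self.vref, dtype=float)
        self.validate()

    # -- indices ---------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolite_ids)

    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    def metabolite_index(self, met: str) -> int:
        try:
            return self.metabolite_ids.index(met)
        except ValueError:
            raise ModelFormatError(f"unknown metabolite {met!r}") from None

    def reaction_index(self, rxn: str) -> int:
        try:
            return self.reaction_ids.index(rxn)
        except ValueError:
            raise ModelFormatError(f"unknown reaction {rxn!r}") from None

    def substrates(self, rxn: str) -> list[tuple[str, int]]:
        """(metabolite, stoichiometric multiplicity) consumed by ``rxn``."""
        j = self.reaction_index(rxn)
        return [
            (self.metabolite_ids[i], int(-self.S[i, j]))
            for i in np.nonzero(self.S[:, j] < 0)[0]
        ]

    def products(self, rxn: str) -> list[tuple[str, int]]:
        """(metabolite, stoichiometric multiplicity) produced by ``rxn``."""
        j = self.reaction_index(rxn)
        return [
            (self.metabolite_ids[i], int(self.S[i, j]))
            for i in np.nonzero(self.S[:, j] > 0)[0]
        ]

    @property
    def exchange_mask(self) -> np.ndarray:
        return np.array([k != "enzymatic" for k in self.kind])

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        n_m, n_r = len(self.metabolite_ids), len(self.reaction_ids)
        if len(set(self.metabolite_ids)) != n_m:
            raise ModelFormatError("duplicate metabolite ids")
        if len(set(self.reaction_ids)) != n_r:
            raise ModelFormatError("duplicate reaction ids")
        if self.S.shape != (n_m, n_r):
            raise ModelFormatError(
                f"S has shape {self.S.shape}, expected {(n_m, n_r)}"
            )
        if not np.allclose(self.S, np.round(self.S)):
            raise ModelFormatError("stoichiometric coefficients must be integers")
        if self.reversible.shape != (n_r,) or self.vref.shape != (n_r,):
            raise ModelFormatError("reversible/vref length must match reactions")
        if len(self.kind) != n_r:
            raise ModelFormatError("kind length must match reactions")
        for rid, k in zip(self.reaction_ids, self.kind):
            if k not in KINDS:
                raise ModelFormatError(f"reaction {rid!r}: unknown kind {k!r}")
        for j, rid in enumerate(self.reaction_ids):
            col = self.S[:, j]
            if not col.any():
                raise ModelFormatError(f"reaction {rid!r}: empty column in S")
            if self.kind[j] == "input_exchange":
                if not (np.count_nonzero(col) == 1 and col.sum() == 1):
                    raise ModelFormatError(
                        f"input exchange {rid!r} must have a single +1 entry"
                    )
            elif self.kind[j] == "output_exchange":
                if not (np.count_nonzero(col) == 1 and col.sum() == -1):
                    raise ModelFormatError(
                        f"output exchange {rid!r} must have a single -1 entry"
                    )
        if np.any(self.vref <= 0):
            bad = [r for r, v in zip(self.reaction_ids, self.vref) if v <= 0]
            raise ModelFormatError(f"vref must be > 0 for all reactions: {bad}")
        for reg in self.regulators:
            self.reaction_index(reg.reaction)
            self.metabolite_index(reg.metabolite)
            if reg.mode != "competitive_inhibition":
                raise ModelFormatError(f"unsupported regulation mode {reg.mode!r}")
        for gname, members in self.groups.items():
            if not members:
                raise ModelFormatError(f"group {gname!r} is empty")
            for rxn in members:
                self.reaction_index(rxn)
            if abs(sum(members.values()) - 1.0) > 1e-12:
                raise ModelFormatError(f"group {gname!r} weights must sum to 1")
        resid = self.S @ self.vref
        if self.check_balance and np.max(np.abs(resid)) > FLUX_BALANCE_TOL:
            bad = [
                m
                for m, r in zip(self.metabolite_ids, resid)
                if abs(r) > FLUX_BALANCE_TOL
            ]
            raise FluxImbalanceError(
                f"reference flux is unbalanced at: {', '.join(bad)}", bad
            )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        reactions = []
        for j, rid in enumerate(self.reaction_ids):
            stoich = {
                self.metabolite_ids[i]: int(self.S[i, j])
                for i in np.nonzero(self.S[:, j])[0]
            }
            reactions.append(
                {
                    "id": rid,
                    "stoich": stoich,
                    "kind": self.kind[j],
                    "reversible": bool(self.reversible[j]),
                    "vref": float(self.vref[j]),
                }
            )
        return {
            "name": self.name,
            "provenance": self.provenance,
            "metabolites": list(self.metabolite_ids),
            "reactions": reactions,
            "regulators": [
                {"reaction": r.reaction, "metabolite": r.metabolite, "mode": r.mode}
                for r in self.regulators
            ],
            "groups": {g: dict(sorted(m.items())) for g, m in self.groups.items()},
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "MetabolicNetwork":
        try:
            metabolites = list(doc["metabolites"])
            reactions = doc["reactions"]
        except (KeyError, TypeError) as exc:
            raise ModelFormatError(f"missing required section: {exc}") from exc
        met_index = {m: i for i, m in enumerate(metabolites)}
        n_m, n_r = len(metabolites), len(reactions)
        S = np.zeros((n_m, n_r))
        rids, kinds, rev, vref = [], [], [], []
        for j, rec in enumerate(reactions):
            try:
                rids.append(rec["id"])
                kinds.append(rec.get("kind", "enzymatic"))
                rev.append(bool(rec.get("reversible", False)))
                vref.append(float(rec["vref"]))
                for met, coef in rec["stoich"].items():
                    if met not in met_index:
                        raise ModelFormatError(
                            f"reaction {rec.get('id', j)!r}: "
                            f"undeclared metabolite {met!r}"
                        )
                    S[met_index[met], j] = coef
            except (KeyError, TypeError, ValueError) as exc:
                if isinstance(exc, ModelFormatError):
                    raise
                raise ModelFormatError(
                    f"reaction entry {j} ({rec.get('id', '?')!r}): {exc}"
                ) from exc
        regulators = [
            Regulator(r["reaction"], r["metabolite"], r.get("mode", "competitive_inhibition"))
            for r in doc.get("regulators", [])
        ]
        groups = {
            g: {r: float(w) for r, w in members.items()}
            for g, members in doc.get("groups", {}).items()
        }
        return cls(
            metabolite_ids=metabolites,
            reaction_ids=rids,
            S=S,
            reversible=np.array(rev),
            kind=kinds,
            vref=np.array(vref),
            regulators=regulators,
            groups=groups,
            name=doc.get("name", "unnamed"),
            provenance=doc.get("provenance", "user"),
        )


@dataclass
class MoietyBasis:
    """Basis of conserved pools: left null vectors of the exchange-stripped S."""

    vectors: np.ndarray  # (n_moieties, n_metabolites)
    labels: list[str]

    @property
    def dim(self) -> int:
        return 0 if self.vectors.size == 0 else self.vectors.shape[0]

    def totals(self, x: np.ndarray) -> np.ndarray:
        """Conserved totals m^T x for a state (or trajectory, states in rows)."""
        if self.dim == 0:
            return np.zeros(np.shape(x)[:-1] + (0,))
        return np.asarray(x) @ self.vectors.T


def load_model(path) -> MetabolicNetwork:
    """Read a JSON model file and validate all structural invariants."""
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"{path}: line {exc.lineno}: {exc.msg}") from exc
    return MetabolicNetwork.from_dict(doc)


def save_model(net: MetabolicNetwork, path) -> None:
    """Write the canonical JSON form (stable key order, trailing newline)."""
    Path(path).write_text(dumps_model(net))


def dumps_model(net: MetabolicNetwork) -> str:
    return json.dumps(net.to_dict(), indent=2, sort_keys=True) + "\n"


def validate_reference_flux(net: MetabolicNetwork) -> np.ndarray:
    """Return the residual S @ vref; its max-abs entry is the imbalance."""
    return net.S @ net.vref


def conserved_moieties(net: MetabolicNetwork) -> MoietyBasis:
    """Conserved-pool basis over the non-exchanged metabolites.

    Exchange columns are stripped and the left null space is computed over
    the metabolites no exchange touches, with rational arithmetic rescaled
    to smallest integer form — cofactor pools come out as clean indicator
    vectors (e.g. NAD + NADH).  Pool totals are conserved both in
    continuous operation (exchanges never touch the pool members) and in
    batch operation (exchanges off).
    """
    closed = net.S[:, ~net.exchange_mask]
    exchanged_rows = set()
    for j in np.nonzero(net.exchange_mask)[0]:
        exchanged_rows.update(np.nonzero(net.S[:, j])[0])
    keep = [i for i in range(net.n_metabolites) if i not in exchanged_rows]
    if not keep or closed.size == 0:
        return MoietyBasis(vectors=np.zeros((0, net.n_metabolites)), labels=[])
    basis = sympy.Matrix(closed[keep].astype(int)).T.nullspace()
    vectors, labels = [], []
    for vec in basis:
        denominators = [sympy.fraction(c)[1] for c in vec]
        scaled = vec * sympy.lcm(denominators)
        content = sympy.gcd([c for c in scaled if c != 0] or [1])
        scaled = scaled / content
        if sum(scaled) < 0:
            scaled = -scaled
        arr = np.zeros(net.n_metabolites)
        arr[keep] = [float(c) for c in scaled]
        vectors.append(arr)
        members = [
            f"{'' if w == 1 else str(int(w)) + '*'}{m}"
            for m, w in zip(net.metabolite_ids, arr)
            if w != 0
        ]
        labels.append("+".join(members))
    vectors = np.array(vectors) if vectors else np.zeros((0, net.n_metabolites))
    return MoietyBasis(vectors=vectors, labels=labels)


def export_stoichiometry_csv(net: MetabolicNetwork, path) -> None:
    """CSV export of S: metabolites as rows, reactions as columns."""
    import pandas as pd

    pd.DataFrame(
        net.S.astype(int), index=net.metabolite_ids, columns=net.reaction_ids
    ).to_csv(path, index_label="metabolite")
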