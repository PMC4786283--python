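"""Built-in validated model files and a toy-network generator.

``get_fixture`` loads the JSON model files shipped with the package — the
same format users write by hand.  All built-in systems are reconstructions
from published pathway descriptions (``provenance="text-reconstruction"``);
see :mod:`emra.fixtures._builders` for the reconstruction logic and
:func:`list_fixtures` for a machine-readable catalog.
"""

from __future__ import annotations

from importlib import resources

import numpy as np

from ..errors import ConfigurationError
from ..network import MetabolicNetwork
from ._builders import BUILDERS, write_fixture_models

FIXTURE_NAMES = tuple(sorted(BUILDERS))

__all__ = [
    "FIXTURE_NAMES",
    "get_fixture",
    "list_fixtures",
    "make_toy_chain",
    "write_fixture_models",
]


def get_fixture(name: str) -> MetabolicNetwork:
    """Load a built-in system by name (validated on load)."""
    if name not in BUILDERS:
        raise ConfigurationError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    ref = resources.files(__package__) / "models" / f"{name}.json"
    from ..network import load_model

    with resources.as_file(ref) as path:
        return load_model(path)


def list_fixtures() -> list[dict]:
    """Catalog entries: name, provenance tag, sizes."""
    out = []
    for name in FIXTURE_NAMES:
        net = get_fixture(name)
        out.append(
            {
                "name": name,
                "provenance": net.provenance,
                "n_metabolites": net.n_metabolites,
                "n_reactions": net.n_reactions,
            }
        )
    return out


def make_toy_chain(
    length: int,
    reversible=None,
    seed: int = 0,
    branch: bool = False,
) -> MetabolicNetwork:
    """Linear chain in -> M1 -> ... -> Mk -> out with unit reference flux.

    Oracle substrate for stability and continuation tests: with all
    reactions irreversible the Jacobian at any admissible parameter draw is
    lower-triangular with negative diagonal, so every constrained draw is
    stable; in the high-K̄ limit the dynamics approach a linear
    first-order cascade with known rate matrix.

    Parameters
    ----------
    length
        Number of internal species (>= 1).
    reversible
        Optional per-conversion flags for the ``length - 1`` internal
        conversion steps.
    branch
        If true, adds a second output drain competing for M1, splitting the
        flux 50/50 — the minimal kinetic-trap branch-point motif.
    """
    if length < 1:
        raise ConfigurationError("length must be >= 1")
    n_steps = length - 1
    if reversible is None:
        reversible = [False] * n_steps
    if len(reversible) != n_steps:
        raise ConfigurationError(f"need {n_steps} reversibility flags")
    mets = [f"M{i + 1}" for i in range(length)]
    chain_flux = 0.5 if branch else 1.0
    reactions = [("IN", {"M1": 1}, "input_exchange", False, 1.0)]
    for i in range(n_steps):
        reactions.append(
            (
                f"E{i + 1}",
                {mets[i]: -1, mets[i + 1]: 1},
                "enzymatic",
                bool(reversible[i]),
                chain_flux,
            )
        )
    reactions.append(("OUT", {mets[-1]: -1}, "output_exchange", False, chain_flux))
    if branch:
        reactions.append(("OUTB", {"M1": -1}, "output_exchange", False, 0.5))
    doc = {
        "name": f"toy_chain_{length}" + ("_branch" if branch else ""),
        "provenance": "generator",
        "metabolites": mets,
        "reactions": [
            {"id": rid, "stoich": st, "kind": kind, "reversible": rev, "vref": v}
            for rid, st, kind, rev, v in reactions
        ],
    }
    return MetabolicNetwork.from_dict(doc)
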