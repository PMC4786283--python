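"""Programmatic definitions of the built-in cell-free systems.

Every network here is reconstructed from published pathway descriptions:
the reaction lists, carbon/cofactor balances and reference flux
distributions are fixed by stoichiometric arithmetic (the reference flux is
the unique steady-state flux mode once the output flux is normalized), and
reversibilities follow three rules — a reaction is irreversible if it is an
ATP-dependent kinase, has a strongly negative standard free energy
(below about -20 kJ/mol), or is a decarboxylation.  All entries carry
``provenance="text-reconstruction"``.

The canonical JSON files shipped under ``models/`` are generated from these
builders; a test asserts they stay in sync.
"""

from __future__ import annotations

from ..network import MetabolicNetwork

_PROV = "text-reconstruction"


def _net(name, metabolites, reactions, regulators=(), groups=None):
    doc = {
        "name": name,
        "provenance": _PROV,
        "metabolites": metabolites,
        "reactions": [
            {
                "id": rid,
                "stoich": stoich,
                "kind": kind,
                "reversible": rev,
                "vref": float(vref),
            }
            for rid, stoich, kind, rev, vref in reactions
        ],
        "regulators": [
            {"reaction": r, "metabolite": m, "mode": "competitive_inhibition"}
            for r, m in regulators
        ],
        "groups": groups or {},
    }
    return MetabolicNetwork.from_dict(doc)


# ---------------------------------------------------------------------------
# Methanol condensation cycle: formaldehyde -> acetyl-phosphate, 100% carbon.
# Metabolite order follows the published normalized-concentration table.

_MCC_METS = ["CH2O", "Ru5P", "H6P", "F6P", "E4P", "S7P", "G3P", "X5P", "R5P", "AcP"]


def _mcc(name, pk_reactions, fluxes, groups=None):
    reactions = [
        ("IN", {"CH2O": 1}, "input_exchange", False, 2),
        ("Hps", {"CH2O": -1, "Ru5P": -1, "H6P": 1}, "enzymatic", False, 2),
        ("Phi", {"H6P": -1, "F6P": 1}, "enzymatic", True, 2),
    ]
    reactions += pk_reactions
    reactions += [
        ("Tal", {"F6P": -1, "E4P": -1, "S7P": 1, "G3P": 1}, "enzymatic", True,
         fluxes["Tal"]),
        ("Tkt1", {"S7P": -1, "G3P": -1, "X5P": 1, "R5P": 1}, "enzymatic", True,
         fluxes["Tkt1"]),
        ("Rpe", {"X5P": -1, "Ru5P": 1}, "enzymatic", True, fluxes["Rpe"]),
        ("Rpi", {"R5P": -1, "Ru5P": 1}, "enzymatic", True, fluxes["Rpi"]),
        ("OUT", {"AcP": -1}, "output_exchange", False, 1),
    ]
    if "Tkt2" in fluxes:
        reactions.insert(
            3,
            ("Tkt2", {"F6P": -1, "G3P": -1, "E4P": 1, "X5P": 1}, "enzymatic",
             True, fluxes["Tkt2"]),
        )
    return _net(name, _MCC_METS, reactions, groups=groups)


def mcc_fpk() -> MetabolicNetwork:
    """MCC running only the F6P-cleaving phosphoketolase activity."""
    return _mcc(
        "mcc_fpk",
        [("Fpk", {"F6P": -1, "E4P": 1, "AcP": 1}, "enzymatic", False, 1)],
        {"Tal": 1, "Tkt1": 1, "Rpe": 1, "Rpi": 1},
    )


def mcc_xpk() -> MetabolicNetwork:
    """MCC running only the X5P-cleaving phosphoketolase activity."""
    return _mcc(
        "mcc_xpk",
        [("Xpk", {"X5P": -1, "G3P": 1, "AcP": 1}, "enzymatic", False, 1)],
        {"Tkt2": 1, "Tal": 1, "Tkt1": 1, "Rpe": 1, "Rpi": 1},
    )


def mcc_mixed_1_3() -> MetabolicNetwork:
    """MCC with both phosphoketolase activities at a 1:3 Fpk:Xpk ratio.

    The two activities form a group perturbed as one variable with fixed
    Vmax weights 1/4 (Fpk) and 3/4 (Xpk).
    """
    return _mcc(
        "mcc_mixed_1_3",
        [
            ("Fpk", {"F6P": -1, "E4P": 1, "AcP": 1}, "enzymatic", False, 0.25),
            ("Xpk", {"X5P": -1, "G3P": 1, "AcP": 1}, "enzymatic", False, 0.75),
        ],
        {"Tkt2": 0.75, "Tal": 1, "Tkt1": 1, "Rpe": 1, "Rpi": 1},
        groups={"PK": {"Fpk": 0.25, "Xpk": 0.75}},
    )


# ---------------------------------------------------------------------------
# Molecular purge valve: pyruvate -> PHB with cofactor-specific PDH isozymes.


def purge_valve_phb() -> MetabolicNetwork:
    """Pyruvate-to-PHB purge valve.

    Two pyruvate dehydrogenases with different cofactor specificity split
    the flux: the NADPH-specific one supplies reducing power for PHB
    synthesis, the NADH-specific one generates excess reducing equivalents
    dissipated by the NADH oxidase NoxE.  PhaA condenses two acetyl-CoA;
    PhaB lumps the NADPH-dependent reduction with polymer formation.
    """
    mets = ["Pyr", "AcCoA", "AcAcCoA", "PHB", "NAD", "NADH", "NADP", "NADPH"]
    reactions = [
        ("IN", {"Pyr": 1}, "input_exchange", False, 2),
        ("PDH_NADH", {"Pyr": -1, "NAD": -1, "AcCoA": 1, "NADH": 1},
         "enzymatic", False, 1),
        ("PDH_NADPH", {"Pyr": -1, "NADP": -1, "AcCoA": 1, "NADPH": 1},
         "enzymatic", False, 1),
        ("PhaA", {"AcCoA": -2, "AcAcCoA": 1}, "enzymatic", True, 1),
        ("PhaB", {"AcAcCoA": -1, "NADPH": -1, "PHB": 1, "NADP": 1},
         "enzymatic", False, 1),
        ("NoxE", {"NADH": -1, "NAD": 1}, "enzymatic", False, 1),
        ("OUT", {"PHB": -1}, "output_exchange", False, 1),
    ]
    return _net("purge_valve_phb", mets, reactions)


# ---------------------------------------------------------------------------
# Glycolysis variants: glucose -> lactate.


def chimeric_glycolysis() -> MetabolicNetwork:
    """ATP-balanced chimeric glycolysis using non-phosphorylating GapN.

    GapN oxidizes GAP directly to 3-phosphoglycerate without substrate-level
    phosphorylation, so ATP consumed by GK and PFK is exactly regenerated by
    PYK: net zero ATP per glucose, net zero NADH (lactate output).
    """
    mets = ["Glc", "G6P", "F6P", "FBP", "DHAP", "GAP", "PG3", "PEP", "Pyr",
            "Lac", "ATP", "ADP", "NAD", "NADH"]
    reactions = [
        ("IN", {"Glc": 1}, "input_exchange", False, 1),
        ("GK", {"Glc": -1, "ATP": -1, "G6P": 1, "ADP": 1}, "enzymatic", False, 1),
        ("PGI", {"G6P": -1, "F6P": 1}, "enzymatic", True, 1),
        ("PFK", {"F6P": -1, "ATP": -1, "FBP": 1, "ADP": 1}, "enzymatic", False, 1),
        ("FBA", {"FBP": -1, "DHAP": 1, "GAP": 1}, "enzymatic", True, 1),
        ("TPI", {"DHAP": -1, "GAP": 1}, "enzymatic", True, 1),
        ("GapN", {"GAP": -1, "NAD": -1, "PG3": 1, "NADH": 1}, "enzymatic",
         False, 2),
        ("ENO", {"PG3": -1, "PEP": 1}, "enzymatic", True, 2),
        ("PYK", {"PEP": -1, "ADP": -1, "Pyr": 1, "ATP": 1}, "enzymatic",
         False, 2),
        ("LDH", {"Pyr": -1, "NADH": -1, "Lac": 1, "NAD": 1}, "enzymatic",
         False, 2),
        ("OUT", {"Lac": -1}, "output_exchange", False, 2),
    ]
    return _net("chimeric_glycolysis", mets, reactions)


def emp_glycolysis_atpd() -> MetabolicNetwork:
    """Canonical EMP glycolysis to lactate, closed by an ATP drain.

    Phosphorylating GAPDH plus PGK yield +2 net ATP per glucose; an
    ATP-hydrolysis drain (ATPD) carries that surplus so a reference steady
    state exists.
    """
    mets = ["Glc", "G6P", "F6P", "FBP", "DHAP", "GAP", "BPG", "PG3", "PEP",
            "Pyr", "Lac", "ATP", "ADP", "NAD", "NADH"]
    reactions = [
        ("IN", {"Glc": 1}, "input_exchange", False, 1),
        ("GK", {"Glc": -1, "ATP": -1, "G6P": 1, "ADP": 1}, "enzymatic", False, 1),
        ("PGI", {"G6P": -1, "F6P": 1}, "enzymatic", True, 1),
        ("PFK", {"F6P": -1, "ATP": -1, "FBP": 1, "ADP": 1}, "enzymatic", False, 1),
        ("FBA", {"FBP": -1, "DHAP": 1, "GAP": 1}, "enzymatic", True, 1),
        ("TPI", {"DHAP": -1, "GAP": 1}, "enzymatic", True, 1),
        ("Gap", {"GAP": -1, "NAD": -1, "BPG": 1, "NADH": 1}, "enzymatic",
         True, 2),
        ("Pgk", {"BPG": -1, "ADP": -1, "PG3": 1, "ATP": 1}, "enzymatic",
         True, 2),
        ("ENO", {"PG3": -1, "PEP": 1}, "enzymatic", True, 2),
        ("PYK", {"PEP": -1, "ADP": -1, "Pyr": 1, "ATP": 1}, "enzymatic",
         False, 2),
        ("LDH", {"Pyr": -1, "NADH": -1, "Lac": 1, "NAD": 1}, "enzymatic",
         False, 2),
        ("ATPD", {"ATP": -1, "ADP": 1}, "enzymatic", False, 2),
        ("OUT", {"Lac": -1}, "output_exchange", False, 2),
    ]
    return _net("emp_glycolysis_atpd", mets, reactions)


# ---------------------------------------------------------------------------
# Glucose -> isoprene: NADPH-dependent glycolysis + mevalonate route.


def _isoprene(name, regulated):
    mets = ["Glc", "G6P", "F6P", "FBP", "DHAP", "GAP", "BPG", "PG3", "PG2",
            "PEP", "Pyr", "AcCoA", "AcAcCoA", "HMGCoA", "MVA", "MVAP",
            "MVAPP", "IPP", "DMAPP", "Iso", "ATP", "ADP", "NADP", "NADPH"]
    v = 2.0 / 3.0  # isoprene-route flux per glucose (2 isoprene : 3 glucose)
    reactions = [
        ("IN", {"Glc": 1}, "input_exchange", False, 1),
        ("GK", {"Glc": -1, "ATP": -1, "G6P": 1, "ADP": 1}, "enzymatic", False, 1),
        ("PGI", {"G6P": -1, "F6P": 1}, "enzymatic", True, 1),
        ("PFK", {"F6P": -1, "ATP": -1, "FBP": 1, "ADP": 1}, "enzymatic", False, 1),
        ("FBA", {"FBP": -1, "DHAP": 1, "GAP": 1}, "enzymatic", True, 1),
        ("TPI", {"DHAP": -1, "GAP": 1}, "enzymatic", True, 1),
        ("GAPDH", {"GAP": -1, "NADP": -1, "BPG": 1, "NADPH": 1}, "enzymatic",
         True, 2),
        ("PGK", {"BPG": -1, "ADP": -1, "PG3": 1, "ATP": 1}, "enzymatic",
         True, 2),
        ("PGM", {"PG3": -1, "PG2": 1}, "enzymatic", True, 2),
        ("ENO", {"PG2": -1, "PEP": 1}, "enzymatic", True, 2),
        ("PYK", {"PEP": -1, "ADP": -1, "Pyr": 1, "ATP": 1}, "enzymatic",
         False, 2),
        ("PDH", {"Pyr": -1, "NADP": -1, "AcCoA": 1, "NADPH": 1}, "enzymatic",
         False, 2),
        ("AtoB", {"AcCoA": -2, "AcAcCoA": 1}, "enzymatic", True, v),
        ("HMGS", {"AcAcCoA": -1, "AcCoA": -1, "HMGCoA": 1}, "enzymatic",
         True, v),
        ("HMGR", {"HMGCoA": -1, "NADPH": -2, "MVA": 1, "NADP": 2},
         "enzymatic", False, v),
        ("MK", {"MVA": -1, "ATP": -1, "MVAP": 1, "ADP": 1}, "enzymatic",
         False, v),
        ("PMK", {"MVAP": -1, "ATP": -1, "MVAPP": 1, "ADP": 1}, "enzymatic",
         False, v),
        ("MDC", {"MVAPP": -1, "ATP": -1, "IPP": 1, "ADP": 1}, "enzymatic",
         False, v),
        ("IDI", {"IPP": -1, "DMAPP": 1}, "enzymatic", True, v),
        ("IspS", {"DMAPP": -1, "Iso": 1}, "enzymatic", False, v),
        ("NADPHD", {"NADPH": -1, "NADP": 1}, "enzymatic", False, 4 * v),
        ("OUT", {"Iso": -1}, "output_exchange", False, v),
    ]
    regulators = [("GK", "G6P")] if regulated else []
    return _net(name, mets, reactions, regulators=regulators)


def glucose_isoprene() -> MetabolicNetwork:
    """Glucose-to-isoprene pathway, no regulation.

    NADPH-specific GAPDH and PDH feed reducing power to the mevalonate
    route; surplus NADPH leaves through an explicit drain (NADPHD).  The
    route is exactly ATP-balanced and converts 3 glucose to 2 isoprene.
    21 perturbable activities: 20 enzymes plus the glucose feed.
    """
    return _isoprene("glucose_isoprene", regulated=False)


def glucose_isoprene_gkreg() -> MetabolicNetwork:
    """Isoprene pathway with competitive G6P inhibition of glucokinase."""
    return _isoprene("glucose_isoprene_gkreg", regulated=True)


BUILDERS = {
    "mcc_fpk": mcc_fpk,
    "mcc_xpk": mcc_xpk,
    "mcc_mixed_1_3": mcc_mixed_1_3,
    "purge_valve_phb": purge_valve_phb,
    "chimeric_glycolysis": chimeric_glycolysis,
    "emp_glycolysis_atpd": emp_glycolysis_atpd,
    "glucose_isoprene": glucose_isoprene,
    "glucose_isoprene_gkreg": glucose_isoprene_gkreg,
}


def write_fixture_models(directory) -> None:
    """(Re)generate the canonical JSON model files under ``directory``."""
    from pathlib import Path

    from ..network import save_model

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, build in BUILDERS.items():
        save_model(build(), directory / f"{name}.json")
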