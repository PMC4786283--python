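{
  "groups": {},
  "metabolites": [
    "Pyr",
    "AcCoA",
    "AcAcCoA",
    "PHB",
    "NAD",
    "NADH",
    "NADP",
    "NADPH"
  ],
  "name": "purge_valve_phb",
  "provenance": "text-reconstruction",
  "reactions": [
    {
      "id": "IN",
      "kind": "input_exchange",
      "reversible": false,
      "stoich": {
        "Pyr": 1
      },
      "vref": 2.0
    },
    {
      "id": "PDH_NADH",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "AcCoA": 1,
        "NAD": -1,
        "NADH": 1,
        "Pyr": -1
      },
      "vref": 1.0
    },
    {
      "id": "PDH_NADPH",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "AcCoA": 1,
        "NADP": -1,
        "NADPH": 1,
        "Pyr": -1
      },
      "vref": 1.0
    },
    {
      "id": "PhaA",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "AcAcCoA": 1,
        "AcCoA": -2
      },
      "vref": 1.0
    },
    {
      "id": "PhaB",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "AcAcCoA": -1,
        "NADP": 1,
        "NADPH": -1,
        "PHB": 1
      },
      "vref": 1.0
    },
    {
      "id": "NoxE",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "NAD": 1,
        "NADH": -1
      },
      "vref": 1.0
    },
    {
      "id": "OUT",
      "kind": "output_exchange",
      "reversible": false,
      "stoich": {
        "PHB": -1
      },
      "vref": 1.0
    }
  ],
  "regulators": []
}
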