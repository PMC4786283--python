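{
  "groups": {},
  "metabolites": [
    "Glc",
    "G6P",
    "F6P",
    "FBP",
    "DHAP",
    "GAP",
    "PG3",
    "PEP",
    "Pyr",
    "Lac",
    "ATP",
    "ADP",
    "NAD",
    "NADH"
  ],
  "name": "chimeric_glycolysis",
  "provenance": "text-reconstruction",
  "reactions": [
    {
      "id": "IN",
      "kind": "input_exchange",
      "reversible": false,
      "stoich": {
        "Glc": 1
      },
      "vref": 1.0
    },
    {
      "id": "GK",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "ADP": 1,
        "ATP": -1,
        "G6P": 1,
        "Glc": -1
      },
      "vref": 1.0
    },
    {
      "id": "PGI",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "F6P": 1,
        "G6P": -1
      },
      "vref": 1.0
    },
    {
      "id": "PFK",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "ADP": 1,
        "ATP": -1,
        "F6P": -1,
        "FBP": 1
      },
      "vref": 1.0
    },
    {
      "id": "FBA",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "DHAP": 1,
        "FBP": -1,
        "GAP": 1
      },
      "vref": 1.0
    },
    {
      "id": "TPI",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "DHAP": -1,
        "GAP": 1
      },
      "vref": 1.0
    },
    {
      "id": "GapN",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "GAP": -1,
        "NAD": -1,
        "NADH": 1,
        "PG3": 1
      },
      "vref": 2.0
    },
    {
      "id": "ENO",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "PEP": 1,
        "PG3": -1
      },
      "vref": 2.0
    },
    {
      "id": "PYK",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "ADP": -1,
        "ATP": 1,
        "PEP": -1,
        "Pyr": 1
      },
      "vref": 2.0
    },
    {
      "id": "LDH",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "Lac": 1,
        "NAD": 1,
        "NADH": -1,
        "Pyr": -1
      },
      "vref": 2.0
    },
    {
      "id": "OUT",
      "kind": "output_exchange",
      "reversible": false,
      "stoich": {
        "Lac": -1
      },
      "vref": 2.0
    }
  ],
  "regulators": []
}
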