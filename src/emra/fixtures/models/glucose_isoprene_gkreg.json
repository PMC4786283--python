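{
  "groups": {},
  "metabolites": [
    "Glc",
    "G6P",
    "F6P",
    "FBP",
    "DHAP",
    "GAP",
    "BPG",
    "PG3",
    "PG2",
    "PEP",
    "Pyr",
    "AcCoA",
    "AcAcCoA",
    "HMGCoA",
    "MVA",
    "MVAP",
    "MVAPP",
    "IPP",
    "DMAPP",
    "Iso",
    "ATP",
    "ADP",
    "NADP",
    "NADPH"
  ],
  "name": "glucose_isoprene_gkreg",
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
      "id": "GAPDH",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "BPG": 1,
        "GAP": -1,
        "NADP": -1,
        "NADPH": 1
      },
      "vref": 2.0
    },
    {
      "id": "PGK",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "ADP": -1,
        "ATP": 1,
        "BPG": -1,
        "PG3": 1
      },
      "vref": 2.0
    },
    {
      "id": "PGM",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "PG2": 1,
        "PG3": -1
      },
      "vref": 2.0
    },
    {
      "id": "ENO",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "PEP": 1,
        "PG2": -1
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
      "id": "PDH",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "AcCoA": 1,
        "NADP": -1,
        "NADPH": 1,
        "Pyr": -1
      },
      "vref": 2.0
    },
    {
      "id": "AtoB",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "AcAcCoA": 1,
        "AcCoA": -2
      },
      "vref": 0.6666666666666666
    },
    {
      "id": "HMGS",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "AcAcCoA": -1,
        "AcCoA": -1,
        "HMGCoA": 1
      },
      "vref": 0.6666666666666666
    },
    {
      "id": "HMGR",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "HMGCoA": -1,
        "MVA": 1,
        "NADP": 2,
        "NADPH": -2
      },
      "vref": 0.6666666666666666
    },
    {
      "id": "MK",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "ADP": 1,
        "ATP": -1,
        "MVA": -1,
        "MVAP": 1
      },
      "vref": 0.6666666666666666
    },
    {
      "id": "PMK",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "ADP": 1,
        "ATP": -1,
        "MVAP": -1,
        "MVAPP": 1
      },
      "vref": 0.6666666666666666
    },
    {
      "id": "MDC",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "ADP": 1,
        "ATP": -1,
        "IPP": 1,
        "MVAPP": -1
      },
      "vref": 0.6666666666666666
    },
    {
      "id": "IDI",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "DMAPP": 1,
        "IPP": -1
      },
      "vref": 0.6666666666666666
    },
    {
      "id": "IspS",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "DMAPP": -1,
        "Iso": 1
      },
      "vref": 0.6666666666666666
    },
    {
      "id": "NADPHD",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "NADP": 1,
        "NADPH": -1
      },
      "vref": 2.6666666666666665
    },
    {
      "id": "OUT",
      "kind": "output_exchange",
      "reversible": false,
      "stoich": {
        "Iso": -1
      },
      "vref": 0.6666666666666666
    }
  ],
  "regulators": [
    {
      "metabolite": "G6P",
      "mode": "competitive_inhibition",
      "reaction": "GK"
    }
  ]
}
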