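{
  "groups": {},
  "metabolites": [
    "CH2O",
    "Ru5P",
    "H6P",
    "F6P",
    "E4P",
    "S7P",
    "G3P",
    "X5P",
    "R5P",
    "AcP"
  ],
  "name": "mcc_fpk",
  "provenance": "text-reconstruction",
  "reactions": [
    {
      "id": "IN",
      "kind": "input_exchange",
      "reversible": false,
      "stoich": {
        "CH2O": 1
      },
      "vref": 2.0
    },
    {
      "id": "Hps",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "CH2O": -1,
        "H6P": 1,
        "Ru5P": -1
      },
      "vref": 2.0
    },
    {
      "id": "Phi",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "F6P": 1,
        "H6P": -1
      },
      "vref": 2.0
    },
    {
      "id": "Fpk",
      "kind": "enzymatic",
      "reversible": false,
      "stoich": {
        "AcP": 1,
        "E4P": 1,
        "F6P": -1
      },
      "vref": 1.0
    },
    {
      "id": "Tal",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "E4P": -1,
        "F6P": -1,
        "G3P": 1,
        "S7P": 1
      },
      "vref": 1.0
    },
    {
      "id": "Tkt1",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "G3P": -1,
        "R5P": 1,
        "S7P": -1,
        "X5P": 1
      },
      "vref": 1.0
    },
    {
      "id": "Rpe",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "Ru5P": 1,
        "X5P": -1
      },
      "vref": 1.0
    },
    {
      "id": "Rpi",
      "kind": "enzymatic",
      "reversible": true,
      "stoich": {
        "R5P": -1,
        "Ru5P": 1
      },
      "vref": 1.0
    },
    {
      "id": "OUT",
      "kind": "output_exchange",
      "reversible": false,
      "stoich": {
        "AcP": -1
      },
      "vref": 1.0
    }
  ],
  "regulators": []
}
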