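{
  "module_assignment": {
    "ASV_0001": 0,
    "ASV_0002": 1,
    "ASV_0003": 2,
    "ASV_0004": 0,
    "ASV_0005": 1,
    "ASV_0006": 2,
    "ASV_0007": 0,
    "ASV_0008": 1,
    "ASV_0009": 2,
    "ASV_0010": 0,
    "ASV_0011": 1,
    "ASV_0012": 2,
    "ASV_0013": 0,
    "ASV_0014": 1,
    "ASV_0015": 2,
    "ASV_0016": 0,
    "ASV_0017": 1,
    "ASV_0018": 2,
    "ASV_0019": 0,
    "ASV_0020": 1,
    "ASV_0021": 2,
    "ASV_0022": 0,
    "ASV_0023": 1,
    "ASV_0024": 2,
    "ASV_0025": 0,
    "ASV_0026": 1,
    "ASV_0027": 2,
    "ASV_0028": 0,
    "ASV_0029": 1,
    "ASV_0030": 2,
    "ASV_0031": 0,
    "ASV_0032": 1,
    "ASV_0033": 2,
    "ASV_0034": 0,
    "ASV_0035": 1,
    "ASV_0036": 2,
    "ASV_0037": 0,
    "ASV_0038": 1,
    "ASV_0039": 2,
    "ASV_0040": 0,
    "ASV_0041": 1,
    "ASV_0042": 2,
    "ASV_0043": 0,
    "ASV_0044": 1,
    "ASV_0045": 2,
    "ASV_0046": 0,
    "ASV_0047": 1,
    "ASV_0048": 2,
    "ASV_0049": 0,
    "ASV_0050": 1,
    "ASV_0051": 2,
    "ASV_0052": 0,
    "ASV_0053": 1,
    "ASV_0054": 2,
    "ASV_0055": 0,
    "ASV_0056": 1,
    "ASV_0057": 2,
    "ASV_0058": 0,
    "ASV_0059": 1,
    "ASV_0060": 2
  },
  "planted_roles": {
    "ASV_0001": "module_hub",
    "ASV_0011": "connector",
    "ASV_0021": "module_hub",
    "ASV_0041": "module_hub"
  },
  "true_paths": [
    [
      "AN",
      "RW",
      0.25
    ],
    [
      "Mg",
      "BD",
      -0.2
    ],
    [
      "NN",
      "BC",
      -0.3
    ],
    [
      "NN",
      "BD",
      -0.3
    ],
    [
      "NN",
      "FD",
      -0.25
    ],
    [
      "NN",
      "RW",
      -0.4
    ],
    [
      "Na",
      "BC",
      -0.35
    ],
    [
      "Na",
      "FC",
      -0.3
    ],
    [
      "RW",
      "BC",
      0.4
    ],
    [
      "RW",
      "BD",
      0.35
    ],
    [
      "RW",
      "FC",
      0.35
    ],
    [
      "RW",
      "FD",
      0.3
    ]
  ]
}
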