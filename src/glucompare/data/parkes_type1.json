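{
  "grid_name": "parkes_consensus_type1",
  "notes": "Parkes consensus error grid for Type 1 diabetes. Boundary vertex coordinates (reference mg/dL, meter mg/dL) as published in Pfutzner A, Klonoff DC, Pardo S, Parkes JL, 'Technical aspects of the Parkes error grid', J Diabetes Sci Technol 2013;7(5):1275-81. Upper boundaries separate zones for meter overestimation (meter > reference), lower boundaries for underestimation; there is no E zone below the identity line in the Type 1 grid. Boundaries are piecewise-linear and extend to the domain edge.",
  "domain": [0.0, 550.0],
  "upper_boundaries": {
    "AB": [[0, 50], [30, 50], [140, 170], [280, 380], [430, 550]],
    "BC": [[0, 60], [30, 60], [50, 80], [70, 110], [260, 550]],
    "CD": [[0, 70], [25, 70], [50, 125], [80, 215], [125, 550]],
    "DE": [[0, 100], [35, 155], [50, 550]]
  },
  "lower_boundaries": {
    "AB": [[50, 0], [50, 30], [170, 145], [385, 300], [550, 450]],
    "BC": [[120, 0], [120, 30], [260, 130], [550, 250]],
    "CD": [[250, 0], [250, 40], [550, 150]]
  }
}
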