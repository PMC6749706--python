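{
  "version": "AD4.1-subset-1",
  "comment": "Per-atom-type Lennard-Jones parameters in the AutoDock4 convention. epsilon: well depth of the like pair, kcal/mol. r0: per-atom well radius, A (half of the like-pair well position Rii). radius: van der Waals radius used for grid occupancy, A (equal to r0 by default).",
  "types": {
    "C":  {"epsilon": 0.150, "r0": 2.000, "radius": 2.000},
    "A":  {"epsilon": 0.150, "r0": 2.000, "radius": 2.000},
    "N":  {"epsilon": 0.160, "r0": 1.750, "radius": 1.750},
    "NA": {"epsilon": 0.160, "r0": 1.750, "radius": 1.750},
    "OA": {"epsilon": 0.200, "r0": 1.600, "radius": 1.600},
    "S":  {"epsilon": 0.200, "r0": 2.000, "radius": 2.000},
    "SA": {"epsilon": 0.200, "r0": 2.000, "radius": 2.000},
    "H":  {"epsilon": 0.020, "r0": 1.000, "radius": 1.000},
    "HD": {"epsilon": 0.020, "r0": 1.000, "radius": 1.000},
    "HS": {"epsilon": 0.020, "r0": 1.000, "radius": 1.000},
    "P":  {"epsilon": 0.200, "r0": 2.100, "radius": 2.100},
    "F":  {"epsilon": 0.080, "r0": 1.545, "radius": 1.545},
    "Cl": {"epsilon": 0.276, "r0": 2.045, "radius": 2.045},
    "Br": {"epsilon": 0.389, "r0": 2.165, "radius": 2.165},
    "I":  {"epsilon": 0.550, "r0": 2.360, "radius": 2.360},
    "Zn": {"epsilon": 0.550, "r0": 0.740, "radius": 0.740},
    "Mg": {"epsilon": 0.875, "r0": 0.650, "radius": 0.650},
    "Mn": {"epsilon": 0.875, "r0": 0.650, "radius": 0.650},
    "Ca": {"epsilon": 0.550, "r0": 0.990, "radius": 0.990},
    "Fe": {"epsilon": 0.010, "r0": 0.650, "radius": 0.650}
  },
  "hbond_capable": ["N", "NA", "OA", "SA", "HD"],
  "hbond_acceptors": ["N", "NA", "OA", "SA"],
  "hbond_donor_h": ["HD"],
  "hbond_wells": {
    "N":  {"epsilon": 5.0, "r0": 1.9},
    "NA": {"epsilon": 5.0, "r0": 1.9},
    "OA": {"epsilon": 5.0, "r0": 1.9},
    "SA": {"epsilon": 1.0, "r0": 2.5}
  }
}
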