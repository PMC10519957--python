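{
  "_comment": [
    "Reference functional-group decompositions for the drug and the polymer",
    "repeat units.  Group tokens resolve in data/group_contributions.csv.",
    "celecoxib: 4-[5-(4-methylphenyl)-3-(trifluoromethyl)pyrazol-1-yl]-",
    "benzenesulfonamide; the pyrazole ring is counted atom-by-atom (ring N,",
    "pyridine-type N, two substituted and one unsubstituted olefinic carbon)",
    "plus one 5-ring closure, the two aromatic rings as para-phenylene units,",
    "and the CF3 and sulfonamide (SO2 + NH2) substituents as single groups.",
    "vinylpyrrolidone / vinyl_acetate: backbone CH2-CH plus the lactam ring",
    "(3 ring CH2, ring closure, tertiary amide CON<) or the acetate ester",
    "(COO + CH3).  hpmcas_average_monomer: one anhydroglucose backbone",
    "(5 CH, 1 CH2, pyranose ring closure, 2 ether O) with its 3 substituent",
    "positions occupied fractionally by the M-grade substituent proportions",
    "methoxy 0.644, hydroxypropoxy 0.089, acetyl 0.111, succinate 0.089 and",
    "free hydroxyl 0.067 (free hydroxyls use the adjacent-diol OH variant",
    "appropriate to the cellulose C2/C3 positions).  Counts are per average",
    "repeat unit and therefore fractional; no atom balance is defined."
  ],
  "celecoxib": {
    "formula": "C17H14F3N3O2S",
    "groups": {
      "CH3": 1,
      "phenylene": 2,
      "CF3": 1,
      "N": 1,
      "=N-": 1,
      "=C<": 2,
      "=CH-": 1,
      "ring5": 1,
      "SO2": 1,
      "NH2": 1
    }
  },
  "vinylpyrrolidone": {
    "formula": "C6H9NO",
    "groups": {
      "CH2": 4,
      "CH": 1,
      "ring5": 1,
      "CON<": 1
    }
  },
  "vinyl_acetate": {
    "formula": "C4H6O2",
    "groups": {
      "CH2": 1,
      "CH": 1,
      "COO": 1,
      "CH3": 1
    }
  },
  "hpmcas_average_monomer": {
    "formula": null,
    "groups": {
      "CH": 5.267,
      "CH2": 1.801,
      "ring6": 1,
      "O": 4.199,
      "CH3": 2.532,
      "OH": 0.267,
      "OH_adj": 0.201,
      "COO": 0.6,
      "COOH": 0.267
    }
  }
}
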