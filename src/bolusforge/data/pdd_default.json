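{
  "comment": "Default electron percent-depth-dose tables. Piecewise-linear curves in water-equivalent depth (mm) vs PDD (%). Characteristic depths follow the broad-beam rules of thumb R100=E/4 cm, R90=E/3.2 cm, Rp=E/2 cm, with R50/R10 placed on a sigmoid falloff (R50 = R90 + 0.32*(Rp-R90), R10 = R90 + 0.70*(Rp-R90)); a buildup knee gives the fast rise + plateau of clinical electron beams; surface dose rises with energy; 2% bremsstrahlung tail beyond the practical range. Not measured beam data: a declared, editable stand-in.",
  "energies": {
    "6":  [[0.0, 82.0], [5.0, 96.0], [15.0, 100.0], [18.75, 90.0], [22.35, 50.0], [26.625, 10.0], [30.0, 3.0], [40.0, 2.0], [1000.0, 2.0]],
    "9":  [[0.0, 85.0], [7.5, 96.0], [22.5, 100.0], [28.125, 90.0], [33.525, 50.0], [39.9375, 10.0], [45.0, 3.0], [55.0, 2.0], [1000.0, 2.0]],
    "12": [[0.0, 88.0], [10.0, 96.0], [30.0, 100.0], [37.5, 90.0], [44.7, 50.0], [53.25, 10.0], [60.0, 3.0], [70.0, 2.0], [1000.0, 2.0]],
    "15": [[0.0, 91.0], [12.5, 96.0], [37.5, 100.0], [46.875, 90.0], [55.875, 50.0], [66.5625, 10.0], [75.0, 3.0], [85.0, 2.0], [1000.0, 2.0]]
  }
}
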