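# Default simulated-ganglion conditions. Values printed in source figures:
# Mrgprd soma area 361 +/- 138 um^2; composition of cutaneous (tibial)
# afferents ~15% Mrgprd, 48.1% CGRP, 8.3% Trpm8, 15.6% Thy1-sampled
# myelinated. Soma-size parameters for the non-Mrgprd classes and the
# territory split are field-realistic choices documented in docs/methods.md.
n_neurons: 8000
semi_axes: [300.0, 250.0, 400.0]
territory_fractions: {tibial: 0.35, peroneal: 0.45, sural: 0.20}
sectioning:
  thickness_um: 30.0
  axial_shrinkage: 0.8
  n_slides: 5
  dz_um: 3.0
subpopulations:
  - {name: mrgprd, fraction: 0.150, soma_area_mean: 361.0, soma_area_sd: 138.0, nucleus_ratio: 0.45, markers: []}
  - {name: cgrp,   fraction: 0.481, soma_area_mean: 380.0, soma_area_sd: 150.0, nucleus_ratio: 0.45, markers: []}
  - {name: trpm8,  fraction: 0.083, soma_area_mean: 300.0, soma_area_sd: 110.0, nucleus_ratio: 0.45, markers: []}
  - {name: thy1,   fraction: 0.156, soma_area_mean: 700.0, soma_area_sd: 250.0, nucleus_ratio: 0.45, markers: []}
  - {name: other,  fraction: 0.130, soma_area_mean: 450.0, soma_area_sd: 200.0, nucleus_ratio: 0.45, markers: []}
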