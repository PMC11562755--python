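# Thy1-CFP (myelinated sample) + FastBlue, 28 d post-transection: the
# co-labelled share RISES from 15.6% to 23.3% because unmyelinated neighbours
# are lost while CFP+ afferents are spared (odds ratio > 1).
scenario_id: thy1_fb
ganglion:
  subpopulations:
    - {name: thy1, fraction: 0.156, soma_area_mean: 700.0, soma_area_sd: 250.0, nucleus_ratio: 0.45, markers: [CFP]}
    - {name: other, fraction: 0.844, soma_area_mean: 400.0, soma_area_sd: 170.0, nucleus_ratio: 0.45, markers: []}
injury:
  axotomized_territories: [tibial, peroneal]
  odds_calibration:
    marker_subpop: thy1
    p_contra: 0.156
    p_ipsi: 0.233
    baseline_survival: {7: 1.0, 28: 0.5}
labels:
  - {label_name: FB, target: territory, territory_restriction: tibial, sensitivity: 0.97, false_positive: 0.0}
  - {label_name: CFP, target: marker, sensitivity: 1.0, false_positive: 0.0}
colabel: {reference: FB, marker: CFP}
timepoints: [28]
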