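# Trpm8 (cold-sensor) reporter + FastBlue, 28 d post-transection:
# co-labelling 8.3% contralateral -> 4.2% ipsilateral (partial loss).
scenario_id: trpm8_fb
ganglion:
  subpopulations:
    - {name: trpm8, fraction: 0.083, soma_area_mean: 300.0, soma_area_sd: 110.0, nucleus_ratio: 0.45, markers: [tdTom]}
    - {name: other, fraction: 0.917, soma_area_mean: 470.0, soma_area_sd: 210.0, nucleus_ratio: 0.45, markers: []}
injury:
  axotomized_territories: [tibial, peroneal]
  odds_calibration:
    marker_subpop: trpm8
    p_contra: 0.083
    p_ipsi: 0.042
    baseline_survival: {7: 1.0, 28: 0.5}
labels:
  - {label_name: FB, target: territory, territory_restriction: tibial, sensitivity: 0.97, false_positive: 0.0}
  - {label_name: tdTom, target: marker, sensitivity: 1.0, false_positive: 0.0}
colabel: {reference: FB, marker: tdTom}
timepoints: [28]
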