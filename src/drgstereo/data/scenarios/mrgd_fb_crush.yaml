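# Mrgprd reporter + FastBlue, 28 d after sciatic crush (regenerating injury):
# co-labelling drops from 15% to 6.0%.
scenario_id: mrgd_fb_crush
ganglion:
  subpopulations:
    - {name: mrgprd, fraction: 0.15, soma_area_mean: 361.0, soma_area_sd: 138.0, nucleus_ratio: 0.45, markers: [YFP]}
    - {name: other, fraction: 0.85, soma_area_mean: 460.0, soma_area_sd: 210.0, nucleus_ratio: 0.45, markers: []}
injury:
  axotomized_territories: [tibial, peroneal]
  odds_calibration:
    marker_subpop: mrgprd
    p_contra: 0.15
    p_ipsi: 0.060
    baseline_survival: {7: 1.0, 28: 0.5}
labels:
  - {label_name: FB, target: territory, territory_restriction: tibial, sensitivity: 0.97, false_positive: 0.0}
  - {label_name: YFP, target: marker, sensitivity: 1.0, false_positive: 0.0}
colabel: {reference: FB, marker: YFP}
timepoints: [28]
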