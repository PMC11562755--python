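# CGRP (Calca, peptidergic) reporter + FastBlue, 28 d post-transection:
# co-labelling 48.1% contralateral -> 34.3% ipsilateral (partial loss).
scenario_id: calca_fb
ganglion:
  subpopulations:
    - {name: calca, fraction: 0.481, soma_area_mean: 380.0, soma_area_sd: 150.0, nucleus_ratio: 0.45, markers: [YFP]}
    - {name: other, fraction: 0.519, soma_area_mean: 490.0, soma_area_sd: 230.0, nucleus_ratio: 0.45, markers: []}
injury:
  axotomized_territories: [tibial, peroneal]
  odds_calibration:
    marker_subpop: calca
    p_contra: 0.481
    p_ipsi: 0.343
    baseline_survival: {7: 1.0, 28: 0.5}
labels:
  - {label_name: FB, target: territory, territory_restriction: tibial, sensitivity: 0.97, false_positive: 0.0}
  - {label_name: YFP, target: marker, sensitivity: 1.0, false_positive: 0.0}
colabel: {reference: FB, marker: YFP}
timepoints: [28]
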