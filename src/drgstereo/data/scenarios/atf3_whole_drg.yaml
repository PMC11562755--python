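# Whole-DRG sciatic transection with an injury-induced reporter (Atf3-driven
# GFP). Axotomized territories tibial+peroneal (0.80 of neurons); overall
# axotomized survival follows the printed whole-population time course, and
# the day-56 endpoint is apportioned across subpopulations so that loss is
# concentrated in small nonpeptidergic/peptidergic classes while myelinated
# afferents are spared (weighted mean exactly 0.39).
scenario_id: atf3_whole_drg
ganglion: default
injury:
  axotomized_territories: [tibial, peroneal]
  axotomized_fraction: 0.80
  overall_survival: {7: 1.0, 14: 0.45, 28: 0.41, 56: 0.39}
  final_survival: {mrgprd: 0.05, cgrp: 0.35, trpm8: 0.25, thy1: 1.0, other: 0.28769}
labels:
  - {label_name: GFP, target: injury, sensitivity: 0.991, false_positive: 0.046}
count_label: GFP
timepoints: [7, 14, 28, 56]
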