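# drgstereo

Design-based stereology of injury-induced sensory-neuron loss in the dorsal
root ganglion (DRG), built around a fully synthetic ganglion → sectioning →
counting simulator with exact ground truth.

After a peripheral nerve injury, a large fraction of DRG neurons die over
weeks, with small nonpeptidergic neurons hit hardest. Quantifying that loss
credibly requires design-based stereology: optical-dissector counting on
serial-section z-stacks combined with Cavalieri volume estimation, so that
total neuron numbers — not biased profile counts — are compared across
animals and timepoints. `drgstereo` implements that entire quantification
chain and, crucially, a deterministic simulator of the tissue and the
microscope, so every estimator in the chain can be validated against known
truth instead of being trusted on faith.

The package covers:

- **Synthetic ganglia** (`drgstereo.ganglion`): an ellipsoidal DRG of ~8000
  neurons in five molecular subpopulations (nonpeptidergic Mrgprd+,
  peptidergic CGRP+, cold-sensing Trpm8+, myelinated Thy1+, other) with
  lognormal soma sizes, concentric nuclei, peripheral-territory assignment,
  scheduled injury-induced death and probabilistic fluorescent labelling.
- **Virtual sectioning** (`drgstereo.sectioning`): axial shrinkage, serial
  30 µm sections with a uniform random phase, 1-in-5 slide sampling, and
  per-section confocal z-stacks with analytic soma/nucleus profiles.
- **Stereology** (`drgstereo.stereology`): the optical-dissector counting
  rule (nucleus visible on ≥1 plane, excluded if visible on the top frame,
  bottom frame included), section volume, Cavalieri ganglion volume
  V = ā·t̄·l, numerical density and total neuron number.
- **Cleared-tissue spots** (`drgstereo.spots`): Imaris-style nuclear-spot
  tables, volume filtering (5–2000 µm³ pass band) and small/medium/large
  size binning.
- **Size distributions** (`drgstereo.distributions`): max-profile soma-area
  sampling and an exact two-sample Kolmogorov–Smirnov test.
- **Proportions** (`drgstereo.proportions`): per-animal co-labelling
  percentages (e.g. tracer-filled neurons also expressing a reporter) with
  paired ipsi/contra summaries.
- **Inference** (`drgstereo.stats`): paired t, one-way ANOVA + Tukey, mixed
  (split-plot) repeated-measures ANOVA + Šídák/Tukey, Shapiro–Wilk gating,
  and noncentral-t power / sample-size analysis.
- **Scenarios & pipeline** (`drgstereo.scenarios`, `drgstereo.pipeline`):
  versioned YAML scenarios (`atf3_whole_drg`, `mrgd_fb_trans`,
  `mrgd_fb_crush`, `trpm8_fb`, `calca_fb`, `thy1_fb`) and a seeded
  end-to-end runner producing tidy cell tables, estimates and summaries.

## Worked example

Count a simulated ganglion exactly as a histologist would — one slide of a
1-in-5 series, dissector counts per z-stack, Cavalieri volume from measured
thickness and mid-plane areas:

```python
from drgstereo import (GanglionConfig, SubpopulationSpec, generate_ganglion,
                       cut_sections, dissector_count_total, estimate_from_series)

config = GanglionConfig(
    n=8000,
    subpopulations=(
        SubpopulationSpec("mrgprd", 0.15, 361.0, 138.0),
        SubpopulationSpec("cgrp", 0.481, 380.0, 150.0),
        SubpopulationSpec("trpm8", 0.083, 300.0, 110.0),
        SubpopulationSpec("thy1", 0.156, 700.0, 250.0),
        SubpopulationSpec("other", 0.13, 450.0, 200.0),
    ),
)
g = generate_ganglion(config, seed=42)
series = cut_sections(g, thickness=30.0, axial_shrinkage=0.8, n_slides=5, seed=43)
print(dissector_count_total(series))   # all slides: exact
est = estimate_from_series(series)     # analyzed slide only: estimate
print(round(est.n_drg))
```

Running `python examples/02_sectioning_and_counting.py` prints:

```
sections collected: 23 on 5 slides (random phase 19.6 um, analyzed slide 2)
dissector count over ALL slides: 8000 (living neurons: 8000)
analyzed sections: 5
mean measured thickness: 29.62 um, mean mid-plane area: 133,107 um^2
V_DRG (Cavalieri) = 90.7 x10^6 um^3
N_v = 8.406e-05 per um^3
N_DRG = 7,623 neurons (truth: 8000)
```

With all slides analyzed the dissector is *exact* (8000/8000); from a single
slide the estimate is unbiased with a per-replicate CV of ~13%.

An end-to-end injury experiment (`python examples/03_injury_time_course.py`):

```
scenario: atf3_whole_drg; timepoints (d): [7, 14, 28, 56]
  day  7: counted  1572.1 neurons/slide, GFP+  1261.4, N_DRG   8151.2
  day 14: counted   887.6 neurons/slide, GFP+   577.0, N_DRG   4476.6
  day 28: counted   832.6 neurons/slide, GFP+   525.1, N_DRG   4139.7
  day 56: counted   832.1 neurons/slide, GFP+   519.5, N_DRG   4501.0
GFP+ count decrease day 7 -> 56: 58.8% (SEM 0.6, n=8)
```

The other scripts under `examples/` walk through ganglion generation, soma
size distributions, co-labelling proportions, cleared-tissue spot binning
and the statistics toolkit; each is a narrative, runnable program.

## Reproduction

The acceptance targets (planned group size, generator fidelity, injury time
course, reporter specificity and co-labelling collapse) are recomputed from
scratch by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which takes a few seconds and writes, e.g.:

```json
{
  "t1": {"value": 3, "n": 1},
  "t2": {"value": 362.0999522462677, "n": 10000},
  "t3": {"value": 60.57277499214631, "n": 20},
  "t4": {"value": 4.7793857196534, "n": 5},
  "t5": {"value": 1.4802075767936826, "n": 20}
}
```

The full test suite, including the property-based acceptance suite
(dissector exactness, stereology unbiasedness over 200 simulated ganglia,
Cavalieri accuracy, KS and Shapiro–Wilk calibration, ANOVA oracle
equivalence, odds-ratio calibration closure), runs in well under a minute:

```bash
python -m pytest -q tests/
```

See `docs/methods.md` for the modelling and estimator details, including the
exactness argument for the dissector counting rule and the choice of pooled
numerical density.
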