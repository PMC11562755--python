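"""Generate a synthetic DRG and inspect its ground truth.

The ganglion is an ellipsoid of ~8000 neurons split into five molecular
subpopulations with lognormal soma sizes and concentric nuclei. Everything
is deterministic given (config, seed).
"""

import numpy as np

from drgstereo import GanglionConfig, SubpopulationSpec, generate_ganglion

config = GanglionConfig(
    n=8000,
    subpopulations=(
        SubpopulationSpec("mrgprd", 0.15, 361.0, 138.0, markers=frozenset({"mrgprd"})),
        SubpopulationSpec("cgrp", 0.481, 380.0, 150.0, markers=frozenset({"cgrp"})),
        SubpopulationSpec("trpm8", 0.083, 300.0, 110.0, markers=frozenset({"trpm8"})),
        SubpopulationSpec("thy1", 0.156, 700.0, 250.0, markers=frozenset({"thy1"})),
        SubpopulationSpec("other", 0.13, 450.0, 200.0),
    ),
)

g = generate_ganglion(config, seed=42)
print(f"neurons: {g.n}, semi-axes (um): {g.semi_axes}")
for name in np.unique(g.subpop):
    sel = g.subpop == name
    print(
        f"  {name:7s} n={int(sel.sum()):5d} "
        f"({sel.mean():.1%})  soma area {g.soma_area[sel].mean():6.1f} "
        f"+/- {g.soma_area[sel].std():.1f} um^2"
    )
for terr in ("tibial", "peroneal", "sural"):
    print(f"  territory {terr:8s}: {(g.territory == terr).mean():.1%}")
print(f"mean nuclear volume: {g.nucleus_volume.mean():.0f} um^3")
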