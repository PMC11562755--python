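"""Retrograde-tracer co-labelling before and after nerve injury.

FastBlue is injected into the tibial territory; the share of FB-filled
neurons that express the Mrgprd reporter collapses after transection because
nonpeptidergic neurons die preferentially. Ipsi- and contralateral ganglia
from the same simulated animals give a paired design.
"""

import warnings

warnings.simplefilter("ignore")

from drgstereo import paired_t, run_scenario, summarize_groups

run = run_scenario("mrgd_fb_trans", seeds=range(6), timepoints=[28])
tab = run.table()[["seed", "side", "colabel_percent"]].rename(
    columns={"seed": "animal", "colabel_percent": "percent"}
)
print(tab.to_string(index=False))

summary = summarize_groups(tab, design="paired", group_col="side",
                           value_col="percent", pair_col="animal")
for side, s in summary["groups"].items():
    print(f"{side:6s}: {s['mean']:5.2f} +/- {s['sem']:.2f}% (n={s['n']})")
print(f"paired delta ({summary['paired_delta']['comparison']}): "
      f"{summary['paired_delta']['mean']:.2f} points")

ipsi = tab[tab["side"] == "ipsi"].sort_values("animal")["percent"]
contra = tab[tab["side"] == "contra"].sort_values("animal")["percent"]
print(paired_t(contra, ipsi).report())
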