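"""Cleared-tissue nuclear-spot analysis: filter debris/doublets by volume and
bin nuclei into small / medium / large size classes."""

from drgstereo import (
    GanglionConfig,
    SubpopulationSpec,
    bin_spots,
    filter_spots,
    generate_ganglion,
    nuclear_spot_table,
    read_spots,
)

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
g = generate_ganglion(config, seed=9)
spots = read_spots(nuclear_spot_table(g, drg_id="L4", side="contra"))
print(f"spots exported: {len(spots)}; volume range "
      f"{spots['volume'].min():.0f}-{spots['volume'].max():.0f} um^3")

filtered = filter_spots(spots)
print(filtered["filter_status"].value_counts().to_string())

binned, counts = bin_spots(filtered, by=["drg_id", "side"])
print(counts.to_string(index=False))
row = counts.iloc[0]
print(f"small share of passing nuclei: "
      f"{row['small'] / (row['small'] + row['combined']):.1%}")
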