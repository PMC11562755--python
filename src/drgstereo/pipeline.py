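"""End-to-end scenario runner and tabular I/O.

``run_scenario`` executes generate → injure → label → section → count /
estimate / co-label for each seed and timepoint of a named scenario, with
fully deterministic sub-seed derivation, and can write every intermediate
table. Cell tables are plain CSV (one row per neuron per analyzed section)
with a semicolon-joined ``labels`` column; every written file embeds the
scenario config hash and package version for provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ganglion import Ganglion, apply_injury, apply_labels, generate_ganglion
from .proportions import colabel_proportion
from .scenarios import ScenarioConfig, load_scenario
from .sectioning import SectionSeries, cut_sections
from .stereology import estimate_from_series

__all__ = [
    "ScenarioRun",
    "run_scenario",
    "cells_from_series",
    "read_cells",
    "write_cells",
    "config_hash",
]

CELL_COLUMNS = [
    "animal",
    "side",
    "section",
    "slide",
    "plane_of_max",
    "neuron_id",
    "soma_area",
    "nucleus_visible",
    "labels",
]


def config_hash(cfg: ScenarioConfig) -> str:
    """Stable short hash of the full scenario document."""
    blob = json.dumps(cfg.raw, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def cells_from_series(
    series: SectionSeries, dz: float, animal: str, side: str
) -> pd.DataFrame:
    """One row per (neuron, analyzed section): max soma profile area, the
    plane index where it occurs, nucleus visibility anywhere in the stack,
    and the neuron's labels."""
    g = series.ganglion
    label_names = sorted(g.labels)
    rows = []
    for sec in series.analyzed_sections:
        stack = series.stack(sec, dz)
        present = stack.areas.max(axis=0) > 0
        if not present.any():
            continue
        ids = stack.neuron_ids[present]
        max_area = stack.areas[:, present].max(axis=0)
        argmax = stack.areas[:, present].argmax(axis=0)
        nuc_any = stack.nucleus_visible[:, present].any(axis=0)
        for j, nid in enumerate(ids):
            labels = ";".join(n for n in label_names if g.labels[n][nid])
            rows.append(
                {
                    "animal": animal,
                    "side": side,
                    "section": sec.index,
                    "slide": sec.slide,
                    "plane_of_max": int(argmax[j]),
                    "neuron_id": int(nid),
                    "soma_area": float(max_area[j]),
                    "nucleus_visible": bool(nuc_any[j]),
                    "labels": labels,
                }
            )
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def write_cells(cells: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a cell table as CSV, with provenance in leading comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        cells.to_csv(fh, index=False)


def read_cells(path) -> pd.DataFrame:
    """Read a cell table, validating mandatory columns; extra columns are
    preserved and comment lines skipped."""
    try:
        df = pd.read_csv(path, comment="#", keep_default_na=False)
    except pd.errors.ParserError as err:
        raise ValueError(f"malformed cell table {path}: {err}") from err
    for col in CELL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cell table {path} is missing mandatory column {col!r}")
    df["nucleus_visible"] = df["nucleus_visible"].astype(bool)
    return df


@dataclass
class ScenarioRun:
    scenario_id: str
    config_hash: str
    version: str
    seeds: list
    timepoints: list
    records: list = field(default_factory=list)   # one dict per (seed, side, timepoint)

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "seed": r["seed"],
                    "side": r["side"],
                    "timepoint": r["timepoint"],
                    "count_total": r["counts"]["total"],
                    **{
                        f"count_{k}": v
                        for k, v in r["counts"].items()
                        if k != "total"
                    },
                    "n_drg": r["estimate"]["n_drg"],
                    "v_drg": r["estimate"]["v_drg"],
                    "colabel_percent": (r.get("colabel") or {}).get("percent"),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        tab = self.table()
        agg = {}
        for (side, tp), sub in tab.groupby(["side", "timepoint"], dropna=False, sort=True):
            key = f"{side}@{tp:g}d" if pd.notna(tp) else side
            entry = {
                "n_seeds": int(len(sub)),
                "mean_count_total": float(sub["count_total"].mean()),
                "mean_n_drg": float(sub["n_drg"].mean()),
                "mean_v_drg": float(sub["v_drg"].mean()),
            }
            for col in tab.columns:
                if col.startswith("count_") and col != "count_total":
                    entry[f"mean_{col}"] = float(sub[col].mean())
            if sub["colabel_percent"].notna().any():
                entry["mean_colabel_percent"] = float(sub["colabel_percent"].mean())
            agg[key] = entry
        return {
            "scenario_id": self.scenario_id,
            "config_hash": self.config_hash,
            "version": self.version,
            "seeds": list(self.seeds),
            "timepoints": list(self.timepoints),
            "groups": agg,
        }

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)
        meta = {"config_hash": self.config_hash, "version": self.version}
        for r in self.records:
            tp = "contra" if r["timepoint"] is None else f"{r['timepoint']:g}d"
            stem = f"seed{r['seed']}_{r['side']}_{tp}"
            write_cells(r["cells"], outdir / f"cells_{stem}.csv", meta)
            with open(outdir / f"estimate_{stem}.json", "w") as fh:
                json.dump({**meta, **r["estimate"]}, fh, indent=2)


def _subseeds(seed: int, n: int) -> list:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n)]


def _measure(
    g: Ganglion,
    cfg: ScenarioConfig,
    section_seed: int,
    animal: str,
    side: str,
    timepoint,
) -> dict:
    sect = cfg.sectioning
    series = cut_sections(
        g,
        thickness=float(sect["thickness_um"]),
        axial_shrinkage=float(sect["axial_shrinkage"]),
        n_slides=int(sect["n_slides"]),
        seed=section_seed,
    )
    dz = float(sect["dz_um"])
    est = estimate_from_series(series, dz=dz)
    counts = {"total": int(sum(s["n_sec"] for s in est.per_section))}
    if cfg.count_label:
        est_label = estimate_from_series(series, dz=dz, include=g.has_label(cfg.count_label))
        counts[cfg.count_label] = int(sum(s["n_sec"] for s in est_label.per_section))
    cells = cells_from_series(series, dz, animal=animal, side=side)
    record = {
        "seed": None,  # filled by caller
        "side": side,
        "timepoint": timepoint,
        "counts": counts,
        "estimate": est.to_dict(),
        "cells": cells,
        "colabel": None,
    }
    if cfg.colabel and len(cells):
        props = colabel_proportion(
            cells, cfg.colabel["reference"], cfg.colabel["marker"], groupby=["animal", "side"]
        )
        if len(props) and props["n_reference"].iloc[0] > 0:
            record["colabel"] = {
                "percent": float(props["percent"].iloc[0]),
                "n_reference": int(props["n_reference"].iloc[0]),
                "n_colabelled": int(props["n_colabelled"].iloc[0]),
            }
    return record


def run_scenario(
    scenario,
    seeds,
    timepoints=None,
    outdir=None,
    include_contra: bool | None = None,
) -> ScenarioRun:
    """Execute a scenario end to end for each seed.

    For every seed, one ganglion is generated, injured and labelled; each
    requested timepoint is sectioned independently (fresh random phase and
    analyzed slide, as separate histology sessions would be) and measured.
    When the scenario defines a co-labelling analysis, an uninjured
    contralateral ganglion from the same simulated animal is measured too.
    Identical (scenario, seeds) inputs reproduce identical outputs.
    """
    cfg = load_scenario(scenario) if isinstance(scenario, str) else scenario
    if timepoints is None:
        timepoints = cfg.timepoints
    if include_contra is None:
        include_contra = cfg.colabel is not None
    chash = config_hash(cfg)
    run = ScenarioRun(
        scenario_id=cfg.scenario_id,
        config_hash=chash,
        version=__version__,
        seeds=list(seeds),
        timepoints=list(timepoints),
    )
    for seed in seeds:
        sub = _subseeds(seed, 4 + 2 * len(timepoints))
        g = generate_ganglion(cfg.ganglion, seed=sub[0])
        animal = f"m{seed}"
        for k, day in enumerate(timepoints):
            gi = apply_injury(g, cfg.injury, day=day, seed=sub[1])
            gl = apply_labels(gi, cfg.labels, seed=sub[2])
            rec = _measure(gl, cfg, section_seed=sub[4 + k], animal=animal, side="ipsi", timepoint=day)
            rec["seed"] = seed
            run.records.append(rec)
        if include_contra:
            gc = apply_labels(g, cfg.labels, seed=sub[2])
            rec = _measure(gc, cfg, section_seed=sub[3], animal=animal, side="contra", timepoint=None)
            rec["seed"] = seed
            run.records.append(rec)
    if outdir is not None:
        run.write(outdir)
    return run
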