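"""Named simulation scenarios shipped as versioned YAML files.

A scenario bundles a ganglion configuration, an injury/survival model, a set
of labelling specifications and the analysis timepoints. Two injury idioms are
supported:

- an explicit whole-population survival time course apportioned across
  subpopulations (``overall_survival`` + ``final_survival``), and
- a two-proportion odds calibration (``odds_calibration``): given the
  co-labelling proportion among tracer-filled neurons before (``p_contra``)
  and after (``p_ipsi``) injury, the marker-positive survival is set to
  ``baseline * rho`` with ``rho = calibrate_survival_ratio(p_contra, p_ipsi)``,
  recomputed at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import yaml

from .ganglion import (
    ConfigurationError,
    GanglionConfig,
    InjuryScenario,
    LabellingSpec,
    SubpopulationSpec,
    calibrate_survival_ratio,
)

__all__ = ["ScenarioConfig", "available_scenarios", "load_scenario", "load_defaults"]


@dataclass
class ScenarioConfig:
    scenario_id: str
    ganglion: GanglionConfig
    injury: InjuryScenario
    labels: list
    timepoints: list
    sectioning: dict
    count_label: str | None = None
    colabel: dict | None = None
    raw: dict = field(default_factory=dict)


def _data_text(name: str) -> str:
    return resources.files("drgstereo.data").joinpath(name).read_text()


def load_defaults() -> dict:
    return yaml.safe_load(_data_text("defaults.yaml"))


def available_scenarios() -> list:
    root = resources.files("drgstereo.data").joinpath("scenarios")
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir() if p.name.endswith(".yaml"))


def _subpops(entries) -> tuple:
    return tuple(
        SubpopulationSpec(
            name=e["name"],
            fraction=float(e["fraction"]),
            soma_area_mean=float(e["soma_area_mean"]),
            soma_area_sd=float(e["soma_area_sd"]),
            nucleus_ratio=float(e.get("nucleus_ratio", 0.45)),
            markers=frozenset(e.get("markers", [])),
        )
        for e in entries
    )


def _build_injury(scenario_id: str, inj: dict, subpops) -> InjuryScenario:
    sub_names = [s.name for s in subpops]
    if "odds_calibration" in inj:
        cal = inj["odds_calibration"]
        rho = calibrate_survival_ratio(float(cal["p_contra"]), float(cal["p_ipsi"]))
        baseline = {float(d): float(s) for d, s in cal["baseline_survival"].items()}
        marker = cal["marker_subpop"]
        if marker not in sub_names:
            raise ConfigurationError(f"odds_calibration marker {marker!r} not a subpopulation")
        schedule = {}
        for name in sub_names:
            if name == marker:
                # Differential loss applies only once baseline loss has begun,
                # so early timepoints (baseline survival 1) stay at 1.
                schedule[name] = {
                    d: (min(1.0, s * rho) if s < 1.0 else 1.0) for d, s in baseline.items()
                }
            else:
                schedule[name] = dict(baseline)
    elif "final_survival" in inj:
        overall = {float(d): float(s) for d, s in inj["overall_survival"].items()}
        final = {k: float(v) for k, v in inj["final_survival"].items()}
        missing = set(sub_names) - set(final)
        if missing:
            raise ConfigurationError(f"final_survival missing subpopulations {sorted(missing)}")
        d_last = max(overall)
        total_loss = 1.0 - overall[d_last]
        schedule = {}
        for name in sub_names:
            # shared loss-time profile f(d) scaled to each class's endpoint
            schedule[name] = {
                d: 1.0 - (1.0 - final[name]) * ((1.0 - s) / total_loss)
                for d, s in overall.items()
            }
    else:
        raise ConfigurationError("injury block needs odds_calibration or final_survival")
    return InjuryScenario(
        scenario_id=scenario_id,
        axotomized_territories=tuple(inj["axotomized_territories"]),
        survival_schedule=schedule,
        axotomized_fraction=inj.get("axotomized_fraction"),
    )


def scenario_from_dict(doc: dict) -> ScenarioConfig:
    defaults = load_defaults()
    gd = doc.get("ganglion", "default")
    if gd == "default":
        gd = {}
    subpop_entries = gd.get("subpopulations", defaults["subpopulations"])
    subpops = _subpops(subpop_entries)
    gcfg = GanglionConfig(
        n=int(gd.get("n_neurons", defaults["n_neurons"])),
        subpopulations=subpops,
        semi_axes=tuple(gd.get("semi_axes", defaults["semi_axes"])),
        territory_fractions=dict(gd.get("territory_fractions", defaults["territory_fractions"])),
    )
    injury = _build_injury(doc["scenario_id"], doc["injury"], subpops)
    labels = [
        LabellingSpec(
            label_name=e["label_name"],
            sensitivity=float(e["sensitivity"]),
            false_positive=float(e.get("false_positive", 0.0)),
            target=e.get("target", "marker"),
            territory_restriction=e.get("territory_restriction"),
        )
        for e in doc.get("labels", [])
    ]
    sectioning = dict(defaults["sectioning"])
    sectioning.update(doc.get("sectioning", {}))
    return ScenarioConfig(
        scenario_id=doc["scenario_id"],
        ganglion=gcfg,
        injury=injury,
        labels=labels,
        timepoints=[float(t) for t in doc.get("timepoints", [28])],
        sectioning=sectioning,
        count_label=doc.get("count_label"),
        colabel=doc.get("colabel"),
        raw=doc,
    )


def load_scenario(name: str) -> ScenarioConfig:
    """Load a shipped scenario by id; unknown ids list the available ones."""
    if name not in available_scenarios():
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(available_scenarios())}"
        )
    return scenario_from_dict(yaml.safe_load(_data_text(f"scenarios/{name}.yaml")))
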