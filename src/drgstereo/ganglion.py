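"""Synthetic dorsal root ganglion (DRG) populations with known ground truth.

A mouse lumbar DRG is modelled as an axis-aligned ellipsoid containing ~8000
sensory neurons. Each neuron is a sphere (soma) with a concentric spherical
nucleus, belongs to a molecular subpopulation (nonpeptidergic Mrgprd+,
peptidergic CGRP+, cold-sensing Trpm8+, myelinated Thy1+, or other), projects
into one peripheral territory of the sciatic nerve (tibial, peroneal or
sural), and may be axotomized by a simulated nerve injury, die on a scheduled
time course, and carry fluorescent labels (genetic reporters or retrograde
tracers) with configurable sensitivity and false-positive rates.

Everything is deterministic given (configuration, seed), so downstream
sectioning, counting and inference can be validated against exact ground
truth.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TERRITORIES = ("tibial", "peroneal", "sural")

__all__ = [
    "SubpopulationSpec",
    "InjuryScenario",
    "LabellingSpec",
    "GanglionConfig",
    "Ganglion",
    "generate_ganglion",
    "apply_injury",
    "apply_labels",
    "calibrate_survival_ratio",
    "lognormal_params",
    "nuclear_spot_table",
    "TERRITORIES",
]


class ConfigurationError(ValueError):
    """Raised for invalid generator / scenario configuration."""


@dataclass(frozen=True)
class SubpopulationSpec:
    """One molecular class of DRG neurons.

    Parameters
    ----------
    name:
        Subpopulation label, e.g. ``"mrgprd"``.
    fraction:
        Proportion of all neurons in this class (fractions over all specs must
        sum to 1).
    soma_area_mean, soma_area_sd:
        Mean and SD (µm²) of the *maximal* soma cross-sectional area. Areas
        are drawn from a lognormal moment-matched to these targets.
    nucleus_ratio:
        Nucleus radius as a fraction of the soma radius (concentric spheres).
    markers:
        Label names intrinsically expressed by members of this class.
    """

    name: str
    fraction: float
    soma_area_mean: float
    soma_area_sd: float
    nucleus_ratio: float = 0.45
    markers: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.soma_area_mean <= 0:
            raise ConfigurationError(f"{self.name}: soma_area_mean must be > 0")
        if self.soma_area_sd < 0:
            raise ConfigurationError(f"{self.name}: soma_area_sd must be >= 0")
        if not 0 < self.nucleus_ratio < 1:
            raise ConfigurationError(f"{self.name}: nucleus_ratio must be in (0,1)")
        if not 0 <= self.fraction <= 1:
            raise ConfigurationError(f"{self.name}: fraction must be in [0,1]")
        object.__setattr__(self, "markers", frozenset(self.markers))


@dataclass(frozen=True)
class InjuryScenario:
    """Axotomy + subpopulation-specific survival time course.

    ``survival_schedule`` maps subpopulation name -> {day: survival fraction}.
    Survival applies only to axotomized neurons (those whose territory appears
    in ``axotomized_territories``); intact neurons always survive. Schedules
    must be non-increasing in time; day 0 is implicitly 1.0. Days between
    scheduled points are linearly interpolated.
    """

    scenario_id: str
    axotomized_territories: tuple
    survival_schedule: dict
    axotomized_fraction: float | None = None

    def __post_init__(self):
        for terr in self.axotomized_territories:
            if terr not in TERRITORIES:
                raise ConfigurationError(f"unknown territory {terr!r}")
        for sub, sched in self.survival_schedule.items():
            days = sorted(sched)
            vals = [sched[d] for d in days]
            if any(not 0 <= v <= 1 for v in vals):
                raise ConfigurationError(f"{sub}: survival fractions must be in [0,1]")
            if any(b > a + 1e-12 for a, b in zip(vals, vals[1:])):
                raise ConfigurationError(f"{sub}: survival must be non-increasing")
            if days and days[0] == 0 and sched[0] != 1.0:
                raise ConfigurationError(f"{sub}: day-0 survival must be 1")

    def survival_at(self, subpop: str, day: float) -> float:
        """Linearly interpolated survival fraction for ``subpop`` at ``day``."""
        if subpop not in self.survival_schedule:
            raise ConfigurationError(
                f"subpopulation {subpop!r} missing from survival schedule of "
                f"{self.scenario_id!r}"
            )
        sched = dict(self.survival_schedule[subpop])
        sched.setdefault(0, 1.0)
        days = np.array(sorted(sched), dtype=float)
        vals = np.array([sched[d] for d in sorted(sched)], dtype=float)
        return float(np.interp(day, days, vals))


@dataclass(frozen=True)
class LabellingSpec:
    """A fluorescent label applied probabilistically to a target set.

    ``target`` selects the membership rule:

    - ``"marker"``: neurons whose subpopulation lists ``label_name`` among its
      intrinsic markers (genetic reporters of molecular identity);
    - ``"injury"``: axotomized neurons (injury-induced reporters, e.g.
      Atf3-driven GFP);
    - ``"territory"``: neurons projecting to ``territory_restriction``
      (retrograde tracers such as FastBlue injected into one skin territory).

    Members are labelled with probability ``sensitivity``; non-members with
    probability ``false_positive``.
    """

    label_name: str
    sensitivity: float
    false_positive: float = 0.0
    target: str = "marker"
    territory_restriction: str | None = None

    def __post_init__(self):
        for p, what in ((self.sensitivity, "sensitivity"), (self.false_positive, "false_positive")):
            if not 0 <= p <= 1:
                raise ConfigurationError(f"{self.label_name}: {what} must be in [0,1]")
        if self.target not in ("marker", "injury", "territory"):
            raise ConfigurationError(f"{self.label_name}: unknown target {self.target!r}")
        if self.target == "territory" and self.territory_restriction not in TERRITORIES:
            raise ConfigurationError(
                f"{self.label_name}: territory target needs a valid territory_restriction"
            )


@dataclass(frozen=True)
class GanglionConfig:
    n: int
    subpopulations: tuple
    semi_axes: tuple = (300.0, 250.0, 400.0)
    territory_fractions: dict = field(
        default_factory=lambda: {"tibial": 0.35, "peroneal": 0.45, "sural": 0.20}
    )

    def __post_init__(self):
        if self.n < 0:
            raise ConfigurationError("n must be >= 0")
        if any(a <= 0 for a in self.semi_axes):
            raise ConfigurationError("semi-axes must be > 0")
        total = sum(s.fraction for s in self.subpopulations)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"subpopulation fractions sum to {total}, not 1")
        tt = sum(self.territory_fractions.values())
        if abs(tt - 1.0) > 1e-9:
            raise ConfigurationError(f"territory fractions sum to {tt}, not 1")
        for t in self.territory_fractions:
            if t not in TERRITORIES:
                raise ConfigurationError(f"unknown territory {t!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["subpopulations"] = [
            {**dataclasses.asdict(s), "markers": sorted(s.markers)}
            for s in self.subpopulations
        ]
        return d


@dataclass
class Ganglion:
    """Array-backed neuron population (one entry per neuron, aligned arrays)."""

    semi_axes: tuple
    seed: int | None
    params: dict
    ids: np.ndarray                 # int
    subpop: np.ndarray              # str (object/str dtype)
    centers: np.ndarray             # (n, 3) µm
    soma_radius: np.ndarray         # µm
    nucleus_radius: np.ndarray      # µm
    nucleus_centers: np.ndarray     # (n, 3) µm
    territory: np.ndarray           # str
    axotomized: np.ndarray          # bool
    alive: np.ndarray               # bool
    labels: dict = field(default_factory=dict)  # name -> bool array

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def soma_area(self) -> np.ndarray:
        """Maximal cross-sectional area πr² of each soma (µm²)."""
        return np.pi * self.soma_radius**2

    @property
    def nucleus_volume(self) -> np.ndarray:
        """Nuclear volume (4/3)πr³ of each neuron (µm³)."""
        return 4.0 / 3.0 * np.pi * self.nucleus_radius**3

    def has_label(self, name: str) -> np.ndarray:
        if name not in self.labels:
            return np.zeros(self.n, dtype=bool)
        return self.labels[name]

    def copy(self) -> "Ganglion":
        return Ganglion(
            semi_axes=tuple(self.semi_axes),
            seed=self.seed,
            params=dict(self.params),
            ids=self.ids.copy(),
            subpop=self.subpop.copy(),
            centers=self.centers.copy(),
            soma_radius=self.soma_radius.copy(),
            nucleus_radius=self.nucleus_radius.copy(),
            nucleus_centers=self.nucleus_centers.copy(),
            territory=self.territory.copy(),
            axotomized=self.axotomized.copy(),
            alive=self.alive.copy(),
            labels={k: v.copy() for k, v in self.labels.items()},
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": self.ids,
                "subpop": self.subpop,
                "x": self.centers[:, 0],
                "y": self.centers[:, 1],
                "z": self.centers[:, 2],
                "soma_radius": self.soma_radius,
                "nucleus_radius": self.nucleus_radius,
                "territory": self.territory,
                "axotomized": self.axotomized,
                "alive": self.alive,
            }
        )
        label_names = sorted(self.labels)
        joined = []
        for i in range(self.n):
            joined.append(";".join(n for n in label_names if self.labels[n][i]))
        df["labels"] = joined
        return df

    def to_csv(self, path, sidecar_path=None) -> None:
        """Write one row per neuron plus a JSON sidecar of config and seed."""
        self.to_dataframe().to_csv(path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {"seed": self.seed, "semi_axes": list(self.semi_axes), "params": self.params},
                    fh,
                    indent=2,
                    default=str,
                )

    @classmethod
    def from_csv(cls, path, sidecar_path=None) -> "Ganglion":
        df = pd.read_csv(path, keep_default_na=False)
        meta = {"seed": None, "semi_axes": (np.nan,) * 3, "params": {}}
        if sidecar_path is not None:
            with open(sidecar_path) as fh:
                meta.update(json.load(fh))
        n = len(df)
        label_names = set()
        parsed = []
        for s in df["labels"].astype(str):
            names = [x for x in s.split(";") if x]
            parsed.append(names)
            label_names.update(names)
        labels = {name: np.zeros(n, dtype=bool) for name in sorted(label_names)}
        for i, names in enumerate(parsed):
            for name in names:
                labels[name][i] = True
        return cls(
            semi_axes=tuple(meta["semi_axes"]),
            seed=meta["seed"],
            params=meta["params"],
            ids=df["id"].to_numpy(int),
            subpop=df["subpop"].to_numpy(str),
            centers=df[["x", "y", "z"]].to_numpy(float),
            soma_radius=df["soma_radius"].to_numpy(float),
            nucleus_radius=df["nucleus_radius"].to_numpy(float),
            nucleus_centers=df[["x", "y", "z"]].to_numpy(float),
            territory=df["territory"].to_numpy(str),
            axotomized=df["axotomized"].to_numpy(bool),
            alive=df["alive"].to_numpy(bool),
            labels=labels,
        )


def lognormal_params(mean: float, sd: float) -> tuple:
    """(mu, sigma) of a lognormal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, np.sqrt(sigma2)


def _uniform_in_ellipsoid(rng, n, semi_axes):
    # Uniform in unit ball (normalized Gaussian direction x U^(1/3) radius),
    # then scaled per axis; affine images of uniform are uniform.
    if n == 0:
        return np.zeros((0, 3))
    d = rng.normal(size=(n, 3))
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    r = rng.random(n) ** (1.0 / 3.0)
    return d * r[:, None] * np.asarray(semi_axes)


def generate_ganglion(config: GanglionConfig, seed: int | None = None) -> Ganglion:
    """Draw a ganglion: positions uniform in the ellipsoid, subpopulations by
    multinomial assignment, soma areas lognormal per subpopulation, nuclei
    concentric. Deterministic given (config, seed)."""
    rng = np.random.default_rng(seed)
    n = config.n
    centers = _uniform_in_ellipsoid(rng, n, config.semi_axes)

    fractions = np.array([s.fraction for s in config.subpopulations])
    sub_idx = rng.choice(len(fractions), size=n, p=fractions / fractions.sum())
    subpop = np.array([config.subpopulations[i].name for i in sub_idx], dtype=object)

    areas = np.empty(n)
    nucleus_ratio = np.empty(n)
    for i, s in enumerate(config.subpopulations):
        mask = sub_idx == i
        if s.soma_area_sd == 0:
            areas[mask] = s.soma_area_mean
        else:
            mu, sigma = lognormal_params(s.soma_area_mean, s.soma_area_sd)
            areas[mask] = rng.lognormal(mu, sigma, size=int(mask.sum()))
        nucleus_ratio[mask] = s.nucleus_ratio
    soma_radius = np.sqrt(areas / np.pi)
    nucleus_radius = nucleus_ratio * soma_radius

    terr_names = [t for t in TERRITORIES if t in config.territory_fractions]
    terr_p = np.array([config.territory_fractions[t] for t in terr_names])
    terr_idx = rng.choice(len(terr_names), size=n, p=terr_p / terr_p.sum())
    territory = np.array([terr_names[i] for i in terr_idx], dtype=object)

    return Ganglion(
        semi_axes=tuple(config.semi_axes),
        seed=seed,
        params=config.to_dict(),
        ids=np.arange(n),
        subpop=subpop,
        centers=centers,
        soma_radius=soma_radius,
        nucleus_radius=nucleus_radius,
        nucleus_centers=centers.copy(),
        territory=territory,
        axotomized=np.zeros(n, dtype=bool),
        alive=np.ones(n, dtype=bool),
        labels={},
    )


def apply_injury(
    g: Ganglion, scenario: InjuryScenario, day: float, seed: int | None = None
) -> Ganglion:
    """Flag axotomized neurons and thin them by the scheduled survival at ``day``.

    Each neuron draws a single latent uniform ``u`` (from ``seed`` alone), and
    is alive at ``day`` iff ``u <= survival(subpop, day)``. Because the draw
    does not depend on ``day``, calling with the same seed at increasing days
    yields nested alive sets whenever the schedule is non-increasing.
    """
    out = g.copy()
    out.axotomized = np.isin(g.territory, list(scenario.axotomized_territories))
    u = np.random.default_rng(seed).random(g.n)
    surv = np.ones(g.n)
    for sub in np.unique(g.subpop):
        surv[g.subpop == sub] = scenario.survival_at(str(sub), day)
    out.alive = np.where(out.axotomized, u <= surv, True)
    out.params = dict(out.params)
    out.params["injury"] = {"scenario_id": scenario.scenario_id, "day": day, "seed": seed}
    return out


def apply_labels(g: Ganglion, specs, seed: int | None = None) -> Ganglion:
    """Assign each label by Bernoulli draws: sensitivity on the target set,
    false_positive off it. Labelling is independent across labels and neurons."""
    out = g.copy()
    rng = np.random.default_rng(seed)
    sub_markers = {}
    for spec in specs:
        if spec.target == "injury":
            member = out.axotomized
        elif spec.target == "territory":
            member = out.territory == spec.territory_restriction
        else:
            for sdict in out.params.get("subpopulations", []):
                sub_markers[sdict["name"]] = set(sdict.get("markers", []))
            member = np.array(
                [spec.label_name in sub_markers.get(s, set()) for s in out.subpop],
                dtype=bool,
            )
        p = np.where(member, spec.sensitivity, spec.false_positive)
        out.labels[spec.label_name] = rng.random(g.n) < p
    return out


def calibrate_survival_ratio(p_contra: float, p_ipsi: float) -> float:
    """Survival odds ratio ρ turning a baseline co-labelling proportion into an
    injured one.

    If marker-positive neurons survive with probability s·ρ and marker-negative
    ones with probability s, the expected post-injury proportion of survivors
    that are marker-positive satisfies odds(p_ipsi) = ρ·odds(p_contra),
    independent of s. Returns ρ = odds(p_ipsi)/odds(p_contra).
    """
    if not 0 < p_contra < 1:
        raise ValueError("p_contra must be strictly inside (0, 1)")
    if not 0 <= p_ipsi < 1:
        raise ValueError("p_ipsi must be in [0, 1)")
    return (p_ipsi / (1 - p_ipsi)) / (p_contra / (1 - p_contra))


def nuclear_spot_table(
    g: Ganglion, drg_id: str = "drg0", side: str = "contra", alive_only: bool = True
) -> pd.DataFrame:
    """Imaris-style spot table of nuclear volumes, emulating a cleared-tissue
    nuclear-marker spot export (one spot per surviving neuron)."""
    mask = g.alive if alive_only else np.ones(g.n, dtype=bool)
    return pd.DataFrame(
        {
            "spot_id": g.ids[mask],
            "x": g.nucleus_centers[mask, 0],
            "y": g.nucleus_centers[mask, 1],
            "z": g.nucleus_centers[mask, 2],
            "volume": g.nucleus_volume[mask],
            "drg_id": drg_id,
            "side": side,
        }
    )


def check_nucleus_section_compatibility(g: Ganglion, thickness: float) -> None:
    """Warn when any nuclear diameter reaches the section thickness (the
    dissector rule then cannot place the nucleus in a single section)."""
    if g.n and (2 * g.nucleus_radius >= thickness).any():
        worst = float(2 * g.nucleus_radius.max())
        warnings.warn(
            f"nuclear diameter up to {worst:.1f} µm >= section thickness "
            f"{thickness} µm; dissector counts may be unreliable",
            stacklevel=2,
        )
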