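"""Virtual cryosectioning and confocal z-stack construction.

The ganglion is cut along z into serial sections of nominal thickness
(default 30 µm) after applying an axial shrinkage factor (processed-tissue
space). Sections are collected serially onto ``n_slides`` slides (section i
goes to slide ``i mod n_slides``) and one slide is chosen at random for
analysis, matching 1-in-5 systematic sampling. A z-stack is built per section
with planes every ``dz`` µm spanning the full section thickness *including
both cut surfaces*: the top plane sits at the upper cut (the dissector's
exclusion plane) and, when ``dz`` divides the thickness, the bottom plane
coincides with the lower cut, which is simultaneously the next section's top
plane. This makes the per-section counting windows of the optical-dissector
rule tile z exactly, so every nucleus is countable in exactly one section.

Soma and nucleus profiles are analytic circle–plane intersections, so every
measured quantity has a closed-form oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ganglion import ConfigurationError, Ganglion, check_nucleus_section_compatibility

__all__ = [
    "Section",
    "SectionSeries",
    "OpticalStack",
    "cut_sections",
    "build_stack",
    "measure_thickness",
    "cell_area",
    "MeasurementError",
]

_EPS = 1e-9


class MeasurementError(RuntimeError):
    """A section could not be measured (e.g. no cell-containing region)."""


@dataclass
class Section:
    index: int
    z_lo: float
    z_hi: float
    slide: int
    n_cells: int = 0
    measured_thickness: float = math.nan
    mid_plane_area: float = math.nan

    @property
    def thickness(self) -> float:
        return self.z_hi - self.z_lo

    @property
    def excluded(self) -> bool:
        return self.n_cells == 0


@dataclass
class OpticalStack:
    """Per-section z-stack: analytic soma profile areas and nucleus visibility
    for every (plane, candidate neuron) pair. ``areas[p, j]`` is the soma
    cross-section (µm²) of neuron ``neuron_ids[j]`` on plane ``p`` (0 where the
    soma does not reach the plane); ``nucleus_visible[p, j]`` flags planes
    cutting the nucleus."""

    section_index: int
    plane_zs: np.ndarray
    neuron_ids: np.ndarray
    areas: np.ndarray
    nucleus_visible: np.ndarray

    @property
    def n_planes(self) -> int:
        return len(self.plane_zs)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p, z in enumerate(self.plane_zs):
            present = self.areas[p] > 0
            rows.append(
                pd.DataFrame(
                    {
                        "section": self.section_index,
                        "plane_index": p,
                        "z": z,
                        "neuron_id": self.neuron_ids[present],
                        "profile_area": self.areas[p, present],
                        "nucleus_visible": self.nucleus_visible[p, present],
                    }
                )
            )
        if not rows:
            return pd.DataFrame(
                columns=["section", "plane_index", "z", "neuron_id", "profile_area", "nucleus_visible"]
            )
        return pd.concat(rows, ignore_index=True)


@dataclass
class SectionSeries:
    """A full serial sectioning of one (processed) ganglion."""

    ganglion: Ganglion            # z-shrunk copy, coordinates in processed space
    semi_axes: tuple              # processed-space ellipsoid semi-axes
    thickness: float
    axial_shrinkage: float
    n_slides: int
    phase: float
    analyzed_slide: int
    sections: list = field(default_factory=list)

    @property
    def l_total(self) -> int:
        """Total number of sections collected across all slides (the Cavalieri
        'length' count)."""
        return len(self.sections)

    def sections_on(self, slide: int) -> list:
        return [s for s in self.sections if s.slide == slide]

    @property
    def analyzed_sections(self) -> list:
        return self.sections_on(self.analyzed_slide)

    def stack(self, section, dz: float = 3.0) -> OpticalStack:
        if isinstance(section, int):
            section = self.sections[section]
        return build_stack(section, self.ganglion, dz)

    def profiles_dataframe(self, dz: float = 3.0, slides=None) -> pd.DataFrame:
        """Long-format per-plane profile table (the CSV export schema)."""
        if slides is None:
            slides = [self.analyzed_slide]
        frames = []
        for sec in self.sections:
            if sec.slide not in slides or sec.excluded:
                continue
            df = self.stack(sec, dz).to_dataframe()
            df.insert(1, "slide", sec.slide)
            frames.append(df)
        if not frames:
            return pd.DataFrame(
                columns=["section", "slide", "plane_index", "z", "neuron_id", "profile_area", "nucleus_visible"]
            )
        return pd.concat(frames, ignore_index=True)

    def manifest(self) -> dict:
        return {
            "thickness": self.thickness,
            "axial_shrinkage": self.axial_shrinkage,
            "n_slides": self.n_slides,
            "phase": self.phase,
            "analyzed_slide": self.analyzed_slide,
            "semi_axes": list(self.semi_axes),
            "sections": [
                {
                    "index": s.index,
                    "z_lo": s.z_lo,
                    "z_hi": s.z_hi,
                    "slide": s.slide,
                    "n_cells": s.n_cells,
                    "measured_thickness": s.measured_thickness,
                    "mid_plane_area": s.mid_plane_area,
                }
                for s in self.sections
            ],
        }


def measure_thickness(
    section: Section, rel_amplitude: float = 0.1, rng=None
) -> float:
    """Apparent section thickness: the mean of the thickest and thinnest
    cell-containing regions. Local thickness varies multiplicatively and
    uniformly within ``±rel_amplitude`` of nominal; with zero amplitude the
    nominal (post-shrinkage) thickness is returned. Unbiased on average."""
    if section.excluded:
        raise MeasurementError(
            f"section {section.index} has no cell-containing region"
        )
    nominal = section.thickness
    if rel_amplitude == 0:
        return nominal
    rng = np.random.default_rng() if rng is None else rng
    thickest = nominal * (1 + rng.uniform(0, rel_amplitude))
    thinnest = nominal * (1 - rng.uniform(0, rel_amplitude))
    return 0.5 * (thickest + thinnest)


def cell_area(section: Section, semi_axes, z_m: float | None = None) -> float:
    """Cell-containing cross-sectional area at the section's middle optical
    plane: the analytic ellipse area π·a_x·a_y·(1 − (z_m/a_z)²), clipped at 0
    beyond the poles."""
    a_x, a_y, a_z = semi_axes
    if z_m is None:
        z_m = 0.5 * (section.z_lo + section.z_hi)
    if section.z_lo >= a_z or section.z_hi <= -a_z:
        warnings.warn(
            f"section {section.index} lies entirely outside the ganglion", stacklevel=2
        )
        return 0.0
    if abs(z_m) >= a_z:
        return 0.0
    return math.pi * a_x * a_y * (1.0 - (z_m / a_z) ** 2)


def cut_sections(
    g: Ganglion,
    thickness: float = 30.0,
    axial_shrinkage: float = 0.8,
    n_slides: int = 5,
    seed: int | None = None,
    phase: float | None = None,
    thickness_noise: float = 0.1,
    dz_for_area: float | None = None,
) -> SectionSeries:
    """Cut a ganglion into serial sections in processed-tissue space.

    z-coordinates are rescaled by ``axial_shrinkage`` before cutting; sections
    of equal nominal ``thickness`` tile the tissue z-extent starting one
    uniform random phase above it (systematic uniform random sampling for the
    Cavalieri estimator). Each section records the slide it lands on, a
    measured (noisy) thickness and its analytic mid-plane cell area; sections
    without any cell-containing region are flagged excluded with a warning.
    """
    if thickness <= 0:
        raise ConfigurationError("thickness must be > 0")
    if not 0 < axial_shrinkage <= 1:
        raise ConfigurationError("axial_shrinkage must be in (0, 1]")
    if n_slides < 1:
        raise ConfigurationError("n_slides must be >= 1")
    check_nucleus_section_compatibility(g, thickness)

    rng = np.random.default_rng(seed)
    proc = g.copy()
    proc.centers[:, 2] *= axial_shrinkage
    proc.nucleus_centers[:, 2] *= axial_shrinkage
    semi_axes = (g.semi_axes[0], g.semi_axes[1], g.semi_axes[2] * axial_shrinkage)

    if phase is None:
        phase = float(rng.uniform(0, thickness))
    analyzed_slide = int(rng.integers(n_slides))

    if proc.n:
        zmin = float(np.min(proc.centers[:, 2] - proc.soma_radius))
        zmax = float(np.max(proc.centers[:, 2] + proc.soma_radius))
    else:
        zmin, zmax = -semi_axes[2], semi_axes[2]
    z0 = zmin - phase
    n_sections = max(1, math.ceil((zmax - z0 - _EPS) / thickness))

    zc = proc.centers[:, 2]
    r = proc.soma_radius
    alive = proc.alive
    sections = []
    for i in range(n_sections):
        z_lo = z0 + i * thickness
        z_hi = z_lo + thickness
        n_cells = int(np.sum(alive & (zc - r < z_hi) & (zc + r > z_lo)))
        sec = Section(index=i, z_lo=z_lo, z_hi=z_hi, slide=i % n_slides, n_cells=n_cells)
        if sec.excluded:
            warnings.warn(f"section {i} contains no cells; excluded from analysis", stacklevel=2)
        else:
            sec.measured_thickness = measure_thickness(sec, thickness_noise, rng)
        sec.mid_plane_area = cell_area(sec, semi_axes) if not sec.excluded else 0.0
        sections.append(sec)

    return SectionSeries(
        ganglion=proc,
        semi_axes=semi_axes,
        thickness=thickness,
        axial_shrinkage=axial_shrinkage,
        n_slides=n_slides,
        phase=phase,
        analyzed_slide=analyzed_slide,
        sections=sections,
    )


def build_stack(section: Section, g: Ganglion, dz: float = 3.0) -> OpticalStack:
    """Confocal z-stack for one section: planes at ``z_lo + k·dz`` for
    ``k = 0..floor(thickness/dz)`` (bottom plane may coincide with the lower
    cut surface). A living neuron contributes a soma profile of area
    π·(r² − (z − z_c)²) to every plane strictly inside its soma, and its
    nucleus is flagged visible on planes strictly inside the nucleus."""
    t = section.thickness
    if not 0 < dz < t:
        raise ConfigurationError("dz must satisfy 0 < dz < section thickness")
    n_planes = int(math.floor(t / dz + _EPS)) + 1
    plane_zs = section.z_lo + dz * np.arange(n_planes)

    zc = g.centers[:, 2]
    r = g.soma_radius
    cand = g.alive & (zc - r < plane_zs[-1]) & (zc + r > plane_zs[0])
    ids = g.ids[cand]
    zc = zc[cand]
    r = r[cand]
    znuc = g.nucleus_centers[cand, 2]
    rnuc = g.nucleus_radius[cand]

    dzmat = plane_zs[:, None] - zc[None, :]
    sq = r[None, :] ** 2 - dzmat**2
    areas = np.where(sq > 0, np.pi * np.clip(sq, 0, None), 0.0)
    nucleus_visible = np.abs(plane_zs[:, None] - znuc[None, :]) < rnuc[None, :]

    return OpticalStack(
        section_index=section.index,
        plane_zs=plane_zs,
        neuron_ids=ids,
        areas=areas,
        nucleus_visible=nucleus_visible,
    )
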