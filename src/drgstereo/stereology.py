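"""Optical-dissector counting and Cavalieri-based total-number estimation.

Counting rule (per z-stack): a neuron is counted iff its nucleus is visible
on at least one optical plane of the stack and *not* visible on the top plane
(plane index 0, the exclusion plane); nuclei visible on the bottom plane are
included. Because consecutive stacks share their boundary plane, each nucleus
is counted in exactly one section of the full series.

Estimators, per analyzed section i on the sampled slide:

    V_sec,i = t_i · a_i          (measured thickness × mid-plane cell area)
    N_v,i   = N_sec,i / V_sec,i  (numerical density)

and for the whole ganglion:

    V_DRG = ā · t̄ · l            (Cavalieri; l = total sections collected)
    N_DRG = N̄_v · V_DRG
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sectioning import OpticalStack, SectionSeries

__all__ = [
    "StereologyEstimate",
    "count_section",
    "section_volume",
    "cavalieri_volume",
    "estimate_total",
    "estimate_from_series",
    "dissector_count_total",
    "CountingError",
]


class CountingError(RuntimeError):
    pass


@dataclass
class StereologyEstimate:
    per_section: list          # dicts: section, n_sec, t, a, v_sec, n_v
    t_bar: float
    a_bar: float
    l: int
    v_drg: float
    n_v_bar: float
    n_drg: float
    n_sections_analyzed: int
    warnings: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "per_section": self.per_section,
            "t_bar": self.t_bar,
            "a_bar": self.a_bar,
            "l": self.l,
            "v_drg": self.v_drg,
            "n_v_bar": self.n_v_bar,
            "n_drg": self.n_drg,
            "n_sections_analyzed": self.n_sections_analyzed,
            "warnings": self.warnings,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def per_section_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_section)


def _include_mask(stack: OpticalStack, include) -> np.ndarray:
    if include is None:
        return np.ones(len(stack.neuron_ids), dtype=bool)
    include = np.asarray(include)
    if include.dtype == bool:
        return include[stack.neuron_ids]
    return np.isin(stack.neuron_ids, include)


def count_section(stack: OpticalStack, include=None) -> int:
    """Dissector count N_sec for one z-stack.

    ``include`` optionally restricts counting to a subset of neurons, given
    either as a boolean array indexed by neuron id (e.g. a label mask) or as
    an array of ids. Each neuron is counted at most once per stack.
    """
    if stack.n_planes < 2:
        raise CountingError("need >= 2 planes to define a top exclusion frame")
    visible_any = stack.nucleus_visible.any(axis=0)
    visible_top = stack.nucleus_visible[0]
    counted = visible_any & ~visible_top & _include_mask(stack, include)
    return int(counted.sum())


def section_volume(t: float, a: float) -> float:
    """V_sec = t · a (µm³)."""
    if t <= 0:
        raise ValueError("thickness must be > 0")
    if a < 0:
        raise ValueError("area must be >= 0")
    return t * a


def cavalieri_volume(a_bar: float, t_bar: float, l: int) -> float:
    """V_DRG = ā · t̄ · l, with l the dimensionless total section count."""
    if a_bar < 0 or t_bar <= 0:
        raise ValueError("a_bar must be >= 0 and t_bar > 0")
    if l != int(l) or int(l) < 1:
        raise ValueError("l must be a positive integer section count")
    return a_bar * t_bar * int(l)


def estimate_total(
    counts,
    thicknesses,
    areas,
    l: int,
    section_indices=None,
    pooled: bool = False,
    zero_vsec: str = "raise",
) -> StereologyEstimate:
    """Assemble the full stereological estimate from per-section measurements.

    Sections with zero V_sec and zero count carry no density information and
    are dropped from N̄_v (they still contribute their area/thickness to the
    Cavalieri terms). A zero V_sec with a nonzero count is contradictory data:
    it raises by default, or is likewise dropped with a warning when
    ``zero_vsec="exclude"`` (the policy used by :func:`estimate_from_series`,
    where an end section's analytic mid-plane can miss a polar cap that the
    counting window still samples). ``pooled=True`` replaces the mean of
    per-section densities by ΣN_sec/ΣV_sec.
    """
    counts = np.asarray(counts, dtype=float)
    thicknesses = np.asarray(thicknesses, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if not (len(counts) == len(thicknesses) == len(areas)):
        raise ValueError("counts, thicknesses and areas must be aligned")
    if len(counts) == 0:
        raise ValueError("no analyzed sections")
    if l < len(counts):
        raise ValueError("l must be at least the number of analyzed sections")
    if section_indices is None:
        section_indices = list(range(len(counts)))

    v_sec = thicknesses * areas
    warns = []
    bad = (v_sec == 0) & (counts > 0)
    if bad.any():
        msg = (
            f"{int(bad.sum())} section(s) have zero V_sec but nonzero counts "
            f"(mid-plane area 0); excluded from the density average"
        )
        if zero_vsec == "raise":
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
        warns.append(msg)

    valid = v_sec > 0
    n_v = np.full(len(counts), np.nan)
    n_v[valid] = counts[valid] / v_sec[valid]

    per_section = [
        {
            "section": int(section_indices[i]),
            "n_sec": float(counts[i]),
            "t": float(thicknesses[i]),
            "a": float(areas[i]),
            "v_sec": float(v_sec[i]),
            "n_v": None if not valid[i] else float(n_v[i]),
        }
        for i in range(len(counts))
    ]

    t_bar = float(np.mean(thicknesses))
    a_bar = float(np.mean(areas))
    v_drg = cavalieri_volume(a_bar, t_bar, int(l))
    if not valid.any():
        n_v_bar = 0.0
    elif pooled:
        n_v_bar = float(counts[valid].sum() / v_sec[valid].sum())
    else:
        n_v_bar = float(np.mean(n_v[valid]))
    return StereologyEstimate(
        per_section=per_section,
        t_bar=t_bar,
        a_bar=a_bar,
        l=int(l),
        v_drg=v_drg,
        n_v_bar=n_v_bar,
        n_drg=n_v_bar * v_drg,
        n_sections_analyzed=int(len(counts)),
        warnings=warns,
    )


def estimate_from_series(
    series: SectionSeries,
    dz: float = 3.0,
    include=None,
    slides=None,
    pooled: bool = True,
) -> StereologyEstimate:
    """Run the full per-slide pipeline: dissector counts, measured thickness
    and analytic mid-plane areas on the analyzed slide (or an explicit slide
    list), with l = total sections collected across all slides.

    The density is pooled over the slide by default (ΣN_sec/ΣV_sec, the ratio
    form standard for disector estimates): end sections near the ganglion
    poles can pair a near-zero mid-plane area with a nonzero count, and the
    resulting extreme per-section densities make the unweighted per-section
    mean (``pooled=False``) far noisier without being less biased."""
    if slides is None:
        slides = [series.analyzed_slide]
    counts, ts, areas, idx = [], [], [], []
    for sec in series.sections:
        if sec.slide not in slides or sec.excluded:
            continue
        stack = series.stack(sec, dz)
        counts.append(count_section(stack, include=include))
        ts.append(sec.measured_thickness)
        areas.append(sec.mid_plane_area)
        idx.append(sec.index)
    return estimate_total(
        counts,
        ts,
        areas,
        l=series.l_total,
        section_indices=idx,
        pooled=pooled,
        zero_vsec="exclude",
    )


def dissector_count_total(series: SectionSeries, dz: float = 3.0, include=None) -> int:
    """Σ N_sec over every section of every slide (the exactness oracle's
    subject: equals the number of alive neurons whose nucleus is visible on at
    least one plane when dz divides the section thickness)."""
    total = 0
    for sec in series.sections:
        if sec.excluded:
            continue
        total += count_section(series.stack(sec, dz), include=include)
    return total


def missed_nucleus_fraction(series: SectionSeries, dz: float = 3.0) -> float:
    """Fraction of alive nuclei invisible on every plane of every stack (can
    happen when the nuclear diameter is below the plane spacing, or when dz
    does not divide the section thickness). The dissector cannot count these;
    a rate above 1% triggers a warning from the estimation pipeline."""
    g = series.ganglion
    alive_ids = g.ids[g.alive]
    seen = np.zeros(int(g.ids.max()) + 1 if g.n else 0, dtype=bool)
    for sec in series.sections:
        if sec.excluded:
            continue
        stack = series.stack(sec, dz)
        vis = stack.nucleus_visible.any(axis=0)
        seen[stack.neuron_ids[vis]] = True
    if len(alive_ids) == 0:
        return 0.0
    frac = 1.0 - seen[alive_ids].mean()
    if frac > 0.01:
        warnings.warn(
            f"{frac:.1%} of nuclei are invisible on every optical plane; "
            "counts will be low",
            stacklevel=2,
        )
    return float(frac)
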