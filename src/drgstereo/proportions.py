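"""Per-animal co-labelling proportions (e.g. the share of tracer-filled
neurons also expressing a subpopulation reporter).

Counting follows blinded two-pass semantics: reference cells (carrying the
reference label, with a visible nucleus) are enumerated independently of the
marker channel, which is only then revealed to score co-labelling. No
stereological correction is applied to these profile counts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["colabel_proportion", "summarize_groups", "has_label"]


def has_label(cells: pd.DataFrame, name: str) -> pd.Series:
    """Boolean series for membership of ``name`` in the semicolon-joined
    ``labels`` column (or an existing boolean column of that name)."""
    if name in cells.columns:
        return cells[name].astype(bool)
    return cells["labels"].fillna("").astype(str).apply(
        lambda s: name in [x for x in s.split(";") if x]
    )


def colabel_proportion(
    cells: pd.DataFrame,
    reference_label: str,
    marker_label: str,
    groupby=("animal", "side"),
) -> pd.DataFrame:
    """Percent of reference-labelled, nucleated cells that also carry the
    marker, per group (one row per animal × side by default).

    Groups without any reference cell are flagged missing (NaN percent) with
    a warning; they are excluded by :func:`summarize_groups`.
    """
    groupby = list(groupby)
    if "nucleus_visible" not in cells.columns:
        raise ValueError("cells table needs a nucleus_visible column")
    ref = has_label(cells, reference_label) & cells["nucleus_visible"].astype(bool)
    mark = has_label(cells, marker_label)
    work = cells[groupby].copy()
    work["_ref"] = ref
    work["_co"] = ref & mark
    rows = []
    for key, sub in work.groupby(groupby, sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n_ref = int(sub["_ref"].sum())
        n_co = int(sub["_co"].sum())
        if n_ref == 0:
            warnings.warn(
                f"group {dict(zip(groupby, key))} has no {reference_label}+ "
                "reference cells; proportion undefined",
                stacklevel=2,
            )
            pct = np.nan
        else:
            pct = 100.0 * n_co / n_ref
        rows.append(
            {
                **dict(zip(groupby, key)),
                "n_reference": n_ref,
                "n_colabelled": n_co,
                "percent": pct,
            }
        )
    return pd.DataFrame(rows)


def summarize_groups(
    records: pd.DataFrame,
    design: str = "unpaired",
    group_col: str = "side",
    value_col: str = "percent",
    pair_col: str = "animal",
) -> dict:
    """Mean ± SEM per group (SEM = SD/√n over animals; undefined for n = 1),
    plus per-animal paired differences for a paired two-level design."""
    if design not in ("paired", "unpaired"):
        raise ValueError("design must be 'paired' or 'unpaired'")
    recs = records.dropna(subset=[value_col])
    out = {"groups": {}, "design": design}
    for level, sub in recs.groupby(group_col, sort=True):
        vals = sub[value_col].to_numpy(float)
        out["groups"][str(level)] = {
            "n": int(vals.size),
            "mean": float(np.mean(vals)),
            "sem": float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size >= 2 else None,
        }
    if design == "paired":
        levels = sorted(recs[group_col].unique())
        if len(levels) != 2:
            raise ValueError(f"paired design needs exactly 2 groups, got {levels}")
        a = recs[recs[group_col] == levels[0]].set_index(pair_col)[value_col]
        b = recs[recs[group_col] == levels[1]].set_index(pair_col)[value_col]
        if set(a.index) != set(b.index):
            raise ValueError(
                f"paired design: {pair_col} ids differ between groups "
                f"({sorted(set(a.index) ^ set(b.index))})"
            )
        delta = (b - a.reindex(b.index)).sort_index()
        out["paired_delta"] = {
            "comparison": f"{levels[1]} - {levels[0]}",
            "per_pair": {str(k): float(v) for k, v in delta.items()},
            "mean": float(delta.mean()),
        }
    return out
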