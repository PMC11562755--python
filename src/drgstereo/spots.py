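"""Cleared-tissue nuclear-spot tables: ingest, volume filtering, size binning.

Spot tables are Imaris-style CSV exports (one row per detected nuclear spot
with XYZ position and volume in µm³). Volumes below 5 µm³ or above 2000 µm³
are flagged as debris/doublets (strict inequalities: the boundary values
pass). Passing spots are binned as small (≤ 258 µm³, the upper bound of
reference nonpeptidergic nuclei), medium (258–400 µm³] and large (> 400 µm³,
the split sitting at the approximate midpoint of the volume distribution);
"combined" aggregates everything above the small bound.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

__all__ = ["read_spots", "filter_spots", "bin_spots", "SpotFormatError"]

FILTER_MIN = 5.0
FILTER_MAX = 2000.0
SMALL_MAX = 258.0
MEDIUM_MAX = 400.0

_CANONICAL = {
    "x": ("x", "position x", "pos x"),
    "y": ("y", "position y", "pos y"),
    "z": ("z", "position z", "pos z"),
    "volume": ("volume", "vol"),
    "spot_id": ("spot_id", "id", "spot id"),
    "drg_id": ("drg_id", "drg", "sample", "image"),
    "side": ("side",),
}


class SpotFormatError(ValueError):
    pass


def _normalize(col: str) -> str:
    col = re.sub(r"\[.*?\]", "", col)          # strip unit brackets, e.g. [µm]
    col = re.sub(r"[^a-z0-9 ]", " ", col.lower())
    return re.sub(r"\s+", " ", col).strip()


def read_spots(source) -> pd.DataFrame:
    """Read a spot table from a CSV path/buffer or DataFrame, mapping common
    Imaris header dialects ("Position X [µm]", "Volume") onto canonical
    columns x/y/z/volume (µm, µm³). Row count is preserved."""
    df = source.copy() if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    renames = {}
    for col in df.columns:
        norm = _normalize(str(col))
        for canon, aliases in _CANONICAL.items():
            if norm in aliases and canon not in renames.values():
                renames[col] = canon
                break
    df = df.rename(columns=renames)
    for needed in ("x", "y", "z", "volume"):
        if needed not in df.columns:
            raise SpotFormatError(f"spot table is missing a {needed!r} column")
    if "spot_id" not in df.columns:
        df.insert(0, "spot_id", np.arange(len(df)))
    df["volume"] = df["volume"].astype(float)
    if (df["volume"] <= 0).any():
        raise SpotFormatError("spot volumes must be > 0")
    return df


def filter_spots(
    spots: pd.DataFrame, v_min: float = FILTER_MIN, v_max: float = FILTER_MAX
) -> pd.DataFrame:
    """Flag each spot pass / too_small (< v_min) / too_large (> v_max).
    Boundary volumes pass. Idempotent; returns a copy with ``filter_status``."""
    if v_min >= v_max:
        raise ValueError("v_min must be < v_max")
    out = spots.copy()
    v = out["volume"].to_numpy(float)
    status = np.full(len(out), "pass", dtype=object)
    status[v < v_min] = "too_small"
    status[v > v_max] = "too_large"
    out["filter_status"] = status
    return out


def bin_spots(
    spots: pd.DataFrame,
    small_max: float = SMALL_MAX,
    medium_max: float = MEDIUM_MAX,
    by=None,
):
    """Assign passing spots to size bins and count them.

    Requires a previously filtered table (``filter_status`` column); refuses
    otherwise. Bin bounds are inclusive on the upper edge: small v ≤ small_max,
    medium small_max < v ≤ medium_max, large v > medium_max; ``combined`` =
    medium + large. Returns ``(table_with_bins, counts)`` where ``counts`` is a
    one-row DataFrame, or one row per group when ``by`` (e.g.
    ``["drg_id", "side"]``) is given.
    """
    if "filter_status" not in spots.columns:
        raise ValueError("spots must be filtered first (run filter_spots)")
    if not small_max < medium_max:
        raise ValueError("small_max must be < medium_max")
    out = spots.copy()
    v = out["volume"].to_numpy(float)
    passing = (out["filter_status"] == "pass").to_numpy()
    size_bin = np.full(len(out), "", dtype=object)
    size_bin[passing & (v <= small_max)] = "small"
    size_bin[passing & (v > small_max) & (v <= medium_max)] = "medium"
    size_bin[passing & (v > medium_max)] = "large"
    out["size_bin"] = size_bin

    def _count(sub: pd.DataFrame) -> pd.Series:
        c = sub.loc[sub["size_bin"] != "", "size_bin"].value_counts()
        small, medium, large = (int(c.get(k, 0)) for k in ("small", "medium", "large"))
        return pd.Series(
            {"small": small, "medium": medium, "large": large, "combined": medium + large}
        )

    if by is None:
        counts = _count(out).to_frame().T
    else:
        rows = []
        for key, sub in out.groupby(list(by), sort=True):
            key = key if isinstance(key, tuple) else (key,)
            rows.append({**dict(zip(by, key)), **_count(sub).to_dict()})
        counts = pd.DataFrame(rows)
    return out, counts
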