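"""Footprint table I/O, quality filtering and fixed-interval thinning.

Footprint tables are pandas DataFrames with columns
(shot_id, beam, track, x, y, <14 metrics>, quality_flag, degrade_flag,
sensitivity). They can come from real L2B HDF5 granules (``read_l2b``)
or from the synthetic generators, and round-trip through CSV and
GeoJSON points.

Quality screening keeps shots with quality_flag == 1, degrade_flag == 0
and waveform sensitivity >= 0.9 (the forest setting). Density thinning
keeps every k-th shot within each beam; the pipeline order is fixed as
filter-then-thin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic import METRIC_SCHEMA

__all__ = [
    "FilterCriteria",
    "FilterReport",
    "read_l2b",
    "filter_footprints",
    "thin_footprints",
    "write_footprint_csv",
    "read_footprint_csv",
    "write_footprint_geojson",
    "read_footprint_geojson",
]

QUALITY_FIELDS = ("quality_flag", "degrade_flag", "sensitivity")


class FormatError(ValueError):
    """Malformed or incomplete input file."""


@dataclass(frozen=True)
class FilterCriteria:
    """Quality screen: flag equalities plus a sensitivity floor."""

    quality_flag_required: int = 1
    degrade_flag_required: int = 0
    sensitivity_min: float = 0.9

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity_min <= 1.0:
            raise ValueError("sensitivity_min must be in [0, 1]")


@dataclass(frozen=True)
class FilterReport:
    """Counts of records removed per criterion (non-exclusive) and kept."""

    n_input: int
    n_kept: int
    removed_quality: int
    removed_degrade: int
    removed_sensitivity: int

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self))
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload


# default dataset paths inside each BEAMXXXX group of an L2B granule
DEFAULT_L2B_LAYOUT: dict[str, str] = {
    "shot_id": "shot_number",
    "x": "geolocation/lon_lowestmode",
    "y": "geolocation/lat_lowestmode",
    "quality_flag": "l2b_quality_flag",
    "degrade_flag": "geolocation/degrade_flag",
    "sensitivity": "sensitivity",
    "cover": "cover",
    "dem": "geolocation/digital_elevation_model",
    "fhd_normal": "fhd_normal",
    "landsat_treecover": "land_cover_data/landsat_treecover",
    "leaf_off_doy": "land_cover_data/leaf_off_doy",
    "leaf_on_doy": "land_cover_data/leaf_on_doy",
    "modis_treecover": "land_cover_data/modis_treecover",
    "modis_nonvegetated": "land_cover_data/modis_nonvegetated",
    "pai": "pai",
    "pgap_thea": "pgap_theta",
    "rg": "rg",
    "rh100": "rh100",
    "rv": "rv",
}


def read_l2b(
    path,
    beams: Optional[Sequence[str]] = None,
    schema: Sequence[str] = METRIC_SCHEMA,
    layout: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Read footprint records from an L2B HDF5 granule.

    ``beams`` selects beam groups (default: every group starting with
    "BEAM"); ``layout`` maps column names to in-group dataset paths
    (defaults follow the official product layout). A requested metric
    with no dataset raises :class:`FormatError` naming the missing path.
    """
    import h5py

    layout = {**DEFAULT_L2B_LAYOUT, **(layout or {})}
    columns = ["shot_id", "x", "y", *schema, "quality_flag", "degrade_flag"]
    if "sensitivity" not in columns:
        columns.append("sensitivity")
    frames = []
    with h5py.File(path, "r") as f:
        beam_names = beams if beams is not None else [
            k for k in f.keys() if k.startswith("BEAM")
        ]
        for beam in beam_names:
            if beam not in f:
                raise FormatError(f"beam group {beam!r} not present in {path}")
            grp = f[beam]
            data = {}
            for col in columns:
                ds_path = layout.get(col, col)
                if ds_path not in grp:
                    raise FormatError(
                        f"dataset {beam}/{ds_path} (column {col!r}) missing in {path}"
                    )
                data[col] = np.asarray(grp[ds_path])
            frame = pd.DataFrame(data)
            frame.insert(1, "beam", beam)
            frame.insert(2, "track", "T0")
            frames.append(frame)
    if not frames:
        raise FormatError(f"no beam groups found in {path}")
    return pd.concat(frames, ignore_index=True)


def filter_footprints(
    table: pd.DataFrame, criteria: FilterCriteria = FilterCriteria()
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the three-way quality screen; order is preserved.

    Returns the kept records plus a report of how many failed each
    criterion (a record can fail several). An empty result is legal.
    """
    missing = [c for c in QUALITY_FIELDS if c not in table.columns]
    if missing:
        raise KeyError(f"table lacks quality fields: {missing}")
    bad_q = table["quality_flag"] != criteria.quality_flag_required
    bad_d = table["degrade_flag"] != criteria.degrade_flag_required
    bad_s = table["sensitivity"] < criteria.sensitivity_min
    keep = ~(bad_q | bad_d | bad_s)
    report = FilterReport(
        n_input=int(len(table)),
        n_kept=int(keep.sum()),
        removed_quality=int(bad_q.sum()),
        removed_degrade=int(bad_d.sum()),
        removed_sensitivity=int(bad_s.sum()),
    )
    return table.loc[keep].copy(), report


def thin_footprints(
    table: pd.DataFrame,
    interval: int,
    offset: int = 0,
    random_offset: bool = False,
    seed: int = 0,
    pooled: bool = False,
) -> pd.DataFrame:
    """Keep every ``interval``-th shot within each beam.

    Shots are ranked by shot_id within (track, beam); ranks congruent to
    ``offset`` (mod interval) are kept, so interval=1 is the identity.
    ``random_offset`` draws a seeded per-beam offset instead (the
    "randomly select" variant); ``pooled`` ranks over the whole ordered
    shot stream rather than per beam.
    """
    if int(interval) < 1:
        raise ValueError(f"interval must be >= 1, got {interval}")
    interval = int(interval)
    if len(table) == 0 or interval == 1 and not random_offset:
        return table.copy()
    rng = np.random.default_rng(seed)
    ordered = table.sort_values(
        ["track", "beam", "shot_id"] if not pooled else ["shot_id"],
        kind="mergesort",
    )
    if pooled:
        ranks = np.arange(len(ordered))
        off = int(rng.integers(interval)) if random_offset else offset % interval
        keep_mask = (ranks - off) % interval == 0
        kept = ordered.loc[keep_mask]
    else:
        groups = ordered.groupby(["track", "beam"], sort=False)
        parts = []
        for _, grp in groups:
            off = int(rng.integers(interval)) if random_offset else offset % interval
            ranks = np.arange(len(grp))
            parts.append(grp.loc[(ranks - off) % interval == 0])
        kept = pd.concat(parts) if parts else ordered.iloc[:0]
    return kept.sort_index().copy()


# ---------------------------------------------------------------------------
# Plain-text round-trips


def write_footprint_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_footprint_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_footprint_geojson(table: pd.DataFrame, path) -> None:
    """Write footprints as a GeoJSON FeatureCollection of points."""
    props = [c for c in table.columns if c not in ("x", "y")]
    features = []
    for rec in table.itertuples(index=False):
        d = rec._asdict()
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [d["x"], d["y"]]},
                "properties": {k: d[k] for k in props},
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_footprint_geojson(path) -> pd.DataFrame:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path} is not a GeoJSON FeatureCollection")
    rows = []
    for feat in gj["features"]:
        row = dict(feat["properties"])
        row["x"], row["y"] = feat["geometry"]["coordinates"]
        rows.append(row)
    df = pd.DataFrame(rows)
    lead = [c for c in ("shot_id", "beam", "track", "x", "y") if c in df.columns]
    return df[lead + [c for c in df.columns if c not in lead]]
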