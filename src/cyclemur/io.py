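"""Readers and writers for the pipeline's file formats.

Storm tracks travel as an IBTrACS-dialect CSV (columns SID, ISO_TIME, LAT,
LON, WMO_WIND, SAFFIR; extra columns are ignored), ranges and islands as
GeoJSON FeatureCollections, trees as Newick (one per line for posterior
samples), and traits as plain CSV.  Malformed rows are collected into a
rejects report — never silently dropped — and schema violations raise with
the offending row number.

Inputs given in lon/lat degrees are projected to planar kilometres with an
equirectangular projection about the domain's mid-latitude, which is what
the 50 km grid and all Euclidean distances assume.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .errors import SchemaError
from .impact import ImpactGrid, SpeciesRange, StormTrack
from .resilience import TraitRecord

EARTH_RADIUS_KM = 6371.0

TRACK_COLUMNS = ["SID", "ISO_TIME", "LAT", "LON", "WMO_WIND", "SAFFIR"]


def project_lonlat(
    lon: np.ndarray, lat: np.ndarray, lat0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular lon/lat (degrees) -> planar km about latitude lat0."""
    x = np.deg2rad(np.asarray(lon)) * EARTH_RADIUS_KM * np.cos(np.deg2rad(lat0))
    y = np.deg2rad(np.asarray(lat)) * EARTH_RADIUS_KM
    return x, y


def read_tracks(path: str | Path, *, planar: bool = True) -> list[StormTrack]:
    """Read an IBTrACS-dialect CSV into StormTrack objects.

    ``planar=True`` treats LON/LAT as planar kilometres already (the
    synthetic path); ``planar=False`` projects degrees equirectangularly
    about the mid-latitude of the file.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    bad = df[~df["SAFFIR"].isin(range(6))]
    if not bad.empty:
        raise SchemaError(
            f"{path}: invalid SAFFIR value {bad['SAFFIR'].iloc[0]!r} "
            f"at row {bad.index[0] + 2}"  # 1-based + header
        )
    if (df["WMO_WIND"] < 0).any():
        row = df.index[df["WMO_WIND"] < 0][0]
        raise SchemaError(f"{path}: negative wind at row {row + 2}")
    if planar:
        df["_x"], df["_y"] = df["LON"], df["LAT"]
    else:
        lat0 = float(df["LAT"].mean())
        df["_x"], df["_y"] = project_lonlat(df["LON"].values, df["LAT"].values, lat0)
    tracks = []
    for sid, grp in df.groupby("SID", sort=False):
        grp = grp.sort_values("ISO_TIME", kind="stable")
        tracks.append(
            StormTrack(
                storm_id=str(sid),
                points=grp[["_x", "_y"]].to_numpy(float),
                wind=grp["WMO_WIND"].to_numpy(float),
                saffir=grp["SAFFIR"].to_numpy(int),
            )
        )
    return tracks


def write_tracks(tracks: list[StormTrack], path: str | Path) -> None:
    rows = []
    for tr in tracks:
        for i in range(tr.n_points):
            rows.append(
                {
                    "SID": tr.storm_id,
                    "ISO_TIME": i,  # synthetic tracks carry an ordinal time
                    "LAT": tr.points[i, 1],
                    "LON": tr.points[i, 0],
                    "WMO_WIND": tr.wind[i],
                    "SAFFIR": int(tr.saffir[i]),
                }
            )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def read_ranges(path: str | Path) -> list[SpeciesRange]:
    """GeoJSON FeatureCollection (property ``species_id``) -> SpeciesRange list."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError(f"{path}: expected a GeoJSON FeatureCollection")
    out, seen = [], set()
    for i, feat in enumerate(gj.get("features", [])):
        props = feat.get("properties") or {}
        sid = props.get("species_id")
        if sid is None:
            raise SchemaError(f"{path}: feature {i} lacks a species_id property")
        if sid in seen:
            raise SchemaError(f"{path}: duplicate species_id {sid!r} at feature {i}")
        seen.add(sid)
        try:
            poly = shape(feat["geometry"])
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise SchemaError(f"{path}: unparseable geometry at feature {i}: {exc}")
        if poly.geom_type == "MultiPolygon":
            poly = max(poly.geoms, key=lambda g: g.area)
        if poly.geom_type != "Polygon" or not poly.is_valid:
            raise SchemaError(f"{path}: feature {i} is not a valid polygon")
        out.append(SpeciesRange(species_id=str(sid), polygon=poly))
    return out


def write_ranges(ranges: list[SpeciesRange], path: str | Path) -> None:
    feats = []
    for rng in ranges:
        props: dict = {"species_id": rng.species_id, "area_ha": rng.area_ha}
        for diam, s in sorted(rng.impact_summaries.items()):
            props.update({f"impact{diam:g}_{k}": v for k, v in s.items()})
        feats.append(
            {"type": "Feature", "geometry": mapping(rng.polygon), "properties": props}
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_island(path: str | Path):
    """First polygon of a GeoJSON file (the island/land mask)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geom = gj["features"][0]["geometry"]
    elif gj.get("type") == "Feature":
        geom = gj["geometry"]
    else:
        geom = gj
    poly = shape(geom)
    if not poly.is_valid:
        raise SchemaError(f"{path}: invalid island geometry")
    return poly


def write_grid(grid: ImpactGrid, path: str | Path) -> None:
    """Per-cell grid as GeoJSON squares with one property per scale."""
    feats = []
    for r in range(grid.n_rows):
        for c in range(grid.n_cols):
            props = {"row": r, "col": c} | {
                f"impact{d:g}": float(v[r, c]) for d, v in sorted(grid.values.items())
            }
            feats.append(
                {
                    "type": "Feature",
                    "geometry": mapping(grid.cell_box(r, c)),
                    "properties": props,
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_trees(path: str | Path) -> list[dendropy.Tree]:
    """Newick trees, one per line, on a shared taxon namespace."""
    tl = dendropy.TreeList.get(path=str(path), schema="newick")
    if not tl:
        raise SchemaError(f"{path}: no trees found")
    return list(tl)


def write_trees(trees: list[dendropy.Tree], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick", suppress_rooting=True).strip() + "\n")


TRAIT_COLUMNS = {
    "species_id": str,
    "energy_conservation": "boolean",
    "terrestrial_use": "boolean",
    "group_size": float,
    "fruit_pct": float,
    "home_range_ha": float,
    "body_mass_g": float,
}


def read_traits(path: str | Path) -> list[TraitRecord]:
    """Raw trait CSV -> TraitRecord list (missing cells stay missing)."""
    df = pd.read_csv(path)
    if "species_id" not in df.columns:
        raise SchemaError(f"{path}: missing species_id column")
    dupes = df["species_id"][df["species_id"].duplicated()]
    if not dupes.empty:
        raise SchemaError(
            f"{path}: duplicate species_id {dupes.iloc[0]!r} at row "
            f"{dupes.index[0] + 2}"
        )
    out = []
    for i, row in df.iterrows():
        def get(col, cast=float):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return cast(row[col])

        try:
            out.append(
                TraitRecord(
                    species_id=str(row["species_id"]),
                    energy_conservation=get("energy_conservation", lambda v: bool(int(v))),
                    terrestrial_use=get("terrestrial_use", lambda v: bool(int(v))),
                    group_size=get("group_size"),
                    fruit_pct=get("fruit_pct"),
                    home_range_ha=get("home_range_ha"),
                    body_mass_g=get("body_mass_g"),
                )
            )
        except Exception as exc:  # noqa: BLE001
            raise SchemaError(f"{path}: row {i + 2}: {exc}")
    return out


def write_traits(records: list[TraitRecord], path: str | Path) -> None:
    rows = [
        {
            "species_id": r.species_id,
            "energy_conservation": None
            if r.energy_conservation is None
            else int(r.energy_conservation),
            "terrestrial_use": None
            if r.terrestrial_use is None
            else int(r.terrestrial_use),
            "group_size": r.group_size,
            "fruit_pct": r.fruit_pct,
            "home_range_ha": r.home_range_ha,
            "body_mass_g": r.body_mass_g,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
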