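"""Readers and writers for the pipeline's file formats.

* Climate stacks: multi-band TIFF (GeoTIFF-compatible container) with the
  grid definition, band names/units and mask encoding stored as a JSON
  document in the TIFF ImageDescription tag; a sidecar ``<path>.json`` is
  accepted as an alternative metadata source.  WGS84 lon/lat is assumed
  throughout (no reprojection).
* Native ranges: GeoJSON FeatureCollections whose features carry a
  ``status`` property (IUCN-style presence codes).
* Introduction events: CSV with one row per release event; missing values
  are empty cells.  The schema is validated with row-level error messages.
* Niche envelopes: GeoJSON in environmental space (coordinates are PCA
  scores, flagged as such in the properties block).
* Environmental spaces: a JSON document of means/sds/loadings/eigenvalues.

All writers round-trip losslessly through the corresponding reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
import tifffile

from .climate import ClimateStack, EnvSpace
from .envelope import NicheEnvelope
from .establishment import FIXED_COLS

__all__ = [
    "read_raster",
    "write_raster",
    "read_ranges",
    "write_ranges",
    "read_events",
    "write_events",
    "read_envelope",
    "write_envelope",
    "read_env_space",
    "write_env_space",
    "write_nmi_results",
    "EVENT_COLUMNS",
]

EVENT_COLUMNS = ("species", "family", "region", "longitude", "latitude", "outcome") + FIXED_COLS


# -- rasters ----------------------------------------------------------------


def write_raster(stack: ClimateStack, path: str | Path) -> None:
    """Write a ClimateStack as multi-band TIFF; masked pixels become NaN."""
    vals = np.where(stack.mask[None, :, :], stack.values, np.nan).astype("float64")
    meta = {
        "extent": list(stack.extent),
        "bands": list(stack.band_names),
        "units": list(stack.band_units),
        "crs": "WGS84 lon/lat",
        "nodata": "NaN",
    }
    tifffile.imwrite(str(path), vals, description=json.dumps(meta))


def read_raster(path: str | Path) -> ClimateStack:
    """Read a multi-band TIFF written by :func:`write_raster` (or compatible)."""
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        vals = tf.asarray().astype(float)
        desc = tf.pages[0].description
    meta = None
    if desc:
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = None
    if meta is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if not sidecar.exists():
            raise ValueError(
                f"no metadata: neither an ImageDescription JSON nor sidecar {sidecar.name}"
            )
        meta = json.loads(sidecar.read_text())
    for key in ("extent", "bands"):
        if key not in meta:
            raise ValueError(f"raster metadata missing '{key}'")
    crs = meta.get("crs", "WGS84 lon/lat")
    if "wgs84" not in crs.lower().replace("-", ""):
        raise ValueError(f"unsupported CRS {crs!r}: rasters must be WGS84 lon/lat")
    if vals.ndim == 2:
        vals = vals[None]
    mask = np.all(np.isfinite(vals), axis=0)
    return ClimateStack(
        values=np.where(mask[None], vals, np.nan),
        mask=mask,
        extent=tuple(meta["extent"]),
        band_names=list(meta["bands"]),
        band_units=list(meta.get("units", [])) or None,
    )


# -- range polygons ---------------------------------------------------------


def write_ranges(ranges, path: str | Path) -> None:
    """Write (geometry, status) pairs as a GeoJSON FeatureCollection."""
    features = []
    for item in ranges:
        geom, status = (item["geometry"], item["status"]) if isinstance(item, dict) else item
        features.append(
            {
                "type": "Feature",
                "properties": {"status": status},
                "geometry": shapely.geometry.mapping(geom),
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def read_ranges(path: str | Path) -> list[tuple]:
    """Read range polygons with their presence status from GeoJSON."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    out = []
    for i, f in enumerate(doc["features"]):
        props = f.get("properties") or {}
        if "status" not in props:
            raise ValueError(f"feature {i} is missing the required 'status' property")
        out.append((shapely.geometry.shape(f["geometry"]), props["status"]))
    return out


# -- introduction events ----------------------------------------------------


def read_events(path: str | Path) -> pd.DataFrame:
    """Read and validate an introduction-events CSV.

    Required columns: species, family, region, longitude, latitude, outcome
    plus the ten model covariates; missing values are empty cells.
    """
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file missing column(s): {missing}")
    errors = []
    outcome = pd.to_numeric(df["outcome"], errors="coerce")
    for i in df.index[~outcome.isin([0, 1])]:
        errors.append(f"row {i}: outcome must be 0 or 1, got {df.loc[i, 'outcome']!r}")
    ni = pd.to_numeric(df["n_individuals"], errors="coerce")
    for i in df.index[ni.notna() & (ni < 1)]:
        errors.append(f"row {i}: n_individuals must be >= 1, got {df.loc[i, 'n_individuals']!r}")
    isl = pd.to_numeric(df["island"], errors="coerce")
    for i in df.index[isl.notna() & ~isl.isin([0, 1])]:
        errors.append(f"row {i}: island must be 0 (mainland) or 1, got {df.loc[i, 'island']!r}")
    if errors:
        raise ValueError("invalid events file:\n" + "\n".join(errors))
    return df


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


# -- envelopes and spaces ---------------------------------------------------


def write_envelope(env: NicheEnvelope, path: str | Path) -> None:
    Path(path).write_text(json.dumps(env.to_geojson_dict()))


def read_envelope(path: str | Path) -> NicheEnvelope:
    return NicheEnvelope.from_geojson_dict(json.loads(Path(path).read_text()))


def write_env_space(space: EnvSpace, path: str | Path) -> None:
    Path(path).write_text(space.to_json())


def read_env_space(path: str | Path) -> EnvSpace:
    return EnvSpace.from_json(Path(path).read_text())


def write_nmi_results(results, path: str | Path, coords: np.ndarray | None = None) -> None:
    """Write per-site NMI results as CSV (site_id, pc1, pc2, inside, ...)."""
    rows = []
    for i, r in enumerate(results):
        pc = coords[i] if coords is not None else (np.nan, np.nan)
        rows.append(
            {
                "site_id": r.site_id,
                "pc1": pc[0],
                "pc2": pc[1],
                "inside": "" if r.inside is None else int(r.inside),
                "distance": r.distance,
                "denominator": r.denominator,
                "nmi": r.nmi,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
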