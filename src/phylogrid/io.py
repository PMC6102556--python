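"""CSV/GeoJSON readers and writers for surfaces and maps."""

from __future__ import annotations

import json

import pandas as pd

from .metrics import DiversitySurface

__all__ = [
    "write_surfaces_csv",
    "read_surfaces_csv",
    "write_geojson_points",
]


def write_surfaces_csv(surfaces: list[DiversitySurface], path) -> None:
    frames = [s.to_frame().reset_index() for s in surfaces]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_surfaces_csv(path) -> list[DiversitySurface]:
    df = pd.read_csv(path, dtype={"cell_id": str})
    out = []
    for (metric, group), sub in df.groupby(["metric", "group"], sort=True):
        sub = sub.set_index("cell_id")
        coords = sub[["x", "y"]] if {"x", "y"}.issubset(sub.columns) else None
        out.append(
            DiversitySurface(metric, sub["value"],
                             None if pd.isna(group) else str(group), coords)
        )
    return out


def write_geojson_points(cells: pd.DataFrame, values: dict, path) -> None:
    """Cell centroids as GeoJSON points with value attributes."""
    features = []
    for cell_id, row in cells.iterrows():
        props = {"cell_id": str(cell_id)}
        for name, series in values.items():
            if cell_id in series.index:
                v = series.loc[cell_id]
                props[name] = v if isinstance(v, str) else float(v)
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Point",
                    "coordinates": [float(row["x"]), float(row["y"])],
                },
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
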