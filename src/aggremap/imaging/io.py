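"""Measurement CSV output and provenance serialization."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .pipeline import MovieMeasurements

__all__ = ["measurements_to_frames_df", "measurements_to_objects_df",
           "write_measurements", "read_measurements_csv"]


def measurements_to_frames_df(result: MovieMeasurements,
                              frame_interval_h: float) -> pd.DataFrame:
    rows = []
    for m in result.measurements:
        rows.append({
            "frame": m.time_index,
            "time_h": m.time_index * frame_interval_h,
            "n_aggregates": m.n_aggregates,
            "total_area_px": m.total_area_px,
        })
    return pd.DataFrame(rows, columns=["frame", "time_h", "n_aggregates",
                                       "total_area_px"])


def measurements_to_objects_df(result: MovieMeasurements) -> pd.DataFrame:
    rows = []
    for m in result.measurements:
        for o in m.objects:
            rows.append({
                "frame": m.time_index,
                "label": o.label,
                "area_px": o.area_px,
                "area_um2": o.area_um2,
                "perimeter_px": o.perimeter_px,
                "circularity": o.circularity,
                "centroid_row": o.centroid[0],
                "centroid_col": o.centroid[1],
            })
    return pd.DataFrame(rows, columns=["frame", "label", "area_px", "area_um2",
                                       "perimeter_px", "circularity",
                                       "centroid_row", "centroid_col"])


def write_measurements(result: MovieMeasurements, outdir: "str | Path",
                       frame_interval_h: float) -> None:
    """Write frames.csv, objects.csv and provenance.json to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    measurements_to_frames_df(result, frame_interval_h).to_csv(
        outdir / "frames.csv", index=False)
    measurements_to_objects_df(result).to_csv(outdir / "objects.csv", index=False)
    prov = dict(result.provenance)
    prov["errors"] = [{"frame": e.time_index, "message": e.message}
                      for e in result.errors]
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2))


def read_measurements_csv(path: "str | Path") -> pd.DataFrame:
    return pd.read_csv(path)
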