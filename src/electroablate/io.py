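"""File formats: measurement CSV, trace CSV, raster CSV+JSON, TIFF images, YAML configs.

All outputs are plain text apart from the 16-bit two-channel TIFF (with a
JSON sidecar carrying the pixel size and world transform).  JSON is written
with sorted keys so identical results are byte-identical on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .electro import CurrentTrace
from .errors import ValidationError
from .fields import FieldSamples, MeasurementGrid, RasterField
from .phantom import Electrode, PhantomConfig, ResistanceModel
from .viability import ViabilityImage

__all__ = [
    "write_measurements", "read_measurements",
    "write_trace", "read_trace",
    "write_raster", "read_raster",
    "write_viability_image", "read_viability_image",
    "config_to_dict", "config_from_dict", "write_config", "read_config",
    "config_hash", "write_json", "read_json",
]


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
    )


def read_json(path):
    return json.loads(Path(path).read_text())


# -- measurements -----------------------------------------------------------

def write_measurements(samples_list, path) -> None:
    """Write one or more FieldSamples to the shared measurement CSV schema."""
    frames = []
    for s in samples_list:
        df = s.data.merge(s.grid.as_frame(), on="site_id")
        df["quantity"] = s.quantity
        frames.append(df[["site_id", "x_mm", "y_mm", "replicate", "quantity", "value"]])
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_measurements(path) -> dict:
    """Read the measurement CSV back into {quantity: FieldSamples}."""
    df = pd.read_csv(path)
    out = {}
    for quantity, sub in df.groupby("quantity", sort=False):
        sites = sub.drop_duplicates("site_id")
        grid = MeasurementGrid(
            site_ids=tuple(sites["site_id"]),
            xy=sites[["x_mm", "y_mm"]].to_numpy(dtype=float),
        )
        out[quantity] = FieldSamples(
            grid=grid,
            quantity=str(quantity),
            data=sub[["site_id", "replicate", "value"]].reset_index(drop=True),
        )
    return out


# -- current traces ----------------------------------------------------------

def write_trace(trace: CurrentTrace, path) -> None:
    pd.DataFrame({"t_s": trace.times, "current_A": trace.currents}).to_csv(
        path, index=False
    )


def read_trace(path) -> CurrentTrace:
    df = pd.read_csv(path)
    return CurrentTrace(
        times=df["t_s"].to_numpy(dtype=float),
        currents=df["current_A"].to_numpy(dtype=float),
    )


# -- rasters ------------------------------------------------------------------

def write_raster(raster: RasterField, csv_path, json_path) -> None:
    np.savetxt(csv_path, raster.masked(), delimiter=",")
    write_json(
        {
            "origin_mm": list(raster.origin),
            "spacing_mm": raster.spacing,
            "quantity": raster.quantity,
            "shape": list(raster.values.shape),
        },
        json_path,
    )


def read_raster(csv_path, json_path) -> RasterField:
    header = read_json(json_path)
    values = np.loadtxt(csv_path, delimiter=",", ndmin=2)
    mask = np.isfinite(values)
    return RasterField(
        origin=tuple(header["origin_mm"]),
        spacing=float(header["spacing_mm"]),
        values=np.where(mask, values, 0.0),
        valid_mask=mask,
        quantity=header.get("quantity", ""),
    )


# -- viability images ---------------------------------------------------------

def write_viability_image(image: ViabilityImage, tiff_path, sidecar_path) -> None:
    stack = np.stack(
        [
            np.clip(np.rint(image.green), 0, 65535).astype(np.uint16),
            np.clip(np.rint(image.red), 0, 65535).astype(np.uint16),
        ]
    )
    tifffile.imwrite(tiff_path, stack)
    write_json(
        {
            "channels": ["green", "red"],
            "pixel_size_um": image.pixel_size_um,
            "origin_mm": list(image.origin_mm),
        },
        sidecar_path,
    )


def read_viability_image(tiff_path, sidecar_path) -> ViabilityImage:
    stack = tifffile.imread(tiff_path)
    meta = read_json(sidecar_path)
    if stack.ndim != 3 or stack.shape[0] != 2:
        raise ValidationError("expected a 2-channel image stack")
    channels = {name: stack[i] for i, name in enumerate(meta["channels"])}
    return ViabilityImage(
        green=channels["green"].astype(float),
        red=channels["red"].astype(float),
        pixel_size_um=float(meta["pixel_size_um"]),
        origin_mm=tuple(meta["origin_mm"]),
    )


# -- configs ------------------------------------------------------------------

def config_to_dict(config: PhantomConfig) -> dict:
    d = dataclasses.asdict(config)
    d["electrodes"] = [dataclasses.asdict(e) for e in config.electrodes]
    d["resistance_model"] = dataclasses.asdict(config.resistance_model)
    return d


def config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    d["electrodes"] = tuple(Electrode(**e) for e in d.get("electrodes", []))
    if "resistance_model" in d:
        d["resistance_model"] = ResistanceModel(**d["resistance_model"])
    return PhantomConfig(**d)


def write_config(config: PhantomConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))


def read_config(path) -> PhantomConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: PhantomConfig) -> str:
    canonical = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
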