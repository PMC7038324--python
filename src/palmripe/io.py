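"""CSV/JSON/PNG readers and writers for the pipeline's exchange formats.

Formats
-------
battery CSV (long)   sample_id, class_label, r_l_ohm, v_l_mV, replicate
moisture CSV         sample_id, moisture_pct
features CSV         sample_id, v_l_mV, r_over_g, label
chart layout JSON    chip grid + reference chip colors (see color.ChartLayout)
homography JSON      3x3 row-major nested list
"""

from __future__ import annotations

from pathlib import Path

import json
import numpy as np
import pandas as pd
from PIL import Image

from .battery import FruitSample
from .classify import FeatureSet
from .color import ChartLayout
from .moisture import RipenessLabel

__all__ = [
    "SchemaError",
    "read_battery_csv",
    "read_moisture_csv",
    "read_features_csv",
    "samples_from_battery_csv",
    "feature_sets_from_frame",
    "read_layout",
    "read_homography",
    "load_image",
    "save_image",
]

BATTERY_COLUMNS = ["sample_id", "class_label", "r_l_ohm", "v_l_mV", "replicate"]
FEATURE_COLUMNS = ["sample_id", "v_l_mV", "r_over_g", "label"]


class SchemaError(ValueError):
    """A CSV is missing required columns or is empty."""


def _require_columns(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise SchemaError(f"{path}: no data rows")


def read_battery_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, BATTERY_COLUMNS, path)
    return df


def read_moisture_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id", "moisture_pct"], path)
    return df


def read_features_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, FEATURE_COLUMNS, path)
    return df


def samples_from_battery_csv(
    battery: pd.DataFrame, moisture: pd.DataFrame | None = None
) -> list[FruitSample]:
    """Assemble per-fruit samples from replicate-level voltage readings.

    Replicates are averaged per (fruit, load); voltages are stored in volts.
    When a moisture table is given it is joined on ``sample_id``.
    """
    moisture_map = (
        dict(zip(moisture["sample_id"], moisture["moisture_pct"]))
        if moisture is not None
        else {}
    )
    samples = []
    means = (
        battery.groupby(["sample_id", "class_label", "r_l_ohm"])["v_l_mV"]
        .mean()
        .reset_index()
    )
    for (sid, label), group in means.groupby(["sample_id", "class_label"], sort=True):
        samples.append(
            FruitSample(
                sample_id=str(sid),
                label=RipenessLabel(label),
                moisture=moisture_map.get(sid),
                voltages={
                    float(r): v / 1000.0
                    for r, v in zip(group["r_l_ohm"], group["v_l_mV"])
                },
            )
        )
    return samples


def feature_sets_from_frame(features: pd.DataFrame) -> dict[str, FeatureSet]:
    """Build the battery / vision / combined feature sets from a feature table."""
    _require_columns(features, FEATURE_COLUMNS, "<features>")
    labels = features["label"].to_numpy()
    vl = features[["v_l_mV"]].to_numpy(dtype=float)
    rg = features[["r_over_g"]].to_numpy(dtype=float)
    return {
        "battery": FeatureSet(kind="battery", matrix=vl, labels=labels),
        "vision": FeatureSet(kind="vision", matrix=rg, labels=labels),
        "combined": FeatureSet(
            kind="combined", matrix=np.hstack([vl, rg]), labels=labels
        ),
    }


def read_layout(path: str | Path) -> ChartLayout:
    return ChartLayout.from_json(Path(path).read_text())


def read_homography(path: str | Path) -> np.ndarray:
    hom = np.asarray(json.loads(Path(path).read_text()), dtype=float)
    if hom.shape != (3, 3):
        raise ValueError(f"{path}: homography must be 3x3, got {hom.shape}")
    return hom


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/JPEG as an (H, W, 3) float array in [0, 255]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=float)


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float image, clipping to [0, 255] and rounding to 8-bit."""
    arr = np.clip(np.rint(np.asarray(image, dtype=float)), 0, 255).astype(np.uint8)
    Image.fromarray(arr).save(path)
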