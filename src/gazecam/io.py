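"""Dataset manifests, gaze logs, run configuration, and checkpoints.

Formats are deliberately plain: CSV manifests and gaze logs, flat YAML
key-value configs, NumPy .npz checkpoint containers, PNG image exports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .attention import ClassifierBundle
from .gaze import FixationSequence, GazePoint
from .nn import TinyConvNet

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "load_manifest",
    "save_manifest",
    "summarize_manifest",
    "load_gaze_log",
    "save_gaze_log",
    "load_config",
    "save_config",
    "save_checkpoint",
    "load_checkpoint",
    "load_image",
    "save_image",
    "save_map_png",
    "load_map_png",
]

MANIFEST_COLUMNS = ("image_id", "patient_id", "label", "split")
SPLIT_TOKENS = ("train", "val", "test")
GAZE_COLUMNS = ("image_id", "timestamp_ms", "x_px", "y_px", "duration_ms")


@dataclass
class RunConfig:
    """Flat run configuration shared by the CLI commands.

    Gaze rendering (sigma, kernel_taps in display pixels), model and
    training hyperparameters, and the seed all live in one schema so every
    run can write a resolved copy of its configuration next to its outputs.
    """

    sigma: float = 30.0
    kernel_taps: int = 199
    weight_by_duration: bool = False
    img_size: int = 64
    num_classes: int = 3
    lr: float = 1e-3
    t0: int = 10
    tmult: int = 2
    batch_train: int = 8
    batch_val: int = 16
    max_epochs: int = 150
    lambda_gaze: float = 1.0
    relu_on: str = "weights"
    cam_class: str = "predicted"
    avg: str = "macro"
    seed: int = 0

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key-value mapping")
    return RunConfig.from_dict(data)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def load_manifest(path: str | Path, check_paths: bool = True) -> pd.DataFrame:
    """Load and validate a dataset manifest CSV.

    Required columns: image_id, patient_id, label, split (+ image_path when
    images live on disk; optional mask_path). Errors name offending rows.
    A per-split, per-class count summary is logged on success.
    """
    df = pd.read_csv(path, dtype={"image_id": str, "patient_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    dup = df[df["image_id"].duplicated(keep=False)]
    if len(dup):
        raise ValueError(
            f"duplicate image_id at rows {sorted(dup.index.tolist())}: "
            f"{sorted(dup['image_id'].unique().tolist())}")
    bad_split = df[~df["split"].isin(SPLIT_TOKENS)]
    if len(bad_split):
        raise ValueError(f"unknown split tokens at rows "
                         f"{sorted(bad_split.index.tolist())}: "
                         f"{sorted(bad_split['split'].unique().tolist())}")
    if not np.issubdtype(df["label"].dtype, np.integer):
        raise ValueError("label column must be integer")
    if (df["label"] < 0).any():
        raise ValueError("labels must be nonnegative integers")
    if check_paths and "image_path" in df.columns:
        base = Path(path).parent
        for i, p in df["image_path"].items():
            if not (base / p).exists() and not Path(p).exists():
                raise ValueError(f"row {i}: image file not found: {p}")
    logger.info("manifest summary:\n%s", summarize_manifest(df).to_string())
    return df


def save_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def summarize_manifest(df: pd.DataFrame) -> pd.DataFrame:
    """Per-class x per-split image counts (a dataset-table style summary)."""
    summary = df.pivot_table(index="label", columns="split", values="image_id",
                             aggfunc="count", fill_value=0)
    return summary.reindex(columns=[s for s in SPLIT_TOKENS
                                    if s in summary.columns])


def load_gaze_log(path: str | Path, screen_w_px: int = 1920,
                  screen_h_px: int = 1080) -> dict[str, FixationSequence]:
    """Load a gaze log CSV into per-image fixation sequences.

    Rows are grouped by image_id and sorted by timestamp. A sampling-rate
    sanity check against the nominal 90 Hz tracker interval logs a warning
    (never an error) when the median inter-sample gap is far off.
    """
    df = pd.read_csv(path, dtype={"image_id": str})
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze log missing required columns: {missing}")
    for col in ("timestamp_ms", "x_px", "y_px", "duration_ms"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df[vals.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"non-numeric {col} at rows "
                             f"{sorted(bad.index.tolist())}")
        df[col] = vals
    out: dict[str, FixationSequence] = {}
    for image_id, grp in df.groupby("image_id", sort=True):
        grp = grp.sort_values("timestamp_ms")
        ts = grp["timestamp_ms"].to_numpy()
        if len(ts) > 2:
            med = float(np.median(np.diff(ts)))
            nominal = 1000.0 / 90.0
            if med > 0 and not 0.2 * nominal <= med <= 5.0 * nominal:
                logger.warning("image %s: median sample interval %.1f ms is far "
                               "from the nominal %.1f ms", image_id, med, nominal)
        points = [GazePoint(x_px=float(r.x_px), y_px=float(r.y_px),
                            timestamp_ms=float(r.timestamp_ms),
                            duration_ms=float(r.duration_ms))
                  for r in grp.itertuples()]
        out[image_id] = FixationSequence(image_id=image_id, points=points,
                                         screen_w_px=screen_w_px,
                                         screen_h_px=screen_h_px)
    return out


def save_gaze_log(sequences: dict[str, FixationSequence], path: str | Path) -> None:
    rows = []
    for image_id, fix in sequences.items():
        for p in fix.points:
            rows.append({"image_id": image_id, "timestamp_ms": p.timestamp_ms,
                         "x_px": p.x_px, "y_px": p.y_px,
                         "duration_ms": p.duration_ms})
    pd.DataFrame(rows, columns=list(GAZE_COLUMNS)).to_csv(path, index=False)


def save_checkpoint(bundle: ClassifierBundle, path: str | Path,
                    config: RunConfig | None = None,
                    extra: dict | None = None) -> None:
    """Serialize a bundle (+ run config) into a single .npz container."""
    arrays = {}
    conv_idx = 0
    for layer in bundle.extractor.layers:
        if hasattr(layer, "W"):
            arrays[f"conv{conv_idx}_W"] = layer.W
            arrays[f"conv{conv_idx}_b"] = layer.b
            conv_idx += 1
    arrays["head_W"] = bundle.head_weights
    arrays["head_b"] = bundle.head_bias
    meta = {
        "num_classes": bundle.num_classes,
        "input_size": bundle.input_size,
        "class_names": bundle.class_names,
        "config": config.to_dict() if config is not None else None,
        "extra": extra or {},
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:  # exact filename, no implicit .npz suffix
        np.savez(fh, **arrays)


def load_checkpoint(path: str | Path) -> tuple[ClassifierBundle, dict]:
    data = np.load(path)
    meta = json.loads(bytes(data["meta_json"]).decode())
    extractor = TinyConvNet.__new__(TinyConvNet)
    extractor.layers = []
    conv_idx = 0
    from .nn import Conv2d, ReLU
    while f"conv{conv_idx}_W" in data:
        W = data[f"conv{conv_idx}_W"]
        layer = Conv2d.__new__(Conv2d)
        layer.W = W.copy()
        layer.b = data[f"conv{conv_idx}_b"].copy()
        layer.ksize, layer.stride, layer.pad = W.shape[-1], 2, 1
        layer.dW = np.zeros_like(layer.W)
        layer.db = np.zeros_like(layer.b)
        layer._win = None
        layer._xshape = None
        extractor.layers.append(layer)
        extractor.layers.append(ReLU())
        conv_idx += 1
    extractor.out_channels = extractor.layers[-2].W.shape[0]
    bundle = ClassifierBundle(
        extractor=extractor,
        head_weights=data["head_W"].copy(),
        head_bias=data["head_b"].copy(),
        num_classes=int(meta["num_classes"]),
        input_size=int(meta["input_size"]),
        class_names=list(meta["class_names"]),
    )
    return bundle, meta


def load_image(path: str | Path) -> np.ndarray:
    """Read an RGB image as (H, W, 3) floats in [0, 1]."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=float) / 255.0


def save_image(image: np.ndarray, path: str | Path) -> None:
    """Write an (H, W, 3) float [0,1] or uint8 array as 8-bit RGB PNG."""
    if image.dtype != np.uint8:
        image = np.clip(np.round(image * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(image, mode="RGB").save(path)


def save_map_png(values: np.ndarray, path: str | Path) -> None:
    """Write a [0,1] map as 16-bit grayscale PNG (65535 = 1.0)."""
    arr = np.clip(np.round(np.asarray(values) * 65535.0), 0, 65535).astype(np.uint16)
    Image.fromarray(arr, mode="I;16").save(path)


def load_map_png(path: str | Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im, dtype=float) / 65535.0
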