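"""Scene directory format, run configuration, and the optional
challenge-ground-truth reader.

A scene directory holds one 8-bit grayscale ``image.png``, per-instance
binary masks ``cell_000.png, cell_001.png, ...`` (0/255), and an
``index.json`` with the image path, seed, config echo, achieved overlap
rate and per-cell bounding boxes. Writer and reader round-trip exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

from .model import ModelConfig
from .synth import InstanceMaskSet, SynthConfig

log = logging.getLogger(__name__)

__all__ = ["FormatError", "RunConfig", "write_scene", "read_scene", "write_dataset", "read_dataset", "read_isbi_mat"]


class FormatError(ValueError):
    """A scene directory or config file violates the on-disk contract."""


@dataclass
class RunConfig:
    """Merged synth + model + evaluation options, YAML round-trippable."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    dsc_threshold: float = 0.7
    strict_threshold: bool = False
    match_method: str = "greedy"
    seed: int = 0
    log_level: str = "INFO"

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["synth"]["n_cells_range"] = list(d["synth"]["n_cells_range"])
        d["synth"]["cell_radius_frac"] = list(d["synth"]["cell_radius_frac"])
        d["model"]["widths"] = list(d["model"]["widths"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(d)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        kw = dict(d)
        for key, sub in (("synth", SynthConfig), ("model", ModelConfig)):
            if key in kw and isinstance(kw[key], dict):
                sub_known = {f.name for f in fields(sub)}
                sub_unknown = set(kw[key]) - sub_known
                if sub_unknown:
                    raise FormatError(f"unknown {key} config keys: {sorted(sub_unknown)}")
                sd = dict(kw[key])
                for tup_key in ("n_cells_range", "cell_radius_frac", "widths"):
                    if tup_key in sd and isinstance(sd[tup_key], list):
                        sd[tup_key] = tuple(sd[tup_key])
                kw[key] = sub(**sd)
        return cls(**kw)


def write_scene(
    out_dir: str | Path,
    image: np.ndarray,
    masks: InstanceMaskSet,
    metadata: dict | None = None,
    scores: np.ndarray | None = None,
) -> Path:
    """Write one scene (image + per-cell mask PNGs + JSON index)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img8 = np.clip(np.asarray(image, dtype=np.float64) * 255.0, 0, 255).round().astype(np.uint8)
    iio.imwrite(out / "image.png", img8)
    names = []
    for i, m in enumerate(masks.masks):
        name = f"cell_{i:03d}.png"
        iio.imwrite(out / name, (m.astype(np.uint8) * 255))
        names.append(name)
    index = {
        "image": "image.png",
        "masks": names,
        "bboxes": [list(b) for b in masks.bounding_boxes()],
        "metadata": metadata or {},
    }
    if scores is not None:
        index["scores"] = [float(s) for s in np.atleast_1d(scores)]
    (out / "index.json").write_text(json.dumps(index, indent=1))
    return out


def read_scene(scene_dir: str | Path) -> tuple[np.ndarray, InstanceMaskSet, dict]:
    """Read a scene directory back; validates masks against the index."""
    d = Path(scene_dir)
    idx_path = d / "index.json"
    if not idx_path.exists():
        raise FormatError(f"missing index.json in {d}")
    try:
        index = json.loads(idx_path.read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"corrupt index.json in {d}: {e}") from e
    img = np.asarray(iio.imread(d / index["image"]), dtype=np.float64) / 255.0
    masks = []
    for name in index["masks"]:
        p = d / name
        if not p.exists():
            raise FormatError(f"mask file {name} listed in index but missing from {d}")
        m = np.asarray(iio.imread(p)) > 127
        if m.shape != img.shape[:2]:
            raise FormatError(f"mask {name} shape {m.shape} inconsistent with image {img.shape[:2]}")
        if not m.any():
            raise FormatError(f"mask {name} is empty")
        masks.append(m)
    meta = dict(index.get("metadata", {}))
    if "scores" in index:
        meta["scores"] = np.asarray(index["scores"], dtype=np.float64)
    return img, InstanceMaskSet(masks), meta


def write_dataset(out_dir: str | Path, scenes, prefix: str = "scene") -> list[Path]:
    out = Path(out_dir)
    paths = []
    for i, (img, masks, meta) in enumerate(scenes):
        paths.append(write_scene(out / f"{prefix}_{i:04d}", img, masks, meta))
    return paths


def read_dataset(root: str | Path) -> list[tuple[np.ndarray, InstanceMaskSet, dict]]:
    root = Path(root)
    dirs = sorted(p for p in root.iterdir() if (p / "index.json").exists())
    if not dirs:
        raise FormatError(f"no scene directories under {root}")
    return [read_scene(d) for d in dirs]


def read_isbi_mat(path: str | Path) -> InstanceMaskSet:
    """Reader for challenge-style ``.mat`` ground truth (external data;
    convenience only, untested in CI).

    Accepts a MAT file whose variables are per-cell binary masks or a cell
    array of masks.
    """
    from scipy.io import loadmat

    raw = loadmat(str(path))
    masks: list[np.ndarray] = []
    for key, val in raw.items():
        if key.startswith("__"):
            continue
        arr = np.asarray(val)
        if arr.dtype == object:
            for cell in arr.ravel():
                masks.append(np.asarray(cell) > 0)
        elif arr.ndim == 2:
            masks.append(arr > 0)
        elif arr.ndim == 3:
            masks.extend(arr[..., i] > 0 for i in range(arr.shape[-1]))
    if not masks:
        raise FormatError(f"no masks found in {path}")
    return InstanceMaskSet(masks)
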