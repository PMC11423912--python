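"""File I/O: multi-channel TIFF images, JSON ground-truth sidecars, YAML config.

Image dialect: multi-page TIFF, one page per channel, with a JSON image
description carrying channel names, pixel size (um/pixel), orientation and
condition labels.  Pixel size is never guessed: loading fails if neither the
file nor the caller supplies it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import tifffile
import yaml

from .errors import ConfigurationError
from .synthetic import (RadialSection, SectionGroundTruth, WholemountGroundTruth,
                        WholemountImage)


def _stack(channels: Dict[str, np.ndarray], order):
    return np.stack([channels[c] for c in order]).astype(np.float32)


def save_section(section: RadialSection, path) -> None:
    order = list(section.channels)
    meta = {
        "kind": "RadialSection",
        "channels": order,
        "pixel_size_um": section.pixel_size,
        "condition": section.condition,
        "stage": section.stage,
        "metadata": section.metadata,
    }
    tifffile.imwrite(path, _stack(section.channels, order),
                     description=json.dumps(meta), photometric="minisblack")


def load_section(path, metadata: Optional[dict] = None) -> RadialSection:
    """Load a multi-channel TIFF as a RadialSection.

    ``metadata`` may supply ``channels``, ``pixel_size_um`` and
    ``medial_on`` when the file lacks them.  Sections recorded with the
    medial edge on the right are mirrored so that medial is always on the
    left in memory.
    """
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    if metadata:
        meta = {**meta, **metadata}
    if data.ndim == 2:
        data = data[None]
    channels = meta.get("channels")
    if channels is None:
        raise ConfigurationError(f"{path}: channel names missing from file and metadata")
    if len(channels) != data.shape[0]:
        raise ConfigurationError(
            f"{path}: {len(channels)} channel names for {data.shape[0]} pages")
    px = meta.get("pixel_size_um")
    if px is None:
        raise ConfigurationError(f"{path}: pixel size missing from file and metadata")
    inner = dict(meta.get("metadata", {}))
    if "medial_on" in meta:
        inner["medial_on"] = meta["medial_on"]
    arrays = {c: np.asarray(data[i], dtype=float) for i, c in enumerate(channels)}
    if inner.get("medial_on") == "right":
        arrays = {c: a[:, ::-1].copy() for c, a in arrays.items()}
        inner["medial_on"] = "left"
        inner["mirrored_on_load"] = True
    return RadialSection(channels=arrays, pixel_size=float(px),
                         condition=str(meta.get("condition", "")),
                         stage=str(meta.get("stage", "")), metadata=inner)


def save_wholemount(image: WholemountImage, path) -> None:
    order = list(image.channels)
    meta = {
        "kind": "WholemountImage",
        "channels": order,
        "pixel_size_um": image.pixel_size,
        "condition": image.condition,
        "stage": image.stage,
        "metadata": image.metadata,
    }
    tifffile.imwrite(path, _stack(image.channels, order),
                     description=json.dumps(meta), photometric="minisblack")


def load_wholemount(path, metadata: Optional[dict] = None) -> WholemountImage:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description
    meta = json.loads(desc) if desc else {}
    if metadata:
        meta = {**meta, **metadata}
    if data.ndim == 2:
        data = data[None]
    channels = meta.get("channels")
    px = meta.get("pixel_size_um")
    if channels is None or len(channels) != data.shape[0]:
        raise ConfigurationError(f"{path}: channel metadata missing or inconsistent")
    if px is None:
        raise ConfigurationError(f"{path}: pixel size missing from file and metadata")
    arrays = {c: np.asarray(data[i], dtype=float) for i, c in enumerate(channels)}
    return WholemountImage(channels=arrays, pixel_size=float(px),
                           condition=str(meta.get("condition", "")),
                           stage=str(meta.get("stage", "")),
                           metadata=dict(meta.get("metadata", {})))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_ground_truth(gt, path) -> None:
    d = _jsonable(dataclasses.asdict(gt))
    d["__type__"] = type(gt).__name__
    Path(path).write_text(json.dumps(d))


def load_ground_truth(path):
    d = json.loads(Path(path).read_text())
    kind = d.pop("__type__")
    if kind == "SectionGroundTruth":
        return SectionGroundTruth(
            path=np.asarray(d["path"]), arclength=np.asarray(d["arclength"]),
            boundary_positions=d["boundary_positions"],
            true_widths=d["true_widths"], total_width=d["total_width"],
            drawn=d.get("drawn", {}),
        )
    if kind == "WholemountGroundTruth":
        return WholemountGroundTruth(
            aligned_ihc_positions=np.asarray(d["aligned_ihc_positions"]).reshape(-1, 2),
            ectopic_ihc_positions=np.asarray(d["ectopic_ihc_positions"]).reshape(-1, 2),
            ectopic_partner_index=np.asarray(d["ectopic_partner_index"], dtype=int),
            ohc_positions=np.asarray(d["ohc_positions"]).reshape(-1, 2),
            true_length=float(d["true_length"]),
            true_doublets_by_region=d["true_doublets_by_region"],
            row_origin_x=float(d["row_origin_x"]),
        )
    raise ConfigurationError(f"{path}: unknown ground-truth type {kind!r}")


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "cochleaquant_out"
    threshold_frac: float = 0.5
    smoothing_window: int = 5
    grid_points: int = 101
    band_halfwidth: float = 5.0
    pairing_distance: float = 12.0
    # cohort sizes follow the published per-figure section/cochlea counts
    cohorts: Dict[str, dict] = field(default_factory=lambda: {
        "e14": {"control": ["e14_control", 15], "cko": ["e14_bcat_cko", 19],
                "seeds": [1, 2]},
        "e15": {"control": ["e15_control", 24], "cko": ["e15_mybl2_cko", 24],
                "seeds": [3, 4]},
        "e15_ki67": {"control": ["e15_control", 22], "cko": ["e15_mybl2_cko", 21],
                     "seeds": [5, 6]},
        "emx2": {"control": ["emx2_control", 8], "cko": ["emx2_bcat_cko", 8],
                 "seeds": [7, 7]},
        "e18_wholemount": {"no_cre": ["e18_nocre", 12],
                           "het": ["e18_sox2cre_het", 9],
                           "cko": ["e18_mybl2_cko", 14],
                           "seeds": [0, 0, 0]},
        "e18_ortho_base": {"control": ["e18_base_control", 32],
                           "cko": ["e18_base_cko", 37], "seeds": [8, 8]},
    })

    def validate(self) -> None:
        if not 0 < self.threshold_frac < 1:
            raise ConfigurationError("threshold_frac must lie in (0, 1)")
        if self.grid_points < 2:
            raise ConfigurationError("grid_points must be >= 2")
        for name, spec in self.cohorts.items():
            for key, val in spec.items():
                if key == "seeds":
                    continue
                preset, n = val
                if int(n) < 1:
                    raise ConfigurationError(
                        f"cohorts[{name}][{key}]: cohort size must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls(**d)
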