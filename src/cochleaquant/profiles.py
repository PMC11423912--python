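"""Intensity profiles along the cochlear duct floor.

The spatial unit of analysis is a one-dimensional fluorescence profile sampled
along the floor of the cochlear duct from the medial to the lateral luminal
edge.  Profiles are min-max normalized (minimum 0, maximum 1) and positions
are normalized to [0, 1] of the total radial width, so sections of different
absolute size and imaging gain can be averaged and compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label

from .errors import AnalysisError, ConfigurationError
from .synthetic import RadialSection

#: default half-width (um) of the band averaged perpendicular to the path
DEFAULT_BAND_HALFWIDTH = 5.0
#: default common grid for cross-sample averaging
DEFAULT_GRID_POINTS = 101


@dataclass
class DuctFloorPath:
    """Medial-first polyline through the epithelial band midline."""

    points: np.ndarray  # (N, 2) (x, y) in um
    arclength: np.ndarray  # (N,) cumulative um, starts at 0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.arclength = np.asarray(self.arclength, dtype=float)
        if self.points.shape[0] < 2:
            raise ConfigurationError("path needs at least 2 points")
        if self.arclength[0] != 0 or np.any(np.diff(self.arclength) <= 0):
            raise ConfigurationError(
                "cumulative arclength must start at 0 and strictly increase")

    @property
    def total_length(self) -> float:
        return float(self.arclength[-1])


@dataclass
class IntensityProfile:
    """Min-max-normalized intensity vs normalized medial->lateral position."""

    channel: str
    positions: np.ndarray  # [0, 1], strictly increasing, endpoints 0 and 1
    values: np.ndarray  # [0, 1] after normalization
    total_width: float  # um
    constant: bool = False  # raw profile had no dynamic range

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.size != self.values.size:
            raise ConfigurationError("positions and values must match in length")
        if self.positions[0] != 0.0 or abs(self.positions[-1] - 1.0) > 1e-9:
            raise ConfigurationError("positions must span [0, 1]")
        if np.any(np.diff(self.positions) <= 0):
            raise ConfigurationError("positions must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return int(self.positions.size)

    @property
    def positions_um(self) -> np.ndarray:
        return self.positions * self.total_width


@dataclass
class AverageProfile:
    """Per-position mean and s.d. of profiles resampled to a common grid."""

    channel: str
    grid: np.ndarray
    mean_values: np.ndarray
    sd_values: np.ndarray
    n: int


def _minmax(values: np.ndarray):
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi - lo < 1e-12:
        return np.zeros_like(values), True
    return (values - lo) / (hi - lo), False


def tissue_mask(section: RadialSection) -> np.ndarray:
    """Binary epithelium mask: Otsu on DAPI, largest connected component."""
    dapi = section.channel("DAPI")
    if float(dapi.max() - dapi.min()) < 1e-12:
        raise AnalysisError("no tissue detected")
    thr = threshold_otsu(dapi)
    mask = dapi > thr
    if not mask.any():
        raise AnalysisError("no tissue detected")
    labels = label(mask)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == int(np.argmax(counts))
    if int(mask.sum()) < 10:
        raise AnalysisError("tissue too small")
    return mask


def trace_duct_floor(section: RadialSection, smooth_um: float = 5.0) -> DuctFloorPath:
    """Trace the epithelial band midline from the DAPI channel.

    Otsu threshold -> largest connected component -> per-column centroid ->
    moving-average smoothing.  The returned polyline runs medial end first;
    sections flagged ``medial_on == 'right'`` are reversed accordingly.
    """
    mask = tissue_mask(section)
    px = section.pixel_size
    col_any = mask.any(axis=0)
    cols = np.where(col_any)[0]
    if cols.size < 2:
        raise AnalysisError("tissue too small")
    rows_idx = np.arange(mask.shape[0], dtype=float)
    weights = mask[:, cols].astype(float)
    yc = (weights * rows_idx[:, None]).sum(axis=0) / weights.sum(axis=0)

    w = max(1, int(round(smooth_um / px)))
    if w > 1:
        kernel = np.ones(w) / w
        norm = np.convolve(np.ones_like(yc), kernel, mode="same")
        yc = np.convolve(yc, kernel, mode="same") / norm

    x_um = (cols + 0.5) * px
    y_um = (yc + 0.5) * px
    pts = np.column_stack([x_um, y_um])
    if section.medial_on == "right":
        pts = pts[::-1]
    seg = np.hypot(*np.diff(pts, axis=0).T)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    return DuctFloorPath(points=pts, arclength=arclen)


def extract_profile(section: RadialSection, path: DuctFloorPath, channel: str,
                    band_halfwidth: float = DEFAULT_BAND_HALFWIDTH) -> IntensityProfile:
    """Sample a channel along the path and min-max normalize.

    Intensity is sampled at uniform arc-length steps (one pixel) and averaged
    perpendicular to the path over +-``band_halfwidth`` um; the band suppresses
    single-pixel noise.  Values are normalized to [0, 1] (zeros with a
    ``constant`` flag if the raw profile has no range); positions are
    normalized so 0 is the medial and 1 the lateral luminal edge.
    """
    img = section.channel(channel)
    if band_halfwidth < 0:
        raise ConfigurationError("band_halfwidth must be >= 0")
    px = section.pixel_size
    total = path.total_length
    n = max(int(np.floor(total / px)), 1)
    s_grid = np.linspace(0.0, total, n + 1)
    x = np.interp(s_grid, path.arclength, path.points[:, 0])
    y = np.interp(s_grid, path.arclength, path.points[:, 1])

    h, w = img.shape
    if (x.min() < 0 or y.min() < 0 or x.max() > w * px or y.max() > h * px):
        raise AnalysisError("path out of bounds")

    tx = np.gradient(x, s_grid)
    ty = np.gradient(y, s_grid)
    norm = np.hypot(tx, ty)
    nx, ny = -ty / norm, tx / norm

    k = int(round(band_halfwidth / px))
    offsets = (np.arange(-k, k + 1) * px) if k > 0 else np.array([0.0])
    sample_x = x[None, :] + offsets[:, None] * nx[None, :]
    sample_y = y[None, :] + offsets[:, None] * ny[None, :]
    # position um -> fractional array index (pixel centres at (i + 0.5) * px)
    rows = sample_y / px - 0.5
    cols_i = sample_x / px - 0.5
    samples = ndi.map_coordinates(img, [rows, cols_i], order=1, mode="nearest")
    raw = samples.mean(axis=0)

    values, is_const = _minmax(raw)
    return IntensityProfile(
        channel=channel, positions=s_grid / total, values=values,
        total_width=total, constant=is_const,
    )


def resample_profile(profile: IntensityProfile, grid_points: int) -> IntensityProfile:
    """Linear interpolation onto a uniform grid of ``grid_points`` positions."""
    if grid_points < 2:
        raise ConfigurationError("grid_points must be >= 2")
    grid = np.linspace(0.0, 1.0, int(grid_points))
    vals = np.interp(grid, profile.positions, profile.values)
    return IntensityProfile(
        channel=profile.channel, positions=grid, values=vals,
        total_width=profile.total_width, constant=profile.constant,
    )


def average_profiles(profiles: Sequence[IntensityProfile],
                     grid_points: int = DEFAULT_GRID_POINTS) -> AverageProfile:
    """Resample to a common grid, then per-position mean and s.d. across samples."""
    if len(profiles) == 0:
        raise ConfigurationError("average_profiles requires a non-empty list")
    channels = {p.channel for p in profiles}
    if len(channels) > 1:
        raise ConfigurationError(f"mixed channels cannot be averaged: {sorted(channels)}")
    grid = np.linspace(0.0, 1.0, int(grid_points))
    stack = np.vstack([np.interp(grid, p.positions, p.values) for p in profiles])
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros_like(mean)
    return AverageProfile(channel=profiles[0].channel, grid=grid,
                          mean_values=mean, sd_values=sd, n=stack.shape[0])


def profiles_to_frame(profiles: Dict[str, IntensityProfile], sample_id: str) -> pd.DataFrame:
    """Tidy long-format table (sample_id, channel, position, value)."""
    rows = []
    for ch, p in profiles.items():
        rows.append(pd.DataFrame({
            "sample_id": sample_id, "channel": ch,
            "position": p.positions, "value": p.values,
        }))
    return pd.concat(rows, ignore_index=True)


def average_to_frame(avg: AverageProfile) -> pd.DataFrame:
    return pd.DataFrame({
        "channel": avg.channel, "position": avg.grid,
        "mean": avg.mean_values, "sd": avg.sd_values, "n": avg.n,
    })
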