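"""Seeded synthetic cochlear images with exact ground truth.

Cross-sections
--------------
A section is an (H, W) multi-channel image of an epithelial band crossed by
the duct-floor path running medial (left) to lateral (right).  Along the
path's arc length ``s`` each marker follows a plateau-per-domain profile with
sigmoidal (normal-CDF) transitions of half-width ``boundary_transition_sigma``
centred exactly on the true domain boundaries, so half-maximum crossings of a
noise-free profile recover the boundaries analytically.  Pixels get a shared
multiplicative lognormal cell texture plus per-channel additive Gaussian
noise.  The ground-truth sidecar records the path, the exact boundary arc
lengths and every drawn per-section parameter.

Wholemounts
-----------
A wholemount is a top view of the hair-cell region: one aligned row of inner
hair cells (IHCs), three rows of outer hair cells laterally, and planted
ectopic IHCs displaced medially from their aligned partner (doublets), with
per-region Poisson counts.  The MYO6 channel carries Gaussian spots at every
cell; SOX2 is a support-cell band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.special import ndtr

from .errors import ConfigurationError
from .presets import DOMAINS, LayoutPreset, WholemountPreset

REGIONS: Tuple[str, ...] = ("base", "mid", "apex")


# ---------------------------------------------------------------------------
# containers

@dataclass
class RadialSection:
    """Multi-channel cross-section image of the cochlear duct."""

    channels: Dict[str, np.ndarray]  # name -> (H, W) array, a.u. >= 0
    pixel_size: float  # um / pixel
    condition: str = "control"
    stage: str = ""
    metadata: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel_size must be > 0")
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ConfigurationError(f"channel arrays differ in shape: {shapes}")

    @property
    def medial_on(self) -> str:
        return str(self.metadata.get("medial_on", "left"))

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown channel {name!r}; available: {sorted(self.channels)}"
            ) from None


@dataclass
class SectionGroundTruth:
    """Exact geometry of a generated section (recovery-test oracle)."""

    path: np.ndarray  # (N, 2) (x, y) um along the duct floor, medial first
    arclength: np.ndarray  # (N,) cumulative um, starts at 0
    boundary_positions: Dict[str, float]  # medial_edge, IS_MS, MS_LS, LS_OS, lateral_edge
    true_widths: Dict[str, float]  # IS, MS, LS, OS in um
    total_width: float
    drawn: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        b = self.boundary_positions
        order = [b["medial_edge"], b["IS_MS"], b["MS_LS"], b["LS_OS"], b["lateral_edge"]]
        if not all(x < y for x, y in zip(order, order[1:])):
            raise ConfigurationError("boundary positions must be strictly increasing")


@dataclass
class WholemountImage:
    """Top-view multi-channel image of the E18.5 hair-cell region."""

    channels: Dict[str, np.ndarray]
    pixel_size: float
    condition: str = "control"
    stage: str = "E18.5"
    metadata: Dict[str, object] = field(default_factory=dict)

    @property
    def medial_side(self) -> str:
        """'low_y' means smaller y (row index) is medial."""
        return str(self.metadata.get("medial_side", "low_y"))

    @property
    def base_side(self) -> str:
        return str(self.metadata.get("base_side", "low_x"))

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise ConfigurationError(
                f"unknown channel {name!r}; available: {sorted(self.channels)}"
            ) from None


@dataclass
class WholemountGroundTruth:
    aligned_ihc_positions: np.ndarray  # (n, 2) um, image coordinates
    ectopic_ihc_positions: np.ndarray  # (m, 2) um
    ectopic_partner_index: np.ndarray  # (m,) index into aligned rows
    ohc_positions: np.ndarray  # (k, 2) um
    true_length: float  # um, first to last aligned IHC
    true_doublets_by_region: Dict[str, int]
    row_origin_x: float  # image x (um) of the first aligned IHC


# ---------------------------------------------------------------------------
# helpers

def derive_child_seed(seed: int, index: int) -> int:
    """Deterministic per-member seed for cohort generation (< 2**31)."""
    ss = np.random.SeedSequence([int(seed), int(index)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float = -np.inf, hi: float = np.inf) -> float:
    """Normal draw truncated symmetrically around the mean.

    Truncation at +-2.5 s.d. (intersected with [lo, hi] symmetrised around the
    mean) keeps the sample mean unbiased while guarding domain bounds.
    """
    if sd == 0:
        return float(mean)
    half = 2.5 * sd
    half = min(half, mean - lo, hi - mean) if np.isfinite(lo) or np.isfinite(hi) else half
    if half <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(200):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= half:
            return float(x)
    return float(mean)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative lognormal noise with mean exactly 1 and the given CV."""
    if cv == 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma, size=size)


def _smooth_step(s: np.ndarray, center: float, sigma: float) -> np.ndarray:
    """Sigmoid rising from 0 to 1 with half-maximum exactly at ``center``."""
    return ndtr((np.asarray(s, dtype=float) - center) / sigma)


def analytic_channel_profile(channel: str, s, *, boundaries: Dict[str, float],
                             sigma: float,
                             plateaus: Optional[Dict[str, float]] = None,
                             band_extent_um: Optional[float] = None,
                             band_level: float = 1.0,
                             band_baseline: float = 0.05,
                             gain: float = 1.0) -> np.ndarray:
    """Noise-free along-path intensity of a channel at arc positions ``s`` (um).

    Plateau channels interpolate the four per-domain plateau levels with
    normal-CDF transitions centred on the true boundaries; medial-band
    channels fall from ``band_level`` to ``band_baseline`` at
    ``band_extent_um``.  This is the exact formula the image generator paints,
    exposed so tests can use it as an independent oracle.
    """
    s = np.asarray(s, dtype=float)
    if plateaus is not None:
        v = np.full_like(s, plateaus["IS"])
        edges = [("IS_MS", "IS", "MS"), ("MS_LS", "MS", "LS"), ("LS_OS", "LS", "OS")]
        for bname, lo, hi in edges:
            v = v + (plateaus[hi] - plateaus[lo]) * _smooth_step(s, boundaries[bname], sigma)
    elif band_extent_um is not None:
        v = band_baseline + (band_level - band_baseline) * (
            1.0 - _smooth_step(s, band_extent_um, sigma)
        )
    else:
        raise ConfigurationError("either plateaus or band_extent_um is required")
    return gain * v


def draw_section_params(preset: LayoutPreset, rng: np.random.Generator) -> Dict[str, float]:
    """Draw the per-section layout parameters in a fixed, seeded order."""
    p: Dict[str, float] = {}
    p["total_width"] = _trunc_normal(rng, preset.total_width_mean,
                                     preset.total_width_sd, lo=10.0)
    p["medial_fraction"] = _trunc_normal(rng, preset.medial_fraction,
                                         preset.medial_fraction_sd, 0.05, 0.95)
    p["is_fraction"] = _trunc_normal(rng, preset.is_fraction_of_medial,
                                     preset.is_fraction_sd, 0.05, 0.95)
    p["ls_fraction"] = _trunc_normal(rng, preset.ls_fraction_of_lateral,
                                     preset.ls_fraction_sd, 0.05, 0.95)
    for ch in sorted(preset.medial_bands):
        band = preset.medial_bands[ch]
        p[f"band_extent:{ch}"] = _trunc_normal(rng, band.extent_mean,
                                               band.extent_sd, 0.05, 0.95)
    marker_channels = sorted(set(preset.channel_plateaus) | set(preset.medial_bands))
    for ch in marker_channels:
        mean_gain = preset.channel_gains.get(ch, 1.0)
        p[f"gain:{ch}"] = mean_gain * float(_lognormal_factor(rng, preset.channel_gain_cv))
    return p


def boundaries_from_params(p: Dict[str, float]) -> Dict[str, float]:
    t, m = p["total_width"], p["medial_fraction"]
    is_ms = p["is_fraction"] * m * t
    ms_ls = m * t
    ls_os = m * t + p["ls_fraction"] * (1.0 - m) * t
    return {"medial_edge": 0.0, "IS_MS": is_ms, "MS_LS": ms_ls,
            "LS_OS": ls_os, "lateral_edge": t}


# ---------------------------------------------------------------------------
# cross-section generation

def make_section(preset: LayoutPreset, seed: int) -> Tuple[RadialSection, SectionGroundTruth]:
    """Generate one synthetic cross-section plus its exact ground truth.

    Deterministic for a given (preset, seed).
    """
    if seed < 0 or int(seed) != seed:
        raise ConfigurationError("seed must be a non-negative integer")
    rng = np.random.default_rng(int(seed))
    p = draw_section_params(preset, rng)
    bounds = boundaries_from_params(p)
    total = p["total_width"]
    px = preset.pixel_size

    # geometry: duct floor runs horizontally (optionally a gentle arc) through
    # the centre of the epithelial band.
    margin = preset.margin
    thickness = preset.epithelium_thickness
    amp = preset.arc_amplitude
    if amp > 0:
        # choose the horizontal extent so the curved path has arc length = total
        from scipy.optimize import brentq

        def arclen(w_ext: float) -> float:
            x = np.linspace(0.0, w_ext, 4096)
            y = amp * np.sin(np.pi * x / w_ext)
            return float(np.sum(np.hypot(np.diff(x), np.diff(y))))

        w_ext = brentq(lambda w: arclen(w) - total, total * 0.5, total)
    else:
        w_ext = total

    width_um = w_ext + 2 * margin
    height_um = thickness + 2 * margin + 2 * amp
    n_cols = int(round(width_um / px))
    n_rows = int(round(height_um / px))
    xs = (np.arange(n_cols) + 0.5) * px  # pixel-centre x in um
    ys = (np.arange(n_rows) + 0.5) * px
    x0 = margin
    in_tissue = (xs >= x0) & (xs <= x0 + w_ext)
    cols = np.where(in_tissue)[0]
    xt = xs[cols] - x0  # 0..w_ext

    yc = margin + amp + thickness / 2.0
    if amp > 0:
        y_path = yc - amp * np.sin(np.pi * xt / w_ext)
        seg = np.hypot(np.diff(xt), np.diff(y_path))
        s = np.concatenate([[0.0], np.cumsum(seg)])
    else:
        y_path = np.full_like(xt, yc)
        s = xt.copy()

    band = np.abs(ys[:, None] - y_path[None, :]) <= thickness / 2.0  # (H, n_cols)

    texture = _lognormal_factor(rng, preset.texture_cv, size=(n_rows, n_cols))

    sigma = preset.boundary_transition_sigma
    channels: Dict[str, np.ndarray] = {}

    def paint(profile_vals: np.ndarray) -> np.ndarray:
        img = np.zeros((n_rows, n_cols))
        img[:, cols] = np.where(band, profile_vals[None, :], 0.0)
        return img

    channels["DAPI"] = paint(np.ones_like(s))
    for ch in sorted(preset.channel_plateaus):
        prof = analytic_channel_profile(
            ch, s, boundaries=bounds, sigma=sigma,
            plateaus=preset.channel_plateaus[ch], gain=p[f"gain:{ch}"],
        )
        channels[ch] = paint(prof)
    for ch in sorted(preset.medial_bands):
        bandspec = preset.medial_bands[ch]
        prof = analytic_channel_profile(
            ch, s, boundaries=bounds, sigma=sigma,
            band_extent_um=p[f"band_extent:{ch}"] * total,
            band_level=bandspec.level, band_baseline=bandspec.baseline,
            gain=p[f"gain:{ch}"],
        )
        channels[ch] = paint(prof)

    for ch in list(channels):
        img = channels[ch] * texture
        if preset.noise_sd_additive > 0:
            img = img + rng.normal(0.0, preset.noise_sd_additive, size=img.shape)
        channels[ch] = np.clip(img, 0.0, None)

    section = RadialSection(
        channels=channels, pixel_size=px,
        condition=preset.condition, stage=preset.stage,
        metadata={"medial_on": "left", "preset": preset.name, "seed": int(seed)},
    )
    widths = {
        "IS": bounds["IS_MS"] - bounds["medial_edge"],
        "MS": bounds["MS_LS"] - bounds["IS_MS"],
        "LS": bounds["LS_OS"] - bounds["MS_LS"],
        "OS": bounds["lateral_edge"] - bounds["LS_OS"],
    }
    gt = SectionGroundTruth(
        path=np.column_stack([xs[cols], yc - (yc - y_path)]),  # (x, y) um
        arclength=s,
        boundary_positions=bounds,
        true_widths=widths,
        total_width=total,
        drawn=p,
    )
    return section, gt


def make_cohort(preset: LayoutPreset, n: int, seed: int
                ) -> List[Tuple[RadialSection, SectionGroundTruth]]:
    """Generate ``n`` independent sections with seeds derived from (seed, index)."""
    if n < 1:
        raise ConfigurationError("cohort size n must be >= 1")
    return [make_section(preset, derive_child_seed(seed, i)) for i in range(n)]


# ---------------------------------------------------------------------------
# wholemount generation

def _region_of(x: np.ndarray, length: float) -> np.ndarray:
    """Region index 0/1/2 = base/mid/apex by longitudinal thirds."""
    idx = np.minimum((np.asarray(x) / (length / 3.0)).astype(int), 2)
    return idx


def make_wholemount(preset: WholemountPreset, seed: int
                    ) -> Tuple[WholemountImage, WholemountGroundTruth]:
    """Generate one synthetic wholemount plus its planted-cell ground truth."""
    if seed < 0 or int(seed) != seed:
        raise ConfigurationError("seed must be a non-negative integer")
    rng = np.random.default_rng(int(seed))
    length = _trunc_normal(rng, preset.length_mean, preset.length_sd, lo=100.0)
    margin = preset.margin
    px = preset.pixel_size
    y0 = margin + preset.ectopic_offset + 5.0  # aligned IHC row
    amp = preset.row_curve_amplitude

    def row_y(x):
        if amp > 0:
            return y0 + amp * np.sin(2 * np.pi * np.asarray(x) / length)
        return np.full_like(np.asarray(x, dtype=float), y0)

    jit = preset.cell_jitter_sd

    # aligned IHC row: endpoints pinned at 0 and length so the measured
    # first-to-last distance equals the true length
    n_ihc = max(int(round(length / preset.ihc_spacing)), 5)
    ax = np.linspace(0.0, length, n_ihc + 1)
    ay = row_y(ax) + np.clip(rng.normal(0.0, jit, size=ax.size), -1.5, 1.5)
    aligned = np.column_stack([ax + margin, ay])

    # three OHC rows lateral (higher y) of the IHC row
    ohc_list = []
    for off in preset.ohc_row_offsets:
        ox = np.arange(0.0, length + 1e-9, preset.ohc_spacing)
        oy = row_y(ox) + off + np.clip(rng.normal(0.0, jit, size=ox.size), -1.5, 1.5)
        ohc_list.append(np.column_stack([ox + margin, oy]))
    ohc = np.vstack(ohc_list)

    # ectopic IHCs: per-region Poisson counts, each paired with a distinct
    # aligned partner and displaced medially (toward low y)
    region_idx = _region_of(ax, length)
    ect_pos, ect_partner = [], []
    true_counts: Dict[str, int] = {}
    for r, region in enumerate(REGIONS):
        mean = preset.doublet_mean_by_region.get(region, 0.0)
        k = int(rng.poisson(mean)) if mean > 0 else 0
        candidates = np.where(region_idx == r)[0]
        k = min(k, candidates.size)
        chosen = rng.choice(candidates, size=k, replace=False) if k else np.array([], int)
        for idx in chosen:
            ex = aligned[idx, 0] + np.clip(rng.normal(0.0, 0.5), -1.0, 1.0)
            ey = (row_y(aligned[idx, 0] - margin)[()] - preset.ectopic_offset
                  + np.clip(rng.normal(0.0, jit), -1.5, 1.5))
            ect_pos.append((ex, ey))
            ect_partner.append(int(idx))
        true_counts[region] = k
    ectopic = np.array(ect_pos, dtype=float).reshape(-1, 2)

    # render
    width_um = length + 2 * margin
    height_um = y0 + max(preset.ohc_row_offsets) + margin
    n_cols = int(round(width_um / px))
    n_rows = int(round(height_um / px))

    myo6 = np.zeros((n_rows, n_cols))
    sig = preset.spot_sigma / px
    half = int(np.ceil(4 * sig))
    all_cells = np.vstack([aligned, ectopic, ohc]) if ectopic.size else np.vstack([aligned, ohc])
    amps = _lognormal_factor(rng, preset.amplitude_cv, size=all_cells.shape[0])
    for (cx, cy), a in zip(all_cells, np.atleast_1d(amps)):
        cxp, cyp = cx / px - 0.5, cy / px - 0.5  # pixel-centre coordinates
        j0, j1 = int(np.floor(cxp)) - half, int(np.floor(cxp)) + half + 1
        i0, i1 = int(np.floor(cyp)) - half, int(np.floor(cyp)) + half + 1
        j0c, j1c = max(j0, 0), min(j1, n_cols)
        i0c, i1c = max(i0, 0), min(i1, n_rows)
        if j0c >= j1c or i0c >= i1c:
            continue
        jj = np.arange(j0c, j1c)
        ii = np.arange(i0c, i1c)
        g = np.exp(-(((ii[:, None] - cyp) ** 2) + ((jj[None, :] - cxp) ** 2)) / (2 * sig ** 2))
        myo6[i0c:i1c, j0c:j1c] += a * g

    ys_um = (np.arange(n_rows) + 0.5) * px
    band = ndtr((ys_um - (y0 - 15.0)) / 3.0) * (1.0 - ndtr((ys_um - (y0 + max(preset.ohc_row_offsets) + 8.0)) / 3.0))
    sox2 = np.tile((preset.sox2_band_gain * band)[:, None], (1, n_cols))

    channels = {}
    for name, img in (("MYO6", myo6), ("SOX2", sox2)):
        if preset.noise_sd > 0:
            img = img + rng.normal(0.0, preset.noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, None)

    image = WholemountImage(
        channels=channels, pixel_size=px,
        condition=preset.condition, stage=preset.stage,
        metadata={"medial_side": "low_y", "base_side": "low_x",
                  "preset": preset.name, "seed": int(seed),
                  "ihc_spacing": preset.ihc_spacing,
                  "spot_sigma": preset.spot_sigma},
    )
    gt = WholemountGroundTruth(
        aligned_ihc_positions=aligned,
        ectopic_ihc_positions=ectopic,
        ectopic_partner_index=np.array(ect_partner, dtype=int),
        ohc_positions=ohc,
        true_length=float(length),
        true_doublets_by_region=true_counts,
        row_origin_x=float(aligned[0, 0]),
    )
    return image, gt


def make_wholemount_cohort(preset: WholemountPreset, n: int, seed: int
                           ) -> List[Tuple[WholemountImage, WholemountGroundTruth]]:
    if n < 1:
        raise ConfigurationError("cohort size n must be >= 1")
    return [make_wholemount(preset, derive_child_seed(seed, i)) for i in range(n)]
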