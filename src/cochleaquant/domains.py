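"""Domain-boundary calling, widths and area/intensity measurements.

Boundary semantics (medial -> lateral): JAG1 marks the medial sensory (MS)
domain, so its rising half-maximum crossing is the IS-MS boundary; E-cadherin
is enriched in the lateral sensory (LS) domain, so its rising edge is the
MS-LS boundary; SOX2 spans MS+LS, so its lateral falling edge is the LS-OS
boundary.  All calls operate on min-max-normalized profiles, which makes them
invariant to affine rescaling of the raw intensities -- thresholding at a
fixed fraction of a normalized profile is what makes fluorescence levels
comparable across sections.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .errors import (ConfigurationError, InconsistentBoundariesError,
                     NoBoundaryError)
from .profiles import IntensityProfile, tissue_mask
from .synthetic import RadialSection

DEFAULT_THRESHOLD_FRAC = 0.5  # half-maximum on normalized profiles
DEFAULT_SMOOTHING_WINDOW = 5  # grid points of moving-average smoothing
DEFAULT_AREA_THRESHOLD_FRAC = 0.2  # of the robust channel max in the tissue


@dataclass
class DomainBoundaries:
    """Ordered boundary arc positions (um from the medial luminal edge)."""

    is_ms: float
    ms_ls: float
    ls_os: float
    lateral_edge: float
    medial_edge: float = 0.0
    source_markers: Dict[str, str] = field(default_factory=dict)
    flags: Dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        order = [self.medial_edge, self.is_ms, self.ms_ls, self.ls_os, self.lateral_edge]
        if not all(a < b for a, b in zip(order, order[1:])):
            raise InconsistentBoundariesError(
                f"boundaries must be strictly ordered, got {order}")


@dataclass
class DomainWidths:
    """Domain widths (um) with the compartment normalizations.

    IS and MS are normalized to the medial compartment (IS+MS); LS and OS to
    the lateral compartment (LS+OS).
    """

    is_: float
    ms: float
    ls: float
    os: float

    @property
    def total(self) -> float:
        return self.is_ + self.ms + self.ls + self.os

    @property
    def medial_compartment(self) -> float:
        return self.is_ + self.ms

    @property
    def lateral_compartment(self) -> float:
        return self.ls + self.os

    @property
    def is_frac(self) -> float:
        return self.is_ / self.medial_compartment

    @property
    def ms_frac(self) -> float:
        return self.ms / self.medial_compartment

    @property
    def ls_frac(self) -> float:
        return self.ls / self.lateral_compartment

    @property
    def os_frac(self) -> float:
        return self.os / self.lateral_compartment


@dataclass
class RegionMeasurement:
    """Thresholded area (um^2) and total intensity (a.u.) of one channel."""

    channel: str
    area: float
    total_intensity: float
    threshold: float
    normalized_area: Optional[float] = None
    normalized_intensity: Optional[float] = None


@dataclass
class NormalizedChange:
    """Values rescaled by the control mean, summarised as a percent change."""

    normalized: np.ndarray
    percent_change: float  # 100 * (mean(normalized) - 1)
    sem: float  # s.e.m. of the normalized values, percent
    #: standard error of the percent-change estimate itself, additionally
    #: propagating the sampling uncertainty of the control mean
    se_change: float = 0.0


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return np.asarray(values, dtype=float)
    kernel = np.ones(int(window)) / int(window)
    norm = np.convolve(np.ones(len(values)), kernel, mode="same")
    return np.convolve(values, kernel, mode="same") / norm


def _upward_crossings(pos_um: np.ndarray, v: np.ndarray, thr: float) -> List[float]:
    idx = np.where((v[:-1] < thr) & (v[1:] >= thr))[0]
    out = []
    for i in idx:
        frac = (thr - v[i]) / (v[i + 1] - v[i])
        out.append(float(pos_um[i] + frac * (pos_um[i + 1] - pos_um[i])))
    return out


def _downward_crossings(pos_um: np.ndarray, v: np.ndarray, thr: float) -> List[float]:
    idx = np.where((v[:-1] >= thr) & (v[1:] < thr))[0]
    out = []
    for i in idx:
        frac = (v[i] - thr) / (v[i] - v[i + 1])
        out.append(float(pos_um[i] + frac * (pos_um[i + 1] - pos_um[i])))
    return out


def detect_boundaries(profiles: Dict[str, IntensityProfile],
                      threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
                      smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
                      ms_marker: str = "jag1",
                      ms_ls_marker: str = "ecad",
                      divergence_tolerance: float = 2.0) -> DomainBoundaries:
    """Call the IS-MS, MS-LS and LS-OS boundaries by profile thresholding.

    Parameters
    ----------
    profiles:
        Mapping with at least ``JAG1``, ``ECAD`` and ``SOX2`` profiles from
        the same section.
    threshold_frac:
        Crossing level on the normalized profiles (default half-maximum).
    ms_marker:
        ``"jag1"`` places the IS-MS boundary at the most medial rising JAG1
        crossing; ``"sox2_minus_ls"`` uses the medial rising edge of SOX2
        instead (equivalent to measuring MS as the SOX2 width minus the LS).
    ms_ls_marker:
        ``"ecad"`` uses the E-cadherin rising edge; ``"both"`` also computes
        the JAG1 falling edge, reports the midpoint and sets a ``divergence``
        flag when the two disagree by more than ``divergence_tolerance`` um.
    """
    if not 0.0 < threshold_frac < 1.0:
        raise ConfigurationError("threshold_frac must lie in (0, 1)")
    for needed in ("JAG1", "ECAD", "SOX2"):
        if needed not in profiles:
            raise ConfigurationError(f"required channel {needed!r} missing from profiles")
    ref = profiles["JAG1"]
    total = ref.total_width

    def prep(channel: str):
        p = profiles[channel]
        return p.positions * total, _smooth(p.values, smoothing_window)

    sources: Dict[str, str] = {}
    flags: Dict[str, bool] = {}

    if ms_marker == "sox2_minus_ls":
        pos, v = prep("SOX2")
        ups = _upward_crossings(pos, v, threshold_frac)
        if not ups:
            raise NoBoundaryError("IS_MS", "no rising SOX2 crossing")
        is_ms = ups[0]
        sources["IS_MS"] = "SOX2"
    else:
        pos, v = prep("JAG1")
        if profiles["JAG1"].constant:
            raise NoBoundaryError("IS_MS", "JAG1 profile is constant")
        ups = _upward_crossings(pos, v, threshold_frac)
        if not ups:
            raise NoBoundaryError("IS_MS", "no rising JAG1 crossing")
        is_ms = ups[0]
        sources["IS_MS"] = "JAG1"

    pos, v = prep("ECAD")
    ups = [u for u in _upward_crossings(pos, v, threshold_frac) if u > is_ms]
    if not ups:
        raise NoBoundaryError("MS_LS", "no rising E-cadherin crossing lateral of IS_MS")
    ms_ls = ups[0]
    sources["MS_LS"] = "ECAD"
    if ms_ls_marker == "both":
        posj, vj = prep("JAG1")
        downs = [d for d in _downward_crossings(posj, vj, threshold_frac) if d > is_ms]
        if downs:
            jag_fall = downs[0]
            if abs(jag_fall - ms_ls) > divergence_tolerance:
                flags["divergence"] = True
            ms_ls = 0.5 * (ms_ls + jag_fall)
            sources["MS_LS"] = "ECAD+JAG1"

    pos, v = prep("SOX2")
    downs = _downward_crossings(pos, v, threshold_frac)
    if not downs:
        raise NoBoundaryError("LS_OS", "no falling SOX2 crossing")
    ls_os = downs[-1]
    sources["LS_OS"] = "SOX2"

    return DomainBoundaries(is_ms=is_ms, ms_ls=ms_ls, ls_os=ls_os,
                            lateral_edge=total, source_markers=sources, flags=flags)


def compute_widths(boundaries: DomainBoundaries) -> DomainWidths:
    """Domain widths from ordered boundaries (telescoping, sums to total)."""
    return DomainWidths(
        is_=boundaries.is_ms - boundaries.medial_edge,
        ms=boundaries.ms_ls - boundaries.is_ms,
        ls=boundaries.ls_os - boundaries.ms_ls,
        os=boundaries.lateral_edge - boundaries.ls_os,
    )


def marker_width_fraction(profile: IntensityProfile,
                          threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
                          smoothing_window: int = DEFAULT_SMOOTHING_WINDOW) -> float:
    """Width of the maximal above-threshold run containing the global maximum,
    as a fraction of the total radial width (used for Ki67 and PRDM16 bands)."""
    if not 0.0 < threshold_frac < 1.0:
        raise ConfigurationError("threshold_frac must lie in (0, 1)")
    if profile.constant:
        raise NoBoundaryError(profile.channel, "constant profile")
    pos = profile.positions * profile.total_width
    v = _smooth(profile.values, smoothing_window)
    above = v >= threshold_frac
    imax = int(np.argmax(v))
    if not above[imax]:
        raise NoBoundaryError(profile.channel, "maximum below threshold")
    # contiguous run containing the maximum
    left = imax
    while left > 0 and above[left - 1]:
        left -= 1
    right = imax
    while right < len(v) - 1 and above[right + 1]:
        right += 1
    # sub-grid edges by interpolation; runs touching the profile ends extend
    # to the luminal edge
    if left == 0:
        s_left = pos[0]
    else:
        frac = (threshold_frac - v[left - 1]) / (v[left] - v[left - 1])
        s_left = pos[left - 1] + frac * (pos[left] - pos[left - 1])
    if right == len(v) - 1:
        s_right = pos[-1]
    else:
        frac = (v[right] - threshold_frac) / (v[right] - v[right + 1])
        s_right = pos[right] + frac * (pos[right + 1] - pos[right])
    return float((s_right - s_left) / profile.total_width)


def robust_channel_max(section: RadialSection, channel: str,
                       percentile: float = 99.5) -> float:
    """High percentile of the channel within the tissue mask (outlier-safe max)."""
    img = section.channel(channel)
    try:
        mask = tissue_mask(section) if "DAPI" in section.channels else None
    except Exception:
        mask = None
    vals = img[mask] if mask is not None else img.ravel()
    return float(np.percentile(vals, percentile))


def measure_area_intensity(section: RadialSection, channel: str,
                           min_threshold: Optional[float] = None,
                           relative_frac: float = DEFAULT_AREA_THRESHOLD_FRAC,
                           restrict_to_tissue: bool = True) -> RegionMeasurement:
    """Above-threshold area and summed intensity of one channel.

    ``min_threshold`` is an absolute level (a.u.); when omitted it defaults to
    ``relative_frac`` x the robust channel maximum inside the tissue mask,
    which keeps the measurement invariant to imaging gain.  When a DAPI
    channel is available the count is restricted to the epithelium mask so
    background noise does not contribute.
    """
    img = section.channel(channel)
    if min_threshold is None:
        min_threshold = relative_frac * robust_channel_max(section, channel)
    elif min_threshold < 0:
        raise ConfigurationError("min_threshold must be >= 0")
    mask = None
    if restrict_to_tissue and "DAPI" in section.channels:
        try:
            mask = tissue_mask(section)
        except Exception:
            mask = None
    sel = img >= min_threshold
    if mask is not None:
        sel &= mask
    area = float(sel.sum()) * section.pixel_size ** 2
    total = float(img[sel].sum())
    return RegionMeasurement(channel=channel, area=area, total_intensity=total,
                             threshold=float(min_threshold))


def normalize_to_control(values: Sequence[float],
                         control_values: Sequence[float]) -> NormalizedChange:
    """Divide by the control mean; summarise as percent change with s.e.m."""
    control = np.asarray(control_values, dtype=float)
    if control.size == 0:
        raise ConfigurationError("control_values must be non-empty")
    cmean = control.mean()
    if cmean == 0:
        raise ConfigurationError("control mean is zero; cannot normalize")
    normalized = np.asarray(values, dtype=float) / cmean
    pc = 100.0 * (normalized.mean() - 1.0)
    sem = (100.0 * normalized.std(ddof=1) / np.sqrt(normalized.size)
           if normalized.size > 1 else 0.0)
    # delta-method SE of the ratio-of-means estimate: the control mean is an
    # estimate too, so its relative uncertainty scales the treated/control ratio
    c_rel = (control.std(ddof=1) / np.sqrt(control.size) / cmean
             if control.size > 1 else 0.0)
    se_change = float(np.hypot(sem, 100.0 * normalized.mean() * c_rel))
    return NormalizedChange(normalized=normalized, percent_change=float(pc),
                            sem=float(sem), se_change=se_change)
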