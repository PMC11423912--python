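"""Hair-cell detection, row fitting and doublet counting on E18.5 wholemounts.

A wholemount shows, from medial to lateral, ectopic inner hair cells (IHCs),
the single aligned IHC row and three outer-hair-cell (OHC) rows.  Cells are
detected as Laplacian-of-Gaussian blobs, the aligned row is fit by a robust
running median, cells medial of the row beyond a tolerance are classified as
ectopic, and each ectopic IHC is paired with its longitudinally nearest
aligned IHC within a pairing distance to form a doublet.  Doublets are binned
into base / mid / apex thirds of the measured cochlear length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max

from .errors import AnalysisError, ConfigurationError
from .synthetic import REGIONS, RadialSection, WholemountImage
from . import domains

DEFAULT_PAIRING_DISTANCE = 12.0  # um, ~1.5 IHC spacings
DEFAULT_ROW_TOLERANCE = 4.0  # um, half a hair-cell radius
DEFAULT_ROW_WINDOW = 100.0  # um, running-median window


@dataclass
class RowCurve:
    """Piecewise-linear y(x) through the aligned IHC row (um coordinates)."""

    centers: np.ndarray
    medians: np.ndarray

    def __call__(self, x) -> np.ndarray:
        return np.interp(np.asarray(x, dtype=float), self.centers, self.medians)

    def arc_length(self, x_start: float, x_end: float, step: float = 1.0) -> float:
        lo, hi = sorted((float(x_start), float(x_end)))
        if hi - lo < step:
            return hi - lo
        xs = np.linspace(lo, hi, max(int(np.ceil((hi - lo) / step)), 2))
        ys = self(xs)
        return float(np.hypot(np.diff(xs), np.diff(ys)).sum())


@dataclass
class HairCellSet:
    """Detected hair cells with classes, row fit and doublet pairing."""

    centroids: np.ndarray  # (n, 2) (x, y) um
    classes: np.ndarray  # per cell: 'aligned_IHC' | 'ectopic_IHC' | 'OHC'
    row_curve: RowCurve
    medial_side: str = "low_y"
    doublet_pairs: List[Tuple[int, int]] = field(default_factory=list)  # (ectopic, aligned)
    region_bins: Optional[np.ndarray] = None

    def indices(self, cls: str) -> np.ndarray:
        return np.where(self.classes == cls)[0]


@dataclass
class CochleaStats:
    """Per-cochlea summary of the counting pipeline."""

    length: float  # um, along the aligned row
    aligned_ihc_count: int
    ectopic_ihc_count: int
    total_doublets: int
    doublets_by_region: Dict[str, int]
    aligned_per_1000um: float
    total_per_1000um: float


def detect_hair_cells(image: WholemountImage, channel: str = "MYO6",
                      spot_sigma: Optional[float] = None,
                      ihc_spacing: Optional[float] = None,
                      threshold_rel: float = 0.3) -> np.ndarray:
    """Detect hair cells as bright blobs; returns (n, 2) sub-pixel centroids in um.

    The channel is filtered with a negated Laplacian of Gaussian at the spot
    scale, local maxima are kept with a suppression radius of 0.6 x the IHC
    spacing, and each peak is refined by the intensity-weighted centroid of
    its local response window.
    """
    img = image.channel(channel).astype(float)
    px = image.pixel_size
    sigma = float(spot_sigma or image.metadata.get("spot_sigma", 2.0)) / px
    spacing = float(ihc_spacing or image.metadata.get("ihc_spacing", 8.0))
    if img.size == 0 or float(img.max()) <= 0:
        return np.empty((0, 2))
    response = -ndi.gaussian_laplace(img, sigma) * sigma ** 2
    np.clip(response, 0.0, None, out=response)
    thr = max(threshold_rel * float(response.max()), 1e-9)
    min_dist = max(1, int(round(0.6 * spacing / px)))
    peaks = peak_local_max(response, min_distance=min_dist, threshold_abs=thr,
                           exclude_border=False)
    if peaks.size == 0:
        return np.empty((0, 2))
    # sub-pixel refinement: centre of mass of the response window
    r = max(1, int(np.ceil(sigma)))
    out = np.empty((peaks.shape[0], 2))
    h, w = response.shape
    for k, (pi, pj) in enumerate(peaks):
        i0, i1 = max(pi - r, 0), min(pi + r + 1, h)
        j0, j1 = max(pj - r, 0), min(pj + r + 1, w)
        win = response[i0:i1, j0:j1]
        tot = win.sum()
        ii, jj = np.mgrid[i0:i1, j0:j1]
        ci = (win * ii).sum() / tot
        cj = (win * jj).sum() / tot
        out[k] = ((cj + 0.5) * px, (ci + 0.5) * px)  # (x, y) um
    return out[np.argsort(out[:, 0])]


def _row_clusters(ys: np.ndarray, gap: float = 6.0) -> List[np.ndarray]:
    """Split sorted y values into row clusters at gaps larger than ``gap`` um."""
    ys = np.sort(ys)
    breaks = np.where(np.diff(ys) > gap)[0]
    return np.split(ys, breaks + 1)


def fit_aligned_row(centroids: np.ndarray, medial_side: str = "low_y",
                    window: float = DEFAULT_ROW_WINDOW) -> RowCurve:
    """Robust running-median curve through the aligned IHC row.

    Per 100-um longitudinal window the cells are clustered on y (rows are
    tight, inter-row gaps are wide); clusters with fewer than 60% of the
    largest cluster's members -- the sparse ectopic outliers -- are ignored,
    and the aligned row is the most medial remaining cluster.  A 3-window
    median filter removes any window where ectopics happened to dominate, so
    the fit tolerates up to ~30% medially displaced ectopics.  Raises
    ``row not identifiable`` for < 5 candidates.
    """
    centroids = np.asarray(centroids, dtype=float)
    if centroids.shape[0] < 5:
        raise AnalysisError("row not identifiable: fewer than 5 IHC-band candidates")
    x, y = centroids[:, 0], centroids[:, 1]
    edges = np.arange(x.min(), x.max() + window, window)
    centers, medians = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (x >= lo) & (x < hi)
        if sel.sum() < 3:
            continue
        clusters = _row_clusters(y[sel])
        biggest = max(len(c) for c in clusters)
        qualifying = [c for c in clusters if len(c) >= 0.6 * biggest]
        chosen = qualifying[0] if medial_side == "low_y" else qualifying[-1]
        centers.append(0.5 * (lo + hi))
        medians.append(float(np.median(chosen)))
    if len(centers) < 1:
        raise AnalysisError("row not identifiable: empty row windows")
    medians = np.asarray(medians, dtype=float)
    if medians.size >= 3:
        from scipy.ndimage import median_filter

        medians = median_filter(medians, size=3, mode="nearest")
    if len(centers) == 1:
        centers = [x.min(), x.max()]
        medians = np.repeat(medians, 2)
    return RowCurve(centers=np.asarray(centers, dtype=float), medians=medians)


def classify_ihcs(centroids: np.ndarray, row_curve: RowCurve,
                  medial_side: str = "low_y",
                  tolerance_row: float = DEFAULT_ROW_TOLERANCE) -> HairCellSet:
    """Classify cells as aligned IHC, ectopic IHC or OHC relative to the row.

    Cells within ``tolerance_row`` of the row are aligned (boundary
    inclusive); cells displaced medially beyond the tolerance are ectopic;
    cells lateral of the row beyond the tolerance are OHCs.
    """
    centroids = np.asarray(centroids, dtype=float)
    x, y = centroids[:, 0], centroids[:, 1]
    sign = -1.0 if medial_side == "low_y" else 1.0
    medial_offset = sign * (y - row_curve(x))  # >0 means medial of the row
    classes = np.where(np.abs(medial_offset) <= tolerance_row, "aligned_IHC",
                       np.where(medial_offset > tolerance_row, "ectopic_IHC", "OHC"))
    return HairCellSet(centroids=centroids, classes=classes.astype(object),
                       row_curve=row_curve, medial_side=medial_side)


def bin_by_region(x_positions: np.ndarray, length: float,
                  origin_x: float = 0.0, base_side: str = "low_x") -> np.ndarray:
    """Assign base / mid / apex by longitudinal thirds of the measured length."""
    if length <= 0:
        raise ConfigurationError("length must be > 0")
    rel = np.asarray(x_positions, dtype=float) - origin_x
    if base_side == "high_x":
        rel = length - rel
    idx = np.clip((rel / (length / 3.0)).astype(int), 0, 2)
    return np.array([REGIONS[i] for i in idx], dtype=object)


def count_doublets(hcset: HairCellSet,
                   pairing_distance: float = DEFAULT_PAIRING_DISTANCE,
                   length: Optional[float] = None,
                   base_side: str = "low_x") -> Tuple[int, Dict[str, int]]:
    """Pair each ectopic IHC with its nearest aligned IHC within the pairing
    distance (greedy nearest-first; each aligned IHC partners at most once).

    Returns the total doublet count and per-region counts binned by thirds of
    the aligned-row length.
    """
    ect = hcset.indices("ectopic_IHC")
    ali = hcset.indices("aligned_IHC")
    by_region = {r: 0 for r in REGIONS}
    hcset.doublet_pairs = []
    if ect.size == 0 or ali.size == 0:
        return 0, by_region
    ex = hcset.centroids[ect, 0]
    ax = hcset.centroids[ali, 0]
    # all candidate pairs within the pairing distance, nearest first
    d = np.abs(ex[:, None] - ax[None, :])
    cand = np.argwhere(d <= pairing_distance)
    order = np.argsort(d[cand[:, 0], cand[:, 1]], kind="stable")
    used_e, used_a = set(), set()
    pairs = []
    for ei, ai in cand[order]:
        if ei in used_e or ai in used_a:
            continue
        used_e.add(int(ei))
        used_a.add(int(ai))
        pairs.append((int(ect[ei]), int(ali[ai])))
    hcset.doublet_pairs = pairs
    if length is None:
        length = float(ax.max() - ax.min())
    origin = float(ax.min())
    if pairs:
        px = np.array([hcset.centroids[e, 0] for e, _ in pairs])
        regions = bin_by_region(px, length, origin_x=origin, base_side=base_side)
        for r in regions:
            by_region[r] += 1
    return len(pairs), by_region


def measure_length(row_curve: RowCurve, x_start: float, x_end: float) -> float:
    """Arc length of the fitted row between the first and last aligned IHC."""
    return row_curve.arc_length(x_start, x_end)


def density_per_1000um(count: int, length: float) -> float:
    """Cells per 1000 um of cochlear length."""
    if length <= 0:
        raise ConfigurationError("length must be > 0")
    return 1000.0 * count / length


def measure_sox2_orthogonal(section: RadialSection,
                            min_threshold: Optional[float] = None,
                            **kwargs) -> domains.RegionMeasurement:
    """SOX2 area/intensity on an orthogonal optical section (delegates to the
    thresholded area/intensity measurement)."""
    return domains.measure_area_intensity(section, "SOX2",
                                          min_threshold=min_threshold, **kwargs)


def analyze_wholemount(image: WholemountImage,
                       pairing_distance: float = DEFAULT_PAIRING_DISTANCE,
                       tolerance_row: float = DEFAULT_ROW_TOLERANCE
                       ) -> Tuple[CochleaStats, HairCellSet]:
    """Full per-cochlea pipeline: detect -> fit row -> classify -> count."""
    centroids = detect_hair_cells(image)
    if centroids.shape[0] < 5:
        raise AnalysisError("row not identifiable: too few detections")
    row = fit_aligned_row(centroids, medial_side=image.medial_side)
    hcs = classify_ihcs(centroids, row, medial_side=image.medial_side,
                        tolerance_row=tolerance_row)
    ali = hcs.indices("aligned_IHC")
    ax = hcs.centroids[ali, 0]
    length = measure_length(row, float(ax.min()), float(ax.max()))
    total, by_region = count_doublets(hcs, pairing_distance=pairing_distance,
                                      length=length, base_side=image.base_side)
    n_aligned = int(ali.size)
    n_ect = int(hcs.indices("ectopic_IHC").size)
    stats = CochleaStats(
        length=length,
        aligned_ihc_count=n_aligned,
        ectopic_ihc_count=n_ect,
        total_doublets=total,
        doublets_by_region=by_region,
        aligned_per_1000um=density_per_1000um(n_aligned, length),
        total_per_1000um=density_per_1000um(n_aligned + n_ect, length),
    )
    return stats, hcs
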