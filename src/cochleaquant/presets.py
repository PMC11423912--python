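"""Generator presets describing cochlear cross-section and wholemount cohorts.

A :class:`LayoutPreset` encodes the radial organisation of the embryonic
cochlear duct floor: the four domains crossed when walking from the medial
luminal edge to the lateral luminal edge -- inner sulcus (IS), medial sensory
(MS), lateral sensory (LS) and outer sulcus (OS).  Marker intensity is modelled
as a per-domain plateau joined by sigmoidal transitions, so the half-maximum
crossing of a marker profile coincides with the true domain boundary.

Preset means carry the published cohort-level measurements (total radial
width, IS fraction of the medial compartment, marker width fractions,
per-region hair-cell doublet counts).  Between-section standard deviations
are calibrated from the published t-test p-values, which pin down the pooled
per-section spread at the published sample sizes (the printed +- values are
not internally consistent with those p-values; see docs/methods.md).

Channels
--------
``DAPI``   nuclear counterstain covering the whole epithelial band (tracing).
``JAG1``   medial-sensory marker; its rising edge is the IS-MS boundary.
``ECAD``   E-cadherin, lateral-sensory marker; rising edge = MS-LS boundary.
``SOX2``   prosensory marker (MS+LS); falling edge = LS-OS boundary.
``MYBL2``  inner-sulcus transcription factor (plateau in IS).
``PORCN``, ``KI67``, ``PRDM16``  medial bands occupying a stated fraction of
the total radial width from the medial edge.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Tuple

import yaml

from .errors import ConfigurationError

DOMAINS: Tuple[str, ...] = ("IS", "MS", "LS", "OS")

#: per-domain plateau levels (arbitrary units in [0, 1]) for the cross-section
#: markers; absolute levels are irrelevant downstream because profiles are
#: min-max normalized and area/intensity measurements are control-normalized.
DEFAULT_PLATEAUS: Dict[str, Dict[str, float]] = {
    "JAG1": {"IS": 0.05, "MS": 1.00, "LS": 0.05, "OS": 0.05},
    "ECAD": {"IS": 0.08, "MS": 0.08, "LS": 1.00, "OS": 0.10},
    "SOX2": {"IS": 0.05, "MS": 1.00, "LS": 1.00, "OS": 0.05},
    "MYBL2": {"IS": 1.00, "MS": 0.05, "LS": 0.05, "OS": 0.05},
}


@dataclass
class MedialBand:
    """A marker expressed in a band starting at the medial luminal edge.

    ``extent_mean`` is the fraction of the total radial width the band
    occupies; the band falls off laterally with the preset's boundary
    transition sigma.  Used for PORCN ("medial half"), Ki67 and PRDM16.
    """

    extent_mean: float
    extent_sd: float = 0.0
    level: float = 1.0
    baseline: float = 0.05


@dataclass
class LayoutPreset:
    """Statistical description of one cross-section cohort (stage x genotype)."""

    name: str
    total_width_mean: float  # um, medial to lateral luminal edge
    total_width_sd: float  # um, between-section s.d.
    medial_fraction: float = 0.55  # fraction of total width that is IS+MS
    medial_fraction_sd: float = 0.03
    is_fraction_of_medial: float = 0.71  # IS width / (IS+MS) width
    is_fraction_sd: float = 0.0
    ls_fraction_of_lateral: float = 0.50  # LS width / (LS+OS) width
    ls_fraction_sd: float = 0.05
    boundary_transition_sigma: float = 3.0  # um, sigmoid half-width
    channel_plateaus: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULT_PLATEAUS)
    )
    medial_bands: Dict[str, MedialBand] = field(default_factory=dict)
    channel_gains: Dict[str, float] = field(default_factory=dict)  # mean gain per channel
    channel_gain_cv: float = 0.0  # between-section lognormal gain CV (all markers)
    noise_sd_additive: float = 0.05  # a.u., on a max plateau of 1
    texture_cv: float = 0.15  # multiplicative lognormal cell texture
    epithelium_thickness: float = 40.0  # um
    pixel_size: float = 0.5  # um / pixel
    margin: float = 20.0  # um of background around the tissue
    arc_amplitude: float = 0.0  # um; >0 bends the duct floor into a gentle arc
    condition: str = "control"
    stage: str = "E14.5"

    def __post_init__(self) -> None:
        for name in ("total_width_mean", "boundary_transition_sigma",
                     "epithelium_thickness", "pixel_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{self.name}: {name} must be > 0")
        for name in ("medial_fraction", "is_fraction_of_medial",
                     "ls_fraction_of_lateral"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigurationError(f"{self.name}: {name} must lie in (0, 1)")
        for name in ("total_width_sd", "noise_sd_additive", "texture_cv",
                     "channel_gain_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{self.name}: {name} must be >= 0")
        for channel, plateaus in self.channel_plateaus.items():
            missing = [d for d in DOMAINS if d not in plateaus]
            if missing:
                raise ConfigurationError(
                    f"{self.name}: channel_plateaus[{channel}] missing domains {missing}"
                )
        for channel, band in self.medial_bands.items():
            if not 0.0 < band.extent_mean < 1.0:
                raise ConfigurationError(
                    f"{self.name}: medial_bands[{channel}].extent_mean must lie in (0, 1)"
                )

    @property
    def channels(self) -> Tuple[str, ...]:
        return ("DAPI",) + tuple(self.channel_plateaus) + tuple(self.medial_bands)


@dataclass
class WholemountPreset:
    """Statistical description of one E18.5 wholemount cohort."""

    name: str
    length_mean: float  # um, base-to-apex along the aligned IHC row
    length_sd: float = 150.0
    ihc_spacing: float = 8.0  # um between neighbouring aligned IHCs
    ohc_rows: int = 3
    ohc_spacing: float = 8.0  # um along the row
    ohc_row_offsets: Tuple[float, ...] = (20.0, 30.0, 40.0)  # um lateral of IHC row
    doublet_mean_by_region: Dict[str, float] = field(
        default_factory=lambda: {"base": 0.0, "mid": 0.0, "apex": 0.0}
    )
    ectopic_offset: float = 10.0  # um medial displacement of ectopic IHCs
    spot_sigma: float = 2.0  # um, Gaussian hair-cell spot s.d.
    sox2_band_gain: float = 1.0
    noise_sd: float = 0.05
    cell_jitter_sd: float = 0.5  # um positional jitter of planted cells
    amplitude_cv: float = 0.10  # per-cell brightness variation
    pixel_size: float = 1.0  # um / pixel
    margin: float = 30.0  # um of background around the planted rows
    row_curve_amplitude: float = 0.0  # um; >0 bends the IHC row sinusoidally
    condition: str = "control"
    stage: str = "E18.5"

    def __post_init__(self) -> None:
        if self.length_mean <= 0:
            raise ConfigurationError(f"{self.name}: length_mean must be > 0")
        for region, mean in self.doublet_mean_by_region.items():
            if mean < 0:
                raise ConfigurationError(
                    f"{self.name}: doublet_mean_by_region[{region}] must be >= 0"
                )
        if self.ohc_rows != len(self.ohc_row_offsets):
            raise ConfigurationError(
                f"{self.name}: ohc_rows must match len(ohc_row_offsets)"
            )
        for name in ("ihc_spacing", "spot_sigma", "pixel_size", "ectopic_offset"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{self.name}: {name} must be > 0")


def _sqrtn(sem: float, n: int) -> float:
    """Between-section s.d. implied by a published s.e.m. at sample size n."""
    return sem * n ** 0.5


def _e14_bands(ki67_extent: float, ki67_sd: float) -> Dict[str, MedialBand]:
    return {
        "PORCN": MedialBand(extent_mean=0.50, extent_sd=0.03),
        "KI67": MedialBand(extent_mean=ki67_extent, extent_sd=ki67_sd),
    }


def _e15_bands(ki67: float, ki67_sd: float, prdm16: float, prdm16_sd: float) -> Dict[str, MedialBand]:
    return {
        "PORCN": MedialBand(extent_mean=0.50, extent_sd=0.03),
        "KI67": MedialBand(extent_mean=ki67, extent_sd=ki67_sd),
        "PRDM16": MedialBand(extent_mean=prdm16, extent_sd=prdm16_sd),
    }


def _build_registry() -> Dict[str, object]:
    reg: Dict[str, object] = {}

    # --- E14.5 cross-sections: Isl1Cre beta-catenin cKO vs littermate control.
    reg["e14_control"] = LayoutPreset(
        name="e14_control",
        total_width_mean=192.2, total_width_sd=8.8,
        is_fraction_of_medial=0.71, is_fraction_sd=0.095,
        medial_bands=_e14_bands(0.40, 0.04),
        channel_gain_cv=0.25,
        condition="control", stage="E14.5",
    )
    reg["e14_bcat_cko"] = LayoutPreset(
        name="e14_bcat_cko",
        total_width_mean=177.9, total_width_sd=8.8,
        is_fraction_of_medial=0.52, is_fraction_sd=0.095,
        medial_bands=_e14_bands(0.40, 0.04),
        channel_gains={"KI67": 0.76},  # 24% lower Ki67 fluorescence
        channel_gain_cv=0.25,
        condition="bcat_cko", stage="E14.5",
    )

    # --- E15.5 cross-sections: Sox2CreER Mybl2 cKO vs control.
    # ls_fraction solved so the *measured* SOX2 area ratio cKO/control equals
    # the published +18% sensory-domain area change given MS 43% -> 62% of an
    # unchanged medial compartment.  The thresholded area of a plateau with
    # sigmoidal edges exceeds the true width by sigma * Phi^-1(0.842) ~ 3 um
    # per edge at the default 0.2-of-max threshold; the solve includes that
    # term (see docs/methods.md for the arithmetic).
    reg["e15_control"] = LayoutPreset(
        name="e15_control",
        total_width_mean=200.0, total_width_sd=12.0,
        is_fraction_of_medial=0.57, is_fraction_sd=0.080,
        ls_fraction_of_lateral=0.698, ls_fraction_sd=0.05,
        medial_bands=_e15_bands(0.45, 0.046, 0.50, 0.039),
        channel_gain_cv=0.08,
        condition="control", stage="E15.5",
    )
    reg["e15_mybl2_cko"] = LayoutPreset(
        name="e15_mybl2_cko",
        total_width_mean=200.0, total_width_sd=12.0,
        is_fraction_of_medial=0.38, is_fraction_sd=0.080,
        ls_fraction_of_lateral=0.698, ls_fraction_sd=0.05,
        medial_bands=_e15_bands(0.40, 0.046, 0.40, 0.039),
        # Ki67 plateau gain calibrated so gain x (40/45 width shrink) gives the
        # published -22% change in *total* Ki67 fluorescence.
        channel_gains={"KI67": 0.78 * 0.45 / 0.40},
        channel_gain_cv=0.08,
        condition="mybl2_cko", stage="E15.5",
    )

    # --- E12.5-style Emx2Cre beta-catenin cKO: only total JAG1 fluorescence is
    # quantified, so the pair reuses the E14.5 layout with a JAG1 gain of 0.29
    # in the cKO (-71% total fluorescence).
    reg["emx2_control"] = LayoutPreset(
        name="emx2_control",
        total_width_mean=160.0, total_width_sd=12.0,
        is_fraction_of_medial=0.5, is_fraction_sd=0.05,
        channel_gain_cv=0.04,
        condition="control", stage="E12.5",
    )
    reg["emx2_bcat_cko"] = LayoutPreset(
        name="emx2_bcat_cko",
        total_width_mean=160.0, total_width_sd=12.0,
        is_fraction_of_medial=0.5, is_fraction_sd=0.05,
        channel_gains={"JAG1": 0.29},
        channel_gain_cv=0.04,
        condition="bcat_cko", stage="E12.5",
    )

    # --- E18.5 orthogonal optical sections for SOX2 area/intensity by region.
    # Layout fractions solved so the cKO/control *measured* SOX2 area ratio
    # (including the ~3 um/edge threshold-tail term) equals the published
    # area change (+47% base, +33% mid, +20% apex); the SOX2 channel gain
    # supplies the remainder of the intensity change.
    def ortho(name, is_frac, ls_frac, sox2_gain, condition, region):
        return LayoutPreset(
            name=name,
            total_width_mean=150.0, total_width_sd=10.0,
            is_fraction_of_medial=is_frac, is_fraction_sd=0.08,
            ls_fraction_of_lateral=ls_frac, ls_fraction_sd=0.05,
            channel_plateaus={"SOX2": dict(DEFAULT_PLATEAUS["SOX2"]),
                              "JAG1": dict(DEFAULT_PLATEAUS["JAG1"]),
                              "ECAD": dict(DEFAULT_PLATEAUS["ECAD"])},
            channel_gains={} if sox2_gain == 1.0 else {"SOX2": sox2_gain},
            channel_gain_cv=0.15,
            condition=condition, stage=f"E18.5-{region}",
        )

    reg["e18_base_control"] = ortho("e18_base_control", 0.600, 0.400, 1.0, "control", "base")
    reg["e18_base_cko"] = ortho("e18_base_cko", 0.3876, 0.600, 1.59 / 1.47, "mybl2_cko", "base")
    reg["e18_mid_control"] = ortho("e18_mid_control", 0.620, 0.380, 1.0, "control", "mid")
    reg["e18_mid_cko"] = ortho("e18_mid_cko", 0.5071, 0.550, 1.43 / 1.33, "mybl2_cko", "mid")
    reg["e18_apex_control"] = ortho("e18_apex_control", 0.640, 0.360, 1.0, "control", "apex")
    reg["e18_apex_cko"] = ortho("e18_apex_cko", 0.5682, 0.450, 1.23 / 1.20, "mybl2_cko", "apex")

    # --- E18.5 wholemount cohorts (hair-cell counting).  Per-region doublet
    # means follow the published base/mid/apex counts; cKO cochleas are 15%
    # shorter than 'no Cre' controls and 8% shorter than Sox2CreER(+/-) ones.
    reg["e18_nocre"] = WholemountPreset(
        name="e18_nocre", length_mean=6000.0,
        doublet_mean_by_region={"base": 1.3, "mid": 3.1, "apex": 6.1},
        condition="no_cre",
    )
    reg["e18_sox2cre_het"] = WholemountPreset(
        name="e18_sox2cre_het", length_mean=5543.0,
        doublet_mean_by_region={"base": 11.5, "mid": 20.33, "apex": 15.4},
        condition="sox2cre_het",
    )
    reg["e18_mybl2_cko"] = WholemountPreset(
        name="e18_mybl2_cko", length_mean=5100.0,
        doublet_mean_by_region={"base": 8.2, "mid": 24.83, "apex": 47.8},
        sox2_band_gain=1.2,
        condition="mybl2_cko",
    )
    return reg


_REGISTRY = _build_registry()

PRESET_NAMES = tuple(sorted(_REGISTRY))


def get_preset(name: str):
    """Return a deep copy of a named preset (LayoutPreset or WholemountPreset)."""
    try:
        return copy.deepcopy(_REGISTRY[name])
    except KeyError:
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        ) from None


def preset_to_yaml(preset, path) -> None:
    """Serialise a preset to YAML."""
    d = dataclasses.asdict(preset)
    d["__type__"] = type(preset).__name__
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def preset_from_yaml(path):
    """Load a preset written by :func:`preset_to_yaml`."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    kind = d.pop("__type__", "LayoutPreset")
    if kind == "WholemountPreset":
        if "ohc_row_offsets" in d:
            d["ohc_row_offsets"] = tuple(d["ohc_row_offsets"])
        return WholemountPreset(**d)
    if "medial_bands" in d:
        d["medial_bands"] = {k: MedialBand(**v) for k, v in d["medial_bands"].items()}
    return LayoutPreset(**d)
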