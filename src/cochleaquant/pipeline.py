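"""End-to-end orchestration: simulate -> profile -> quantify -> statistics.

The cohort helpers here are the units the acceptance analysis is built from:
each generates a seeded synthetic cohort, runs the full measurement pipeline
on every image (never consulting the ground truth) and returns a tidy table
of per-section or per-cochlea measurements.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import domains, profiles, stats, wholemount
from .errors import AnalysisError, ConfigurationError
from .io import RunConfig
from .presets import LayoutPreset, WholemountPreset, get_preset
from .synthetic import RadialSection, derive_child_seed, make_cohort, make_wholemount_cohort

logger = logging.getLogger("cochleaquant")

BOUNDARY_CHANNELS = ("JAG1", "ECAD", "SOX2")


def analyze_section(section: RadialSection,
                    threshold_frac: float = domains.DEFAULT_THRESHOLD_FRAC,
                    smoothing_window: int = domains.DEFAULT_SMOOTHING_WINDOW,
                    band_halfwidth: float = profiles.DEFAULT_BAND_HALFWIDTH,
                    area_channels: Sequence[str] = (),
                    width_fraction_channels: Sequence[str] = ()) -> Dict[str, float]:
    """Measure one section: boundaries, widths, band fractions, areas.

    Returns a flat row of measurements; ground truth is never consulted.
    """
    path = profiles.trace_duct_floor(section)
    profs = {
        ch: profiles.extract_profile(section, path, ch, band_halfwidth)
        for ch in BOUNDARY_CHANNELS if ch in section.channels
    }
    row: Dict[str, float] = {
        "condition": section.condition,
        "stage": section.stage,
        "total_width": path.total_length,
    }
    if all(ch in profs for ch in BOUNDARY_CHANNELS):
        bounds = domains.detect_boundaries(profs, threshold_frac=threshold_frac,
                                           smoothing_window=smoothing_window)
        w = domains.compute_widths(bounds)
        row.update({
            "is_um": w.is_, "ms_um": w.ms, "ls_um": w.ls, "os_um": w.os,
            "medial_um": w.medial_compartment, "lateral_um": w.lateral_compartment,
            "is_frac_pct": 100 * w.is_frac, "ms_frac_pct": 100 * w.ms_frac,
            "ls_frac_pct": 100 * w.ls_frac, "os_frac_pct": 100 * w.os_frac,
        })
    for ch in width_fraction_channels:
        if ch in section.channels:
            prof = profiles.extract_profile(section, path, ch, band_halfwidth)
            row[f"{ch.lower()}_width_frac_pct"] = 100 * domains.marker_width_fraction(
                prof, threshold_frac=threshold_frac, smoothing_window=smoothing_window)
    for ch in area_channels:
        if ch in section.channels:
            m = domains.measure_area_intensity(section, ch)
            row[f"{ch.lower()}_area_um2"] = m.area
            row[f"{ch.lower()}_intensity"] = m.total_intensity
    return row


def analyze_section_cohort(preset: Union[str, LayoutPreset], n: int, seed: int,
                           area_channels: Sequence[str] = ("SOX2", "KI67", "JAG1"),
                           width_fraction_channels: Sequence[str] = ("KI67",),
                           **kwargs) -> pd.DataFrame:
    """Generate a seeded cohort and measure every section.

    Per-section measurement errors are logged and skipped so one degenerate
    section does not void a cohort.
    """
    if isinstance(preset, str):
        preset = get_preset(preset)
    rows = []
    for i, (section, _gt) in enumerate(make_cohort(preset, n, seed)):
        try:
            row = analyze_section(section, area_channels=area_channels,
                                  width_fraction_channels=width_fraction_channels,
                                  **kwargs)
        except AnalysisError as exc:
            logger.warning("section %d of %s skipped: %s", i, preset.name, exc)
            continue
        row["section_id"] = f"{preset.name}_{seed}_{i}"
        rows.append(row)
    return pd.DataFrame(rows)


def analyze_wholemount_cohort(preset: Union[str, WholemountPreset], n: int, seed: int,
                              pairing_distance: float = wholemount.DEFAULT_PAIRING_DISTANCE
                              ) -> pd.DataFrame:
    """Generate a seeded wholemount cohort and run the counting pipeline."""
    if isinstance(preset, str):
        preset = get_preset(preset)
    rows = []
    for i, (image, _gt) in enumerate(make_wholemount_cohort(preset, n, seed)):
        try:
            cstats, _ = wholemount.analyze_wholemount(image, pairing_distance=pairing_distance)
        except AnalysisError as exc:
            logger.warning("wholemount %d of %s skipped: %s", i, preset.name, exc)
            continue
        row = {
            "condition": image.condition,
            "cochlea_id": f"{preset.name}_{seed}_{i}",
            "length_um": cstats.length,
            "aligned_ihc_count": cstats.aligned_ihc_count,
            "ectopic_ihc_count": cstats.ectopic_ihc_count,
            "total_doublets": cstats.total_doublets,
            "aligned_per_1000um": cstats.aligned_per_1000um,
            "total_per_1000um": cstats.total_per_1000um,
        }
        for region, count in cstats.doublets_by_region.items():
            row[f"doublets_{region}"] = count
        rows.append(row)
    return pd.DataFrame(rows)


def percent_change(treated: Sequence[float], control: Sequence[float]) -> domains.NormalizedChange:
    """Control-mean normalization of a treated cohort (positive = increase)."""
    return domains.normalize_to_control(treated, control)


WIDTH_MEASUREMENTS = ("total_width", "medial_um", "lateral_um",
                      "is_frac_pct", "ms_frac_pct", "ls_frac_pct", "os_frac_pct")


def width_family_design(control: str, cko: str, family: str) -> Dict[str, List[dict]]:
    """The seven-panel width comparison family (Bonferroni m = 7)."""
    return {family: [
        {"measurement": m, "groups": [control, cko], "test": "t"}
        for m in WIDTH_MEASUREMENTS
    ]}


def run_pipeline(config: Optional[RunConfig] = None,
                 outdir: Optional[str] = None) -> Dict[str, object]:
    """Execute every experiment family in the config and write the report.

    Writes per-cohort CSV tables, a JSON report of the headline quantities,
    a copy of the config and a log; re-running with the same config and seed
    reproduces every number exactly.
    """
    config = config or RunConfig()
    config.validate()
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_json = json.dumps(asdict(config), sort_keys=True)
    cfg_hash = hashlib.sha256(cfg_json.encode()).hexdigest()[:12]
    kwargs = dict(threshold_frac=config.threshold_frac,
                  smoothing_window=config.smoothing_window,
                  band_halfwidth=config.band_halfwidth)

    report: Dict[str, object] = {"config_hash": cfg_hash, "seed": config.seed}
    tables: Dict[str, pd.DataFrame] = {}

    def cohort_seed(s: int) -> int:
        return derive_child_seed(config.seed, s)

    co = config.cohorts
    # E14.5 and E15.5 section geometry
    for fam in ("e14", "e15"):
        if fam not in co:
            continue
        spec = co[fam]
        s_ctrl, s_cko = spec["seeds"]
        ctrl = analyze_section_cohort(spec["control"][0], int(spec["control"][1]),
                                      cohort_seed(s_ctrl), **kwargs)
        cko = analyze_section_cohort(spec["cko"][0], int(spec["cko"][1]),
                                     cohort_seed(s_cko), **kwargs)
        table = pd.concat([ctrl, cko], ignore_index=True)
        tables[f"{fam}_widths"] = table
        design = width_family_design(ctrl["condition"].iloc[0],
                                     cko["condition"].iloc[0], f"{fam}_widths")
        tables[f"{fam}_stats"] = stats.compare_conditions(table, design)
        report[f"{fam}_mean_is_frac_pct_control"] = float(ctrl["is_frac_pct"].mean())
        report[f"{fam}_mean_is_frac_pct_cko"] = float(cko["is_frac_pct"].mean())
        report[f"{fam}_mean_total_width_control"] = float(ctrl["total_width"].mean())
        report[f"{fam}_mean_total_width_cko"] = float(cko["total_width"].mean())
        if fam == "e15":
            ch = percent_change(cko["sox2_area_um2"], ctrl["sox2_area_um2"])
            report["e15_sox2_area_pct_change"] = ch.percent_change

    if "e15_ki67" in co:
        spec = co["e15_ki67"]
        s_ctrl, s_cko = spec["seeds"]
        ctrl = analyze_section_cohort(spec["control"][0], int(spec["control"][1]),
                                      cohort_seed(s_ctrl), **kwargs)
        cko = analyze_section_cohort(spec["cko"][0], int(spec["cko"][1]),
                                     cohort_seed(s_cko), **kwargs)
        ch = percent_change(cko["ki67_intensity"], ctrl["ki67_intensity"])
        report["e15_ki67_fluorescence_pct_change"] = ch.percent_change
        tables["e15_ki67"] = pd.concat([ctrl, cko], ignore_index=True)

    if "emx2" in co:
        spec = co["emx2"]
        s_ctrl, s_cko = spec["seeds"]
        ctrl = analyze_section_cohort(spec["control"][0], int(spec["control"][1]),
                                      cohort_seed(s_ctrl), **kwargs)
        cko = analyze_section_cohort(spec["cko"][0], int(spec["cko"][1]),
                                     cohort_seed(s_cko) + 1, **kwargs)
        ch = percent_change(cko["jag1_intensity"], ctrl["jag1_intensity"])
        report["e12_jag1_fluorescence_pct_change"] = ch.percent_change
        tables["emx2_jag1"] = pd.concat([ctrl, cko], ignore_index=True)

    if "e18_wholemount" in co:
        spec = co["e18_wholemount"]
        seeds = spec["seeds"]
        groups = {}
        for gi, ((key, val), s) in enumerate(zip(
                ((k, v) for k, v in spec.items() if k != "seeds"), seeds)):
            groups[key] = analyze_wholemount_cohort(
                val[0], int(val[1]), cohort_seed(s) + gi,
                pairing_distance=config.pairing_distance)
        table = pd.concat(groups.values(), ignore_index=True)
        tables["e18_wholemounts"] = table
        conditions = [g["condition"].iloc[0] for g in groups.values()]
        if len(groups) >= 3:
            design = {"e18_doublets": [
                {"measurement": "total_doublets", "groups": conditions,
                 "test": "anova_tukey"}]}
            tables["e18_stats"] = stats.compare_conditions(table, design)
        for key, g in groups.items():
            report[f"e18_mean_total_doublets_{key}"] = float(g["total_doublets"].mean())
            report[f"e18_mean_length_{key}"] = float(g["length_um"].mean())

    if "e18_ortho_base" in co:
        spec = co["e18_ortho_base"]
        s_ctrl, s_cko = spec["seeds"]
        ctrl = analyze_section_cohort(spec["control"][0], int(spec["control"][1]),
                                      cohort_seed(s_ctrl), area_channels=("SOX2",),
                                      width_fraction_channels=(), **kwargs)
        cko = analyze_section_cohort(spec["cko"][0], int(spec["cko"][1]),
                                     cohort_seed(s_cko) + 1, area_channels=("SOX2",),
                                     width_fraction_channels=(), **kwargs)
        ch = percent_change(cko["sox2_area_um2"], ctrl["sox2_area_um2"])
        report["e18_base_sox2_area_pct_change"] = ch.percent_change
        tables["e18_ortho_base"] = pd.concat([ctrl, cko], ignore_index=True)

    for name, table in tables.items():
        table.to_csv(out / f"{name}.csv", index=False)
    config.to_yaml(out / "config.yaml")
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s (config %s)", out, cfg_hash)
    return report
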