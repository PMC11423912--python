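# cochleaquant

Quantitative spatial analysis of the developing mouse cochlear epithelium.

During embryonic development the floor of the cochlear duct is partitioned,
from medial to lateral, into four radial domains: the inner sulcus (IS,
Kölliker's organ), the medial sensory (MS) and lateral sensory (LS) halves of
the prosensory domain, and the outer sulcus (OS).  Where the IS-MS boundary
falls — and how conditional knockouts of β-catenin or *Mybl2* move it —
determines the size of the future sensory epithelium.  This package
implements the measurement pipeline such studies rely on, as tested, reusable
code for developmental biologists and image analysts:

- **Synthetic cochlear images with known ground truth.**  Multi-channel
  cross-sections (DAPI, JAG1, E-cadherin, SOX2, MYBL2, PORCN, Ki67, PRDM16)
  whose markers follow plateau-per-domain intensity profiles with sigmoidal
  boundary transitions, and E18.5-style wholemounts with one aligned row of
  inner hair cells (IHCs), three rows of outer hair cells and planted ectopic
  IHC doublets.  Presets encode published cohort statistics, so every
  downstream stage is testable without any image download.
- **Spatial profiles.**  The duct floor is traced from DAPI (Otsu threshold →
  largest component → smoothed per-column centroid) and each channel is
  sampled along its arc length, averaged over a ±5 µm perpendicular band, and
  min-max normalized: intensity *v(s) ∈ [0, 1]* versus normalized
  medial→lateral position *s ∈ [0, 1]*.
- **Boundary calling and domain widths.**  Boundaries are half-maximum
  crossings of normalized profiles: IS-MS at the rising JAG1 edge, MS-LS at
  the rising E-cadherin edge, LS-OS at the falling SOX2 edge.  Widths are
  reported with the field's compartment normalizations, IS/(IS+MS),
  LS/(LS+OS), plus marker band widths (Ki67, PRDM16) as fractions of the
  total radial width, and thresholded marker area/total intensity normalized
  to the control cohort mean.
- **Wholemount hair-cell counting.**  Laplacian-of-Gaussian spot detection,
  robust running-median fit of the aligned IHC row, classification of
  medially displaced ectopic IHCs, greedy nearest-neighbour doublet pairing
  within 12 µm, base/mid/apex binning by thirds of the measured cochlear
  length, and densities per 1000 µm.
- **Statistics.**  Independent two-tailed Student's *t*-tests with Bonferroni
  correction per comparison family, one-way ANOVA with post-hoc Tukey HSD for
  three-group comparisons, and type-7 box-plot summaries.

## Worked example

```python
import cochleaquant as cq

# one synthetic E14.5 control cross-section, then the full measurement chain
section, truth = cq.make_section(cq.get_preset("e14_control"), seed=0)
path = cq.trace_duct_floor(section)
profiles = {ch: cq.extract_profile(section, path, ch)
            for ch in ("JAG1", "ECAD", "SOX2")}
bounds = cq.detect_boundaries(profiles, threshold_frac=0.5)
widths = cq.compute_widths(bounds)
print(f"total width     : {widths.total:6.1f} um (truth {truth.total_width:.1f})")
print(f"IS-MS boundary  : {bounds.is_ms:6.1f} um (truth {truth.boundary_positions['IS_MS']:.1f})")
print(f"IS % of medial  : {100*widths.is_frac:6.1f} %")

# cohorts at published sample sizes: 15 control vs 19 beta-catenin-cKO sections
ctrl = cq.analyze_section_cohort("e14_control", 15, seed=1)
cko  = cq.analyze_section_cohort("e14_bcat_cko", 19, seed=2)
comp = cq.students_t_test(ctrl["is_frac_pct"], cko["is_frac_pct"],
                          labels=("control", "bcat_cko"))
print(f"cohort IS%      : {comp.means[0]:.1f} vs {comp.means[1]:.1f}  "
      f"(t={comp.statistic:.2f}, p={comp.p_raw:.2e})")
```

prints

```
total width     :  193.0 um (truth 193.3)
IS-MS boundary  :   81.3 um (truth 81.4)
IS % of medial  :   77.0 %
cohort IS%      : 71.4 vs 55.3  (t=4.51, p=8.13e-05)
```

The single-section numbers show the measurement chain recovering this
section's own geometry (boundaries to well under a micrometre); the cohort
line shows the biological contrast the presets encode — the inner sulcus
occupies ~71% of the medial compartment in controls and shrinks in the
knockout, a highly significant difference at these sample sizes.

A command-line interface mirrors the library:

```bash
cochleaquant simulate --preset e14_control --n 15 --seed 1 --outdir sim/
cochleaquant profile sim/*.tif --out profiles.csv
cochleaquant quantify-domains sim/*.tif --out domains.csv
cochleaquant all --seed 0 --outdir run/     # every experiment family + report
```

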