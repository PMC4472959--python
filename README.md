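# gliaquant

Quantification tools for CB2-receptor neuroinflammation imaging: multi-channel
immunofluorescence analysis around amyloid-β plaques, and small-animal PET
time-activity-curve / SUV analysis — with a synthetic-phantom module that
plants known ground truth so every estimator in the chain can be validated
end-to-end.

## Who this is for

Labs quantifying glial activation in amyloid-bearing mouse models (and
similar neuroinflammation settings) from confocal/epifluorescence images of
marker co-stainings (DAPI, CB2, CD68, NeuN, GFAP), and from dynamic PET of a
CB2-targeted radiotracer. The package re-implements, as tested and scriptable
code, the measurement chain usually assembled by hand in Fiji/PMOD:

- **preprocess** — rolling-ball background subtraction; percent-of-max
  normalization.
- **masks** — IsoData (iterative intermeans) marker thresholds;
  "upper third of the intensity distribution" voxel surfaces;
  autofluorescent-granule exclusion masks from the DAPI channel;
  marker/background partitions (priority CD68 > GFAP > NeuN).
- **density** — integrated intensity per unit area of a measured channel
  (typically CB2) in marker-positive/negative/background regions, with
  granule-excluded areas, and genotype × marker group tables (mean ± SEM
  over images).
- **profiles** — radial profiles around plaque centers with plaque-core
  radius estimation (first rise above min + 20 % of range of the smoothed
  CB2 trace); box plot-profiles averaged along the short axis; per-channel
  peak positions, pairwise offsets in μm, and DAPI < CB2 < CD68 ordering
  along the core-outward axis.
- **fluorodiscrim** — error rates of separating neurons from astroglia when
  NeuN and mouse-GFAP share one fluorochrome, using an independent
  rabbit-GFAP stain as the reference (Gaussian blur → IsoData → overlap
  arithmetic).
- **pet** — frame schedules (`"20x3,30x2,60x2,120x3,300x4"` or
  `"20 sec x 3, …"`), SUV = (tissue concentration / injected dose) × body
  weight, duration-weighted windowed means, peak/at-time values,
  baseline-vs-blockade fold reduction.
- **stats** — one-way ANOVA, two-way mixed ANOVA (genotype between-subject,
  cell marker repeated), Fisher's LSD post-hoc.
- **synthetic** — phantom generators: confocal fields with DAPI-dense plaque
  cores, CD68⁺ microglia whose processes end in plates at the core, a CB2
  halo between plate and core, a CB2 membrane ring offset ~1.5 μm outward of
  the CD68 cytoplasm, NeuN⁺ neurons with cytoplasmic CB2 and cross-channel
  autofluorescent granules, GFAP⁺ astrocytes; shared-fluorochrome fields
  with planted overlap fractions; bolus-injection TACs sampled on the
  30-min dynamic frame schedule.

## Worked example

```python
import numpy as np
from gliaquant import pet
from gliaquant.profiles import ProfileBox, box_profile, peak_report
from gliaquant.synthetic import (ad_baseline, blockade_pair,
                                 engulfment_default, generate_if_phantom,
                                 generate_tac)
from gliaquant.synthetic.presets import default_schedule

sched = default_schedule()                       # 14 frames, 30 min
tac = generate_tac(ad_baseline(), sched, seed=1)[0]
peak, interval = pet.peak_suv(tac)
print(f"peak SUV          : {peak:.2f}  (frame {interval[0]:.0f}-{interval[1]:.0f} s)")
print(f"SUV at 10 min     : {pet.value_at(tac, 10.0):.2f}")

spec = blockade_pair()
base = generate_tac(spec, sched, 1, condition="baseline")[0]
blk = generate_tac(spec, sched, 2, condition="blockade")[0]
b, k, fold = pet.blockade_comparison(base, blk)
print(f"2-10 min mean SUV : baseline {b:.2f}, blockade {k:.2f}  ({fold:.2f}-fold reduction)")

stack, gt = generate_if_phantom(engulfment_default(), seed=1)
box = ProfileBox(gt.plaque_centers_px[0], gt.microglia_body_centers_px[0], width_px=16)
rep = peak_report(box_profile(stack, box, channels=["DAPI", "CB2", "CD68"]))
print(f"CB2-CD68 peak offset: {abs(rep.offset('CB2', 'CD68')):.2f} um "
      f"(DAPI < CB2 < CD68 outward: {rep.ordering_dapi_cb2_cd68})")
```

prints

```
peak SUV          : 2.29  (frame 40-60 s)
SUV at 10 min     : 0.67
2-10 min mean SUV : baseline 1.80, blockade 0.65  (2.77-fold reduction)
CB2-CD68 peak offset: 1.53 um (DAPI < CB2 < CD68 outward: True)
```

The whole-brain tracer bolus peaks at ~2.3 SUV in the 40–60 s frame and
washes out to ~0.67 SUV by 10 min; pre-blocking the receptor cuts the
2–10 min uptake ~2.8-fold, demonstrating binding specificity. On the image
side, the CB2 intensity peak at a microglial engulfment synapse sits ~1.5 μm
from the CD68 peak, between the CD68 plate and the DAPI-dense plaque core —
the membrane-localization signature the profile analysis is built to detect.

A command-line interface mirrors the library
(`gliaquant simulate|quantify|profile|s3|pet|stats`, each with `--seed`,
`--out` and YAML `--config`).

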