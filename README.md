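# neuroquant

Quantification of mTOR recruitment to LAMP1-positive late endosomes and of
P-pS6 (mTORC1 activity) in multi-channel fluorescence micrographs of
cultured neurons — together with a synthetic neuron-image generator that
provides full ground truth, so every stage of the analysis can be validated
without any microscope data.

## Who this is for

Neuronal mTORC1 signalling studies commonly read out two image-based
quantities:

1. **Recruitment of mTOR to late endosomes (LEs)** in dendrites, measured
   as an object-based enrichment ratio: mean mTOR fluorescence inside
   segmented LAMP1-positive objects (**IN**) divided by the mean in
   ring-shaped regions of nearby cytoplasm (**OUT**),

   `ratio = mean(mTOR | IN) / mean(mTOR | OUT)`,

   with the OUT ring defined as all pixels whose Euclidean distance *d* to
   the nearest object satisfies `gap < d <= gap + width` (defaults: 6-px
   gap, 4-px width), both masks restricted to a MAP2-derived dendrite
   mask.  A ratio of 1 means no recruitment.
2. **Compartmentalised P-pS6 immunofluorescence** as an mTORC1 activity
   proxy: whole-neuron, somatic and dendritic mean intensities (the soma
   and dendrite masks partition the MAP2 mask), per-soma intensity
   distributions with a percentile-shift analysis (fraction of treated
   somata brighter than the control distribution's 75th percentile),
   intensity profiles along dendrites, and detection of discrete activity
   hot spots.

Standard pre-processing (rolling-ball background subtraction, mean/isodata
auto-thresholding, puncta segmentation with a strict size floor) and the
group-comparison statistics used for such readouts (Welch t / Mann-Whitney;
ANOVA + Tukey / Kruskal-Wallis + Dunn, chosen by normality and variance
checks) are built in.

## Worked example

Simulate two conditions with known ground-truth enrichment, run the full
recruitment measurement, and compare the groups:

```python
import numpy as np
from neuroquant import (GeometryParams, PhotophysicsParams, make_geometry,
                        render, rolling_ball_subtract, segment_les,
                        auto_threshold, build_in_out, in_out_ratio,
                        compare_two)

ratios = {}
for condition, enrichment in {"control": 1.33, "glycine": 2.18}.items():
    ratios[condition] = []
    for seed in range(5):
        truth = make_geometry(GeometryParams(image_shape=(256, 256),
                                             n_neurons=3, seed=seed))
        phys = PhotophysicsParams(mtor_enrichment=enrichment,
                                  poisson_noise=True, seed=seed + 1)
        image = render(truth, phys)
        mtor = rolling_ball_subtract(image["mTOR"], ball_diameter=75)
        les = segment_les(image["LAMP1"], min_area=25)
        dendrites = auto_threshold(image["MAP2"], method="mean")
        masks = build_in_out(les, dendrites, gap=6, width=4)
        ratios[condition].append(in_out_ratio(mtor, masks).ratio)
    vals = np.array(ratios[condition])
    print(f"{condition}: IN/OUT = {vals.mean():.2f} "
          f"+/- {vals.std(ddof=1)/np.sqrt(len(vals)):.2f} SEM (n={len(vals)})")

print(compare_two(ratios["control"], ratios["glycine"],
                  names=("control", "glycine")).summary())
```

prints

```
control: IN/OUT = 1.32 +/- 0.00 SEM (n=5)
glycine: IN/OUT = 2.11 +/- 0.01 SEM (n=5)
test: welch-t
statistic = -70.3008, p = 9.902e-10 [***]
  control: n=5, mean=1.31885 +/- 0.00492 SEM, normal=True (p=0.845)
  glycine: n=5, mean=2.1072 +/- 0.0101 SEM, normal=True (p=0.11)
```

The per-image ratios recover the generator's enrichment settings (1.33 and
2.18) to within a few percent under Poisson noise — the residual downward
bias at high enrichment comes from the noise floor of min/max morphology in
the rolling-ball background estimate and is characterised in
`docs/methods.md` — and the two conditions separate decisively.

## Command line

The same pipelines are available as subcommands operating on TIFF inputs
and a manifest CSV:

```sh
neuroquant simulate -o fixtures -n 4 --condition control=1.33 --condition glycine=2.18 --seed 1
neuroquant recruitment -m fixtures/manifest.csv -o results
neuroquant activity    -m fixtures/manifest.csv -o results
neuroquant profiles    -m fixtures/manifest.csv -o results
neuroquant stats -i tidy.csv -o results
```

Every output CSV starts with a comment header (tool version, configuration
hash, seed); re-running an analysis on unchanged inputs reproduces the
files byte for byte.

## Layout

- `neuroquant.simulate` — synthetic field generator and ground truth
- `neuroquant.imgproc` — rolling-ball subtraction, auto-thresholds, masks
- `neuroquant.puncta` — LE segmentation, size filter, IN/ring-OUT geometry
- `neuroquant.recruitment` — IN/OUT ratio, clustering index
- `neuroquant.activity` — compartment means, per-soma tables, percentile shift
- `neuroquant.profiles` — dendrite line profiles, hot-spot detection
- `neuroquant.stats` — test-selection tree, exact Mann-Whitney, post-hocs
- `neuroquant.pipeline` / `neuroquant.cli` — manifests, CSV outputs, CLI

See `docs/methods.md` for the underlying models, parameter defaults and
known limitations.
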