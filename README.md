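# tilt3d

An image-computable, normative analysis of local 3D surface-tilt estimation
from stereo images. The package generates synthetic stereo scenes with
pixel-registered range maps, computes groundtruth surface orientation from
the range data, measures three local image cues (luminance, disparity and
texture orientation gradients), trains a nonparametric MMSE tilt estimator
(the 64³ "estimate cube") on (cue, tilt) samples, and reproduces a
psychophysics-style evaluation: circular summary statistics per tilt bin,
conditional error/truth distributions, bias-corrected trial-by-trial
circular correlations with bootstrap CIs, covariate effects
(slant/distance/tilt variance) and Monte Carlo experiment repeats.

Because the natural-scene stereo database such analyses are built on is
proprietary, the `stereo_synth` module emulates it: textured planes (1/f
noise, 3.5 and 5.25 cpd plaids) at configurable tilt/slant/distance, with
depth-covarying shading, optional smooth height perturbations ("bumpy"
surfaces with controllable local tilt variance), a cardinal-heavy tilt
prior, and a synthetic observer (axial von-Mises noise + lapses) standing in
for human responses.

## Modules

| module | role |
|---|---|
| `tilt3d.stereo_synth` | scene rendering, stimulus sampling, synthetic observer |
| `tilt3d.surface_truth` | groundtruth tilt/slant/tilt-variance from range maps |
| `tilt3d.image_cues` | luminance/disparity/texture cues, local contrast |
| `tilt3d.tilt_estimator` | estimate cube: build, lookup, holdout |
| `tilt3d.circstats` | axial circular statistics, Fisher–Lee correlation, bootstrap |
| `tilt3d.eval_pipeline` | summary statistics, conditional distributions, analyses |
| `tilt3d.io_cli` | TIFF/CSV/cube formats, run configuration, CLI |

Angles are degrees throughout; unsigned tilt lives on [0, 180) and all
statistics treat it as axial (doubled-angle) data. File formats are
documented in `SCHEMA.md`.

## CLI

```sh
tilt3d synth --config cfg.yaml --n-per-bin 150 --bins 24 --seed 1 --out patches/
tilt3d truth --patches patches/ --out manifest.csv
tilt3d cues  --patches patches/ --manifest manifest.csv --out manifest.csv
tilt3d train --config cfg.yaml --bins 64 --min-count 10 --out cube.bin
tilt3d estimate --cube cube.bin --manifest manifest.csv --out trials.csv
tilt3d evaluate --trials trials.csv --seed 1 --out evaluation/
tilt3d run --config cfg.yaml --seed 1 --out run_out/   # all stages
```

`RunConfig` round-trips through a single YAML file; every stage derives its
randomness from the global seed via named substreams, and reruns with the
same config produce byte-identical outputs.

Minimal Python example:

```python
import numpy as np
from tilt3d import stereo_synth, tilt_estimator

tilts = stereo_synth.sample_tilt_prior(200_000, seed=0)          # cardinal-heavy prior
cues = stereo_synth.simulate_natural_cue_samples(tilts, seed=1)  # noisy cue triplets
cube = tilt_estimator.build_cube((cues, tilts), bins_per_cue=64)
estimate = tilt_estimator.estimate_tilt(cube, np.array([30.0, 35.0, 28.0]))
```

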