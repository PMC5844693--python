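# File formats and column schemas

All CSV files: comma-separated, UTF-8, header row, `.` decimal point.
All angles are stored in degrees.

## Patch files

Multi-page 32-bit float TIFF, pages in order: `left`, `right`, `range`,
`occlusion` (0/1). A JSON sidecar (same stem, `.json`) stores the scene spec,
the viewing geometry, the achieved contrast and the stimulus id.

## Manifest CSV (`manifest.csv`)

| column | meaning |
|---|---|
| stimulus_id | unique stimulus identifier |
| patch_file | TIFF filename relative to the patch directory |
| tilt | construction (signed) tilt of the scene spec, [0, 360) |
| slant | construction slant, degrees |
| distance | patch-center distance, meters |
| contrast | achieved windowed RMS contrast of the left image |

Appended by the `truth` stage: `truth_tilt_signed` [0,360), `truth_tilt`
(unsigned, [0,180)), `truth_slant`, `tilt_variance` — all recomputed from the
rendered range map.

Appended by the `cues` stage: `lum_cue`, `disp_cue`, `tex_cue` (degrees
[0,180), NaN when unreliable) and `lum_ok`, `disp_ok`, `tex_ok` flags.

## Trials CSV (`trials.csv`)

| column | meaning |
|---|---|
| stimulus_id | matches the manifest |
| truth_tilt | unsigned groundtruth tilt, [0, 180) |
| estimate | unsigned tilt estimate, [0, 180) |
| error | signed circular error estimate − truth, (−90, 90] |
| error_bc | bias-corrected error (per-truth-bin mean error removed) |
| slant, distance, contrast, tilt_variance | stimulus covariates |
| observer_id | "model" or a synthetic-observer label |

## Estimate cube (`cube.bin` + `cube.json`)

`cube.bin`: flat float64 array of length 3·B³ — per-cell doubled-angle
resultant real parts, then imaginary parts, then counts. `cube.json`: bins
per cue, min count, prior mean, metadata. Round-trips bit-exactly.

## Run configuration

Single YAML document mirroring `tilt3d.io_cli.RunConfig` (nested sections:
`geometry`, `truth`, `cues`, `sampling`). Round-trips losslessly.
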