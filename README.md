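# fxmvol

Single-cell volumetry and motility analysis for **fluorescence-exclusion
microscopy (FxM)**, with a synthetic ground-truth experiment generator and the
companion bulk swelling assays (buoyant-density gradients, Coulter-counter
series).

## The problem

Immune cells such as neutrophils swell by ~15% within minutes of sensing a
chemoattractant, while simultaneously spreading (a transient ~5–8% volume
*loss*) and switching into fast, persistent migration. Measuring these
percent-level volume changes in single cells requires FxM: cells sit in a
shallow chamber of known height h<sub>chamber</sub> filled with a fluorescent
dye they exclude, so each cell casts an intensity *deficit* proportional to
its height profile. The cell volume is

&nbsp;&nbsp;&nbsp;&nbsp;V = (px² / α) · Σ<sub>(x,y)∈A</sub> (I<sub>max</sub> − I(x,y)),&nbsp;&nbsp;&nbsp;&nbsp;α = (I<sub>max</sub> − I<sub>min</sub>) / h<sub>chamber</sub>

where A is the cell footprint, I<sub>max</sub> the median local background
(the counterfactual signal had the cell not been there), I<sub>min</sub> the
signal at the PDMS pillars that touch the chamber roof (zero dye column), and
px the pixel size. Extracting clean volume traces demands a chain of image
operations — denoising, Scharr edge detection with a log-domain threshold,
flood-fill foreground extraction, seeded-watershed instance splitting,
tracking, and per-frame multiquadric flatfield correction — each of which this
package implements and validates by recovering known ground truth from
synthetic chamber images.

Track kinematics use the windowed velocity
ν<sub>i</sub> = |r<sub>i+τ</sub> − r<sub>i−τ</sub>| / (t<sub>i+τ</sub> − t<sub>i−τ</sub>)
(τ = 3 frames ≈ 1 min) and an angular-alignment statistic in [−1, 1]
(+1 straight, −1 reversal, ≈0 for Brownian motion) computed between track
positions separated by 10 µm of traveled path.

## Worked example

```python
import fxmvol as fx

# a synthetic chamber: 50 dye-excluding cells, 120 frames at 10 s spacing,
# stimulation at frame 18, 1% noise, 20% illumination nonuniformity
ds = fx.simulate_experiment(fx.SimConfig())
result = fx.run_pipeline(fx.FrameSet.from_dataset(ds))

med = result.volumes.groupby("time_s")["volume_norm"].median()
post = med[med.index >= ds.stim_time]
print(f"spreading dip:    {100 * (1 - post.min()):.1f}%")
print(f"swelling plateau: {100 * (med[med.index >= med.index.max() - 120].median() - 1):.1f}%")
```

prints (seed 0):

```
spreading dip:    5.7%
swelling plateau: 14.5%
```

i.e. the pipeline recovers the programmed biphasic volume response — a 6%
spreading dip and a saturating swell toward +15% — from the rendered images
alone; per-cell-frame volumes agree with the rasterized ground truth to a
median error of about 0.2%.

The same stages are scriptable from the shell:

```bash
fxmvol simulate --config sim.yaml --output-dir data/ --seed 1
fxmvol run      --config run.yaml --output-dir out/
fxmvol density  --fractions fractions.csv --output-dir out/
fxmvol coulter  --samples coulter.csv --output-dir out/
```

`run.yaml` is a flat key-value document; minimal keys are `input_dir`,
`pixel_size` (µm), `chamber_height` (µm) and `stim_time` (s), plus any stage
parameter to override (e.g. `denoise_sigma`, `max_disp_um`, `ff_n_points`).
`sim.yaml` accepts any `SimConfig` field (`n_cells`, `n_frames`,
`swell_fraction`, `speed_post`, ...). Outputs are CSV tables (`tracks.csv`,
`volumes.csv`, `motility.csv`, summaries), a label TIFF, and a JSON manifest
with the seed and config hash.

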