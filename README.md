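# glut4tirf

Quantification of insulin-stimulated GLUT4 vesicle trafficking in TIRF
(total internal reflection fluorescence) microscopy time-lapse data,
with a synthetic-movie simulator that provides ground truth for every
analysis stage.

## The problem

Insulin triggers the delivery of GLUT4-carrying vesicles from
intracellular stores to the plasma membrane. TIRF microscopy
illuminates only a thin evanescent zone (`I(z) = I0·e^(−z/d)`, with
penetration depth `d ≈ 110 nm`) above the coverslip, so the adherent
cell footprint reports vesicles docked at or moving near the membrane.
This package implements the standard quantification chain for such
data:

1. **Preprocessing** — rolling-ball background subtraction (grayscale
   opening with a ball-cap structuring element), median despeckling,
   local-outlier removal.
2. **Mobile/static decomposition** — per 1-min bin, the per-pixel
   average projection retains stationary structures;
   `mobile = max(0, frame − average)` isolates moving vesicles and
   `static = frame − mobile` the docked ones, with exact conservation.
3. **Focus detection** — vesicles are local maxima with ≥75% of their
   integrated intensity within a 5 px radius and a half-maximum support
   of at least a 2 px-radius disk; counts are reported per 100 µm²
   region of interest per time bin.
4. **Translocation kinetics** — footprint fluorescence normalised to
   the pre-insulin baseline is fitted with
   `R(t) = 1 + (A − 1)(1 − 2^(−t/t½))`, giving the plateau
   fold-increase `A` and half-time `t½`; the evanescent depth is
   calibrated from a 10 µm bead image.
5. **Screen quantification** — per-field HA/GFP (surface/total
   reporter) and GFP/DAPI ratios with basal-normalisation conventions,
   Pearson/Manders colocalisation, Welch t-tests and two-way ANOVA.

Since no public raw data exist for these experiments, the simulator is a
first-class component: movies with docked and diffusing vesicles under
evanescent illumination, bead calibration images, and multi-channel cell
fields, all with exported ground truth. See `docs/methods.md` for the
model and its assumptions.

## Worked example

```python
import numpy as np
from glut4tirf import (AcquisitionGeometry, SimulationConfig,
                       simulate_tirf_movie, preprocess_stack,
                       intensity_series, fit_translocation, run_dynamics)

geometry = AcquisitionGeometry(pixel_size=0.1, frame_interval=15.0)
config = SimulationConfig(
    field_size=(256, 256), duration_pre=180, duration_post=1800,
    static_density_pre=4.0, static_density_post=4.0 * 3.3,
    mobile_density_pre=1.0, mobile_density_post=3.3,
    transition_halftime=12.3, seed=42)

movie, truth = simulate_tirf_movie(config, geometry)
clean = preprocess_stack(movie)
times, series = intensity_series(clean, frames_per_timepoint=2)
fit = fit_translocation(times, series)
print(f"fold = {fit.fold:.2f}, t_half = {fit.t_half:.1f} min")
```

prints (seed 42):

```
fold = 3.65, t_half = 11.9 min
```

i.e. the fitted TIRF-zone plateau recovers the configured 3.3-fold
density increase and its 12.3 min half-time to within the stochastic
accuracy of a single movie (≈ ±10% here; means over seeds converge on
the ground truth). The estimator classes (`StackPreprocessor`,
`VesicleDynamicsAnalyzer`, `TranslocationKinetics`,
`PenetrationDepthEstimator`) wrap the same operations in
scikit-learn's fit/transform idiom:

```python
from glut4tirf import TranslocationKinetics
est = TranslocationKinetics().fit(times, series)
est.fold_, est.t_half_
```

## Command line

```sh
glut4 simulate  --out movie.tif --seed 1 --duration-post 600
glut4 preprocess --in movie.tif --out clean.tif --ball-radius 10
glut4 dynamics  --in clean.tif --out counts.csv --n-rois 9
glut4 kinetics  --in clean.tif --out fit.json
glut4 run       --config run.yaml     # multi-stage, manifest + checksums
```

Movies travel as ImageJ-compatible multi-page TIFF with a JSON metadata
sidecar; counts as tidy CSV (bin_index, t_min, roi_index, mobile_count,
static_count).

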