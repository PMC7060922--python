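# Methods

## Scope and rationale

`glut4tirf` quantifies insulin-stimulated trafficking of GLUT4-carrier
vesicles near the plasma membrane from TIRF (total internal reflection
fluorescence) time-lapse data, and the companion fixed-cell screen
readouts (surface/total reporter ratios, colocalisation). Because no raw
image data are available for this kind of experiment, the package ships a
first-class synthetic-data module: every analysis stage is validated in
closed loop — published summary values are used as simulator ground truth
and the pipeline must read them back.

## Optical and kinetic model

**Evanescent illumination.** Excitation decays with height `z` above the
coverslip as `I(z) = I0·exp(−z/d)`. The default penetration depth is
`d = 110 nm`. A vesicle at height `z` renders as a 2-D Gaussian spot of
amplitude `brightness·exp(−z/d)`; the effective spot width default is
`psf_sigma = 2 px` (≈200 nm at 0.1 µm/px), the convolution of vesicle
size, optical PSF and camera blur. Spots are truncated at 4σ (99.97% of
the flux), which bounds rendering cost; the conservation property test
verifies the truncated flux against the analytic integral `2πσ²·amp`.

**Penetration-depth calibration.** A large bead (default 10 µm) resting
on the glass converts lateral offset `r` into height
`z(r) = R − sqrt(R² − r²)`, so log-intensity is linear in `z` with slope
`−1/d`. The estimator averages *log*-intensity (not intensity) in 1-px
annuli: the mean of a linear function of `z` stays on the line, so the
noise-free recovery is exact to machine precision. The fit range
`z ≤ 3·d̂` is iterated three times from a 150 nm initial guess; a
non-negative slope (or a flat profile) raises a "not evanescent" error.

**Vesicle populations.** Docked ("static") vesicles hold a fixed
(x, y, z); mobile vesicles perform lateral Brownian motion with effective
diffusion coefficient `D` (default `3×10⁻³ µm²/s`, an rms excursion of
~0.6 µm per minute — the restricted, tethered mobility regime reported
for near-membrane GLUT4 carriers; genuinely fast axial transits blur
below detectability and are not the counted class). Vesicle heights are
drawn uniformly on `[0, 300] nm`; with `d = 110 nm` this produces a
broad, right-skewed amplitude distribution, which is the dominant noise
source in small-field recovery studies. Populations live on the field
plus a rendering margin (4σ + 1 µm) with *reflecting* boundaries:
reflection conserves the population and keeps the equilibrium density
uniform, whereas absorbing edges with uniform respawn would deplete the
margin and crowd the interior (~25% density bias in early testing).
Target counts follow the configured density with a single uniform dither
offset per movie, which removes integer-rounding bias in expectation
across seeds.

**Insulin response.** After the insulin frame, each pool's density
relaxes from its basal to its stimulated value as a single exponential
parameterised by a half-time, matching the monotone approach to plateau
of measured translocation time courses. The fitted model is

    R(t) = 1                                   t < 0
    R(t) = 1 + (A − 1)·(1 − 2^(−t/t½))         t ≥ 0

on the series normalised to the pre-insulin mean. `A` is the plateau
fold-increase; `t½` is the time to half of the total increase. The fit
is bounded (`A ≤ 10·max(series)`, `t½ ≤ 2×` the observation span):
beyond roughly twice the observation window the plateau is statistically
unidentifiable and unbounded fits escape along the high-`A`/high-`t½`
ridge. A flat series returns `A = 1` with `t½` flagged undefined. The
fit is invariant to rescaling the raw series.

**Noise.** Poisson photon noise on the full frame (background + spots),
then Gaussian read noise (default σ = 1.5), clipped at zero. The uneven
diffuse background is a random low-order polynomial plus three broad
Gaussian blobs (default offset 10, amplitude 5 — TIRF backgrounds are
intrinsically low). Both noise sources can be disabled for exactness
tests.

## Image conditioning

The chain is rolling-ball background subtraction → 3×3 median
("despeckle") → local-outlier removal, in that order. The rolling ball
is implemented exactly as grayscale opening with a ball-cap structuring
element (radius default 10 px); the unit tests compare it against a
naive pixel-by-pixel morphology oracle. In the chain, the background is
estimated on a 3×3 mean-smoothed copy and subtracted from the original
(the behaviour of the standard ImageJ implementation): without
presmoothing the opening rides the lower envelope of the noise and
leaves a ~2σ additive floor that biases ratio measurements. The
background estimate is capped at the image so the output stays in
`[0, input]`. Edges use reflective padding throughout (the
`scipy.ndimage` "reflect" convention). The 3×3 median attenuates a
σ = 2 px spot peak by ~30% (including sub-pixel sampling); the
attenuation is uniform and multiplicative, so fold-change and ratio
readouts are unaffected.

## Mobile/static decomposition and counting

Frames are segmented into 60 s bins (a trailing remainder shorter than
half a bin merges into the last bin). Within a bin,
`mobile[f] = max(0, frame − average_projection)` and
`static[f] = frame − mobile[f]`; negatives are clipped into the static
part, which makes the conservation `mobile + static = frame` exact
bit-for-bit.

Foci must satisfy three criteria: (i) an 8-neighbourhood local maximum
above threshold; (ii) ≥75% of the integrated intensity within a 5 px
radius, relative to the 10 px support (the literal "75% of the peak
intensity" is a single pixel, for which containment is meaningless, so
containment is read as integral containment); (iii) the connected
half-maximum region holds at least the area of a 2 px-radius disk
(13 px). Note (iii) implies an effective minimum spot width of
σ ≈ 1.8 px — criteria are pixel-denominated, so analysis assumes
adequately sampled spots. Equal-valued plateaus are represented by their
lexicographically smallest (row, column) pixel; accepted peaks closer
than 5 px merge into the brighter one. The default threshold is the
image median + 4 robust σ (median absolute deviation × 1.4826).

**Counting design.** Static foci are counted on the bin's static-stack
average projection. Mobile foci are detected on *every frame* of the
mobile stack and the per-bin count is the mean over frames: this is the
unbiased estimator of the instantaneous number of moving vesicles
present, the quantity a per-area density describes. The alternative —
one detection on the bin's maximum projection — undercounts realistic
movers, because a vesicle wandering further than the containment radius
during a bin leaves a track whose integral containment fails criterion
(ii); it remains available via `mobile_projection="max"`. A consequence
of per-frame averaging is that `mobile_count` is fractional while
`static_count` stays integer.

Shot noise at a bright docked vesicle fluctuates with σ ≈ √intensity and
survives the decomposition; a flat background threshold cannot separate
it from genuine movers. A mobile focus must therefore also exceed
`4·sqrt(average_projection)` at its position — the Poisson noise scale
of the stationary signal it sits on, using the same 4σ convention as the
flat threshold. In instrumented runs this gate removed every
static-vesicle artefact and no true detection.

Counts are reported per ROI per bin; ROIs are non-overlapping 100 µm²
squares placed on a grid, with times as bin midpoints relative to
insulin addition.

## Screen quantification

Per-field (not per-cell) channel means are the unit of analysis. The
HA/GFP ratio uses two normalisation conventions: per-treatment (each
group's basal mean ≡ 1; isolates the insulin response within a group)
and cross-group (all groups over the control basal mean; exposes
insulin-independent basal shifts such as a knockdown that elevates
surface reporter 2.7-fold while abolishing the insulin response).
GFP/DAPI is the total-reporter abundance proxy with the same
conventions. Fields with a zero denominator are excluded and reported in
an error list, not silently dropped.

Colocalisation reports Pearson's r plus Manders M1/M2. Default Manders
thresholds are per-channel Otsu; threshold 0 gives the original Manders
definition (used for the exactness fixtures). Group comparisons use
Welch's unequal-variance t-test for pairwise designs — deliberately,
where equal-variance Student's test might be expected, because
field-level variances differ between conditions and Welch is
conservative — and a two-way ANOVA (with interaction, type-II sums of
squares) for the screen design. A 1000-replicate null simulation checks
the 5% type-I error calibration.

## Validation studies and problem sizes

The closed-loop studies (in `glut4tirf.validation`, re-run by
`scripts/acceptance.py`) use these generator settings as ground truth:
plateau folds 1.89 (HeLa-like) and 3.3 (adipocyte-like) with half-times
17.1 and 12.3 min; post-insulin steady-state mobile density 2 per
100 µm²; penetration depth 110 nm; control-screen insulin response
3-fold; knockdown basal elevation 2.7-fold.

Problem sizes are the package's own choices for single-CPU runs:

* **Kinetics movies** — 256×256 px (25.6 µm footprint, ≈660 µm², ~33
  vesicles basal), one frame per 15 s for 3 min pre + 35 min post
  insulin (≈2 half-times, needed for plateau identifiability),
  timepoints of 2 frames. Intensity time courses need dense
  timepoints rather than a high frame rate, and a footprint of this size
  is needed because the z-amplitude randomness of individual arrivals
  dominates small-field variance. 10 seeds per cell type.
* **Dynamics movies** — 300×300 px, one frame per 3 s, 2 min pre +
  8 min post, density transition half-time 1 min so the final five
  one-minute bins sit on the plateau; the 3×3 grid of 100 µm² ROIs tiles
  the whole footprint, which suppresses the frozen spatial Poisson
  fluctuation of the ~18 persistent mobile vesicles. 10 seeds.
* **Screen fields** — 16 fields per condition, noise-free (the
  conventions are exact identities there).

## What the simulator does and does not emulate

Emulated: evanescent depth-dependent brightness, docked vs
restricted-mobile vesicle pools with an insulin-triggered density
change, Poisson + read noise, uneven diffuse background, co-registered
multi-channel cell fields with configurable surface fraction and
overlap. Not emulated: fusion-event photophysics (flash/spread),
photobleaching, directed/cytoskeletal transport, cell-shape
heterogeneity and cell-to-cell expression variance within a field,
stage drift, and multi-colour TIRF. Passing the closed-loop studies
shows the *analysis* is faithful under the stated model; it does not
certify performance on real data with the unmodelled features above.

## Numerical choices and degenerate inputs

* Conservation of the decomposition is asserted bit-exactly; "all frames
  identical ⇒ nothing mobile" holds to float epsilon of the mean.
* `bin_stack` rejects bins shorter than two frames (average projection
  undefined); `decompose_bin` rejects single-frame stacks.
* Blank or constant references raise in `footprint_mask`; constant
  channels flag Pearson's r as undefined; degenerate groups (n = 1) flag
  the t-test.
* Movies are written as ImageJ-compatible float32 multi-page TIFF with a
  JSON sidecar (geometry, insulin frame, seed); ground truth as CSV.
* One run seed fans out to stage- and study-level child seeds via
  counter-based `SeedSequence` derivation (CRC32 of the study label), so
  every stage is reproducible independently of execution order.

## Known limitations

* Mobile-count recovery carries a small negative bias (a few percent)
  from frames in which a vesicle sits near its own bin-average position
  and its residual loses the half-maximum support criterion.
* The per-movie plateau fit is right-skewed when the observation window
  is much shorter than `t½`; the bounded fit controls but does not
  eliminate this, which is why recovery studies report means over seeds
  on ≥30 min windows.
* Otsu-thresholded Manders coefficients underestimate the placed overlap
  fraction (spot tails fall below threshold); threshold-0 Manders is
  exact for disjoint/co-placed constructions.
* The foci criteria are pixel-denominated; undersampled data
  (spot σ < ~1.8 px) would fail criterion (iii) by construction.
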