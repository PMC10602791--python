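# Methods

## Temperature-rate model

Development at incubation temperature *T* (°C) is assumed linear in time
with rate `r(T) = 0.055·T − c` reference-hours per wall-clock hour,
`c = 0.57 °C`. The model is evaluated as printed: at the 28.5 °C reference
it gives 0.9975, not exactly 1, and we do not renormalise. It is undefined
at or below `c/0.055 ≈ 10.36 °C`, where the rate becomes nonpositive;
`relative_rate` raises there rather than extrapolating. Stage labels are
reference-equivalent hpf, `h = t·r(T)` for wall-clock time `t` since
fertilisation.

When two populations are compared, predicted stage is regressed against
**wall-clock** hours post fertilisation (the `time_h`/`true_hpf` column),
not against the temperature-adjusted label: a perfect model predicts the
adjusted stage, so the slope against wall-clock time is `r(T)` and the
ratio of slopes between a 25.0 °C and a 28.5 °C population is
0.805/0.9975 ≈ 0.807. Regressing against the adjusted label would give
slope ≈ 1 for every temperature and carry no rate information.

## Network

The regressor is a deliberately small sequential CNN: x-only centre crop
(width → input height, so 224×320 → 224×224 at full scale, 64×96 → 64×64 at
desk scale), a rescaling layer, `n` units of (3×3 convolution with 'same'
padding, ReLU, 2×2 max-pool), then flatten → dense(ReLU) → dropout →
dense(1). Cropping only in x reflects the plate acquisition geometry
(width > height) and removes x-translation artefacts introduced by
augmentation. 'Same' padding makes each unit exactly halve the spatial
size, so configuration validation reduces to `floor(size / 2^n) ≥ 1`.

Full-scale defaults are 5 conv units with (16, 32, 64, 128, 256) filters
and a 512-wide dense layer, dropout 0.5, Adam at 5·10⁻⁴, 500 epochs; these
follow the AlexNet-derivative lineage the architecture belongs to and are
all configurable. The desk-scale variant used by the test-suite
(`scaled_config`) is 3 units (8, 16, 32), dense 64, dropout 0.2, Adam at
2·10⁻³ for 30 epochs on 64×96 inputs — sized so a full
simulate/train/discriminate experiment runs in ~2 minutes on one CPU core.

The forward and backward passes (im2col convolution, switch-based pooling,
inverted dropout) and Adam are implemented directly on NumPy arrays, which
keeps the dependency surface minimal and gives exact control over the
backward pass for saliency and freezing. Gradients are verified against
central finite differences in the test-suite. The loss is unweighted MSE in
hpf²; reported "loss ≈ 10" therefore reads as ≈ 3.2 h RMSE. Predictions are
raw network outputs — they are not clipped to nonnegative hpf, so a
population's through-origin fit is not biased near the origin.

Training requires disjoint train/validation well sets and refuses
overlapping wells: frames of one embryo are near-duplicates, and splitting
them across sets would leak. Checkpoints are a `.npz` of weights plus a
JSON sidecar of the configuration and a CSV loss history.

## Augmentation

Six transforms, applied per image, training only (inference is bit-identical
pass-through): histogram equalisation (p = 0.5), saturation scaling
(p = 0.5, factor uniform in [0.6, 1.4]), additive Gaussian noise
(σ = 0.02), horizontal and vertical flips (p = 0.5 each), x-translation
(uniform up to 20 % of width) and zoom (factor within ±30 %). The
translation and zoom bounds are fixed by the acquisition geometry; the
probabilities are conventional choices. Images are carried as three
replicated grayscale channels so the saturation transform is well defined
(it is an effective no-op on pure grayscale, and meaningful if colour data
are supplied). Translation and zoom fill exposed regions by edge
replication, avoiding dark borders that saliency maps would latch onto.

At desk scale the acceptance experiments train *without* augmentation: with
a few hundred images and 30 epochs there is no overfitting for augmentation
to prevent, and the zoom transform in particular destroys the apparent-size
cue that dominates the synthetic renderer's stage signal. Augmentation
remains the default for full-scale training.

## Transfer learning

Fine-tuning freezes parameters by whole layers, unfrozen greedily from the
output end until the retrained fraction reaches the requested target; the
achieved fraction is reported (it is the smallest whole-layer fraction at
or above the target, and can be much larger when the dense layer dominates
the parameter count, as it does in the desk-scale architecture). Frozen
parameters are bit-identical before and after fine-tuning — the optimiser
never touches them. The default fine-tuning rate, 10⁻⁴, is one fifth of the
initial training rate, and the default schedule is 1,200 epochs; the
desk-scale direction test uses 20 epochs at 4·10⁻⁴ (one fifth of the scaled
training rate).

## Saliency

Attribution uses the DeconvNet backward rule: the output scalar is
propagated backwards with each ReLU transmitting only the positive part of
the incoming signal, independent of its forward activation; max-pool layers
route through the forward switch locations; convolution and dense layers
apply transposed weights; dropout is inactive. The three-channel signal is
reduced by the maximum of absolute values, so maps are nonnegative with the
spatial shape of the cropped input. For a purely linear model this reduces
to |weights|, which the test-suite asserts in closed form.

## Slope statistics

- Through-origin slope: `m = Σxy / Σx²`, the least-squares minimiser of
  `Σ(y − mx)²` (cross-checked against a brute-force grid minimiser).
- R² is the conventional `1 − SS_res/Σ(y − ȳ)²`. For fits forced through
  the origin it can be negative; when y is constant (`SS_tot = 0`) it is
  reported as undefined (`None`) rather than ±∞.
- Residual summaries use divisor *n* for the SD and divisor *n − 1* inside
  the SEM. The mismatch is deliberate: it replicates the documented defaults
  of the NumPy `std` and SciPy `sem` routines respectively.
- Slope bands resample **without replacement** ("random subsets of the
  data" rather than a classical bootstrap; `replace=True` is available as a
  switch) and report the min–max of the resampled slopes, not percentiles.
  With `k = n` every resample is the full data set and the band collapses
  to the full-data slope. Subsets are drawn by chunked partial Fisher–Yates
  shuffles, exact and O(n_boot·n), deterministic given the seed.
- Two populations are distinguishable iff their slope bands are disjoint;
  the margin is the gap between the intervals (negative = overlap width).
  For through-origin cones, slope-interval disjointness implies the
  prediction cones are disjoint at every x > 0, so no separate
  per-x threshold is reported.

## Synthetic plates

The simulator stands in for real plate time-lapses: one embryo per well,
frames at a fixed interval (default 15 min) from ~3 hpf, per-well
fertilisation-time jitter uniform in [0, 0.5] h (clutches are laid within
~30 min), two temperatures with rates from the model above, 16-bit
single-channel TIFFs plus a `path,well,frame,time_h,temperature_c,hpf`
manifest.

The morphology model is invented, not photorealistic: an elliptical yolk
(shrinking slightly with stage), a circular-arc body wrapping the yolk
(arc grows with stage), a tapering tail (length grows), somite-like
periodic stripes (`floor(stage/1.5)`, capped at 30), an eye disc appearing
at 24 hpf-equivalent, and pigmentation increasing from 0.15 to 0.9 — all
monotone in stage by construction, resolvable at 64–256 px, over a bright
background with a mild illumination gradient and Gaussian noise, at random
position and orientation. A trivial statistic (mean intensity) is already
rank-correlated with stage, which the tests assert before any CNN enters.

What passing tests therefore show is that the pipeline — loading,
well-based splitting, training, prediction, slope statistics — correctly
recovers relative developmental rates *when the image signal is monotone
and learnable*. They do not show that the scaled CNN would stage real
embryos: real clutches vary in size, focus, chorion appearance and
developmental asynchrony far beyond the jitter modelled here, and real
staging accuracy requires the full-scale network trained on archived
acquisitions. The "distribution-shifted site" used in the transfer test
differs only in camera noise and illumination, a mild stand-in for a real
microscope change.

## Desk-scale experiment sizes

The acceptance experiments use 24-well plates, 40 hourly frames from 3 hpf,
64×96 px images; training uses 12 wells (480 images) for 30 epochs; slope
bands use k = 100 with 10,000 resamples; the band-nesting check uses
n = 5,000 synthetic prediction points with residual σ = 2.136 h and 100
repeat seeds. These sizes were chosen once as the smallest at which the
rate-ratio and band structure are stable.

## Known limitations

- The NumPy network trains on one core; it is not a tool for full-scale
  (hundreds of thousands of images) training runs.
- Whole-layer freezing makes the achievable retrained fractions coarse;
  the dense layer's dominance means small targets still retrain most
  parameters at desk scale.
- The min–max band widens without bound as `n_boot` grows (it is an extreme
  statistic, not a quantile); it is used because it is the field's stated
  convention, with percentile bands available as an option.
- `hpf` labels are stored temperature-adjusted; tooling that expects
  wall-clock labels should read `time_h`.
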