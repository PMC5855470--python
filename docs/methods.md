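# Methods

`odormix` implements an electronic-nose analysis for multi-component odorant
mixtures: small feedforward neural networks map an 8-channel chemical-sensor
reading to panel-rated odour intensity (OI, 0–6) and hedonic tone (HT, −4 to
+4), and odour interactions — intensity synergism, hedonic neutralization —
are detected by comparing panel-observed and network-predicted values against
additive mixture theory. Because no public dataset of this kind exists, the
package ships a synthetic-study generator that plays the role of the
laboratory: everything downstream is exercised, end to end, on data whose
ground truth is known.

## The regression core

**Model.** A feedforward network with layer rule `y_i = f_i(w_i [1; y_{i-1}])`,
where `w_i` is an `n_i x (n_{i-1}+1)` matrix whose first column holds the
thresholds. Hidden layers use tanh or Leaky ReLU (leak `a`, default 0.03);
the output layer is linear, as a regression head requires. Inputs are
z-scored per channel and the single output is z-scored during training and
inverted at prediction time, so error metrics read directly in verbal-scale
units (one unit = one class). Normalization statistics always come from the
learning partition, never from held-out data.

**Training.** Full-batch gradient descent on the mean squared error with
sign-based per-weight adaptive steps (iRprop−): a weight's step grows by
`step_up` (1.2) while its gradient keeps its sign, shrinks by `step_down`
(0.5) on a sign flip (the flipped update is skipped), with step bounds
[1e−9, 1]. This leaves two controlling factors plus bounds, suits the small
sample size, and is deterministic given the seed. Default 300 epochs; the
weights returned are the best-on-training-loss snapshot. With ~40–150
trainable weights and n = 150, longer schedules start fitting panel noise,
which is visible in cross-validation; 300 epochs sits on the flat part of
the validation curve for the small architectures the selection favours.

**Initialisation.** Glorot-uniform weights (`±sqrt(6/(fan_in+fan_out))`),
zero thresholds, optionally replaced by stacked-denoising-autoencoder
pretraining: each hidden layer in sequence is trained to reconstruct its
clean input from a corrupted copy (additive Gaussian, sd 0.1 on normalized
inputs; masking available) through a mirror decoder, encoder weights are
kept, and clean encodings feed the next layer. The corrupted copy is drawn
once per layer because the full-batch optimizer assumes a deterministic
objective. The output layer stays random.

**Structure selection.** The held-out test phase is split off first; the
learning+validation phase is shuffled into K = 5 near-equal folds. Each
candidate in the 11-structure grid (8-10-0-1 … 8-5-5-1, a zero meaning the
layer is absent) × {tanh, leaky_relu:0.03} is trained K times on K−1 folds;
RMSECV is the square root of the pooled validation MSE and R²(CV) the mean
per-fold R², both in original scale units. Lowest RMSECV wins; ties break on
higher R², then fewer weights. Per-fold normalization uses only the K−1
training folds (leak-free); fitting on the whole learning+validation phase
is available via a flag. The winner is refit on all learning+validation
samples and scored on the test phase (RMSEP overall and per component
count).

## Interaction detection

The theoretical mixture intensity is the Patte–Laffort value — the Euclidean
norm of the intensities each component would have alone — and the
theoretical hedonic tone is the algebraic sum of component tones. Component
values come either from the generator's own psychophysics
(`generator_truth`) or from a Weber–Fechner fit to single-compound
measurements (`calibrated`). A sample is called an interaction when the
observed (panel mean) or predicted (network) value differs from the
theoretical one by more than δ = 0.5 scale units — half a verbal class, the
scale's resolution; a one-sample t-test over the four assessors is available
instead (α = 0.05), falling back to the margin rule when assessor variance
is zero. For intensity, a significant excess is synergism; for hedonic tone,
significant attenuation toward zero is neutralization and amplification away
from zero synergism. The theoretical value is clipped to the reporting scale
before comparison: observations cannot leave the scale, so an off-scale
additive prediction would otherwise always register as an interaction.
Agreement between the panel path and the network path is tabulated per
component count as: of the samples the panel flags, the fraction the network
flags with the same verdict.

## The synthetic study

The generator emulates a two-phase design: 150 learning+validation and 80
test samples of 2–5-component aqueous mixtures of toluene (5–80 ppm),
acetone (200–3200 ppm), triethylamine (5–80 ppm), α-pinene (1–16 ppm) and
n-butanol (20–320 ppm), rated by a 4-person panel on the discrete VDI 3940
scales, with mixtures spanning OI 0.5–5.5 and HT −3.5 to +1.

**Component psychophysics.** Weber–Fechner: `OI_i = k · log10(C/OT_eff)`.
Literature aqueous thresholds are carried on each compound as a documented
property, but they sit orders of magnitude below the working ranges (a
toluene solution at the bottom of its range is ~100× its aqueous threshold),
which would pin every mixture at the top of the scale. The law therefore
uses an effective perceptual threshold — absorbing headspace partitioning
and panel conditions — calibrated together with `k` so each compound runs
from intensity 0.3 at the bottom of its concentration range to 4.0 at the
top (`k ≈ 3.1` for the 16-fold ranges). Hedonic contribution is
proportional to component intensity, `HT_i = h_c · OI_i / 4.0`, with units
+0.5 (toluene), −0.8 (acetone), −2.5 (triethylamine), +1.5 (α-pinene),
−1.8 (n-butanol): positive only for the pleasant odour types.

**Composition sampling.** Each sample draws a target mixture intensity
uniformly inside the study window and splits it across a random component
subset via a Dirichlet direction on the squared intensities; concentrations
follow by inverting the Weber–Fechner law. Directions are redrawn for the
same intensity target until every component lies inside its concentration
range, so the intensity distribution stays near-uniform at every mixture
size. This emulates a deliberate, panel-calibrated sample design;
independent log-uniform concentration draws are physically plausible for a
naive lab but concentrate the summed intensity of 4–5-component mixtures in
a narrow band, contradicting the stated 0.5–5.5 coverage at every size.

**Interactions (ground truth).** Deterministic functions of composition, so
the phenomena are in principle recoverable from sensor data. Intensity
synergism is level-dependent hyperadditivity: the additive intensity is
amplified by `synergy_factor` (default 1.3) once it passes a fixed onset
(default 3.5 scale units, linear ramp half-width 0.1). Hedonic
neutralization requires α-pinene high in its concentration range; the
per-count position threshold is set from the configured prevalence
(defaults 0.30/0.45/0.55/0.70 for 2–5 components, matching the flag
fractions the emulated study reports), and the whole hedonic sum shrinks
toward zero by the neutralization factor (default 0.4). Setting an
interaction prevalence of zero disables the corresponding effect exactly;
an explicit intensity-interaction prevalence recalibrates the onset to the
matching intensity quantile by Monte Carlo with a fixed internal seed.
Samples are rejection-sampled so the perceived (post-interaction) values
stay inside the study windows and below the scale ceiling — no clipping in
the data path.

**Sensor array.** Channel `j` responds `r_j = Σ_c a_cj · C_c^{e_cj}`,
linear for the PID and electrochemical channels, square-root power law for
the five metal-oxide channels, scaled so each compound's top-of-range
contribution equals its selectivity entry (headspace partitioning folds
into the affinities). The selectivity matrix reflects the sensors' target
gases — the PID sees all VOCs, the ammonia cell mostly the amine, MOS
channels broad and overlapping — while keeping the 5×8 matrix well
conditioned (minimum singular value ≈ 0.26) so the array can actually
discriminate five compounds. Multiplicative Gaussian channel noise, default
5 %.

**Panel.** Each of four assessors reports `round(value + N(0, sd))` clipped
to the scale; means are therefore quarter-unit granular. The per-assessor
sd is the configured base value (default 0.25) scaled by
`1 + (k−2)/3` for a k-component sample: panels rate complex mixtures less
consistently, which is what drives prediction error and detection
difficulty upward with mixture complexity in the emulated study.
Discretization is treated as part of the stochastic assessor model: in the
exact zero-noise limit the idealized panel reports the continuous perceived
value, which keeps the noiseless null (no interactions, no noise) free of
false detections on both paths.

**What the generator does not model.** Valve timing, flow rates,
temperature/humidity control, sensor drift and recovery transients, Henry's
law headspace chemistry, assessor-specific biases or drift, and any
interaction mechanism beyond the two above. Passing tests on this generator
show the pipeline recovers known structure of the kinds described — not
that it would perform identically on laboratory data.

## Sensor-contribution analysis

PCA on the channel correlation matrix (channels carry different units);
loadings are eigenvectors scaled by the square root of their eigenvalues,
with the largest-magnitude entry of each component made positive so output
is reproducible across linear-algebra backends. On the component plane the
angle between two loading vectors reads as correlation (≈0° strongly
positive, ≈180° strongly negative, ≈90° independent), and a channel's
contribution to a component is its absolute loading; ranking ties break on
channel name.

## Numerical and design notes

- Population (not sample) standard deviations throughout normalization;
  degenerate channels get scale 1 and a log warning.
- Leaky-ReLU derivative at 0 is taken as 1 (right derivative).
- Training raises an error naming the epoch if the loss goes non-finite.
- `select_best` is deterministic; CV fold seeds derive from the training
  seed and fold index; a study derives all stage seeds from one master seed
  via `SeedSequence`, so reruns are byte-identical.
- Table I/O reads floats with round-trip precision; model artifacts are a
  single JSON file that round-trips bit-exactly.
- Only full-batch training is supported; the adaptive-step scheme is a
  full-batch method and the study scale (n = 150) does not need minibatches.

## Known limitations

- On default synthetic data the held-out error does not grow strictly
  monotonically with component count: the noise floor does (by
  construction), but the model-error component is largest for 2–3-component
  mixtures, where the 10 possible pairs/triples fragment the 150 training
  samples into small per-subset groups, and smallest for 5-component
  mixtures, which all lie on a single composition manifold. With exactly
  five compounds this combinatorial support effect competes with the
  complexity-driven noise growth, and per-count errors (20 test samples
  each) are noisy at this scale, so the count ordering holds only on
  average, not strictly in every run.
- Hedonic tone is predicted less well than intensity (typical test R²
  ≈ 0.75–0.85 vs ≈ 0.92–0.96), mirroring the harder, sign-structured
  mapping; hedonic interaction agreement is correspondingly lower.
- Interaction-agreement percentages are ratios of small counts (a handful
  of flagged samples per component count) and fluctuate strongly between
  seeds, as they do in the study this emulates.
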