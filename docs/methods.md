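# Methods

## Data model and simulator

A session is 15 runs × 5 trials of 2.2 s at 500 Hz over the 8 dry
occipito-parietal channels PO7, O1, Oz, O2, PO8, PO3, POz, PO4; each of the
5 burst codes is cued exactly once per run (75 trials, 15 per class). Only
task trials are emitted; cue periods carry no data.

**Burst codes.** Onsets are drawn sequentially with gap = 0.35 s +
Exp(mean); the exponential mean is `1/rate − 0.35 s`, clamped to 20 ms when
the refractory gap alone saturates the nominal 3 Hz rate. Candidates are
rejected until the onset count is within ±1 of `rate × duration` and the
zero-lag Pearson correlation with every accepted code is ≤ 0.25 (default).
Each flash occupies 4 frames (~67 ms) of the 60 frames/s bit sequence; at
3 Hz this yields ≈ 20 % flash-labeled samples, i.e. the ~4:1 non-flash to
flash ratio that motivates undersampling the training set.

**Evoked response.** A Ricker (difference-of-Gaussians, biphasic) template
of 0.35 s, parameterized by peak latency (default 0.20 s), width (40 ms)
and peak-to-peak amplitude (µV), convolved with the cued code's onset train.
Per-flash amplitude jitter is multiplicative truncated Gaussian; latency
jitter shifts each onset. The source projects through a fixed unit-norm,
Oz-dominant spatial pattern.

**Background.** Per channel and independently across channels: narrowband
Gaussian noise per EEG band (δ 1–4, θ 4–8, α 8–13, β 13–35 Hz; FFT-masked
white noise scaled to a per-band RMS amplitude), 1/f-amplitude pink noise,
and white sensor noise. Defaults (ERP 5 µV p2p, pink 3 µV, bands ≈ 1–2 µV
RMS, sensor 1 µV) put a single mid-cohort participant near 70–80 % epoch
accuracy with TS-LDA, matching the mid-range of dry-EEG cohorts. The
`heterogeneous_cohort_specs` cohort sweeps amplitude 2→10 µV, amplitude
jitter 0.8→0.2, latency jitter 20→5 ms and δ/pink noise downward across 24
participants so decoding spans low (<70 %) to high performers.

**What the simulator does not model:** eye blinks/EMG, electrode drift,
photic-driving nonlinearity, cue-period data, or cross-channel correlated
background sources. Tests passing on this generator therefore demonstrate
the pipeline's correctness and its sensitivity to the modeled factors
(amplitude, jitter, band power), not field performance on real dry-EEG
recordings.

## Preprocessing

FIR band-pass 1–45 Hz: windowed-sinc (Hamming), ~1 Hz transition, applied
forward–backward (zero phase; stopband attenuation doubled). Epochs of
0.35 s (175 samples) start at every sample of a trial with the `L − Nt`
endpoint convention, reproducing 15 × (2.2 − 0.35) × 500 = 13 875 epochs
per class; an epoch's label is the 60 Hz code bit (sample-and-held at
500 Hz) at its start sample. Standardization divides by one scalar SD over
the participant's training epochs. Training sets are rebalanced 1:1 by
random undersampling; test sets are left imbalanced.

Splits: WP trains on the target's first two runs (10 trials = 22 s of
data) and tests on runs 3–15; DA adds all 75 trials of one source
participant (8.5× the WP training size). A leakage guard asserts that no
target test trial reaches any training fit.

## Participant-specific spatial chain

xDAWN estimates the evoked response by least squares with a Toeplitz onset
design over the continuous record (equivalently, by target-epoch averaging
when responses do not overlap, as here with the 0.35 s refractory gap) and
solves the generalized eigenproblem C_evoked u = λ C_total u; the top 4
unit-norm filters are kept, each sign-normalized so its evoked extremum is
positive (deterministic predictor values). Super epochs stack epoch
components 1–3 over the 4 filtered evoked components exactly as specified
by the decoding chain's 7-row layout; the 3-vs-4 asymmetry is kept but both
counts are configurable. Per-epoch 7×7 covariances use the Ledoit–Wolf
closed form (vectorized across epochs; cross-checked against the reference
implementation per epoch).

Alignment transports each epoch with the calibration covariances' Fréchet
mean under the affine-invariant metric. The printed transport multiplies by
R̄ itself; the default here is the whitening form R̄^{-1/2}, because it has
the testable invariant that the calibration covariance cloud maps to one
with identity Riemannian mean — the shared feature space across
participants — while the literal form is retained as `mode="literal"`.
The Fréchet mean uses the standard fixed-point iteration from the
arithmetic-mean initialization and raises if the gradient norm misses the
tolerance within `max_iter`.

## Predictors and screening

Five predictors from target epochs: peak-to-peak amplitude and peak latency
of the averaged target epoch (Oz in sensor space, first xDAWN component
after the participant-specific chain), relative band power (Welch, one
Hann segment per 0.35 s epoch, 4× zero padding to resolve the δ band,
`detrend=False` since the 1 Hz high-pass already removed offsets; band mean
over the 1–45 Hz mean; 8 channels in BP, components 1–4 in AP), broadband
SNR (target over non-target PSD), and the mean of the strictly-upper-
triangle Spearman correlations between target epochs. Wavelet spaces
(BPWave/APWave) replace the epoch series by the stack of Gabor magnitude
envelopes of the designated channel; shape predictors use the pointwise
maximum envelope, and spectral predictors are undefined there by
construction. Screening regresses accuracy on each predictor (OLS; Wald
test on the slope) with a configurable go/no-go threshold, default 0.70 —
the boundary below which users are counted as low performers.

## Decoders

All classifiers expose sklearn-style `fit` / `predict_proba` and a `seed`.

**TS-LDA.** xDAWN(4) fit on flash epochs; each filtered epoch is augmented
with the filtered flash prototype (8 × 175), summarized by a Ledoit–Wolf
covariance, projected to the tangent space at the training Riemannian mean
(36 coordinates) and classified with shrinkage LDA. Deterministic.

**CNN.** Spatial conv (kernel (8, 1)) + batch norm, temporal (1, 32) and
spatio-temporal (5, 5) convs with dilation (1, 2) / (2, 2) and leaky ReLU,
each block followed by (1, 2) max pooling and dropout 0.5; dense 256 →
softmax 2; Adam at 10⁻³. Filter counts per block are not fixed by the
architecture description; the defaults (16, 8, 4) keep the model in the
tens of thousands of parameters. Max-pool sizes are likewise unstated;
pooling by 2 along time is used. Dropout is inference-disabled, so
predictions are deterministic given a fitted model.

**GREEN.** 22 Gabor wavelets with centers on the 0–4.4 octave grid
(f = 2^octave Hz) and widths of 1.5 cycles (FWHM), truncated to the epoch
with a warning; per wavelet, the channel covariance of the complex
coefficients' real representation; one shared SPD block — learnable
shrinkage α = sigmoid(ρ), BiMap to 4 channels with QR retraction to the
Stiefel manifold after each optimizer step, ReEig floor 10⁻⁴ — then matrix
log at the identity (no batch reference is defined inside the network),
upper-triangle vectorization (10 × 22 = 220 features) and a 20 → 10 → 2
head with dropout (default rate 0.4, the bottom of the search grid; GREEN
trains with Adam at 3·10⁻³ — its learning rate is a free parameter, chosen
for reliable convergence of the small head within the 20-epoch budget).
The SPD block and head always train end-to-end;
`learn_wavelets=True` additionally places the wavelet centers/widths in
the gradient graph (kernels rebuilt per step). The default keeps them
fixed: on the short 0.35 s epochs the filterbank is near-saturated and the
extra graph multiplies training cost. The published hyperparameter grid
(wavelet count 6–30 step 2, dropout 0.4–0.8 step 0.1, max octave 3.6–5.0
step 0.2; 520 combinations, 5-fold CV) is exposed via
`green_hyperparameter_grid()` and sklearn model selection, not run by
default.

Neural training: 20 epochs, batch 256, Adam 10⁻³, optional early stopping
on a 10 % validation split. Pretrain/fine-tune fits on the source
participant and continues training on the target's calibration with the WP
budget; for TS-LDA (closed form) the tangent reference and LDA are refit on
the pooled data.

## Trial decoding

Hard per-epoch predictions (probability mode available) are compared with
each code's prefix by Pearson correlation at every epoch, computed with
cumulative sums; zero-variance prefixes give r = 0 by convention, and
correlation argmax ties break to the lowest code index. Epochs whose
correlation vector is entirely tied (no information yet, e.g. a constant
prediction prefix) cast no vote: the dynamic-stopping rule — decide when
the last 30 votes agree — cannot fire on them, so a constant classifier
defers to end-of-trial, as intended. The earliest possible stop is
therefore epoch 30.

## Statistics

Model comparisons: Wilcoxon signed-rank per metric (two-sided reported;
one-sided feeding the combination), Stouffer z = Σ Φ⁻¹(1−pᵢ)/√k with a
two-sided combined p from |z|, SMD = mean(Δ)/SD(Δ), Bonferroni over all
pairwise comparisons in a call. Identical score vectors return p = 1 and
SMD = 0 rather than erroring. Repeated-measures ANOVAs are intentionally
not reimplemented; the report exposes the per-cell means needed to run them
externally.

## Problem sizes and numerical choices

The test and acceptance runs use stride-8 or stride-16 epoching (116 or 58
of the 925 stride-1 starts per trial) and cohorts of 2–24 participants,
with the neural models at their default 20-epoch training budget; these
sizes are the package's default demonstration scale and are printed
alongside every reported value.
Tolerances: Fréchet mean gradient ≤ 1e-8 (50 iterations default), ReEig
floor 1e-4, Ledoit–Wolf shrinkage per its closed form, FIR transition
~1 Hz. Degenerate inputs are defined rather than left to chance: zero-
variance standardization raises, single-class undersampling raises,
single-class truth yields a missing balanced accuracy, empty calibration
raises.

## Known limitations

- The simulator's background is spatially independent across channels;
  real EEG has strong cross-channel correlation, which would make xDAWN's
  job harder than here.
- GREEN's wavelet learning is off by default (see above); enabling it is
  supported but slow at scale.
- The combined ("C-") scheme pools standardized epochs across participants
  when fitting the spatial chain; with two very dissimilar participants the
  pooled xDAWN can be dominated by the larger-amplitude one.
- Dynamic-stopping epochs are counted at the epoching stride in use, so
  stop-epoch values are comparable only within a fixed stride.
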