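# Methods

## The detection problem

A 6×7 matrix speller flashes its 6 rows and 7 columns in random order; one
*sequence* flashes all 13 lines once, so the attended character's row and
column give 2 target flashes per 13. A *run* of 8 sequences (104 flashes)
spells one character; a session holds 5 runs. Each flash is classified from
a single EEG epoch spanning −100…+800 ms around flash onset: targets elicit
a P300 — a positive centro-parietal deflection peaking roughly 300–450 ms
after the stimulus whose amplitude and latency differ systematically between
individuals (and, in this package's generative model, with sex and age
group). That between-subject variability is exactly what makes classifiers
trained on one group of participants degrade on a new participant, and what
the model below is designed to absorb.

## Model

The detector is a wide-and-deep binary classifier sharing one bias `b` and a
sigmoid head:

    P(y = 1 | x) = σ( w_wideᵀ [x, φ(x)] + w_convᵀ a_lf + b )

**Wide (memorizing) branch.** The input is the concatenation
`x = [d1, d2, dφ]`: `d1` the flattened 30-channel × 90-sample epoch (2700
values, row-major, microvolts), `d2` the one-hot participant attributes
(subject id, sex, age group; length T), and `dφ` the cross products
`ψ_k = ∏_{i: c_ki = 1} d2_i` — for 0/1 features, the AND of the selected
indicators. The default cross specification is all pairwise crosses between
distinct attribute blocks (sex×age, subject×sex, subject×age). The logit is
linear, `w·x + b` — a logistic regression that can memorize
participant-specific offsets.

**Deep (generalizing) branch.** The one-hot vector is embedded through a
T×90 table into a 90-sample row, stacked under the 30 EEG channels to form a
31×90 tensor, and passed through three 1-D convolutions applied identically
to each of the 31 rows (no cross-channel mixing before the dense head),
kernel 7, LeakyReLU (negative slope 0.01). The time widths are 90 → 42 → 18
→ 13: strides 2, 2, 1, with a single left zero-pad on the third layer.
Parameter counts are 16·1·7+16 = 128, 32·1·7·16+32 = 3616 and
16·7·32+16 = 3600; the flattened activation `a_lf` has 31·13·16 = 6448
entries feeding one dense unit (no separate bias — the bias is shared with
the wide branch). Because the embedding depends only on the participant, it
is computed once per participant and cached for repeated prediction.

**Unknown participants.** A subject id outside the training vocabulary
encodes as an all-zero subject block while sex and age group remain set, so
a never-seen participant is still scored using demographics — the mechanism
the leave-one-subject-out evaluation exercises. The age-group vocabulary is
taken from the study design's canonical bins (young/mid/older by default),
not from the observed sample, so a held-out participant from an unobserved
bin still encodes.

## Optimization

All trainable parameters — wide weights, embedding, convolution filters and
the dense head — are updated per coordinate by FTRL-Proximal on mini-batch
gradients of the mean logistic loss. Each coordinate keeps an accumulator
`z` and squared-gradient sum `q`; one step is

    σ = (√(q + g²) − √q) / α
    q ← q + g²;   z ← z + g − σ·w
    w = 0                                    if |z| ≤ λ₁
      = −(z − λ₁·sgn z) / (λ₂ + (β + √q)/α)  otherwise

the closed-form argmin of the proximal objective
`G·w + ½Σσ_s(w − w_s)² + λ₁|w| + ½λ₂w²` with the β term acting as a
quadratic stabilizer centered at the origin. The effective learning rate
α/(β+√q) is per-coordinate: rarely active features keep a large rate; the L1
truncation zeroes weights whose accumulator never escapes λ₁, producing
sparse wide weights. Ties |z| = λ₁ truncate to zero (the limit of the
else-branch). Wide weights initialize at zero (the FTRL convention); deep
weights initialize uniform scaled by fan-in, seeded. An Adagrad option for
the deep branch exists (`deep_optimizer="adaptive"`) for users who prefer
the conventional wide/deep split, but the default applies FTRL to the whole
mixed model.

Defaults: α = 0.05, β = 1, λ₁ = 1e−5, λ₂ = 1e−4, batch size 64, 3 passes.
These are training configuration, chosen for reliable convergence on the
generator's default conditions (the training loss plateaus by the third
pass); none is claimed to be optimal.

One subtlety matters when FTRL trains a network rather than a linear model:
the optimizer state must be initialized *consistently with the initial
weights*. A state with z = 0 but nonzero weights has its proximal argmin at
the origin, so the first step discards the random initialization and the
CNN collapses to a bias predictor. The optimizer therefore initializes
z₀ = −w₀(λ₂ + β/α) − λ₁·sgn(w₀), making the initial weights the argmin of
the initial objective; training then proceeds from the initialization as
intended. Gradients are computed by hand-written
backprop in numpy — the optimizer needs per-coordinate access, and at ~16k
parameters (2717 wide + ~1.4k embedding + 7.3k conv + 6.4k dense for an
8-subject vocabulary) an autodiff framework adds nothing. The deep branch
computes in float32 during training for speed; optimizer state stays
float64.

## Preprocessing

The offline chain is: select the 30-electrode 10-20 montage (FP1…O2, fixed
order); bandpass 0.1–30 Hz with a third-order Butterworth (zero-phase
forward-backward by default, which doubles the effective magnitude order;
a causal mode serves the online path); epoch −100…+800 ms around each flash
(half-open sample windows, 0-based, stimulus at sample 0; edge-clipped
epochs are dropped and counted); subtract the per-epoch per-channel mean of
the −100…0 ms interval; reject any epoch with a sample outside ±100 μV
*after* baseline correction (so constant offsets cannot trigger rejection);
decimate to 100 Hz (anti-alias FIR, integer factor only), making a 900 ms
epoch exactly 90 samples. The model input is the full 900 ms epoch including
the baseline interval — the 30×90 shape fixes this choice.

The online path takes the most recent 1 s of signal every 0.5 s, filters it
causally, crops to the trailing 900 ms, baseline-corrects on that crop's
first 100 ms, decimates, and scores with the cached participant embedding.

## Synthetic cohort

The study's EEG is private, so the package ships a generator that emulates
the paradigm and the population structure end to end:

* **Schedule** — uniformly random permutation of the 13 lines per sequence;
  onsets spaced by flash duration + ISI (defaults 100 + 75 ms; the real
  inter-stimulus timing is a free design parameter, and these defaults are
  ordinary speller practice, not a claim about the source study).
* **Evoked response** — a Gaussian bump (SD 55 ms) peaking `p300_latency` ms
  after onset with peak `p300_amplitude` μV, scaled across channels by a
  centro-parietal topography (gain 1.0 at Cz/CPz/Pz falling to 0.25
  frontally). Per-trial latency jitter is Gaussian (SD 8 ms). Non-target
  flashes evoke nothing by default (configurable).
* **Background** — per-channel 1/f-power noise (flat below 0.5 Hz, no DC)
  plus a 10 Hz alpha sinusoid at half the noise scale; default noise RMS
  8 μV.
* **Population structure** — amplitude mean 8 μV, +0.8 for females, −1 per
  age bin, SD 0.8; latency mean 320 ms, +10 for females, +40 per age bin,
  SD 15 ms. These realize the premise that the evoked response varies with
  sex and age, giving the wide branch something to memorize and the
  leave-one-subject-out design something to transfer.

What the generator does *not* emulate: volume conduction and channel
covariance (channels share only the deterministic topography, their noise is
independent), eye-blink/EMG artifacts, non-stationarity across a session,
and overlap-free responses (with the default 175 ms SOA, epochs overlap and
a target's P300 bleeds into neighbouring epochs — deliberately kept, since
real spellers have the same contamination). Passing tests therefore show the
pipeline and model are correct and that the architecture can exploit
subject-conditional structure; they do not certify real-EEG accuracy levels.

## Numerical choices

* Loss probabilities are clipped to [1e−7, 1 − 1e−7]; the loss is undefined
  at exactly 0/1.
* The sigmoid is computed in its numerically stable split form.
* Accuracy thresholds probabilities at 0.5, with p = 0.5 counted as a
  predicted target.
* Character decoding sums per-flash probabilities per line over a run's 8
  sequences; the predicted row/column are the arg-max over rows/columns,
  ties to the lowest index.
* Within-subject cross-validation uses stratified 5 folds (preserving the
  2:11 target ratio) with seeded shuffling; each fold is the 20% test set.
* EDF export quantizes to 16 bits with a 1% physical-range margin; the
  portable container (zip of .npy arrays + JSON metadata) is lossless.

## Evaluation designs and problem sizes

Three harnesses mirror the study designs: per-subject stratified 5-fold CV;
leave-one-subject-out (train on 7, test on the held-out participant, 8
folds); and random disjoint 4-train/4-test subject splits repeated 4 times.
All are pure functions of (data, classifier factory, config, seed) and accept
any classifier meeting the fit/predict_proba contract, so scikit-learn
baselines run unchanged.

The shipped cross-subject evaluation uses an 8-subject cohort, one session
(5 runs = 520 epochs) per subject at 1000 Hz acquisition decimated to
100 Hz — a desk-scale rendering of the study design chosen so a full
leave-one-subject-out sweep (8 model fits on ~3600 epochs each) completes in
minutes on one CPU core.

## Known limitations

* Conv geometry is defined by the published feature-map widths; stride-2
  arithmetic alone cannot produce the third layer's width 13 from 18, so the
  third layer uses stride 1 with one left zero-pad. Alternative geometries
  are configurable but change the dense head size.
* FTRL on convolution weights is unusual (adaptive per-coordinate L1 on
  shared filters); it converges here but can zero filters at aggressive λ₁.
* On this generator the participant-conditioning pathways add little beyond
  the CNN itself: the conv stack is shift-tolerant enough to cover the
  cohort's latency spread without knowing who the participant is, so the
  deep branch with (or even without) its embedding performs on par with the
  full two-branch model in the cross-subject evaluation. The
  wide-branch-removed ablation can therefore tie or narrowly beat the full
  model here — separating the branches' contributions appears to require
  the real-data effects listed above that the generator omits.
* The generator's independence of channel noise inflates the benefit of
  many channels relative to real EEG.
* No significance testing or information-transfer-rate metrics; accuracy is
  the only reported score.
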