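# p300wide

Wide-and-deep single-trial P300 detection for matrix-speller brain–computer
interfaces, with an FTRL-Proximal trainer, the full speller preprocessing
chain, a synthetic paradigm/EEG generator, and cross-subject evaluation
harnesses.

## The problem

A 6×7 character matrix flashes its rows and columns; attending a character
makes its row and column flashes elicit a P300 — a positive centro-parietal
EEG deflection ~300–450 ms post-stimulus. Spelling one character means
classifying 104 single-trial epochs (8 sequences × 13 flashes, 2 targets per
sequence) into target/non-target. Classifiers trained on one group of
participants typically degrade on a new participant because P300 amplitude
and latency vary between individuals (systematically with sex and age). This
package implements a detector built to absorb that variability: a *wide*
logistic-regression branch that can memorize participant-specific structure,
and a *deep* CNN branch that learns features shared across participants.

## The model

With `x = [d₁, d₂, d_φ]` (flattened 30×90 epoch in μV; one-hot participant
attributes; their cross products `ψ_k = ∏_{i:c_ki=1} d₂ᵢ`):

```
P(y = 1 | x) = σ( w_wideᵀ [x, φ(x)] + w_convᵀ a_lf + b )
```

The deep branch embeds `d₂` into a 90-sample row, stacks it under the 30 EEG
channels (31×90), and applies three per-row 1-D convolutions along time
(16, 32, 16 filters, kernel 7, LeakyReLU; time widths 90→42→18→13), giving
flattened activations `a_lf` of length 31·13·16 = 6448. Both branches share
one bias and one sigmoid head. An unseen participant encodes with a zero
subject block while sex/age remain active, so the model scores participants
it never trained on.

Every parameter is trained per coordinate with **FTRL-Proximal**
(per-coordinate learning rates α/(β+√q), L1 proximal truncation, L2
smoothing) on mini-batch gradients of the logistic loss — the L1 term drives
exact zeros in the wide weights. See `docs/methods.md` for the update rule,
its proximal objective, and all modeling choices.

## Worked example

```python
import p300wide as pw

# simulate a 3-participant cohort: one session = 5 runs x 104 flashes each
cohort = pw.generate_cohort(n_subjects=3, seed=3)
dataset, profiles = pw.build_dataset(cohort)   # preprocess to (n, 30, 90)

# leave-one-subject-out: train on 2 participants, test on the third
table = pw.leave_one_subject_out(
    dataset,
    lambda: pw.WideDeepP300Classifier(random_state=0),
    profiles=profiles,
)
print(table[["participant", "accuracy"]].round(3))
```

Output:

```
S01: sex=F age=mid amplitude=8.3 uV latency=362 ms -> 520 clean epochs (80 targets)
S02: sex=F age=older amplitude=7.0 uV latency=387 ms -> 520 clean epochs (80 targets)
S03: sex=M age=mid amplitude=7.1 uV latency=366 ms -> 520 clean epochs (80 targets)
participant  accuracy
        S01     0.977
        S02     0.904
        S03     0.944
mean held-out accuracy: 0.942
```

Each row is the single-trial accuracy on a participant whose data (and
subject id) never appeared in training — the cross-subject setting where
participant-blind classifiers typically drop. Character decoding aggregates
the per-flash probabilities of one run over its 8 sequences:

```python
clf = pw.WideDeepP300Classifier(random_state=0)
eset = dataset["S01"]
clf.fit(eset.epochs[104:], eset.labels[104:],
        subject_ids=eset.subject_ids[104:], profiles=profiles)
run = cohort[0][1][0].markers[:104]
probs = clf.predict_proba(eset.epochs[:104], subject_ids=eset.subject_ids[:104])[:, 1]
row, col = pw.decode_character(probs, [m.line_index for m in run])
# -> decoded character: row 4, column 5 (truth: row 4, column 5)
```

A command-line interface covers the same flow
(`p300wide simulate|preprocess|train|experiment`, see `--help`).

## Package layout

| module | contents |
|---|---|
| `containers` | `ContinuousRecording`, `EpochSet`, `EventMarker` |
| `io` | EDF+ read (mne) / minimal EDF+ write; lossless zip container |
| `simulate` | paradigm schedule, ERP model, 1/f + alpha background, cohorts |
| `preprocess` | montage, 0.1–30 Hz Butterworth, epoching, baseline, ±100 μV rejection, decimation |
| `features` | one-hot participant blocks, cross products, wide-input assembly |
| `network` | both branches, manual backprop, parameter counts, serialization |
| `ftrl` | FTRL-Proximal step/optimizer and the training loop |
| `estimator` | `WideDeepP300Classifier` (sklearn API) and a baseline adapter |
| `experiments` | within-subject CV, leave-one-subject-out, split-half, online sliding prediction, character decoding |
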