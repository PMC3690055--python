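# eegcam — head-movement artifact rejection for headset EEG

Consumer EEG headsets are convenient but mechanically fragile: a head
rotation shifts the electrodes and floods the recording with artifact.
`eegcam` detects those contaminated stretches by fusing the EEG itself with
the image stream of a frontal (scene-facing) camera worn by the user, and
excises them, leaving clean EEG for downstream brain–computer-interface
processing.

## Method

Per 128-sample EEG epoch (128 samples/s, 127-sample overlap, epochs
normalized to [−1, 1]) the package computes 12 frequency-band magnitudes
(3–15 … 59–61 Hz, via the DFT) and 13 time-domain statistics (moments,
zero crossings, derivative statistics, and the Hjorth parameters activity,
mobility, complexity).  Per frame pair (30 frames/s) it computes four
motion features: mean pixel difference, mean Sobel-edge difference, and
the average magnitude and count of Shi–Tomasi corners tracked with
pyramidal Lucas–Kanade.

Features are synchronized at the camera cadence and fused:

1. z-score, then Fisher LDA — directions **u** maximizing
   |uᵀM_B u| / |uᵀM_W u|, with the dimension count selected on the
   training data;
2. a soft-margin SVM f(x) = sgn(Σ_k a_k y_k K(x_k, x) + b) over a kernel
   grid (linear / polynomial / RBF / sigmoid), with Class 1 = still = −1
   and Class 2 = movement = +1;
3. a decision threshold on the raw SVM output tuned for the smallest
   average of Type-1 (still flagged as moving) and Type-2 (movement
   missed) error rates.

Intervals classified as movement are merged into sections and removed from
the EEG.  Accuracy is reported with two-fold cross-validation by whole
trials.  Because no public recordings exist for this task, the package
includes a deterministic synthetic-session generator (spectrally distinct
EEG classes; a panning frontal scene with tremor, posture adjustments and
natural yaw pauses) that reproduces the qualitative structure of the
problem; see `docs/methods.md`.

## Worked example

```bash
# 1. a miniature synthetic session (1 subject, 5 s trials, 4 trials)
eegcam simulate --out session --seed 7 --subjects 1 --duration 5

# 2. features for one still trial
eegcam extract --eeg session/s00c1t1/eeg.csv \
               --frames session/s00c1t1/frames \
               --out s00c1t1.csv --label 1
# -> wrote 120 feature vectors to s00c1t1.csv

# 3. train on all four trials (repeat --features for each CSV), then
#    excise movement sections from a moving trial
eegcam train --features s00c1t1.csv --features s00c1t2.csv \
             --features s00c2t1.csv --features s00c2t2.csv \
             --feature-set image+freq --out model.json --seed 0
# -> trained lda_svm pipeline: k=1 kernel={'kernel': 'linear', ...}
#    threshold=0.0480 -> model.json
eegcam detect --model model.json --eeg session/s00c2t1/eeg.csv \
              --frames session/s00c2t1/frames \
              --out-sections sections.tsv --out-eeg retained.csv
# -> 1 rejected sections; retained 128/640 samples
```

`extract` reports 120 vectors: 150 frames, minus frame 0 (no preceding
frame) and the 29 frames inside the first second, before a complete EEG
epoch exists.  `detect` on this moving trial rejects the whole governed
span [1.0 s, 5.0 s) and keeps only the 128 samples of the first second
that precede the first classified instant.  `sections.tsv` lists the
half-open `[start_s, end_s)` intervals with label 2 marking rejected EEG;
`retained.csv` holds what survives.

The same workflow is available as a library; `eegcam.benchmark.run_seed`
runs the full synchronize → LDA → SVM → threshold pipeline on a synthetic
session and returns the Type-1/Type-2/average errors for the fused and
single-modality detectors.

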