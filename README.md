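# pcgnet

Classification of heart-sound recordings (phonocardiograms, PCG) into
**normal** vs **abnormal** with a customized one-dimensional
convolutional network — the screening task behind automated detection of
congenital heart disease from stethoscope audio.  The package implements
the complete pipeline: WAV ingestion, Butterworth band-pass filtering,
resampling to a canonical 2000 Hz, fixed-length windowing with
wrap-padding, pitch-shift augmentation for class balance, a
stratified/recording-grouped train–validation–test split, CNN training
with Adam on cross-entropy, and evaluation (confusion matrix,
sensitivity/specificity, ROC/AUC).  A synthetic heart-sound simulator
makes every stage testable without clinical data.

It is aimed at researchers in biomedical signal processing who want a
transparent, dependency-light reference implementation: the network —
six blocks of `conv1d(k=3) → batch-norm → ReLU → max-pool(2) →
dropout(0.25)` with filters (64, 128, 128, 64, 32, 16), then
`dense(128) → dropout(0.5)` and a softmax (or sigmoid) head — is written
in plain numpy, including backpropagation, so every arithmetic step is
inspectable.

## The model in brief

A window of T samples (4 s × 2000 Hz = 8000 by default) passes through
blocks l = 1…6:

    y_l = Dropout(MaxPool(ReLU(BN(Conv1D(y_{l-1}, F_l, K=3))), P=2), R=0.25)

Same-padding convolutions leave the time axis to the pooling, so block l
outputs T / 2^l time steps; after six blocks a 4-s window is 125 × 16
features, flattened into `dense(128)` and a 2-way softmax.  Training
minimises cross-entropy with Adam (η = 10⁻³); *abnormal* is the positive
class, hard labels use a 0.5 cut on P(abnormal), and the ROC/AUC is
threshold-free with tie-grouped thresholds (trapezoidal AUC equals the
Mann–Whitney pair statistic).  See `docs/methods.md` for assumptions,
parameter meanings and limitations.

## Worked example

`examples/05_train_and_evaluate.py` runs the whole pipeline on 30 + 30
synthetic recordings (15 epochs, one CPU, a few minutes):

```
60 recordings -> 180 windows; split train/val/test = (132, 24, 27)
  epoch 0: train loss 1.071 acc 0.55 | val loss 0.660 acc 0.62
  ...
  epoch 14: train loss 0.012 acc 1.00 | val loss 0.016 acc 1.00

held-out test (27 windows): accuracy 1.000, sensitivity 1.000, specificity 1.000, AUC 1.000
confusion: {'tp': 15, 'tn': 12, 'fp': 0, 'fn': 0}
```

The 180 windows come from cutting each 10-s recording into three 4-s
windows (the third wrap-padded); the split is grouped by recording, so
the 27 test windows come from recordings the network never saw.
Accuracy is the fraction of test windows labeled correctly at the 0.5
cut; AUC 1.0 means every abnormal window outscored every normal one.
The other examples are single-topic: simulation and band energies (01),
filtering and windowing (02), pitch-shift augmentation (03), and split
bookkeeping (04).

The same workflow is available from a shell:

```bash
pcgnet simulate   --out data --n-normal 30 --n-abnormal 30 --seed 1
pcgnet preprocess --manifest data/manifest.csv --out segs --seed 1
pcgnet train      --store segs/segments.npz --out run --seed 1 --epochs 15
pcgnet evaluate   --checkpoint run/checkpoint.npz --store run/test_segments.npz --out run
```

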