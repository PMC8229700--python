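# heartprint

Single-heartbeat ECG biometric recognition: who is this, from half a
second of heartbeat?

The electrocardiogram is a behavioral-physiological biometric — the
shape of one PQRST complex is stable within a person and distinctive
between people. `heartprint` implements a complete recognition
pipeline around that observation, for signal-processing researchers and
biometrics practitioners who want a reproducible, CPU-friendly
reference implementation:

* **Fiducial detection** — R-peaks from curvature minima with an
  adaptive threshold and search-back; P-peaks from a Hilbert-envelope
  locator in the 245 ms window before each R.
* **Segmentation** — blind fixed windows, R-centered windows, R-R and
  P-P intervals, plus averaging-based augmentation to a fixed
  per-subject segment count.
* **Entropy enhancement** — each segment becomes a continuous wavelet
  transform (CWT) scalogram image; the gain in identity information is
  quantified by the biometric system entropy (BSE), the KL divergence
  between genuine and imposter score densities:
  `BSE = ∫ f_G log(f_G / f_I)`.
* **A small residual CNN** — 27 layers, 324 K learnable parameters
  (100 classes), trained with SGD (momentum 0.9, batch 150, lr 0.001),
  implemented in pure NumPy with verified gradients.
* **Evaluation protocol** — stratified 10-fold and two-fold session
  cross-validation; identification accuracy; verification by
  one-vs-rest collapse of the confusion matrix with
  FRR/FAR/TAR/TRR/HTER, McNemar's test (Yates correction), Fisher-Z
  population summaries and cumulative accuracy distributions.
* **A synthetic ECG generator** — multi-subject, multi-session records
  with exact ground-truth fiducials, so the whole chain is testable
  without downloading any data.

Readers of WFDB (text header, 16-bit format) and single-column CSV are
included; PhysioNet-style corpora can be mapped to subjects/sessions
with a plain-text manifest.

## Worked example

Generate a synthetic two-subject corpus, detect fiducials, and cut
R-centered heartbeats:

```sh
$ heartprint synth --subjects 2 --sessions 1 --duration 20 --seed 4 --out data/
wrote 2 records; manifest data/manifest.txt

$ heartprint detect data/s000_1.csv --fs 500 --out fids.txt
21 R-peaks, 20 P-peaks -> fids.txt

$ heartprint segment data/s000_1.csv --fs 500 --scheme r_centered --window 0.5 --out segs.csv
19 r_centered segments -> segs.csv
```

Each detected record yields one R index per heartbeat (~21 beats in
20 s at a resting rate) and one P-peak for every R with full left
context. The scaled identification experiment — 10 synthetic subjects,
100 scalogram images each, the small CNN at 32 px for 10 epochs,
2-fold cross-validation — prints:

```sh
$ heartprint phase1 --subjects 10 --seed 1 --out phase1.csv
      scheme  window_s  accuracy  n_folds
       blind       0.5     0.190        2
  r_centered       0.5     0.998        2
```

Read: anchoring the 0.5 s window on the R-peak gives 99.8 % held-out
identification accuracy at desk scale, while the same window cut
blindly (random phase relative to the heartbeat) reaches only 19 % —
the segment, not the classifier, carries most of the identity signal.
The entropy analysis makes the same point at the representation level:

```sh
$ heartprint entropy --subjects 20 --seed 1
BSE time-domain: 4.390 nats; CWT-domain: 7.015 nats
```

Genuine and imposter score distributions separate more in the
time–frequency domain than in the time domain — the scalogram image is
the more identity-bearing representation.

The library mirrors the CLI: `synth_ecg` generation, `fiducials`
detection, `segmentation`, `scalogram`, `entropy`, `nn.smallcnn`, and
`experiments.run_phase1/2/3` are all importable functions. A
`phase2`/`phase3` verb runs the session-scenario and
identification/verification analyses on a two-session population.

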