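# seascape

A desk-scale software pipeline for **animal-borne underwater soundscape
logging**. A tag carried by a free-ranging marine animal (the motivating
platform is a green sea turtle) records duty-cycled audio, classifies each
sound on board into a three-level taxonomy — biophony / geophony /
anthrophony at Level 1, down to species, call type or vessel type at
Level 3 — reduces every 5-min recording to a compact top-3 summary, and
transmits summaries and GPS fixes over a 560-byte-packet cellular link in
the few seconds the animal spends at the surface. Onshore, the summaries
become kernel-density *soundscape maps* of where each sound source occurs.

This package re-creates that whole data path in Python so it can be
studied, tested and extended without hardware or field data:

- `seascape.taxonomy` / `seascape.synth` — the 52-class sound library
  (51 sound classes + background) with per-class synthesis archetypes
  (pulse trains, FM tones, harmonic stacks, noise bands) mixed into
  1/f ambient noise at controlled SNR;
- `seascape.deployment` — simulated tag deployments: dive/surfacing
  profile, duty-cycled recordings with ground-truth event schedules,
  60-s sensor sampling, GPS fixes only while surfaced;
- `seascape.prep` — the on-logger chain: 1024-point STFT (0.5 overlap;
  0.9 in the PC variant), log-frequency axis over 60 Hz–20 kHz,
  per-bin temporal-median noise subtraction, sliding 2-s windows,
  192×192 8-bit images (a 300-s recording → 60 segments × 4 = 240 images);
- `seascape.classify` — a scikit-learn-style baseline image classifier
  (multinomial logistic regression on downsampled pixels) standing in for
  the tag's quantized CNN, with Level-3→2→1 roll-up and top-k;
- `seascape.metrics` — Precision/Recall/F-measure, Top-1/Top-5 accuracy
  and confusion matrices at any taxonomy level;
- `seascape.telemetry` — mean-probability top-3 summarization, a bit-exact
  ≤ 560-byte packet codec (≤ 13 records/packet), and the
  surfacing-triggered transmission scheduler with the
  3-consecutive-failure discard rule;
- `seascape.geomap` — GPS↔sound association (±1 h window), the ≥ 2 m
  depth filter, Gaussian-KDE soundscape maps (> 10 points required),
  positioning RMSE and data-recovery bookkeeping.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

```python
import seascape as ss
from seascape import metrics, prep, synth

tax = ss.build_default_taxonomy()
print(f"{len(tax)} classes; Level-1 categories: {tax.level_labels(1)}")

# one labeled clip: a moray-like pulse train at 15 dB SNR over ambient noise
req = ss.SynthesisRequest(class_id=0, duration=5.0, snr_db=15.0, seed=7)
wav = ss.synthesize_sound(tax, req)

# the on-logger chain: 5-s segments -> median-filtered log spectrogram
# -> 2-s windows -> 192x192 images
images = prep.preprocess_recording(wav)
print(f"images from a 5-s recording: {len(images)}")

# train the baseline classifier on a small synthetic set and evaluate
images, labels = synth.make_training_set(tax, examples_per_class=10, snr_db=15.0, seed=0)
(tr_x, tr_y), (te_x, te_y) = ss.split_dataset(images, labels, 0.7, seed=0)
model = ss.train_baseline(tr_x, tr_y, tax, seed=0)
pvs = [model.predict_vector(im) for im in te_x]
for level in (1, 2, 3):
    top1 = metrics.accuracy(te_y, pvs, tax, k=1, level=level)
    top5 = metrics.accuracy(te_y, pvs, tax, k=5, level=level)
    print(f"Level {level}: Top-1 {100*top1:.1f}%  Top-5 {100*top5:.1f}%")
```

prints

```
52 classes; Level-1 categories: ('biophony', 'anthrophony', 'geophony', 'background')
images from a 5-s recording: 4
Level 1: Top-1 92.9%  Top-5 99.4%
Level 2: Top-1 88.5%  Top-5 98.7%
Level 3: Top-1 78.2%  Top-5 93.6%
```

The accuracies are held-out scores on the *synthetic* library at 10
examples per class: Top-5 beats Top-1 and coarse levels beat fine ones by
construction, and accuracy rises further at the default 40 examples per
class. They characterize the pipeline, not field recordings.

A command-line interface mirrors the stages: `seascape generate`,
`preprocess`, `train`, `classify`, `summarize`, `transmit-sim`, `evaluate`
and `map` (see `seascape --help`).

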