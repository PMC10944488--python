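# Methods

`seascape` is a desk-scale re-creation of the data path of an animal-borne
underwater soundscape logger: a tag on a free-ranging marine animal records
duty-cycled audio, classifies it on board into a three-level sound-source
taxonomy, reduces each recording to a compact summary, and transmits
summaries and GPS positions opportunistically while the animal surfaces to
breathe. Because the original field sound library is not available, the
package ships a synthetic stand-in for every stage, so the whole chain can
be exercised, tested and measured on one CPU with no external data.

## Sound taxonomy and synthetic library

The default library has 52 classes: 51 sound classes organized as
biophony → {fish, marine mammals, invertebrates}, geophony → {waves, rain},
anthrophony → {vessels, construction, active acoustics}, plus one
*background* class (ambient noise with no identifiable event) that sits
outside the three categories. Class parameters live in a shipped JSON file
(`seascape/data/default_taxonomy.json`), so the library is data, not code.

Each class is realized by one of four archetypes:

- **pulse trains** (fish knocks and drumming, snapping, pile driving):
  Gabor clicks of a class-specific center frequency and bandwidth repeated
  at the class's pulse rate with small amplitude jitter;
- **FM tones** (whistles, moans, pings): a sinusoid whose instantaneous
  frequency sweeps the class's band sinusoidally at 1–3 Hz;
- **harmonic stacks** (vessel engine/propeller lines): harmonics of a
  fundamental with 1/h amplitude decay, slight detuning, and a slow
  amplitude throb;
- **noise bands** (waves, rain, crackle): Gaussian noise band-passed with
  raised-cosine edges.

All event energy is confined to the observed band of 60 Hz–20 kHz
(verified spectrally per class). The background is Gaussian noise with a
1/f power tilt — the simplest stationary surrogate for ambient ocean noise
that the median filter is meant to remove. SNR is defined as the RMS ratio
of event to background *inside the event's nominal band*; mixing is scaled
to hit the requested SNR exactly, and tests require the achieved value
within 1 dB. Every waveform is a pure function of (parameters, seed), mono,
44.1 kHz, 16-bit.

Per-class parameter choices are plausible rather than faithful: no
propagation, multipath, or species-accurate call modeling is attempted.
Class bands were placed so that classes of *different* Level-1 categories
rarely share a band; residual overlap (e.g. broadband snapping vs. mid-band
construction noise) is deliberate and bounds what the classifier can do.

## On-logger pre-processing

The chain (in `seascape.prep`) matches the logger arithmetic exactly:

1. a 300-s recording splits into sixty 5-s segments (tails shorter than 5 s
   are dropped, as firmware reads fixed blocks);
2. each segment gets a 1024-point Hann STFT at 0.5 overlap (hop 512;
   a 5-s segment yields floor((220500−1024)/512)+1 = 429 frames). The
   PC-side variant uses 10-s segments at 0.9 overlap. Magnitudes are
   converted to dB (full-scale sine ≈ 0 dB) with a −100 dB floor and
   interpolated onto 192 geometrically spaced frequency bins from 60 Hz to
   20 kHz;
3. the per-frequency-bin **temporal median** over the segment is
   subtracted and negative residuals clip to the floor. The median over a
   5-s context estimates the stationary background as long as an event
   occupies under half the frames, which the event-placement model
   guarantees; a kernel-based 2-D median was rejected because it would blur
   exactly the transients we want to keep;
4. a 2-s window slides in 1-s steps (4 windows per 5-s segment, 9 per
   10-s), and each window is resampled to 192 time columns and min–max
   normalized to an 8-bit 192×192 image. A window with no dynamic range
   renders mid-gray rather than dividing by zero.

So a 5-min recording yields 60 × 4 = 240 images. One printed description
of the horizontal resolution (0.015 s per pixel) is inconsistent with
2 s ÷ 192 columns ≈ 0.0104 s; the implementation uses 2 s ÷ 192.

Arithmetic is double precision; the original firmware computes in single
precision, and the pipeline's contract is stability to ~1e-4 relative, not
bit-reproduction of the device.

## Classifier

The original system runs a quantized MobileNet on the tag. Reproducing
that model is out of scope; the baseline here is multinomial logistic
regression on 4×4-block-averaged (48×48), standardized pixels, exposed as
a scikit-learn estimator (`SpectroImageClassifier`). It trains in seconds
on a CPU, is seed-deterministic, and is *pluggable* — anything with
`fit`/`predict_proba` over 192×192 tiles can stand in.

Training uses Level-3 labels only. Level-2/Level-1 predictions are the
taxonomy parents of the Level-3 argmax ("implicit" coarse classification);
this makes the accuracy ordering Level 1 ≥ Level 2 ≥ Level 3 a provable
property, which the suite checks. A summed-child-mass roll-up is available
as an option. All ties (argmax, top-k, roll-up) break toward the lowest
class id.

Training clips are 5-s segments with the event occupying a random 1.2–2.2-s
sub-interval — the same placement distribution the deployment simulator
uses — reduced to the 2-s window best covering the event. Matching the two
distributions matters: a classifier trained only on perfectly centered
events degrades sharply on deployment audio where windows cover events
partially.

Under the default study conditions (52 classes, 40 examples per class,
15 dB SNR, stratified 70/30 split) the suite requires held-out Level-1
Top-1 accuracy ≥ 0.85. This is a property bar for the synthetic library,
not a claim about field data: synthetic classes are cleaner, the background
is stationary, and there is no propagation loss, so these numbers say the
*pipeline* works, not that real reef recordings would classify this well.

## Evaluation

`seascape.metrics` implements the standard one-vs-rest decomposition:
Precision = TP/(TP+FP), Recall = TP/(TP+FN), F = 2RP/(R+P), and Top-1/Top-5
accuracy, each computable at any taxonomy level via parent mapping.
Averaging is macro by default with micro as an option, both labeled —
single-number-per-level reports elsewhere do not always state the mode. A
class never predicted has undefined precision; it scores 0 and is flagged.
Structural identities (micro recall = Top-1 accuracy; Top-5 ≥ Top-1;
coarse ≥ fine; permutation invariance) are tested on random label sets.
Background is included as a class by default and can be excluded by flag.

## Telemetry

Each recording reduces to one record: per-class probabilities averaged over
all 240 images, the top three classes by mean probability (highest first),
plus depth, temperature, and the vector magnitudes √(x²+y²+z²) of
acceleration and geomagnetism sampled at the recording start. Transmitting
the top three *with* their mean probabilities keeps the summary auditable;
whether the original tag sent the probabilities is not documented.

The packet codec is self-describing, little-endian: a 7-byte header
(magic, version, device id, sequence, count) and up to 13 records per
packet — classification records of 19 bytes (1-byte class ids, so up to
256 classes; probabilities quantized to 1/255, depth to 1 cm, temperature
to 0.01 °C, acceleration to 1 mg, magnetic field to 0.1 µT) and position
records of 14 bytes (lat/lon as signed 1e-5°, error ≤ 10⁻⁵ degree
≈ 1 m). Worst case 7 + 13×19 = 254 bytes, far under the 560-byte link
limit. Integer fields round-trip exactly; quantization bounds are enforced
with errors naming the offending field, and malformed payloads decode to
structured errors carrying the byte offset.

The transmission scheduler replays the tag's policy: transmission is
possible only while surfaced; the modem costs a uniform 6–10-s activation
delay per attempt (so a ~10-s breath usually allows one attempt); the
oldest unsent packet whose data already exists goes first; three
consecutive failures of the same packet discard it (counter resets on a
success); nothing is sent twice. Discard granularity is the packet — the
documented behavior ("the data is discarded") does not say whether a datum
or a packet is dropped, and packet granularity is the declared choice. The
suite checks the scheduler against an independent discrete-event replay on
100 randomized scenarios.

## Deployment simulator

A deployment emulates a tagged sea turtle: 5-min recordings every 30 min,
sensors every 60 s, dives to a uniform-random depth in 2–15 m with linear
descent/ascent ramps, surfacings of ~10 s (normal, sd 2 s, floor 3 s), and
exponential inter-surfacing intervals with a 6-min mean — a plausible
shallow-water foraging/resting rhythm; only the ~10-s surfacing duration is
documented, the rest is the generator's own choice. GPS fixes occur only
during surfacings, succeed with probability 0.9, and carry 22.6 m per-axis
Gaussian error so the 2-D RMSE of fixes around a stationary animal is
~32 m, the scale reported for surfacing-triggered fast-fix GPS in a tank
evaluation. The animal drifts (σ = 100 m) around one or more *sites*, each
optionally restricted to a subset of sound classes, which is what lets an
end-to-end run check that a site-restricted class maps back to its site.
Sound events are scheduled per 5-s segment with a configurable probability
and the same placement distribution as training clips; the ground-truth
label of every segment is logged. Audio renders lazily per recording from
a stored per-recording seed, so simulating long deployments is cheap until
waveforms are needed.

## Soundscape mapping

Summaries are geo-tagged with the nearest GPS fix within one hour before
or after the sound (an exact tie prefers the earlier fix — the position
observed before the sound); records without a qualifying fix stay unmapped.
Near-surface records are dropped with an inclusive ≥ 2 m depth filter,
since surface currents and waves contaminate shallow classifications.
Per-class density uses a separable Gaussian KDE on a lat/lon grid:
Scott's-rule bandwidth per axis (floored so coincident points stay
finite), grid padded by five bandwidths so the density integrates to 1
within 2%. The "more than 10 points" rule is strict (≥ 11) with an
explicit override. Distances are great-circle (haversine, mean Earth
radius), adequate at the tens-of-km scale. Recovery bookkeeping reports
both pooled-count and mean-of-ratio recovery percentages (the published
field rates do not say which pooling was used), restricted to deployments
with at least one successful transmission, with duration mean/sd over all
deployments.

## Problem sizes and seeds

Default test/acceptance sizes are deliberately desk-scale: 40 clips per
class for training (2 080 images), 1 000 codec fuzz cases, 100 scheduler
scenarios, and a 24-h simulated deployment with 25-s recordings for the
end-to-end map check — sizes at which every stage's behavior is already
fully exercised. All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`, so any run is exactly reproducible.

## Known limitations

- The synthetic library does not imitate real species; absolute accuracy
  numbers on it do not transfer to field recordings, and published
  field-model accuracies are not reproducible without the original
  5 999-sample library.
- The background model is stationary; real ambient noise is not, and the
  median filter's effectiveness on nonstationary noise is untested here.
- No open-set handling: sounds outside the taxonomy will be absorbed by
  the nearest class.
- The scheduler models only packet-size and timing constraints, not a real
  cellular/MQTT stack; energy, RAM and flash budgets of the device are out
  of scope.
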