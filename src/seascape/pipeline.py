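"""End-to-end glue: run the on-logger chain over a simulated deployment."""

from __future__ import annotations

from . import deployment as dep
from .classify import ProbabilityVector, SpectroImageClassifier
from .prep import preprocess_recording
from .taxonomy import SoundTaxonomy
from .telemetry import ClassificationSummary, summarize_window


def classify_deployment(
    dataset: dep.DeploymentDataset,
    model: SpectroImageClassifier,
    taxonomy: SoundTaxonomy,
) -> list[ClassificationSummary]:
    """Render, preprocess, classify and summarize every recording.

    This is the logger's per-recording data path: waveform -> spectrogram
    images -> per-image probability vectors -> one mean-probability top-3
    summary with the sensor context at the recording start.
    """
    class_ids = tuple(int(c) for c in model.classes_)
    summaries = []
    for rec in dataset.recordings:
        wav = dep.render_recording(rec, taxonomy, snr_db=dataset.plan.snr_db)
        images = preprocess_recording(wav, source_recording_id=rec.recording_id)
        probs = model.predict_proba(images)
        pvs = [ProbabilityVector(class_ids, p) for p in probs]
        sensor = dep.sensor_sample_at(dataset, rec.start_time_s)
        summaries.append(summarize_window(pvs, sensor, rec.start_time_s))
    return summaries
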