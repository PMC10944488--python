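import pytest

import seascape as ss
from seascape import classify, synth


@pytest.fixture(scope="session")
def taxonomy():
    return ss.build_default_taxonomy()


@pytest.fixture(scope="session")
def trained_library(taxonomy):
    """Baseline classifier trained under the study conditions.

    40 examples per class at 15 dB SNR over the full 52-class library,
    stratified 70/30 split.  Returns (model, test_labels, test_prob_vectors).
    Session-scoped: training runs once for the whole suite.
    """
    images, labels = synth.make_training_set(taxonomy, examples_per_class=40, snr_db=15.0, seed=0)
    (tr_x, tr_y), (te_x, te_y) = classify.split_dataset(images, labels, 0.7, seed=0)
    model = classify.train_baseline(tr_x, tr_y, taxonomy, seed=0)
    probs = model.predict_proba(te_x)
    class_ids = tuple(int(c) for c in model.classes_)
    pvs = [classify.ProbabilityVector(class_ids, p) for p in probs]
    return model, te_y, pvs


@pytest.fixture(scope="session")
def mini_model(taxonomy):
    """Small 6-class model (one class per Level-2-ish group) for fast tests."""
    ids = [0, 15, 25, 31, 45, 51]
    images, labels = [], []
    for cid in ids:
        for k in range(8):
            clip = synth.synthesize_training_clip(taxonomy, cid, seed=k, snr_db=18.0)
            images.append(synth.training_image(taxonomy, clip))
            labels.append(cid)
    (tr_x, tr_y), (te_x, te_y) = classify.split_dataset(images, labels, 0.7, seed=0)
    model = classify.train_baseline(tr_x, tr_y, taxonomy, seed=0)
    return model, (te_x, te_y)
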