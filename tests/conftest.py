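"""Shared fixtures: the synthetic study system and a trained classifier.

The trained pipeline model is expensive (minutes), so it is built once per
session and shared by the training-dependent tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from etnet.genomio import one_hot_encode
from etnet.model import build_model, reduced_config
from etnet.synthfix import FixtureSpec, fixture_dataset, make_fixture, make_sequence_pairs
from etnet.traineval import manifest_tensors, train_arrays

FIXTURE_SEED = 11
TRAIN_WINDOW = 320


@pytest.fixture(scope="session")
def study_system():
    """Default synthetic genome/enhancers/loops with ground truth."""
    return make_fixture(FixtureSpec(seed=FIXTURE_SEED))


@pytest.fixture(scope="session")
def study_manifest(study_system):
    """Balanced labeled dataset manifest built from the study system."""
    return fixture_dataset(study_system, neg_strategy="random", seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def study_tensors(study_system, study_manifest):
    return manifest_tensors(study_manifest, study_system.genome, TRAIN_WINDOW)


@pytest.fixture(scope="session")
def trained_pipeline(study_system, study_tensors):
    """Reduced-config classifier trained end-to-end on the study system."""
    cfg = reduced_config(seq_len=TRAIN_WINDOW, conv_channels=24)
    model = build_model(cfg, seed=1)
    history = train_arrays(model, study_tensors["train"], study_tensors["validation"],
                           lr=1e-3, epochs=100, batch_size=50, seed=3)
    return model, history


def _encode(seqs):
    return np.stack([one_hot_encode(s) for s in seqs])


@pytest.fixture(scope="session")
def overfit_run():
    """Reduced-config model overfit on 200 planted-motif sequence pairs."""
    lefts, rights, labels = make_sequence_pairs(200, 200, seed=7)
    xl, xr = _encode(lefts), _encode(rights)
    model = build_model(reduced_config(), seed=1)
    history = train_arrays(model, (xl, xr, labels), val_data=None, lr=1e-3,
                           epochs=100, batch_size=50, seed=3)
    return model, (xl, xr, labels), history


@pytest.fixture(scope="session")
def motif_model():
    """Motif-driven classifier: trained on a stream of sequence pairs (a
    fresh sample every epoch), so memorization cannot reduce the loss and
    the model must learn the planted motif-co-occurrence rule. Used by the
    attribution and SNP analyses."""
    val = make_sequence_pairs(100, 200, seed=8)

    def stream(epoch):
        p = make_sequence_pairs(300, 200, seed=5000 + epoch)
        return _encode(p.lefts), _encode(p.rights), p.labels

    model = build_model(reduced_config(), seed=1)
    train_arrays(model, stream,
                 val_data=(_encode(val[0]), _encode(val[1]), val[2]),
                 lr=1e-3, epochs=150, batch_size=50, seed=3)
    return model


@pytest.fixture
def tiny_model():
    """Small untrained model for fast contract tests."""
    cfg = reduced_config(seq_len=40, conv_channels=4, mlp_hidden=8, n_heads=2,
                         d_value_total=8, d_qk_total=8, ffn_dim=16, head_hidden=4)
    return build_model(cfg, seed=0)
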