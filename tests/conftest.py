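"""Shared fixtures: a desk-scale pretrained network and synthetic data.

The pretrained model is session-scoped because CPU pretraining is the
most expensive fixture; every consumer treats it as read-only.
"""

import numpy as np
import pytest

from cxrfuse.model import FusionNet, ModelConfig
from cxrfuse.synthetic import CohortSimParams, generate_multilabel_images
from cxrfuse.training import TrainConfig, pretrain

PRETRAIN_STREAM_SIZE = 300
DESK_INPUT = 64


@pytest.fixture(scope="session")
def pretrained_model():
    """Two-branch network pretrained on a synthetic 14-label stream at
    the desk-scale profile (64 px, 10 epochs x 60 steps, batch 8)."""
    model = FusionNet(ModelConfig.desk_scale(input_size=DESK_INPUT, seed=0))
    images, labels = generate_multilabel_images(
        CohortSimParams(n_patients=PRETRAIN_STREAM_SIZE, seed=100))
    model, history = pretrain(model, images, labels,
                              TrainConfig.desk_scale(seed=0))
    model.history = history
    return model


@pytest.fixture(scope="session")
def eval_stream():
    """Held-out multilabel images never seen in pretraining."""
    return generate_multilabel_images(
        CohortSimParams(n_patients=250, seed=200))


@pytest.fixture(scope="session")
def label_aucs(pretrained_model, eval_stream):
    """Per-label ROC-AUC of the pretrained network on the held-out
    stream: which finding channels the network actually learned."""
    from sklearn.metrics import roc_auc_score

    images, labels = eval_stream
    p = pretrained_model.extract_latent(images, layer=-1, batch_size=32)
    return np.array([roc_auc_score(labels[:, j], p[:, j])
                     for j in range(labels.shape[1])])
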