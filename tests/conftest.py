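"""Shared fixtures: the synthetic study dataset and the with/without-gaze
ablation runs reused by the training-behavior and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from gazecam.attention import (compute_network_attention, create_tiny_bundle,
                               forward)
from gazecam.evaluation import attention_alignment
from gazecam.gaze import render_gaze_map
from gazecam.synthetic import PhantomSpec, ScanpathSpec, generate_dataset
from gazecam.training import Sample, TrainConfig, evaluate_accuracy, train

# Desk-scale study conditions: 30 patients of 64x64 phantoms (~150/50/50
# images per split), gaze rendered at sigma = img_size/10.
GAZE_SIGMA = 6.4
GAZE_TAPS = 39
ABLATION_SEEDS = (0, 1, 2)
ABLATION_EPOCHS = 30


def build_split_samples(seed: int = 0, n_patients: int = 30):
    """Generate the synthetic study and render its gaze maps."""
    records, manifest = generate_dataset(
        PhantomSpec(n_patients=n_patients, seed=seed), ScanpathSpec(), seed=seed)
    split = dict(zip(manifest["image_id"], manifest["split"]))
    out = {"train": [], "val": [], "test": []}
    for r in records:
        gm = render_gaze_map(r.fixations, r.image.shape[1], r.image.shape[0],
                             sigma=GAZE_SIGMA, kernel_taps=GAZE_TAPS).values
        out[split[r.image_id]].append(
            Sample(r.image_id, r.image, r.label, gm, r.mask))
    return out


def run_arm(samples, lambda_gaze: float, seed: int, epochs: int = ABLATION_EPOCHS):
    """Train one ablation arm; return (test accuracy, mean attention IoU, state)."""
    cfg = TrainConfig(max_epochs=epochs, lambda_gaze=lambda_gaze, seed=seed)
    model = create_tiny_bundle(num_classes=3, input_size=64, seed=seed)
    best, state = train(model, samples["train"], samples["val"], cfg)
    acc = evaluate_accuracy(best, samples["test"])
    ious = []
    for s in samples["test"]:
        logits, fmap = forward(best, s.image)
        att = compute_network_attention(fmap, best, int(np.argmax(logits)),
                                        s.image.shape[0], s.image.shape[1])
        ious.append(attention_alignment(att, s.mask))
    return acc, float(np.mean(ious)), state


@pytest.fixture(scope="session")
def study_samples():
    return build_split_samples(seed=0)


@pytest.fixture(scope="session")
def ablation_results(study_samples):
    """Paired-seed with/without-gaze runs at the study conditions."""
    results = {}
    for seed in ABLATION_SEEDS:
        for lam in (1.0, 0.0):
            results[(lam, seed)] = run_arm(study_samples, lam, seed)
    return results


@pytest.fixture(scope="session")
def tiny_train_samples():
    """A 20-image set (6 patients) for fast training-behavior tests."""
    records, _ = generate_dataset(PhantomSpec(n_patients=6, seed=3),
                                  ScanpathSpec(), seed=3)
    samples = []
    for r in records[:20]:
        gm = render_gaze_map(r.fixations, 64, 64, sigma=GAZE_SIGMA,
                             kernel_taps=GAZE_TAPS).values
        samples.append(Sample(r.image_id, r.image, r.label, gm, r.mask))
    return samples
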