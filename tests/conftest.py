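"""Shared fixtures.

``phantom_recovery_runs`` is the expensive session fixture: for three fixed
seeds it generates a 400-slice four-class noise-free phantom cohort, runs
the preprocessing tail, trains the desk-scale VAE, calibrates rectangular
boundaries on a stratified labelled half and evaluates class agreement on
the held-out half.  Several tests (cluster separation, end-to-end recovery)
share its results so training happens once per session per seed.
"""

from __future__ import annotations

import numpy as np
import pytest

import plaquevae as pv
from plaquevae.classify import calibrate_boundaries, classify_points
from plaquevae.preprocess import standardize_slice

E2E_SEEDS = (1, 2, 3)
SLICES_PER_CLASS = 100
E2E_EPOCHS = 100


@pytest.fixture(scope="session")
def four_class_stack():
    """Small noise-free stack with one slice per class (deterministic)."""
    spec = pv.PhantomSpec(class_sequence=(1, 2, 3, 4), noise_sd=0.0, seed=11)
    return pv.generate_phantom(spec, lesion_id="mini")


def _recovery_run(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    seq = tuple(
        rng.permutation(
            [1] * SLICES_PER_CLASS
            + [2] * SLICES_PER_CLASS
            + [3] * SLICES_PER_CLASS
            + [4] * SLICES_PER_CLASS
        ).tolist()
    )
    stack = pv.generate_phantom(
        pv.PhantomSpec(class_sequence=seq, noise_sd=0.0, seed=seed)
    )
    images = np.stack([standardize_slice(sl) for sl in stack.slices])
    labels = np.asarray(stack.labels)
    config = pv.VaeConfig.desk_scale(seed=seed, epochs=E2E_EPOCHS)
    results = pv.TissueVAE(images, config).fit()
    points = results.encode(images)
    held_in = np.zeros(len(labels), dtype=bool)
    for c in (1, 2, 3, 4):
        idx = np.nonzero(labels == c)[0]
        held_in[rng.choice(idx, size=len(idx) // 2, replace=False)] = True
    boundaries, cal_agreement = calibrate_boundaries(
        points[held_in], labels[held_in]
    )
    predicted = classify_points(points[~held_in], boundaries)
    agreement = float(np.mean(predicted == labels[~held_in]))
    return {
        "seed": seed,
        "results": results,
        "points": points,
        "labels": labels,
        "held_in": held_in,
        "boundaries": boundaries,
        "calibration_agreement": cal_agreement,
        "held_out_agreement": agreement,
    }


@pytest.fixture(scope="session")
def phantom_recovery_runs():
    return [_recovery_run(seed) for seed in E2E_SEEDS]
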