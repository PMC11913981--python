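"""Desk-scale end-to-end workflows on the synthetic spine phantom.

Convenience wrappers that assemble the pieces — phantom cohort generation,
preprocessing to the [-1, 1] scale, two-stage training and chained
inference — at sizes a laptop CPU handles in minutes.  These are the
configurations exercised by the example scripts and the end-to-end tests;
real-data training would use the defaults in :mod:`spinesynth.model`
(patch (16, 192, 192) or (16, 256, 256), learning rate 2e-5) instead.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .model import GeneratorConfig, TrainConfig, TASKS, train
from .phantom import (
    MODALITIES,
    PhantomSpec,
    build_tissue_map,
    random_spec,
    render_study,
)
from .volume import rescale_intensity

__all__ = [
    "DESK_PHANTOM",
    "desk_train_config",
    "desk_generator_config",
    "make_phantom_cohort",
    "lesion_mask",
    "constant_baseline_l1",
    "copy_baseline_l1",
]

#: phantom template for desk-scale runs: small enough for CPU training,
#: large enough that the (16, 64, 64) training patch is a genuine random crop
DESK_PHANTOM = PhantomSpec(
    shape=(20, 72, 72), spacing=(3.0, 1.1, 1.1), n_vertebrae=4, disc_thickness=4,
    noise_sd=0.02,
)


def desk_train_config(task: str, seed: int = 0, epochs: int = 30) -> TrainConfig:
    """Desk-scale training conditions: patch (16, 64, 64), Adam lr 1e-3.

    The learning rate is raised from the full-scale default 2e-5 because the
    toy networks (base width 8) see only a few hundred optimizer steps.
    """
    return TrainConfig(
        learning_rate=1e-3,
        batch_size=3,
        patch_size=(16, 64, 64),
        epochs=epochs,
        replication_factor=1,
        resolution_range=None,
        jitter=True,
        seed=seed,
    )


def desk_generator_config(task: str) -> GeneratorConfig:
    n_inputs = len(TASKS[task][0])
    return GeneratorConfig(in_channels=n_inputs + 3, base_channels=8, levels=3)


def make_phantom_cohort(n_subjects: int, seed: int = 0, template: PhantomSpec = DESK_PHANTOM):
    """Randomized phantom subjects ready for training.

    Returns ``(studies, specs)``: ``studies`` maps subject id to
    {modality: ImageVolume} rescaled to [-1, 1] on a common grid, ``specs``
    holds the per-subject :class:`~spinesynth.phantom.PhantomSpec` (lesion
    ground truth included).
    """
    rng = np.random.default_rng(seed)
    studies, specs = {}, {}
    for s in range(n_subjects):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = random_spec(template, sub_seed)
        raw = render_study(spec)
        studies[f"sub-{s:03d}"] = {m: rescale_intensity(raw[m]) for m in MODALITIES}
        specs[f"sub-{s:03d}"] = spec
    return studies, specs


def lesion_mask(spec: PhantomSpec, kinds=("modic1",)) -> np.ndarray:
    """Boolean mask of the lesion voxels of the given kinds, and the vertebra mask."""
    t = build_tissue_map(spec)
    lesion = np.zeros(t.labels.shape, dtype=bool)
    ii, jj, kk = np.indices(t.labels.shape, dtype=float)
    for les in spec.lesions:
        if les.kind in kinds:
            c = les.center
            lesion |= ((ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2) <= les.radius**2
    vertebra = t.labels == 1
    return lesion, vertebra


def constant_baseline_l1(studies: dict, task: str) -> float:
    """Validation L1 of the best constant predictor (per-volume target mean)."""
    target = TASKS[task][1]
    errs = []
    for study in studies.values():
        y = study[target].data
        errs.append(float(np.mean(np.abs(y - y.mean()))))
    return float(np.mean(errs))


def copy_baseline_l1(studies: dict, task: str, source: str = "t2w") -> float:
    """Validation L1 of simply passing the T2w input through as the prediction."""
    target = TASKS[task][1]
    errs = []
    for study in studies.values():
        errs.append(float(np.mean(np.abs(study[source].data - study[target].data))))
    return float(np.mean(errs))
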