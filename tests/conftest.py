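"""Shared fixtures: phantom participants and small synthetic volumes."""

from __future__ import annotations

import numpy as np
import pytest

from tlfmri.core import LabeledVolume, REQUIRED_LABELS, VolumeGrid
from tlfmri.phantom import PhantomConfig, generate_anatomy, generate_dataset
from tlfmri.pipeline import run_task_pipeline


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig(seed=0)


@pytest.fixture(scope="session")
def anatomy(default_config):
    return generate_anatomy(default_config)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One full phantom participant (task + rest) at the default settings."""
    return generate_dataset(default_config)


@pytest.fixture(scope="session")
def task_result(dataset):
    return run_task_pipeline(
        dataset.labels, dataset.task_runs, dataset.task_schedules, dataset.task_motion
    )


def make_minimal_labels(shape=(16, 16, 16)) -> LabeledVolume:
    """Tiny hand-built label volume with every required name present.

    Structures are single small blobs placed far apart; useful for unit
    tests of mask algebra that need full validity but simple geometry.
    """
    grid = VolumeGrid(shape)
    labels = np.zeros(shape, dtype=np.int16)
    label_map = {name: i + 1 for i, name in enumerate(REQUIRED_LABELS)}
    # lay each non-brain structure out as a distinct single voxel along a line
    coords = iter(
        (x, y, z)
        for z in (2, 5, 8, 11)
        for y in (2, 5, 8, 11)
        for x in (2, 5, 8, 11)
    )
    for name in REQUIRED_LABELS:
        if name == "brain":
            continue
        x, y, z = next(coords)
        labels[x, y, z] = label_map[name]
    brain_fill = labels == 0
    brain_fill[0, :, :] = brain_fill[-1, :, :] = False
    brain_fill[:, 0, :] = brain_fill[:, -1, :] = False
    brain_fill[:, :, 0] = brain_fill[:, :, -1] = False
    labels[brain_fill] = label_map["brain"]
    return LabeledVolume(grid=grid, labels=labels, label_map=label_map)


@pytest.fixture()
def minimal_labels() -> LabeledVolume:
    return make_minimal_labels()
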