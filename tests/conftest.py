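"""Shared fixtures.

Heavy artifacts (the seeded benchmark dataset and the trained selected
networks) are session-scoped so the acceptance benchmarks, the cascade
sanity run and the directional head/crop comparisons all reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from irgaze.geometry import DeviceGeometry, EyeParams, EyeState, \
    optic_axis_from_visual
from irgaze.synth import generate_dataset

BENCH_SEED = 7


@pytest.fixture(scope="session")
def dev() -> DeviceGeometry:
    return DeviceGeometry()


@pytest.fixture(scope="session")
def params() -> EyeParams:
    return EyeParams()


def random_eye_state(rng: np.random.Generator, dev: DeviceGeometry,
                     params: EyeParams, z: float | None = None):
    """An eye fixating a random screen point from a realistic pose."""
    if z is None:
        z = rng.uniform(220, 380)
    c = np.array([z * np.tan(np.radians(rng.uniform(-2, 2))),
                  z * np.tan(np.radians(rng.uniform(6, 10.5))), z])
    target = np.array([rng.uniform(10, dev.screen_size[0] - 10),
                       rng.uniform(10, dev.screen_size[1] - 10)])
    v = dev.screen_to_camera(target) - c
    v /= np.linalg.norm(v)
    return EyeState(c, optic_axis_from_visual(v, params)), target


@pytest.fixture(scope="session")
def small_dataset():
    """A light dataset for renderer/dataset statistics tests."""
    return generate_dataset(8, 20, seed=3, n_aug=2)


@pytest.fixture(scope="session")
def benchmark_dataset_session():
    from irgaze.benchmarks import benchmark_dataset
    return benchmark_dataset(BENCH_SEED)


@pytest.fixture(scope="session")
def trained_classifier(benchmark_dataset_session):
    from irgaze.benchmarks import classifier_benchmark
    net, acc, n_val, hist = classifier_benchmark(benchmark_dataset_session,
                                                 BENCH_SEED)
    return {"net": net, "accuracy": acc, "n_val": n_val, "history": hist}


@pytest.fixture(scope="session")
def trained_pupil_fine(benchmark_dataset_session):
    from irgaze.benchmarks import position_benchmark
    net, err, gross, n_val, hist = position_benchmark(
        benchmark_dataset_session, "pupil_fine", "pupil", BENCH_SEED)
    return {"net": net, "mean_err": err, "gross": gross, "n_val": n_val,
            "history": hist}


@pytest.fixture(scope="session")
def trained_cr_a(benchmark_dataset_session):
    from irgaze.benchmarks import position_benchmark
    net, err, gross, n_val, hist = position_benchmark(
        benchmark_dataset_session, "cr_a", "glint_a", BENCH_SEED)
    return {"net": net, "mean_err": err, "gross": gross, "n_val": n_val,
            "history": hist}
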