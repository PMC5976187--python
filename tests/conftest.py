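"""Shared fixtures: phantoms and their cost images are expensive, so they
are built once per session and reused across test modules."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import vesseltrace as vt
from vesseltrace import cooperative as coop
from vesseltrace import cost as cost_mod
from vesseltrace import phantom as ph

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


class PhantomBundle:
    """A rendered phantom with its cost image and resampled truth curves."""

    def __init__(self, spec, omega: float = 1.0):
        self.spec = spec
        self.seq1, self.seq2, self.truth = ph.make_phantom(spec)
        params = ph.study_cost_params(spec, omega=omega)
        image = cost_mod.multispectral_cost([self.seq1, self.seq2], self.truth.seeds, params)
        self.cost = cost_mod.crop_roi(image, self.truth.seeds)
        self.seeds = self.truth.seeds
        delta = 0.1
        self.manual_ica = vt.resample_path(self.truth.centerline_ICA.points, delta)
        self.manual_eca = vt.resample_path(self.truth.centerline_ECA.points, delta)
        self._results = {}

    def result(self, method: str):
        if method not in self._results:
            self._results[method] = coop.run_method(method, self.cost, self.seeds)
        return self._results[method]


@pytest.fixture(scope="session")
def clean_bundle():
    return PhantomBundle(ph.PhantomSpec())


@pytest.fixture(scope="session")
def faint_bundle():
    return PhantomBundle(ph.faint_branch_preset())


@pytest.fixture(scope="session")
def noise_free_bundle():
    spec = replace(ph.PhantomSpec(), noise_sd=0.0)
    return PhantomBundle(spec)


def mean_pairwise_distance(path_a, path_b, z_min: float) -> float:
    """Symmetric mean of point-to-other-curve distances for the path
    portions above z_min (used to quantify post-bifurcation coincidence)."""
    from scipy.spatial import cKDTree

    a = path_a.points[path_a.points[:, 2] > z_min]
    b = path_b.points[path_b.points[:, 2] > z_min]
    da, _ = cKDTree(b).query(a)
    db, _ = cKDTree(a).query(b)
    return 0.5 * (float(da.mean()) + float(db.mean()))


def min_distance_beyond_kappa(result, x_bif) -> float:
    """Minimum inter-centerline distance beyond each path's constraint start."""
    from scipy.spatial import cKDTree

    ia = coop.constraint_start(result.centerline_ICA, x_bif)
    ib = coop.constraint_start(result.centerline_ECA, x_bif)
    a = result.centerline_ICA.points[ia:]
    b = result.centerline_ECA.points[ib:]
    return float(cKDTree(b).query(a)[0].min())
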