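"""Shared fixtures: reference parameter sets and a scriptable fake RNG."""

import warnings

import numpy as np
import pytest

from woundca import CAParams


@pytest.fixture(autouse=True)
def _silence_range_warnings():
    """Physiological-range warnings are exercised explicitly in dedicated
    tests; elsewhere they are noise."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def id2_params():
    """HT-1080 condition Id 2: dense monolayer, 371 µm wound."""
    return CAParams(tm=0.075, td=24.0, rho=2.9e-3, delta=20.0, b0=371.0, seed=0)


@pytest.fixture
def small_params():
    """A fast-running mid-box condition on a small lattice."""
    return CAParams(tm=0.1, td=24.0, rho=2.5e-3, delta=20.0, b0=120.0, seed=0)


class ScriptedRNG:
    """Stands in for a numpy Generator, replaying scripted draws.

    ``permutations`` maps a size to the permutation to return; ``uniforms``
    is consumed in order by ``random`` calls (scalar per requested element).
    """

    def __init__(self, permutations=None, uniforms=()):
        self._perms = dict(permutations or {})
        self._uniforms = list(uniforms)

    def permutation(self, n):
        if n in self._perms:
            return np.asarray(self._perms[n], dtype=np.int64)
        return np.arange(n, dtype=np.int64)

    def random(self, size=None):
        if size is None:
            return self._uniforms.pop(0)
        shape = (size,) if np.isscalar(size) else tuple(size)
        count = int(np.prod(shape))
        vals = [self._uniforms.pop(0) for _ in range(count)]
        return np.asarray(vals, dtype=float).reshape(shape)
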