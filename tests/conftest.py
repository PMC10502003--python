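"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's own code paths: surface
distances by exhaustive all-pairs search over explicitly enumerated
boundary voxels, quantiles by direct sort-and-interpolate.
"""

from __future__ import annotations

import numpy as np
import pytest

from segensemble import BinaryMask


def mask(arr, spacing=(1.0, 1.0, 1.0), label="") -> BinaryMask:
    return BinaryMask(np.asarray(arr, dtype=bool), spacing, label)


def single_voxel(shape, idx, spacing=(1.0, 1.0, 1.0)) -> BinaryMask:
    v = np.zeros(shape, dtype=bool)
    v[idx] = True
    return BinaryMask(v, spacing)


def random_mask(rng: np.random.Generator, shape=(8, 8, 8),
                p=0.3, spacing=(1.0, 1.0, 1.0), nonempty=True) -> BinaryMask:
    v = rng.random(shape) < p
    if nonempty and not v.any():
        v[tuple(rng.integers(0, s) for s in shape)] = True
    return BinaryMask(v, spacing)


def brute_boundary(voxels: np.ndarray) -> np.ndarray:
    """Boundary voxel coordinates by explicit 6-neighbour inspection,
    out-of-grid counting as background."""
    coords = []
    for idx in np.argwhere(voxels):
        for axis in range(3):
            for step in (-1, 1):
                n = idx.copy()
                n[axis] += step
                if (n[axis] < 0 or n[axis] >= voxels.shape[axis]
                        or not voxels[tuple(n)]):
                    coords.append(idx)
                    break
            else:
                continue
            break
    return np.array(coords).reshape(-1, 3)


def brute_surface_distances(a: BinaryMask, b: BinaryMask) -> np.ndarray:
    """All directed nearest boundary-to-boundary distances (both
    directions) by O(B1*B2) pairwise search, in mm."""
    sp = np.asarray(a.spacing)
    ba = brute_boundary(a.voxels) * sp
    bb = brute_boundary(b.voxels) * sp
    d = np.sqrt(((ba[:, None, :] - bb[None, :, :]) ** 2).sum(axis=2))
    return np.concatenate([d.min(axis=1), d.min(axis=0)])


def sorted_quantile(values, q: float) -> float:
    """Linear-interpolation quantile computed from first principles."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = q * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(v[lo] * (1 - frac) + v[hi] * frac)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
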