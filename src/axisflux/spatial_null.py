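"""Hemisphere-aware spherical spin permutations.

Parcellated brain maps are spatially autocorrelated, so naive permutation
tests of map-map association are anticonservative.  The spin test rotates
parcel centroid positions on the sphere — preserving the map's spatial
covariance while breaking its correspondence with other maps — and
reassigns each rotated centroid to the nearest original centroid within its
hemisphere.  The right hemisphere receives the sagittally mirrored rotation
so the null respects bilateral symmetry.  This module is the shared backend
for map decoding, t-map comparison and dispersion-specificity tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ParcellationMeta, ValidationError

__all__ = ["SpinIndex", "generate_spins", "spin_pvalue"]


@dataclass(frozen=True)
class SpinIndex:
    """P × n_perm permutation table from spherical rotations.

    Column j maps each parcel position i to the original parcel whose
    centroid is nearest to i's rotated centroid; a spun map is
    ``values[index[:, j]]``.  Assignments are hemisphere-preserving and may
    be many-to-one, as is standard for centroid-based spin tests.
    """

    index: np.ndarray
    seed: int

    def __post_init__(self):
        idx = np.asarray(self.index, int)
        if idx.ndim != 2:
            raise ValidationError("index must be P × n_perm")
        P = idx.shape[0]
        if idx.min() < 0 or idx.max() >= P:
            raise ValidationError("index entries out of range")
        object.__setattr__(self, "index", idx)

    @property
    def n_perm(self) -> int:
        return self.index.shape[1]

    @property
    def n_parcels(self) -> int:
        return self.index.shape[0]

    def apply(self, values: np.ndarray, j: int) -> np.ndarray:
        """Spin a parcel map by permutation j."""
        return np.asarray(values)[self.index[:, j]]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform rotation: QR of a Gaussian matrix, determinant fixed to +1."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, [0, 1]] = q[:, [1, 0]]
    return q


def generate_spins(
    meta: ParcellationMeta, n_perm: int, seed: int = 0
) -> SpinIndex:
    """Draw ``n_perm`` spherical rotations and build the permutation table.

    Per permutation a uniform random rotation is applied to left-hemisphere
    centroids and its sagittal mirror to right-hemisphere centroids; each
    rotated centroid is reassigned to the nearest original centroid in the
    same hemisphere.  Deterministic given the seed.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    cen = meta.centroids
    if not np.allclose(np.linalg.norm(cen, axis=1), 1.0, atol=1e-9):
        raise ValidationError("centroids must be unit-norm")
    rng = np.random.default_rng(seed)
    mirror = np.diag([-1.0, 1.0, 1.0])
    hemis = [meta.hemisphere == h for h in ("L", "R")]
    index = np.empty((meta.n_parcels, n_perm), dtype=int)
    for j in range(n_perm):
        rot_l = _random_rotation(rng)
        rot_r = mirror @ rot_l @ mirror
        for mask, rot in zip(hemis, (rot_l, rot_r)):
            ids = np.flatnonzero(mask)
            pts = cen[ids]
            rotated = pts @ rot.T
            # nearest original centroid within hemisphere = max cosine
            nearest = np.argmax(rotated @ pts.T, axis=1)
            index[ids, j] = ids[nearest]
    return SpinIndex(index=index, seed=seed)


def identity_spins(meta: ParcellationMeta, n_perm: int = 1) -> SpinIndex:
    """Identity permutation table (test hook for the unrotated case)."""
    idx = np.tile(np.arange(meta.n_parcels)[:, None], (1, n_perm))
    return SpinIndex(index=idx, seed=-1)


def spin_pvalue(
    observed: float, null_values: np.ndarray, two_sided: bool = True
) -> float:
    """Permutation p-value with the +1 correction (never exactly zero).

    Two-sided: p = (1 + #{|null| >= |obs|}) / (1 + n); one-sided uses the
    raw comparison null >= obs.
    """
    null_values = np.asarray(null_values, float)
    if null_values.size == 0:
        raise ValidationError("empty null distribution")
    if two_sided:
        count = np.sum(np.abs(null_values) >= abs(observed))
    else:
        count = np.sum(null_values >= observed)
    return float((1 + count) / (1 + null_values.size))
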