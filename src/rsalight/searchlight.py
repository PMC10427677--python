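"""Spherical-searchlight maps of within-condition pattern consistency.

For every in-mask voxel, the trial-by-voxel beta patterns inside a
2-voxel-radius sphere (33 voxels when complete) are correlated pairwise
across trials; the mean of the upper triangle of the trial-by-trial Pearson
matrix is stored at the sphere's center.  The anxiety-minus-neutral
difference map subtracts raw r values voxelwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .glm import BetaStack

DEFAULT_RADIUS = 2
DEFAULT_MIN_VOXELS = 10
_CHUNK = 512


@dataclass(frozen=True)
class SphereOffsets:
    radius_voxels: int
    offsets: np.ndarray  # (k, 3) int, lexicographic, includes (0,0,0)

    def __len__(self) -> int:
        return len(self.offsets)


@dataclass
class SimilarityMap:
    subject_id: str
    condition: str  # anxiety | neutral | anxiety_minus_neutral
    data: np.ndarray  # 3-D, NaN where invalid
    valid: np.ndarray  # 3-D bool
    radius_voxels: int
    n_trials: int
    n_dropped_pairs: int = 0


def sphere_offsets(radius_voxels: int) -> SphereOffsets:
    """All integer lattice offsets with Euclidean norm <= radius (33 at radius 2)."""
    if radius_voxels < 0 or int(radius_voxels) != radius_voxels:
        raise ValueError(f"radius must be a non-negative integer, got {radius_voxels}")
    r = int(radius_voxels)
    rng = range(-r, r + 1)
    offs = [
        (i, j, k)
        for i in rng
        for j in rng
        for k in rng
        if i * i + j * j + k * k <= r * r
    ]
    return SphereOffsets(radius_voxels=r, offsets=np.array(sorted(offs), dtype=int))


def mean_pairwise_correlation(vectors: np.ndarray) -> float:
    """Mean Pearson r over all unordered trial pairs (upper triangle).

    Pairs involving a zero-variance trial vector are excluded; returns NaN if
    no valid pair remains.
    """
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2 or v.shape[0] < 2:
        raise ValueError("need a (n_trials >= 2, n_voxels) matrix")
    if v.shape[1] < 2:
        raise ValueError("need at least 2 voxels per trial vector")
    sd = v.std(axis=1)
    ok = sd > 0
    if ok.sum() < 2:
        return float("nan")
    r = np.corrcoef(v[ok])
    iu = np.triu_indices_from(r, k=1)
    return float(r[iu].mean())


def searchlight_map(
    betas: BetaStack,
    mask: np.ndarray | None = None,
    radius_voxels: int = DEFAULT_RADIUS,
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> SimilarityMap:
    """Consistency map: mean pairwise trial-pattern correlation per center voxel.

    Spheres are clipped to the mask; centers whose clipped sphere has fewer
    than ``min_voxels`` voxels are marked invalid (NaN).
    """
    grid = betas.data.shape[1:]
    if mask is None:
        mask = betas.mask
    mask = np.asarray(mask).astype(bool)
    if mask.shape != grid:
        raise ValueError(f"mask shape {mask.shape} != beta grid {grid}")
    if not mask.any():
        raise ValueError("empty mask")
    T = betas.n_trials
    if T < 2:
        raise ValueError("searchlight needs at least 2 trials")

    offsets = sphere_offsets(radius_voxels).offsets  # (K, 3)
    K = len(offsets)
    centers = np.argwhere(mask)  # (N, 3)
    flat_betas = betas.data.reshape(T, -1)
    shape = np.asarray(grid)

    out = np.full(grid, np.nan)
    valid = np.zeros(grid, dtype=bool)
    dropped_pairs = 0

    for start in range(0, len(centers), _CHUNK):
        ctr = centers[start:start + _CHUNK]  # (C, 3)
        C = len(ctr)
        neigh = ctr[:, None, :] + offsets[None, :, :]  # (C, K, 3)
        inside = np.all((neigh >= 0) & (neigh < shape), axis=2)
        clipped = np.clip(neigh, 0, shape - 1)
        flat_idx = np.ravel_multi_index(
            (clipped[..., 0], clipped[..., 1], clipped[..., 2]), grid
        )
        w = inside & mask.reshape(-1)[flat_idx]  # (C, K)
        nv = w.sum(axis=1)  # voxels per clipped sphere
        ok_center = nv >= max(min_voxels, 2)

        data = flat_betas[:, flat_idx]  # (T, C, K)
        wf = w[None, :, :]
        nvf = np.maximum(nv, 1)[None, :, None]
        m = (data * wf).sum(axis=2, keepdims=True) / nvf
        xc = (data - m) * wf
        ss = (xc**2).sum(axis=2)  # (T, C)
        zero_var = ss <= 0
        with np.errstate(invalid="ignore", divide="ignore"):
            xn = xc / np.sqrt(ss)[:, :, None]
        xn[zero_var] = 0.0
        xcn = np.ascontiguousarray(xn.transpose(1, 0, 2))  # (C, T, K)
        G = xcn @ xcn.transpose(0, 2, 1)  # (C, T, T)

        pair_ok = (~zero_var.T[:, :, None]) & (~zero_var.T[:, None, :])
        iu = np.triu_indices(T, k=1)
        g = G[:, iu[0], iu[1]]  # (C, n_pairs)
        pok = pair_ok[:, iu[0], iu[1]]
        n_ok = pok.sum(axis=1)
        with np.errstate(invalid="ignore"):
            vals = np.where(n_ok > 0, (g * pok).sum(axis=1) / np.maximum(n_ok, 1), np.nan)
        center_valid = ok_center & (n_ok > 0)
        dropped_pairs += int((((len(iu[0]) - n_ok)) * ok_center).sum())

        ci = np.ravel_multi_index((ctr[:, 0], ctr[:, 1], ctr[:, 2]), grid)
        out.reshape(-1)[ci[center_valid]] = vals[center_valid]
        valid.reshape(-1)[ci[center_valid]] = True

    if dropped_pairs:
        warnings.warn(
            f"{dropped_pairs} zero-variance trial pairs dropped from sphere means",
            RuntimeWarning,
        )
    return SimilarityMap(
        subject_id=betas.subject_id,
        condition=betas.condition,
        data=out,
        valid=valid,
        radius_voxels=radius_voxels,
        n_trials=T,
        n_dropped_pairs=dropped_pairs,
    )


def difference_map(anxiety: SimilarityMap, neutral: SimilarityMap) -> SimilarityMap:
    """Voxelwise anxiety-minus-neutral subtraction of raw r values."""
    if anxiety.data.shape != neutral.data.shape:
        raise ValueError("similarity maps are on different grids")
    if anxiety.radius_voxels != neutral.radius_voxels:
        raise ValueError("similarity maps use different searchlight radii")
    if anxiety.subject_id != neutral.subject_id:
        raise ValueError("similarity maps belong to different subjects")
    valid = anxiety.valid & neutral.valid
    data = np.full(anxiety.data.shape, np.nan)
    data[valid] = anxiety.data[valid] - neutral.data[valid]
    return SimilarityMap(
        subject_id=anxiety.subject_id,
        condition="anxiety_minus_neutral",
        data=data,
        valid=valid,
        radius_voxels=anxiety.radius_voxels,
        n_trials=min(anxiety.n_trials, neutral.n_trials),
    )
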