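"""Nonparametric permutation inference with TFCE and max-statistic FWE control.

Three designs are supported, all with Freedman-Lane handling of nuisance
covariates: a two-sample group contrast, a one-sample (sign-flip) test, and
a covariate-slope (correlation) test.  Each permutation's enhanced map
maximum forms the null; familywise-error p-values are
``(#{max_null >= observed TFCE} + 1) / (n_perm + 1)``.

TFCE transforms a statistic map by integrating ``extent^E * height^H`` over
thresholds, removing the need for a cluster-forming threshold.  Defaults
(E=0.5, H=2, dh=max/100, 26-connectivity) follow the common neuroimaging
convention.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass(frozen=True)
class TFCEParams:
    E: float = 0.5
    H: float = 2.0
    dh: float | None = None  # absolute step; None -> max(stat)/n_steps
    n_steps: int = 100
    connectivity: int = 26

    def __post_init__(self):
        if self.E < 0 or self.H < 0:
            raise ValueError("TFCE exponents must be non-negative")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.connectivity not in _STRUCTURES:
            raise ValueError("connectivity must be 6, 18 or 26")


@dataclass
class PermutationResult:
    stat_map: np.ndarray
    tfce_map: np.ndarray
    fwe_p_map: np.ndarray
    max_null: np.ndarray
    n_permutations: int
    seed: int | None
    design: str
    exhaustive: bool = False
    params: TFCEParams = field(default_factory=TFCEParams)


def tfce(stat_map: np.ndarray, params: TFCEParams = TFCEParams(),
         mask: np.ndarray | None = None) -> np.ndarray:
    """Threshold-free cluster enhancement of the positive part of a map.

    TFCE(v) = sum over thresholds h of e_h(v)^E * h^H * dh, where e_h(v) is
    the size of the connected component containing v among voxels >= h.
    Negative values are the caller's concern (run on the negated map).
    """
    stat = np.asarray(stat_map, dtype=float)
    if not np.all(np.isfinite(stat)):
        raise ValueError("stat map contains non-finite values")
    pos = np.where(stat > 0, stat, 0.0)
    if mask is not None:
        pos = np.where(np.asarray(mask, dtype=bool), pos, 0.0)
    peak = pos.max()
    out = np.zeros_like(pos)
    if peak <= 0:
        return out
    dh = params.dh if params.dh is not None else peak / params.n_steps
    structure = _STRUCTURES[params.connectivity]
    h = dh
    while h <= peak + 1e-12:
        supra = pos >= h
        labels, n = ndimage.label(supra, structure=structure)
        if n == 0:
            break
        sizes = np.bincount(labels.reshape(-1))
        extent = sizes[labels]  # component size at each suprathreshold voxel
        out += np.where(supra, extent**params.E * h**params.H * dh, 0.0)
        h += dh
    return out


# ---------------------------------------------------------------------------
# voxelwise GLM machinery


def _as_stack(maps) -> np.ndarray:
    arr = np.asarray(maps, dtype=float)
    if arr.ndim < 2:
        raise ValueError("need a stack of subject maps")
    return arr.reshape(arr.shape[0], -1), arr.shape[1:]


def _glm_t(X: np.ndarray, Y: np.ndarray, col: int,
           XtX_inv: np.ndarray | None = None) -> np.ndarray:
    """t statistic for one design column, vectorized over map columns of Y."""
    n, p = X.shape
    if XtX_inv is None:
        XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - p
    mse = (resid**2).sum(axis=0) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(XtX_inv[col, col] * mse)
        t = beta[col] / se
    return np.where(se > 0, t, 0.0)


def _fwe_p(obs_tfce: np.ndarray, max_null: np.ndarray) -> np.ndarray:
    m = len(max_null)
    exceed = (max_null[None, :] >= obs_tfce.reshape(-1, 1)).sum(axis=1)
    return ((exceed + 1) / (m + 1)).reshape(obs_tfce.shape)


def _freedman_lane(
    Y: np.ndarray,
    X: np.ndarray,
    col: int,
    rearrangements,
    n_perm: int,
    params: TFCEParams,
    grid: tuple,
    seed: int | None,
    design: str,
    mask: np.ndarray | None,
    exhaustive: bool,
    kind: str = "perm",
) -> PermutationResult:
    """Core engine: observed t/TFCE plus max-TFCE null under Freedman-Lane.

    ``rearrangements`` yields permutation index arrays (``kind='perm'``) or
    +-1 sign vectors (``kind='sign'``); nuisance = all design columns except
    ``col``.
    """
    n, p = X.shape
    if n - p < 1:
        raise ValueError(
            f"{n} subjects leave no residual degrees of freedom for a "
            f"{p}-column design"
        )
    XtX_inv = np.linalg.inv(X.T @ X)
    t_obs = _glm_t(X, Y, col, XtX_inv)
    tfce_obs = tfce(t_obs.reshape(grid), params, mask=mask)

    Z = np.delete(X, col, axis=1)
    gamma = np.linalg.lstsq(Z, Y, rcond=None)[0]
    fitted = Z @ gamma
    resid = Y - fitted

    max_null = np.empty(n_perm)
    for b, arr in enumerate(itertools.islice(rearrangements, n_perm)):
        arr = np.asarray(arr)
        if kind == "sign":
            Ystar = fitted + resid * arr[:, None]
        else:
            Ystar = fitted + resid[arr]
        t_b = _glm_t(X, Ystar, col, XtX_inv)
        max_null[b] = tfce(t_b.reshape(grid), params, mask=mask).max()
    fwe = _fwe_p(tfce_obs, max_null)
    if mask is not None:
        m3 = np.asarray(mask, dtype=bool)
        fwe = np.where(m3, fwe, 1.0)
    return PermutationResult(
        stat_map=t_obs.reshape(grid),
        tfce_map=tfce_obs,
        fwe_p_map=fwe,
        max_null=max_null,
        n_permutations=n_perm,
        seed=seed,
        design=design,
        exhaustive=exhaustive,
        params=params,
    )


def _perm_indices(n: int, n_perm: int, rng: np.random.Generator):
    """Random permutations, or exhaustive enumeration when n! <= n_perm."""
    total = math.factorial(n)
    if total <= n_perm:
        return ([np.array(p) for p in itertools.permutations(range(n))], total, True)
    return ((rng.permutation(n) for _ in range(n_perm)), n_perm, False)


def _two_sample_perms(group: np.ndarray, n_perm: int, rng: np.random.Generator):
    """Label rearrangements as index permutations exchanging group members."""
    n = len(group)
    idx1 = np.where(group)[0]
    total = math.comb(n, len(idx1))
    if total <= n_perm:
        def gen():
            base = np.arange(n)
            for comb in itertools.combinations(range(n), len(idx1)):
                perm = np.empty(n, dtype=int)
                new1 = np.array(comb)
                new0 = np.setdiff1d(base, new1)
                # map: positions of group1 receive subjects `new1`, etc.
                perm[idx1] = new1
                perm[np.where(~group)[0]] = new0
                yield perm
        return gen(), total, True
    return ((rng.permutation(n) for _ in range(n_perm)), n_perm, False)


def _sign_flips(n: int, n_perm: int, rng: np.random.Generator):
    total = 2**n if n < 63 else float("inf")
    if total <= n_perm:
        def gen():
            for bits in itertools.product((1, -1), repeat=n):
                yield np.array(bits)
        return gen(), int(total), True
    return (
        (rng.choice([-1, 1], size=n) for _ in range(n_perm)),
        n_perm,
        False,
    )


def _check_nperm(n_perm: int):
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; FWE p-values will be coarse")


# ---------------------------------------------------------------------------
# public designs


def permute_two_sample(
    maps,
    group_labels,
    covariates: np.ndarray | None = None,
    n_perm: int = 5000,
    params: TFCEParams = TFCEParams(),
    seed: int | None = None,
    mask: np.ndarray | None = None,
) -> PermutationResult:
    """Group-contrast t per voxel (first group > second) with FWE via max-TFCE.

    ``group_labels`` is a boolean/binary array (True = group of interest) or a
    sequence of two labels; covariates (n, k) are nuisance regressors.
    """
    _check_nperm(n_perm)
    Y, grid = _as_stack(maps)
    labels = np.asarray(group_labels)
    if labels.dtype != bool:
        uniq = sorted(pd.unique(labels))
        if len(uniq) != 2:
            raise ValueError(f"expected 2 groups, got {uniq}")
        labels = labels == uniq[0]
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    n = len(labels)
    cols = [labels.astype(float)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.append(cov)
    X = np.column_stack([np.ones(n), *cols])
    rng = np.random.default_rng(seed)
    if covariates is None:
        # without nuisance terms the statistic depends only on the labelling,
        # so the C(n, n1) relabellings can be enumerated exhaustively
        perms, n_eff, exhaustive = _two_sample_perms(labels, n_perm, rng)
    else:
        perms, n_eff, exhaustive = _perm_indices(n, n_perm, rng)
    return _freedman_lane(
        Y, X, 1, perms, n_eff, params, grid, seed, "two_sample", mask, exhaustive
    )


def permute_one_sample(
    maps,
    covariates: np.ndarray | None = None,
    n_perm: int = 5000,
    params: TFCEParams = TFCEParams(),
    seed: int | None = None,
    direction: str = "greater",
    mask: np.ndarray | None = None,
) -> PermutationResult:
    """One-sample mean test (sign-flipping null) with nuisance covariates.

    ``direction='less'`` negates the maps to test the opposite tail.
    """
    _check_nperm(n_perm)
    Y, grid = _as_stack(maps)
    n = Y.shape[0]
    if n < 3:
        raise ValueError("one-sample test needs at least 3 subjects")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if direction == "less":
        Y = -Y
    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cov = cov - cov.mean(axis=0)  # center so the intercept is the mean
        cols.append(cov)
    X = np.column_stack(cols)
    rng = np.random.default_rng(seed)
    flips, n_eff, exhaustive = _sign_flips(n, n_perm, rng)
    return _freedman_lane(
        Y, X, 0, flips, n_eff, params, grid, seed, f"one_sample_{direction}",
        mask, exhaustive, kind="sign",
    )


def permute_correlation(
    maps,
    covariate_values,
    nuisance: np.ndarray | None = None,
    n_perm: int = 5000,
    params: TFCEParams = TFCEParams(),
    seed: int | None = None,
    mask: np.ndarray | None = None,
) -> PermutationResult:
    """Covariate-slope t per voxel (positive association) with max-TFCE FWE."""
    _check_nperm(n_perm)
    Y, grid = _as_stack(maps)
    x = np.asarray(covariate_values, dtype=float)
    if np.std(x) == 0:
        raise ValueError("covariate is constant")
    n = len(x)
    cols = [x]
    if nuisance is not None:
        nu = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nu.shape[0] != n:
            nu = nu.T
        cols.append(nu)
    X = np.column_stack([np.ones(n), *cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design: covariate duplicated in nuisance?")
    rng = np.random.default_rng(seed)
    perms, n_eff, exhaustive = _perm_indices(n, n_perm, rng)
    return _freedman_lane(
        Y, X, 1, perms, n_eff, params, grid, seed, "correlation", mask, exhaustive
    )


def cluster_table(
    result: PermutationResult,
    alpha: float = 0.05,
    affine: np.ndarray | None = None,
    label_volume: np.ndarray | None = None,
    label_names: dict[int, str] | None = None,
    top: int | None = 10,
) -> pd.DataFrame:
    """Connected components of the FWE p < alpha mask, sorted by peak statistic.

    Columns: cluster, t_max, size_voxels, peak x/y/z (0-based voxel indices,
    plus mm coordinates when an affine is given), optional region label.
    """
    sig = result.fwe_p_map < alpha
    structure = _STRUCTURES[result.params.connectivity]
    labels, n = ndimage.label(sig, structure=structure)
    rows = []
    for k in range(1, n + 1):
        comp = labels == k
        stat = np.where(comp, result.stat_map, -np.inf)
        peak = np.unravel_index(np.argmax(stat), stat.shape)
        row = {
            "t_max": float(result.stat_map[peak]),
            "size_voxels": int(comp.sum()),
            "x": int(peak[0]),
            "y": int(peak[1]),
            "z": int(peak[2]),
        }
        if affine is not None:
            mm = affine @ np.array([*peak, 1.0])
            row.update({"x_mm": mm[0], "y_mm": mm[1], "z_mm": mm[2]})
        if label_volume is not None:
            lab = int(label_volume[peak])
            row["region"] = (label_names or {}).get(lab, str(lab))
        rows.append(row)
    table = pd.DataFrame(rows)
    if len(table):
        table = table.sort_values("t_max", ascending=False, ignore_index=True)
        if top is not None:
            table = table.head(top)
        table.insert(0, "cluster", np.arange(1, len(table) + 1))
    return table
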