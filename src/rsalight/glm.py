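"""Single-trial beta estimation with the least-squares "sum" (LSS) scheme.

Each trial gets its own GLM: one regressor for the target trial, one summing
all remaining trials, optional discrete-cosine drift columns, optional
confounds, and an intercept.  The target column's OLS coefficient becomes
that trial's beta volume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DEFAULT_HRF_MODEL, dct_drift_basis, trial_regressors

DEFAULT_DRIFT_CUTOFF_S = 100.0

#: condition threshold above which a design is treated as rank-deficient
_COND_LIMIT = 1e10


class RankDeficientDesignError(np.linalg.LinAlgError):
    pass


@dataclass
class LSSDesign:
    """Design matrix for one trial's LSS fit.

    ``matrix`` is (n_volumes, p); column 0 models the target trial.
    ``others_dropped`` records that the summed-other-trials column was empty
    (single-trial run) and was removed.
    """

    matrix: np.ndarray
    names: list[str]
    trial_index: int
    others_dropped: bool = False

    @property
    def target_column(self) -> int:
        return 0


@dataclass
class BetaStack:
    """Per-subject, per-condition stack of single-trial beta volumes."""

    subject_id: str
    condition: str
    data: np.ndarray  # (n_trials, x, y, z)
    mask: np.ndarray  # (x, y, z) bool
    events: pd.DataFrame
    flat_voxels: list = field(default_factory=list)  # all-zero time series flagged

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def build_lss_design(
    events: pd.DataFrame,
    trial_index: int,
    tr: float,
    n_volumes: int,
    hrf_model: str = DEFAULT_HRF_MODEL,
    drift_cutoff_s: float | None = DEFAULT_DRIFT_CUTOFF_S,
    confounds: np.ndarray | None = None,
    _regressors: np.ndarray | None = None,
) -> LSSDesign:
    """Target-trial + summed-others design for ``trial_index``."""
    n_trials = len(events)
    if not 0 <= trial_index < n_trials:
        raise IndexError(f"trial_index {trial_index} out of range 0..{n_trials - 1}")
    regs = (
        _regressors
        if _regressors is not None
        else trial_regressors(events, tr, n_volumes, hrf_model)
    )
    target = regs[trial_index]
    others = regs.sum(axis=0) - target
    cols = [target]
    names = [f"trial_{trial_index:03d}"]
    others_dropped = False
    if np.allclose(others, 0.0):
        others_dropped = True
    else:
        cols.append(others)
        names.append("other_trials")
    if drift_cutoff_s is not None:
        drift = dct_drift_basis(n_volumes, tr, drift_cutoff_s)
        for j in range(drift.shape[1]):
            cols.append(drift[:, j])
            names.append(f"drift_{j + 1:02d}")
    if confounds is not None:
        confounds = np.atleast_2d(np.asarray(confounds, dtype=float))
        if confounds.shape[0] != n_volumes:
            confounds = confounds.T
        for j in range(confounds.shape[1]):
            cols.append(confounds[:, j])
            names.append(f"confound_{j + 1:02d}")
    cols.append(np.ones(n_volumes))
    names.append("intercept")
    X = np.column_stack(cols)
    if np.linalg.cond(X) > _COND_LIMIT:
        raise RankDeficientDesignError(
            f"rank-deficient LSS design for trial {trial_index} "
            "(duplicate onsets or collinear confounds?)"
        )
    return LSSDesign(matrix=X, names=names, trial_index=trial_index,
                     others_dropped=others_dropped)


def fit_trial_betas(
    run_4d: np.ndarray,
    events: pd.DataFrame,
    mask: np.ndarray | None,
    tr: float,
    hrf_model: str = DEFAULT_HRF_MODEL,
    drift_cutoff_s: float | None = DEFAULT_DRIFT_CUTOFF_S,
    confounds: np.ndarray | None = None,
    subject_id: str = "",
    condition: str | None = None,
) -> BetaStack:
    """OLS per voxel, one design per trial; target coefficients -> BetaStack.

    Uses precomputed cross-products so the per-trial solve is a small linear
    system; equivalent to per-trial ``lstsq`` for well-conditioned designs.
    """
    run_4d = np.asarray(run_4d, dtype=float)
    grid = run_4d.shape[:3]
    n_volumes = run_4d.shape[3]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask).astype(bool)
    if mask.shape != grid:
        raise ValueError(f"mask shape {mask.shape} != run grid {grid}")
    if condition is None:
        condition = str(events["trial_type"].iloc[0]) if len(events) else ""

    Y = run_4d[mask].T  # (n_volumes, n_mask_voxels)
    flat = np.where(~Y.any(axis=0))[0]
    if flat.size:
        warnings.warn(
            f"{flat.size} all-zero voxel time series inside mask; betas set to 0",
            RuntimeWarning,
        )

    regs = trial_regressors(events, tr, n_volumes, hrf_model)
    n_trials = len(events)
    betas = np.zeros((n_trials, Y.shape[1]))
    # cross-products shared across the per-trial designs
    RY = regs @ Y  # (n_trials, V)
    sumRY = RY.sum(axis=0)
    nuisY = []  # drift/confound/intercept rows of X'Y, fixed across trials
    if drift_cutoff_s is not None:
        drift = dct_drift_basis(n_volumes, tr, drift_cutoff_s)
        if drift.shape[1]:
            nuisY.append(drift.T @ Y)
    if confounds is not None:
        conf = np.atleast_2d(np.asarray(confounds, dtype=float))
        if conf.shape[0] != n_volumes:
            conf = conf.T
        nuisY.append(conf.T @ Y)
    nuisY.append(Y.sum(axis=0, keepdims=True))
    nuisY = np.vstack(nuisY)
    for i in range(n_trials):
        design = build_lss_design(
            events, i, tr, n_volumes, hrf_model, drift_cutoff_s, confounds,
            _regressors=regs,
        )
        X = design.matrix
        A = X.T @ X
        parts = [RY[i][None, :]]
        if not design.others_dropped:
            parts.append((sumRY - RY[i])[None, :])
        parts.append(nuisY)
        b = np.vstack(parts)
        coef = np.linalg.solve(A, b)
        betas[i] = coef[design.target_column]

    data = np.zeros((n_trials, *grid))
    data[:, mask] = betas
    return BetaStack(
        subject_id=subject_id,
        condition=condition,
        data=data,
        mask=mask,
        events=events.reset_index(drop=True),
        flat_voxels=list(flat),
    )


def highpass_filter(
    run_4d: np.ndarray,
    cutoff_s: float,
    tr: float,
    preserve_mean: bool = True,
) -> np.ndarray:
    """Remove fluctuations slower than ``cutoff_s`` by discrete-cosine projection."""
    run_4d = np.asarray(run_4d, dtype=float)
    n_volumes = run_4d.shape[-1]
    basis = dct_drift_basis(n_volumes, tr, cutoff_s)  # validates cutoff
    Y = run_4d.reshape(-1, n_volumes).T  # (t, voxels)
    mean = Y.mean(axis=0, keepdims=True)
    Yc = Y - mean
    if basis.shape[1]:
        Q, _ = np.linalg.qr(basis)
        Yc = Yc - Q @ (Q.T @ Yc)
    out = Yc + (mean if preserve_mean else 0.0)
    return out.T.reshape(run_4d.shape)
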