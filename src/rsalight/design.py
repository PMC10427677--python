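"""HRF-convolved trial regressors and drift bases shared by the simulator and the GLM.

The forward model and the single-trial GLM must agree on how a 2-s word
presentation maps onto the BOLD time course; both therefore call
:func:`trial_regressors`, which convolves each event's boxcar with the
canonical double-gamma HRF (SPM shape: peak 6 s, undershoot 16 s, ratio 1/6)
and normalizes each trial regressor to unit peak so that fitted betas are in
the same units as simulated pattern amplitudes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from nilearn.glm.first_level.hemodynamic_models import glover_hrf, spm_hrf
from scipy.signal import fftconvolve

DEFAULT_HRF_MODEL = "spm"

_HRF_KERNELS = {"spm": spm_hrf, "glover": glover_hrf}


def trial_regressors(
    events: pd.DataFrame,
    tr: float,
    n_volumes: int,
    hrf_model: str = DEFAULT_HRF_MODEL,
    oversampling: int = 16,
) -> np.ndarray:
    """One HRF-convolved regressor per event row.

    Each event's boxcar (its onset/duration, sampled at tr/oversampling) is
    convolved with the canonical HRF kernel and resampled on the volume grid;
    all trials are convolved in one vectorized FFT pass.

    Parameters
    ----------
    events : DataFrame with ``onset`` and ``duration`` columns (seconds).
    tr : repetition time in seconds.
    n_volumes : number of volumes in the run.

    Returns
    -------
    (n_trials, n_volumes) array, each row scaled to unit peak.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if hrf_model not in _HRF_KERNELS:
        raise ValueError(f"hrf_model must be one of {sorted(_HRF_KERNELS)}")
    kernel = _HRF_KERNELS[hrf_model](tr, oversampling=oversampling)
    dt = tr / oversampling
    n_hi = n_volumes * oversampling
    onsets = events["onset"].to_numpy(dtype=float)
    durations = events["duration"].to_numpy(dtype=float)
    if np.any(durations <= 0):
        raise ValueError("event durations must be positive")
    if np.any(onsets < 0) or np.any(onsets + durations > n_volumes * tr + 1e-9):
        raise ValueError("events fall outside the acquisition window")
    start = np.round(onsets / dt).astype(int).clip(0, n_hi - 1)
    stop = np.round((onsets + durations) / dt).astype(int).clip(1, n_hi)
    boxcars = np.zeros((len(events), n_hi))
    for i, (a, b) in enumerate(zip(start, stop)):
        boxcars[i, a:b] = 1.0
    conv = fftconvolve(boxcars, kernel[None, :], axes=1)[:, :n_hi]
    out = conv[:, ::oversampling].copy()
    peaks = np.abs(out).max(axis=1)
    if np.any(peaks == 0):
        bad = np.where(peaks == 0)[0]
        raise ValueError(
            f"trials {bad.tolist()} produce all-zero regressors "
            "(events outside the acquisition window?)"
        )
    return out / peaks[:, None]


def dct_drift_basis(n_volumes: int, tr: float, cutoff_s: float) -> np.ndarray:
    """Discrete-cosine drift columns with period longer than ``cutoff_s``.

    Returns an (n_volumes, k) matrix (DC term excluded; the model intercept
    covers it).  k may be 0 when the run is shorter than the cutoff.
    """
    if cutoff_s <= 2 * tr:
        raise ValueError(f"cutoff {cutoff_s}s must exceed 2*TR ({2 * tr}s)")
    run_s = n_volumes * tr
    # DCT-II component j has period 2*run_s/j; keep periods > cutoff.
    k = int(np.floor(2.0 * run_s / cutoff_s))
    t = np.arange(n_volumes)
    cols = [
        np.cos(np.pi * (t + 0.5) * j / n_volumes) for j in range(1, k + 1)
    ]
    if not cols:
        return np.empty((n_volumes, 0))
    return np.column_stack(cols)
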