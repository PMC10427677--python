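"""Anxiety-circuit ROI assembly, r-to-z averaging, and group ANCOVA.

The merged mask is the union of probabilistic regions thresholded at their
stated levels (>=).  A subject's ROI score is the mean Fisher z (atanh r)
over valid in-mask voxels of a similarity map; group differences are tested
with an ANCOVA (score ~ group + age + pds), and a leave-one-region-out loop
checks sensitivity of the group test to each constituent region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .searchlight import SimilarityMap

_ATANH_CLIP = 1.0 - 1e-7


@dataclass
class ROISet:
    regions: dict[str, tuple[np.ndarray, float]]  # name -> (prob volume, threshold)
    merged_mask: np.ndarray

    def region_mask(self, name: str) -> np.ndarray:
        vol, thr = self.regions[name]
        return vol >= thr


@dataclass
class RoiScore:
    subject_id: str
    condition: str
    z_value: float
    n_voxels_used: int


@dataclass
class AncovaResult:
    f_stat: float
    df_num: int
    df_den: int
    p_value: float
    coef_table: pd.DataFrame
    n_used: int
    dropped_subjects: list


def build_roi(
    regions: dict[str, np.ndarray],
    thresholds: dict[str, float] | float,
) -> ROISet:
    """Binarize each probabilistic region at its threshold (>=) and merge by union."""
    if not isinstance(thresholds, dict):
        thresholds = {name: float(thresholds) for name in regions}
    out: dict[str, tuple[np.ndarray, float]] = {}
    merged = None
    for name, vol in regions.items():
        thr = float(thresholds[name])
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"threshold for {name!r} must be in [0, 1], got {thr}")
        binary = np.asarray(vol) >= thr
        if not binary.any():
            raise ValueError(f"region {name!r} is empty after thresholding at {thr}")
        out[name] = (np.asarray(vol), thr)
        merged = binary if merged is None else (merged | binary)
    if merged is None:
        merged = np.zeros((0,), dtype=bool)
    return ROISet(regions=out, merged_mask=merged)


def roi_zscore(sim_map: SimilarityMap, mask: np.ndarray) -> RoiScore:
    """Mean Fisher z over valid in-mask voxels; |r|=1 clipped before atanh."""
    mask = np.asarray(mask).astype(bool)
    sel = mask & sim_map.valid & np.isfinite(sim_map.data)
    if not sel.any():
        raise ValueError("no valid similarity values inside the ROI mask")
    r = sim_map.data[sel]
    if np.any(np.abs(r) >= 1.0):
        warnings.warn(
            "correlations at |r|>=1 clipped before r-to-z transform", RuntimeWarning
        )
        r = np.clip(r, -_ATANH_CLIP, _ATANH_CLIP)
    return RoiScore(
        subject_id=sim_map.subject_id,
        condition=sim_map.condition,
        z_value=float(np.arctanh(r).mean()),
        n_voxels_used=int(sel.sum()),
    )


def group_ancova(
    scores: pd.Series | dict,
    records: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "pds"),
) -> AncovaResult:
    """ANCOVA of per-subject scores on group with nuisance covariates.

    Model: score ~ group + covariates (OLS).  The group effect is tested with
    a 1-numerator-df F (the squared coefficient t).  Subjects with missing
    covariates are dropped listwise.
    """
    scores = pd.Series(scores)
    df = records.set_index("subject_id").loc[scores.index].copy()
    df["score"] = scores
    needed = ["score", "group", *covariates]
    complete = df[needed].notna().all(axis=1)
    dropped = list(df.index[~complete])
    if dropped:
        warnings.warn(f"listwise deletion of {dropped} (missing covariates)")
    df = df[complete]
    groups = df["group"].unique()
    if len(groups) != 2 or (df["group"].value_counts() < 2).any():
        raise ValueError("need two groups with at least 2 subjects each")
    g = (df["group"] == sorted(groups)[0]).astype(float)  # alphabetical: AN=1
    X = np.column_stack(
        [np.ones(len(df)), g.to_numpy()]
        + [df[c].astype(float).to_numpy() for c in covariates]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular ANCOVA design (collinear covariates?)")
    fit = sm.OLS(df["score"].astype(float).to_numpy(), X).fit()
    names = ["intercept", f"group[{sorted(groups)[0]}]"] + list(covariates)
    coef_table = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "t": fit.tvalues, "p": fit.pvalues},
        index=names,
    )
    t_group = float(fit.tvalues[1])
    df_den = int(fit.df_resid)
    f_stat = t_group**2
    p = float(fit.pvalues[1])  # identical to the F(1, df_den) two-tailed p
    return AncovaResult(
        f_stat=f_stat,
        df_num=1,
        df_den=df_den,
        p_value=p,
        coef_table=coef_table,
        n_used=len(df),
        dropped_subjects=dropped,
    )


def subject_roi_scores(
    sim_maps: dict[str, SimilarityMap], mask: np.ndarray
) -> pd.Series:
    """z-score per subject over one mask, for maps keyed by subject_id."""
    return pd.Series(
        {sid: roi_zscore(m, mask).z_value for sid, m in sim_maps.items()}
    )


def leave_one_region_out(
    regions: dict[str, np.ndarray],
    thresholds: dict[str, float] | float,
    sim_maps: dict[str, SimilarityMap],
    records: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "pds"),
) -> list[tuple[str | None, AncovaResult]]:
    """Full-mask ANCOVA plus one ANCOVA per omitted region (None = full mask)."""
    if len(regions) < 2:
        raise ValueError("need at least 2 regions for leave-one-out")
    full = build_roi(regions, thresholds)
    results: list[tuple[str | None, AncovaResult]] = [
        (None, group_ancova(subject_roi_scores(sim_maps, full.merged_mask), records, covariates))
    ]
    for omit in regions:
        sub = {k: v for k, v in regions.items() if k != omit}
        roiset = build_roi(sub, thresholds)
        if not roiset.merged_mask.any():
            warnings.warn(f"omitting {omit!r} empties the mask; skipped")
            continue
        scores = subject_roi_scores(sim_maps, roiset.merged_mask)
        results.append((omit, group_ancova(scores, records, covariates)))
    return results
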