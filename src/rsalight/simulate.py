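"""Synthetic fMRI paradigm, BOLD, cohort, and atlas-fixture generation.

The simulator emulates a two-session fast event-related word paradigm
(20 words x 3 repetitions = 60 two-second trials per session, TR 1 s,
487 volumes) for two groups of adolescents (a patient group, ``AN``, and a
``control`` group).  The key quantity injected with known ground truth is the
*within-condition pattern consistency* c: each trial's multivoxel response in
a region is ``sqrt(c)*shared + sqrt(1-c)*noise`` so the expected pairwise
Pearson correlation between trial patterns equals c.  A clinical-anxiety-like
score (HAM-A) is coupled to each subject's injected consistency through a
Gaussian latent so downstream brain-behaviour correlation analyses have a
recoverable target.
"""

from __future__ import annotations

import dataclasses
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .design import DEFAULT_HRF_MODEL, trial_regressors

CONDITIONS = ("anxiety", "neutral")
GROUPS = ("AN", "control")

#: Region roles mirrored by the default atlas fixture (amygdala, anterior
#: cingulate, insula, medial prefrontal cortex at a 50% threshold; ventral
#: tegmental area and bed nucleus of the stria terminalis, which are small,
#: at 0.001).  Centers are fractions of the grid; radii are in voxels on the
#: 20-voxel reference grid and scale with the grid.
_REGION_FRACTIONS = (
    {"name": "amygdala", "center": (0.25, 0.25, 0.25), "radius": 2.0, "threshold": 0.5},
    {"name": "acc", "center": (0.25, 0.70, 0.25), "radius": 2.0, "threshold": 0.5},
    {"name": "insula", "center": (0.70, 0.25, 0.25), "radius": 2.0, "threshold": 0.5},
    {"name": "mpfc", "center": (0.70, 0.70, 0.70), "radius": 2.5, "threshold": 0.5},
    {"name": "vta", "center": (0.70, 0.70, 0.25), "radius": 1.5, "threshold": 0.001},
    {"name": "bnst", "center": (0.25, 0.25, 0.70), "radius": 1.5, "threshold": 0.001},
)


def default_region_specs(grid_shape: tuple[int, int, int] = (20, 20, 20)) -> list[dict]:
    """Six fixture regions placed proportionally on the given grid."""
    scale = min(grid_shape) / 20.0
    specs = []
    for f in _REGION_FRACTIONS:
        specs.append(
            {
                "name": f["name"],
                "center": tuple(int(round(c * s)) for c, s in zip(f["center"], grid_shape)),
                "radius": max(1.0, f["radius"] * scale),
                "threshold": f["threshold"],
            }
        )
    return specs


DEFAULT_REGION_SPECS = tuple(default_region_specs())


class ConfigurationError(ValueError):
    pass


def _default_consistency_map() -> dict:
    # Effect injected in one region ("mpfc"), anxiety condition, AN group only.
    return {
        "mpfc": {
            "anxiety": {"AN": 0.7, "control": 0.0},
            "neutral": {"AN": 0.0, "control": 0.0},
        }
    }


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    ``consistency_map`` maps region name -> condition -> group -> c, the
    expected inter-trial pattern correlation injected in that region.
    ``covariate_coupling`` is the latent correlation between a subject's
    injected consistency and the simulated HAM-A-like score.
    """

    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size: float = 2.0
    tr: float = 1.0
    n_volumes: int = 487
    n_words: int = 20
    n_reps: int = 3
    n_subjects_per_group: tuple[int, int] = (25, 22)
    consistency_map: dict = field(default_factory=_default_consistency_map)
    consistency_jitter_sd: float = 0.08
    noise_sd: float = 0.5
    drift_amplitude: float = 1.0
    n_drift_terms: int = 3
    covariate_coupling: float = 0.9
    stimulus_duration: float = 2.0
    iti_range: tuple[float, float] = (2.0, 6.0)
    lead_in: float = 10.0
    hrf_model: str = DEFAULT_HRF_MODEL
    seed: int = 0

    @property
    def n_trials(self) -> int:
        return self.n_words * self.n_reps

    def validate(self, searchlight_radius: int = 2) -> None:
        for r, cmap in self.consistency_map.items():
            for cond, per_group in cmap.items():
                if cond not in CONDITIONS:
                    raise ConfigurationError(f"unknown condition {cond!r}")
                for g, c in per_group.items():
                    if not 0.0 <= c <= 1.0:
                        raise ConfigurationError(
                            f"consistency for {r}/{cond}/{g} is {c}, outside [0, 1]"
                        )
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")
        if any(s < 2 * searchlight_radius + 1 for s in self.grid_shape):
            raise ConfigurationError(
                f"grid {self.grid_shape} too small for searchlight radius "
                f"{searchlight_radius}"
            )
        _check_run_capacity(self)


def _check_run_capacity(config: SimulationConfig) -> None:
    minimal = (
        config.lead_in
        + config.n_trials * (config.stimulus_duration + config.iti_range[0])
    )
    run_s = config.n_volumes * config.tr
    if minimal > run_s:
        raise ConfigurationError(
            f"run of {run_s:.0f}s cannot fit {config.n_trials} trials: "
            f"needs at least {minimal:.0f}s "
            f"({minimal - run_s:.0f}s short)"
        )


# ---------------------------------------------------------------------------
# paradigm


def generate_paradigm(
    config: SimulationConfig, session: str, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Event table for one session: columns onset/duration/trial_type/word_id/repetition.

    Word order is randomized; onset-to-onset gaps are the 2-s stimulus plus a
    uniform 2-6 s jitter, rescaled to fit the run when needed.  Deterministic
    given the seed.
    """
    if session not in CONDITIONS:
        raise ValueError(f"session must be one of {CONDITIONS}")
    _check_run_capacity(config)
    rng = np.random.default_rng(seed)
    pairs = list(itertools.product(range(1, config.n_words + 1), range(1, config.n_reps + 1)))
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]

    n = config.n_trials
    itis = rng.uniform(*config.iti_range, size=n - 1) if n > 1 else np.empty(0)
    run_s = config.n_volumes * config.tr
    # leave room for the last stimulus (and a little HRF tail when possible)
    budget = run_s - config.lead_in - n * config.stimulus_duration
    if itis.size and itis.sum() > budget:
        itis *= budget / itis.sum()
    onsets = config.lead_in + np.concatenate(
        [[0.0], np.cumsum(itis + config.stimulus_duration)]
    )
    onsets = np.round(onsets, 3)
    table = pd.DataFrame(
        {
            "onset": onsets,
            "duration": config.stimulus_duration,
            "trial_type": session,
            "word_id": [p[0] for p in pairs],
            "repetition": [p[1] for p in pairs],
        }
    )
    assert table["onset"].iloc[-1] + config.stimulus_duration <= run_s + 1e-9
    return table


# ---------------------------------------------------------------------------
# patterns and BOLD


def generate_trial_patterns(
    region_n_voxels: int,
    c: float,
    n_trials: int,
    rng: int | np.random.Generator,
) -> np.ndarray:
    """Trial-by-voxel amplitudes with expected pairwise correlation ``c``.

    pattern_i = sqrt(c) * shared + sqrt(1-c) * eps_i with shared and eps_i
    independent standard-normal voxel vectors.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"consistency c={c} outside [0, 1]")
    if region_n_voxels < 1:
        raise ValueError("region must contain at least one voxel")
    rng = np.random.default_rng(rng)
    shared = rng.standard_normal(region_n_voxels)
    eps = rng.standard_normal((n_trials, region_n_voxels))
    return np.sqrt(c) * shared[None, :] + np.sqrt(1.0 - c) * eps


def simulate_bold(
    paradigm: pd.DataFrame,
    trial_patterns: np.ndarray,
    config: SimulationConfig,
    seed: int | np.random.Generator,
    drift: bool | None = None,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Forward model: 4-D run (x, y, z, t).

    Each trial's spatial pattern is scaled by the HRF-convolved 2-s boxcar,
    summed over trials, plus slow cosine drift and white Gaussian noise.
    ``trial_patterns`` has shape (n_trials, *grid_shape) or
    (n_trials, n_voxels) for a flattened grid.
    """
    rng = np.random.default_rng(seed)
    n_trials = len(paradigm)
    patterns = np.asarray(trial_patterns, dtype=float)
    if patterns.shape[0] != n_trials:
        raise ValueError(
            f"{patterns.shape[0]} pattern rows for {n_trials} paradigm rows"
        )
    flat = patterns.reshape(n_trials, -1)
    n_vox = int(np.prod(config.grid_shape))
    if flat.shape[1] != n_vox:
        raise ValueError(
            f"patterns cover {flat.shape[1]} voxels, grid has {n_vox}"
        )
    regs = trial_regressors(paradigm, config.tr, config.n_volumes, config.hrf_model)
    data = flat.T @ regs  # (n_vox, n_volumes)

    sd = config.noise_sd if noise_sd is None else noise_sd
    use_drift = (config.drift_amplitude > 0) if drift is None else drift
    if use_drift and config.drift_amplitude > 0:
        t = np.arange(config.n_volumes)
        basis = np.array(
            [
                np.cos(np.pi * (t + 0.5) * j / config.n_volumes)
                for j in range(1, config.n_drift_terms + 1)
            ]
        )
        coef = rng.normal(scale=config.drift_amplitude, size=(n_vox, config.n_drift_terms))
        data += coef @ basis
    if sd > 0:
        data += rng.normal(scale=sd, size=data.shape)
    return data.reshape(*config.grid_shape, config.n_volumes)


# ---------------------------------------------------------------------------
# atlas fixture


def generate_atlas_fixture(
    grid_shape: tuple[int, int, int],
    region_specs: Iterable[Mapping] | None = None,
    allow_overlap: bool = False,
) -> dict[str, np.ndarray]:
    """Probabilistic region volumes standing in for atlas-derived ROIs.

    Each spec is a mapping with ``name``, ``center`` (voxel coords),
    ``radius`` (voxels) and optionally ``threshold``.  The probability
    profile is ``p(d) = clip(1 - d / (2*radius), 0, 1)`` so that
    thresholding at 0.5 recovers the analytic sphere of the given radius.
    """
    if region_specs is None:
        region_specs = default_region_specs(grid_shape)
    vols: dict[str, np.ndarray] = {}
    grid = np.indices(grid_shape).reshape(3, -1).T.astype(float)
    support = {}
    for spec in region_specs:
        center = np.asarray(spec["center"], dtype=float)
        radius = float(spec["radius"])
        if np.any(center < 0) or np.any(center >= np.asarray(grid_shape)):
            raise ValueError(f"region {spec['name']!r} center outside grid")
        d = np.linalg.norm(grid - center, axis=1)
        p = np.clip(1.0 - d / (2.0 * radius), 0.0, 1.0).reshape(grid_shape)
        thr = float(spec.get("threshold", 0.5))
        vols[spec["name"]] = p
        support[spec["name"]] = p >= thr
    if not allow_overlap:
        names = list(support)
        for a, b in itertools.combinations(names, 2):
            if np.any(support[a] & support[b]):
                raise ValueError(
                    f"regions {a!r} and {b!r} overlap after thresholding"
                )
    return vols


def default_region_thresholds(
    region_specs: Iterable[Mapping] | None = None,
    grid_shape: tuple[int, int, int] = (20, 20, 20),
) -> dict[str, float]:
    if region_specs is None:
        region_specs = default_region_specs(grid_shape)
    return {s["name"]: float(s.get("threshold", 0.5)) for s in region_specs}


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Cohort:
    """Lazy synthetic cohort.

    ``participants`` holds one SubjectRecord row per subject;
    ``ground_truth`` maps subject_id -> region -> condition -> injected c.
    Runs are large, so they are generated on demand by :meth:`subject_run`
    (bit-reproducible: each subject/session derives its own child seed).
    """

    config: SimulationConfig
    participants: pd.DataFrame
    ground_truth: dict
    region_masks: dict[str, np.ndarray]
    _run_seeds: dict = field(repr=False, default_factory=dict)
    _pattern_seeds: dict = field(repr=False, default_factory=dict)

    def subject_events(self, subject_id: str, condition: str) -> pd.DataFrame:
        seed = self._run_seeds[(subject_id, condition)]
        return generate_paradigm(self.config, condition, np.random.default_rng(seed))

    def subject_patterns(self, subject_id: str, condition: str) -> np.ndarray:
        """(n_trials, *grid) amplitude array with the injected consistency."""
        cfg = self.config
        rng = np.random.default_rng(self._pattern_seeds[(subject_id, condition)])
        n_vox = int(np.prod(cfg.grid_shape))
        flat = generate_trial_patterns(n_vox, 0.0, cfg.n_trials, rng).reshape(
            cfg.n_trials, -1
        )
        truth = self.ground_truth[subject_id]
        for region, per_cond in truth.items():
            c = per_cond.get(condition, 0.0)
            mask = self.region_masks[region].reshape(-1)
            if c > 0 and mask.any():
                flat[:, mask] = generate_trial_patterns(
                    int(mask.sum()), c, cfg.n_trials, rng
                )
        return flat.reshape(cfg.n_trials, *cfg.grid_shape)

    def subject_run(
        self, subject_id: str, condition: str
    ) -> tuple[np.ndarray, pd.DataFrame]:
        """4-D BOLD run plus its event table for one subject/session."""
        events = self.subject_events(subject_id, condition)
        patterns = self.subject_patterns(subject_id, condition)
        seed = self._run_seeds[(subject_id, condition)] + 1
        return (
            simulate_bold(events, patterns, self.config, seed),
            events,
        )


def _region_masks(config: SimulationConfig) -> dict[str, np.ndarray]:
    specs = default_region_specs(config.grid_shape)
    vols = generate_atlas_fixture(config.grid_shape, specs)
    thr = default_region_thresholds(specs)
    return {name: vols[name] >= thr[name] for name in vols}


def generate_cohort(config: SimulationConfig, seed: int | None = None) -> Cohort:
    """Two-group cohort with injected consistency and a coupled HAM-A score.

    AN subjects receive elevated c in the regions named by
    ``config.consistency_map`` (anxiety condition by default); the HAM-A-like
    score is generated from a Gaussian latent correlated at
    ``config.covariate_coupling`` with the subject-level consistency latent.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    n_an, n_ctrl = config.n_subjects_per_group
    n = n_an + n_ctrl
    children = ss.spawn(1 + 2 * n)
    rng = np.random.default_rng(children[0])
    groups = ["AN"] * n_an + ["control"] * n_ctrl
    ids = [f"sub-{i + 1:03d}" for i in range(n)]

    # Subject-level latent modulating injected consistency around the group base.
    z1 = rng.standard_normal(n)

    region_masks = _region_masks(config)
    ground_truth: dict = {}
    for i, (sid, group) in enumerate(zip(ids, groups)):
        truth: dict = {}
        for region, per_cond in config.consistency_map.items():
            if region not in region_masks:
                raise ConfigurationError(f"unknown region {region!r} in consistency_map")
            truth[region] = {}
            for cond in CONDITIONS:
                base = per_cond.get(cond, {}).get(group, 0.0)
                c = base
                if base > 0:
                    c = float(
                        np.clip(base + config.consistency_jitter_sd * z1[i], 0.0, 1.0)
                    )
                truth[region][cond] = c
        ground_truth[sid] = truth

    # Injected-consistency scalar per subject (mean over the entries the
    # consistency_map defines); HAM-A is linear in its standardized value plus
    # independent Gaussian noise, so corr(HAM-A, injected c) ~= coupling.
    c_scalar = np.array(
        [
            np.mean(
                [
                    ground_truth[sid][region][cond]
                    for region, per_cond in config.consistency_map.items()
                    for cond in per_cond
                ]
            )
            if config.consistency_map
            else 0.0
            for sid in ids
        ]
    )
    if np.std(c_scalar) > 0:
        u = (c_scalar - c_scalar.mean()) / c_scalar.std()
    else:  # no injected variation: couple to the latent instead
        u = z1
    rho = config.covariate_coupling
    z2 = rho * u + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)

    # Clinical covariates: marginals loosely follow adolescent AN vs control
    # samples (HAM-A on a cohort-wide marginal so the coupling is not confounded
    # with a separately imposed group shift).
    age = np.where(
        np.array(groups) == "AN",
        rng.normal(14.6, 1.9, n),
        rng.normal(16.2, 1.8, n),
    ).clip(10, 19)
    pds = np.where(
        np.array(groups) == "AN",
        rng.normal(14.1, 4.4, n),
        rng.normal(17.9, 1.5, n),
    ).clip(3, 20)
    ham_a = np.clip(11.0 + 7.0 * z2, 0.0, 56.0)
    rate_anx = np.clip(np.round(0.35 * ham_a + rng.normal(0, 1.5, n)), 0, 10)
    rate_neu = np.clip(np.round(0.30 * ham_a - 1.0 + rng.normal(0, 2.0, n)), 0, 10)
    medicated = np.where(
        np.array(groups) == "AN", rng.random(n) < 17 / 25, False
    )

    participants = pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "age": np.round(age, 1),
            "pds": np.round(pds, 1),
            "ham_a": np.round(ham_a, 1),
            "anxiety_rating_post_anxiety_run": rate_anx,
            "anxiety_rating_post_neutral_run": rate_neu,
            "medicated": medicated,
        }
    )

    run_seeds = {}
    pattern_seeds = {}
    for i, sid in enumerate(ids):
        for j, cond in enumerate(CONDITIONS):
            child = children[1 + 2 * i + j]
            st = child.generate_state(2)
            run_seeds[(sid, cond)] = int(st[0] % (2**31 - 2))
            pattern_seeds[(sid, cond)] = int(st[1] % (2**31 - 2))

    return Cohort(
        config=dataclasses.replace(config),
        participants=participants,
        ground_truth=ground_truth,
        region_masks=region_masks,
        _run_seeds=run_seeds,
        _pattern_seeds=pattern_seeds,
    )
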