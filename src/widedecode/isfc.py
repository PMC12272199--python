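"""Sedation arm: data-driven task vector, GLM beta maps, state-wise
decoding inputs, and within-/inter-subject functional connectivity.

The naturalistic-listening runs have no stimulus model, so the training
subjects' average seed-region (auditory analog) timecourse stands in as
the task vector.  Per-voxel GLM betas of task and rest runs against that
vector feed the decile and whole-ROI decoders.  Intersubject functional
connectivity (ISFC) correlates one subject's seed timecourse with the
other subjects' mean target timecourse, isolating stimulus-locked shared
variance: during rest there is no common source of variance and ISFC is
zero in expectation.  Connectivity is averaged across subjects on the
Fisher-z scale.  A permutation test compares state-mean ISFC vectors via
a Wald-type quadratic form, permuting state labels within subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import (
    BootstrapConfig,
    Bootstrap632Result,
    auc_columns,
    bootstrap_632plus_generic,
)
from .decoders import ActivationMapStack, build_decile_decoders, paired_t_values
from .synthetic import (
    MapStudy,
    MapStudyTruth,
    RegionSet,
    SedationStudy,
    SubjectTimeseries,
)

__all__ = [
    "TaskVector",
    "ConnectivityEstimate",
    "roi_mean_timecourse",
    "seed_task_vector",
    "glm_beta_map",
    "sedation_map_study",
    "sedation_decile_decoding",
    "sedation_roi_decoding",
    "within_subject_fc",
    "intersubject_fc",
    "isfc_state_matrix",
    "state_permutation_test",
]

_R_LIMIT = 1.0 - 1e-12


@dataclass
class TaskVector:
    s: np.ndarray
    provenance: str = ""


@dataclass
class ConnectivityEstimate:
    r: float
    z: float
    kind: str                    # "within_subject" | "intersubject"
    seed_region: str
    target_region: str
    state: str
    run_type: str
    per_subject_z: np.ndarray = field(default_factory=lambda: np.array([]))
    n_excluded: int = 0


def roi_mean_timecourse(ts: SubjectTimeseries | np.ndarray, region: np.ndarray) -> np.ndarray:
    """Per-timepoint mean over the region's voxels."""
    data = ts.data if isinstance(ts, SubjectTimeseries) else np.asarray(ts, dtype=float)
    region = np.asarray(region, dtype=np.int64)
    if region.size == 0:
        raise ValueError("region is empty")
    return data[:, region].mean(axis=1)


def seed_task_vector(
    train_ts: list[SubjectTimeseries], seed_region: np.ndarray
) -> TaskVector:
    """Average the training subjects' seed-region mean timecourses.

    Must never be handed test-subject runs: the non-circularity of the
    downstream evaluation depends on it.
    """
    if not train_ts:
        raise ValueError("need at least one training subject")
    run_types = {ts.run_type for ts in train_ts}
    if run_types != {"task"}:
        raise ValueError(f"task vector must come from task runs only, got {sorted(run_types)}")
    courses = np.stack([roi_mean_timecourse(ts, seed_region) for ts in train_ts])
    ids = ",".join(ts.subject_id for ts in train_ts)
    return TaskVector(s=courses.mean(axis=0), provenance=f"task runs of [{ids}]")


def _glm_betas(data: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Simple regression of every voxel column on [1, s]; returns (beta, t)."""
    T = data.shape[0]
    s_c = s - s.mean()
    ss = float(s_c @ s_c)
    if ss <= 0:
        raise ValueError("task vector is constant")
    x_c = data - data.mean(axis=0)
    beta = (s_c @ x_c) / ss
    resid = x_c - np.outer(s_c, beta)
    dof = T - 2
    sigma2 = (resid**2).sum(axis=0) / dof
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / np.sqrt(sigma2 / ss)
    t[~np.isfinite(t)] = 0.0
    return beta, t


def glm_beta_map(
    ts: SubjectTimeseries | np.ndarray, task: TaskVector | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel slope (beta) and t-statistic of the voxel timecourse
    regressed on [1, s(t)]."""
    data = ts.data if isinstance(ts, SubjectTimeseries) else np.asarray(ts, dtype=float)
    s = task.s if isinstance(task, TaskVector) else np.asarray(task, dtype=float)
    if data.shape[0] != s.shape[0]:
        raise ValueError("task vector length does not match the timeseries")
    return _glm_betas(data, s)


def _state_data(study: SedationStudy, state: str) -> tuple[np.ndarray, np.ndarray]:
    """(task, rest) arrays of shape (n_subjects, T, p), subject-ordered."""
    subjects = study.subjects()
    missing = [
        s for s in subjects
        for rt in ("task", "rest")
        if (s, state, rt) not in study.runs
    ]
    if missing:
        raise ValueError(f"missing task/rest runs for subjects: {sorted(set(missing))}")
    task = np.stack([study.get(s, state, "task").data for s in subjects])
    rest = np.stack([study.get(s, state, "rest").data for s in subjects])
    return task, rest


def _all_betas(task: np.ndarray, rest: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    beta_task = np.stack([_glm_betas(task[i], s)[0] for i in range(task.shape[0])])
    beta_rest = np.stack([_glm_betas(rest[i], s)[0] for i in range(rest.shape[0])])
    return beta_task, beta_rest


def sedation_map_study(
    study: SedationStudy, state: str, task_vector: TaskVector | np.ndarray | None = None
) -> MapStudy:
    """Fixed-task-vector decoding inputs: task beta maps (interest) vs
    rest beta maps (no interest) for one state.

    For the non-circular bootstrap evaluation use
    :func:`sedation_decile_decoding`, which re-derives the task vector
    from the training subjects inside every replicate.
    """
    task, rest = _state_data(study, state)
    if task_vector is None:
        seed_idx = study.regions[study.config.seed_region]
        ts = study.state_runs(state, "task")
        task_vector = seed_task_vector(ts, seed_idx)
    s = task_vector.s if isinstance(task_vector, TaskVector) else np.asarray(task_vector)
    beta_task, beta_rest = _all_betas(task, rest, s)
    ids = study.subjects()
    return MapStudy(
        maps_interest=ActivationMapStack(beta_task, list(ids)),
        maps_nointerest=ActivationMapStack(beta_rest, list(ids)),
        truth=MapStudyTruth(
            delta=np.zeros(beta_task.shape[1]),
            loadings=np.zeros((beta_task.shape[1], 0)),
            factor_scores=np.zeros((beta_task.shape[0], 0)),
        ),
    )


def _seed_courses(task: np.ndarray, seed_idx: np.ndarray) -> np.ndarray:
    return task[:, :, seed_idx].mean(axis=2)   # subjects x time


def sedation_decile_decoding(
    study: SedationStudy,
    state: str,
    config: BootstrapConfig | None = None,
    n_bins: int = 10,
    voxels: np.ndarray | None = None,
) -> Bootstrap632Result:
    """Per-state decile decoding (task vs rest) with the task vector and
    decoders re-derived from the training subjects in every replicate.

    ``voxels`` optionally restricts decoder construction (e.g. to
    off-seed voxels)."""
    config = config or BootstrapConfig()
    task, rest = _state_data(study, state)
    seed_idx = study.regions[study.config.seed_region]
    courses = _seed_courses(task, seed_idx)
    vox = slice(None) if voxels is None else np.asarray(voxels, dtype=np.int64)

    def theta_fn(train: np.ndarray, test: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        s = courses[train].mean(axis=0)
        beta_task, beta_rest = _all_betas(task, rest, s)
        bt, br = beta_task[:, vox], beta_rest[:, vox]
        t = paired_t_values(bt[train], br[train])
        decoders = build_decile_decoders(t, n_bins)
        return auc_columns(bt[test] @ decoders.weights, br[test] @ decoders.weights)

    return bootstrap_632plus_generic(theta_fn, task.shape[0], config)


def sedation_roi_decoding(
    study: SedationStudy,
    state: str,
    config: BootstrapConfig | None = None,
    regions: list[str] | None = None,
) -> tuple[Bootstrap632Result, list[str]]:
    """Whole-ROI signed-t decoders (no deciles), one AUC per region."""
    config = config or BootstrapConfig()
    task, rest = _state_data(study, state)
    seed_idx = study.regions[study.config.seed_region]
    courses = _seed_courses(task, seed_idx)
    names = regions if regions is not None else list(study.regions.regions)
    idx_sets = [study.regions[name] for name in names]
    p = task.shape[2]

    def theta_fn(train: np.ndarray, test: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        s = courses[train].mean(axis=0)
        beta_task, beta_rest = _all_betas(task, rest, s)
        t = paired_t_values(beta_task[train], beta_rest[train])
        weights = np.zeros((p, len(names)))
        for j, idx in enumerate(idx_sets):
            weights[idx, j] = t[idx]
        return auc_columns(beta_task[test] @ weights, beta_rest[test] @ weights)

    return bootstrap_632plus_generic(theta_fn, task.shape[0], config), names


def _fisher_average(r_values: np.ndarray) -> tuple[float, float, np.ndarray, int]:
    """Fisher-z average across subjects; |r| = 1 values are excluded."""
    r_values = np.asarray(r_values, dtype=float)
    keep = np.abs(r_values) < _R_LIMIT
    n_excluded = int((~keep).sum())
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} correlation(s) with |r| = 1 from Fisher averaging")
    z = np.arctanh(r_values[keep])
    per_z = np.arctanh(np.clip(r_values, -_R_LIMIT, _R_LIMIT))
    if z.size == 0:
        # e.g. seed correlated with itself: every r is exactly 1
        return float("nan"), float("nan"), per_z, n_excluded
    z_mean = float(z.mean())
    return float(np.tanh(z_mean)), z_mean, per_z, n_excluded


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def within_subject_fc(
    study: SedationStudy,
    seed_region: str,
    target_regions: list[str],
    state: str,
    run_type: str = "task",
) -> list[ConnectivityEstimate]:
    """corr(seed mean tc, target mean tc) per subject, Fisher-averaged."""
    seed_idx = study.regions[seed_region]
    out = []
    for target in target_regions:
        t_idx = study.regions[target]
        rs = []
        for sid in study.subjects():
            ts = study.get(sid, state, run_type)
            r = _corr(roi_mean_timecourse(ts, seed_idx), roi_mean_timecourse(ts, t_idx))
            if not np.isnan(r):
                rs.append(r)
        r_group, z_group, per_z, n_exc = _fisher_average(np.asarray(rs))
        out.append(ConnectivityEstimate(
            r=r_group, z=z_group, kind="within_subject",
            seed_region=seed_region, target_region=target,
            state=state, run_type=run_type, per_subject_z=per_z, n_excluded=n_exc,
        ))
    return out


def intersubject_fc(
    study: SedationStudy,
    seed_region: str,
    target_regions: list[str],
    state: str,
    run_type: str = "task",
) -> list[ConnectivityEstimate]:
    """ISFC: corr(subject i's seed tc, mean target tc of subjects j != i).

    Passing the seed region itself as a target yields seed-to-seed ISFC.
    """
    subjects = study.subjects()
    if len(subjects) < 3:
        raise ValueError("ISFC needs >= 3 subjects")
    seed_idx = study.regions[seed_region]
    seed_courses = {
        sid: roi_mean_timecourse(study.get(sid, state, run_type), seed_idx)
        for sid in subjects
    }
    out = []
    for target in target_regions:
        t_idx = study.regions[target]
        target_courses = np.stack([
            roi_mean_timecourse(study.get(sid, state, run_type), t_idx) for sid in subjects
        ])
        rs = []
        for i, sid in enumerate(subjects):
            others = np.delete(target_courses, i, axis=0).mean(axis=0)
            r = _corr(seed_courses[sid], others)
            if not np.isnan(r):
                rs.append(r)
        r_group, z_group, per_z, n_exc = _fisher_average(np.asarray(rs))
        out.append(ConnectivityEstimate(
            r=r_group, z=z_group, kind="intersubject",
            seed_region=seed_region, target_region=target,
            state=state, run_type=run_type, per_subject_z=per_z, n_excluded=n_exc,
        ))
    return out


def isfc_state_matrix(
    study: SedationStudy,
    seed_region: str | None = None,
    target_regions: list[str] | None = None,
    run_type: str = "task",
) -> tuple[np.ndarray, list[str], list[str]]:
    """Subject-level ISFC contributions as (subjects, states, pairs) Fisher-z.

    Pairs are seed-to-target for every target region (seed-to-seed
    included when the seed is listed among the targets)."""
    cfg = study.config
    seed_region = seed_region or cfg.seed_region
    if target_regions is None:
        target_regions = list(study.regions.regions)
    states = cfg.state_labels
    subjects = study.subjects()
    z = np.zeros((len(subjects), len(states), len(target_regions)))
    for si, state in enumerate(states):
        ests = intersubject_fc(study, seed_region, target_regions, state, run_type)
        for pi, est in enumerate(ests):
            z[:, si, pi] = est.per_subject_z
    return z, states, target_regions


def state_permutation_test(
    isfc_by_state: np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Wald-type permutation test of "no change across states".

    ``isfc_by_state`` holds subject-level Fisher-z ISFC values with shape
    (subjects, states, pairs).  The statistic is
    n_subjects * sum_s (m_s - m)' S_pooled^-1 (m_s - m) where m_s are
    state-mean vectors and S_pooled is the pooled within-state covariance
    of the subject-level vectors; under the null it is approximately
    chi-square with pairs * (states - 1) degrees of freedom.  The null
    distribution is built by permuting state labels within each subject;
    p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    z = np.asarray(isfc_by_state, dtype=float)
    if z.ndim == 2:
        z = z[:, :, None]
    n_subj, n_states, n_pairs = z.shape
    if n_states < 2:
        raise ValueError("need >= 2 states")
    if n_perm < 99:
        warnings.warn("n_perm < 99 gives a very coarse permutation p-value")

    def statistic(data: np.ndarray) -> float:
        m_s = data.mean(axis=0)                       # states x pairs
        grand = m_s.mean(axis=0)
        resid = data - m_s[None, :, :]
        flat = resid.reshape(-1, n_pairs)
        cov = np.cov(flat, rowvar=False, ddof=n_states)
        cov = np.atleast_2d(cov)
        eps = 1e-10 * max(np.trace(cov) / n_pairs, 1.0)
        cov = cov + eps * np.eye(n_pairs)
        inv = np.linalg.inv(cov)
        diff = m_s - grand[None, :]
        return float(n_subj * np.einsum("sp,pq,sq->", diff, inv, diff))

    obs = statistic(z)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = np.stack([z[i, rng.permutation(n_states), :] for i in range(n_subj)])
        if statistic(perm) >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return obs, p
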