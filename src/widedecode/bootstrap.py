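"""Out-of-sample discrimination via the floor-free 0.632+ bootstrap.

Decoder performance is quantified as an AUC from the Mann-Whitney
U-statistic.  The apparent (train = test = full sample) AUC is
optimistically biased; the 0.632+ estimator blends it with the mean
out-of-bag bootstrap AUC using a weight driven by the relative
overfitting rate R:

    R = 1                          if mean OOB AUC <= 0.5
    R = (app - oob) / (app - 0.5)  if app > oob      (clamped to [0, 1])
    R = 0                          otherwise
    w = 0.632 / (1 - 0.368 R)
    theta_632+ = (1 - w) * app + w * oob

Deliberately, the conventional max(oob, 0.5) floor is NOT applied, so
estimates may dip below chance; applying the floor would bias downstream
variance estimates.

All resampling is on the subject level; paired maps travel together into
the bootstrap sample, and decoders (t-map and bins) are fully re-derived
inside each bootstrap sample so nothing from the full sample leaks into
the out-of-bag evaluation.  Per-replicate RNG substreams are spawned from
the root seed by counter, so results are reproducible and independent of
any parallel scheduling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import rankdata

from .decoders import ScoreMatrix, build_decile_decoders, paired_t_values
from .synthetic import MapStudy

__all__ = [
    "AucEstimate",
    "BootstrapConfig",
    "Bootstrap632Result",
    "AucCovariance",
    "mann_whitney_auc",
    "auc_columns",
    "combine_632plus",
    "evaluate_apparent",
    "bootstrap_632plus",
    "bootstrap_632plus_arrays",
    "bootstrap_632plus_generic",
    "nested_bootstrap_cov",
    "residualize_scores",
    "residualize_paired_scores",
]


@dataclass
class AucEstimate:
    auc: float
    n_interest: int
    n_nointerest: int


@dataclass
class BootstrapConfig:
    n_replicates: int = 100
    outer_replicates: int = 500
    inner_replicates: int = 100
    seed: int | None = None
    min_oob: int = 2

    def validate(self) -> None:
        for name in ("n_replicates", "outer_replicates", "inner_replicates", "min_oob"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class Bootstrap632Result:
    theta_app: np.ndarray        # apparent AUC per decoder
    theta_boot: np.ndarray       # mean out-of-bag AUC per decoder
    replicates: np.ndarray       # n_replicates x n_decoders OOB AUCs
    R_hat: np.ndarray
    w_hat: np.ndarray
    theta_632plus: np.ndarray
    n_redraws: int = 0


@dataclass
class AucCovariance:
    estimates: np.ndarray        # point 0.632+ estimates (full sample)
    replicates: np.ndarray       # outer_replicates x n_decoders 0.632+ estimates
    covariance: np.ndarray       # n_decoders x n_decoders


def mann_whitney_auc(
    scores_interest: np.ndarray, scores_nointerest: np.ndarray
) -> AucEstimate:
    """AUC = (#wins + 0.5 #ties) / (n_I * n_NI) over all cross pairs."""
    a = np.asarray(scores_interest, dtype=float).ravel()
    b = np.asarray(scores_nointerest, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("score vectors must be non-empty")
    auc = float(auc_columns(a[:, None], b[:, None])[0])
    return AucEstimate(auc=auc, n_interest=a.size, n_nointerest=b.size)


def auc_columns(interest: np.ndarray, nointerest: np.ndarray) -> np.ndarray:
    """Column-wise Mann-Whitney AUC between two (n x k) score matrices.

    Rank-based: equivalent to counting cross pairs with ties scored 0.5.
    """
    a = np.atleast_2d(np.asarray(interest, dtype=float))
    b = np.atleast_2d(np.asarray(nointerest, dtype=float))
    n_a, n_b = a.shape[0], b.shape[0]
    ranks = rankdata(np.concatenate([a, b], axis=0), axis=0, method="average")
    u = ranks[:n_a].sum(axis=0) - n_a * (n_a + 1) / 2.0
    return u / (n_a * n_b)


def combine_632plus(
    theta_app: np.ndarray, theta_boot: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Relative overfitting rate, weight, and floor-free 0.632+ estimate."""
    app = np.atleast_1d(np.asarray(theta_app, dtype=float))
    boot = np.atleast_1d(np.asarray(theta_boot, dtype=float))
    R = np.zeros_like(app)
    low = boot <= 0.5
    R[low] = 1.0
    over = (~low) & (app > boot)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (app - boot) / (app - 0.5)
    R[over] = ratio[over]
    R = np.clip(R, 0.0, 1.0)
    w = 0.632 / (1.0 - 0.368 * R)
    theta = (1.0 - w) * app + w * boot
    return R, w, theta


def _decile_theta(
    interest: np.ndarray,
    nointerest: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    n_bins: int,
    rng: np.random.Generator | None,
    voxel_sampler: Callable[[np.random.Generator], np.ndarray] | None,
    tmap_transform: Callable[[np.ndarray, int, np.random.Generator], np.ndarray] | None,
) -> np.ndarray:
    vox = voxel_sampler(rng) if voxel_sampler is not None else slice(None)
    tr_i = interest[train][:, vox]
    tr_n = nointerest[train][:, vox]
    t = paired_t_values(tr_i, tr_n)
    if tmap_transform is not None:
        t = tmap_transform(t, len(train) - 1, rng)
    decoders = build_decile_decoders(t, n_bins)
    s_i = interest[test][:, vox] @ decoders.weights
    s_n = nointerest[test][:, vox] @ decoders.weights
    return auc_columns(s_i, s_n)


def evaluate_apparent(study: MapStudy, n_bins: int = 10) -> np.ndarray:
    """Per-bin apparent AUC: decoders built and scored on the full sample."""
    n = study.n_subjects
    idx = np.arange(n)
    return _decile_theta(
        study.maps_interest.values, study.maps_nointerest.values,
        idx, idx, n_bins, None, None, None,
    )


def _resample(
    rng: np.random.Generator, n: int, min_oob: int, max_tries: int = 1000
) -> tuple[np.ndarray, np.ndarray, int]:
    """Subject-level bootstrap draw; redraw until >= min_oob are out of bag."""
    redraws = 0
    for _ in range(max_tries):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size >= min_oob:
            return boot, oob, redraws
        redraws += 1
    raise RuntimeError(f"could not draw a bootstrap sample with >= {min_oob} OOB subjects")


def bootstrap_632plus_generic(
    theta_fn: Callable[[np.ndarray, np.ndarray, np.random.Generator], np.ndarray],
    n_subjects: int,
    config: BootstrapConfig,
    min_oob: int | None = None,
    stochastic_apparent: bool = False,
) -> Bootstrap632Result:
    """Run the floor-free 0.632+ procedure around an arbitrary fit/score map.

    ``theta_fn(train_idx, test_idx, rng)`` must return a vector of
    performance values in [0, 1] with chance at 0.5.  When the fit itself
    is stochastic (e.g. per-replicate noise injection or voxel
    subsampling), set ``stochastic_apparent`` so the apparent term is
    averaged over replicate-matched draws instead of evaluated once.
    """
    config.validate()
    if n_subjects < 4:
        raise ValueError(f"0.632+ bootstrap needs >= 4 subjects, got {n_subjects}")
    min_oob = config.min_oob if min_oob is None else min_oob
    b = config.n_replicates
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(2 * b)
    all_idx = np.arange(n_subjects)

    reps = []
    n_redraws = 0
    for i in range(b):
        rng = np.random.default_rng(streams[i])
        boot, oob, r = _resample(rng, n_subjects, min_oob)
        n_redraws += r
        reps.append(theta_fn(boot, oob, rng))
    replicates = np.asarray(reps)
    theta_boot = replicates.mean(axis=0)

    if stochastic_apparent:
        apparent = np.mean(
            [theta_fn(all_idx, all_idx, np.random.default_rng(streams[b + i])) for i in range(b)],
            axis=0,
        )
    else:
        apparent = theta_fn(all_idx, all_idx, np.random.default_rng(streams[b]))
    apparent = np.atleast_1d(np.asarray(apparent, dtype=float))

    R, w, theta = combine_632plus(apparent, theta_boot)
    return Bootstrap632Result(
        theta_app=apparent, theta_boot=theta_boot, replicates=replicates,
        R_hat=R, w_hat=w, theta_632plus=theta, n_redraws=n_redraws,
    )


def bootstrap_632plus_arrays(
    interest: np.ndarray,
    nointerest: np.ndarray,
    config: BootstrapConfig,
    n_bins: int = 10,
    voxel_sampler: Callable[[np.random.Generator], np.ndarray] | None = None,
    tmap_transform: Callable[[np.ndarray, int, np.random.Generator], np.ndarray] | None = None,
) -> Bootstrap632Result:
    """Decile-decoder 0.632+ bootstrap on raw paired (n x p) arrays."""
    interest = np.asarray(interest, dtype=float)
    nointerest = np.asarray(nointerest, dtype=float)
    if interest.shape != nointerest.shape:
        raise ValueError("paired stacks must have identical shapes")
    stochastic = voxel_sampler is not None or tmap_transform is not None

    def theta_fn(train: np.ndarray, test: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return _decile_theta(
            interest, nointerest, train, test, n_bins, rng, voxel_sampler, tmap_transform
        )

    return bootstrap_632plus_generic(
        theta_fn, interest.shape[0], config, stochastic_apparent=stochastic
    )


def bootstrap_632plus(
    study: MapStudy,
    config: BootstrapConfig,
    n_bins: int = 10,
    voxel_sampler: Callable[[np.random.Generator], np.ndarray] | None = None,
    tmap_transform: Callable[[np.ndarray, int, np.random.Generator], np.ndarray] | None = None,
) -> Bootstrap632Result:
    """Decile-decoder 0.632+ bootstrap for a paired map study."""
    return bootstrap_632plus_arrays(
        study.maps_interest.values, study.maps_nointerest.values,
        config, n_bins, voxel_sampler, tmap_transform,
    )


def nested_bootstrap_cov(
    study: MapStudy,
    config: BootstrapConfig,
    n_bins: int = 10,
    transform: Callable[[np.ndarray], np.ndarray] | None = None,
) -> AucCovariance:
    """Variance-covariance of the per-decoder 0.632+ estimates.

    The outer loop resamples subjects with replacement; each outer
    replicate runs the complete inner 0.632+ procedure on the resampled
    study.  ``transform`` (e.g. squeeze + logit) is applied to each outer
    estimate vector before the covariance is computed.
    """
    config.validate()
    interest = study.maps_interest.values
    nointerest = study.maps_nointerest.values
    n = interest.shape[0]
    root = np.random.SeedSequence(config.seed)
    outer_streams = root.spawn(config.outer_replicates + 1)

    point_seed = int(np.random.default_rng(outer_streams[-1]).integers(0, 2**31 - 1))
    point = bootstrap_632plus_arrays(
        interest, nointerest,
        BootstrapConfig(
            n_replicates=config.inner_replicates, seed=point_seed, min_oob=config.min_oob
        ),
        n_bins,
    ).theta_632plus

    rows = []
    for o in range(config.outer_replicates):
        rng = np.random.default_rng(outer_streams[o])
        idx = rng.integers(0, n, size=n)
        inner = BootstrapConfig(
            n_replicates=config.inner_replicates,
            seed=int(rng.integers(0, 2**31 - 1)),
            min_oob=config.min_oob,
        )
        res = bootstrap_632plus_arrays(interest[idx], nointerest[idx], inner, n_bins)
        est = res.theta_632plus
        rows.append(transform(est) if transform is not None else est)
    replicates = np.asarray(rows)
    cov = np.cov(replicates, rowvar=False)
    cov = np.atleast_2d(cov)
    if transform is not None:
        point = transform(point)
    return AucCovariance(estimates=point, replicates=replicates, covariance=cov)


def residualize_paired_scores(
    scores_interest: np.ndarray,
    scores_nointerest: np.ndarray,
    covariates_interest: np.ndarray,
    covariates_nointerest: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Jointly orthogonalize both conditions' dot products to per-scan
    covariates (e.g. head motion summaries) and report the per-column
    change in AUC.

    The two score matrices are stacked and residualized with a single
    fit, so covariate-driven separation (a systematic motion difference
    between conditions) is removed while a genuine condition difference
    orthogonal to the covariates survives.  When the covariates were
    measured once per subject rather than per scan, pass only
    ``covariates_interest``.  Returns (residual interest, residual
    no-interest, delta AUC) with delta AUC = AUC(before) - AUC(after).
    """
    a = np.atleast_2d(np.asarray(scores_interest, dtype=float))
    b = np.atleast_2d(np.asarray(scores_nointerest, dtype=float))
    if a.shape != b.shape:
        raise ValueError("paired score matrices must have identical shapes")
    c_a = np.atleast_2d(np.asarray(covariates_interest, dtype=float))
    c_b = c_a if covariates_nointerest is None else np.atleast_2d(
        np.asarray(covariates_nointerest, dtype=float)
    )
    before = auc_columns(a, b)
    stacked = residualize_scores(np.vstack([a, b]), np.vstack([c_a, c_b]))
    n = a.shape[0]
    res_a, res_b = stacked.scores[:n], stacked.scores[n:]
    after = auc_columns(res_a, res_b)
    return res_a, res_b, before - after


def residualize_scores(
    scores: ScoreMatrix | np.ndarray, covariates: np.ndarray
) -> ScoreMatrix:
    """Orthogonalize decoder dot products to nuisance covariates.

    Each score column is replaced by its residual from a least-squares
    projection onto [1, covariates].  Collinear covariate columns are
    handled by a minimum-norm fit (a warning is emitted).
    """
    y = scores.scores if isinstance(scores, ScoreMatrix) else np.asarray(scores, dtype=float)
    y = np.atleast_2d(y)
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != y.shape[0]:
        raise ValueError("covariate rows must align with subjects")
    X = np.column_stack([np.ones(y.shape[0]), c])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("covariates are rank deficient; using minimum-norm projection")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    cond = scores.condition if isinstance(scores, ScoreMatrix) else ""
    return ScoreMatrix(scores=resid, condition=cond)
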