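"""Across-subject covariance decoding in principal-component space.

The condition-of-interest maps are column-wise z-scored and decomposed
with an SVD; dimensionality is chosen by parallel analysis against
phase-scrambled surrogates (which preserve each map's amplitude spectrum,
hence its spatial autocorrelation, while destroying cross-subject
covariance).  Out-of-sample maps from both conditions are independently
z-scored, projected into the training component space, summarized as
multivariate Gaussians, and classified by which condition's summary has
the smaller Kullback-Leibler divergence from the training summary.  The
win rate, aggregated with the floor-free 0.632+ weighting, is the
expected out-of-sample classification accuracy.  A whole-mask signed-t
decoder with a univariate (k = 1) KL rule serves as the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .bootstrap import BootstrapConfig, Bootstrap632Result, bootstrap_632plus_generic
from .decoders import ActivationMapStack, paired_t_values
from .synthetic import MapStudy

__all__ = [
    "PrincipalSpace",
    "SurrogateEnsemble",
    "GaussianSummary",
    "zscore_columns",
    "pca_svd",
    "phase_scramble",
    "parallel_analysis",
    "gaussian_kl",
    "kl_classify",
    "principal_angles",
    "replicate_accuracy_correlation",
]


@dataclass
class PrincipalSpace:
    loadings: np.ndarray            # voxels x k, orthonormal columns
    scores: np.ndarray              # subjects x k
    explained_variance: np.ndarray  # per component
    column_means: np.ndarray
    column_sds: np.ndarray

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        total = self.explained_variance.sum()
        return self.explained_variance / total if total > 0 else self.explained_variance


@dataclass
class SurrogateEnsemble:
    n_surrogates: int
    spectra: np.ndarray             # n_surrogates x n_components EV ratios
    thresholds: np.ndarray          # per-rank percentile of the null spectra
    percentile: float


@dataclass
class GaussianSummary:
    mu: np.ndarray
    sigma: np.ndarray

    @property
    def k(self) -> int:
        return self.mu.shape[0]


def zscore_columns(
    values: np.ndarray, return_record: bool = False
) -> np.ndarray | tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring; constant columns map to all-zeros."""
    x = np.asarray(values, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 rows")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    safe = np.where(sds > 0, sds, 1.0)
    z = (x - means) / safe
    z[:, sds == 0] = 0.0
    if return_record:
        return z, means, sds
    return z


def pca_svd(values: np.ndarray | ActivationMapStack) -> PrincipalSpace:
    """PCA of a subjects x voxels matrix via SVD of the z-scored data.

    Components are sign-fixed so each loading's largest-magnitude entry
    is positive; explained variance is singular value^2 / (n - 1).
    """
    x = values.values if isinstance(values, ActivationMapStack) else np.asarray(values, float)
    z, means, sds = zscore_columns(x, return_record=True)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt.T
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = z @ loadings
    ev = s**2 / (x.shape[0] - 1)
    return PrincipalSpace(
        loadings=loadings, scores=scores, explained_variance=ev,
        column_means=means, column_sds=sds,
    )


def phase_scramble(
    maps: np.ndarray,
    rng: np.random.Generator | int | None = None,
    grid_shape: tuple[int, ...] | None = None,
) -> np.ndarray:
    """Fourier phase-scrambled surrogate(s) with identical amplitude spectra.

    Each map (row of a 2-D input, or the 1-D input itself) is DFT'd, its
    phases are replaced by uniform random phases with Hermitian symmetry
    (DC and Nyquist bins stay real), and the inverse transform is taken.
    With ``grid_shape`` the scrambling runs on the 3-D volume instead of
    the flattened voxel vector.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    x = np.asarray(maps, dtype=float)
    single = x.ndim == 1
    rows = x[None, :] if single else x
    out = np.empty_like(rows)
    for i, row in enumerate(rows):
        if grid_shape is not None:
            vol = row.reshape(grid_shape)
            f = np.fft.fftn(vol)
            # Hermitian-symmetric random phases: take the phases of the FFT
            # of a real white-noise volume (DC forced positive so the mean
            # is preserved)
            g = np.fft.fftn(rng.normal(size=grid_shape))
            mag = np.abs(g)
            mag[mag == 0] = 1.0
            unit = g / mag
            dc = (0,) * len(grid_shape)
            unit[dc] = 1.0 if f[dc].real >= 0 else -1.0  # mean preserved
            sur = np.fft.ifftn(np.abs(f) * unit).real
            out[i] = sur.ravel()
        else:
            f = np.fft.rfft(row)
            spectrum = np.abs(f) * np.exp(
                1j * rng.uniform(0, 2 * np.pi, size=f.shape)
            )
            spectrum[0] = f[0]  # DC kept verbatim: mean preserved
            if row.shape[0] % 2 == 0:
                spectrum[-1] = f[-1]  # Nyquist bin must stay real
            sur = np.fft.irfft(spectrum, n=row.shape[0])
            out[i] = sur
    return out[0] if single else out


def parallel_analysis(
    values: np.ndarray | ActivationMapStack,
    n_surrogates: int = 100,
    percentile: float = 95.0,
    seed: int | None = None,
    grid_shape: tuple[int, ...] | None = None,
) -> tuple[int, SurrogateEnsemble]:
    """Retained dimensionality against the phase-scrambled noise floor.

    k is the largest m such that the observed explained-variance ratio
    exceeds the per-rank ``percentile`` of the surrogate spectra at every
    rank j <= m.
    """
    x = values.values if isinstance(values, ActivationMapStack) else np.asarray(values, float)
    observed = pca_svd(x).explained_variance_ratio
    root = np.random.SeedSequence(seed)
    spectra = np.empty((n_surrogates, observed.shape[0]))
    for i, stream in enumerate(root.spawn(n_surrogates)):
        sur = phase_scramble(x, np.random.default_rng(stream), grid_shape=grid_shape)
        spectra[i] = pca_svd(sur).explained_variance_ratio
    thresholds = np.percentile(spectra, percentile, axis=0)
    above = observed > thresholds
    k = int(np.argmin(above)) if not above.all() else observed.shape[0]
    ensemble = SurrogateEnsemble(
        n_surrogates=n_surrogates, spectra=spectra,
        thresholds=thresholds, percentile=percentile,
    )
    return k, ensemble


def _regularize_cov(sigma: np.ndarray, eps_scale: float = 1e-8) -> np.ndarray:
    sigma = np.atleast_2d(np.asarray(sigma, dtype=float))
    sigma = 0.5 * (sigma + sigma.T)
    k = sigma.shape[0]
    eps = eps_scale * np.trace(sigma) / k
    if eps <= 0:
        eps = eps_scale
    if np.linalg.eigvalsh(sigma)[0] < eps:
        sigma = sigma + eps * np.eye(k)
    return sigma


def summarize_gaussian(scores: np.ndarray) -> GaussianSummary:
    """Mean and (regularized) covariance of component-space projections."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[0] < 2:
        raise ValueError("need >= 2 samples to estimate a covariance")
    mu = scores.mean(axis=0)
    sigma = np.cov(scores, rowvar=False, ddof=1)
    return GaussianSummary(mu=mu, sigma=_regularize_cov(sigma))


def gaussian_kl(test: GaussianSummary, train: GaussianSummary) -> float:
    """KL(test || train) between multivariate Gaussian summaries, in nats.

    0.5 * ( tr(S_train^-1 S_test) - k + dmu' S_train^-1 dmu
            + ln(det S_train / det S_test) )
    """
    if test.k != train.k:
        raise ValueError("summaries have different dimensionality")
    k = test.k
    s_train = _regularize_cov(train.sigma)
    s_test = _regularize_cov(test.sigma)
    sign_tr, logdet_train = np.linalg.slogdet(s_train)
    sign_te, logdet_test = np.linalg.slogdet(s_test)
    if sign_tr <= 0 or sign_te <= 0:
        raise np.linalg.LinAlgError("covariance not positive definite after regularization")
    inv_train = np.linalg.inv(s_train)
    dmu = train.mu - test.mu
    val = 0.5 * (
        np.trace(inv_train @ s_test) - k + dmu @ inv_train @ dmu
        + logdet_train - logdet_test
    )
    return float(val)


def kl_classify(
    study: MapStudy,
    k: int = 4,
    config: BootstrapConfig | None = None,
    mode: Literal["pc_space", "univariate_t"] = "pc_space",
) -> Bootstrap632Result:
    """0.632+ classification accuracy of the KL decision rule.

    Per replicate: fit the decoder on the bootstrap training sample
    (PCA of z-scored interest maps, or the whole-mask signed-t map),
    project independently z-scored out-of-bag maps of both conditions,
    summarize each condition as a Gaussian, and award a win (1) when the
    interest condition is KL-closer to the training summary.
    """
    config = config or BootstrapConfig()
    interest = study.maps_interest.values
    nointerest = study.maps_nointerest.values
    n = interest.shape[0]
    if n < 8:
        raise ValueError("KL classification needs >= 8 subjects")

    def theta_fn(train: np.ndarray, test: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if mode == "pc_space":
            space = pca_svd(interest[train])
            load = space.loadings[:, :k]
            train_scores = space.scores[:, :k]
            test_i = zscore_columns(interest[test]) @ load
            test_n = zscore_columns(nointerest[test]) @ load
        elif mode == "univariate_t":
            t = paired_t_values(interest[train], nointerest[train])
            train_scores = (interest[train] @ t)[:, None]
            test_i = (interest[test] @ t)[:, None]
            test_n = (nointerest[test] @ t)[:, None]
        else:
            raise ValueError(f"unknown mode {mode!r}")
        summary_train = summarize_gaussian(train_scores)
        kl_i = gaussian_kl(summarize_gaussian(test_i), summary_train)
        kl_n = gaussian_kl(summarize_gaussian(test_n), summary_train)
        return np.array([1.0 if kl_i < kl_n else 0.0])

    min_oob = max(config.min_oob, (k if mode == "pc_space" else 1) + 1)
    return bootstrap_632plus_generic(theta_fn, n, config, min_oob=min_oob)


def replicate_accuracy_correlation(a: Bootstrap632Result, b: Bootstrap632Result) -> float:
    """Pearson correlation between two decoders' replicate win series.

    Run both decoders with the same bootstrap config/seed so replicate i
    uses the same subject resample in each.
    """
    x = a.replicates.ravel()
    y = b.replicates.ravel()
    if x.std() == 0 or y.std() == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def principal_angles(basis_a: np.ndarray, basis_b: np.ndarray) -> np.ndarray:
    """Principal angles (degrees) between two column subspaces."""
    qa, _ = np.linalg.qr(np.asarray(basis_a, dtype=float))
    qb, _ = np.linalg.qr(np.asarray(basis_b, dtype=float))
    svals = np.linalg.svd(qa.T @ qb, compute_uv=False)
    return np.degrees(np.arccos(np.clip(svals, -1.0, 1.0)))
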