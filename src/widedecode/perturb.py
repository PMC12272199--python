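"""Boundary-condition experiments for the decile decoders.

Three controls probe where the widespread-information finding breaks
down: (1) Gaussian noise whose per-voxel SD is proportional to the
voxel's t-statistic (so high-SNR voxels are not preferentially spared),
after which the noisy t values are converted to Pearson r for decoding;
(2) random voxel subsampling down to a target decoder size; and (3)
voxel-count-matched comparisons between named regions (anatomical or
tissue-class analogs).  Noise injection and voxel subsampling happen
inside every 0.632+ replicate and the resulting AUCs are averaged across
iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bootstrap import BootstrapConfig, bootstrap_632plus_arrays
from .decoders import TStatMap, t_to_r
from .synthetic import MapStudy, RegionSet

__all__ = [
    "NoisePerturbation",
    "SubsampleSpec",
    "add_snr_scaled_noise",
    "noise_perturbation_curve",
    "subsample_decoder_voxels",
    "matched_region_subsample",
]

DEFAULT_NOISE_LEVELS = (0, 1, 2, 3, 4, 5)
DEFAULT_SUBSAMPLE_SIZES = (100, 250, 500, 1000, 2500, 5000, 7500, 10735)


@dataclass
class NoisePerturbation:
    c_levels: tuple[float, ...] = DEFAULT_NOISE_LEVELS
    n_iterations: int = 500
    seed: int | None = None

    def validate(self) -> None:
        if any(c < 0 for c in self.c_levels):
            raise ValueError("noise multipliers must be >= 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class SubsampleSpec:
    sizes: tuple[int, ...] = DEFAULT_SUBSAMPLE_SIZES
    n_iterations: int = 500
    seed: int | None = None

    def validate(self, n_voxels: int) -> None:
        if any(s < 1 for s in self.sizes):
            raise ValueError("subsample sizes must be >= 1")
        too_big = [s for s in self.sizes if s > n_voxels]
        if too_big:
            raise ValueError(f"subsample sizes {too_big} exceed the {n_voxels}-voxel mask")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def add_snr_scaled_noise(
    tmap: TStatMap | np.ndarray, c: float, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """t' = t + e, e ~ Normal(0, sd = c * |t|); t = 0 voxels get no noise.

    c * |t| is read as the standard deviation of the injected noise.
    """
    if c < 0:
        raise ValueError("c must be >= 0")
    t = tmap.t if isinstance(tmap, TStatMap) else np.asarray(tmap, dtype=float)
    if c == 0:
        return t.copy()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return t + rng.normal(0.0, 1.0, size=t.shape) * (c * np.abs(t))


def _run_decile_bootstrap(study: MapStudy, config: BootstrapConfig, n_bins, **kw):
    return bootstrap_632plus_arrays(
        study.maps_interest.values, study.maps_nointerest.values, config, n_bins, **kw
    )


def noise_perturbation_curve(
    study: MapStudy,
    perturbation: NoisePerturbation | None = None,
    config: BootstrapConfig | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """Mean 0.632+ AUC per (c, decile) with SNR-scaled noise injected and
    t converted to r inside each replicate."""
    perturbation = perturbation or NoisePerturbation()
    perturbation.validate()
    config = config or BootstrapConfig()
    rows = []
    for c in perturbation.c_levels:
        cfg = BootstrapConfig(
            n_replicates=perturbation.n_iterations,
            seed=config.seed, min_oob=config.min_oob,
        )

        def transform(t: np.ndarray, df: int, rng: np.random.Generator) -> np.ndarray:
            return t_to_r(add_snr_scaled_noise(t, c, rng), df=df)

        res = _run_decile_bootstrap(study, cfg, n_bins, tmap_transform=transform)
        for d in range(n_bins):
            rows.append({
                "c": c, "decile": d + 1,
                "auc": res.theta_632plus[d],
                "theta_app": res.theta_app[d],
                "theta_boot": res.theta_boot[d],
            })
    return pd.DataFrame(rows)


def _voxel_sampler(pool: np.ndarray, size: int):
    pool = np.asarray(pool, dtype=np.int64)
    if size == pool.size:
        # full pool: exact no-op relative to the unsubsampled pipeline
        return None if pool.size and np.array_equal(pool, np.arange(pool.size)) else (
            lambda rng: pool
        )

    def sampler(rng: np.random.Generator) -> np.ndarray:
        return np.sort(rng.choice(pool, size=size, replace=False))

    return sampler


def subsample_decoder_voxels(
    study: MapStudy,
    spec: SubsampleSpec | None = None,
    config: BootstrapConfig | None = None,
    n_bins: int = 10,
) -> pd.DataFrame:
    """AUC-vs-decoder-size table; a fresh uniform voxel subset is drawn
    inside each 0.632+ replicate."""
    spec = spec or SubsampleSpec()
    config = config or BootstrapConfig()
    p = study.n_voxels
    spec.validate(p)
    pool = np.arange(p)
    rows = []
    for size in spec.sizes:
        cfg = BootstrapConfig(
            n_replicates=spec.n_iterations, seed=config.seed, min_oob=config.min_oob
        )
        res = _run_decile_bootstrap(
            study, cfg, n_bins, voxel_sampler=_voxel_sampler(pool, size)
        )
        for d in range(n_bins):
            rows.append({
                "size": size, "decile": d + 1,
                "auc": res.theta_632plus[d],
                "theta_app": res.theta_app[d],
                "theta_boot": res.theta_boot[d],
            })
    return pd.DataFrame(rows)


def matched_region_subsample(
    study: MapStudy,
    regions: RegionSet,
    match_size: int,
    config: BootstrapConfig | None = None,
    n_bins: int = 10,
    n_iterations: int | None = None,
) -> pd.DataFrame:
    """Per-region decile AUCs with decoders built from ``match_size``
    voxels resampled from each region inside every replicate."""
    config = config or BootstrapConfig()
    small = [name for name, idx in regions.regions.items() if idx.size < match_size]
    if small:
        raise ValueError(f"regions smaller than match_size={match_size}: {small}")
    rows = []
    for name, idx in regions.regions.items():
        cfg = BootstrapConfig(
            n_replicates=n_iterations or config.n_replicates,
            seed=config.seed, min_oob=config.min_oob,
        )
        res = _run_decile_bootstrap(
            study, cfg, n_bins, voxel_sampler=_voxel_sampler(idx, match_size)
        )
        for d in range(n_bins):
            rows.append({
                "region": name, "decile": d + 1, "size": match_size,
                "auc": res.theta_632plus[d],
                "theta_app": res.theta_app[d],
                "theta_boot": res.theta_boot[d],
            })
    return pd.DataFrame(rows)
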