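"""Synthetic map and sedation-timeseries studies with known ground truth.

Two families of studies are generated:

* **Map studies** — paired per-subject activation (beta) maps for a
  condition of interest and of no interest.  The interest condition adds a
  per-voxel mean effect ``delta`` (widespread-and-weak, localized, or
  null) and optionally a low-rank across-subject latent component with
  spatially smooth loadings, on top of a shared baseline map and i.i.d.
  Gaussian noise.
* **Sedation studies** — multi-subject timeseries in which a common
  smoothed stimulus signal drives a seed region at constant amplitude and
  every other voxel at an amplitude attenuated by a per-state sedation
  parameter ``g``; matched rest runs carry no stimulus.  A per-run shared
  within-subject noise component gives all regions of one subject common
  variance, emulating stable intrinsic network structure.

All generators are deterministic given their config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .decoders import ActivationMapStack

__all__ = [
    "ConfigError",
    "MapStudyConfig",
    "MapStudyTruth",
    "MapStudy",
    "SedationStudyConfig",
    "SubjectTimeseries",
    "SedationStudy",
    "RegionSet",
    "gen_map_study",
    "gen_sedation_study",
    "gen_region_set",
    "default_sedation_regions",
]

SignalProfile = Literal["widespread", "localized", "null"]

#: default sedation states: Ramsey-scale inspired labels with stimulus
#: attenuation g per state (awake must have g = 0)
DEFAULT_STATES: tuple[tuple[str, float], ...] = (
    ("awake", 0.0),
    ("light", 0.4),
    ("deep", 0.8),
    ("recover", 0.3),
)

#: one seed (auditory analog) plus four target regions
DEFAULT_REGION_SIZES: dict[str, int] = {
    "auditory": 40,
    "posterior": 40,
    "anterior": 40,
    "visual": 40,
    "motor": 40,
}


class ConfigError(ValueError):
    """Invalid study configuration; the message names the offending field."""


@dataclass
class MapStudyConfig:
    n_subjects: int = 30
    n_voxels: int = 2000
    signal_profile: SignalProfile = "widespread"
    effect_scale: float = 0.3
    blob_fraction: float = 0.1
    latent_rank: int = 0
    latent_strength: float = 0.0
    noise_sd: float = 1.0
    motion_corr: float = 0.0
    grid_shape: tuple[int, ...] | None = None
    seed: int | None = None

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ConfigError("n_subjects must be >= 3")
        if self.n_voxels < 10:
            raise ConfigError("n_voxels must be >= 10")
        if self.signal_profile not in ("widespread", "localized", "null"):
            raise ConfigError(f"signal_profile unknown: {self.signal_profile!r}")
        if not 0 < self.blob_fraction <= 1:
            raise ConfigError("blob_fraction must be in (0, 1]")
        for name in ("effect_scale", "latent_strength", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.latent_rank < 0:
            raise ConfigError("latent_rank must be >= 0")
        if not -1 <= self.motion_corr <= 1:
            raise ConfigError("motion_corr must be in [-1, 1]")
        if self.grid_shape is not None and int(np.prod(self.grid_shape)) < self.n_voxels:
            raise ConfigError("grid_shape product must be >= n_voxels")


@dataclass
class MapStudyTruth:
    """Generating parameters stored for parameter-recovery tests."""

    delta: np.ndarray           # per-voxel true mean effect
    loadings: np.ndarray        # voxels x latent_rank (column RMS = 1)
    factor_scores: np.ndarray   # subjects x latent_rank


@dataclass
class MapStudy:
    maps_interest: ActivationMapStack
    maps_nointerest: ActivationMapStack
    truth: MapStudyTruth
    motion: np.ndarray | None = None
    config: MapStudyConfig | None = None

    @property
    def n_subjects(self) -> int:
        return self.maps_interest.n_subjects

    @property
    def n_voxels(self) -> int:
        return self.maps_interest.n_voxels


def _smooth_columns(x: np.ndarray, width: int) -> np.ndarray:
    """Moving-average smoothing along axis 0, then rescale to unit RMS."""
    sm = uniform_filter1d(x, size=max(int(width), 1), axis=0, mode="wrap")
    rms = np.sqrt((sm**2).mean(axis=0, keepdims=True))
    rms[rms == 0] = 1.0
    return sm / rms


def gen_map_study(config: MapStudyConfig) -> MapStudy:
    """Generate a paired two-condition map study.

    no-interest map:  baseline + noise
    interest map:     baseline + delta + latent + noise
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_subjects, config.n_voxels

    # smooth shared baseline; cancels in the pairing but gives maps a
    # realistic common spatial structure
    baseline = _smooth_columns(rng.normal(size=(p, 1)), width=p // 50 or 1)[:, 0]

    if config.signal_profile == "widespread":
        delta = rng.normal(0.0, config.effect_scale, size=p)
    elif config.signal_profile == "localized":
        # a coherent activation blob: constant positive effect across a
        # contiguous block (the classical suprathreshold cluster)
        block = int(round(config.blob_fraction * p))
        block = max(block, 1)
        start = int(rng.integers(0, p - block + 1))
        delta = np.zeros(p)
        delta[start : start + block] = config.effect_scale
    else:  # null
        delta = np.zeros(p)

    rank = config.latent_rank if config.signal_profile != "null" else 0
    strength = config.latent_strength if config.signal_profile != "null" else 0.0
    if rank > 0:
        loadings = _smooth_columns(rng.normal(size=(p, rank)), width=p // 50 or 1)
        scores = rng.normal(0.0, strength, size=(n, rank))
        latent = scores @ loadings.T
    else:
        loadings = np.zeros((p, 0))
        scores = np.zeros((n, 0))
        latent = 0.0

    eps_interest = rng.normal(0.0, config.noise_sd, size=(n, p))
    eps_nointerest = rng.normal(0.0, config.noise_sd, size=(n, p))

    interest = baseline[None, :] + delta[None, :] + latent + eps_interest
    nointerest = baseline[None, :] + eps_nointerest

    subject_ids = [f"sub-{i:03d}" for i in range(n)]
    mask = np.arange(p) if config.grid_shape is not None else None
    stack_kw = dict(mask=mask, grid_shape=config.grid_shape)
    maps_interest = ActivationMapStack(interest, list(subject_ids), **stack_kw)
    maps_nointerest = ActivationMapStack(nointerest, list(subject_ids), **stack_kw)

    # subject-level motion summary, correlated with mean map amplitude
    amp = interest.mean(axis=1)
    amp_std = (amp - amp.mean()) / (amp.std() if amp.std() > 0 else 1.0)
    r = config.motion_corr
    motion = (r * amp_std + np.sqrt(max(1 - r**2, 0.0)) * rng.normal(size=n))[:, None]

    return MapStudy(
        maps_interest=maps_interest,
        maps_nointerest=maps_nointerest,
        truth=MapStudyTruth(delta=delta, loadings=loadings, factor_scores=scores),
        motion=motion,
        config=config,
    )


@dataclass
class RegionSet:
    """Disjoint named voxel index sets; unlabeled voxels are background."""

    regions: dict[str, np.ndarray]
    n_voxels: int
    grid_shape: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, idx in self.regions.items():
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size == 0:
                raise ConfigError(f"region {name!r} is empty")
            if idx.max() >= self.n_voxels or idx.min() < 0:
                raise ConfigError(f"region {name!r} has out-of-range voxel indices")
            overlap = seen.intersection(idx.tolist())
            if overlap:
                raise ConfigError(f"region {name!r} overlaps previously defined regions")
            seen.update(idx.tolist())
            self.regions[name] = idx

    def __getitem__(self, name: str) -> np.ndarray:
        return self.regions[name]

    @property
    def background(self) -> np.ndarray:
        labeled = np.concatenate(list(self.regions.values())) if self.regions else []
        mask = np.ones(self.n_voxels, dtype=bool)
        mask[np.asarray(labeled, dtype=np.int64)] = False
        return np.flatnonzero(mask)

    def labels(self) -> np.ndarray:
        out = np.full(self.n_voxels, "background", dtype=object)
        for name, idx in self.regions.items():
            out[idx] = name
        return out


def gen_region_set(
    region_sizes: dict[str, int],
    n_voxels: int,
    grid_shape: tuple[int, ...] | None = None,
) -> RegionSet:
    """Contiguous, disjoint labeled voxel blocks of the requested sizes."""
    total = sum(region_sizes.values())
    if any(s < 1 for s in region_sizes.values()):
        raise ConfigError("region sizes must be >= 1")
    if total > n_voxels:
        raise ConfigError(f"requested {total} region voxels but only {n_voxels} available")
    regions: dict[str, np.ndarray] = {}
    cursor = 0
    for name, size in region_sizes.items():
        regions[name] = np.arange(cursor, cursor + size, dtype=np.int64)
        cursor += size
    return RegionSet(regions=regions, n_voxels=n_voxels, grid_shape=grid_shape)


def default_sedation_regions(background_voxels: int = 200) -> RegionSet:
    """One seed plus four target regions over a small synthetic 'brain'."""
    n_voxels = sum(DEFAULT_REGION_SIZES.values()) + background_voxels
    return gen_region_set(dict(DEFAULT_REGION_SIZES), n_voxels)


@dataclass
class SubjectTimeseries:
    """Time x voxels matrix for one subject, state and run type."""

    data: np.ndarray
    subject_id: str
    state: str
    run_type: Literal["task", "rest"]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("timeseries must be 2-D (time x voxels)")
        if np.isnan(self.data).any():
            raise ValueError("timeseries contains missing values")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


@dataclass
class SedationStudyConfig:
    n_subjects: int = 17
    n_timepoints: int = 150
    region_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_REGION_SIZES))
    background_voxels: int = 200
    seed_region: str = "auditory"
    states: tuple[tuple[str, float], ...] = DEFAULT_STATES
    seed_amplitude: float = 1.0
    offseed_amplitude: float = 0.05
    subject_gain_sd: float = 0.5
    noise_sd: float = 1.0
    shared_noise_sd: float = 0.5
    stimulus_bandwidth: float = 3.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ConfigError("n_subjects must be >= 3")
        if self.n_timepoints < 10:
            raise ConfigError("n_timepoints must be >= 10")
        if self.seed_region not in self.region_sizes:
            raise ConfigError(f"seed_region {self.seed_region!r} not in region_sizes")
        if any(s < 1 for s in self.region_sizes.values()):
            raise ConfigError("every region size must be >= 1")
        for label, g in self.states:
            if not 0 <= g <= 1:
                raise ConfigError(f"attenuation for state {label!r} must be in [0, 1]")
            if label == "awake" and g != 0:
                raise ConfigError("awake state must have attenuation 0")
        for name in (
            "noise_sd", "shared_noise_sd", "seed_amplitude",
            "offseed_amplitude", "subject_gain_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.stimulus_bandwidth <= 0:
            raise ConfigError("stimulus_bandwidth must be > 0")

    @property
    def n_voxels(self) -> int:
        return sum(self.region_sizes.values()) + self.background_voxels

    @property
    def state_labels(self) -> list[str]:
        return [label for label, _ in self.states]

    def attenuation(self, state: str) -> float:
        for label, g in self.states:
            if label == state:
                return g
        raise ConfigError(f"unknown state {state!r}")


@dataclass
class SedationStudy:
    runs: dict[tuple[str, str, str], SubjectTimeseries]  # (subject, state, run_type)
    stimulus: np.ndarray
    regions: RegionSet
    config: SedationStudyConfig

    def get(self, subject_id: str, state: str, run_type: str) -> SubjectTimeseries:
        return self.runs[(subject_id, state, run_type)]

    def subjects(self) -> list[str]:
        return [f"sub-{i:03d}" for i in range(self.config.n_subjects)]

    def state_runs(self, state: str, run_type: str) -> list[SubjectTimeseries]:
        return [self.get(s, state, run_type) for s in self.subjects()]


def _smooth_signal(rng: np.random.Generator, n: int, bandwidth: float) -> np.ndarray:
    """Gaussian-kernel smoothed standard-normal process, standardized."""
    s = gaussian_filter1d(rng.normal(size=n), sigma=bandwidth, mode="wrap")
    s = s - s.mean()
    sd = s.std()
    return s / (sd if sd > 0 else 1.0)


def gen_sedation_study(config: SedationStudyConfig) -> SedationStudy:
    """Generate the four-state task/rest timeseries study.

    Task run of subject i in a state with attenuation g:
    ``x_v(t) = b_i * a_v(g) * s(t) + shared_noise_sd * c(t) + noise`` with
    ``a_v(g) = seed_amplitude`` on seed voxels and
    ``offseed_amplitude * (1 - g)`` elsewhere.  Rest runs omit the
    stimulus term.  ``s(t)`` is shared by all subjects and states;
    ``c(t)`` is private to each subject-state-run; ``b_i`` is a
    per-subject responsiveness gain ~ Normal(1, subject_gain_sd^2), the
    between-subject variability that keeps across-subject decoding off
    the ceiling.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    p = config.n_voxels
    T = config.n_timepoints
    regions = gen_region_set(dict(config.region_sizes), p)
    stimulus = _smooth_signal(rng, T, config.stimulus_bandwidth)
    s_hat = stimulus / np.linalg.norm(stimulus)
    gains = rng.normal(1.0, config.subject_gain_sd, size=config.n_subjects)

    seed_idx = regions[config.seed_region]
    runs: dict[tuple[str, str, str], SubjectTimeseries] = {}
    for i in range(config.n_subjects):
        sid = f"sub-{i:03d}"
        for state, g in config.states:
            amp = np.full(p, config.offseed_amplitude * (1.0 - g))
            amp[seed_idx] = config.seed_amplitude
            amp = gains[i] * amp
            for run_type in ("task", "rest"):
                # broadband intrinsic fluctuation shared by all voxels of
                # one subject-run; intrinsic activity is modeled as
                # independent of the stimulus, enforced as exact sample
                # orthogonality so chance correlation at finite T cannot
                # masquerade as stimulus response
                common = rng.normal(size=T)
                common = common - (common @ s_hat) * s_hat
                noise = rng.normal(0.0, config.noise_sd, size=(T, p))
                data = config.shared_noise_sd * common[:, None] + noise
                if run_type == "task":
                    data = data + np.outer(stimulus, amp)
                runs[(sid, state, run_type)] = SubjectTimeseries(
                    data=data, subject_id=sid, state=state, run_type=run_type
                )
    return SedationStudy(runs=runs, stimulus=stimulus, regions=regions, config=config)
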