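"""Decile-binned signed-t decoders for paired activation-map studies.

Two stacks of per-subject GLM beta maps (condition of interest vs. no
interest) are compared with a voxel-wise paired t-test.  The voxels are
then partitioned into ``n_bins`` near-equal bins by |t| (decile binning by
default), and each bin becomes a linear decoder whose weights are the
signed t-statistics of its member voxels and zero elsewhere.  Scoring a
map against a decoder is a plain dot product — a weighted sum of
stimulus-related activity over the bin's voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ActivationMapStack",
    "TStatMap",
    "DecileDecoderSet",
    "ScoreMatrix",
    "paired_t_map",
    "paired_t_values",
    "t_to_r",
    "build_decile_decoders",
    "decile_membership",
    "decoder_scores",
]


class AlignmentError(ValueError):
    """Subject order / shape mismatch between paired map stacks."""


@dataclass
class ActivationMapStack:
    """Subjects x voxels matrix of GLM beta values for one condition.

    ``mask`` optionally carries the linear voxel indices of a 3-D grid
    (C-order over mask-true voxels) together with ``grid_shape``/``affine``
    so stacks can round-trip through NIfTI volumes.
    """

    values: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    mask: np.ndarray | None = None
    grid_shape: tuple[int, ...] | None = None
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("map stack must be 2-D (subjects x voxels)")
        if np.isnan(self.values).any():
            raise ValueError("map stack contains missing values")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(self.values.shape[0])]
        if len(self.subject_ids) != self.values.shape[0]:
            raise AlignmentError("subject_ids length does not match row count")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.values.shape[1]


@dataclass
class TStatMap:
    """Per-voxel paired t-statistics with their degrees of freedom."""

    t: np.ndarray
    df: int
    n_subjects: int

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if not np.isfinite(self.t).all():
            raise ValueError("t-statistic map contains non-finite values")


@dataclass
class DecileDecoderSet:
    """Signed-t weights split into |t|-magnitude bins.

    ``weights`` is voxels x n_bins; column ``d`` holds the signed t value
    on bin-(d+1) member voxels and 0 elsewhere.  ``membership`` maps each
    voxel to its 1-based bin index (1 = lowest |t|, n_bins = highest).
    """

    weights: np.ndarray
    membership: np.ndarray
    n_bins: int


@dataclass
class ScoreMatrix:
    """Subjects x n_bins matrix of decoder dot products."""

    scores: np.ndarray
    condition: str = ""


def _check_paired(stack_interest: ActivationMapStack, stack_nointerest: ActivationMapStack) -> None:
    if stack_interest.values.shape != stack_nointerest.values.shape:
        raise AlignmentError(
            f"shape mismatch: {stack_interest.values.shape} vs {stack_nointerest.values.shape}"
        )
    if stack_interest.subject_ids != stack_nointerest.subject_ids:
        raise AlignmentError("subject order differs between the two stacks")


def paired_t_values(interest: np.ndarray, nointerest: np.ndarray) -> np.ndarray:
    """Voxel-wise paired t-statistics from two aligned (n x p) arrays.

    Zero-variance voxels are assigned t = 0 so the decile partition stays
    total.  This is the hot inner loop of every bootstrap replicate, hence
    the array-level entry point next to :func:`paired_t_map`.
    """
    d = np.asarray(interest, dtype=float) - np.asarray(nointerest, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError(f"paired t-test needs n >= 3 subjects, got {n}")
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = 0.0
    return t


def paired_t_map(
    stack_interest: ActivationMapStack, stack_nointerest: ActivationMapStack
) -> TStatMap:
    """Voxel-wise paired t-test between interest and no-interest maps."""
    _check_paired(stack_interest, stack_nointerest)
    n = stack_interest.n_subjects
    t = paired_t_values(stack_interest.values, stack_nointerest.values)
    return TStatMap(t=t, df=n - 1, n_subjects=n)


def t_to_r(tmap: TStatMap | np.ndarray, df: int | None = None) -> np.ndarray:
    """Convert t-statistics to Pearson correlations, r = t / sqrt(t^2 + df)."""
    if isinstance(tmap, TStatMap):
        t, df = tmap.t, tmap.df
    else:
        t = np.asarray(tmap, dtype=float)
        if df is None:
            raise ValueError("df required when passing a raw array")
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    return t / np.sqrt(t**2 + df)


def decile_membership(t: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """1-based bin index per voxel: rank voxels by |t| ascending and split
    the ranks into ``n_bins`` contiguous near-equal bins.

    Boundary ties are broken by stable sort on (|t|, voxel index) so the
    partition is deterministic.  Bin sizes differ by at most one voxel.
    """
    t = np.asarray(t, dtype=float)
    p = t.shape[0]
    if p < n_bins:
        raise ValueError(f"need at least {n_bins} voxels, got {p}")
    order = np.argsort(np.abs(t), kind="stable")
    membership = np.empty(p, dtype=np.int64)
    # np.array_split puts the larger chunks first, i.e. in the low-|t| bins
    for b, chunk in enumerate(np.array_split(order, n_bins), start=1):
        membership[chunk] = b
    return membership


def build_decile_decoders(tmap: TStatMap | np.ndarray, n_bins: int = 10) -> DecileDecoderSet:
    """Build the signed-t bin decoders from a t-statistic map."""
    t = tmap.t if isinstance(tmap, TStatMap) else np.asarray(tmap, dtype=float)
    membership = decile_membership(t, n_bins)
    weights = np.zeros((t.shape[0], n_bins))
    for b in range(1, n_bins + 1):
        sel = membership == b
        weights[sel, b - 1] = t[sel]
    return DecileDecoderSet(weights=weights, membership=membership, n_bins=n_bins)


def decoder_scores(
    decoders: DecileDecoderSet | np.ndarray, stack: ActivationMapStack | np.ndarray,
    condition: str = "",
) -> ScoreMatrix:
    """Dot products between each map and each bin decoder (subjects x bins)."""
    weights = decoders.weights if isinstance(decoders, DecileDecoderSet) else np.asarray(decoders)
    values = stack.values if isinstance(stack, ActivationMapStack) else np.asarray(stack)
    if values.shape[1] != weights.shape[0]:
        raise AlignmentError(
            f"voxel count mismatch: maps have {values.shape[1]}, decoders {weights.shape[0]}"
        )
    return ScoreMatrix(scores=values @ weights, condition=condition)
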