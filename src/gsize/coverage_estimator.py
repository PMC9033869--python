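"""Genome-size estimation from mapped-read depth.

Modal-depth detection over a per-base depth profile, sum-of-coverage
extrapolation (total mapped bases / modal depth), and the Lander-Waterman
formula G = N*L/C. Zero-depth positions contribute 0 to the coverage sum but
are always excluded from the modal search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Union

import numpy as np

__all__ = [
    "DepthProfile",
    "MappingSizeEstimate",
    "NoModalDepthError",
    "depth_histogram",
    "modal_depth",
    "estimate_size_from_depth",
    "lander_waterman_size",
]

#: Per-reference vectors of non-negative integer depth, one value per base.
DepthProfile = Mapping[str, np.ndarray]


class NoModalDepthError(ValueError):
    """No sites at or above the requested minimum depth."""


@dataclass
class MappingSizeEstimate:
    modal_depth: int
    total_mapped_bases: int
    genome_size: int  # round(total_mapped_bases / modal_depth)


def _concat(profile: DepthProfile) -> np.ndarray:
    vecs = [np.asarray(v, dtype=np.int64) for v in profile.values()]
    if not vecs or sum(len(v) for v in vecs) == 0:
        raise ValueError("empty depth profile")
    for v in vecs:
        if (v < 0).any():
            raise ValueError("depths must be non-negative")
    return np.concatenate(vecs)


def depth_histogram(profile: DepthProfile) -> Dict[int, int]:
    """Map depth -> number of sites at that depth.

    Sums reconcile exactly: site counts add to the number of positions and
    depth x site count adds to the total mapped bases.
    """
    depths = _concat(profile)
    binned = np.bincount(depths)
    return {int(d): int(c) for d, c in enumerate(binned) if c > 0}


def _smoothed(dense: np.ndarray) -> np.ndarray:
    """Width-3 moving average (same length, edge-truncated window)."""
    kernel = np.ones(3)
    sums = np.convolve(dense, kernel, mode="same")
    norms = np.convolve(np.ones_like(dense, dtype=float), kernel, mode="same")
    return sums / norms


def modal_depth(
    hist: Mapping[int, int], min_depth: int = 1, smooth: bool = False
) -> int:
    """Depth with the maximum site count at/above ``min_depth``.

    Depth-0 sites are always excluded; ties break toward the smaller depth.
    ``smooth`` applies a width-3 moving average before peak picking (off by
    default: the raw peak is used).
    """
    if min_depth < 1:
        min_depth = 1
    eligible = {d: c for d, c in hist.items() if d >= min_depth}
    if not eligible:
        raise NoModalDepthError(f"no sites at depth >= {min_depth}")
    if smooth:
        dense = np.zeros(max(eligible) + 1, dtype=float)
        for d, c in eligible.items():
            dense[d] = c
        smoothed = _smoothed(dense)
        smoothed[:min_depth] = -1.0
        return int(np.argmax(smoothed))
    best = max(eligible.values())
    return min(d for d, c in eligible.items() if c == best)


def estimate_size_from_depth(
    profile: DepthProfile, min_depth: int = 1, smooth: bool = False
) -> MappingSizeEstimate:
    """Sum all coverages and divide by the modal depth.

    A collapsed repeat with N true copies shows an N-fold depth excess over
    its single retained copy, so its assembly length is counted N times —
    recovering the true genome size in the noiseless limit.
    """
    hist = depth_histogram(profile)
    modal = modal_depth(hist, min_depth=min_depth, smooth=smooth)
    total = int(sum(d * c for d, c in hist.items()))
    return MappingSizeEstimate(
        modal_depth=modal,
        total_mapped_bases=total,
        genome_size=int(round(total / modal)),
    )


def lander_waterman_size(
    n_reads: Union[int, float], read_length: Union[int, float], modal_coverage: Union[int, float]
) -> float:
    """G = N * L / C."""
    if n_reads <= 0 or read_length <= 0 or modal_coverage <= 0:
        raise ValueError("read count, read length and modal coverage must be positive")
    return n_reads * read_length / modal_coverage
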