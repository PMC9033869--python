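"""Canonical k-mer counting and k-mer-spectrum genome-size estimation.

The estimator is the plain modal-coverage procedure: count canonical k-mers
(lexicographic minimum of a word and its reverse complement) across a read
set, build the multiplicity histogram, locate the modal k-mer coverage above
an error cutoff, and divide the total number of retained k-mers by the mode.
No mixture-model fitting is performed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence, Tuple, Union

import numpy as np

from gsize.simgenome import ReadSet, encode

__all__ = [
    "KmerHistogram",
    "KmerSizeEstimate",
    "NoModalPeakError",
    "count_kmers",
    "modal_kmer_coverage",
    "estimate_size_from_kmers",
    "estimate_size_sweep",
    "DEFAULT_K_SWEEP",
]

DEFAULT_K_SWEEP: Tuple[int, ...] = (21, 23, 25, 27, 29, 31)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class NoModalPeakError(ValueError):
    """Histogram has no genomic peak (counts monotone decreasing) —
    coverage is too low for a modal estimate."""


@dataclass
class KmerHistogram:
    """Multiplicity -> number of distinct canonical k-mers seen that often."""

    k: int
    counts: Dict[int, int]

    def __post_init__(self) -> None:
        if self.k % 2 == 0:
            raise ValueError("k must be odd (even k admits self-complementary words)")
        if any(m < 1 for m in self.counts):
            raise ValueError("multiplicities must be >= 1")

    @property
    def total_kmers(self) -> int:
        """Total k-mers ingested: sum of multiplicity x count."""
        return sum(m * c for m, c in self.counts.items())

    @property
    def distinct_kmers(self) -> int:
        return sum(self.counts.values())

    def dense(self) -> np.ndarray:
        """Counts as a dense vector indexed by multiplicity (index 0 unused)."""
        if not self.counts:
            return np.zeros(1, dtype=np.int64)
        arr = np.zeros(max(self.counts) + 1, dtype=np.int64)
        for m, c in self.counts.items():
            arr[m] = c
        return arr


@dataclass
class KmerSizeEstimate:
    k: int
    modal_coverage: int
    error_cutoff: int
    genome_size: int
    total_kmers_used: int


def _sequences_of(reads: Union[ReadSet, Mapping[str, str], Iterable[str]]) -> Sequence[str]:
    if isinstance(reads, ReadSet):
        return reads.reads
    if isinstance(reads, Mapping):
        return list(reads.values())
    return list(reads)


def count_kmers(
    reads: Union[ReadSet, Mapping[str, str], Iterable[str]], k: int
) -> KmerHistogram:
    """Count canonical k-mers over every length-k window of every sequence.

    Windows containing non-ACGT symbols are skipped. ``reads`` may be a
    :class:`~gsize.simgenome.ReadSet`, a FASTA-style ``{name: seq}`` mapping,
    or any iterable of sequences. Rejects even ``k`` and, for a ReadSet,
    ``k`` larger than the read length.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd")
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(reads, ReadSet) and k > reads.read_length:
        raise ValueError(f"k={k} exceeds read length {reads.read_length}")
    seqs = _sequences_of(reads)
    if not seqs:
        return KmerHistogram(k=k, counts={})
    if k <= 31:
        counts = _count_kmers_packed(seqs, k)
    else:
        counts = _count_kmers_dict(seqs, k)
    return KmerHistogram(k=k, counts=counts)


def _count_kmers_packed(seqs: Sequence[str], k: int) -> Dict[int, int]:
    """2-bit packed counting (fits in uint64 for k <= 31)."""
    # concatenate with a sentinel (-1) between sequences so windows never
    # span read boundaries
    parts = []
    sentinel = np.array([-1], dtype=np.int8)
    for s in seqs:
        parts.append(encode(s))
        parts.append(sentinel)
    codes = np.concatenate(parts[:-1])
    n = len(codes)
    if n < k:
        return {}
    m = n - k + 1
    invalid = (codes < 0).astype(np.int64)
    bad = np.concatenate([[0], np.cumsum(invalid)])
    window_ok = (bad[k:] - bad[:-k]) == 0

    safe = np.where(codes < 0, 0, codes).astype(np.uint64)
    fw = np.zeros(m, dtype=np.uint64)
    rc = np.zeros(m, dtype=np.uint64)
    three = np.uint64(3)
    for j in range(k):
        c = safe[j : j + m]
        fw |= c << np.uint64(2 * (k - 1 - j))
        rc |= (three - c) << np.uint64(2 * j)
    canonical = np.minimum(fw, rc)[window_ok]
    if canonical.size == 0:
        return {}
    _, per_kmer = np.unique(canonical, return_counts=True)
    mults, ncounts = np.unique(per_kmer, return_counts=True)
    return {int(m_): int(c_) for m_, c_ in zip(mults, ncounts)}


def _count_kmers_dict(seqs: Sequence[str], k: int) -> Dict[int, int]:
    """String-dictionary fallback for k > 31."""
    table: Dict[str, int] = {}
    valid = set("ACGT")
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            word = seq[i : i + k]
            if not valid.issuperset(word):
                continue
            rc = word.translate(_COMPLEMENT)[::-1]
            canon = word if word <= rc else rc
            table[canon] = table.get(canon, 0) + 1
    counts: Dict[int, int] = {}
    for c in table.values():
        counts[c] = counts.get(c, 0) + 1
    return counts


def resolve_error_cutoff(hist: KmerHistogram) -> int:
    """Automatic error cutoff: the first multiplicity at which counts start
    rising when scanning upward from multiplicity 1 (the far side of the
    error valley). Raises :class:`NoModalPeakError` when counts never rise
    (monotone decreasing histogram — no genomic peak)."""
    dense = hist.dense()
    for m in range(2, len(dense)):
        if dense[m] > dense[m - 1]:
            return m
    raise NoModalPeakError(
        "no modal peak: k-mer counts are monotone decreasing above multiplicity 1 "
        "(coverage too low for a modal estimate)"
    )


def modal_kmer_coverage(
    hist: KmerHistogram, error_cutoff: Union[int, str] = "auto"
) -> int:
    """Multiplicity with the largest distinct-k-mer count at/above the
    cutoff; ties break toward the smaller multiplicity."""
    if not hist.counts:
        raise NoModalPeakError("empty histogram")
    cutoff = resolve_error_cutoff(hist) if error_cutoff == "auto" else int(error_cutoff)
    eligible = {m: c for m, c in hist.counts.items() if m >= cutoff}
    if not eligible:
        raise NoModalPeakError(f"no k-mer multiplicities at or above cutoff {cutoff}")
    best = max(eligible.values())
    return min(m for m, c in eligible.items() if c == best)


def estimate_size_from_kmers(
    hist: KmerHistogram,
    error_cutoff: Union[int, str] = "auto",
    include_error_kmers: bool = False,
) -> KmerSizeEstimate:
    """Genome size = (total k-mers at/above the cutoff) / modal coverage.

    With ``include_error_kmers=True`` the numerator includes every
    multiplicity (the alternative convention); the default excludes
    presumed-error k-mers below the cutoff.
    """
    cutoff = resolve_error_cutoff(hist) if error_cutoff == "auto" else int(error_cutoff)
    modal = modal_kmer_coverage(hist, cutoff)
    if include_error_kmers:
        total = hist.total_kmers
    else:
        total = sum(m * c for m, c in hist.counts.items() if m >= cutoff)
    size = int(round(total / modal))
    return KmerSizeEstimate(
        k=hist.k,
        modal_coverage=modal,
        error_cutoff=cutoff,
        genome_size=size,
        total_kmers_used=total,
    )


def estimate_size_sweep(
    reads: Union[ReadSet, Mapping[str, str], Iterable[str]],
    ks: Sequence[int] = DEFAULT_K_SWEEP,
    error_cutoff: Union[int, str] = "auto",
    include_error_kmers: bool = False,
) -> Dict[int, KmerSizeEstimate]:
    """Repeat the estimate across word sizes (default 21-31, odd)."""
    seqs = _sequences_of(reads)
    return {
        k: estimate_size_from_kmers(
            count_kmers(seqs, k), error_cutoff, include_error_kmers
        )
        for k in ks
    }
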