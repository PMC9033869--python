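"""Sequence and table I/O shared by every pipeline stage.

File dialects honored here:

* FASTA: wrapped at a configurable line width (default 60) on output;
  lowercase input is uppercased; non-ACGT symbols are preserved (downstream
  k-mer windows and alignment seeds skip them).
* k-mer histogram: 2-column TSV ``multiplicity<TAB>count`` (the layout
  produced by ``jellyfish histo``).
* per-base depth: 3-column TSV ``reference<TAB>position(1-based)<TAB>depth``
  (the common ``samtools depth`` layout); positions may be sparse, missing
  positions are depth 0.
* BED: 0-based half-open annotation intervals.
"""

from __future__ import annotations

import os
from typing import Dict, Iterable, Mapping, Tuple

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_fastq",
    "write_bed",
    "read_kmer_histogram",
    "write_kmer_histogram",
    "read_depth_tsv",
    "write_depth_tsv",
]


def read_fasta(path: str | os.PathLike) -> Dict[str, str]:
    """Read a FASTA file into an ordered ``{name: sequence}`` mapping.

    Sequence names are the first whitespace-delimited token of the header.
    Raises ``ValueError`` on an empty file or duplicate names.
    """
    seqs: Dict[str, str] = {}
    with open(path) as handle:
        for header, seq in SimpleFastaParser(handle):
            name = header.split()[0] if header.split() else header
            if name in seqs:
                raise ValueError(f"duplicate sequence name: {name!r}")
            seqs[name] = seq.upper()
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    return seqs


def write_fasta(
    seqs: Mapping[str, str], path: str | os.PathLike, line_width: int = 60
) -> None:
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                handle.write(seq[i : i + line_width] + "\n")


def write_fastq(
    reads: Iterable[Tuple[str, str]], path: str | os.PathLike, quality_char: str = "I"
) -> None:
    """Write ``(read_id, sequence)`` pairs as FASTQ with a constant quality."""
    with open(path, "w") as handle:
        for read_id, seq in reads:
            handle.write(f"@{read_id}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_bed(
    intervals: Iterable[Tuple[str, int, int, str]], path: str | os.PathLike
) -> None:
    """Write ``(contig, start, end, name)`` as BED (0-based half-open)."""
    with open(path, "w") as handle:
        for contig, start, end, name in intervals:
            handle.write(f"{contig}\t{start}\t{end}\t{name}\n")


def read_kmer_histogram(path: str | os.PathLike) -> Dict[int, int]:
    """Read a 2-column multiplicity/count TSV (``jellyfish histo`` dialect)."""
    counts: Dict[int, int] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(f"malformed histogram line: {line!r}")
            mult, count = int(fields[0]), int(fields[1])
            if mult < 1:
                raise ValueError("multiplicities must be >= 1")
            counts[mult] = counts.get(mult, 0) + count
    return counts


def write_kmer_histogram(counts: Mapping[int, int], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for mult in sorted(counts):
            handle.write(f"{mult}\t{counts[mult]}\n")


def read_depth_tsv(
    path: str | os.PathLike,
    reference_lengths: Mapping[str, int] | None = None,
) -> Dict[str, np.ndarray]:
    """Read a 3-column depth TSV into per-reference depth vectors.

    Positions are 1-based in the file and may be sparse: positions absent
    from the file are depth 0. If ``reference_lengths`` is given, vectors
    are allocated at those lengths (positions beyond them are an error);
    otherwise each vector is sized to the largest position seen.
    """
    records: Dict[str, list] = {}
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"malformed depth line: {line!r}")
            ref, pos, depth = fields[0], int(fields[1]), int(fields[2])
            if pos < 1:
                raise ValueError("positions are 1-based; got %d" % pos)
            if depth < 0:
                raise ValueError("negative depth")
            records.setdefault(ref, []).append((pos, depth))
    profile: Dict[str, np.ndarray] = {}
    for ref, pairs in records.items():
        positions = np.array([p for p, _ in pairs], dtype=np.int64)
        depths = np.array([d for _, d in pairs], dtype=np.int64)
        if reference_lengths is not None:
            if ref not in reference_lengths:
                raise ValueError(f"unknown reference {ref!r}")
            length = int(reference_lengths[ref])
            if positions.max() > length:
                raise ValueError(f"position beyond reference length for {ref!r}")
        else:
            length = int(positions.max())
        vec = np.zeros(length, dtype=np.int64)
        vec[positions - 1] = depths
        profile[ref] = vec
    if reference_lengths is not None:
        for ref, length in reference_lengths.items():
            profile.setdefault(ref, np.zeros(int(length), dtype=np.int64))
    if not profile:
        raise ValueError(f"no depth records found in {path}")
    return profile


def write_depth_tsv(
    profile: Mapping[str, np.ndarray],
    path: str | os.PathLike,
    include_zero: bool = True,
) -> None:
    """Write per-reference depth vectors as a 1-based 3-column TSV."""
    with open(path, "w") as handle:
        for ref, vec in profile.items():
            for i, depth in enumerate(np.asarray(vec), start=1):
                if include_zero or depth > 0:
                    handle.write(f"{ref}\t{i}\t{int(depth)}\n")
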