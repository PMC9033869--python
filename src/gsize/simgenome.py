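"""Synthetic genomes with controlled repeat structure.

Generates genomes whose repeat content (dispersed families with divergence,
tandem arrays), optional heteromorphic sex-chromosome pair and base
composition are fully specified; simulates uniformly placed substitution-error
reads from them; and produces collapsed-repeat "assemblies" in which each
repeat family is represented by fewer copies than truly exist. True read
placements are retained so that exact pileups can be computed without any
external mapper.

Coordinates are 0-based half-open everywhere in this module; the depth-TSV
boundary (``fileio``) is the only 1-based surface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "RepeatFamilySpec",
    "GenomeSpec",
    "Interval",
    "SimulatedGenome",
    "ReadSet",
    "CollapsedAssembly",
    "PlacementError",
    "simulate_genome",
    "simulate_reads",
    "collapse_assembly",
    "diploidize",
    "pileup_depth",
    "pileup_on_collapsed",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

UNIQUE_LABEL = "unique"


class PlacementError(ValueError):
    """Dispersed repeat copies could not be placed without overlap."""


def encode(seq: str) -> np.ndarray:
    """2-bit encode a sequence; non-ACGT symbols become -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


@dataclass(frozen=True)
class RepeatFamilySpec:
    """One repeat family: dispersed copies or a single tandem array."""

    family_id: str
    kind: str  # "dispersed" | "tandem"
    unit_length: int
    copy_number: int
    divergence: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("dispersed", "tandem"):
            raise ValueError(f"kind must be 'dispersed' or 'tandem', got {self.kind!r}")
        if self.unit_length < 1:
            raise ValueError("unit_length must be >= 1")
        if self.copy_number < 1:
            raise ValueError("copy_number must be >= 1")
        if not (0.0 <= self.divergence < 0.5):
            raise ValueError("divergence must be in [0, 0.5)")

    @property
    def total_length(self) -> int:
        return self.unit_length * self.copy_number


@dataclass(frozen=True)
class GenomeSpec:
    unique_length: int
    families: Tuple[RepeatFamilySpec, ...] = ()
    sex_pair: Optional[Tuple[int, int]] = None  # (Z_length, W_length)
    base_composition: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "families", tuple(self.families))
        if self.unique_length < 0:
            raise ValueError("unique_length must be >= 0")
        ids = [f.family_id for f in self.families]
        if len(set(ids)) != len(ids):
            raise ValueError("family_id values must be unique")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or (comp < 0).any() or abs(comp.sum() - 1.0) > 1e-9:
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        if self.sex_pair is not None:
            z, w = self.sex_pair
            if z < 1 or w < 1:
                raise ValueError("sex_pair lengths must be >= 1")

    @property
    def true_size(self) -> int:
        size = self.unique_length + sum(f.total_length for f in self.families)
        if self.sex_pair is not None:
            size += self.sex_pair[0] + self.sex_pair[1]
        return size


@dataclass(frozen=True)
class Interval:
    """0-based half-open annotated interval. ``copy_index`` orders copies
    within a family; it is None for unique intervals."""

    contig: str
    start: int
    end: int
    label: str
    copy_index: Optional[int] = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimulatedGenome:
    contigs: Dict[str, str]
    annotations: List[Interval]
    families: Dict[str, RepeatFamilySpec]
    consensus: Dict[str, str]  # family_id -> consensus unit sequence
    true_size: int

    def __post_init__(self) -> None:
        total = sum(len(s) for s in self.contigs.values())
        if total != self.true_size:
            raise ValueError("sum of contig lengths must equal true_size")

    @property
    def contig_lengths(self) -> Dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def repeat_bases(self) -> int:
        return sum(iv.length for iv in self.annotations if iv.label != UNIQUE_LABEL)

    @property
    def repeat_fraction(self) -> float:
        return self.repeat_bases / self.true_size if self.true_size else 0.0

    @property
    def sex_average(self) -> Optional[float]:
        """(Z + W) / 2 — what read-based estimators see for a heteromorphic
        pair present in a single (female-type) individual."""
        if "Z" in self.contigs and "W" in self.contigs:
            return (len(self.contigs["Z"]) + len(self.contigs["W"])) / 2.0
        return None

    def annotations_for(self, contig: str) -> List[Interval]:
        return [iv for iv in self.annotations if iv.contig == contig]


@dataclass
class ReadSet:
    reads: List[str]
    read_length: int
    error_rate: float
    origins: List[Tuple[str, int]]  # (contig, 0-based start) per read

    def __post_init__(self) -> None:
        if len(self.reads) != len(self.origins):
            raise ValueError("reads and origins must have equal length")
        for r in self.reads:
            if len(r) != self.read_length:
                raise ValueError("every read must have length read_length")

    @property
    def count(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclass
class CollapsedAssembly:
    contigs: Dict[str, str]
    # family_id -> true copy count represented by each retained copy
    collapse_map: Dict[str, List[int]]
    # affine map from true-genome annotation intervals to collapsed coords:
    # (contig, start, end, target_start); target position = pos - start + target_start
    segment_map: List[Tuple[str, int, int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


def _random_seq(rng: np.random.Generator, length: int, comp: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=length, p=comp).astype(np.int8)


def _mutate(
    rng: np.random.Generator, codes: np.ndarray, rate: float
) -> np.ndarray:
    """Substitute each base independently with probability ``rate`` to one of
    the three other bases (so every substituted site truly differs)."""
    if rate <= 0:
        return codes.copy()
    out = codes.copy()
    hits = np.nonzero(rng.random(len(codes)) < rate)[0]
    if len(hits):
        shift = rng.integers(1, 4, size=len(hits)).astype(np.int8)
        out[hits] = (out[hits] + shift) % 4
    return out


def simulate_genome(spec: GenomeSpec, max_attempts_per_copy: int = 1000) -> SimulatedGenome:
    """Build a genome realizing ``spec`` exactly.

    Dispersed copies and tandem arrays are placed at non-overlapping,
    uniformly sampled intervals of the main contig by rejection sampling
    (largest elements first); the gaps are filled with unique background
    sequence. Raises :class:`PlacementError` when the attempt budget is
    exhausted — placement feasibility is the caller's responsibility.
    """
    rng = np.random.default_rng(spec.seed)
    comp = np.asarray(spec.base_composition, dtype=float)

    consensus: Dict[str, np.ndarray] = {
        f.family_id: _random_seq(rng, f.unit_length, comp) for f in spec.families
    }

    # Elements to place in the main contig: one per dispersed copy, one per
    # whole tandem array.
    elements: List[Tuple[int, RepeatFamilySpec, int]] = []  # (length, family, copy0)
    for fam in spec.families:
        if fam.kind == "dispersed":
            for c in range(fam.copy_number):
                elements.append((fam.unit_length, fam, c))
        else:
            elements.append((fam.total_length, fam, 0))
    main_length = spec.unique_length + sum(e[0] for e in elements)

    placed: List[Tuple[int, int, RepeatFamilySpec, int]] = []  # (start,end,fam,copy0)
    order = sorted(range(len(elements)), key=lambda i: -elements[i][0])
    for idx in order:
        elen, fam, copy0 = elements[idx]
        if elen > main_length:
            raise PlacementError(f"element of family {fam.family_id!r} exceeds contig")
        ok = False
        for _ in range(max_attempts_per_copy):
            s = int(rng.integers(0, main_length - elen + 1))
            e = s + elen
            if all(e <= ps or s >= pe for ps, pe, _, _ in placed):
                placed.append((s, e, fam, copy0))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place a copy of family {fam.family_id!r} without overlap "
                f"after {max_attempts_per_copy} attempts; reduce repeat density"
            )
    placed.sort(key=lambda t: t[0])

    main = np.empty(main_length, dtype=np.int8)
    annotations: List[Interval] = []
    copy_counter: Dict[str, int] = {f.family_id: 0 for f in spec.families}
    cursor = 0
    contig_name = "chr1"

    def fill_unique(upto: int) -> None:
        nonlocal cursor
        if upto > cursor:
            main[cursor:upto] = _random_seq(rng, upto - cursor, comp)
            annotations.append(Interval(contig_name, cursor, upto, UNIQUE_LABEL))
            cursor = upto

    for s, e, fam, _copy0 in placed:
        fill_unique(s)
        if fam.kind == "dispersed":
            ci = copy_counter[fam.family_id]
            main[s:e] = _mutate(rng, consensus[fam.family_id], fam.divergence)
            annotations.append(Interval(contig_name, s, e, fam.family_id, ci))
            copy_counter[fam.family_id] += 1
        else:  # tandem array: adjacent units, each annotated separately
            for u in range(fam.copy_number):
                us, ue = s + u * fam.unit_length, s + (u + 1) * fam.unit_length
                main[us:ue] = _mutate(rng, consensus[fam.family_id], fam.divergence)
                annotations.append(Interval(contig_name, us, ue, fam.family_id, u))
            copy_counter[fam.family_id] = fam.copy_number
        cursor = e
    fill_unique(main_length)

    contigs: Dict[str, str] = {}
    if main_length > 0:
        contigs[contig_name] = decode(main)
    elif not spec.families and spec.unique_length == 0 and spec.sex_pair is None:
        raise ValueError("empty genome specification")

    if spec.sex_pair is not None:
        for name, length in zip(("Z", "W"), spec.sex_pair):
            contigs[name] = decode(_random_seq(rng, length, comp))
            annotations.append(Interval(name, 0, length, UNIQUE_LABEL))

    return SimulatedGenome(
        contigs=contigs,
        annotations=annotations,
        families={f.family_id: f for f in spec.families},
        consensus={fid: decode(c) for fid, c in consensus.items()},
        true_size=spec.true_size,
    )


def simulate_reads(
    genome: SimulatedGenome | Mapping[str, str],
    target_coverage: float,
    read_length: int,
    error_rate: float = 0.0,
    seed: Optional[int] = None,
) -> ReadSet:
    """Sample N = ceil(C*G/L) reads uniformly over the genome.

    Contigs are chosen proportionally to their number of valid start
    positions (length - L + 1); substitution errors are applied i.i.d. at
    ``error_rate``. True placements are recorded per read.
    """
    if target_coverage <= 0:
        raise ValueError("target_coverage must be positive")
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must be in [0, 1)")

    contigs = genome.contigs if isinstance(genome, SimulatedGenome) else dict(genome)
    names = list(contigs)
    lengths = np.array([len(contigs[n]) for n in names], dtype=np.int64)
    if read_length > lengths.min():
        raise ValueError("read_length exceeds the shortest contig")
    true_size = (
        genome.true_size
        if isinstance(genome, SimulatedGenome)
        else int(lengths.sum())
    )

    n_reads = math.ceil(target_coverage * true_size / read_length)
    rng = np.random.default_rng(seed)

    starts_per_contig = lengths - read_length + 1
    weights = starts_per_contig / starts_per_contig.sum()
    contig_idx = rng.choice(len(names), size=n_reads, p=weights)
    starts = (rng.random(n_reads) * starts_per_contig[contig_idx]).astype(np.int64)

    encoded = {n: encode(contigs[n]) for n in names}
    reads: List[str] = []
    origins: List[Tuple[str, int]] = []
    window = np.arange(read_length)
    for ci_val in range(len(names)):
        mask = contig_idx == ci_val
        if not mask.any():
            continue
        c_starts = starts[mask]
        mat = encoded[names[ci_val]][c_starts[:, None] + window[None, :]]
        if error_rate > 0:
            errs = rng.random(mat.shape) < error_rate
            shift = rng.integers(1, 4, size=mat.shape).astype(np.int8)
            mat = np.where(errs, (mat + shift) % 4, mat)
        for row, s in zip(mat, c_starts):
            reads.append(decode(row))
            origins.append((names[ci_val], int(s)))
    # restore sampling order so output is independent of contig grouping
    order = np.argsort(np.concatenate([np.nonzero(contig_idx == v)[0] for v in range(len(names))]), kind="stable")
    reads = [reads[i] for i in order]
    origins = [origins[i] for i in order]
    return ReadSet(reads=reads, read_length=read_length, error_rate=error_rate, origins=origins)


def _even_split(total: int, parts: int) -> List[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def collapse_assembly(
    genome: SimulatedGenome, retained_copies_per_family: int = 1
) -> CollapsedAssembly:
    """Collapse every repeat family to ``retained_copies_per_family`` copies.

    Unique sequence is untouched. Retained dispersed copies are replaced by
    the family consensus (what an assembler would reconstruct from the pile
    of diverged copies); tandem arrays are truncated to the first retained
    units. ``collapse_map`` records how many true copies each retained copy
    represents, and ``segment_map`` carries an exact coordinate map from the
    true genome onto the collapsed assembly for pileup computation.
    """
    r = retained_copies_per_family
    if r < 1:
        raise ValueError("retained_copies_per_family must be >= 1")

    contigs: Dict[str, str] = {}
    collapse_map: Dict[str, List[int]] = {}
    segment_map: List[Tuple[str, int, int, int]] = []

    # target start (collapsed coords) of each retained copy, keyed by
    # (contig, family_id, retained_index)
    retained_pos: Dict[Tuple[str, str, int], int] = {}
    deferred: List[Tuple[Interval, int]] = []  # dropped repeat intervals

    for contig, seq in genome.contigs.items():
        out_parts: List[str] = []
        out_cursor = 0
        for iv in sorted(genome.annotations_for(contig), key=lambda v: v.start):
            if iv.label == UNIQUE_LABEL:
                out_parts.append(seq[iv.start : iv.end])
                segment_map.append((contig, iv.start, iv.end, out_cursor))
                out_cursor += iv.length
                continue
            fam = genome.families[iv.label]
            n_retained = min(r, fam.copy_number)
            if iv.copy_index is not None and iv.copy_index < n_retained:
                cons = genome.consensus[iv.label]
                kept_seq = cons if fam.kind == "dispersed" else seq[iv.start : iv.end]
                out_parts.append(kept_seq)
                retained_pos[(contig, iv.label, iv.copy_index)] = out_cursor
                segment_map.append((contig, iv.start, iv.end, out_cursor))
                out_cursor += iv.length
            else:
                deferred.append((iv, n_retained))
        collapsed_seq = "".join(out_parts)
        if collapsed_seq:
            contigs[contig] = collapsed_seq

    # Map each dropped copy onto one retained copy of its family (round robin
    # by copy index) and tally represented counts.
    for fid, fam in genome.families.items():
        n_retained = min(r, fam.copy_number)
        collapse_map[fid] = _even_split(fam.copy_number, n_retained)
    for iv, n_retained in deferred:
        target_idx = iv.copy_index % n_retained
        tpos = retained_pos[(iv.contig, iv.label, target_idx)]
        segment_map.append((iv.contig, iv.start, iv.end, tpos))

    return CollapsedAssembly(
        contigs=contigs, collapse_map=collapse_map, segment_map=segment_map
    )


def diploidize(
    genome: SimulatedGenome, heterozygosity: float, seed: Optional[int] = None
) -> SimulatedGenome:
    """Duplicate the genome into two haplotypes differing at ``heterozygosity``
    per-base substitutions. ``true_size`` of the result is the 2C total; the
    1C ground truth remains ``genome.true_size``."""
    rng = np.random.default_rng(seed)
    contigs: Dict[str, str] = {}
    annotations: List[Interval] = []
    for hap in ("hapA", "hapB"):
        for name, seq in genome.contigs.items():
            new = f"{name}_{hap}"
            codes = encode(seq)
            if hap == "hapB":
                codes = _mutate(rng, codes, heterozygosity)
            contigs[new] = decode(codes)
            for iv in genome.annotations_for(name):
                annotations.append(
                    Interval(new, iv.start, iv.end, iv.label, iv.copy_index)
                )
    return SimulatedGenome(
        contigs=contigs,
        annotations=annotations,
        families=dict(genome.families),
        consensus=dict(genome.consensus),
        true_size=2 * genome.true_size,
    )


def pileup_depth(
    readset: ReadSet, contig_lengths: Mapping[str, int]
) -> Dict[str, np.ndarray]:
    """Exact per-base depth from recorded true placements."""
    diffs = {
        name: np.zeros(int(length) + 1, dtype=np.int64)
        for name, length in contig_lengths.items()
    }
    L = readset.read_length
    for contig, start in readset.origins:
        d = diffs[contig]
        d[start] += 1
        d[start + L] -= 1
    return {name: np.cumsum(d[:-1]) for name, d in diffs.items()}


def pileup_on_collapsed(
    readset: ReadSet, genome: SimulatedGenome, collapsed: CollapsedAssembly
) -> Dict[str, np.ndarray]:
    """Depth over the collapsed assembly implied by true read placements.

    Each read footprint is split at true-genome annotation boundaries and
    every piece is mapped affinely through ``segment_map``; reads from
    dropped repeat copies therefore pile up on the retained copy, giving the
    N-fold depth excess that collapsed repeats produce.
    """
    # per-contig sorted segment starts for bisection
    by_contig: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for contig in genome.contigs:
        segs = sorted(
            [s for s in collapsed.segment_map if s[0] == contig], key=lambda s: s[1]
        )
        starts = np.array([s[1] for s in segs], dtype=np.int64)
        ends = np.array([s[2] for s in segs], dtype=np.int64)
        targets = np.array([s[3] for s in segs], dtype=np.int64)
        by_contig[contig] = (starts, ends, targets)

    diffs = {
        name: np.zeros(len(seq) + 1, dtype=np.int64)
        for name, seq in collapsed.contigs.items()
    }
    L = readset.read_length
    for contig, rstart in readset.origins:
        starts, ends, targets = by_contig[contig]
        rend = rstart + L
        i = int(np.searchsorted(starts, rstart, side="right")) - 1
        pos = rstart
        while pos < rend and i < len(starts):
            seg_s, seg_e, seg_t = int(starts[i]), int(ends[i]), int(targets[i])
            piece_end = min(rend, seg_e)
            tpos = pos - seg_s + seg_t
            d = diffs[contig]
            d[tpos] += 1
            d[tpos + (piece_end - pos)] -= 1
            pos = piece_end
            i += 1
    return {name: np.cumsum(d[:-1]) for name, d in diffs.items()}
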