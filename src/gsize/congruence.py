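"""Assembly cross-consistency by synthetic-read alignment.

Shreds an assembly into non-overlapping fixed-length synthetic reads
(default 240 bp), aligns them to a reference assembly with a seed-and-extend
local aligner (exact seed words, ungapped extension, windowed affine-gap
dynamic programming) under blastn-style scoring (match +1, mismatch -1, gap
open 3, gap extend 2, costs positive), and tabulates per-pair mean query
cover %, mapped fraction and the proportion of mapped reads whose best
alignment exceeds 95% identity.

Alignments can be dumped in BLAST ``-outfmt 6`` column order so real BLAST
output can be substituted for the built-in aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

from gsize.simgenome import encode

__all__ = [
    "MATCH",
    "MISMATCH",
    "GAP_OPEN",
    "GAP_EXTEND",
    "SyntheticRead",
    "SyntheticReadLibrary",
    "LocalAlignment",
    "CongruenceResult",
    "shred_assembly",
    "SeedIndex",
    "align_reads",
    "congruence_stats",
    "congruence_matrix",
    "matrix_to_table",
    "alignments_to_outfmt6",
    "karlin_lambda",
    "min_score_for_evalue",
]

MATCH = 1
MISMATCH = -1
GAP_OPEN = 3  # positive cost; a length-g gap costs GAP_OPEN + g * GAP_EXTEND
GAP_EXTEND = 2

#: Karlin-Altschul K for the ungapped +1/-1 system; a documented constant —
#: E-values here calibrate the score floor, they are not full BLAST parity.
KARLIN_K = 0.62

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SyntheticRead:
    read_id: str
    sequence: str
    contig: str
    offset: int  # 0-based start in the source contig


@dataclass
class SyntheticReadLibrary:
    source_label: str
    fragment_length: int
    reads: List[SyntheticRead]
    dropped_bases: int = 0

    def __len__(self) -> int:
        return len(self.reads)


@dataclass
class LocalAlignment:
    query_id: str
    ref_id: str
    score: int
    identities: int
    aligned_length: int
    mismatches: int
    gap_opens: int
    gaps: int
    q_start: int  # 0-based half-open, forward query coordinates
    q_end: int
    s_start: int  # 0-based half-open, forward reference coordinates
    s_end: int
    strand: str  # '+' or '-'
    evalue: float = float("nan")

    @property
    def identity(self) -> float:
        return self.identities / self.aligned_length

    @property
    def query_span(self) -> Tuple[int, int]:
        return (self.q_start, self.q_end)


@dataclass
class CongruenceResult:
    query_label: str
    ref_label: str
    n_reads: int
    mean_query_cover_pct: float
    mapped_fraction: float
    high_identity_fraction: float  # of mapped reads, best alignment identity > 95%


def shred_assembly(
    assembly: Mapping[str, str], fragment_length: int = 240, label: str = "assembly"
) -> SyntheticReadLibrary:
    """Tile each contig into non-overlapping fragments; the trailing
    remainder (< fragment_length) is dropped and tallied."""
    if fragment_length < 1:
        raise ValueError("fragment_length must be >= 1")
    reads: List[SyntheticRead] = []
    dropped = 0
    for contig, seq in assembly.items():
        n_frags = len(seq) // fragment_length
        dropped += len(seq) - n_frags * fragment_length
        for i in range(n_frags):
            start = i * fragment_length
            reads.append(
                SyntheticRead(
                    read_id=f"{label}:{contig}:{start}",
                    sequence=seq[start : start + fragment_length],
                    contig=contig,
                    offset=start,
                )
            )
    return SyntheticReadLibrary(
        source_label=label,
        fragment_length=fragment_length,
        reads=reads,
        dropped_bases=dropped,
    )


def karlin_lambda(base_composition: Sequence[float]) -> float:
    """Unique positive root of sum_ij p_i p_j exp(lambda * s_ij) = 1 for the
    +1/-1 substitution scores (ln 3 under uniform composition)."""
    p = np.asarray(base_composition, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
        raise ValueError("base_composition must be probabilities summing to 1")
    p_match = float((p * p).sum())

    def f(lam: float) -> float:
        return p_match * math.exp(lam) + (1 - p_match) * math.exp(-lam) - 1.0

    return float(brentq(f, 1e-9, 50.0))


def min_score_for_evalue(
    evalue: float, query_length: int, ref_length: int, lam: float, k: float = KARLIN_K
) -> int:
    """Smallest integer score S with K*m*n*exp(-lam*S) <= evalue."""
    if evalue <= 0:
        raise ValueError("evalue must be positive")
    s = (math.log(k * query_length * ref_length) - math.log(evalue)) / lam
    return max(1, math.ceil(s))


def _alignment_evalue(
    score: int, query_length: int, ref_length: int, lam: float, k: float = KARLIN_K
) -> float:
    return k * query_length * ref_length * math.exp(-lam * score)


class SeedIndex:
    """Exact seed-word index over a reference assembly.

    Words containing non-ACGT symbols are not indexed. Lookup is by packed
    2-bit word value via binary search over a sorted value array, so results
    are independent of hash iteration order.
    """

    def __init__(self, reference: Mapping[str, str], word_size: int = 11):
        if word_size < 1 or word_size > 31:
            raise ValueError("word_size must be in 1..31")
        self.word_size = word_size
        self.contig_names: List[str] = list(reference)
        self.contig_codes: List[np.ndarray] = [encode(reference[n]) for n in self.contig_names]
        self.total_length = int(sum(len(c) for c in self.contig_codes))
        counts = np.zeros(4, dtype=np.int64)
        vals_parts, ci_parts, pos_parts = [], [], []
        for ci, codes in enumerate(self.contig_codes):
            counts += np.bincount(codes[codes >= 0], minlength=4)
            vals, pos = _word_values(codes, word_size)
            vals_parts.append(vals)
            ci_parts.append(np.full(len(vals), ci, dtype=np.int32))
            pos_parts.append(pos)
        vals = np.concatenate(vals_parts) if vals_parts else np.empty(0, dtype=np.uint64)
        ci = np.concatenate(ci_parts) if ci_parts else np.empty(0, dtype=np.int32)
        pos = np.concatenate(pos_parts) if pos_parts else np.empty(0, dtype=np.int64)
        order = np.lexsort((pos, ci, vals))
        self._vals = vals[order]
        self._ci = ci[order]
        self._pos = pos[order]
        total = counts.sum()
        self.base_composition = (
            (counts / total) if total else np.full(4, 0.25)
        )
        self.karlin_lambda = karlin_lambda(self.base_composition)

    def lookup(self, value: int) -> Tuple[np.ndarray, np.ndarray]:
        value = np.uint64(value)
        lo = int(np.searchsorted(self._vals, value, side="left"))
        hi = int(np.searchsorted(self._vals, value, side="right"))
        return self._ci[lo:hi], self._pos[lo:hi]

    def lookup_many(self, values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Range bounds in the sorted word table for a vector of values."""
        values = values.astype(np.uint64, copy=False)
        lo = np.searchsorted(self._vals, values, side="left")
        hi = np.searchsorted(self._vals, values, side="right")
        return lo, hi


def _word_values(codes: np.ndarray, w: int) -> Tuple[np.ndarray, np.ndarray]:
    """Packed values of every valid length-w window plus their positions."""
    n = len(codes)
    if n < w:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=np.int64)
    m = n - w + 1
    invalid = (codes < 0).astype(np.int64)
    bad = np.concatenate([[0], np.cumsum(invalid)])
    ok = (bad[w:] - bad[:-w]) == 0
    safe = np.where(codes < 0, 0, codes).astype(np.uint64)
    vals = np.zeros(m, dtype=np.uint64)
    for j in range(w):
        vals |= safe[j : j + m] << np.uint64(2 * (w - 1 - j))
    positions = np.nonzero(ok)[0].astype(np.int64)
    return vals[positions], positions


def _kadane_on_diagonal(
    q_codes: np.ndarray, r_codes: np.ndarray, diag: int
) -> Tuple[int, int, int]:
    """Best ungapped local segment on one diagonal.

    Returns (score, q_start, q_end); (0, 0, 0) when nothing positive.
    """
    L = len(q_codes)
    lo = max(0, -diag)
    hi = min(L, len(r_codes) - diag)
    if hi <= lo:
        return 0, 0, 0
    q = q_codes[lo:hi]
    r = r_codes[lo + diag : hi + diag]
    s = np.where((q == r) & (q >= 0), MATCH, MISMATCH)
    best = run = 0
    best_start = best_end = run_start = 0
    for i, v in enumerate(s):
        if run <= 0:
            run = int(v)
            run_start = i
        else:
            run += int(v)
        if run > best:
            best = run
            best_start, best_end = run_start, i + 1
    return best, lo + best_start, lo + best_end


def _affine_local_dp(
    q: np.ndarray, r: np.ndarray
) -> Optional[Tuple[int, int, int, int, int, int, int, int, int]]:
    """Full Smith-Waterman with affine gaps under the module scoring.

    Returns (score, qs, qe, ss, se, identities, aligned_length, mismatches,
    gap_opens) or None if no positive-scoring alignment exists. The best
    cell with the smallest (query, ref) end coordinates wins ties, making
    output deterministic.
    """
    m, n = len(q), len(r)
    NEG = -(10**9)
    open_cost = GAP_OPEN + GAP_EXTEND
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap consuming reference
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap consuming query
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        qi = q[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei = E[i]
        Fi, Fi1 = F[i], F[i - 1]
        for j in range(1, n + 1):
            e = max(Hi[j - 1] - open_cost, Ei[j - 1] - GAP_EXTEND)
            f = max(Hi1[j] - open_cost, Fi1[j] - GAP_EXTEND)
            sub = MATCH if (qi == r[j - 1] and qi >= 0) else MISMATCH
            h = Hi1[j - 1] + sub
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            Ei[j] = e
            Fi[j] = f
            Hi[j] = h
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return None

    # traceback
    i, j = bi, bj
    identities = mismatches = gap_opens = aligned = 0
    state = "H"
    while i > 0 and j > 0:
        h = H[i][j]
        if state == "H":
            if h == 0:
                break
            sub = MATCH if (q[i - 1] == r[j - 1] and q[i - 1] >= 0) else MISMATCH
            if h == H[i - 1][j - 1] + sub:
                aligned += 1
                if sub == MATCH:
                    identities += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif h == E[i][j]:
                state = "E"
            elif h == F[i][j]:
                state = "F"
            else:  # pragma: no cover - defensive
                break
        elif state == "E":
            aligned += 1
            if E[i][j] == H[i][j - 1] - open_cost:
                gap_opens += 1
                state = "H"
            j -= 1
        else:  # state == "F"
            aligned += 1
            if F[i][j] == H[i - 1][j] - open_cost:
                gap_opens += 1
                state = "H"
            i -= 1
    qs, ss = i, j
    return best, qs, bi, ss, bj, identities, aligned, mismatches, gap_opens


def align_read(
    read: SyntheticRead | str,
    index: SeedIndex,
    max_alignments: int = 10,
    min_score: Optional[int] = None,
    evalue: float = 1e-10,
    max_candidates: int = 50,
    dp_pad: int = 30,
) -> List[LocalAlignment]:
    """Seed-and-extend alignment of one read against the indexed reference.

    Candidate diagonals come from exact seed-word hits on both strands; each
    is scored by ungapped extension, then refined by windowed affine-gap DP
    unless already a perfect full-length match. Up to ``max_alignments``
    non-duplicate alignments with score >= ``min_score`` are returned,
    ordered by (score desc, reference position asc). ``min_score`` defaults
    to the floor implied by ``evalue`` under ungapped Karlin-Altschul
    statistics for the reference composition.
    """
    if isinstance(read, str):
        read = SyntheticRead("query", read, "query", 0)
    seq = read.sequence.upper()
    L = len(seq)
    w = index.word_size
    if w > L:
        raise ValueError("seed word length exceeds read length")
    lam = index.karlin_lambda
    if min_score is None:
        min_score = min_score_for_evalue(evalue, L, max(index.total_length, 1), lam)
    trigger = max(1, min_score - 10)  # ungapped score needed to attempt DP

    candidates: List[LocalAlignment] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else seq.translate(_COMPLEMENT)[::-1]
        q_codes = encode(s)
        vals, qpos = _word_values(q_codes, w)
        diag_hits: Dict[Tuple[int, int], int] = {}
        los, his = index.lookup_many(vals)
        for qp, lo, hi in zip(qpos, los, his):
            for t in range(lo, hi):
                key = (int(index._ci[t]), int(index._pos[t]) - int(qp))
                diag_hits[key] = diag_hits.get(key, 0) + 1
        ranked = sorted(diag_hits.items(), key=lambda kv: (-kv[1], kv[0]))[:max_candidates]
        for (ci, diag), _count in ranked:
            r_codes = index.contig_codes[ci]
            score, qs, qe = _kadane_on_diagonal(q_codes, r_codes, diag)
            if score < trigger:
                continue
            if score == L:  # perfect full-length match; DP cannot improve
                aln = _make_alignment(
                    read, index, ci, strand, L, score, 0, L, diag, diag + L,
                    identities=L, aligned=L, mismatches=0, gap_opens=0, lam=lam,
                )
                candidates.append(aln)
                continue
            ws = max(0, diag - dp_pad)
            we = min(len(r_codes), diag + L + dp_pad)
            result = _affine_local_dp(q_codes, r_codes[ws:we])
            if result is None:
                continue
            dscore, dqs, dqe, dss, dse, ident, aligned, mism, gopen = result
            candidates.append(
                _make_alignment(
                    read, index, ci, strand, L, dscore, dqs, dqe, ws + dss, ws + dse,
                    identities=ident, aligned=aligned, mismatches=mism,
                    gap_opens=gopen, lam=lam,
                )
            )

    candidates.sort(
        key=lambda a: (-a.score, a.ref_id, a.s_start, a.strand, a.q_start)
    )
    kept: List[LocalAlignment] = []
    for aln in candidates:
        if aln.score < min_score:
            continue
        dup = False
        for prev in kept:
            if prev.ref_id != aln.ref_id:
                continue
            ov = min(prev.s_end, aln.s_end) - max(prev.s_start, aln.s_start)
            if ov > 0 and ov > 0.5 * (aln.s_end - aln.s_start):
                dup = True
                break
        if not dup:
            kept.append(aln)
        if len(kept) >= max_alignments:
            break
    return kept


def _make_alignment(
    read: SyntheticRead,
    index: SeedIndex,
    ci: int,
    strand: str,
    L: int,
    score: int,
    qs: int,
    qe: int,
    ss: int,
    se: int,
    identities: int,
    aligned: int,
    mismatches: int,
    gap_opens: int,
    lam: float,
) -> LocalAlignment:
    # qs/qe are coordinates on the searched (possibly reverse-complemented)
    # strand; report in forward query coordinates.
    if strand == "-":
        qs, qe = L - qe, L - qs
    gaps = aligned - identities - mismatches
    return LocalAlignment(
        query_id=read.read_id,
        ref_id=index.contig_names[ci],
        score=score,
        identities=identities,
        aligned_length=aligned,
        mismatches=mismatches,
        gap_opens=gap_opens,
        gaps=gaps,
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
        strand=strand,
        evalue=_alignment_evalue(score, L, max(index.total_length, 1), lam),
    )


def align_reads(
    library: SyntheticReadLibrary,
    reference: Mapping[str, str],
    word_size: int = 11,
    max_alignments: int = 10,
    min_score: Optional[int] = None,
    evalue: float = 1e-10,
) -> List[List[LocalAlignment]]:
    """Align every read of a library; returns one alignment list per read."""
    if not reference:
        raise ValueError("reference is empty")
    if word_size > library.fragment_length:
        raise ValueError("seed word length exceeds fragment length")
    index = SeedIndex(reference, word_size=word_size)
    return [
        align_read(
            read, index, max_alignments=max_alignments,
            min_score=min_score, evalue=evalue,
        )
        for read in library.reads
    ]


def _union_length(intervals: Iterable[Tuple[int, int]]) -> int:
    total = 0
    last_end = -1
    for start, end in sorted(intervals):
        start = max(start, last_end)
        if end > start:
            total += end - start
            last_end = end
        last_end = max(last_end, end)
    return total


def congruence_stats(
    library: SyntheticReadLibrary,
    alignments: Sequence[Sequence[LocalAlignment]],
    query_label: Optional[str] = None,
    ref_label: str = "reference",
) -> CongruenceResult:
    """Tabulate mean query cover %, mapped fraction and >95%-identity
    fraction (strict inequality, best-scoring alignment per read, computed
    over mapped reads only; unmapped reads contribute 0 to mean cover)."""
    if not library.reads:
        raise ValueError("empty read library")
    if len(alignments) != len(library.reads):
        raise ValueError("one alignment list per read is required")
    L = library.fragment_length
    covers: List[float] = []
    mapped = 0
    high_identity = 0
    for alns in alignments:
        if not alns:
            covers.append(0.0)
            continue
        mapped += 1
        covers.append(_union_length(a.query_span for a in alns) / L)
        best = max(alns, key=lambda a: a.score)
        if best.identity > 0.95:
            high_identity += 1
    n = len(library.reads)
    return CongruenceResult(
        query_label=query_label or library.source_label,
        ref_label=ref_label,
        n_reads=n,
        mean_query_cover_pct=100.0 * float(np.mean(covers)),
        mapped_fraction=mapped / n,
        high_identity_fraction=(high_identity / mapped) if mapped else 0.0,
    )


def congruence_matrix(
    assemblies: Mapping[str, Mapping[str, str]],
    fragment_length: int = 240,
    word_size: int = 11,
    max_alignments: int = 10,
    min_score: Optional[int] = None,
    evalue: float = 1e-10,
) -> Dict[Tuple[str, str], CongruenceResult]:
    """All ordered (query, reference) pairs, self-pairs included."""
    if len(assemblies) < 2:
        raise ValueError("at least two assemblies are required")
    libraries = {
        label: shred_assembly(seqs, fragment_length, label=label)
        for label, seqs in assemblies.items()
    }
    results: Dict[Tuple[str, str], CongruenceResult] = {}
    for ref_label, ref_seqs in assemblies.items():
        index = SeedIndex(ref_seqs, word_size=word_size)
        for q_label, library in libraries.items():
            alns = [
                align_read(
                    read, index, max_alignments=max_alignments,
                    min_score=min_score, evalue=evalue,
                )
                for read in library.reads
            ]
            results[(q_label, ref_label)] = congruence_stats(
                library, alns, query_label=q_label, ref_label=ref_label
            )
    return results


def matrix_to_table(results: Mapping[Tuple[str, str], CongruenceResult]):
    """Render the matrix with queries in columns and references in rows;
    each cell is 'cover% (high-identity fraction)'."""
    import pandas as pd

    queries = sorted({q for q, _ in results})
    refs = sorted({r for _, r in results})
    table = pd.DataFrame(index=refs, columns=queries, dtype=object)
    for (q, r), res in results.items():
        table.loc[r, q] = (
            f"{res.mean_query_cover_pct:.2f}% ({res.high_identity_fraction:.2f})"
        )
    table.index.name = "reference"
    table.columns.name = "query"
    return table


def alignments_to_outfmt6(
    alignments: Iterable[LocalAlignment], query_length: Optional[int] = None
) -> List[str]:
    """Tab-separated rows in BLAST -outfmt 6 column order:
    qseqid sseqid pident length mismatch gapopen qstart qend sstart send
    evalue bitscore. Coordinates are 1-based inclusive; minus-strand hits
    have sstart > send. The raw score stands in for the bit score."""
    rows = []
    for a in alignments:
        if a.strand == "+":
            sstart, send = a.s_start + 1, a.s_end
        else:
            sstart, send = a.s_end, a.s_start + 1
        rows.append(
            "\t".join(
                [
                    a.query_id,
                    a.ref_id,
                    f"{100.0 * a.identity:.2f}",
                    str(a.aligned_length),
                    str(a.mismatches),
                    str(a.gap_opens),
                    str(a.q_start + 1),
                    str(a.q_end),
                    str(sstart),
                    str(send),
                    f"{a.evalue:.2e}",
                    str(a.score),
                ]
            )
        )
    return rows
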