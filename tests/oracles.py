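"""Independent brute-force oracles used to validate the package's fast paths.

These deliberately share no code with the implementations they check.
"""

from __future__ import annotations

from typing import Dict, Iterable

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def naive_canonical_kmer_histogram(seqs: Iterable[str], k: int) -> Dict[int, int]:
    """Dictionary enumeration of canonical k-mer multiplicities."""
    table: Dict[str, int] = {}
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            word = seq[i : i + k]
            if any(c not in "ACGT" for c in word):
                continue
            canon = min(word, revcomp(word))
            table[canon] = table.get(canon, 0) + 1
    hist: Dict[int, int] = {}
    for mult in table.values():
        hist[mult] = hist.get(mult, 0) + 1
    return hist


def smith_waterman_affine_score(
    a: str,
    b: str,
    match: int = 1,
    mismatch: int = -1,
    gap_open: int = 3,
    gap_extend: int = 2,
) -> int:
    """Best local alignment score with affine gaps.

    A gap of length g costs gap_open + g * gap_extend (blastn-style positive
    costs). Plain full-matrix dynamic programming, no heuristics.
    """
    m, n = len(a), len(b)
    neg = float("-inf")
    first_gap = gap_open + gap_extend
    prev_h = [0] * (n + 1)
    prev_f = [neg] * (n + 1)
    best = 0
    for i in range(1, m + 1):
        cur_h = [0] * (n + 1)
        cur_f = [neg] * (n + 1)
        e = neg
        ai = a[i - 1]
        for j in range(1, n + 1):
            e = max(cur_h[j - 1] - first_gap, e - gap_extend)
            f = max(prev_h[j] - first_gap, prev_f[j] - gap_extend)
            diag = prev_h[j - 1] + (match if ai == b[j - 1] else mismatch)
            h = max(0, diag, e, f)
            cur_h[j] = h
            cur_f[j] = f
            if h > best:
                best = h
        prev_h, prev_f = cur_h, cur_f
    return int(best)


def ols_fit(xs, ys):
    """Closed-form simple least squares: slope, intercept, r_squared."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((x - mx) ** 2 for x in xs)
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    syy = sum((y - my) ** 2 for y in ys)
    slope = sxy / sxx
    intercept = my - slope * mx
    r2 = 1.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return slope, intercept, r2
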