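"""Discrepancy arithmetic and consolidated multi-method size reports.

Computes the missing-DNA gap (cytometric 1C size minus assembly size), the
repeat/non-repeat partition of a cytometric genome given an assembly repeat
fraction, the 1C base-pair equivalent of a 2C picogram difference, and a
one-genome table comparing every estimator against the cytometric (or, for
simulations, true) size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Tuple

import pandas as pd

from gsize._utils import round_half_away, round_to_nearest
from gsize.cytometry import GB_PER_PG

__all__ = [
    "SizeComparison",
    "RepeatPartition",
    "missing_dna",
    "repeat_partition",
    "pg_diff_to_1c_mbp",
    "consolidated_report",
]

MBP_PER_PG = 1000.0 * GB_PER_PG  # 978 Mbp per pg


@dataclass
class SizeComparison:
    assembly_size_mbp: Optional[float]
    kmer_size_mbp: Optional[float]
    mapping_size_mbp: Optional[float]
    cytometric_1C_mbp: float
    missing_dna_mbp: Optional[float]
    repeat_fraction_of_assembly: Optional[float] = None


@dataclass
class RepeatPartition:
    non_repetitive_mbp: float  # headline, rounded to nearest 100 Mbp
    repetitive_or_uncaptured_mbp: float  # cytometric - headline non-repetitive
    repetitive_pct: float  # of the cytometric size
    non_repetitive_exact_mbp: float
    repetitive_or_uncaptured_exact_mbp: float


def missing_dna(cytometric_1C_mbp: float, assembly_mbp: float) -> float:
    """Cytometric 1C size minus assembly size (Mbp); warns when negative."""
    if cytometric_1C_mbp <= 0 or assembly_mbp <= 0:
        raise ValueError("sizes must be positive")
    gap = cytometric_1C_mbp - assembly_mbp
    if gap < 0:
        warnings.warn(
            "assembly is larger than the cytometric genome size "
            f"({assembly_mbp} > {cytometric_1C_mbp} Mbp)",
            stacklevel=2,
        )
    return gap


def repeat_partition(
    cytometric_1C_mbp: float, assembly_mbp: float, repeat_fraction: float
) -> RepeatPartition:
    """Partition the cytometric genome into non-repetitive vs
    repetitive-or-uncaptured DNA.

    The non-repetitive portion is the assembly's non-repeat share; the
    headline figure is rounded to the nearest 100 Mbp before subtraction
    (exact values are returned alongside). The percentage is relative to the
    cytometric size.
    """
    if not (0.0 <= repeat_fraction <= 1.0):
        raise ValueError("repeat_fraction must be in [0, 1]")
    if cytometric_1C_mbp <= 0 or assembly_mbp <= 0:
        raise ValueError("sizes must be positive")
    non_rep_exact = assembly_mbp * (1.0 - repeat_fraction)
    if non_rep_exact > cytometric_1C_mbp:
        raise ValueError(
            "non-repetitive assembly content exceeds the cytometric genome size"
        )
    non_rep = round_to_nearest(non_rep_exact, 100)
    repetitive = cytometric_1C_mbp - non_rep
    return RepeatPartition(
        non_repetitive_mbp=non_rep,
        repetitive_or_uncaptured_mbp=repetitive,
        repetitive_pct=100.0 * repetitive / cytometric_1C_mbp,
        non_repetitive_exact_mbp=non_rep_exact,
        repetitive_or_uncaptured_exact_mbp=cytometric_1C_mbp - non_rep_exact,
    )


def pg_diff_to_1c_mbp(two_C_pg_diff: float, nearest: int = 10) -> float:
    """1C Mbp equivalent of a 2C picogram difference: pg x 978 / 2, rounded
    to the nearest ``nearest`` Mbp (default 10)."""
    if two_C_pg_diff < 0:
        raise ValueError("difference must be non-negative")
    return round_to_nearest(two_C_pg_diff * MBP_PER_PG / 2.0, nearest)


def consolidated_report(
    cytometric_1C_mbp: float,
    estimates_mbp: Mapping[str, float],
    repeat_fraction: Optional[float] = None,
) -> Tuple[SizeComparison, pd.DataFrame]:
    """One row per method with its size and ratio to the reference size.

    ``cytometric_1C_mbp`` is the comparison baseline: the cytometric size
    for real data, the simulated true size for simulations. Recognized
    method keys: ``assembly``, ``kmer``, ``mapping`` (others are reported in
    the table but not placed in :class:`SizeComparison`).
    """
    if not estimates_mbp:
        raise ValueError("at least one estimate is required")
    if cytometric_1C_mbp <= 0:
        raise ValueError("reference size must be positive")
    rows = [
        {
            "method": "cytometric/true",
            "size_mbp": round_half_away(cytometric_1C_mbp, 1),
            "ratio_to_reference": 1.0,
        }
    ]
    for method, size in estimates_mbp.items():
        rows.append(
            {
                "method": method,
                "size_mbp": round_half_away(size, 1),
                "ratio_to_reference": round_half_away(size / cytometric_1C_mbp, 3),
            }
        )
    table = pd.DataFrame(rows)
    assembly = estimates_mbp.get("assembly")
    comparison = SizeComparison(
        assembly_size_mbp=assembly,
        kmer_size_mbp=estimates_mbp.get("kmer"),
        mapping_size_mbp=estimates_mbp.get("mapping"),
        cytometric_1C_mbp=cytometric_1C_mbp,
        missing_dna_mbp=(
            missing_dna(cytometric_1C_mbp, assembly) if assembly else None
        ),
        repeat_fraction_of_assembly=repeat_fraction,
    )
    return comparison, table
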