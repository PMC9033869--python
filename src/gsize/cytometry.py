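"""Cytometric genome-size calculators.

Flow-cytometry (FCM) fluorescence-ratio conversion, Feulgen image analysis
densitometry (FIAD) integrated-optical-density conversion against internal
reference standards of known 2C DNA content, calibration regression,
pg <-> Gb conversion (1 pg = 0.978 Gb) and 2C <-> 1C halving/doubling, plus
the mean/SEM/CV summaries used for per-specimen reporting.

Rounding convention throughout: half-away-from-zero, 2 decimals for pg and
Gb, 3 decimals for SEM. The coefficient of variation is defined on the raw
fluorescence/IOD measurements, not on converted picogram values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from gsize._utils import round_half_away

__all__ = [
    "PG_PER_GB",
    "GB_PER_PG",
    "ReferenceStandard",
    "STANDARDS",
    "FcmSample",
    "FiadMeasurement",
    "FiadResult",
    "CytometryRecord",
    "fcm_dna_content",
    "fiad_dna_content",
    "calibration_curve",
    "pg_to_gb",
    "gb_to_pg",
    "combine_standards",
    "summarize_specimens",
    "derive_1C",
    "derive_2C_from_gamete",
    "make_record",
    "process_fcm_table",
    "process_fiad_table",
]

GB_PER_PG = 0.978  # 1 pg DNA = 0.978 Gb
PG_PER_GB = 1.0 / GB_PER_PG


@dataclass(frozen=True)
class ReferenceStandard:
    """Internal reference standard of known 2C DNA content."""

    name: str
    two_C_pg: float

    def __post_init__(self) -> None:
        if self.two_C_pg <= 0:
            raise ValueError("standard 2C value must be positive")


STANDARDS: Dict[str, ReferenceStandard] = {
    s.name: s
    for s in (
        ReferenceStandard("chicken", 2.50),
        ReferenceStandard("human", 7.00),
        ReferenceStandard("trout", 5.2),
        ReferenceStandard("fruit-fly", 0.40),
    )
}


@dataclass(frozen=True)
class FcmSample:
    label: str
    mean_FL: float
    standard_FL: float
    standard: ReferenceStandard

    def __post_init__(self) -> None:
        if self.mean_FL <= 0 or self.standard_FL <= 0:
            raise ValueError("fluorescence values must be positive")


@dataclass(frozen=True)
class FiadMeasurement:
    specimen: str
    iod_values: Tuple[float, ...]
    standard_mean_iod: float
    standard: ReferenceStandard

    def __post_init__(self) -> None:
        object.__setattr__(self, "iod_values", tuple(self.iod_values))
        if not self.iod_values:
            raise ValueError("at least one nucleus is required")
        if any(v <= 0 for v in self.iod_values) or self.standard_mean_iod <= 0:
            raise ValueError("IOD values must be positive")


@dataclass
class FiadResult:
    per_nucleus_pg: List[float]
    mean_pg: float
    sem_pg: Optional[float]  # None for a single nucleus
    cv_pct: float  # CV of the raw IOD values (sample SD / mean * 100)
    n: int


@dataclass
class CytometryRecord:
    """Per-specimen 2C estimate with provenance, convertible to Gb and 1C."""

    specimen: str
    method: str  # "FCM" | "FIAD"
    per_standard_pg: Dict[str, float]
    combined_pg: float  # mean across standards (unrounded)
    two_C_gb: float  # round2(combined_pg * 0.978)
    one_C_pg: float
    one_C_gb: float
    cv_pct: Optional[float] = None
    sem_pg: Optional[float] = None
    n: Optional[int] = None


def fcm_dna_content(sample: FcmSample) -> float:
    """pg = mean FL of the sample x standard 2C pg / mean FL of the standard."""
    return sample.mean_FL * sample.standard.two_C_pg / sample.standard_FL


def fiad_dna_content(measurement: FiadMeasurement) -> FiadResult:
    """Per-nucleus pg = (pg_s / IOD_s) x IOD_c; summaries over nuclei."""
    factor = measurement.standard.two_C_pg / measurement.standard_mean_iod
    per_nucleus = [factor * v for v in measurement.iod_values]
    iods = np.asarray(measurement.iod_values, dtype=float)
    n = len(per_nucleus)
    mean_pg = float(np.mean(per_nucleus))
    if n > 1:
        sem_pg = float(np.std(per_nucleus, ddof=1) / math.sqrt(n))
        cv = float(100.0 * np.std(iods, ddof=1) / np.mean(iods))
    else:
        sem_pg = None
        cv = 0.0
    return FiadResult(per_nucleus_pg=per_nucleus, mean_pg=mean_pg, sem_pg=sem_pg, cv_pct=cv, n=n)


def calibration_curve(
    standards: Sequence[Tuple[float, float]]
) -> Tuple[float, float, float]:
    """Ordinary least squares of known pg on measured mean IOD.

    ``standards`` is a sequence of (mean IOD, known pg). Returns (slope,
    intercept, r_squared). Rejects fewer than two points and coincident IODs.
    """
    if len(standards) < 2:
        raise ValueError("at least two standards are required")
    iod = np.asarray([s[0] for s in standards], dtype=float)
    pg = np.asarray([s[1] for s in standards], dtype=float)
    if np.ptp(iod) == 0:
        raise ValueError("standard IOD values are coincident")
    fit = stats.linregress(iod, pg)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue**2)


def pg_to_gb(pg: float, rounded: bool = True) -> float:
    """Gb = pg x 0.978, reported rounded half-away-from-zero to 2 decimals."""
    if pg < 0:
        raise ValueError("picogram value must be non-negative")
    gb = pg * GB_PER_PG
    return round_half_away(gb, 2) if rounded else gb


def gb_to_pg(gb: float, rounded: bool = True) -> float:
    if gb < 0:
        raise ValueError("gigabase value must be non-negative")
    pg = gb / GB_PER_PG
    return round_half_away(pg, 2) if rounded else pg


def combine_standards(values: Sequence[float]) -> float:
    """Arithmetic mean of per-standard pg estimates (conversion to Gb is
    applied after averaging)."""
    if len(values) < 1:
        raise ValueError("at least one value is required")
    return float(np.mean(values))


def summarize_specimens(values: Sequence[float]) -> Tuple[float, Optional[float]]:
    """Across-specimen mean (2 decimals) and SEM (sample SD / sqrt(n), 3
    decimals; None for a single specimen)."""
    if len(values) < 1:
        raise ValueError("at least one value is required")
    mean = round_half_away(float(np.mean(values)), 2)
    if len(values) < 2:
        return mean, None
    sem = float(np.std(values, ddof=1) / math.sqrt(len(values)))
    return mean, round_half_away(sem, 3)


def derive_1C(two_C_pg: float) -> float:
    if two_C_pg <= 0:
        raise ValueError("2C value must be positive")
    return two_C_pg / 2.0


def derive_2C_from_gamete(one_C_pg: float) -> float:
    if one_C_pg <= 0:
        raise ValueError("1C value must be positive")
    return one_C_pg * 2.0


def make_record(
    specimen: str,
    method: str,
    per_standard_pg: Dict[str, float],
    cv_pct: Optional[float] = None,
    sem_pg: Optional[float] = None,
    n: Optional[int] = None,
) -> CytometryRecord:
    """Assemble a per-specimen record: combine standards, convert, halve."""
    if method not in ("FCM", "FIAD"):
        raise ValueError("method must be 'FCM' or 'FIAD'")
    combined = combine_standards(list(per_standard_pg.values()))
    return CytometryRecord(
        specimen=specimen,
        method=method,
        per_standard_pg=dict(per_standard_pg),
        combined_pg=combined,
        two_C_gb=pg_to_gb(combined),
        one_C_pg=derive_1C(combined),
        one_C_gb=round_half_away(derive_1C(combined) * GB_PER_PG, 2),
        cv_pct=cv_pct,
        sem_pg=sem_pg,
        n=n,
    )


_TABLE_COLUMNS = ["specimen", "method", "value", "value_type", "standard_name", "standard_value"]


def _check_table(df: pd.DataFrame) -> None:
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"input table is missing columns: {missing}")


def process_fcm_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample FCM conversion from a tidy measurement table.

    One row per (specimen, standard) pair: ``value`` is the sample's mean FL
    and ``standard_value`` the standard's mean FL; ``standard_name`` selects
    the built-in 2C content. Returns one row per specimen with per-standard
    and combined pg plus Gb and 1C columns.
    """
    _check_table(df)
    fcm = df[df["method"].str.upper() == "FCM"]
    rows = []
    for specimen, grp in fcm.groupby("specimen", sort=False):
        per_standard: Dict[str, float] = {}
        for _, row in grp.iterrows():
            std = STANDARDS[str(row["standard_name"])]
            sample = FcmSample(
                label=str(specimen),
                mean_FL=float(row["value"]),
                standard_FL=float(row["standard_value"]),
                standard=std,
            )
            per_standard[std.name] = fcm_dna_content(sample)
        rec = make_record(str(specimen), "FCM", per_standard, n=len(grp))
        rows.append(_record_to_row(rec))
    return pd.DataFrame(rows)


def process_fiad_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-specimen FIAD conversion from a tidy per-nucleus table.

    One row per nucleus: ``value`` is the nucleus IOD and ``standard_value``
    the standard's mean IOD. Nuclei group by (specimen, standard).
    """
    _check_table(df)
    fiad = df[df["method"].str.upper() == "FIAD"]
    rows = []
    for specimen, grp in fiad.groupby("specimen", sort=False):
        per_standard: Dict[str, float] = {}
        cv = None
        sem = None
        n_nuclei = 0
        for std_name, sgrp in grp.groupby("standard_name", sort=False):
            std = STANDARDS[str(std_name)]
            m = FiadMeasurement(
                specimen=str(specimen),
                iod_values=tuple(float(v) for v in sgrp["value"]),
                standard_mean_iod=float(sgrp["standard_value"].iloc[0]),
                standard=std,
            )
            result = fiad_dna_content(m)
            per_standard[std.name] = result.mean_pg
            cv, sem, n_nuclei = result.cv_pct, result.sem_pg, result.n
        rec = make_record(
            str(specimen), "FIAD", per_standard, cv_pct=cv, sem_pg=sem, n=n_nuclei
        )
        rows.append(_record_to_row(rec))
    return pd.DataFrame(rows)


def _record_to_row(rec: CytometryRecord) -> Dict[str, object]:
    row: Dict[str, object] = {
        "specimen": rec.specimen,
        "method": rec.method,
        "n": rec.n,
    }
    for std, pg in rec.per_standard_pg.items():
        row[f"pg_vs_{std}"] = round_half_away(pg, 2)
    row["combined_pg"] = round_half_away(rec.combined_pg, 2)
    row["two_C_gb"] = rec.two_C_gb
    row["one_C_pg"] = round_half_away(rec.one_C_pg, 2)
    row["one_C_gb"] = rec.one_C_gb
    row["cv_pct"] = rec.cv_pct
    row["sem_pg"] = None if rec.sem_pg is None else round_half_away(rec.sem_pg, 3)
    return row
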