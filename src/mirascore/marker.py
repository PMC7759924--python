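"""Quartile-index combined two-marker score.

Each patient's normalized hsa-miR-375 and RASD1 levels are mapped, within the
cohort and separately per marker, to a quartile index 1–4; the index
difference d = index(miR-375) − index(RASD1) in {−3..3} defines three strata:

* ``MIR_HIGH``  (d > 0): the microRNA outranks its target — expected high-risk,
* ``EQUAL``     (d = 0): both markers sit in the same quartile,
* ``RASD1_HIGH`` (d < 0): the target outranks the microRNA.

Because the construction is rank-based it is invariant to any strictly
monotone rescaling of either marker, which is what makes levels from two
different assay platforms comparable.  A continuous companion score for ROC
analysis is the miR-375/RASD1 ratio, either of raw normalized levels or (the
scale-free default) of within-cohort fractional ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Stratum",
    "BiomarkerPair",
    "CombinedMarker",
    "quartile_index",
    "combine",
    "ratio_score",
    "ratio_scores",
    "read_pairs_csv",
    "markers_to_frame",
]


class Stratum(str, Enum):
    MIR_HIGH = "MIR_HIGH"
    EQUAL = "EQUAL"
    RASD1_HIGH = "RASD1_HIGH"


@dataclass(frozen=True)
class BiomarkerPair:
    """Per-patient normalized levels of the two markers."""

    patient_id: str
    mir375: float
    rasd1: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mir375) and math.isfinite(self.rasd1)):
            raise ValueError(f"patient {self.patient_id}: non-finite marker level")
        if self.mir375 < 0 or self.rasd1 < 0:
            raise ValueError(f"patient {self.patient_id}: negative marker level")


@dataclass(frozen=True)
class CombinedMarker:
    """Per-patient quartile indices, index difference d, and stratum label."""

    patient_id: str
    mir_quartile: int
    rasd1_quartile: int
    d: int
    stratum: Stratum

    def __post_init__(self) -> None:
        if self.d != self.mir_quartile - self.rasd1_quartile:
            raise ValueError("d must equal mir_quartile - rasd1_quartile")
        expected = (
            Stratum.MIR_HIGH if self.d > 0 else Stratum.EQUAL if self.d == 0 else Stratum.RASD1_HIGH
        )
        if self.stratum != expected:
            raise ValueError(f"stratum {self.stratum} inconsistent with d={self.d}")


def quartile_index(cohort_values: Sequence[float], x: float) -> int:
    """Map a cohort member's value to its within-cohort quartile index 1–4.

    Quartile boundaries Q1, Q2, Q3 are the empirical 25/50/75% quantiles under
    the linear-interpolation definition; the mapping is lower-open /
    upper-closed (x <= Q1 -> 1, Q1 < x <= Q2 -> 2, Q2 < x <= Q3 -> 3,
    x > Q3 -> 4), so the cohort minimum and maximum always land in 1 and 4 and
    boundary ties share the lower index.
    """
    values = np.asarray(cohort_values, dtype=float)
    if values.size < 4:
        raise ValueError("quartile indexing needs a cohort of at least 4 values")
    if not np.all(np.isfinite(values)) or not math.isfinite(x):
        raise ValueError("non-finite value in quartile indexing")
    q1, q2, q3 = np.quantile(values, [0.25, 0.5, 0.75])
    if x <= q1:
        return 1
    if x <= q2:
        return 2
    if x <= q3:
        return 3
    return 4


def combine(pairs: Sequence[BiomarkerPair]) -> list[CombinedMarker]:
    """Quartile-index both markers over the cohort and form d and the stratum.

    Quartiles are computed within this cohort, separately per marker; applying
    the marker to a new cohort therefore requires re-running ``combine`` on
    that cohort.  Swapping the two marker columns negates every d.
    """
    if len(pairs) < 4:
        raise ValueError("combined marker needs a cohort of at least 4 patients")
    mir = [p.mir375 for p in pairs]
    ras = [p.rasd1 for p in pairs]
    out: list[CombinedMarker] = []
    for p in pairs:
        qm = quartile_index(mir, p.mir375)
        qr = quartile_index(ras, p.rasd1)
        d = qm - qr
        stratum = Stratum.MIR_HIGH if d > 0 else Stratum.EQUAL if d == 0 else Stratum.RASD1_HIGH
        out.append(CombinedMarker(p.patient_id, qm, qr, d, stratum))
    return out


def _fractional_ranks(values: np.ndarray) -> np.ndarray:
    """Midrank-based fractional ranks scaled to (0, 1]."""
    return stats.rankdata(values, method="average") / values.size


def ratio_scores(pairs: Sequence[BiomarkerPair], mode: str = "rank") -> np.ndarray:
    """miR-375/RASD1 ratio score per patient, for ROC analysis.

    ``mode="rank"`` (default) divides within-cohort fractional ranks (midranks
    for ties, scaled to (0,1]) — scale-free across assay platforms.
    ``mode="raw"`` divides the raw normalized levels and requires rasd1 > 0.
    """
    mir = np.array([p.mir375 for p in pairs], dtype=float)
    ras = np.array([p.rasd1 for p in pairs], dtype=float)
    if mode == "rank":
        return _fractional_ranks(mir) / _fractional_ranks(ras)
    if mode == "raw":
        if np.any(ras == 0):
            bad = [p.patient_id for p, r in zip(pairs, ras) if r == 0]
            raise ValueError(f"raw ratio undefined for RASD1 = 0 (patients {bad})")
        return mir / ras
    raise ValueError(f"unknown ratio mode {mode!r}")


def ratio_score(pair: BiomarkerPair, cohort: Sequence[BiomarkerPair] | None = None, mode: str = "rank") -> float:
    """Single-patient ratio score; rank mode needs the cohort for the ranking."""
    if mode == "raw":
        if pair.rasd1 == 0:
            raise ValueError(f"raw ratio undefined for RASD1 = 0 (patient {pair.patient_id})")
        return pair.mir375 / pair.rasd1
    if cohort is None:
        raise ValueError("rank mode requires the cohort")
    idx = next(i for i, p in enumerate(cohort) if p.patient_id == pair.patient_id)
    return float(ratio_scores(cohort, mode="rank")[idx])


def read_pairs_csv(path) -> list[BiomarkerPair]:
    """Read patient_id, mir375, rasd1 CSV into biomarker pairs."""
    df = pd.read_csv(path, float_precision="round_trip")
    need = {"patient_id", "mir375", "rasd1"}
    if not need <= set(df.columns):
        raise ValueError(f"pairs CSV needs columns {sorted(need)}")
    return [
        BiomarkerPair(str(r.patient_id), float(r.mir375), float(r.rasd1))
        for r in df.itertuples(index=False)
    ]


def markers_to_frame(markers: Sequence[CombinedMarker]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in markers],
            "mir_quartile": [m.mir_quartile for m in markers],
            "rasd1_quartile": [m.rasd1_quartile for m in markers],
            "d": [m.d for m in markers],
            "stratum": [m.stratum.value for m in markers],
        }
    )
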