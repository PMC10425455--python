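"""Reference quality chemistry for loquat fruit.

Fruit colour is summarised by the colour *e* statistic computed from CIELAB
coordinates, ``e = 1000 a* / (L* b*)``, which contrasts the red-green (a*)
against the lightness x yellow-blue (L*, b*) directions.  Maturity stages
I/II/III are defined by thresholds on a*: below 8.33 (green, stage I),
between 8.33 and 15.41 inclusive (turning, stage II), above 15.41 (ripe,
stage III).  Firmness is measured in kg/cm^2 and soluble solids content
(SSC) in degrees Brix.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError

#: a* thresholds separating maturity stages I/II and II/III.
STAGE_THRESHOLD_LOW = 8.33
STAGE_THRESHOLD_HIGH = 15.41


class MaturityStage(str, enum.Enum):
    I = "I"
    II = "II"
    III = "III"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


STAGES: tuple[MaturityStage, ...] = (
    MaturityStage.I,
    MaturityStage.II,
    MaturityStage.III,
)


def colour_e_value(L_star: float, a_star: float, b_star: float) -> float:
    """Colour *e* statistic ``1000 a* / (L* b*)`` from CIELAB coordinates.

    Raises
    ------
    DomainError
        If ``L_star`` or ``b_star`` is zero (the statistic is undefined).
    """
    if L_star == 0:
        raise DomainError("colour e value undefined: L_star is zero")
    if b_star == 0:
        raise DomainError("colour e value undefined: b_star is zero")
    return 1000.0 * a_star / (L_star * b_star)


def assign_maturity_stage(a_star: float) -> MaturityStage:
    """Map a CIELAB a* reading to a maturity stage.

    Both thresholds are assigned to stage II (closed interval) so the three
    stage predicates partition the real line.
    """
    if not math.isfinite(a_star):
        raise DomainError(f"a_star must be finite, got {a_star!r}")
    if a_star < STAGE_THRESHOLD_LOW:
        return MaturityStage.I
    if a_star <= STAGE_THRESHOLD_HIGH:
        return MaturityStage.II
    return MaturityStage.III


@dataclass(frozen=True)
class SummaryStats:
    """Count, range, mean and (n-1) standard deviation of one quantity."""

    num: int
    range_min: float
    range_max: float
    mean: float
    sd: float


def summarize_quality(values: Iterable[float]) -> SummaryStats:
    """Summary statistics (count, min-max, mean, n-1 SD) of one quality column."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise DomainError("cannot summarise an empty collection of values")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SummaryStats(
        num=int(arr.size),
        range_min=float(arr.min()),
        range_max=float(arr.max()),
        mean=float(arr.mean()),
        sd=sd,
    )


@dataclass(frozen=True)
class QualityRecord:
    """One fruit's reference chemistry: CIELAB colour, firmness, SSC, stage."""

    sample_id: str
    L_star: float
    a_star: float
    b_star: float
    colour_e: float
    firmness: float
    ssc: float
    stage: MaturityStage

    def __post_init__(self) -> None:
        expected_e = colour_e_value(self.L_star, self.a_star, self.b_star)
        if not math.isclose(self.colour_e, expected_e, rel_tol=1e-9, abs_tol=1e-9):
            raise DomainError(
                f"{self.sample_id}: colour_e={self.colour_e} inconsistent with "
                f"1000*a/(L*b)={expected_e}"
            )
        if self.stage != assign_maturity_stage(self.a_star):
            raise DomainError(
                f"{self.sample_id}: stage {self.stage} inconsistent with a*={self.a_star}"
            )
        if self.firmness <= 0:
            raise DomainError(f"{self.sample_id}: firmness must be > 0")
        if self.ssc < 0:
            raise DomainError(f"{self.sample_id}: ssc must be >= 0")


@dataclass
class QualityTable:
    """Ordered collection of :class:`QualityRecord` with provenance."""

    records: list[QualityRecord] = field(default_factory=list)
    provenance: str = "synthetic"  # {"synthetic", "measured"}

    def __post_init__(self) -> None:
        if not self.records:
            raise DomainError("QualityTable must contain at least one record")
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise DomainError("sample_ids must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    def column(self, name: str) -> np.ndarray:
        """Numeric column (``colour_e``, ``firmness``, ``ssc``, ...) as an array."""
        return np.array([getattr(r, name) for r in self.records], dtype=float)

    @property
    def stages(self) -> list[MaturityStage]:
        return [r.stage for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [r.sample_id for r in self.records],
                "L": [r.L_star for r in self.records],
                "a": [r.a_star for r in self.records],
                "b": [r.b_star for r in self.records],
                "colour_e": [r.colour_e for r in self.records],
                "firmness": [r.firmness for r in self.records],
                "ssc": [r.ssc for r in self.records],
                "stage": [r.stage.value for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, provenance: str = "measured") -> "QualityTable":
        records = [
            QualityRecord(
                sample_id=str(row.sample_id),
                L_star=float(row.L),
                a_star=float(row.a),
                b_star=float(row.b),
                colour_e=float(row.colour_e),
                firmness=float(row.firmness),
                ssc=float(row.ssc),
                stage=MaturityStage(row.stage),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records=records, provenance=provenance)

    @classmethod
    def from_csv(cls, path, provenance: str = "measured") -> "QualityTable":
        return cls.from_frame(pd.read_csv(path), provenance=provenance)

    def summarize(self, name: str) -> SummaryStats:
        return summarize_quality(self.column(name))
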