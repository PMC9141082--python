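"""Chromosome measurement tables.

A :class:`MeasurementTable` is the pivot object of the pipeline: the
synthetic generator emits one per species, the image-measurement stage
recovers one from a metaphase spread, and the karyotype analytics consume
one.  The on-disk form is a TSV with columns ``chromosome_id, pair_index,
long_arm, short_arm, unit``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import MeasurementError

_LEVAN_BOUNDS = ((1.70, "m"), (3.00, "sm"), (7.00, "st"))


def arm_ratio(long_arm: float, short_arm: float) -> float:
    """Levan arm ratio: longer arm over shorter arm, orientation-free, >= 1."""
    if long_arm <= 0 or short_arm <= 0:
        raise MeasurementError(
            f"arm lengths must be positive, got ({long_arm}, {short_arm})"
        )
    a, b = sorted((float(long_arm), float(short_arm)))
    return b / a


def classify_levan(ratio: float) -> str:
    """Levan centromere class for an arm ratio.

    Bands: m <= 1.70 < sm <= 3.00 < st <= 7.00 < t.  Boundaries are
    inclusive toward the more symmetric class.
    """
    if ratio < 1.0:
        raise MeasurementError(f"arm ratio {ratio} < 1")
    for bound, cls in _LEVAN_BOUNDS:
        if ratio <= bound:
            return cls
    return "t"


@dataclass(frozen=True)
class ChromosomeMeasurement:
    """One chromosome's arm lengths and derived descriptors."""

    chromosome_id: str
    long_arm: float
    short_arm: float
    pair_index: int | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.short_arm <= 0 or self.long_arm <= 0:
            raise MeasurementError(
                f"{self.chromosome_id}: arm lengths must be positive"
            )
        if self.long_arm < self.short_arm:
            # normalize orientation: long arm is the longer one
            longer, shorter = self.short_arm, self.long_arm
            object.__setattr__(self, "long_arm", longer)
            object.__setattr__(self, "short_arm", shorter)

    @property
    def total_length(self) -> float:
        return self.long_arm + self.short_arm

    @property
    def arm_ratio(self) -> float:
        return arm_ratio(self.long_arm, self.short_arm)

    @property
    def levan_class(self) -> str:
        return classify_levan(self.arm_ratio)


@dataclass(frozen=True)
class MeasurementTable:
    """A species' complement of chromosome measurements."""

    species_id: str
    rows: tuple[ChromosomeMeasurement, ...]
    length_unit: str = "um"
    provenance: str = "fixture-generated"

    def __post_init__(self) -> None:
        ids = [r.chromosome_id for r in self.rows]
        if len(ids) != len(set(ids)):
            raise MeasurementError(f"{self.species_id}: duplicate chromosome ids")

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def with_rows(self, rows: Iterable[ChromosomeMeasurement]) -> "MeasurementTable":
        return replace(self, rows=tuple(rows))

    def total_lengths(self) -> list[float]:
        return [r.total_length for r in self.rows]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chromosome_id": [r.chromosome_id for r in self.rows],
                "pair_index": [r.pair_index for r in self.rows],
                "long_arm": [r.long_arm for r in self.rows],
                "short_arm": [r.short_arm for r in self.rows],
                "unit": self.length_unit,
                "total_length": [r.total_length for r in self.rows],
                "arm_ratio": [r.arm_ratio for r in self.rows],
                "levan_class": [r.levan_class for r in self.rows],
            }
        )

    def write_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        cols = ["chromosome_id", "pair_index", "long_arm", "short_arm", "unit"]
        self.to_frame()[cols].to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        species_id: str | None = None,
        provenance: str = "file",
    ) -> "MeasurementTable":
        df = pd.read_csv(path, sep="\t")
        required = {"chromosome_id", "long_arm", "short_arm"}
        missing = required - set(df.columns)
        if missing:
            raise MeasurementError(f"{path}: missing columns {sorted(missing)}")
        unit = str(df["unit"].iloc[0]) if "unit" in df.columns and len(df) else "um"
        rows = []
        for rec in df.itertuples(index=False):
            pair = getattr(rec, "pair_index", None)
            pair = None if pair is None or pd.isna(pair) else int(pair)
            rows.append(
                ChromosomeMeasurement(
                    chromosome_id=str(rec.chromosome_id),
                    long_arm=float(rec.long_arm),
                    short_arm=float(rec.short_arm),
                    pair_index=pair,
                )
            )
        return cls(
            species_id=species_id or Path(path).stem,
            rows=tuple(rows),
            length_unit=unit,
            provenance=provenance,
        )
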