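"""Karyotype descriptors: relative lengths, Levan formula, Stebbins cytotype.

The descriptors follow the classical conventions of plant cytogenetics:

* per-chromosome arm ratio = long arm / short arm (>= 1), binned into the
  Levan centromere classes m / sm / st / t;
* the karyotype formula counts chromosomes per class, e.g. ``2n = 2x =
  20m + 2sm``;
* the Stebbins cytotype combines a row (proportion of chromosomes with arm
  ratio > 2:1 — 0, (0, 0.5], (0.5, 1), 1 for rows 1-4) with a column from
  the longest/shortest chromosome ratio (< 2 -> A, [2, 4] -> B, > 4 -> C).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import MeasurementError
from .fixtures import LEVAN_CLASSES
from .measurements import (
    ChromosomeMeasurement,
    MeasurementTable,
    arm_ratio,
    classify_levan,
)

__all__ = [
    "arm_ratio",
    "classify_levan",
    "relative_lengths",
    "order_by_length",
    "pair_homologs",
    "class_counts",
    "karyotype_formula",
    "interchromosomal_ratio",
    "stebbins_cytotype",
    "KaryotypeResult",
    "analyze_karyotype",
]


@dataclass(frozen=True)
class KaryotypeResult:
    """Everything a published karyotype table row reports for one species."""

    species_id: str
    formula_string: str
    class_counts: dict[str, int]
    ls_ratio: float
    stebbins_row: int
    stebbins_col: str
    two_n: int
    ploidy: int = 2

    @property
    def cytotype(self) -> str:
        return f"{self.stebbins_row}{self.stebbins_col}"


def _require_rows(table: MeasurementTable) -> None:
    if len(table) == 0:
        raise MeasurementError("empty measurement table")


def relative_lengths(table: MeasurementTable) -> np.ndarray:
    """Each chromosome's total length as a percentage of the whole diploid
    complement; sums to 100."""
    _require_rows(table)
    totals = np.asarray(table.total_lengths(), dtype=float)
    return 100.0 * totals / totals.sum()


def order_by_length(table: MeasurementTable) -> MeasurementTable:
    """Longest-to-shortest ordering with a deterministic tie-break
    (arm ratio ascending, then chromosome id)."""
    rows = sorted(
        table.rows,
        key=lambda r: (-r.total_length, r.arm_ratio, r.chromosome_id),
    )
    return table.with_rows(rows)


def _signal_signature(sites, chromosome_id: str) -> frozenset:
    return frozenset(
        (s.channel, s.arm, round(s.position_fraction, 1))
        for s in sites
        if s.chromosome_id == chromosome_id
    )


def pair_homologs(
    table: MeasurementTable,
    sites: Sequence | None = None,
    length_rtol: float = 0.02,
) -> MeasurementTable:
    """Assign pair indices to a diploid complement.

    Rows are sorted by length and paired adjacently.  When FISH sites are
    supplied, runs of near-equal lengths (within ``length_rtol``) are
    re-paired to maximize signal-pattern agreement, which resolves the
    ambiguity between neighbouring pairs of similar size.
    """
    if len(table) % 2:
        raise MeasurementError(
            f"diploid complement expected: odd row count {len(table)}"
        )
    ordered = list(order_by_length(table).rows)

    if sites is not None and ordered:
        # runs of consecutive near-equal lengths are pairing-ambiguous;
        # re-order within pair-aligned even runs to match signal patterns
        runs: list[list[ChromosomeMeasurement]] = [[ordered[0]]]
        for row in ordered[1:]:
            if runs[-1][-1].total_length - row.total_length <= (
                length_rtol * runs[-1][-1].total_length
            ):
                runs[-1].append(row)
            else:
                runs.append([row])
        reordered: list[ChromosomeMeasurement] = []
        for run in runs:
            if len(run) % 2 or len(reordered) % 2:
                reordered.extend(run)
                continue
            remaining = list(run)
            while remaining:
                first = remaining.pop(0)
                sig = _signal_signature(sites, first.chromosome_id)
                best, best_score = 0, None
                for j, cand in enumerate(remaining):
                    csig = _signal_signature(sites, cand.chromosome_id)
                    score = len(sig & csig) - len(sig ^ csig)
                    if best_score is None or score > best_score:
                        best, best_score = j, score
                reordered.extend((first, remaining.pop(best)))
        ordered = reordered

    from dataclasses import replace

    out = []
    for k, row in enumerate(ordered):
        out.append(replace(row, pair_index=k // 2 + 1))
    return table.with_rows(out)


def class_counts(table: MeasurementTable) -> dict[str, int]:
    """Chromosome count per Levan class, in class order, zero counts omitted."""
    _require_rows(table)
    counts = {cls: 0 for cls in LEVAN_CLASSES}
    for row in table:
        counts[row.levan_class] += 1
    return {k: v for k, v in counts.items() if v}


def karyotype_formula(table: MeasurementTable, ploidy: int = 2) -> str:
    """Karyotype formula string, e.g. ``"2n = 2x = 14m + 12sm + 2st"``."""
    counts = class_counts(table)
    body = " + ".join(f"{v}{k}" for k, v in counts.items())
    return f"2n = {ploidy}x = {body}"


def interchromosomal_ratio(table: MeasurementTable) -> float:
    """Longest / shortest total chromosome length (Stebbins column input)."""
    _require_rows(table)
    totals = table.total_lengths()
    return max(totals) / min(totals)


def stebbins_cytotype(table: MeasurementTable) -> tuple[int, str, str]:
    """Stebbins asymmetry category ``(row, column, label)``.

    Boundary handling: longest/shortest exactly 2 (or 4) stays in column B;
    a proportion of exactly 0.5 stays in row 2.
    """
    _require_rows(table)
    ls = interchromosomal_ratio(table)
    col = "A" if ls < 2.0 else ("B" if ls <= 4.0 else "C")
    p = sum(1 for r in table if r.arm_ratio > 2.0) / len(table)
    if p == 0:
        row = 1
    elif p <= 0.5:
        row = 2
    elif p < 1:
        row = 3
    else:
        row = 4
    return row, col, f"{row}{col}"


def analyze_karyotype(table: MeasurementTable, ploidy: int = 2) -> KaryotypeResult:
    """Full karyotype summary for one species' measurement table."""
    row, col, _ = stebbins_cytotype(table)
    return KaryotypeResult(
        species_id=table.species_id,
        formula_string=karyotype_formula(table, ploidy),
        class_counts=class_counts(table),
        ls_ratio=interchromosomal_ratio(table),
        stebbins_row=row,
        stebbins_col=col,
        two_n=len(table),
        ploidy=ploidy,
    )
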