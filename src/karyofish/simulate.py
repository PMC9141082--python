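"""Synthetic measurement tables from karyotype fixtures.

The generator inverts the analytics: given a fixture's class composition,
longest/shortest ratio and cytotype row, it constructs a diploid complement
that the Levan/Stebbins analytics map back onto exactly the encoded
karyotype.  Haploid lengths follow a geometric decay between the longest
and shortest chromosome; the two homologs of a pair are identical at zero
noise; measurement noise is an independent multiplicative Gaussian
perturbation per arm, truncated at +/- 3 SD so lengths stay positive.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy import stats

from .errors import ConstructionError
from .fixtures import KaryotypeFixture, parse_cytotype
from .measurements import ChromosomeMeasurement, MeasurementTable

#: Representative within-class arm ratios (Levan bands m<=1.70<sm<=3.00<st<=7.00<t).
#: The sm value depends on the fixture's Stebbins row: a row-1 karyotype has no
#: chromosome with arm ratio > 2, so its sm chromosomes sit at 1.9; rows >= 2
#: use 2.2.
DEFAULT_CLASS_RATIOS = {"m": 1.3, "sm": 2.2, "st": 4.0, "t": 8.0}
ROW1_SM_RATIO = 1.9


def class_arm_ratios(stebbins_row: int,
                     overrides: Mapping[str, float] | None = None) -> dict[str, float]:
    """Representative arm ratio per Levan class, consistent with a Stebbins row."""
    ratios = dict(DEFAULT_CLASS_RATIOS)
    if stebbins_row == 1:
        ratios["sm"] = ROW1_SM_RATIO
    if overrides:
        ratios.update(overrides)
    return ratios


def _check_feasible(fixture: KaryotypeFixture, ratios: Mapping[str, float]) -> None:
    row, _col = parse_cytotype(fixture.expected_cytotype)
    counts = {k: v for k, v in fixture.class_counts.items() if v}
    for cls, count in counts.items():
        if count % 2:
            raise ConstructionError(
                f"{fixture.species_id}: class {cls} count {count} is odd; "
                "a diploid complement needs whole homolog pairs"
            )
    asym = sum(v for k, v in counts.items() if ratios[k] > 2.0)
    p = asym / fixture.two_n
    want = {1: p == 0, 2: 0 < p <= 0.5, 3: 0.5 < p < 1, 4: p == 1}[row]
    if not want:
        raise ConstructionError(
            f"{fixture.species_id}: class composition {counts} with arm ratios "
            f"{ratios} gives proportion {p:.3f} of chromosomes with ratio > 2, "
            f"incompatible with Stebbins row {row}"
        )
    if fixture.n_pairs == 1 and abs(fixture.ls_ratio - 1.0) > 1e-12:
        raise ConstructionError(
            f"{fixture.species_id}: a single homolog pair forces ls_ratio = 1, "
            f"got {fixture.ls_ratio}"
        )


def haploid_lengths(fixture: KaryotypeFixture) -> np.ndarray:
    """Haploid total lengths (um), longest first, geometric decay to longest/ls_ratio."""
    n = fixture.n_pairs
    longest = fixture.longest_um
    if n == 1:
        return np.array([longest])
    ratio = fixture.ls_ratio ** (-1.0 / (n - 1))
    return longest * ratio ** np.arange(n)


def pair_classes(fixture: KaryotypeFixture) -> list[str]:
    """Levan class per homolog pair, longest pair first.

    Classes are laid out in symmetry order (m first, then sm, st, t) along
    the length-sorted complement; the real assignment of classes to length
    ranks is not recoverable from a karyotype formula, so a deterministic
    convention is used.
    """
    out: list[str] = []
    for cls in ("m", "sm", "st", "t"):
        out.extend([cls] * (fixture.class_counts.get(cls, 0) // 2))
    return out


def generate_measurement_table(
    fixture: KaryotypeFixture,
    seed: int = 0,
    noise_cv: float = 0.0,
    ratio_overrides: Mapping[str, float] | None = None,
) -> MeasurementTable:
    """Build a diploid measurement table realizing the fixture's karyotype.

    At ``noise_cv = 0`` the table is deterministic (seed-independent), the
    Levan classifier reproduces ``class_counts`` exactly, and the
    longest/shortest total-length ratio equals ``ls_ratio`` to within 1e-9.
    At positive ``noise_cv`` each arm is scaled by an independent factor
    ``1 + e`` with ``e ~ Normal(0, noise_cv)`` truncated at +/- 3 SD.
    """
    if noise_cv < 0:
        raise ConstructionError(f"noise_cv must be >= 0, got {noise_cv}")
    fixture.validate()
    row, _ = parse_cytotype(fixture.expected_cytotype)
    ratios = class_arm_ratios(row, ratio_overrides)
    _check_feasible(fixture, ratios)

    lengths = haploid_lengths(fixture)
    classes = pair_classes(fixture)
    rows: list[ChromosomeMeasurement] = []
    for i, (total, cls) in enumerate(zip(lengths, classes), start=1):
        a = ratios[cls]
        long_arm = total * a / (1.0 + a)
        short_arm = total / (1.0 + a)
        for homolog in "ab":
            rows.append(
                ChromosomeMeasurement(
                    chromosome_id=f"{i:02d}{homolog}",
                    long_arm=long_arm,
                    short_arm=short_arm,
                    pair_index=i,
                )
            )

    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        n = len(rows)
        eps = stats.truncnorm.rvs(-3.0, 3.0, scale=noise_cv, size=(n, 2),
                                  random_state=rng)
        rows = [
            ChromosomeMeasurement(
                chromosome_id=r.chromosome_id,
                long_arm=r.long_arm * (1.0 + eps[k, 0]),
                short_arm=r.short_arm * (1.0 + eps[k, 1]),
                pair_index=r.pair_index,
            )
            for k, r in enumerate(rows)
        ]

    return MeasurementTable(
        species_id=fixture.species_id,
        rows=tuple(rows),
        length_unit="um",
        provenance="fixture-generated",
    )
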