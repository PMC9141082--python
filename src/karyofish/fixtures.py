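"""Ground-truth karyotype fixtures.

A :class:`KaryotypeFixture` encodes everything the pipeline needs to
synthesize a species' diploid metaphase complement: the chromosome number
(2n), the centromere-class composition (Levan classes), the longest/shortest
chromosome length ratio that fixes the Stebbins column, the expected
cytotype label, and the per-homolog-pair 5S rDNA FISH signal assignments.

Five Fabaceae fixtures ship with the package (three *Robinia* taxa,
*Styphnolobium japonicum* and *Amorpha fruticosa*).  User fixtures with the
same JSON schema are loaded from a file path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

from .errors import FixtureValidationError, UnknownSpeciesError

LEVAN_CLASSES = ("m", "sm", "st", "t")
CHANNELS = ("FAM", "TAMRA")
ARMS = ("long", "short")
INTENSITIES = ("strong", "weak")
ZYGOSITIES = ("both-homologs", "one-homolog")

#: Packaged species, in the presentation order of the study.
PACKAGED_SPECIES = (
    "robinia_pseudoacacia",
    "robinia_pseudoacacia_idaho",
    "robinia_pseudoacacia_decaisneana",
    "styphnolobium_japonicum",
    "amorpha_fruticosa",
)

_ALIASES = {
    "idaho": "robinia_pseudoacacia_idaho",
    "decaisneana": "robinia_pseudoacacia_decaisneana",
}


@dataclass(frozen=True)
class SignalAssignment:
    """One locus-specific FISH signal assigned to a homolog pair.

    ``position_fraction`` measures from the centromere toward the telomere
    as a fraction of the arm length.  ``zygosity`` is ``both-homologs`` for
    an ordinary site present on both homologs; ``one-homolog`` restricts the
    site to a single homolog and is only legal when the pair is
    heteromorphic in intensity (one strong and one weak homolog).
    """

    pair_index: int
    channel: str
    arm: str
    position_fraction: float
    intensity: str = "strong"
    zygosity: str = "both-homologs"

    def validate(self, n_pairs: int) -> None:
        if self.channel not in CHANNELS:
            raise FixtureValidationError(f"unknown channel {self.channel!r}")
        if self.arm not in ARMS:
            raise FixtureValidationError(f"unknown arm {self.arm!r}")
        if not 0.0 <= self.position_fraction <= 1.0:
            raise FixtureValidationError(
                f"position_fraction {self.position_fraction} outside [0, 1]"
            )
        if self.intensity not in INTENSITIES:
            raise FixtureValidationError(f"unknown intensity {self.intensity!r}")
        if self.zygosity not in ZYGOSITIES:
            raise FixtureValidationError(f"unknown zygosity {self.zygosity!r}")
        if not 1 <= self.pair_index <= n_pairs:
            raise FixtureValidationError(
                f"pair_index {self.pair_index} outside [1, {n_pairs}]"
            )


@dataclass(frozen=True)
class KaryotypeFixture:
    """Per-species karyotype and signal-pattern ground truth."""

    species_id: str
    species_name: str
    two_n: int
    ploidy: int
    class_counts: Mapping[str, int]
    ls_ratio: float
    expected_cytotype: str
    signal_pairs: Sequence[SignalAssignment] = ()
    length_profile: Mapping[str, float] = field(default_factory=lambda: {"longest_um": 4.0})
    notes: str = ""

    @property
    def n_pairs(self) -> int:
        return self.two_n // 2

    @property
    def longest_um(self) -> float:
        return float(self.length_profile.get("longest_um", 4.0))

    def validate(self) -> None:
        if self.two_n <= 0 or self.two_n % 2:
            raise FixtureValidationError(
                f"two_n must be a positive even integer, got {self.two_n}"
            )
        if self.ploidy <= 0 or self.two_n % self.ploidy:
            raise FixtureValidationError(
                f"two_n={self.two_n} not divisible by ploidy={self.ploidy}"
            )
        unknown = set(self.class_counts) - set(LEVAN_CLASSES)
        if unknown:
            raise FixtureValidationError(f"unknown Levan classes {sorted(unknown)}")
        if any(v < 0 for v in self.class_counts.values()):
            raise FixtureValidationError("negative class count")
        total = sum(self.class_counts.values())
        if total != self.two_n:
            raise FixtureValidationError(
                f"class_counts sum {total} != two_n {self.two_n}"
            )
        if self.ls_ratio < 1.0:
            raise FixtureValidationError(f"ls_ratio {self.ls_ratio} < 1")
        if self.longest_um <= 0:
            raise FixtureValidationError("longest_um must be positive")
        row, col = parse_cytotype(self.expected_cytotype)
        del row, col
        by_pair: dict[int, list[SignalAssignment]] = {}
        for sig in self.signal_pairs:
            sig.validate(self.n_pairs)
            by_pair.setdefault(sig.pair_index, []).append(sig)
        # one-homolog assignments are only legal in heteromorphic pairs
        for pair, sigs in by_pair.items():
            singles = [s for s in sigs if s.zygosity == "one-homolog"]
            if singles and len({s.intensity for s in singles}) < 2:
                raise FixtureValidationError(
                    f"pair {pair}: one-homolog assignments require differing "
                    "intensities between homologs"
                )

    def tamra_pairs(self) -> tuple[int, ...]:
        """Distinct homolog-pair indices bearing a 5S (TAMRA) site."""
        return tuple(sorted({s.pair_index for s in self.signal_pairs
                             if s.channel == "TAMRA"}))


def parse_cytotype(label: str) -> tuple[int, str]:
    """Split a Stebbins label like ``"2B"`` into (row, column)."""
    if (
        not isinstance(label, str)
        or len(label) != 2
        or label[0] not in "1234"
        or label[1] not in "ABC"
    ):
        raise FixtureValidationError(f"malformed Stebbins cytotype {label!r}")
    return int(label[0]), label[1]


def _fixture_from_dict(data: dict) -> KaryotypeFixture:
    try:
        signal_pairs = tuple(
            SignalAssignment(**sig) for sig in data.get("signal_pairs", ())
        )
        fixture = KaryotypeFixture(
            species_id=data["species_id"],
            species_name=data.get("species_name", data["species_id"]),
            two_n=data["two_n"],
            ploidy=data.get("ploidy", 2),
            class_counts=dict(data["class_counts"]),
            ls_ratio=float(data["ls_ratio"]),
            expected_cytotype=data["expected_cytotype"],
            signal_pairs=signal_pairs,
            length_profile=dict(data.get("length_profile", {"longest_um": 4.0})),
            notes=data.get("notes", ""),
        )
    except (KeyError, TypeError) as exc:
        raise FixtureValidationError(f"malformed fixture: {exc}") from exc
    fixture.validate()
    return fixture


def load_species_fixture(species_id: str | Path) -> KaryotypeFixture:
    """Load a packaged species fixture by id (or alias), or a JSON file.

    Raises :class:`UnknownSpeciesError` for an unrecognized id and
    :class:`FixtureValidationError` for a fixture violating an invariant.
    """
    if isinstance(species_id, Path) or str(species_id).endswith(".json"):
        path = Path(species_id)
        if not path.exists():
            raise UnknownSpeciesError(f"fixture file {path} not found")
        return _fixture_from_dict(json.loads(path.read_text()))
    key = _ALIASES.get(str(species_id), str(species_id))
    if key not in PACKAGED_SPECIES:
        raise UnknownSpeciesError(
            f"unknown species {species_id!r}; packaged ids: {', '.join(PACKAGED_SPECIES)}"
        )
    text = (
        resources.files("karyofish.data.fixtures")
        .joinpath(f"{key}.json")
        .read_text()
    )
    return _fixture_from_dict(json.loads(text))


def load_all_fixtures() -> list[KaryotypeFixture]:
    """All five packaged fixtures in presentation order."""
    return [load_species_fixture(sp) for sp in PACKAGED_SPECIES]
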