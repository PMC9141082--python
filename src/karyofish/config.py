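"""Run configuration with lossless TOML round-tripping."""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .errors import KaryofishError
from .fixtures import PACKAGED_SPECIES


@dataclass
class RunConfig:
    """Parameters of a full pipeline run; every field has a default."""

    species: list[str] = field(default_factory=lambda: list(PACKAGED_SPECIES))
    seed: int = 1
    noise_cv: float = 0.0
    pixel_size_um: float = 0.05
    linkage: str = "average"
    weight_n_pairs: float = 1.0
    weight_categories: float = 0.5
    weight_heteromorphic: float = 0.25
    out_dir: str = "karyofish_out"
    log_level: str = "INFO"

    def weights(self) -> dict[str, float]:
        return {
            "n_pairs": self.weight_n_pairs,
            "categories": self.weight_categories,
            "heteromorphic": self.weight_heteromorphic,
        }

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        lines = []
        for f in fields(self):
            value = getattr(self, f.name)
            lines.append(f"{f.name} = {_toml_value(value)}")
        path.write_text("\n".join(lines) + "\n")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise KaryofishError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(value, (list, tuple)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    raise KaryofishError(f"cannot serialize {type(value).__name__} to TOML")
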