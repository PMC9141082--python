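"""Karyotype summary reports, signal tables and run manifests."""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy

from .config import RunConfig
from .errors import MeasurementError
from .karyotype import KaryotypeResult
from .profiles import (
    Dendrogram,
    SignalProfile,
    cluster_profiles,
    dissimilarity_matrix,
    write_profiles_json,
)
from .signals import SignalSite, position_category


def karyotype_table(results: Sequence[KaryotypeResult]) -> pd.DataFrame:
    """Summary table: Species, Karyotype, Cytotype, Arm Ratio (4 dp)."""
    if not results:
        raise MeasurementError("no karyotype results to report")
    return pd.DataFrame(
        {
            "Species": [r.species_id for r in results],
            "Karyotype": [r.formula_string for r in results],
            "Cytotype": [r.cytotype for r in results],
            "Arm Ratio": [f"{r.ls_ratio:.4f}" for r in results],
        }
    )


def signals_table(sites: Sequence[SignalSite]) -> pd.DataFrame:
    rows = []
    for s in sites:
        rows.append(
            {
                "chromosome_id": s.chromosome_id,
                "channel": s.channel,
                "arm": s.arm,
                "position_fraction": (
                    None if s.position_fraction is None
                    else round(s.position_fraction, 4)
                ),
                "category": (
                    None if s.position_fraction is None
                    else position_category(s.position_fraction)
                ),
                "intensity": s.intensity,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chromosome_id", "channel", "arm", "position_fraction",
                 "category", "intensity"],
    )


def write_report(
    results: Sequence[KaryotypeResult],
    out_dir: str | Path,
    profiles: Sequence[SignalProfile] = (),
    sites_by_species: Mapping[str, Sequence[SignalSite]] | None = None,
    config: RunConfig | None = None,
    linkage: str = "average",
    weights: dict[str, float] | None = None,
) -> dict[str, Path]:
    """Emit the full report bundle into ``out_dir``.

    Always writes the karyotype table and a run manifest; signal tables,
    profile JSON, the dissimilarity matrix and the Newick tree are written
    when their inputs are supplied.
    """
    if not results:
        raise MeasurementError("no karyotype results to report")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    table2 = out / "karyotype_table.tsv"
    karyotype_table(results).to_csv(table2, sep="\t", index=False)
    paths["karyotype_table"] = table2

    for species, sites in (sites_by_species or {}).items():
        p = out / f"signals_{species}.tsv"
        signals_table(sites).to_csv(p, sep="\t", index=False)
        paths[f"signals_{species}"] = p

    if profiles:
        paths["profiles"] = write_profiles_json(profiles, out / "profiles.json")
        dm = dissimilarity_matrix(profiles, weights)
        dm_path = out / "dissimilarity.tsv"
        dm.to_csv(dm_path, sep="\t")
        paths["dissimilarity"] = dm_path
        if len(profiles) >= 2:
            tree: Dendrogram = cluster_profiles(profiles, linkage, weights)
            tree_path = out / "similarity_tree.nwk"
            tree_path.write_text(tree.newick() + "\n")
            paths["tree"] = tree_path

    manifest = {
        "config": (config or RunConfig()).to_dict(),
        "species": [r.species_id for r in results],
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2) + "\n")
    paths["manifest"] = man_path
    return paths
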