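"""Species-level 5S rDNA signal profiles and phenetic clustering.

A :class:`SignalProfile` condenses a species' 5S pattern into the number of
5S-bearing homolog pairs, the site count per arm-position category, and the
number of intensity-heteromorphic pairs.  The pairwise dissimilarity is a
weighted L1 distance on those counts (a pseudometric), and profiles are
grouped by standard agglomerative clustering into a similarity dendrogram
— a signal-pattern phenogram, not a phylogeny estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .errors import MeasurementError
from .fixtures import KaryotypeFixture
from .measurements import MeasurementTable
from .signals import CATEGORIES, SignalSite, position_category

#: Default dissimilarity weights: differences in the number of 5S-bearing
#: pairs dominate, then arm-position composition, then heteromorphism.
DEFAULT_WEIGHTS = {"n_pairs": 1.0, "categories": 0.5, "heteromorphic": 0.25}


@dataclass(frozen=True)
class SignalProfile:
    """Species-level multiset summary of 5S rDNA FISH sites."""

    species_id: str
    n_pairs_5s: int
    category_counts: dict[str, int] = field(default_factory=dict)
    heteromorphic_pairs: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs_5s < 0 or self.heteromorphic_pairs < 0:
            raise MeasurementError("profile counts must be non-negative")
        unknown = set(self.category_counts) - set(CATEGORIES)
        if unknown:
            raise MeasurementError(f"unknown categories {sorted(unknown)}")
        if any(v < 0 for v in self.category_counts.values()):
            raise MeasurementError("negative category count")
        if sum(self.category_counts.values()) < self.n_pairs_5s:
            raise MeasurementError(
                "fewer 5S sites than 5S-bearing pairs: each bearing pair "
                "contributes at least one site"
            )

    def category_vector(self) -> np.ndarray:
        return np.array([self.category_counts.get(c, 0) for c in CATEGORIES],
                        dtype=float)


def profile_from_fixture(fixture: KaryotypeFixture) -> SignalProfile:
    """Encode a packaged fixture's 5S assignments as a profile.

    A both-homologs assignment contributes two sites, a one-homolog
    assignment one; a pair with differing homolog intensities counts as
    heteromorphic.
    """
    counts = dict.fromkeys(CATEGORIES, 0)
    by_pair: dict[int, set[str]] = {}
    for sig in fixture.signal_pairs:
        if sig.channel != "TAMRA":
            continue
        n_sites = 2 if sig.zygosity == "both-homologs" else 1
        counts[position_category(sig.position_fraction)] += n_sites
        by_pair.setdefault(sig.pair_index, set()).add(sig.intensity)
    hetero = sum(1 for kinds in by_pair.values() if len(kinds) > 1)
    return SignalProfile(
        species_id=fixture.species_id,
        n_pairs_5s=len(by_pair),
        category_counts={k: v for k, v in counts.items() if v},
        heteromorphic_pairs=hetero,
    )


def encode_signal_profile(
    table: MeasurementTable,
    sites: Sequence[SignalSite],
    species_id: str | None = None,
) -> SignalProfile:
    """Profile from measured chromosomes (with pair indices) and 5S sites.

    A homolog pair counts once however many of its homologs bear a site;
    pairs whose homologs differ in intensity class are heteromorphic.
    """
    pair_of = {r.chromosome_id: r.pair_index for r in table}
    if any(v is None for v in pair_of.values()):
        raise MeasurementError("pair indices missing: run pair_homologs first")
    counts = dict.fromkeys(CATEGORIES, 0)
    by_pair: dict[int, dict[str, set[str]]] = {}
    for site in sites:
        if site.channel != "TAMRA":
            continue
        if site.chromosome_id not in pair_of:
            raise MeasurementError(
                f"site references unknown chromosome {site.chromosome_id!r}"
            )
        counts[position_category(site.position_fraction)] += 1
        rec = by_pair.setdefault(pair_of[site.chromosome_id], {})
        rec.setdefault(site.chromosome_id, set()).add(site.intensity)
    hetero = 0
    for homologs in by_pair.values():
        kinds = [("weak" if "weak" in v else "strong") for v in homologs.values()]
        if len(set(kinds)) > 1:
            hetero += 1
    return SignalProfile(
        species_id=species_id or table.species_id,
        n_pairs_5s=len(by_pair),
        category_counts={k: v for k, v in counts.items() if v},
        heteromorphic_pairs=hetero,
    )


def profile_dissimilarity(
    p: SignalProfile,
    q: SignalProfile,
    weights: dict[str, float] | None = None,
) -> float:
    """Weighted L1 dissimilarity between two signal profiles.

    ``d = w_n |Δ n_pairs| + w_c Σ_cat |Δ sites| + w_h |Δ heteromorphic|`` —
    symmetric, zero iff the profiles agree on all counts, and a pseudometric
    (weighted L1 on the concatenated count vector).
    """
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    if any(v < 0 for v in w.values()):
        raise MeasurementError("dissimilarity weights must be non-negative")
    return float(
        w["n_pairs"] * abs(p.n_pairs_5s - q.n_pairs_5s)
        + w["categories"] * np.abs(p.category_vector() - q.category_vector()).sum()
        + w["heteromorphic"] * abs(p.heteromorphic_pairs - q.heteromorphic_pairs)
    )


def dissimilarity_matrix(
    profiles: Sequence[SignalProfile],
    weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    ids = [p.species_id for p in profiles]
    n = len(profiles)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = profile_dissimilarity(
                profiles[i], profiles[j], weights
            )
    return pd.DataFrame(mat, index=ids, columns=ids)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over species profiles."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray  # scipy (n-1, 4) linkage encoding

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def merges(self) -> list[tuple[frozenset, frozenset, float]]:
        """Each merge as (left leaf set, right leaf set, height)."""
        n = len(self.labels)
        clusters: dict[int, frozenset] = {
            i: frozenset([self.labels[i]]) for i in range(n)
        }
        out = []
        for k, (a, b, h, _size) in enumerate(self.linkage_matrix):
            left, right = clusters[int(a)], clusters[int(b)]
            out.append((left, right, float(h)))
            clusters[n + k] = left | right
        return out

    def join_order(self) -> list[frozenset]:
        """Cluster contents in merge order (roots last)."""
        return [left | right for left, right, _h in self.merges()]

    def newick(self) -> str:
        """Newick string with branch lengths from merge heights
        (ultrametric: child branch = parent height - child height)."""
        root = to_tree(self.linkage_matrix)

        def fmt(node, parent_height):
            blen = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{blen:.6g}"
            inner = ",".join(fmt(ch, node.dist) for ch in
                             (node.left, node.right))
            return f"({inner}):{blen:.6g}"

        inner = ",".join(fmt(ch, root.dist) for ch in (root.left, root.right))
        return f"({inner});"


def cluster_profiles(
    profiles: Sequence[SignalProfile],
    method: str = "average",
    weights: dict[str, float] | None = None,
) -> Dendrogram:
    """Agglomerative clustering of signal profiles.

    ``method`` is ``"average"`` (UPGMA) or ``"single"``.  Ties are broken
    deterministically by the input species order.
    """
    if len(profiles) < 2:
        raise MeasurementError("clustering needs at least 2 profiles")
    if method not in ("average", "single"):
        raise MeasurementError(f"unsupported linkage {method!r}")
    dm = dissimilarity_matrix(profiles, weights)
    condensed = squareform(dm.values, checks=False)
    z = linkage(condensed, method=method)
    return Dendrogram(labels=tuple(dm.index), linkage_matrix=z)


def write_profiles_json(profiles: Iterable[SignalProfile],
                        path: str | Path) -> Path:
    path = Path(path)
    payload = [
        {
            "species_id": p.species_id,
            "n_pairs_5s": p.n_pairs_5s,
            "category_counts": p.category_counts,
            "heteromorphic_pairs": p.heteromorphic_pairs,
        }
        for p in profiles
    ]
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
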