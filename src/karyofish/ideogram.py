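"""Ideogram plotting: relative-length bar karyograms with centromere marks
and 5S site positions."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .errors import MeasurementError
from .karyotype import order_by_length, relative_lengths
from .measurements import MeasurementTable

# reproducible vector output
matplotlib.rcParams["svg.hashsalt"] = "karyofish"


def plot_ideogram(
    table: MeasurementTable,
    sites: Sequence | None = None,
    path: str | Path = "ideogram.svg",
    title: str | None = None,
) -> Path:
    """Draw a bar-style ideogram ordered longest to shortest.

    Each bar's height is the chromosome's relative length (% of the diploid
    complement); a horizontal mark shows the centromere (the long arm is
    drawn below it); 5S sites, when given, are drawn as dots at their
    fractional arm positions.  Output is deterministic for fixed input.
    """
    if len(table) == 0:
        raise MeasurementError("cannot plot an empty table")
    ordered = order_by_length(table)
    rel = relative_lengths(ordered)
    site_map: dict[str, list] = {}
    for s in sites or ():
        if s.channel == "TAMRA" and s.chromosome_id is not None:
            site_map.setdefault(s.chromosome_id, []).append(s)

    fig, ax = plt.subplots(figsize=(max(4.0, 0.32 * len(ordered)), 3.2))
    width = 0.62
    for x, (row, height) in enumerate(zip(ordered, rel)):
        ax.bar(x, height, width=width, color="#9db8d9", edgecolor="black",
               linewidth=0.6, zorder=2)
        cen_y = height * row.long_arm / row.total_length
        ax.plot([x - width / 2, x + width / 2], [cen_y, cen_y],
                color="black", linewidth=1.4, zorder=3)
        for s in site_map.get(row.chromosome_id, ()):
            if s.position_fraction is None:
                continue
            if s.arm == "long":
                y = cen_y - s.position_fraction * cen_y
            else:
                y = cen_y + s.position_fraction * (height - cen_y)
            ax.plot([x], [y], marker="o", color="#c23b3b",
                    markersize=4 if s.intensity == "strong" else 2.5, zorder=4)
    ax.set_xticks(range(len(ordered)))
    ax.set_xticklabels([r.chromosome_id for r in ordered],
                       rotation=90, fontsize=6)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("relative length (%)")
    ax.set_title(title or table.species_id)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, metadata={"Date": None} if path.suffix == ".svg" else None)
    plt.close(fig)
    return path
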