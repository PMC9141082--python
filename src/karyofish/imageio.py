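"""Metaphase image persistence: 16-bit TIFF stacks, PNG previews and
ground-truth sidecar JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .render import (
    CHANNEL_ORDER,
    ChromosomeTruth,
    GroundTruth,
    MetaphaseImage,
    TruthSite,
)


def save_image(image: MetaphaseImage, path: str | Path,
               preview: bool = True) -> Path:
    """Write a 3-page TIFF stack (DAPI, FAM, TAMRA), a ground-truth JSON
    sidecar when present, and an 8-bit RGB PNG preview."""
    path = Path(path)
    stack = np.stack([image.channels[ch] for ch in CHANNEL_ORDER])
    tifffile.imwrite(
        path, stack, photometric="minisblack",
        metadata={"axes": "CYX", "channels": ",".join(CHANNEL_ORDER),
                  "pixel_size_um": image.pixel_size_um},
    )
    if image.ground_truth is not None:
        truth_path = path.with_suffix(".truth.json")
        truth_path.write_text(json.dumps(_truth_to_dict(image.ground_truth),
                                         indent=1) + "\n")
    if preview:
        _write_preview(image, path.with_suffix(".png"))
    return path


def _write_preview(image: MetaphaseImage, path: Path) -> None:
    import imageio.v3 as iio

    def to8(ch):
        arr = image.channels[ch].astype(float)
        lo, hi = arr.min(), max(arr.max(), arr.min() + 1)
        return ((arr - lo) / (hi - lo) * 255).astype(np.uint8)

    rgb = np.stack([to8("TAMRA"), to8("FAM"), to8("DAPI")], axis=-1)
    iio.imwrite(path, rgb)


def load_image(path: str | Path) -> MetaphaseImage:
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    pixel_size = float(meta.get("pixel_size_um", 1.0))
    channels = {ch: stack[i] for i, ch in enumerate(CHANNEL_ORDER)}
    truth = None
    truth_path = path.with_suffix(".truth.json")
    if truth_path.exists():
        truth = _truth_from_dict(json.loads(truth_path.read_text()))
    return MetaphaseImage(channels=channels, pixel_size_um=pixel_size,
                          ground_truth=truth)


def _truth_to_dict(truth: GroundTruth) -> dict:
    return {
        "chromosomes": [
            {
                "chromosome_id": c.chromosome_id,
                "pair_index": c.pair_index,
                "total_um": c.total_um,
                "long_um": c.long_um,
                "short_um": c.short_um,
                "centromere_rc": list(c.centromere_rc),
                "centerline": np.round(c.centerline, 2).tolist(),
                "sites": [
                    {
                        "channel": s.channel, "arm": s.arm,
                        "position_fraction": s.position_fraction,
                        "intensity": s.intensity,
                        "row": round(s.row, 2), "col": round(s.col, 2),
                    }
                    for s in c.sites
                ],
            }
            for c in truth.chromosomes
        ]
    }


def _truth_from_dict(data: dict) -> GroundTruth:
    chroms = []
    for c in data.get("chromosomes", []):
        sites = tuple(
            TruthSite(
                chromosome_id=c["chromosome_id"],
                channel=s["channel"], arm=s["arm"],
                position_fraction=s["position_fraction"],
                intensity=s["intensity"], row=s["row"], col=s["col"],
            )
            for s in c.get("sites", [])
        )
        chroms.append(ChromosomeTruth(
            chromosome_id=c["chromosome_id"],
            pair_index=c.get("pair_index"),
            total_um=c["total_um"], long_um=c["long_um"],
            short_um=c["short_um"],
            centerline=np.asarray(c.get("centerline", []), dtype=float),
            centromere_rc=tuple(c.get("centromere_rc", (0.0, 0.0))),
            sites=sites,
        ))
    return GroundTruth(tuple(chroms))
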