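"""Synthetic three-channel metaphase spread rendering.

Chromosomes are drawn as smoothly bent capsules on a DAPI channel, with a
width minimum (primary constriction) at the centromere position implied by
the arm lengths and a tapered tip at each telomere.  The telomeric
oligonucleotide probe (FAM, green) puts one spot at each chromosome end;
locus-specific 5S rDNA probes (TAMRA, red) are placed at their assigned
fractional arm positions.  Every rendered object is recorded in a ground
truth structure so downstream measurement can be validated.

The model is deliberately simple optics: Gaussian spots, soft capsule
edges, constant background plus Gaussian read noise.  There is no
hybridization chemistry, no chromatid substructure and no satellites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import PlacementError
from .fixtures import SignalAssignment
from .measurements import MeasurementTable

CHANNEL_ORDER = ("DAPI", "FAM", "TAMRA")


@dataclass(frozen=True)
class RenderParams:
    """Rendering geometry and photometry (lengths in micrometres)."""

    pixel_size_um: float = 0.05
    width_um: float = 0.45              # chromosome body width
    constriction_depth: float = 0.55    # fractional width loss at centromere
    constriction_sigma_um: float = 0.12
    taper_um: float = 0.15              # telomeric taper length
    taper_floor: float = 0.12           # minimum width fraction at the tip
    spot_sigma_um: float = 0.08
    spot_amp: float = 20000.0
    weak_amp_fraction: float = 0.35     # weak spot amplitude / strong amplitude
    dapi_amp: float = 18000.0
    background: float = 800.0
    noise_sd: float = 60.0
    max_bend_deg: float = 35.0
    edge_soft_px: float = 1.0
    overlap: str = "forbid"             # "forbid" | "allow"
    canvas: tuple[int, int] | None = None  # auto-sized if None
    cell_margin_px: int = 12


@dataclass(frozen=True)
class TruthSite:
    """Ground truth for one rendered FISH spot."""

    chromosome_id: str
    channel: str
    arm: str
    position_fraction: float
    intensity: str
    row: float
    col: float


@dataclass(frozen=True)
class ChromosomeTruth:
    """Ground truth for one rendered chromosome."""

    chromosome_id: str
    pair_index: int | None
    total_um: float
    long_um: float
    short_um: float
    centerline: np.ndarray  # (n, 2) float pixel coordinates (row, col)
    centromere_rc: tuple[float, float]
    sites: tuple[TruthSite, ...]


@dataclass(frozen=True)
class GroundTruth:
    chromosomes: tuple[ChromosomeTruth, ...] = ()

    def sites(self, channel: str | None = None) -> list[TruthSite]:
        out = [s for c in self.chromosomes for s in c.sites]
        if channel is not None:
            out = [s for s in out if s.channel == channel]
        return out


@dataclass(frozen=True)
class MetaphaseImage:
    """Three registered 16-bit channels with pixel size and optional truth."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    ground_truth: GroundTruth | None = None

    def __post_init__(self) -> None:
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channel shapes differ: {shapes}")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


def _arc_points(length_px: float, bend_rad: float, step: float = 0.25) -> np.ndarray:
    """Centerline samples of an arc of given length and total turning angle,
    centred on its bounding box, as (n, 2) xy coordinates."""
    n = max(int(round(length_px / step)) + 1, 8)
    s = np.linspace(0.0, length_px, n)
    if abs(bend_rad) < 1e-3:
        pts = np.stack([s, np.zeros_like(s)], axis=1)
    else:
        radius = length_px / bend_rad
        ang = s / radius
        pts = np.stack([radius * np.sin(ang), radius * (1 - np.cos(ang))], axis=1)
    pts -= (pts.min(axis=0) + pts.max(axis=0)) / 2.0
    return pts


def _radii(s: np.ndarray, length: float, centromere_s: float,
           p: RenderParams) -> np.ndarray:
    px = p.pixel_size_um
    base = p.width_um / px / 2.0
    sigma = p.constriction_sigma_um / px
    constr = 1.0 - p.constriction_depth * np.exp(
        -((s - centromere_s) ** 2) / (2.0 * sigma ** 2)
    )
    taper = np.clip(np.minimum(s, length - s) / (p.taper_um / px),
                    p.taper_floor, 1.0)
    return np.maximum(base * constr * taper, 1.0)


def _stamp_body(canvas: np.ndarray, pts_rc: np.ndarray, radii: np.ndarray,
                amp: float, soft: float) -> None:
    rmax = radii.max() + soft + 1
    lo = np.maximum(np.floor(pts_rc.min(axis=0) - rmax).astype(int), 0)
    hi = np.minimum(np.ceil(pts_rc.max(axis=0) + rmax).astype(int) + 1,
                    canvas.shape)
    rr, cc = np.mgrid[lo[0]:hi[0], lo[1]:hi[1]]
    grid = np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)
    dist, idx = cKDTree(pts_rc).query(grid, workers=1)
    inten = amp * np.clip((radii[idx] - dist) / soft + 0.5, 0.0, 1.0)
    canvas[lo[0]:hi[0], lo[1]:hi[1]] += inten.reshape(rr.shape)


def _stamp_spot(canvas: np.ndarray, rc: tuple[float, float], amp: float,
                sigma_px: float) -> None:
    r0, c0 = rc
    w = int(math.ceil(4 * sigma_px)) + 1
    lo_r, hi_r = max(int(r0) - w, 0), min(int(r0) + w + 1, canvas.shape[0])
    lo_c, hi_c = max(int(c0) - w, 0), min(int(c0) + w + 1, canvas.shape[1])
    rr, cc = np.mgrid[lo_r:hi_r, lo_c:hi_c]
    canvas[lo_r:hi_r, lo_c:hi_c] += amp * np.exp(
        -((rr - r0) ** 2 + (cc - c0) ** 2) / (2.0 * sigma_px ** 2)
    )


def _point_at(s_query: float, s: np.ndarray, pts: np.ndarray) -> np.ndarray:
    return np.stack([np.interp(s_query, s, pts[:, 0]),
                     np.interp(s_query, s, pts[:, 1])])


def render_metaphase_image(
    table: MeasurementTable,
    signals: Sequence[SignalAssignment] = (),
    seed: int = 0,
    params: RenderParams | None = None,
) -> MetaphaseImage:
    """Render a metaphase spread for a measurement table.

    Homolog pairs come from the table's ``pair_index``; signal assignments
    reference those pairs.  With ``overlap="forbid"`` each chromosome is
    confined to its own grid cell (with random orientation, bend and
    jitter), so footprints are pairwise disjoint by construction; a canvas
    explicitly too small for that raises :class:`PlacementError`.
    """
    p = params or RenderParams()
    rng = np.random.default_rng(seed)
    px = p.pixel_size_um

    n = len(table)
    if n == 0:
        shape = p.canvas or (512, 512)
        channels = {
            ch: _finalize(np.zeros(shape), p, rng) for ch in CHANNEL_ORDER
        }
        return MetaphaseImage(channels=channels, pixel_size_um=px,
                              ground_truth=GroundTruth())

    unit_scale = px if table.length_unit == "px" else 1.0
    lengths_px = np.array([r.total_length * unit_scale / px for r in table])
    max_len = lengths_px.max()
    cell_min = int(math.ceil(max_len)) + 2 * p.cell_margin_px

    if p.canvas is None:
        ncols = max(int(math.ceil(math.sqrt(n))), 1)
        nrows = int(math.ceil(n / ncols))
        cell = cell_min
        shape = (nrows * cell, ncols * cell)
    else:
        shape = p.canvas
        ncols = max(int(shape[1] // cell_min), 1)
        nrows = int(math.ceil(n / ncols))
        cell = min(shape[0] // nrows, shape[1] // ncols)
        if p.overlap == "forbid" and cell < cell_min:
            raise PlacementError(
                f"canvas {shape} cannot hold {n} chromosomes of up to "
                f"{max_len:.0f} px without overlap"
            )

    dapi = np.zeros(shape)
    fam = np.zeros(shape)
    tamra = np.zeros(shape)
    spot_sigma_px = p.spot_sigma_um / px

    # map pair_index -> TAMRA assignments; one-homolog assignments are dealt
    # to successive homologs of the pair in listed order
    per_pair: dict[int, list[SignalAssignment]] = {}
    for sig in signals:
        per_pair.setdefault(sig.pair_index, []).append(sig)
    homolog_rank: dict[int, int] = {}

    cell_order = rng.permutation(nrows * ncols)[:n]
    truths: list[ChromosomeTruth] = []

    for k, meas in enumerate(table):
        L = lengths_px[k]
        short_px = meas.short_arm * unit_scale / px
        bend = math.radians(rng.uniform(-p.max_bend_deg, p.max_bend_deg))
        phi = rng.uniform(0.0, 2.0 * math.pi)
        jit = rng.uniform(-1.0, 1.0, size=2)

        pts = _arc_points(L, bend)
        rot = np.array([[math.cos(phi), -math.sin(phi)],
                        [math.sin(phi), math.cos(phi)]])
        pts = pts @ rot.T
        extent = pts.max(axis=0) - pts.min(axis=0)

        if p.overlap == "forbid":
            ci = int(cell_order[k])
            centre = np.array([(ci // ncols + 0.5) * cell,
                               (ci % ncols + 0.5) * cell])
            slack = np.maximum((cell - extent) / 2.0 - p.cell_margin_px / 2.0, 0.0)
            centre = centre + jit * slack
        else:
            half = extent / 2.0 + 2.0
            centre = np.array([
                rng.uniform(half[0], shape[0] - half[0]),
                rng.uniform(half[1], shape[1] - half[1]),
            ])
        pts_rc = pts - (pts.min(axis=0) + pts.max(axis=0)) / 2.0 + centre

        s = np.linspace(0.0, L, len(pts_rc))
        radii = _radii(s, L, short_px, p)
        # inset the stamped centerline by the tip radius so the rounded end
        # caps extend exactly to the nominal chromosome length
        inset = min(float(radii[0]), L / 4), min(float(radii[-1]), L / 4)
        keep = (s >= inset[0]) & (s <= L - inset[1])
        _stamp_body(dapi, pts_rc[keep], radii[keep], p.dapi_amp, p.edge_soft_px)

        sites: list[TruthSite] = []
        # telomeric FAM spots: one per chromosome end
        for s_end, arm in ((min(1.5, L / 4), "short"), (L - min(1.5, L / 4), "long")):
            rc = _point_at(s_end, s, pts_rc)
            _stamp_spot(fam, (rc[0], rc[1]), p.spot_amp, spot_sigma_px)
            sites.append(TruthSite(meas.chromosome_id, "FAM", arm, 1.0,
                                   "strong", rc[0], rc[1]))

        # locus-specific assignments for this chromosome's pair
        if meas.pair_index is not None and meas.pair_index in per_pair:
            rank = homolog_rank.get(meas.pair_index, 0)
            homolog_rank[meas.pair_index] = rank + 1
            singles_seen = 0
            for sig in per_pair[meas.pair_index]:
                if sig.zygosity == "one-homolog":
                    if singles_seen != rank:
                        singles_seen += 1
                        continue
                    singles_seen += 1
                frac = sig.position_fraction
                if sig.arm == "short":
                    s_pos = short_px * (1.0 - frac)
                else:
                    s_pos = short_px + frac * (L - short_px)
                s_pos = float(np.clip(s_pos, 1.0, L - 1.0))
                rc = _point_at(s_pos, s, pts_rc)
                amp = p.spot_amp * (p.weak_amp_fraction
                                    if sig.intensity == "weak" else 1.0)
                target = tamra if sig.channel == "TAMRA" else fam
                _stamp_spot(target, (rc[0], rc[1]), amp, spot_sigma_px)
                sites.append(TruthSite(meas.chromosome_id, sig.channel,
                                       sig.arm, frac, sig.intensity,
                                       rc[0], rc[1]))

        cen_rc = _point_at(short_px, s, pts_rc)
        truths.append(ChromosomeTruth(
            chromosome_id=meas.chromosome_id,
            pair_index=meas.pair_index,
            total_um=meas.total_length * unit_scale,
            long_um=meas.long_arm * unit_scale,
            short_um=meas.short_arm * unit_scale,
            centerline=pts_rc,
            centromere_rc=(float(cen_rc[0]), float(cen_rc[1])),
            sites=tuple(sites),
        ))

    channels = {
        "DAPI": _finalize(dapi, p, rng),
        "FAM": _finalize(fam, p, rng),
        "TAMRA": _finalize(tamra, p, rng),
    }
    return MetaphaseImage(channels=channels, pixel_size_um=px,
                          ground_truth=GroundTruth(tuple(truths)))


def _finalize(canvas: np.ndarray, p: RenderParams,
              rng: np.random.Generator) -> np.ndarray:
    noisy = canvas + p.background + rng.normal(0.0, p.noise_sd, canvas.shape)
    return np.clip(np.round(noisy), 0, 65535).astype(np.uint16)
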