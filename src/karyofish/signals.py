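"""FISH spot detection and arm-position mapping.

Spots are local intensity structures above a robust per-channel threshold
(median + k * MAD after background subtraction and light smoothing).  Each
spot is assigned to the chromosome mask containing its centroid, or to the
nearest mask within a small radius; anything further away is reported in
the ``unassigned`` list rather than silently dropped.  A spot is classed
``weak`` when its summed intensity falls below ``weak_fraction`` times the
median spot intensity of its channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ChannelMissingError, MeasurementError
from .measure import centromere_arc_position, _arc_length, _smooth_path
from .measurements import ChromosomeMeasurement
from .render import MetaphaseImage
from .segmentation import ChromosomeMask

#: Position-category thresholds on the centromere->telomere arm fraction.
CATEGORY_BOUNDS = (
    (0.15, "centromeric"),
    (0.70, "interstitial"),
    (0.90, "proximal-telomeric"),
)
CATEGORIES = ("centromeric", "interstitial", "proximal-telomeric", "telomeric")


@dataclass(frozen=True)
class SpotParams:
    k_sigma: float = 6.0           # detection threshold in robust SDs
    smooth_sigma: float = 1.0
    min_area: int = 3              # pixels above threshold
    weak_fraction: float = 0.5     # weak iff raw < weak_fraction * median
    assign_radius_px: float = 8.0
    channels: tuple[str, ...] = ("FAM", "TAMRA")


@dataclass(frozen=True)
class SignalSite:
    """One detected (or encoded) FISH spot on a chromosome."""

    chromosome_id: str | None
    channel: str
    arm: str | None
    position_fraction: float | None
    intensity: str
    raw_intensity: float
    row: float
    col: float


@dataclass(frozen=True)
class DetectedSignals:
    sites: tuple[SignalSite, ...]
    unassigned: tuple[SignalSite, ...] = ()

    def on_channel(self, channel: str) -> list[SignalSite]:
        return [s for s in self.sites if s.channel == channel]

    def bearing_chromosomes(self, channel: str) -> set[str]:
        return {s.chromosome_id for s in self.on_channel(channel)}


def position_category(fraction: float) -> str:
    """Map a centromere->telomere arm fraction onto the verbal position
    vocabulary: centromeric <= 0.15 < interstitial <= 0.70 <
    proximal-telomeric < 0.90 <= telomeric."""
    if not 0.0 <= fraction <= 1.0:
        raise MeasurementError(f"position fraction {fraction} outside [0, 1]")
    for bound, cat in CATEGORY_BOUNDS:
        if fraction < bound or (cat == "centromeric" and fraction <= bound):
            return cat
    return "telomeric"


def locate_signal_on_arm(site: SignalSite,
                         measurement: ChromosomeMeasurement) -> str:
    """Position category of a site on its measured chromosome."""
    if (
        site.chromosome_id is not None
        and site.chromosome_id != measurement.chromosome_id
    ):
        raise MeasurementError(
            f"site on {site.chromosome_id} does not belong to "
            f"{measurement.chromosome_id}"
        )
    if site.position_fraction is None:
        raise MeasurementError("site has no arm position")
    return position_category(site.position_fraction)


def _project_on_mask(mask: ChromosomeMask, row: float, col: float,
                     pixel_size: float) -> tuple[str, float]:
    """Arm label and centromere->telomere fraction of a point on a mask."""
    path, _radius = mask.skeleton
    path = _smooth_path(path)
    s = _arc_length(path)
    d2 = (path[:, 0] - row) ** 2 + (path[:, 1] - col) ** 2
    idx = int(np.argmin(d2))
    s_c, total, r0, _flags = centromere_arc_position(mask)
    s_pos = float(s[idx]) + r0
    arm_a = s_c
    arm_b = total - s_c
    if s_pos <= s_c:
        frac = (s_c - s_pos) / arm_a if arm_a > 0 else 0.0
        arm = "short" if arm_a <= arm_b else "long"
    else:
        frac = (s_pos - s_c) / arm_b if arm_b > 0 else 0.0
        arm = "short" if arm_b < arm_a else "long"
    return arm, float(np.clip(frac, 0.0, 1.0))


def detect_signals(
    image: MetaphaseImage,
    masks: list[ChromosomeMask],
    params: SpotParams | None = None,
) -> DetectedSignals:
    """Detect FISH spots on the requested channels and map them onto masks."""
    params = params or SpotParams()
    sites: list[SignalSite] = []
    unassigned: list[SignalSite] = []

    for channel in params.channels:
        if channel not in image.channels:
            raise ChannelMissingError(channel)
        data = image.channels[channel].astype(float)
        bg = float(np.median(data))
        sm = ndimage.gaussian_filter(data - bg, params.smooth_sigma)
        mad = float(np.median(np.abs(sm - np.median(sm)))) * 1.4826
        thr = params.k_sigma * max(mad, 1e-6)
        bw = sm > thr
        labels, n_lab = ndimage.label(bw)
        if n_lab == 0:
            continue
        raw_spots: list[tuple[float, float, float]] = []
        for k in range(1, n_lab + 1):
            region = labels == k
            if region.sum() < params.min_area:
                continue
            rr, cc = np.nonzero(region)
            weights = sm[rr, cc]
            r0 = float(np.average(rr, weights=weights))
            c0 = float(np.average(cc, weights=weights))
            raw = float((data[rr, cc] - bg).sum())
            raw_spots.append((r0, c0, raw))
        if not raw_spots:
            continue
        med = float(np.median([sp[2] for sp in raw_spots]))
        for r0, c0, raw in raw_spots:
            intensity = "weak" if raw < params.weak_fraction * med else "strong"
            owner = _owner_mask(masks, r0, c0, params.assign_radius_px)
            if owner is None:
                unassigned.append(SignalSite(None, channel, None, None,
                                             intensity, raw, r0, c0))
                continue
            arm, frac = _project_on_mask(owner, r0, c0, image.pixel_size_um)
            sites.append(SignalSite(
                chromosome_id=f"chr{owner.label:02d}",
                channel=channel,
                arm=arm,
                position_fraction=frac,
                intensity=intensity,
                raw_intensity=raw,
                row=r0,
                col=c0,
            ))
    return DetectedSignals(tuple(sites), tuple(unassigned))


def _owner_mask(masks: list[ChromosomeMask], row: float, col: float,
                radius: float) -> ChromosomeMask | None:
    for mask in masks:
        if mask.contains(row, col):
            return mask
    best, best_d = None, radius
    for mask in masks:
        b = mask.bbox
        if (row < b[0] - radius or row > b[2] + radius
                or col < b[1] - radius or col > b[3] + radius):
            continue
        rr, cc = np.nonzero(mask.local_mask)
        d = np.sqrt(((rr + b[0]) - row) ** 2 + ((cc + b[1]) - col) ** 2).min()
        if d <= best_d:
            best, best_d = mask, float(d)
    return best
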