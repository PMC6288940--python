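"""Automated read-depth arbitration, boundary refinement and validation.

This replaces per-call visual inspection of read depth with explicit,
configurable rules.  The diploid baseline for a call is the median window
depth over 50 kb flanks on each side (windows overlapping other same-sample
calls are masked out so CNV-dense neighbourhoods do not bias the baseline).

* state assignment: region mean / flank median <= 0.70 -> loss,
  >= 1.30 -> gain, otherwise the call is an invalid (false-positive) call.
  Expected ratios are 0.5 per lost copy and 1.5 for a single extra copy;
  the defaults sit slightly inside the midpoints to favour precision.
* boundary refinement: scanning from the flank toward the event, the new
  boundary is the left (right) edge of the first window where depth
  crosses ``cross_fraction x flank median`` in the state's direction and
  stays crossed for ``sustain_windows`` windows; a candidate crossing must
  also keep its mean depth across the next ``lookahead_windows`` windows on
  the crossed side, which suppresses chance noise runs in long flanks.
* validation: every carrier of a region must reproduce its claimed state on
  its own track; two non-carrier reference samples must sit in the normal
  depth band.  Regions with no surviving carrier are discarded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core_io import COMPLEX, GAIN, LOSS, DepthTrack, GenomicInterval

logger = logging.getLogger(__name__)

INVALID = "invalid"


@dataclass
class ArbitrationConfig:
    flank_bp: int = 50_000
    loss_max_ratio: float = 0.70
    gain_min_ratio: float = 1.30
    normal_band: Tuple[float, float] = (0.80, 1.25)
    sustain_windows: int = 3
    lookahead_windows: int = 10
    loss_cross_fraction: float = 0.75
    gain_cross_fraction: float = 1.25
    min_flank_windows: int = 10

    def __post_init__(self) -> None:
        if not (0.0 < self.loss_max_ratio < 1.0 < self.gain_min_ratio):
            raise ValueError("need 0 < loss_max_ratio < 1 < gain_min_ratio")
        lo, hi = self.normal_band
        if not (0.0 < lo < 1.0 < hi):
            raise ValueError("normal_band bounds must satisfy 0 < low < 1 < high")


class FlankUnavailable(RuntimeError):
    """Too few usable flank windows: the call cannot be arbitrated."""


def _mask_windows(mask: np.ndarray, track: DepthTrack, chrom: str, start: int, end: int) -> None:
    """Clear mask for windows overlapping [start, end)."""
    w = track.window_size
    n = len(mask)
    i0 = max(0, start // w)
    i1 = min(n, math.ceil(end / w))
    if i1 > i0:
        mask[i0:i1] = False


def _flank_values(
    track: DepthTrack,
    region: GenomicInterval,
    cfg: ArbitrationConfig,
    exclude: Sequence[GenomicInterval] = (),
) -> np.ndarray:
    w = track.window_size
    chrom = region.chrom
    arr = track.depths[chrom]
    n = len(arr)
    mask = np.zeros(n, dtype=bool)
    # windows fully inside each flank span (truncated at chromosome ends)
    for lo, hi in (
        (max(0, region.start - cfg.flank_bp), region.start),
        (region.end, min(track.chrom_length(chrom), region.end + cfg.flank_bp)),
    ):
        i0 = max(0, math.ceil(lo / w))
        i1 = min(n, hi // w)
        if i1 > i0:
            mask[i0:i1] = True
    # never count windows touching the region itself or other calls
    _mask_windows(mask, track, chrom, region.start, region.end)
    for iv in exclude:
        if iv.chrom == chrom:
            _mask_windows(mask, track, chrom, iv.start, iv.end)
    return arr[mask]


def flank_median(
    track: DepthTrack,
    region: GenomicInterval,
    cfg: ArbitrationConfig,
    exclude: Sequence[GenomicInterval] = (),
) -> float:
    """Median window depth over the two flanks, masking other calls.

    Raises :class:`FlankUnavailable` when fewer than
    ``cfg.min_flank_windows`` usable windows remain.
    """
    vals = _flank_values(track, region, cfg, exclude)
    if len(vals) < cfg.min_flank_windows:
        raise FlankUnavailable(
            f"{region}: only {len(vals)} usable flank windows "
            f"(need >= {cfg.min_flank_windows})"
        )
    return float(np.median(vals))


def region_ratio(
    track: DepthTrack,
    region: GenomicInterval,
    cfg: ArbitrationConfig,
    exclude: Sequence[GenomicInterval] = (),
) -> Optional[float]:
    """Mean in-region depth over flank median; None when the flank is zero."""
    fm = flank_median(track, region, cfg, exclude)
    if fm == 0:
        return None
    return track.region_mean(region) / fm


def assign_state(
    track: DepthTrack,
    region: GenomicInterval,
    cfg: ArbitrationConfig,
    exclude: Sequence[GenomicInterval] = (),
) -> str:
    """Loss/gain/invalid from the region-to-flank depth ratio."""
    ratio = region_ratio(track, region, cfg, exclude)
    if ratio is None:
        logger.info("assign_state: %s flank median is 0, call invalid", region)
        return INVALID
    if ratio <= cfg.loss_max_ratio:
        return LOSS
    if ratio >= cfg.gain_min_ratio:
        return GAIN
    return INVALID


def _first_crossing(
    arr: np.ndarray,
    crossed: np.ndarray,
    lo: int,
    hi: int,
    level: float,
    is_loss: bool,
    cfg: ArbitrationConfig,
    from_left: bool,
) -> Optional[int]:
    """First window index (scanning outward-in) with a sustained crossing.

    ``from_left`` scans lo..hi-1 ascending and returns the run start;
    otherwise scans descending and returns the run end (inclusive index).
    The crossing must also pass the lookahead-mean check toward the event.
    """
    s = cfg.sustain_windows
    la = max(cfg.lookahead_windows, s)
    idx = range(lo, hi - s + 1) if from_left else range(hi - 1, lo + s - 2, -1)
    for c in idx:
        if from_left:
            run = crossed[c:c + s]
        else:
            run = crossed[c - s + 1:c + 1]
        if len(run) < s or not run.all():
            continue
        if from_left:
            look = arr[c:min(c + la, hi)]
        else:
            look = arr[max(c - la + 1, lo):c + 1]
        m = look.mean()
        if (is_loss and m < level) or (not is_loss and m > level):
            return c
    return None


def refine_boundaries(
    track: DepthTrack,
    region: GenomicInterval,
    state: str,
    cfg: ArbitrationConfig,
    exclude: Sequence[GenomicInterval] = (),
) -> Tuple[GenomicInterval, bool]:
    """Move boundaries to the initial sustained depth crossing on each side.

    Returns ``(interval, refined)``; on any failure (no sustained crossing,
    unusable flank, or a refined interval that no longer reproduces the
    claimed state) the original interval is returned with ``refined=False``.
    """
    if state not in (LOSS, GAIN):
        raise ValueError(f"refine_boundaries needs a loss/gain state, got {state!r}")
    try:
        fm = flank_median(track, region, cfg, exclude)
    except FlankUnavailable:
        logger.info("refine_boundaries: %s flank unavailable, keeping boundaries", region)
        return region, False
    if fm == 0:
        return region, False

    is_loss = state == LOSS
    level = (cfg.loss_cross_fraction if is_loss else cfg.gain_cross_fraction) * fm
    w = track.window_size
    chrom = region.chrom
    arr = track.depths[chrom]
    n = len(arr)
    crossed = arr < level if is_loss else arr > level

    # scan spans never reach into other same-sample calls: their depth is
    # displaced too and would fake a crossing
    lo_bp = max(0, region.start - cfg.flank_bp)
    hi_bp = min(track.chrom_length(chrom), region.end + cfg.flank_bp)
    for iv in exclude:
        if iv.chrom != chrom:
            continue
        if iv.end <= region.start:
            lo_bp = max(lo_bp, iv.end)
        if iv.start >= region.end:
            hi_bp = min(hi_bp, iv.start)

    mid_w = min(max(((region.start + region.end) // 2) // w, region.start // w + 1), n)
    lo = max(0, math.ceil(lo_bp / w))
    hi = min(n, hi_bp // w)

    c_start = _first_crossing(arr, crossed, lo, mid_w, level, is_loss, cfg, from_left=True)
    c_end = _first_crossing(arr, crossed, mid_w, hi, level, is_loss, cfg, from_left=False)
    if c_start is None or c_end is None or c_end < c_start:
        logger.info("refine_boundaries: %s no sustained crossing, keeping boundaries", region)
        return region, False

    new_start = c_start * w
    new_end = min((c_end + 1) * w, track.chrom_length(chrom))
    if new_end <= new_start:
        return region, False
    refined = GenomicInterval(chrom, new_start, new_end)
    if assign_state(track, refined, cfg, exclude) != state:
        logger.info(
            "refine_boundaries: refined %s -> %s fails state check, keeping boundaries",
            region, refined,
        )
        return region, False
    return refined, True


@dataclass
class RegionValidation:
    """Outcome of comparing a region's carriers with normal-state references."""

    carrier_pass: Dict[Tuple[str, str], bool] = field(default_factory=dict)
    reference_ratios: Dict[str, float] = field(default_factory=dict)
    references_normal: bool = True
    unvalidatable: bool = False
    verdict: bool = False


def validate_region(
    carriers: Sequence[Tuple[DepthTrack, str]],
    references: Sequence[DepthTrack],
    region: GenomicInterval,
    cfg: ArbitrationConfig,
    exclude_map: Optional[Mapping[str, Sequence[GenomicInterval]]] = None,
) -> RegionValidation:
    """Depth-validate a region against >=2 non-carrier reference samples.

    Each (track, claimed_state) carrier passes iff :func:`assign_state`
    reproduces its claimed state; each reference must sit in the normal
    band.  Verdict is true iff at least one carrier passes and all
    references are normal.  With fewer than two references the region is
    flagged unvalidatable and retained.
    """
    exclude_map = exclude_map or {}
    res = RegionValidation()
    for track, claimed in carriers:
        try:
            got = assign_state(track, region, cfg, exclude_map.get(track.sample, ()))
        except FlankUnavailable:
            got = INVALID
        res.carrier_pass[(track.sample, claimed)] = got == claimed

    if len(references) < 2:
        logger.warning("validate_region: %s has <2 reference samples, unvalidatable", region)
        res.unvalidatable = True
        res.verdict = any(res.carrier_pass.values())
        return res

    lo, hi = cfg.normal_band
    for ref in references:
        try:
            ratio = region_ratio(ref, region, cfg, exclude_map.get(ref.sample, ()))
        except FlankUnavailable:
            ratio = None
        res.reference_ratios[ref.sample] = math.nan if ratio is None else ratio
        if ratio is None or not (lo <= ratio <= hi):
            res.references_normal = False
    res.verdict = res.references_normal and any(res.carrier_pass.values())
    return res
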