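"""Caller-specific filtering and the two-caller >=80%-overlap consensus.

Caller A (cn.MOPS-style) keeps losses with median expected log fold change
strictly below -1 and gains strictly above 0.6.  Caller B (CNVnator-style)
keeps calls of size >= 1 kb with q0 < 0.5 and p < 0.001 (strict).  A
caller-A call becomes a consensus CNV when same-sample caller-B calls cover
at least ``min_overlap_fraction`` (default 0.8) of its span; coverage is
the union of all overlapping B calls, so the consensus is invariant to how
caller B fragments an event (one caller routinely splits a single event
into ~10 pieces).  When any supporting B call disagrees on loss/gain the
consensus is routed to read-depth arbitration with its state unresolved.
"""

from __future__ import annotations

import logging
import statistics
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set

from .core_io import (
    AGREED,
    ARBITRATED,
    CALLER_A,
    CALLER_B,
    GAIN,
    LOSS,
    CnvCall,
    ConsensusCnv,
    ContractError,
)

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds for caller filters and the consensus overlap rule."""

    a_loss_max_lfc: float = -1.0
    a_gain_min_lfc: float = 0.6
    b_min_size: int = 1000
    b_max_q0: float = 0.5
    b_max_p: float = 0.001
    min_overlap_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.min_overlap_fraction <= 1.0):
            raise ValueError("min_overlap_fraction must be in (0, 1]")
        if self.b_min_size < 1:
            raise ValueError("b_min_size must be >= 1")


def _require_caller(calls: Iterable[CnvCall], caller: str) -> None:
    for c in calls:
        if c.caller != caller:
            raise ContractError(f"expected caller {caller} calls, found caller {c.caller}")


def filter_caller_a(calls: Sequence[CnvCall], cfg: FilterConfig) -> List[CnvCall]:
    """Keep losses with median_lfc < a_loss_max_lfc and gains > a_gain_min_lfc.

    Both inequalities are strict: a loss at exactly -1 or a gain at exactly
    0.6 is dropped.
    """
    _require_caller(calls, CALLER_A)
    return [
        c for c in calls
        if (c.state == LOSS and c.median_lfc < cfg.a_loss_max_lfc)
        or (c.state == GAIN and c.median_lfc > cfg.a_gain_min_lfc)
    ]


def filter_caller_b(calls: Sequence[CnvCall], cfg: FilterConfig) -> List[CnvCall]:
    """Keep calls with length >= b_min_size (inclusive), q0 < b_max_q0 and
    p_val < b_max_p (both strict)."""
    _require_caller(calls, CALLER_B)
    return [
        c for c in calls
        if c.interval.length >= cfg.b_min_size
        and c.q0 < cfg.b_max_q0
        and c.p_val < cfg.b_max_p
    ]


def _union_coverage(a_start: int, a_end: int, spans: List) -> int:
    """Bases of [a_start, a_end) covered by the union of the given spans."""
    clipped = sorted(
        (max(s, a_start), min(e, a_end)) for s, e in spans if min(e, a_end) > max(s, a_start)
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def find_consensus(
    calls_a: Sequence[CnvCall],
    calls_b: Sequence[CnvCall],
    cfg: FilterConfig,
) -> List[ConsensusCnv]:
    """Emit one consensus CNV per sufficiently B-supported caller-A call.

    support_fraction = |union of same-sample B calls ∩ A| / length(A);
    the consensus interval is the caller-A interval.  State is A's state
    when every overlapping B call agrees, otherwise unresolved
    (``state_source='arbitrated'``).
    """
    _require_caller(calls_a, CALLER_A)
    _require_caller(calls_b, CALLER_B)
    for b in calls_b:
        if b.interval.length < cfg.b_min_size:
            raise ContractError(
                f"caller-B input looks unfiltered: call of length {b.interval.length} "
                f"< b_min_size {cfg.b_min_size}"
            )

    b_index: Dict = defaultdict(list)
    for b in calls_b:
        b_index[(b.sample, b.interval.chrom)].append(b)
    for key in b_index:
        b_index[key].sort(key=lambda c: (c.interval.start, c.interval.end))

    out: List[ConsensusCnv] = []
    for a in sorted(calls_a, key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.sample)):
        iv = a.interval
        overlapping = [
            b for b in b_index.get((a.sample, iv.chrom), [])
            if b.interval.start < iv.end and b.interval.end > iv.start
        ]
        covered = _union_coverage(iv.start, iv.end, [(b.interval.start, b.interval.end) for b in overlapping])
        support = covered / iv.length
        if support < cfg.min_overlap_fraction:
            continue
        states = {b.state for b in overlapping}
        if states == {a.state}:
            out.append(ConsensusCnv(iv, a.sample, a.state, AGREED, support))
        else:
            out.append(ConsensusCnv(iv, a.sample, None, ARBITRATED, support))
    return out


def flag_sample_outliers(call_counts: Mapping[str, int], k: float = 10.0) -> Set[str]:
    """Samples whose raw call count exceeds median + k * MAD.

    Formalizes outlier exclusion by call-count inspection (a sample with
    ~25x the typical count is flagged).  With fewer than 4 samples the rule
    is unstable: a warning is logged and nothing is flagged.
    """
    if len(call_counts) < 4:
        logger.warning("flag_sample_outliers: fewer than 4 samples, flagging nothing")
        return set()
    counts = list(call_counts.values())
    med = statistics.median(counts)
    mad = statistics.median(abs(c - med) for c in counts)
    threshold = med + k * mad
    flagged = {s for s, c in call_counts.items() if c > threshold}
    if flagged:
        logger.info(
            "flag_sample_outliers: flagged %s (median=%s, MAD=%s, k=%s)",
            sorted(flagged), med, mad, k,
        )
    return flagged
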