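"""CNVR construction: cross-sample merging, classification, statistics,
gene annotation and the breed-private report.

Consensus CNVs from all samples are merged transitively on each chromosome;
overlapping or bookended (gap 0) intervals join one region, matching the
default behaviour of ``bedtools merge``.  A region is *loss* or *gain* when
all member states agree, *complex* otherwise, and a *singleton* when
exactly one distinct sample contributes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd
from intervaltree import IntervalTree

from .core_io import (
    COMPLEX,
    GAIN,
    LOSS,
    Cnvr,
    ConsensusCnv,
    GeneRecord,
    GenomicInterval,
    SampleMetadata,
    ValidationError,
)

#: size-class boundaries in bp: <20 kb, 20-50, 50-100, 100-500, >=500 kb
DEFAULT_SIZE_BOUNDS: Tuple[int, ...] = (20_000, 50_000, 100_000, 500_000)
SIZE_CLASS_LABELS: Tuple[str, ...] = ("<20kb", "20-50kb", "50-100kb", "100-500kb", ">=500kb")


def classify_states(states: Sequence[str]) -> str:
    uniq = set(states)
    if uniq == {LOSS}:
        return LOSS
    if uniq == {GAIN}:
        return GAIN
    return COMPLEX


def merge_to_cnvrs(calls: Sequence[ConsensusCnv]) -> List[Cnvr]:
    """Merge validated consensus CNVs across samples into CNVRs.

    Transitive merge of overlapping/bookended intervals per chromosome;
    deterministic (output sorted by chrom, start) and order-invariant in
    the input.
    """
    for c in calls:
        if c.state not in (LOSS, GAIN):
            raise ValidationError(f"call {c.interval} ({c.sample}) has unresolved state")
    out: List[Cnvr] = []
    by_chrom: Dict[str, List[ConsensusCnv]] = {}
    for c in calls:
        by_chrom.setdefault(c.interval.chrom, []).append(c)
    for chrom in sorted(by_chrom):
        chunk = sorted(by_chrom[chrom], key=lambda c: (c.interval.start, c.interval.end, c.sample))
        cur: List[ConsensusCnv] = []
        cur_end = None
        for c in chunk:
            if cur_end is None or c.interval.start <= cur_end:  # overlap or bookended
                cur.append(c)
                cur_end = max(cur_end or c.interval.end, c.interval.end)
            else:
                out.append(_finish_region(chrom, cur))
                cur, cur_end = [c], c.interval.end
        if cur:
            out.append(_finish_region(chrom, cur))
    return out


def _finish_region(chrom: str, members: List[ConsensusCnv]) -> Cnvr:
    start = min(c.interval.start for c in members)
    end = max(c.interval.end for c in members)
    pairs = frozenset((c.sample, c.state) for c in members)
    state = classify_states([c.state for c in members])
    singleton = len({c.sample for c in members}) == 1
    return Cnvr(GenomicInterval(chrom, start, end), state, pairs, singleton)


def assign_calls_to_cnvrs(
    calls: Sequence[ConsensusCnv], cnvrs: Sequence[Cnvr]
) -> Dict[int, List[ConsensusCnv]]:
    """Map cnvr index -> member calls (each call lies in exactly one CNVR)."""
    trees: Dict[str, IntervalTree] = {}
    for i, r in enumerate(cnvrs):
        trees.setdefault(r.interval.chrom, IntervalTree()).addi(
            r.interval.start, r.interval.end, i
        )
    out: Dict[int, List[ConsensusCnv]] = {i: [] for i in range(len(cnvrs))}
    for c in calls:
        hits = trees.get(c.interval.chrom, IntervalTree()).overlap(
            c.interval.start, c.interval.end
        )
        if len(hits) != 1:
            raise ValidationError(
                f"call {c.interval} maps to {len(hits)} CNVRs (expected exactly 1)"
            )
        out[next(iter(hits)).data].append(c)
    return out


@dataclass
class CnvrStats:
    n_cnvrs: int
    n_loss: int
    n_gain: int
    n_complex: int
    n_singletons: int
    genome_fraction: float
    per_chromosome: Dict[str, Tuple[int, float]] = field(default_factory=dict)
    size_class_counts: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_cnvrs": self.n_cnvrs,
            "n_loss": self.n_loss,
            "n_gain": self.n_gain,
            "n_complex": self.n_complex,
            "n_singletons": self.n_singletons,
            "genome_fraction": self.genome_fraction,
            "per_chromosome": {c: list(v) for c, v in self.per_chromosome.items()},
            "size_class_counts": dict(self.size_class_counts),
        }


def size_class(length: int, bounds: Sequence[int] = DEFAULT_SIZE_BOUNDS) -> str:
    for b, label in zip(bounds, SIZE_CLASS_LABELS):
        if length < b:
            return label
    return SIZE_CLASS_LABELS[len(bounds)]


def compute_stats(
    cnvrs: Sequence[Cnvr],
    chrom_lengths: Mapping[str, int],
    size_bounds: Sequence[int] = DEFAULT_SIZE_BOUNDS,
) -> CnvrStats:
    """Summary statistics: counts per state, singleton count, genome
    fraction covered, per-chromosome coverage and size-class counts."""
    missing = sorted({r.interval.chrom for r in cnvrs} - set(chrom_lengths))
    if missing:
        raise ValidationError(f"CNVR chromosome(s) not in length table: {', '.join(missing)}")
    genome = sum(chrom_lengths.values())
    by_state = {LOSS: 0, GAIN: 0, COMPLEX: 0}
    per_chrom_bp: Dict[str, int] = {c: 0 for c in chrom_lengths}
    per_chrom_n: Dict[str, int] = {c: 0 for c in chrom_lengths}
    class_counts = {label: 0 for label in SIZE_CLASS_LABELS[: len(size_bounds) + 1]}
    total_bp = 0
    for r in cnvrs:
        by_state[r.state] += 1
        total_bp += r.interval.length
        per_chrom_bp[r.interval.chrom] += r.interval.length
        per_chrom_n[r.interval.chrom] += 1
        class_counts[size_class(r.interval.length, size_bounds)] += 1
    per_chromosome = {
        c: (per_chrom_n[c], per_chrom_bp[c] / chrom_lengths[c]) for c in chrom_lengths
    }
    return CnvrStats(
        n_cnvrs=len(cnvrs),
        n_loss=by_state[LOSS],
        n_gain=by_state[GAIN],
        n_complex=by_state[COMPLEX],
        n_singletons=sum(1 for r in cnvrs if r.singleton),
        genome_fraction=total_bp / genome if genome else 0.0,
        per_chromosome=per_chromosome,
        size_class_counts=class_counts,
    )


def annotate_genes(
    cnvrs: Sequence[Cnvr], genes: Sequence[GeneRecord]
) -> Dict[Cnvr, List[str]]:
    """Assign each gene overlapping a CNVR by >=1 bp (bookending excluded)."""
    trees: Dict[str, IntervalTree] = {}
    for g in genes:
        trees.setdefault(g.interval.chrom, IntervalTree()).addi(
            g.interval.start, g.interval.end, g
        )
    out: Dict[Cnvr, List[str]] = {}
    for r in cnvrs:
        hits = trees.get(r.interval.chrom, IntervalTree()).overlap(
            r.interval.start, r.interval.end
        )
        found = sorted({h.data for h in hits}, key=lambda g: (g.interval.start, g.gene_name))
        out[r] = [g.gene_name for g in found]
    return out


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def breed_private_report(
    cnvrs: Sequence[Cnvr],
    metadata: Sequence[SampleMetadata],
    gene_map: Optional[Mapping[Cnvr, List[str]]] = None,
) -> pd.DataFrame:
    """CNVRs whose >=2 member samples all belong to one breed.

    The percentage column is ``round(100 * n_members / breed size)`` with
    half-up rounding over the post-exclusion breed sizes (2 of 3 -> 67,
    5 of 6 -> 83, 2 of 2 -> 100).
    """
    breed_of = {m.sample: m.breed for m in metadata}
    breed_sizes: Dict[str, int] = {}
    for m in metadata:
        breed_sizes[m.breed] = breed_sizes.get(m.breed, 0) + 1

    rows = []
    for r in cnvrs:
        samples = sorted(r.samples)
        missing = [s for s in samples if s not in breed_of]
        if missing:
            raise ValidationError(f"samples missing from metadata: {', '.join(missing)}")
        if len(samples) < 2:
            continue
        breeds = {breed_of[s] for s in samples}
        if len(breeds) != 1:
            continue
        breed = next(iter(breeds))
        n = len(samples)
        rows.append(
            {
                "chrom": r.interval.chrom,
                "start": r.interval.start,
                "end": r.interval.end,
                "length": r.interval.length,
                "breed": breed,
                "n_members": n,
                "pct_of_breed": _round_half_up(100.0 * n / breed_sizes[breed]),
                "state": r.state,
                "genes": ",".join(gene_map.get(r, [])) if gene_map else "",
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "length", "breed",
            "n_members", "pct_of_breed", "state", "genes",
        ],
    )
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
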