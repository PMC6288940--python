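"""Domain types, interval arithmetic and file I/O for the CNV→CNVR pipeline.

Coordinate convention
---------------------
Every interval in this package is half-open ``[start, end)`` on a named
chromosome, so ``length == end - start``.  Published breed-private CNVR
coordinates satisfy this identity exactly (printed length equals
``end - start`` for every region), so printed ``(start, end)`` pairs are
usable directly under this rule.  BED input/output is native (0-based,
half-open); GFF3 (1-based, closed) is converted on read.

File dialects
-------------
Two minimal tab-separated caller dialects carry exactly the fields the
downstream filters use:

* caller A (cn.MOPS-style): ``chrom start end sample state median_lfc``
* caller B (CNVnator-style): ``chrom start end sample state q0 p_val``

Windowed read depth arrives as bedGraph and is re-binned to fixed,
0-anchored windows; the final partial window of a chromosome keeps its
true (shorter) base span for averaging.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

LOSS = "loss"
GAIN = "gain"
COMPLEX = "complex"
STATES = (LOSS, GAIN)

CALLER_A = "A"
CALLER_B = "B"

#: chromosome labels treated as sex chromosomes (excluded from autosomal
#: statistics by default; the analysis is autosomal)
SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y", "chrM", "MT"})


class FormatError(ValueError):
    """A file could not be parsed (malformed row, bad header, ...)."""


class ValidationError(ValueError):
    """A record violates a domain invariant (coordinates, bounds, ...)."""


class ContractError(ValueError):
    """An operation received input that violates its precondition."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic span ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValidationError(f"end must exceed start: {self}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlap_length(self, other) > 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 if disjoint/other chrom).

    Half-open semantics: bookended intervals (``a.end == b.start``) share
    nothing.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class CnvCall:
    """One raw call from one caller for one sample.

    Caller A calls carry ``median_lfc`` (median of the expected log fold
    change) and nothing else; caller B calls carry ``q0`` (fraction of
    zero-mapping-quality reads) and ``p_val``.
    """

    interval: GenomicInterval
    sample: str
    caller: str
    state: str
    median_lfc: Optional[float] = None
    q0: Optional[float] = None
    p_val: Optional[float] = None

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValidationError(f"state must be loss/gain, got {self.state!r}")
        if self.caller == CALLER_A:
            if self.median_lfc is None or self.q0 is not None or self.p_val is not None:
                raise ValidationError("caller-A calls carry median_lfc only")
        elif self.caller == CALLER_B:
            if self.median_lfc is not None or self.q0 is None or self.p_val is None:
                raise ValidationError("caller-B calls carry q0 and p_val only")
            if not (0.0 <= self.q0 <= 1.0):
                raise ValidationError(f"q0 outside [0,1]: {self.q0}")
            if not (0.0 <= self.p_val <= 1.0):
                raise ValidationError(f"p_val outside [0,1]: {self.p_val}")
        else:
            raise ValidationError(f"caller must be A or B, got {self.caller!r}")


AGREED = "agreed"
ARBITRATED = "arbitrated"


@dataclass(frozen=True)
class ConsensusCnv:
    """A caller-A call confirmed by >=80% same-sample caller-B coverage.

    ``state`` is None while ``state_source == 'arbitrated'`` and the
    read-depth arbitration has not yet resolved the caller disagreement.
    """

    interval: GenomicInterval
    sample: str
    state: Optional[str]
    state_source: str
    support_fraction: float
    validated: bool = False

    def __post_init__(self) -> None:
        if self.state_source not in (AGREED, ARBITRATED):
            raise ValidationError(f"bad state_source {self.state_source!r}")
        if self.state_source == AGREED and self.state not in STATES:
            raise ValidationError("agreed consensus must carry a loss/gain state")
        if self.state is not None and self.state not in STATES:
            raise ValidationError(f"bad state {self.state!r}")
        if not (0.0 <= self.support_fraction <= 1.0):
            raise ValidationError(f"support_fraction outside [0,1]: {self.support_fraction}")


@dataclass(frozen=True)
class Cnvr:
    """A cross-sample merged CNV region.

    ``members`` is the set of (sample, state) contributions; the region is
    ``complex`` when both losses and gains contribute, and a singleton when
    exactly one distinct sample contributes.
    """

    interval: GenomicInterval
    state: str
    members: frozenset  # of (sample, state) tuples
    singleton: bool

    @property
    def samples(self) -> frozenset:
        return frozenset(s for s, _ in self.members)


@dataclass(frozen=True)
class SampleMetadata:
    sample: str
    breed: str
    group: str


@dataclass(frozen=True)
class GeneRecord:
    interval: GenomicInterval
    gene_id: str
    gene_name: str


@dataclass
class DepthTrack:
    """Per-sample windowed mean read depth, 0-anchored fixed windows.

    ``depths[chrom]`` has ``ceil(chrom_length / window_size)`` entries; the
    last window may span fewer bases (its mean is over its true span).
    """

    sample: str
    window_size: int
    depths: Dict[str, np.ndarray]
    chrom_lengths: Optional[Dict[str, int]] = None

    def n_windows(self, chrom: str) -> int:
        return len(self.depths[chrom])

    def chrom_length(self, chrom: str) -> int:
        if self.chrom_lengths and chrom in self.chrom_lengths:
            return self.chrom_lengths[chrom]
        return self.n_windows(chrom) * self.window_size

    def window_range(self, region: GenomicInterval, inner: bool = False) -> Tuple[int, int]:
        """Window index range ``[i0, i1)`` for a region.

        ``inner=False``: windows overlapping the region;
        ``inner=True``: windows fully contained in it.
        """
        w = self.window_size
        n = self.n_windows(region.chrom)
        if inner:
            i0 = math.ceil(region.start / w)
            i1 = region.end // w
        else:
            i0 = region.start // w
            i1 = math.ceil(region.end / w)
        return max(0, min(i0, n)), max(0, min(i1, n))

    def region_values(self, region: GenomicInterval, inner: bool = False) -> np.ndarray:
        i0, i1 = self.window_range(region, inner=inner)
        if i1 <= i0 and inner:  # region smaller than one window: fall back
            i0, i1 = self.window_range(region, inner=False)
        return self.depths[region.chrom][i0:i1]

    def region_mean(self, region: GenomicInterval, inner: bool = True) -> float:
        vals = self.region_values(region, inner=inner)
        if len(vals) == 0:
            raise ValidationError(f"region {region} covers no windows")
        return float(vals.mean())


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _check_chroms(chroms: Iterable[str], chrom_lengths: Optional[Mapping[str, int]], what: str) -> None:
    if chrom_lengths is None:
        return
    offenders = sorted({c for c in chroms if c not in chrom_lengths})
    if offenders:
        raise ValidationError(f"{what}: unknown chromosome(s) {', '.join(offenders)}")


def _read_tsv_rows(path, expected_header: Sequence[str]):
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file (header expected)") from None
        if [h.strip() for h in header] != list(expected_header):
            raise FormatError(
                f"{path}: bad header {header!r}, expected {list(expected_header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(expected_header):
                raise FormatError(
                    f"{path}: line {lineno}: expected {len(expected_header)} fields, got {len(row)}"
                )
            yield lineno, row


CALLER_A_HEADER = ("chrom", "start", "end", "sample", "state", "median_lfc")
CALLER_B_HEADER = ("chrom", "start", "end", "sample", "state", "q0", "p_val")


def _parse_interval(path, lineno: int, chrom: str, start: str, end: str) -> GenomicInterval:
    try:
        iv = GenomicInterval(chrom, int(start), int(end))
    except (ValueError, ValidationError) as exc:
        raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return iv


def read_caller_a(path, chrom_lengths: Optional[Mapping[str, int]] = None) -> List[CnvCall]:
    """Read the caller-A (cn.MOPS-style) TSV dialect."""
    calls: List[CnvCall] = []
    for lineno, row in _read_tsv_rows(path, CALLER_A_HEADER):
        iv = _parse_interval(path, lineno, row[0], row[1], row[2])
        try:
            calls.append(
                CnvCall(iv, row[3], CALLER_A, row[4].strip().lower(), median_lfc=float(row[5]))
            )
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
    _check_chroms((c.interval.chrom for c in calls), chrom_lengths, str(path))
    return calls


def read_caller_b(path, chrom_lengths: Optional[Mapping[str, int]] = None) -> List[CnvCall]:
    """Read the caller-B (CNVnator-style) TSV dialect."""
    calls: List[CnvCall] = []
    for lineno, row in _read_tsv_rows(path, CALLER_B_HEADER):
        iv = _parse_interval(path, lineno, row[0], row[1], row[2])
        try:
            calls.append(
                CnvCall(
                    iv, row[3], CALLER_B, row[4].strip().lower(),
                    q0=float(row[5]), p_val=float(row[6]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
    _check_chroms((c.interval.chrom for c in calls), chrom_lengths, str(path))
    return calls


def write_caller_a(calls: Sequence[CnvCall], path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t", lineterminator="\n")
        wr.writerow(CALLER_A_HEADER)
        for c in calls:
            wr.writerow(
                [c.interval.chrom, c.interval.start, c.interval.end, c.sample, c.state,
                 repr(c.median_lfc)]
            )


def write_caller_b(calls: Sequence[CnvCall], path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t", lineterminator="\n")
        wr.writerow(CALLER_B_HEADER)
        for c in calls:
            wr.writerow(
                [c.interval.chrom, c.interval.start, c.interval.end, c.sample, c.state,
                 repr(c.q0), repr(c.p_val)]
            )


CONSENSUS_HEADER = (
    "chrom", "start", "end", "sample", "state", "state_source", "support_fraction", "validated"
)


def write_consensus(calls: Sequence[ConsensusCnv], path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t", lineterminator="\n")
        wr.writerow(CONSENSUS_HEADER)
        for c in calls:
            wr.writerow(
                [c.interval.chrom, c.interval.start, c.interval.end, c.sample,
                 c.state if c.state is not None else ".",
                 c.state_source, repr(c.support_fraction), int(c.validated)]
            )


def read_consensus(path) -> List[ConsensusCnv]:
    out: List[ConsensusCnv] = []
    for lineno, row in _read_tsv_rows(path, CONSENSUS_HEADER):
        iv = _parse_interval(path, lineno, row[0], row[1], row[2])
        state = None if row[4] == "." else row[4]
        try:
            out.append(
                ConsensusCnv(iv, row[3], state, row[5], float(row[6]), bool(int(row[7])))
            )
        except (ValueError, ValidationError) as exc:
            raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return out


def read_chrom_lengths(path, exclude_sex: bool = False) -> Dict[str, int]:
    """Two-column TSV ``chrom<TAB>length``; insertion order is chromosome order."""
    lengths: Dict[str, int] = {}
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}: line {lineno}: expected chrom<TAB>length")
            try:
                n = int(row[1])
            except ValueError:
                raise FormatError(f"{path}: line {lineno}: bad length {row[1]!r}") from None
            if n <= 0:
                raise FormatError(f"{path}: line {lineno}: non-positive length")
            if exclude_sex and row[0] in SEX_CHROMS:
                continue
            lengths[row[0]] = n
    return lengths


def write_chrom_lengths(lengths: Mapping[str, int], path) -> None:
    with open(path, "w", newline="") as fh:
        for chrom, n in lengths.items():
            fh.write(f"{chrom}\t{n}\n")


METADATA_HEADER = ("sample", "breed", "group")


def read_metadata(path) -> List[SampleMetadata]:
    out = []
    seen = set()
    for lineno, row in _read_tsv_rows(path, METADATA_HEADER):
        if row[0] in seen:
            raise ValidationError(f"{path}: line {lineno}: duplicate sample {row[0]!r}")
        seen.add(row[0])
        out.append(SampleMetadata(row[0], row[1], row[2]))
    return out


def write_metadata(meta: Sequence[SampleMetadata], path) -> None:
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh, delimiter="\t", lineterminator="\n")
        wr.writerow(METADATA_HEADER)
        for m in meta:
            wr.writerow([m.sample, m.breed, m.group])


# --- genes -----------------------------------------------------------------


def _parse_gff3_attrs(text: str) -> Dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_genes(path, chrom_lengths: Optional[Mapping[str, int]] = None) -> List[GeneRecord]:
    """Read gene records from BED (native) or GFF3 (converted to half-open)."""
    path = Path(path)
    genes: List[GeneRecord] = []
    if path.suffix.lower() in (".gff", ".gff3", ".gtf"):
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                cols = line.split("\t")
                if len(cols) < 9:
                    raise FormatError(f"{path}: line {lineno}: expected 9 GFF3 columns")
                if cols[2].lower() != "gene":
                    continue
                try:
                    # GFF3 is 1-based closed; convert to 0-based half-open.
                    iv = GenomicInterval(cols[0], int(cols[3]) - 1, int(cols[4]))
                except (ValueError, ValidationError) as exc:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from None
                attrs = _parse_gff3_attrs(cols[8])
                gid = attrs.get("ID", f"gene{len(genes) + 1}")
                genes.append(GeneRecord(iv, gid, attrs.get("Name", gid)))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t")
                if len(cols) < 3:
                    raise FormatError(f"{path}: line {lineno}: expected >=3 BED columns")
                try:
                    iv = GenomicInterval(cols[0], int(cols[1]), int(cols[2]))
                except (ValueError, ValidationError) as exc:
                    raise FormatError(f"{path}: line {lineno}: {exc}") from None
                name = cols[3] if len(cols) > 3 else f"gene{len(genes) + 1}"
                genes.append(GeneRecord(iv, name, name))
    _check_chroms((g.interval.chrom for g in genes), chrom_lengths, str(path))
    return genes


def write_genes_bed(genes: Sequence[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.interval.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.gene_name}\n")


def read_bed(path) -> List[GenomicInterval]:
    """Read plain intervals from a BED file (first three columns)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >=3 BED columns")
            try:
                out.append(GenomicInterval(cols[0], int(cols[1]), int(cols[2])))
            except (ValueError, ValidationError) as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
    return out


def sort_key(chrom_order: Sequence[str]):
    rank = {c: i for i, c in enumerate(chrom_order)}

    def key(iv: GenomicInterval):
        return (rank.get(iv.chrom, len(rank)), iv.chrom, iv.start, iv.end)

    return key


def write_bed(cnvrs: Sequence[Cnvr], path, chrom_order: Optional[Sequence[str]] = None) -> None:
    """Write CNVRs as BED4 (name = state[,singleton])."""
    order = chrom_order or sorted({c.interval.chrom for c in cnvrs})
    key = sort_key(order)
    with open(path, "w") as fh:
        for r in sorted(cnvrs, key=lambda r: key(r.interval)):
            name = r.state + (",singleton" if r.singleton else "")
            fh.write(f"{r.interval.chrom}\t{r.interval.start}\t{r.interval.end}\t{name}\n")


# --- depth tracks ----------------------------------------------------------


def read_depth_bedgraph(
    path,
    window_size: int = 100,
    chrom_lengths: Optional[Mapping[str, int]] = None,
    sample: Optional[str] = None,
) -> DepthTrack:
    """Re-bin a sorted, non-overlapping bedGraph to fixed windows.

    Gaps get depth 0.  Window means weight each covered base equally; the
    final partial window averages over its true span.
    """
    path = Path(path)
    if sample is None:
        sample = path.name.split(".")[0]
    chroms: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 bedGraph columns")
            try:
                s, e, v = int(cols[1]), int(cols[2]), float(cols[3])
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from None
            if e <= s or s < 0:
                raise FormatError(f"{path}: line {lineno}: bad interval {s}-{e}")
            chroms.setdefault(cols[0], []).append((s, e, v))
    _check_chroms(chroms, chrom_lengths, str(path))

    w = window_size
    depths: Dict[str, np.ndarray] = {}
    for chrom, rows in chroms.items():
        arr = np.asarray(rows, dtype=float)
        starts, ends, vals = arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2]
        if not (np.all(np.diff(starts) >= 0) and np.all(starts[1:] >= ends[:-1])):
            raise FormatError(f"{path}: {chrom}: bedGraph intervals overlap or are unsorted")
        if chrom_lengths is not None:
            length = chrom_lengths[chrom]
            if ends[-1] > length:
                raise ValidationError(f"{path}: {chrom}: interval beyond chromosome end")
        else:
            length = int(ends[-1])
        n_win = math.ceil(length / w)
        sums = np.zeros(n_win + 1)  # +1 slot guards the diff trick at the edge
        diff = np.zeros(n_win + 1)
        i0 = starts // w
        i1 = (ends - 1) // w
        same = i0 == i1
        # intervals confined to one window
        np.add.at(sums, i0[same], vals[same] * (ends[same] - starts[same]))
        # split intervals: partial head, partial tail, full middle windows
        sp = ~same
        if sp.any():
            np.add.at(sums, i0[sp], vals[sp] * ((i0[sp] + 1) * w - starts[sp]))
            np.add.at(sums, i1[sp], vals[sp] * (ends[sp] - i1[sp] * w))
            np.add.at(diff, i0[sp] + 1, vals[sp] * w)
            np.add.at(diff, i1[sp], -vals[sp] * w)
        sums += np.cumsum(diff)
        spans = np.full(n_win, float(w))
        if length % w:
            spans[-1] = length % w
        depths[chrom] = sums[:n_win] / spans

    if chrom_lengths is not None:
        for chrom, length in chrom_lengths.items():
            if chrom not in depths:
                depths[chrom] = np.zeros(math.ceil(length / w))
    lengths = dict(chrom_lengths) if chrom_lengths is not None else None
    return DepthTrack(sample=sample, window_size=w, depths=depths, chrom_lengths=lengths)


def write_bedgraph(track: DepthTrack, path) -> None:
    """Write a DepthTrack as bedGraph, merging runs of equal window values."""
    w = track.window_size
    with open(path, "w") as fh:
        for chrom in track.depths:
            vals = track.depths[chrom]
            length = track.chrom_length(chrom)
            if len(vals) == 0:
                continue
            change = np.flatnonzero(np.diff(vals)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(vals)]))
            for s, e in zip(starts, ends):
                bp_end = min(int(e) * w, length)
                fh.write(f"{chrom}\t{int(s) * w}\t{bp_end}\t{vals[s]:g}\n")
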