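"""Ground-truthed cohort simulator.

Emulates the inputs of a multi-breed, ~30x whole-genome CNV survey on a
small synthetic genome (default 5 chromosomes x 20 Mb):

* a breeds-within-geographic-groups cohort design (default 3 groups x
  4 breeds x 3 samples = 36 cats);
* planted non-overlapping CNV regions with group-structured carrier
  frequencies (each region has a "home" group where it is common and a low
  background frequency elsewhere), log-uniform lengths over 5-530 kb and a
  loss:gain mix of 0.84 (both matching the observed CNVR size range and
  state mix of the study design this emulates);
* per-sample windowed read depth ~ NegativeBinomial with mean
  ``mean_depth * copy_number / 2`` (gamma-Poisson mixture; overdispersion
  configurable);
* two caller outputs: caller A emits one call per detected event with
  jittered boundaries and a median log-fold-change statistic; caller B
  splits each event into ~``caller_b_fragmentation`` contiguous fragments
  (>=85% coverage) with per-fragment q0 and p-values.  Both emit false
  calls; a fraction of caller-B events carries a wrong loss/gain label
  (feeding the arbitration path), and a fraction of the false events is
  emitted by both callers (shared artifacts that only depth validation can
  remove).

Caller quality statistics are drawn with a deliberate selection-effect
shift away from the filter boundary: a caller reports a call when its
internal evidence is strong, so the reported statistic for a true event is
biased beyond the naive ``log2(cn/2)``.  Without this, a heterozygous
deletion (``log2(1/2) = -1``) would sit exactly on the strict ``< -1``
filter and half of all true het-deletion calls would be rejected, which is
not how these filters behave on real calls.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .core_io import (
    CALLER_A,
    CALLER_B,
    GAIN,
    LOSS,
    CnvCall,
    DepthTrack,
    GeneRecord,
    GenomicInterval,
    SampleMetadata,
    write_bedgraph,
    write_caller_a,
    write_caller_b,
    write_chrom_lengths,
    write_genes_bed,
    write_metadata,
)


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_groups: int = 3
    breeds_per_group: int = 4
    samples_per_breed: int = 3
    n_true_cnvrs: int = 150
    cnvr_length_range: Tuple[int, int] = (5_000, 530_000)  # log-uniform
    loss_fraction: float = 0.84
    home_freq_beta: Tuple[float, float] = (2.0, 2.0)
    away_freq_beta: Tuple[float, float] = (1.0, 12.0)
    mean_depth: float = 30.0
    nb_dispersion: float = 50.0  # gamma shape; var = mu + mu^2/k
    window_size: int = 100
    n_chroms: int = 5
    chrom_length: int = 20_000_000
    min_gap: int = 25_000
    hom_loss_fraction: float = 0.2  # carriers with copy number 0 (vs 1)
    multi_gain_fraction: float = 0.2  # carriers with copy number 4 (vs 3)
    a_detect_rate: float = 0.97
    b_detect_rate: float = 0.98
    caller_boundary_jitter_windows: int = 2
    a_lfc_shift: float = 0.35
    a_lfc_noise_sd: float = 0.2
    caller_b_fragmentation: float = 10.0
    b_fragment_fail_rate: float = 0.04
    b_max_gap_fraction: float = 0.10
    wrong_state_fraction: float = 0.10
    caller_fp_rate: float = 0.3  # false events per Mb per sample
    fp_shared_fraction: float = 0.5  # false events emitted by both callers
    n_genes: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_groups", "breeds_per_group", "samples_per_breed", "window_size",
                     "n_chroms", "chrom_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("loss_fraction", "wrong_state_fraction", "fp_shared_fraction",
                     "a_detect_rate", "b_detect_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1]")
        if self.n_true_cnvrs < 0:
            raise ValueError("n_true_cnvrs must be >= 0")

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {f"chrS{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass(frozen=True)
class TrueCnvr:
    interval: GenomicInterval
    state: str
    carriers: Mapping[str, int]  # sample -> copy number (never 2)


@dataclass
class TruthSet:
    events: List[TrueCnvr]

    def calls_for(self, sample: str) -> List[TrueCnvr]:
        return [e for e in self.events if sample in e.carriers]

    def to_json(self) -> str:
        payload = [
            {
                "chrom": e.interval.chrom,
                "start": e.interval.start,
                "end": e.interval.end,
                "state": e.state,
                "carriers": dict(sorted(e.carriers.items())),
            }
            for e in self.events
        ]
        return json.dumps(payload, indent=1, sort_keys=True)


def _rngs(seed: int, n: int) -> List[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# cohort and truth
# ---------------------------------------------------------------------------


def simulate_cohort(cfg: SimConfig) -> Tuple[TruthSet, List[SampleMetadata]]:
    """Plant non-overlapping CNVRs with group-structured carriers.

    Deterministic under ``cfg.seed``; every planted region has at least one
    carrier (redrawn otherwise), so the truth set contains only events that
    are present in the cohort.
    """
    rng = _rngs(cfg.seed, 4)[0]
    metadata: List[SampleMetadata] = []
    groups = [f"group{g + 1}" for g in range(cfg.n_groups)]
    for g, group in enumerate(groups):
        for b in range(cfg.breeds_per_group):
            breed = f"BR{g + 1}{chr(ord('A') + b)}"
            for i in range(cfg.samples_per_breed):
                metadata.append(SampleMetadata(f"{breed}_{i + 1}", breed, group))
    group_of = {m.sample: m.group for m in metadata}
    samples = [m.sample for m in metadata]

    chrom_lengths = cfg.chrom_lengths
    chroms = list(chrom_lengths)
    placed: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    events: List[TrueCnvr] = []
    lo, hi = cfg.cnvr_length_range
    total_len = sum(chrom_lengths.values())
    probs = np.array([chrom_lengths[c] / total_len for c in chroms])

    for _ in range(cfg.n_true_cnvrs):
        length = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        for attempt in range(1000):
            chrom = chroms[int(rng.choice(len(chroms), p=probs))]
            L = chrom_lengths[chrom]
            if L - length - 2 * cfg.min_gap <= 0:
                continue
            start = int(rng.integers(cfg.min_gap, L - length - cfg.min_gap))
            end = start + length
            ok = all(
                end + cfg.min_gap <= s or start >= e + cfg.min_gap
                for s, e in placed[chrom]
            )
            if ok:
                placed[chrom].append((start, end))
                break
        else:
            raise RuntimeError(
                "could not place all requested CNVRs without overlap; "
                "use a longer genome or fewer/shorter regions"
            )
        state = LOSS if rng.random() < cfg.loss_fraction else GAIN
        home = groups[int(rng.integers(len(groups)))]
        freq = {
            g: float(rng.beta(*(cfg.home_freq_beta if g == home else cfg.away_freq_beta)))
            for g in groups
        }
        carriers: Dict[str, int] = {}
        for attempt in range(100):
            carriers = {}
            for s in samples:
                if rng.random() < freq[group_of[s]]:
                    if state == LOSS:
                        cn = 0 if rng.random() < cfg.hom_loss_fraction else 1
                    else:
                        cn = 4 if rng.random() < cfg.multi_gain_fraction else 3
                    carriers[s] = cn
            if carriers:
                break
        if not carriers:  # pathological frequencies: force one home carrier
            home_samples = [s for s in samples if group_of[s] == home]
            s = home_samples[int(rng.integers(len(home_samples)))]
            carriers = {s: 1 if state == LOSS else 3}
        events.append(TrueCnvr(GenomicInterval(chrom, start, end), state, carriers))

    events.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    return TruthSet(events), metadata


def simulate_genes(cfg: SimConfig) -> List[GeneRecord]:
    """Uniformly placed synthetic gene annotation (1-50 kb spans)."""
    rng = _rngs(cfg.seed, 4)[3]
    chrom_lengths = cfg.chrom_lengths
    chroms = list(chrom_lengths)
    genes = []
    for i in range(cfg.n_genes):
        chrom = chroms[int(rng.integers(len(chroms)))]
        length = int(rng.integers(1_000, 50_000))
        start = int(rng.integers(0, chrom_lengths[chrom] - length))
        name = f"GENE{i + 1:04d}"
        genes.append(GeneRecord(GenomicInterval(chrom, start, start + length), name, name))
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return genes


# ---------------------------------------------------------------------------
# depth
# ---------------------------------------------------------------------------


def copy_number_windows(truth: TruthSet, cfg: SimConfig, sample: str) -> Dict[str, np.ndarray]:
    """Per-window copy number for one sample (2 outside planted events)."""
    w = cfg.window_size
    out = {
        chrom: np.full(math.ceil(L / w), 2, dtype=np.int8)
        for chrom, L in cfg.chrom_lengths.items()
    }
    for e in truth.events:
        cn = e.carriers.get(sample)
        if cn is None:
            continue
        i0 = e.interval.start // w
        i1 = math.ceil(e.interval.end / w)
        out[e.interval.chrom][i0:i1] = cn
    return out


def simulate_depth(
    truth: TruthSet, cfg: SimConfig, samples: Sequence[str]
) -> Dict[str, DepthTrack]:
    """Windowed depth per sample: NB(mean = mean_depth * cn/2, shape k)."""
    rng = _rngs(cfg.seed, 4)[1]
    k = cfg.nb_dispersion
    tracks: Dict[str, DepthTrack] = {}
    chrom_lengths = cfg.chrom_lengths
    for sample in samples:
        cn = copy_number_windows(truth, cfg, sample)
        depths: Dict[str, np.ndarray] = {}
        for chrom, cn_arr in cn.items():
            mu = cfg.mean_depth * cn_arr.astype(float) / 2.0
            if k > 0:
                lam = rng.gamma(shape=k, scale=mu / k)
            else:  # Poisson limit
                lam = mu
            depths[chrom] = rng.poisson(lam).astype(float)
        tracks[sample] = DepthTrack(
            sample=sample, window_size=cfg.window_size, depths=depths,
            chrom_lengths=dict(chrom_lengths),
        )
    return tracks


# ---------------------------------------------------------------------------
# caller emulation
# ---------------------------------------------------------------------------


def _false_events(cfg: SimConfig, truth: TruthSet, rng: np.random.Generator,
                  samples: Sequence[str]) -> Dict[str, List[Tuple[GenomicInterval, str, bool]]]:
    """Per-sample false events: (interval, state, shared-with-other-caller).

    Placed away from planted regions so a call at a true locus is
    unambiguously a true call.
    """
    chrom_lengths = cfg.chrom_lengths
    genome_mb = sum(chrom_lengths.values()) / 1e6
    truth_by_chrom: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chrom_lengths}
    for e in truth.events:
        truth_by_chrom[e.interval.chrom].append((e.interval.start, e.interval.end))
    chroms = list(chrom_lengths)
    out: Dict[str, List[Tuple[GenomicInterval, str, bool]]] = {}
    for sample in samples:
        events = []
        n_fp = rng.poisson(cfg.caller_fp_rate * genome_mb)
        for _ in range(n_fp):
            for attempt in range(200):
                chrom = chroms[int(rng.integers(len(chroms)))]
                length = int(round(math.exp(rng.uniform(math.log(2_000), math.log(50_000)))))
                L = chrom_lengths[chrom]
                if L <= length:
                    continue
                start = int(rng.integers(0, L - length))
                end = start + length
                if all(end + cfg.min_gap <= s or start >= e + cfg.min_gap
                       for s, e in truth_by_chrom[chrom]):
                    state = LOSS if rng.random() < cfg.loss_fraction else GAIN
                    shared = rng.random() < cfg.fp_shared_fraction
                    events.append((GenomicInterval(chrom, start, end), state, shared))
                    break
        out[sample] = events
    return out


def _jitter(iv: GenomicInterval, rng: np.random.Generator, cfg: SimConfig) -> GenomicInterval:
    j = cfg.caller_boundary_jitter_windows
    w = cfg.window_size
    L = cfg.chrom_lengths[iv.chrom]
    if j == 0:
        return iv
    start = iv.start + int(rng.integers(-j, j + 1)) * w
    end = iv.end + int(rng.integers(-j, j + 1)) * w
    start = max(0, min(start, L - w))
    end = max(start + w, min(end, L))
    return GenomicInterval(iv.chrom, start, end)


def _loss_lfc(cn: int, rng: np.random.Generator, cfg: SimConfig) -> float:
    base = math.log2(max(cn, 0.25) / 2.0)
    return base - cfg.a_lfc_shift + rng.normal(0.0, cfg.a_lfc_noise_sd)


def _gain_lfc(cn: int, rng: np.random.Generator, cfg: SimConfig) -> float:
    return math.log2(cn / 2.0) + cfg.a_lfc_shift + rng.normal(0.0, cfg.a_lfc_noise_sd)


@dataclass
class CallerOutputs:
    calls_a: List[CnvCall]
    calls_b: List[CnvCall]
    #: (sample, event index) pairs whose caller-B state label was flipped
    flipped: set = field(default_factory=set)


def simulate_callers(
    truth: TruthSet, cfg: SimConfig, samples: Sequence[str]
) -> CallerOutputs:
    """Emulate both caller outputs over the same cohort.

    A single routine keeps the two callers' views of each event consistent
    (shared false events, one flip decision per event/carrier)."""
    rng = _rngs(cfg.seed, 4)[2]
    fp = _false_events(cfg, truth, rng, samples)
    calls_a: List[CnvCall] = []
    calls_b: List[CnvCall] = []
    flipped = set()

    for ei, e in enumerate(truth.events):
        for sample in sorted(e.carriers):
            cn = e.carriers[sample]
            flip_b = rng.random() < cfg.wrong_state_fraction
            if flip_b:
                flipped.add((sample, ei))
            b_state = ({LOSS: GAIN, GAIN: LOSS}[e.state]) if flip_b else e.state
            if rng.random() < cfg.a_detect_rate:
                iv = _jitter(e.interval, rng, cfg)
                lfc = _loss_lfc(cn, rng, cfg) if e.state == LOSS else _gain_lfc(cn, rng, cfg)
                calls_a.append(CnvCall(iv, sample, CALLER_A, e.state, median_lfc=round(lfc, 4)))
            if rng.random() < cfg.b_detect_rate:
                calls_b.extend(
                    _fragment_event(e.interval, sample, b_state, rng, cfg)
                )

    for sample in samples:
        for iv, state, shared in fp[sample]:
            emit_a = shared or rng.random() < 0.5
            emit_b = shared or not emit_a
            if emit_a:
                lfc = _loss_lfc(1, rng, cfg) if state == LOSS else _gain_lfc(3, rng, cfg)
                calls_a.append(CnvCall(_jitter(iv, rng, cfg), sample, CALLER_A, state,
                                       median_lfc=round(lfc, 4)))
            if emit_b:
                calls_b.extend(_fragment_event(iv, sample, state, rng, cfg))

    key = lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.sample)
    calls_a.sort(key=key)
    calls_b.sort(key=key)
    return CallerOutputs(calls_a, calls_b, flipped)


def _fragment_event(
    iv: GenomicInterval, sample: str, state: str, rng: np.random.Generator, cfg: SimConfig
) -> List[CnvCall]:
    """Split an event into contiguous fragments covering >= ~90% of it.

    Fragment count ~ 1 + Poisson(mean - 1), capped so no fragment is
    shorter than ~1.5 kb (the emulated caller works at 100 bp windows and
    does not emit sub-kb pieces)."""
    mean = cfg.caller_b_fragmentation
    n_frag = 1 + rng.poisson(max(mean - 1.0, 0.0))
    n_frag = max(1, min(int(n_frag), iv.length // 1500))
    # random internal cut points -> contiguous chunks
    if n_frag > 1:
        cuts = np.sort(rng.choice(np.arange(1, iv.length // 100), size=n_frag - 1,
                                  replace=False)) * 100
        bounds = [0, *cuts.tolist(), iv.length]
    else:
        bounds = [0, iv.length]
    calls = []
    for i in range(n_frag):
        s, e = bounds[i], bounds[i + 1]
        span = e - s
        gap = int(span * rng.uniform(0.0, cfg.b_max_gap_fraction))
        if rng.random() < 0.5:
            s += gap
        else:
            e -= gap
        if e - s < 100:
            continue
        if rng.random() < cfg.b_fragment_fail_rate:
            # fragment the downstream filter should reject
            q0 = float(rng.uniform(0.5, 0.9))
            p_val = float(rng.uniform(0.001, 0.5))
        else:
            q0 = float(np.clip(rng.beta(1.5, 15.0), 0.0, 0.499))
            p_val = float(10 ** rng.uniform(-8, -3.5))
        calls.append(
            CnvCall(GenomicInterval(iv.chrom, iv.start + s, iv.start + e), sample,
                    CALLER_B, state, q0=round(q0, 4), p_val=p_val)
        )
    return calls


# ---------------------------------------------------------------------------
# whole-cohort convenience and disk output
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    cfg: SimConfig
    truth: TruthSet
    metadata: List[SampleMetadata]
    tracks: Dict[str, DepthTrack]
    calls_a: List[CnvCall]
    calls_b: List[CnvCall]
    flipped: set
    genes: List[GeneRecord]

    @property
    def samples(self) -> List[str]:
        return [m.sample for m in self.metadata]

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return self.cfg.chrom_lengths


def simulate_all(cfg: SimConfig) -> Cohort:
    truth, metadata = simulate_cohort(cfg)
    samples = [m.sample for m in metadata]
    tracks = simulate_depth(truth, cfg, samples)
    outputs = simulate_callers(truth, cfg, samples)
    genes = simulate_genes(cfg)
    return Cohort(cfg, truth, metadata, tracks, outputs.calls_a, outputs.calls_b,
                  outputs.flipped, genes)


def write_cohort(cohort: Cohort, outdir, write_depth: bool = True) -> None:
    """Write a simulated cohort in the pipeline's input file dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_chrom_lengths(cohort.chrom_lengths, outdir / "chroms.tsv")
    write_metadata(cohort.metadata, outdir / "samples.tsv")
    write_caller_a(cohort.calls_a, outdir / "caller_a.tsv")
    write_caller_b(cohort.calls_b, outdir / "caller_b.tsv")
    write_genes_bed(cohort.genes, outdir / "genes.bed")
    (outdir / "truth.json").write_text(cohort.truth.to_json())
    if write_depth:
        depth_dir = outdir / "depths"
        depth_dir.mkdir(exist_ok=True)
        for sample, track in cohort.tracks.items():
            write_bedgraph(track, depth_dir / f"{sample}.bedGraph")


# ---------------------------------------------------------------------------
# truth-based evaluation
# ---------------------------------------------------------------------------


def _reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    from .core_io import overlap_length

    ov = overlap_length(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


def evaluate_cnvrs(
    predicted, truth: TruthSet, min_reciprocal: float = 0.5
) -> Dict[str, float]:
    """Recall/precision of predicted CNVRs vs planted regions.

    A prediction recovers a true region when they overlap reciprocally by
    >= ``min_reciprocal`` and the states are compatible (a complex region
    is compatible with either single state)."""
    def compatible(pred_state: str, true_state: str) -> bool:
        return pred_state == true_state or pred_state == "complex"

    matched_truth = set()
    matched_pred = set()
    for pi, p in enumerate(predicted):
        for ti, t in enumerate(truth.events):
            if _reciprocal_overlap(p.interval, t.interval) >= min_reciprocal and compatible(
                p.state, t.state
            ):
                matched_truth.add(ti)
                matched_pred.add(pi)
    recall = len(matched_truth) / len(truth.events) if truth.events else 1.0
    precision = len(matched_pred) / len(predicted) if predicted else 1.0
    return {"recall": recall, "precision": precision,
            "n_predicted": len(predicted), "n_true": len(truth.events)}


def boundary_errors_windows(predicted, truth: TruthSet, window_size: int,
                            min_reciprocal: float = 0.5) -> List[float]:
    """|boundary error| in windows, both sides of every matched region."""
    errs: List[float] = []
    for p in predicted:
        best, best_ov = None, 0.0
        for t in truth.events:
            ov = _reciprocal_overlap(p.interval, t.interval)
            if ov > best_ov:
                best, best_ov = t, ov
        if best is None or best_ov < min_reciprocal:
            continue
        errs.append(abs(p.interval.start - best.interval.start) / window_size)
        errs.append(abs(p.interval.end - best.interval.end) / window_size)
    return errs


def is_true_call(interval: GenomicInterval, sample: str, truth: TruthSet,
                 min_fraction: float = 0.5) -> bool:
    """Does >= half of the call lie in a planted event carried by the sample?"""
    from .core_io import overlap_length

    for e in truth.events:
        if sample in e.carriers and overlap_length(interval, e.interval) >= min_fraction * interval.length:
            return True
    return False
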