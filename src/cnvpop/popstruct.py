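"""CNVR-based population structure: binary scoring matrix, UPGMA clustering
with multiscale-bootstrap AU/BP support, and PCA.

The scoring matrix encodes presence (1) / absence (0) of any CNV per sample
in each CNVR, restricted to CNVRs shared by at least two samples.  Samples
are clustered by UPGMA (size-weighted average linkage, deterministic
lexicographic tie-breaks) on 1 - Pearson correlation (default) or Jaccard
distance between sample columns.

Branch support follows the multiscale bootstrap: CNVR rows are resampled
with replacement at sizes n' = round(n * r) over a grid of scales r, the
tree is rebuilt per resample, and each original cluster's recovery
frequency BP_r is recorded.  Writing z_r = Phi^-1(1 - BP_r), the model
z_r = v * sqrt(r) + c / sqrt(r) is fitted per cluster by binomial maximum
likelihood (counts at each scale are Binomial(B, Phi(-z_r))), and the
approximately unbiased p-value is AU = 1 - Phi(v - c); BP is the plain
bootstrap probability at r = 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster
from scipy.optimize import minimize
from scipy.stats import norm

from .core_io import Cnvr, ContractError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_SCALES: Tuple[float, ...] = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))


# ---------------------------------------------------------------------------
# scoring matrix
# ---------------------------------------------------------------------------


@dataclass
class ScoringMatrix:
    """Binary CNVR x sample presence/absence matrix."""

    cnvr_ids: List[str]
    samples: List[str]
    data: np.ndarray  # shape (n_cnvrs, n_samples), dtype uint8

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.data, index=self.cnvr_ids, columns=self.samples)


def build_matrix(
    cnvrs: Sequence[Cnvr], samples: Sequence[str], min_share: int = 2
) -> ScoringMatrix:
    """Rows = CNVRs with >= ``min_share`` distinct member samples."""
    sample_idx = {s: i for i, s in enumerate(samples)}
    ids: List[str] = []
    rows: List[np.ndarray] = []
    for r in sorted(cnvrs, key=lambda r: (r.interval.chrom, r.interval.start, r.interval.end)):
        members = r.samples
        missing = sorted(members - set(sample_idx))
        if missing:
            raise ValidationError(f"CNVR member sample(s) not in sample list: {', '.join(missing)}")
        if len(members) < min_share:
            continue
        row = np.zeros(len(samples), dtype=np.uint8)
        for s in members:
            row[sample_idx[s]] = 1
        ids.append(f"{r.interval.chrom}:{r.interval.start}-{r.interval.end}")
        rows.append(row)
    data = np.vstack(rows) if rows else np.zeros((0, len(samples)), dtype=np.uint8)
    return ScoringMatrix(ids, list(samples), data)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _binary_distance(data: np.ndarray, method: str) -> np.ndarray:
    """Pairwise sample (column) distances of a rows-by-samples 0/1 matrix."""
    x = data.astype(float)
    n = x.shape[1]
    if method == "correlation":
        xc = x - x.mean(axis=0)
        s = np.sqrt((xc * xc).sum(axis=0))
        denom = np.outer(s, s)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (xc.T @ xc) / denom
        d = 1.0 - r
        d[~np.isfinite(d)] = 1.0  # zero-variance columns: maximal dissimilarity
    elif method == "jaccard":
        b = (x > 0).astype(float)
        inter = b.T @ b
        sums = b.sum(axis=0)
        union = sums[:, None] + sums[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - inter / union
        d[union == 0] = 0.0  # two all-zero columns are identical
    else:
        raise ValueError(f"unknown distance method {method!r}")
    np.fill_diagonal(d, 0.0)
    d = np.maximum(d, 0.0)
    return (d + d.T) / 2.0


def sample_distance(m: ScoringMatrix, method: str = "correlation") -> np.ndarray:
    """Symmetric sample-by-sample distance matrix (zero diagonal)."""
    if len(m.samples) < 2:
        raise ContractError("sample_distance needs >= 2 samples")
    if method == "correlation" and m.n_rows:
        zero_var = [s for s, v in zip(m.samples, m.data.std(axis=0)) if v == 0]
        if zero_var:
            logger.warning(
                "zero-variance sample column(s) %s: correlation distance set to 1", zero_var
            )
    return _binary_distance(m.data, method)


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


@dataclass
class ClusterTree:
    """Rooted ultrametric tree over samples (UPGMA).

    ``linkage`` is in scipy format (leaves 0..n-1 in ``labels`` order);
    ``leafsets[k]`` is the label set of the cluster created by merge ``k``.
    ``au_p``/``bp_p`` are filled by :func:`au_pvalues`.
    """

    labels: List[str]
    linkage: np.ndarray
    leafsets: List[FrozenSet[str]]
    au_p: Optional[np.ndarray] = None
    bp_p: Optional[np.ndarray] = None

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2] / 2.0

    def cophenetic_matrix(self) -> np.ndarray:
        from scipy.spatial.distance import squareform

        return squareform(cophenet(self.linkage))

    def cut(self, k: int) -> Dict[str, int]:
        assignment = fcluster(self.linkage, t=k, criterion="maxclust")
        return {lab: int(a) for lab, a in zip(self.labels, assignment)}

    def to_newick(self, annotate: bool = True) -> str:
        n = len(self.labels)
        names: Dict[int, str] = {i: self.labels[i] for i in range(n)}

        def node_str(idx: int) -> str:
            if idx < n:
                return names[idx]
            k = idx - n
            left, right, dist = int(self.linkage[k, 0]), int(self.linkage[k, 1]), self.linkage[k, 2]
            h = dist / 2.0

            def blen(child: int) -> float:
                ch = 0.0 if child < n else self.linkage[child - n, 2] / 2.0
                return h - ch

            parts = f"({node_str(left)}:{blen(left):.6g},{node_str(right)}:{blen(right):.6g})"
            note = ""
            if annotate and self.au_p is not None and self.bp_p is not None:
                note = f"[&&NHX:au={self.au_p[k]:.3f}:bp={self.bp_p[k]:.3f}]"
            return parts + note

        return node_str(2 * n - 2) + ";"


def upgma(dist: np.ndarray, labels: Sequence[str]) -> ClusterTree:
    """Size-weighted average-linkage clustering with deterministic ties.

    Ties on the joining distance are broken by the lexicographically
    smallest pair of cluster ids, a cluster's id being the sorted tuple of
    its leaf labels.
    """
    d = np.asarray(dist, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n != len(labels):
        raise ValueError("distance matrix shape does not match labels")
    if np.isnan(d).any():
        raise ValueError("NaN in distance matrix")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if n < 2:
        raise ContractError("upgma needs >= 2 items")

    # cluster bookkeeping: key (sorted label tuple), scipy node id, size
    clusters: List[dict] = [
        {"key": (lab,), "id": i, "size": 1, "leaves": frozenset([lab])}
        for i, lab in enumerate(labels)
    ]
    dd: Dict[Tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dd[(i, j)] = d[i, j]

    linkage = np.zeros((n - 1, 4))
    leafsets: List[FrozenSet[str]] = []
    next_id = n
    for step in range(n - 1):
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                ki, kj = clusters[i]["key"], clusters[j]["key"]
                pair_key = (ki, kj) if ki <= kj else (kj, ki)
                cand = (dd[(i, j)], pair_key)
                if best is None or cand < best[0]:
                    best = (cand, i, j)
        (_, _), bi, bj = best
        ci, cj = clusters[bi], clusters[bj]
        join_d = dd[(bi, bj)]
        new = {
            "key": tuple(sorted(ci["key"] + cj["key"])),
            "id": next_id,
            "size": ci["size"] + cj["size"],
            "leaves": ci["leaves"] | cj["leaves"],
        }
        lo_id, hi_id = sorted((ci["id"], cj["id"]))
        linkage[step] = [lo_id, hi_id, join_d, new["size"]]
        leafsets.append(new["leaves"])
        # size-weighted average distances to the new cluster
        new_dd: Dict[Tuple[int, int], float] = {}
        remaining = [c for k, c in enumerate(clusters) if k not in (bi, bj)]
        old_index = [k for k in range(len(clusters)) if k not in (bi, bj)]
        for a in range(len(remaining)):
            for b in range(a + 1, len(remaining)):
                ia, ib = old_index[a], old_index[b]
                new_dd[(a, b)] = dd[(min(ia, ib), max(ia, ib))]
        m = len(remaining)
        for a in range(m):
            ia = old_index[a]
            dai = dd[(min(ia, bi), max(ia, bi))]
            daj = dd[(min(ia, bj), max(ia, bj))]
            new_dd[(a, m)] = (ci["size"] * dai + cj["size"] * daj) / new["size"]
        clusters = remaining + [new]
        dd = new_dd
        next_id += 1

    return ClusterTree(list(labels), linkage, leafsets)


def _upgma_leafsets_fast(dist: np.ndarray) -> List[int]:
    """Leafset bitmasks of all internal nodes (fast path for bootstrap).

    Same linkage rule as :func:`upgma`; ties broken by first flat argmin,
    which is deterministic but index-based (tie handling is immaterial for
    counting cluster recovery over random resamples).
    """
    n = dist.shape[0]
    d = dist.astype(float).copy()
    np.fill_diagonal(d, np.inf)
    sizes = np.ones(n)
    masks = [1 << i for i in range(n)]
    alive = np.ones(n, dtype=bool)
    out: List[int] = []
    for _ in range(n - 1):
        flat = np.argmin(d)
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        # weighted-average update into row/col i
        wi, wj = sizes[i], sizes[j]
        merged = (wi * d[i, :] + wj * d[j, :]) / (wi + wj)
        d[i, :] = merged
        d[:, i] = merged
        d[i, i] = np.inf
        d[j, :] = np.inf
        d[:, j] = np.inf
        sizes[i] = wi + wj
        alive[j] = False
        masks[i] |= masks[j]
        out.append(masks[i])
    return out


# ---------------------------------------------------------------------------
# multiscale bootstrap and AU p-values
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Per-cluster recovery counts at each resampling scale."""

    tree: ClusterTree
    scales: List[float]
    n_used: List[int]  # resample size per scale (0 = scale dropped)
    B: int
    counts: np.ndarray  # shape (n_internal_nodes, n_scales)


def multiscale_bootstrap(
    m: ScoringMatrix,
    scales: Sequence[float] = DEFAULT_SCALES,
    B: int = 10_000,
    seed: Optional[int] = None,
    method: str = "correlation",
) -> BootstrapResult:
    """Resample CNVR rows with replacement at sizes round(n*r), rebuild the
    UPGMA tree, and count recovery of each original cluster."""
    if B <= 0:
        raise ValueError("B must be a positive number of bootstrap resamples")
    n = m.n_rows
    if n < 2:
        raise ContractError("multiscale_bootstrap needs a matrix with >= 2 rows")
    d0 = sample_distance(m, method)
    tree = upgma(d0, m.samples)

    idx_of = {s: i for i, s in enumerate(m.samples)}
    target_masks = []
    for ls in tree.leafsets:
        mask = 0
        for s in ls:
            mask |= 1 << idx_of[s]
        target_masks.append(mask)

    rng = np.random.default_rng(seed)
    counts = np.zeros((len(target_masks), len(scales)), dtype=np.int64)
    n_used: List[int] = []
    data = m.data
    for si, r in enumerate(scales):
        npr = int(round(n * r))
        if npr < 2:
            logger.warning("scale %s gives resample size %d < 2: dropped", r, npr)
            n_used.append(0)
            continue
        n_used.append(npr)
        for _ in range(B):
            rows = rng.integers(0, n, size=npr)
            d = _binary_distance(data[rows], method)
            found = set(_upgma_leafsets_fast(d))
            for ei, mask in enumerate(target_masks):
                if mask in found:
                    counts[ei, si] += 1
    return BootstrapResult(tree, list(scales), n_used, B, counts)


@dataclass
class AuResult:
    au_p: np.ndarray
    bp_p: np.ndarray
    v: np.ndarray
    c: np.ndarray
    flags: List[str]  # '', 'saturated', 'degenerate'


def _fit_vc(rs: np.ndarray, ks: np.ndarray, B: int) -> Optional[Tuple[float, float]]:
    """Binomial-ML fit of z_r = v*sqrt(r) + c/sqrt(r); WLS init/fallback."""
    bp = ks / B
    z = norm.ppf(np.clip(1.0 - bp, 1e-12, 1 - 1e-12))
    x1, x2 = np.sqrt(rs), 1.0 / np.sqrt(rs)
    # WLS with binomial-delta-method weights
    p = np.clip(bp, 1e-9, 1 - 1e-9)
    wts = B * norm.pdf(z) ** 2 / (p * (1 - p))
    X = np.column_stack([x1, x2])
    try:
        beta, *_ = np.linalg.lstsq(X * np.sqrt(wts)[:, None], z * np.sqrt(wts), rcond=None)
    except np.linalg.LinAlgError:
        return None
    v0, c0 = float(beta[0]), float(beta[1])

    def nll(theta):
        v, c = theta
        zr = v * x1 + c * x2
        pr = np.clip(norm.cdf(-zr), 1e-12, 1 - 1e-12)
        return -np.sum(ks * np.log(pr) + (B - ks) * np.log1p(-pr))

    res = minimize(nll, x0=[v0, c0], method="Nelder-Mead")
    if res.success and np.isfinite(res.fun):
        return float(res.x[0]), float(res.x[1])
    return v0, c0  # WLS fallback


def au_pvalues(result: BootstrapResult) -> AuResult:
    """AU and BP p-values per internal node from multiscale counts."""
    n_edges, _ = result.counts.shape
    B = result.B
    scales = np.asarray(result.scales)
    usable_scale = np.asarray(result.n_used) > 0
    # BP at the scale closest to r = 1
    si1 = int(np.argmin(np.abs(scales - 1.0)))

    au = np.zeros(n_edges)
    bp = np.zeros(n_edges)
    vv = np.full(n_edges, np.nan)
    cc = np.full(n_edges, np.nan)
    flags: List[str] = []
    for e in range(n_edges):
        ks = result.counts[e]
        bp[e] = ks[si1] / B
        informative = usable_scale & (ks > 0) & (ks < B)
        if informative.sum() < 2:
            # saturated (all 0 or all B) or degenerate: AU falls back to BP
            if np.all(ks[usable_scale] == B):
                au[e] = 1.0
                flags.append("saturated")
            elif np.all(ks[usable_scale] == 0):
                au[e] = 0.0
                flags.append("saturated")
            else:
                au[e] = bp[e]
                flags.append("degenerate")
            continue
        fit = _fit_vc(scales[informative], ks[informative], B)
        if fit is None:
            au[e] = bp[e]
            flags.append("degenerate")
            continue
        v, c = fit
        vv[e], cc[e] = v, c
        au[e] = float(1.0 - norm.cdf(v - c))
        flags.append("")
    return AuResult(au, bp, vv, cc, flags)


def attach_support(tree: ClusterTree, au: AuResult) -> ClusterTree:
    tree.au_p = au.au_p
    tree.bp_p = au.bp_p
    return tree


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    samples: List[str]
    scores: np.ndarray  # (n_samples, n_components)
    variance_fraction: np.ndarray
    loadings: np.ndarray  # (n_components, n_variables)


def pca(m: ScoringMatrix, scale: bool = False) -> PcaResult:
    """PCA of samples on centered (optionally scaled) CNVR presence rows.

    Samples are observations, CNVR rows are variables.  Component signs are
    fixed by making each component's largest-magnitude loading positive.
    """
    if len(m.samples) < 2 or m.n_rows < 2:
        raise ContractError("pca needs >= 2 samples and >= 2 CNVR rows")
    x = m.data.T.astype(float)  # samples x variables
    xc = x - x.mean(axis=0)
    if scale:
        sd = xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    nonzero = var > var.max() * 1e-12 if var.size else np.array([], dtype=bool)
    u, s, vt, var = u[:, nonzero], s[nonzero], vt[nonzero], var[nonzero]
    scores = u * s
    for j in range(vt.shape[0]):
        i = int(np.argmax(np.abs(vt[j])))
        if vt[j, i] < 0:
            vt[j] = -vt[j]
            scores[:, j] = -scores[:, j]
    frac = var / var.sum() if var.size else var
    return PcaResult(list(m.samples), scores, frac, vt)
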