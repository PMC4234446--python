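"""Pairwise motif alignment, empirical significance, trees and families.

Motifs are compared column-by-column with the Pearson correlation of their
frequency vectors, the metric recommended for position-matrix comparison.
The best ungapped alignment over all offsets and both orientations is the
one maximising the *summed* column correlation; the reported ``score`` is
the mean correlation over the aligned columns, so it lives in [-1, 1].
Selecting by the sum rather than the mean prevents spurious short overlaps
(which trivially reach mean ~1) from outranking long, informative ones.

Significance is calibrated against a seeded decoy null: column-shuffled
database motifs aligned to column-shuffled query-width motifs.  The decoy
best-alignment statistic is a maximum over a small number of near-Gaussian
sums, so its upper tail decays like a Gaussian; the null is therefore
summarised by a location/scale (normal-tail) fit rather than a Gumbel one,
whose exponential tail grossly overstates the far tail for this statistic.
E-values are ``db_size * P(S >= s)`` under that fit.

Motif families are obtained by average-linkage (UPGMA) clustering of the
pairwise distance ``(1 - score) / 2`` and cutting the tree at a branch-length
threshold (default 0.05): leaves connected through edges all shorter than
the threshold form one group.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm
import skbio

from .errors import ValidationError
from .motif_model import NucleotideMotif, normalize_to_pwm, reverse_complement


@dataclass
class MotifAlignment:
    """Best ungapped alignment between two motifs.

    ``offset`` is the target start relative to the query start (after
    orienting the target); ``score`` is the mean per-column Pearson
    correlation over the ``ncols`` aligned columns.
    """

    query_id: str
    target_id: str
    offset: int
    orientation: str  # "forward" | "revcomp"
    ncols: int
    score: float
    e_value: float | None = None

    @property
    def sum_score(self) -> float:
        """Summed column correlation; the significance statistic."""
        return self.score * self.ncols


@dataclass
class NullModel:
    """Decoy best-alignment score distribution for one query width."""

    scores: np.ndarray  # sorted decoy sum-scores
    n_decoys: int
    seed: int
    fit: tuple[float, float]  # (location, scale) of the normal-tail fit
    query_width: int = 0

    def sf(self, sum_score: float) -> float:
        """P(decoy best sum-score >= sum_score) under the tail fit."""
        loc, scale = self.fit
        if scale <= 0:
            return 1.0 if sum_score <= loc else 0.0
        return float(norm.sf((sum_score - loc) / scale))


@dataclass
class MotifTree:
    newick: str
    leaf_ids: list[str]


@dataclass
class MotifGroup:
    group_id: str
    member_ids: list[str]


# ---------------------------------------------------------------------------
# Column metric and alignment
# ---------------------------------------------------------------------------

def column_pcc(col_a, col_b) -> float:
    """Pearson correlation of two base-frequency 4-vectors.

    Zero-variance (uniform) columns correlate 0 with anything, by decision:
    the correlation is undefined there and a flat column carries no signal.
    """
    a = np.asarray(col_a, dtype=float)
    b = np.asarray(col_b, dtype=float)
    if not (np.isclose(a.sum(), 1.0, atol=1e-6)
            and np.isclose(b.sum(), 1.0, atol=1e-6)):
        raise ValidationError("columns must be frequency vectors summing to 1")
    return float(_pcc_rows(a[None, :], b[None, :])[0])


def _pcc_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of two (k, 4) frequency blocks."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((ac * ac).sum(axis=1))
    nb = np.sqrt((bc * bc).sum(axis=1))
    denom = na * nb
    out = np.zeros(a.shape[0])
    ok = denom > 1e-12
    out[ok] = (ac * bc).sum(axis=1)[ok] / denom[ok]
    return np.clip(out, -1.0, 1.0)


def _best_alignment_arrays(pq: np.ndarray, pt: np.ndarray, min_overlap: int):
    """Best (sum, ncols, offset) for one orientation of target vs query."""
    wq, wt = len(pq), len(pt)
    best = None
    for off in range(-(wt - min_overlap), wq - min_overlap + 1):
        qs, qe = max(0, off), min(wq, off + wt)
        k = qe - qs
        if k < min_overlap:
            continue
        s = float(_pcc_rows(pq[qs:qe], pt[qs - off:qe - off]).sum())
        cand = (s, k, off)
        if best is None or _better(cand, best):
            best = cand
    return best


def _better(cand, best) -> bool:
    s, k, off = cand
    bs, bk, boff = best
    if s > bs + 1e-12:
        return True
    if s < bs - 1e-12:
        return False
    if k != bk:
        return k > bk
    return abs(off) < abs(boff)


def align_motifs(a: NucleotideMotif, b: NucleotideMotif,
                 min_overlap: int = 5,
                 both_strands: bool = True) -> MotifAlignment:
    """Best ungapped alignment of ``b`` against ``a``.

    Ties are broken toward more aligned columns, then smaller |offset|,
    then the forward orientation.
    """
    if min_overlap > min(a.width, b.width):
        raise ValidationError(
            f"min_overlap {min_overlap} exceeds the narrower motif "
            f"({min(a.width, b.width)} columns)")
    pq = normalize_to_pwm(a)
    candidates = []
    for orient, target in (("forward", b),
                           ("revcomp", reverse_complement(b))):
        if orient == "revcomp" and not both_strands:
            continue
        pt = normalize_to_pwm(target)
        best = _best_alignment_arrays(pq, pt, min_overlap)
        if best is not None:
            candidates.append((best, orient))
    (s, k, off), orient = candidates[0]
    for cand, o in candidates[1:]:
        if _better(cand, (s, k, off)):
            (s, k, off), orient = cand, o
    return MotifAlignment(query_id=a.id, target_id=b.id, offset=off,
                          orientation=orient, ncols=k, score=s / k)


# ---------------------------------------------------------------------------
# Empirical null and E-values
# ---------------------------------------------------------------------------

def _column_shuffle(m: NucleotideMotif, rng: np.random.Generator) -> NucleotideMotif:
    perm = rng.permutation(m.width)
    return NucleotideMotif(id=m.id, counts=m.counts[perm], nsites=m.nsites)


def _resize(counts: np.ndarray, width: int, rng: np.random.Generator) -> np.ndarray:
    w = counts.shape[0]
    if w == width:
        return counts
    if w > width:
        start = rng.integers(0, w - width + 1)
        return counts[start:start + width]
    extra = counts[rng.integers(0, w, size=width - w)]
    return np.vstack([counts, extra])


def build_null(db: list[NucleotideMotif], query_width: int,
               n_decoys: int = 1000, seed: int = 0,
               min_overlap: int = 5) -> NullModel:
    """Decoy distribution of best-alignment sum-scores for a query width.

    Each decoy aligns a column-shuffled database motif against a
    column-shuffled, width-adjusted database motif, destroying positional
    signal while keeping the column composition of the database.
    """
    if not db:
        raise ValidationError("empty motif database")
    rng = np.random.default_rng(seed)
    scores = np.empty(n_decoys)
    for i in range(n_decoys):
        target = _column_shuffle(db[rng.integers(len(db))], rng)
        qsrc = _column_shuffle(db[rng.integers(len(db))], rng)
        qcounts = _resize(qsrc.counts, query_width, rng)
        query = NucleotideMotif(id="decoy", counts=qcounts)
        aln = align_motifs(query, target,
                           min_overlap=min(min_overlap, query_width,
                                           target.width))
        scores[i] = aln.sum_score
    loc = float(scores.mean())
    scale = float(scores.std(ddof=1))
    return NullModel(scores=np.sort(scores), n_decoys=n_decoys, seed=seed,
                     fit=(loc, scale), query_width=query_width)


def motif_evalue(aln: MotifAlignment, null: NullModel, db_size: int) -> float:
    """E-value of a motif alignment: db_size * P(S >= s) under the null.

    Monotone non-increasing in the alignment score and linear in db_size;
    capped at db_size (a score below the whole null gives E ~ db_size).
    """
    p = min(1.0, null.sf(aln.sum_score))
    return db_size * p


# ---------------------------------------------------------------------------
# Distance matrix, UPGMA tree, family cutting
# ---------------------------------------------------------------------------

def pairwise_distance_matrix(motifs: list[NucleotideMotif],
                             min_overlap: int = 5) -> np.ndarray:
    """Symmetric distance matrix d = (1 - mean column correlation) / 2."""
    n = len(motifs)
    if n < 2:
        raise ValidationError("need at least 2 motifs")
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mo = min(min_overlap, motifs[i].width, motifs[j].width)
            aln = align_motifs(motifs[i], motifs[j], min_overlap=mo)
            d[i, j] = d[j, i] = (1.0 - aln.score) / 2.0
    return d


def _fmt_bl(x: float) -> str:
    return f"{x:.10g}"


def upgma_tree(dist: np.ndarray, ids: list[str]) -> MotifTree:
    """Average-linkage agglomeration with deterministic tie-breaking.

    At each step the pair with the smallest distance merges; ties are broken
    by the lexicographically smallest pair of cluster labels (a cluster is
    labelled by its lexicographically smallest leaf).  Node height is half
    the merge distance, so a two-leaf tree at distance d reads
    ``(A:d/2,B:d/2);``.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(ids)
    if dist.shape != (n, n):
        raise ValidationError("distance matrix shape does not match ids")
    if not np.allclose(dist, dist.T, atol=1e-9):
        raise ValidationError("distance matrix must be symmetric")
    clusters = {i: {"newick": ids[i], "height": 0.0, "size": 1,
                    "label": ids[i]} for i in range(n)}
    d = {frozenset((i, j)): dist[i, j]
         for i in range(n) for j in range(i + 1, n)}
    next_id = n
    while len(clusters) > 1:
        best_key, best_val, best_labels = None, None, None
        for key, val in d.items():
            i, j = sorted(key)
            labels = tuple(sorted((clusters[i]["label"], clusters[j]["label"])))
            if (best_val is None or val < best_val - 1e-12
                    or (abs(val - best_val) <= 1e-12 and labels < best_labels)):
                best_key, best_val, best_labels = key, val, labels
        i, j = sorted(best_key)
        ci, cj = clusters.pop(i), clusters.pop(j)
        height = best_val / 2.0
        bl_i, bl_j = height - ci["height"], height - cj["height"]
        a, b = sorted(((ci, bl_i), (cj, bl_j)), key=lambda t: t[0]["label"])
        newick = (f"({a[0]['newick']}:{_fmt_bl(a[1])},"
                  f"{b[0]['newick']}:{_fmt_bl(b[1])})")
        merged = {"newick": newick, "height": height,
                  "size": ci["size"] + cj["size"],
                  "label": min(ci["label"], cj["label"])}
        new_d = {}
        for key, val in d.items():
            if i in key or j in key:
                continue
            new_d[key] = val
        for k in clusters:
            dik = d[frozenset((i, k))]
            djk = d[frozenset((j, k))]
            new_d[frozenset((next_id, k))] = (
                (ci["size"] * dik + cj["size"] * djk)
                / (ci["size"] + cj["size"]))
        clusters[next_id] = merged
        d = new_d
        next_id += 1
    root = next(iter(clusters.values()))
    return MotifTree(newick=root["newick"] + ";", leaf_ids=list(ids))


_ROMAN = [(1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
          (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
          (5, "V"), (4, "IV"), (1, "I")]


def _roman(n: int) -> str:
    out = []
    for val, sym in _ROMAN:
        while n >= val:
            out.append(sym)
            n -= val
    return "".join(out)


def cut_tree_groups(tree: MotifTree, branch_threshold: float = 0.05,
                    override: dict[str, str] | None = None
                    ) -> list[MotifGroup]:
    """Partition leaves into groups of mutually close motifs.

    Two leaves share a group when every edge on the path between them is
    shorter than ``branch_threshold``.  Groups are labelled with Roman
    numerals in decreasing size, ties by first-leaf order.  ``override``
    forces named motifs into named groups regardless of topology (used for
    curated exceptions).
    """
    t = skbio.TreeNode.read(io.StringIO(tree.newick))
    parent = {}

    def ok(node):
        length = node.length if node.length is not None else 0.0
        return length < branch_threshold

    # union-find over tree nodes through short edges
    uf = {}

    def find(x):
        while uf[x] != x:
            uf[x] = uf[uf[x]]
            x = uf[x]
        return x

    for node in t.traverse(include_self=True):
        uf[id(node)] = id(node)
    node_by_id = {id(node): node for node in t.traverse(include_self=True)}
    for node in t.traverse(include_self=False):
        if ok(node):
            ra, rb = find(id(node)), find(id(node.parent))
            uf[ra] = rb
    comp_leaves: dict[int, list[str]] = {}
    for leaf in t.tips():
        comp_leaves.setdefault(find(id(leaf)), []).append(leaf.name)
    order = {mid: i for i, mid in enumerate(tree.leaf_ids)}
    groups = sorted(comp_leaves.values(),
                    key=lambda ms: (-len(ms), min(order.get(m, 1 << 30)
                                                  for m in ms)))
    result = [MotifGroup(group_id=_roman(i + 1),
                         member_ids=sorted(ms, key=lambda m: order.get(m, 0)))
              for i, ms in enumerate(groups)]
    if override:
        by_id = {g.group_id: g for g in result}
        for motif_id, gid in override.items():
            for g in result:
                if motif_id in g.member_ids:
                    g.member_ids.remove(motif_id)
            if gid not in by_id:
                g = MotifGroup(group_id=gid, member_ids=[])
                result.append(g)
                by_id[gid] = g
            by_id[gid].member_ids.append(motif_id)
        result = [g for g in result if g.member_ids]
    return result
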