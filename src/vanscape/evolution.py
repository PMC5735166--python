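"""Repeat and phylogeny toolkit: dot plots, tandem repeats, distances, NJ.

DNA dot plots use exact word matches (default word 10); protein dot plots
use the dotmatcher convention of an ungapped sliding window scored with a
substitution matrix against a threshold (defaults: window 10, threshold 23,
BLOSUM62).  Tandem repeats are detected from self-match periodicities
(a simplified, deterministic stand-in for Tandem Repeats Finder's
probabilistic alignment model).  Distances between aligned sequences are
Poisson-corrected, d = -ln(1 - p), and trees are built by neighbour
joining with column-bootstrap supports.
"""

from __future__ import annotations

import io as _io
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import Phylo
from Bio.Align import substitution_matrices

GAP_CHARS = set("-.")


@dataclass
class DotPlot:
    seq_x_id: str
    seq_y_id: str
    mode: str                      # "dna_word" | "protein_window"
    params: dict
    points: set[tuple[int, int]]
    #: maximal runs of points with constant x - y: (offset, start_x, length)
    diagonals: list[tuple[int, int, int]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        pts = sorted(self.points)
        return pd.DataFrame(pts, columns=["x", "y"])


@dataclass
class TandemRepeat:
    seq_id: str
    start: int
    end: int
    unit_length: int
    copy_number: float
    consensus_unit: str
    percent_identity: float


@dataclass
class DistanceMatrixAndTree:
    labels: list[str]
    d: np.ndarray
    tree: str                      # newick with branch lengths
    #: bipartition (frozenset of leaf names, canonical side) -> support
    supports: dict[frozenset, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Dot plots
# ---------------------------------------------------------------------------

def _assemble_diagonals(points: set[tuple[int, int]]) -> list[tuple[int, int, int]]:
    by_offset: dict[int, list[int]] = {}
    for x, y in points:
        by_offset.setdefault(x - y, []).append(x)
    diags = []
    for off in sorted(by_offset):
        xs = sorted(by_offset[off])
        start, prev = xs[0], xs[0]
        for x in xs[1:]:
            if x != prev + 1:
                diags.append((off, start, prev - start + 1))
                start = x
            prev = x
        diags.append((off, start, prev - start + 1))
    return diags


def dotplot_dna(seq_x: str, seq_y: str, word: int = 10,
                x_id: str = "x", y_id: str = "y") -> DotPlot:
    """Exact-word dot plot: a point at (x, y) iff the two length-``word``
    substrings starting there are identical."""
    seq_x, seq_y = seq_x.upper(), seq_y.upper()
    if word > min(len(seq_x), len(seq_y)):
        raise ValueError("word length exceeds a sequence length")
    index: dict[str, list[int]] = {}
    for y in range(len(seq_y) - word + 1):
        index.setdefault(seq_y[y:y + word], []).append(y)
    points = set()
    for x in range(len(seq_x) - word + 1):
        for y in index.get(seq_x[x:x + word], ()):
            points.add((x, y))
    return DotPlot(x_id, y_id, "dna_word", {"word": word}, points,
                   _assemble_diagonals(points))


def dotplot_protein(seq_x: str, seq_y: str, window: int = 10, threshold: int = 23,
                    matrix: str = "BLOSUM62", x_id: str = "x",
                    y_id: str = "y") -> DotPlot:
    """Windowed substitution-score dot plot (dotmatcher convention).

    A point is placed at (x, y) iff the summed matrix score of the ungapped
    length-``window`` comparison starting there reaches ``threshold``.
    """
    mat = substitution_matrices.load(matrix)
    alphabet = str(mat.alphabet)
    lut = {c: i for i, c in enumerate(alphabet)}
    m = np.array(mat)

    def encode(s):
        try:
            return np.array([lut[c] for c in s.upper()])
        except KeyError as exc:
            raise ValueError(f"residue {exc} not in {matrix} alphabet") from exc

    ix, iy = encode(seq_x), encode(seq_y)
    lx, ly = len(ix), len(iy)
    points = set()
    for off in range(-(ly - 1), lx):
        x0, y0 = max(off, 0), max(-off, 0)
        n = min(lx - x0, ly - y0)
        if n < window:
            continue
        scores = m[ix[x0:x0 + n], iy[y0:y0 + n]]
        wsum = np.convolve(scores, np.ones(window), mode="valid")
        for k in np.nonzero(wsum >= threshold)[0]:
            points.add((x0 + int(k), y0 + int(k)))
    return DotPlot(x_id, y_id, "protein_window",
                   {"window": window, "threshold": threshold, "matrix": matrix},
                   points, _assemble_diagonals(points))


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def find_tandem_repeats(seq: str, min_unit: int = 2, max_unit: int = 100,
                        min_copies: float = 2.0, min_identity: float = 0.9,
                        seq_id: str = "seq") -> list[TandemRepeat]:
    """Detect tandem repeats from self-match periodicity.

    For each candidate unit length u, positions where seq[i] == seq[i+u]
    mark period-u self-similarity; maximal stretches whose running identity
    stays at or above ``min_identity`` and that span at least
    ``min_copies`` units are reported.  Overlapping calls from different
    unit lengths are resolved by keeping the longest span.
    """
    if min_unit < 1:
        raise ValueError("min_unit must be >= 1")
    seq = seq.upper()
    L = len(seq)
    candidates: list[TandemRepeat] = []
    arr = np.frombuffer(seq.encode(), dtype="S1")
    for u in range(min_unit, min(max_unit, L // 2) + 1):
        m = arr[:-u] == arr[u:]
        i = 0
        n = len(m)
        while i < n:
            if not m[i]:
                i += 1
                continue
            # greedy extension keeping running identity >= threshold
            matches, j = 0, i
            last_match = i - 1
            while j < n:
                matches += int(m[j])
                if matches / (j - i + 1) < min_identity:
                    break
                if m[j]:
                    last_match = j
                j += 1
            span = last_match - i + 1 + u
            if span >= min_copies * u:
                candidates.append(_make_repeat(seq, seq_id, i, i + span, u))
            i = max(last_match + 1, i + 1)
    # keep longest span among overlapping calls
    candidates.sort(key=lambda r: (-(r.end - r.start), r.unit_length, r.start))
    kept: list[TandemRepeat] = []
    for cand in candidates:
        if all(cand.end <= k.start or cand.start >= k.end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda r: r.start)
    return kept


def _make_repeat(seq: str, seq_id: str, start: int, end: int, unit: int) -> TandemRepeat:
    span = end - start
    copies = [seq[start + k * unit:start + (k + 1) * unit]
              for k in range(span // unit)]
    consensus = "".join(
        max(set(col), key=lambda b: (col.count(b), b)) for col in zip(*copies))
    ident = np.mean([
        sum(a == b for a, b in zip(c, consensus)) / unit for c in copies])
    return TandemRepeat(seq_id, start, end, unit, span / unit, consensus, float(ident))


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def poisson_distance(aligned_a: str, aligned_b: str) -> float:
    """Poisson correction distance d = -ln(1 - p) over ungapped columns.

    p is the proportion of differing columns among columns without a gap
    in either sequence.  Undefined (NaN) when there are no ungapped
    columns or when p = 1.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    total = diff = 0
    for a, b in zip(aligned_a.upper(), aligned_b.upper()):
        if a in GAP_CHARS or b in GAP_CHARS:
            continue
        total += 1
        diff += a != b
    if total == 0:
        return math.nan
    p = diff / total
    if p >= 1.0:
        return math.nan
    return -math.log(1.0 - p)


def distance_matrix(alignment: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Pairwise Poisson-corrected distance matrix (labels in sorted order)."""
    labels = sorted(alignment)
    n = len(labels)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = poisson_distance(alignment[labels[i]], alignment[labels[j]])
    return labels, d


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

def neighbor_joining(d: np.ndarray, labels: list[str]) -> str:
    """Standard neighbour joining; returns a newick string with branch lengths.

    Deterministic: at equal Q the lowest-index pair (in current node order)
    is merged.  On an additive input matrix the returned tree reproduces
    every leaf-to-leaf path length exactly.  Raises on NaN entries or
    asymmetric input.
    """
    d = np.asarray(d, dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix contains NaN")
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if n < 2:
        raise ValueError("need at least two taxa")
    if n != len(labels):
        raise ValueError("labels/matrix size mismatch")
    nodes = [str(x) for x in labels]
    D = d.copy()
    while len(nodes) > 2:
        m = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        new = f"({nodes[i]}:{li:.12g},{nodes[j]}:{lj:.12g})"
        dk = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.zeros((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[:-1, -1] = D2[-1, :-1] = dk[keep]
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
    half = D[0, 1] / 2.0
    return f"({nodes[0]}:{half:.12g},{nodes[1]}:{half:.12g});"


def tree_leaf_distances(newick: str) -> pd.DataFrame:
    """Leaf-to-leaf path-length matrix of a newick tree (labels sorted)."""
    tree = Phylo.read(_io.StringIO(newick), "newick")
    leaves = sorted(tree.get_terminals(), key=lambda c: c.name)
    names = [c.name for c in leaves]
    depths = tree.depths()
    n = len(leaves)
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        mrca = tree.common_ancestor(leaves[i], leaves[j])
        d[i, j] = d[j, i] = depths[leaves[i]] + depths[leaves[j]] - 2 * depths[mrca]
    return pd.DataFrame(d, index=names, columns=names)


def bipartitions(newick: str) -> set[frozenset]:
    """Non-trivial bipartitions of a tree, each as its canonical leaf side.

    The canonical side is the one not containing the alphabetically first
    leaf, so rooted representations of the same unrooted tree agree.
    """
    tree = Phylo.read(_io.StringIO(newick), "newick")
    all_leaves = frozenset(c.name for c in tree.get_terminals())
    ref = min(all_leaves)
    out = set()
    for clade in tree.get_nonterminals():
        side = frozenset(c.name for c in clade.get_terminals())
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def bootstrap_tree(alignment: dict[str, str], n_replicates: int = 100,
                   seed: int = 0) -> DistanceMatrixAndTree:
    """NJ tree with bootstrap supports from column resampling.

    Alignment columns are resampled with replacement per replicate; the
    support of an internal edge of the full-data tree is the fraction of
    replicate trees containing the same bipartition.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    labels, d = distance_matrix(alignment)
    tree = neighbor_joining(d, labels)
    orig_bi = bipartitions(tree)
    counts = dict.fromkeys(orig_bi, 0)
    rng = np.random.default_rng(seed)
    mat = np.array([list(alignment[name]) for name in labels])
    ncol = mat.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, ncol)
        rep = {name: "".join(mat[i, cols]) for i, name in enumerate(labels)}
        _, rd = distance_matrix(rep)
        if np.isnan(rd).any():
            continue
        rep_bi = bipartitions(neighbor_joining(rd, labels))
        for b in orig_bi & rep_bi:
            counts[b] += 1
    supports = {b: c / n_replicates for b, c in counts.items()}
    return DistanceMatrixAndTree(labels, d, tree, supports)
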