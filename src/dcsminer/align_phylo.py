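"""Desk-scale protein alignment and distance-based phylogenetics.

Global affine-gap pairwise alignment (Gotoh), progressive multiple sequence
alignment over a neighbor-joining guide tree, Poisson-corrected distances,
neighbor joining with deterministic tie-breaks, bootstrap bipartition
supports, monophyly queries and the DTC-vs-SHC relatedness filter.

A gap of length ``k`` costs ``gap_open + k * gap_extend``.  Neighbor joining
is exact on additive distance matrices, which is the property the test suite
exploits; it stands in for likelihood tree inference at desk scale, with
topology-level statements (monophyly, bipartition support) as the intended
readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

from .seqio import ProteinRecord

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
GAP = "-"

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

#: Poisson distance cap (applied when p >= 1 - exp(-POISSON_CAP))
POISSON_CAP = 5.0


@dataclass(frozen=True)
class Alignment:
    """An ordered, equal-length gapped alignment."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment rows: lengths {sorted(lengths)}")

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def ungapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


def _blosum62() -> np.ndarray:
    table = substitution_matrices.load("BLOSUM62")
    out = np.zeros((len(ALPHABET), len(ALPHABET)))
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = table[a][b]
    return out


_BLOSUM62 = _blosum62()


def _as_matrix(substitution_matrix) -> np.ndarray:
    if substitution_matrix is None:
        return _BLOSUM62
    if isinstance(substitution_matrix, np.ndarray):
        if substitution_matrix.shape != (len(ALPHABET), len(ALPHABET)):
            raise ValueError("substitution matrix must be 21x21 over "
                             + ALPHABET)
        return substitution_matrix
    out = np.zeros((len(ALPHABET), len(ALPHABET)))
    for (a, b), score in substitution_matrix.items():
        out[_AA_INDEX[a], _AA_INDEX[b]] = score
        out[_AA_INDEX[b], _AA_INDEX[a]] = score
    return out


def match_mismatch_matrix(match: float = 1.0, mismatch: float = -1.0) -> np.ndarray:
    """A uniform match/mismatch substitution matrix (toy scoring)."""
    out = np.full((len(ALPHABET), len(ALPHABET)), mismatch)
    np.fill_diagonal(out, match)
    return out


def _profile_freqs(rows: Sequence[str]) -> np.ndarray:
    """Column residue frequencies over the 21-letter alphabet (gap rows are
    zero, so gap fractions simply dilute the expected substitution score)."""
    n_cols = len(rows[0])
    freqs = np.zeros((n_cols, len(ALPHABET)))
    for row in rows:
        for j, ch in enumerate(row):
            if ch != GAP:
                freqs[j, _AA_INDEX[ch]] += 1.0
    return freqs / len(rows)


_STATE_M, _STATE_IX, _STATE_IY = 0, 1, 2


def _gotoh(sp: np.ndarray, gap_open: float, gap_extend: float
           ) -> tuple[float, list[tuple[int, int]]]:
    """Affine-gap global alignment over a precomputed column-score matrix.

    Returns the optimal score and the column operations as (i, j) pairs where
    0 means a gap (Ix consumes a column of A, Iy a column of B).  Traceback
    ties prefer substitution over a gap in A over a gap in B.
    """
    m, n = sp.shape
    neg = -np.inf
    go_ge = gap_open + gap_extend
    M = np.full((m + 1, n + 1), neg)
    Ix = np.full((m + 1, n + 1), neg)
    Iy = np.full((m + 1, n + 1), neg)
    M[0, 0] = 0.0
    cols = np.arange(n + 1, dtype=float)

    with np.errstate(invalid="ignore"):
        # A gap may open from a substitution state or from a gap in the other
        # sequence (both pay the full opening cost), so
        # Iy[i][j] = max_{k<j} (max(M, Ix)[i][k] - open - (j-k)*extend),
        # computed as a running maximum of c[k] = base[k] - open + extend*k.
        c0 = M[0] - gap_open + gap_extend * cols
        acc = np.maximum.accumulate(c0)
        Iy[0, 1:] = acc[:-1] - gap_extend * cols[1:]
        for i in range(1, m + 1):
            Ix[i] = np.maximum(np.maximum(M[i - 1], Iy[i - 1]) - go_ge,
                               Ix[i - 1] - gap_extend)
            prev_best = np.maximum(np.maximum(M[i - 1], Ix[i - 1]), Iy[i - 1])
            M[i, 1:] = sp[i - 1] + prev_best[:-1]
            c = np.maximum(M[i], Ix[i]) - gap_open + gap_extend * cols
            acc = np.maximum.accumulate(c)
            Iy[i, 1:] = acc[:-1] - gap_extend * cols[1:]

    finals = (M[m, n], Iy[m, n], Ix[m, n])  # preference order M > Iy > Ix
    score = max(finals)
    state = (_STATE_M, _STATE_IY, _STATE_IX)[int(np.argmax(finals))]

    ops: list[tuple[int, int]] = []
    i, j = m, n
    while i > 0 or j > 0:
        if state == _STATE_M:
            ops.append((i, j))
            prev = (M[i - 1, j - 1], Iy[i - 1, j - 1], Ix[i - 1, j - 1])
            state = (_STATE_M, _STATE_IY, _STATE_IX)[int(np.argmax(prev))]
            i, j = i - 1, j - 1
        elif state == _STATE_IX:
            ops.append((i, 0))
            candidates = (M[i - 1, j] - go_ge, Ix[i - 1, j] - gap_extend,
                          Iy[i - 1, j] - go_ge)
            state = (_STATE_M, _STATE_IX, _STATE_IY)[int(np.argmax(candidates))]
            i -= 1
        else:  # Iy
            ops.append((0, j))
            candidates = (M[i, j - 1] - go_ge, Iy[i, j - 1] - gap_extend,
                          Ix[i, j - 1] - go_ge)
            state = (_STATE_M, _STATE_IY, _STATE_IX)[int(np.argmax(candidates))]
            j -= 1
    ops.reverse()
    return float(score), ops


def _merge_profiles(a: Alignment, b: Alignment, matrix: np.ndarray,
                    gap_open: float, gap_extend: float) -> tuple[Alignment, float]:
    fa = _profile_freqs(a.rows)
    fb = _profile_freqs(b.rows)
    sp = fa @ matrix @ fb.T
    score, ops = _gotoh(sp, gap_open, gap_extend)
    new_a = ["" for _ in a.rows]
    new_b = ["" for _ in b.rows]
    for i, j in ops:
        for r, row in enumerate(a.rows):
            new_a[r] += row[i - 1] if i > 0 else GAP
        for r, row in enumerate(b.rows):
            new_b[r] += row[j - 1] if j > 0 else GAP
    return Alignment(a.ids + b.ids, tuple(new_a) + tuple(new_b)), score


def _as_record(seq: ProteinRecord | str, fallback_id: str) -> ProteinRecord:
    if isinstance(seq, ProteinRecord):
        return seq
    return ProteinRecord(fallback_id, seq)


def pairwise_align(a: ProteinRecord | str, b: ProteinRecord | str,
                   substitution_matrix=None,
                   gap_open: float = DEFAULT_GAP_OPEN,
                   gap_extend: float = DEFAULT_GAP_EXTEND,
                   ) -> tuple[Alignment, float]:
    """Optimal global alignment of two sequences under affine gap costs.

    Returns the alignment and its score.  Default scoring is BLOSUM62 with
    gap open 10 and extend 0.5 (half-bit scale).  Both sequences must be
    non-empty.
    """
    rec_a = _as_record(a, "a")
    rec_b = _as_record(b, "b")
    if not rec_a.residues or not rec_b.residues:
        raise ValueError("pairwise_align requires non-empty sequences")
    matrix = _as_matrix(substitution_matrix)
    align_a = Alignment((rec_a.id,), (rec_a.residues,))
    align_b = Alignment((rec_b.id,), (rec_b.residues,))
    return _merge_profiles(align_a, align_b, matrix, gap_open, gap_extend)


def kmer_distance_matrix(records: Sequence[ProteinRecord], k: int = 3) -> DistanceMatrix:
    """Cosine distances between k-mer count vectors (guide-tree distance)."""
    k = max(1, min(k, min(len(r) for r in records)))
    vectors = []
    for rec in records:
        counts: dict[str, int] = {}
        for i in range(len(rec.residues) - k + 1):
            kmer = rec.residues[i:i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
        vectors.append(counts)
    n = len(records)
    data = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            vi, vj = vectors[i], vectors[j]
            dot = sum(c * vj.get(kmer, 0) for kmer, c in vi.items())
            ni = math.sqrt(sum(c * c for c in vi.values()))
            nj = math.sqrt(sum(c * c for c in vj.values()))
            dist = 1.0 - dot / (ni * nj)
            data[i, j] = data[j, i] = max(0.0, dist)
    return DistanceMatrix(data, [r.id for r in records])


def progressive_msa(records: Sequence[ProteinRecord],
                    substitution_matrix=None,
                    gap_open: float = DEFAULT_GAP_OPEN,
                    gap_extend: float = DEFAULT_GAP_EXTEND) -> Alignment:
    """Progressive multiple alignment over a neighbor-joining guide tree.

    The guide tree is built from 3-mer count cosine distances; profiles are
    merged in guide-tree order by profile–profile global alignment.
    Deterministic; duplicate ids raise ``ValueError``.
    """
    if len(records) < 2:
        raise ValueError("progressive_msa requires at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in MSA input")
    matrix = _as_matrix(substitution_matrix)
    by_id = {r.id: r for r in records}

    def leaf(rec_id: str) -> Alignment:
        return Alignment((rec_id,), (by_id[rec_id].residues,))

    if len(records) == 2:
        merged, _ = _merge_profiles(leaf(ids[0]), leaf(ids[1]), matrix,
                                    gap_open, gap_extend)
        return merged

    guide = neighbor_joining(kmer_distance_matrix(records))

    def build(node: TreeNode) -> Alignment:
        if node.is_tip():
            return leaf(node.name)
        children = sorted(node.children, key=_min_tip_name)
        current = build(children[0])
        for child in children[1:]:
            current, _ = _merge_profiles(current, build(child), matrix,
                                         gap_open, gap_extend)
        return current

    return build(guide)


def _min_tip_name(node: TreeNode) -> str:
    if node.is_tip():
        return node.name
    return min(tip.name for tip in node.tips())


def poisson_distance(alignment: Alignment) -> DistanceMatrix:
    """Poisson-corrected pairwise distances with pairwise gap deletion.

    For each pair, p is the mismatch fraction over columns where neither row
    has a gap and d = −ln(1 − p), capped at 5.0.  A pair with zero
    comparable columns raises ``ValueError`` naming the pair.
    """
    rows = [np.frombuffer(row.encode(), dtype="S1") for row in alignment.rows]
    gaps = [row == GAP.encode() for row in rows]
    n = len(rows)
    data = np.zeros((n, n))
    p_cap = 1.0 - math.exp(-POISSON_CAP)
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~(gaps[i] | gaps[j])
            total = int(usable.sum())
            if total == 0:
                raise ValueError(
                    f"no comparable columns between {alignment.ids[i]!r} "
                    f"and {alignment.ids[j]!r}")
            p = float((rows[i][usable] != rows[j][usable]).sum()) / total
            d = POISSON_CAP if p >= p_cap else -math.log(1.0 - p)
            data[i, j] = data[j, i] = d
    return DistanceMatrix(data, list(alignment.ids))


def _clamp(x: float) -> float:
    return x if x > 0 else 0.0


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Standard neighbor joining; exact on additive matrices.

    Ties in the Q criterion are broken by the lexicographically smallest
    (cluster, cluster) label pair, where a cluster is labeled by its smallest
    leaf.  Negative branch-length estimates are clamped to zero.  The result
    is unrooted (trifurcating root).
    """
    labels = list(dm.ids)
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            dist[(a, b)] = float(dm[i, j])
    nodes: dict[str, TreeNode] = {lab: TreeNode(name=lab) for lab in labels}
    active = sorted(labels)

    def d(a: str, b: str) -> float:
        return 0.0 if a == b else dist[(a, b)] if (a, b) in dist else dist[(b, a)]

    while len(active) > 3:
        r = len(active)
        sums = {a: sum(d(a, b) for b in active) for a in active}
        best = None
        for x in range(len(active)):
            for y in range(x + 1, len(active)):
                a, b = active[x], active[y]
                q = (r - 2) * d(a, b) - sums[a] - sums[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = d(a, b)
        la = 0.5 * dab + (sums[a] - sums[b]) / (2.0 * (r - 2))
        lb = dab - la
        la, lb = (la if la > 0 else 0.0), (lb if lb > 0 else 0.0)
        child_a, child_b = nodes.pop(a), nodes.pop(b)
        child_a.length = la
        child_b.length = lb
        new_label = min(a, b)
        merged = TreeNode(children=[child_a, child_b])
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d(a, c) + d(b, c) - dab)
            dist[(new_label, c)] = max(duc, 0.0)
            dist[(c, new_label)] = dist[(new_label, c)]
        active = sorted([c for c in active if c not in (a, b)] + [new_label])
        nodes[new_label] = merged

    a, b, c = active
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    nodes[a].length = _clamp(0.5 * (d(a, b) + d(a, c) - d(b, c)))
    nodes[b].length = _clamp(0.5 * (d(a, b) + d(b, c) - d(a, c)))
    nodes[c].length = _clamp(0.5 * (d(a, c) + d(b, c) - d(a, b)))
    return root


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized to the
    side not containing the lexicographically smallest leaf."""
    leaves = frozenset(tip.name for tip in tree.tips())
    anchor = min(leaves)
    out: set[frozenset[str]] = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(tip.name for tip in node.tips())
        if anchor in side:
            side = leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out.add(side)
    return out


def is_monophyletic(tree: TreeNode, label_set: Iterable[str]) -> bool:
    """True iff some edge of the unrooted tree separates exactly *label_set*
    from the rest.  Singletons (and their complements) are trivially true."""
    labels = frozenset(label_set)
    leaves = frozenset(tip.name for tip in tree.tips())
    unknown = labels - leaves
    if unknown:
        raise ValueError(f"unknown leaf labels: {sorted(unknown)}")
    if not (1 <= len(labels) < len(leaves)):
        raise ValueError("label set must be a proper non-empty subset of leaves")
    if len(labels) == 1 or len(labels) == len(leaves) - 1:
        return True
    anchor = min(leaves)
    canonical = leaves - labels if anchor in labels else labels
    return canonical in bipartitions(tree)


def bootstrap_support(alignment: Alignment, replicates: int, seed: int = 0,
                      ) -> TreeNode:
    """Neighbor-joining tree with bootstrap bipartition supports.

    Columns are resampled with replacement per replicate; the support on each
    internal edge of the full-data tree is the count of replicates whose tree
    contains the same bipartition.  Deterministic given the seed.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    tree = neighbor_joining(poisson_distance(alignment))
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    n_cols = alignment.n_cols
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rows = tuple("".join(row[c] for c in cols) for row in alignment.rows)
        resampled = Alignment(alignment.ids, rows)
        try:
            rep_tree = neighbor_joining(poisson_distance(resampled))
        except ValueError:  # a pair lost all comparable columns
            continue
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1

    leaves = frozenset(tip.name for tip in tree.tips())
    anchor = min(leaves)
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = frozenset(tip.name for tip in node.tips())
        if anchor in side:
            side = leaves - side
        if side in counts:
            node.name = str(counts[side])
    return tree


def alignment_distance(a: ProteinRecord | str, b: ProteinRecord | str) -> float:
    """Poisson-corrected distance from a global pairwise alignment."""
    seq_a = a.residues if isinstance(a, ProteinRecord) else a
    seq_b = b.residues if isinstance(b, ProteinRecord) else b
    alignment, _ = pairwise_align(ProteinRecord("__q__", seq_a),
                                  ProteinRecord("__r__", seq_b))
    return float(poisson_distance(alignment)[0, 1])


def closer_to_group(query: ProteinRecord | str,
                    dtc_refs: Sequence[ProteinRecord | str],
                    shc_refs: Sequence[ProteinRecord | str],
                    distance_fn: Callable[[ProteinRecord | str, ProteinRecord | str], float] | None = None,
                    ) -> str:
    """Relatedness filter for γβ-didomain proteins.

    Returns ``"DTC_LIKE"`` iff the mean distance to the diterpene-cyclase
    references is strictly smaller than the mean distance to the
    squalene–hopene-cyclase references; ties are resolved to ``"SHC_LIKE"``
    (conservative removal from the DTC dataset).
    """
    if not dtc_refs or not shc_refs:
        raise ValueError("both reference sets must be non-empty")
    distance_fn = distance_fn or alignment_distance
    mean_dtc = sum(distance_fn(query, ref) for ref in dtc_refs) / len(dtc_refs)
    mean_shc = sum(distance_fn(query, ref) for ref in shc_refs) / len(shc_refs)
    return "DTC_LIKE" if mean_dtc < mean_shc else "SHC_LIKE"
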