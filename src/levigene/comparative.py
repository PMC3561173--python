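"""Pairwise identity, UPGMA trees and bootstrap supports.

The comparative stage mirrors how small-phage genome papers summarize
relatedness: global protein/RNA alignments reported as percent identity,
and rooted ultrametric trees built by UPGMA from distance matrices, with
clade confidence from column-resampling bootstrap (500 replicates by
default).  The multiple aligner is a deterministic progressive aligner
(identity-distance guide tree, profile-profile merge) — adequate for the
closely controlled synthetic families this package is validated on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from Bio.Align import substitution_matrices

NEG_INF = float("-inf")


# ---------------------------------------------------------------------------
# scoring parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignParams:
    """Substitution scoring + affine gap costs.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (both
    negative).  ``identity_denominator`` selects the percent-identity
    convention: all alignment columns ("columns", default) or the shorter
    ungapped sequence length ("shorter").
    """

    score: Callable[[str, str], float]
    gap_open: float
    gap_extend: float
    alphabet: str = "protein"
    identity_denominator: str = "columns"


def _blosum62() -> Callable[[str, str], float]:
    mat = substitution_matrices.load("BLOSUM62")
    def s(a: str, b: str) -> float:
        return float(mat[a, b])
    return s


def protein_params(identity_denominator: str = "columns") -> AlignParams:
    return AlignParams(_blosum62(), -11.0, -1.0, "protein", identity_denominator)


def rna_params(identity_denominator: str = "columns") -> AlignParams:
    def s(a: str, b: str) -> float:
        return 2.0 if a == b else -1.0
    return AlignParams(s, -5.0, -2.0, "rna", identity_denominator)


# ---------------------------------------------------------------------------
# pairwise global alignment (Needleman-Wunsch / Gotoh affine)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: float
    n_identical: int
    n_columns: int
    identity_pct: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned rows differ in length")


def global_align(a: str, b: str, params: AlignParams) -> PairwiseAlignment:
    """Optimal global alignment under affine gaps (Gotoh's algorithm).

    Deterministic tie-break in the traceback: prefer the diagonal move,
    then the vertical (gap in *b*), then the horizontal.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    for ch in set(a) | set(b):
        try:
            params.score(ch, ch)
        except (KeyError, IndexError) as exc:
            raise ValueError(
                f"alphabet mismatch: {ch!r} not scorable by the substitution table"
            ) from exc
    n, m = len(a), len(b)
    go, ge = params.gap_open, params.gap_extend
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)  # gap in b (consumes a)
    Y = np.full((n + 1, m + 1), NEG_INF)  # gap in a (consumes b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = params.score(ai, b[j - 1])
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)
    score = max(M[n, m], X[n, m], Y[n, m])

    # traceback, diagonal > up > left
    ra: list[str] = []
    rb: list[str] = []
    i, j = n, m
    state = max((("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m])),
                key=lambda t: (t[1], t[0] == "M", t[0] == "X"))[0]
    eps = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            s = params.score(a[i - 1], b[j - 1])
            target = M[i, j] - s
            if abs(M[i - 1, j - 1] - target) < eps:
                nxt = "M"
            elif abs(X[i - 1, j - 1] - target) < eps:
                nxt = "X"
            else:
                nxt = "Y"
            ra.append(a[i - 1])
            rb.append(b[j - 1])
            i, j = i - 1, j - 1
            state = nxt
        elif state == "X":
            if i > 1 or j > 0:
                if abs(M[i - 1, j] + go - X[i, j]) < eps:
                    nxt = "M"
                elif abs(X[i - 1, j] + ge - X[i, j]) < eps:
                    nxt = "X"
                else:
                    nxt = "Y"
            else:
                nxt = "X"
            ra.append(a[i - 1])
            rb.append("-")
            i -= 1
            state = nxt if i > 0 or j > 0 else "M"
        else:  # Y
            if j > 1 or i > 0:
                if abs(M[i, j - 1] + go - Y[i, j]) < eps:
                    nxt = "M"
                elif abs(X[i, j - 1] + go - Y[i, j]) < eps:
                    nxt = "X"
                else:
                    nxt = "Y"
            else:
                nxt = "Y"
            ra.append("-")
            rb.append(b[j - 1])
            j -= 1
            state = nxt if i > 0 or j > 0 else "M"
    aligned_a = "".join(reversed(ra))
    aligned_b = "".join(reversed(rb))
    return _finish_alignment(aligned_a, aligned_b, float(score), params)


def _finish_alignment(
    aligned_a: str, aligned_b: str, score: float, params: AlignParams
) -> PairwiseAlignment:
    n_cols = len(aligned_a)
    n_id = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    if params.identity_denominator == "shorter":
        denom = min(
            len(aligned_a.replace("-", "")), len(aligned_b.replace("-", ""))
        )
    else:
        denom = n_cols
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=score,
        n_identical=n_id,
        n_columns=n_cols,
        identity_pct=100.0 * n_id / denom,
    )


# ---------------------------------------------------------------------------
# distance matrices
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if np.isnan(self.d).any() or (self.d < 0).any():
            raise ValueError("distances must be finite and non-negative")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("self-distances must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def to_tsv(self) -> str:
        lines = ["\t".join([""] + self.labels)]
        for lab, row in zip(self.labels, self.d):
            lines.append("\t".join([lab] + [f"{x:.6f}" for x in row]))
        return "\n".join(lines) + "\n"


def identity_matrix(
    seqs: Sequence[str],
    labels: Sequence[str] | None = None,
    params: AlignParams | None = None,
) -> DistanceMatrix:
    """d[i][j] = 1 - identity_pct(i, j) / 100, aligning each unordered pair
    once so the matrix is symmetric by construction."""
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    params = params or protein_params()
    labels = list(labels) if labels else [f"seq{i + 1}" for i in range(len(seqs))]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                aln = global_align(seqs[i], seqs[j], params)
            except ValueError as exc:
                raise ValueError(f"pair ({i}, {j}): {exc}") from exc
            d[i, j] = d[j, i] = 1.0 - aln.identity_pct / 100.0
    return DistanceMatrix(labels, d)


def p_distance_matrix(
    alignment: Sequence[tuple[str, str]]
) -> DistanceMatrix:
    """Pairwise p-distances (fraction of differing columns, pairwise
    deletion of gapped columns) from an equal-length alignment."""
    labels = [lab for lab, _ in alignment]
    rows = [seq for _, seq in alignment]
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("ragged alignment")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = diff = 0
            for x, y in zip(rows[i], rows[j]):
                if x == "-" or y == "-":
                    continue
                valid += 1
                if x != y:
                    diff += 1
            d[i, j] = d[j, i] = diff / valid if valid else 0.0
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# UPGMA and bootstrap
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    """Rooted ultrametric tree node; height in distance units above leaves."""

    name: Optional[str] = None
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0
    support: Optional[float] = None  # percent, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset[str]:
        return frozenset(l.name for l in self.leaves())

    def internal_nodes(self) -> list["TreeNode"]:
        if self.is_leaf:
            return []
        out = [self]
        for c in self.children:
            out.extend(c.internal_nodes())
        return out

    def clades(self) -> set[frozenset[str]]:
        """Leaf-label sets of all internal nodes (including the root)."""
        return {nd.leaf_names() for nd in self.internal_nodes()}

    def newick(self, with_support: bool = True) -> str:
        def fmt(node: TreeNode, parent_height: Optional[float]) -> str:
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c, node.height) for c in node.children)
                label = ""
                if with_support and node.support is not None:
                    label = f"{node.support:g}"
                body = f"({inner}){label}"
            if parent_height is None:
                return body
            return f"{body}:{parent_height - node.height:.6f}"

        return fmt(self, None) + ";"

    def cophenetic(self) -> DistanceMatrix:
        """Pairwise cophenetic distances (2 x height of the MRCA)."""
        labels = sorted(self.leaf_names())
        idx = {l: i for i, l in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> frozenset[str]:
            if node.is_leaf:
                return frozenset([node.name])
            sets = [walk(c) for c in node.children]
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    for x in sets[a]:
                        for y in sets[b]:
                            d[idx[x], idx[y]] = d[idx[y], idx[x]] = 2 * node.height
            return frozenset().union(*sets)

        walk(self)
        return DistanceMatrix(labels, d)


def upgma(dm: DistanceMatrix) -> TreeNode:
    """UPGMA agglomeration: arithmetic-mean linkage with cluster-size
    weighting; node height = merge distance / 2 (ultrametric by
    construction).  Ties are broken by smallest cluster indices."""
    if dm.n < 2:
        raise ValueError("need at least 2 taxa")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=lab) for i, lab in enumerate(dm.labels)
    }
    sizes = {i: 1 for i in nodes}
    dist: dict[tuple[int, int], float] = {}
    for i in range(dm.n):
        for j in range(i + 1, dm.n):
            dist[(i, j)] = float(dm.d[i, j])
    next_id = dm.n
    while len(nodes) > 1:
        (i, j), dmin = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        new = TreeNode(children=[nodes[i], nodes[j]], height=dmin / 2.0)
        ni, nj = sizes[i], sizes[j]
        del nodes[i], nodes[j], sizes[i], sizes[j]
        for k in list(nodes):
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            dnew = (ni * dist[a] + nj * dist[b]) / (ni + nj)
            del dist[a], dist[b]
            dist[(min(k, next_id), max(k, next_id))] = dnew
        del dist[(i, j)]
        nodes[next_id] = new
        sizes[next_id] = ni + nj
        next_id += 1
    return next(iter(nodes.values()))


def bootstrap_tree(
    alignment: Sequence[tuple[str, str]],
    n_reps: int = 500,
    seed: int = 0,
) -> TreeNode:
    """UPGMA tree from p-distances with column-bootstrap clade supports.

    Columns are resampled with replacement ``n_reps`` times (replicate r
    draws from an RNG substream derived from (seed, r), so supports are
    reproducible and independent of evaluation order); the support of each
    internal node of the full-data tree is the percentage of replicate
    trees containing its leaf set.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    labels = [lab for lab, _ in alignment]
    rows = [seq for _, seq in alignment]
    L = len(rows[0])
    if any(len(r) != L for r in rows):
        raise ValueError("ragged alignment")
    main = upgma(p_distance_matrix(alignment))
    counts: dict[frozenset[str], int] = {c: 0 for c in main.clades()}
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        cols = rng.integers(0, L, size=L)
        rep_rows = ["".join(row[c] for c in cols) for row in rows]
        rep_tree = upgma(p_distance_matrix(list(zip(labels, rep_rows))))
        for clade in rep_tree.clades():
            if clade in counts:
                counts[clade] += 1
    for node in main.internal_nodes():
        node.support = 100.0 * counts[node.leaf_names()] / n_reps
    return main


# ---------------------------------------------------------------------------
# progressive multiple alignment
# ---------------------------------------------------------------------------

def align_multi(
    seqs: Sequence[str],
    labels: Sequence[str] | None = None,
    params: AlignParams | None = None,
) -> list[tuple[str, str]]:
    """Progressive multiple alignment.

    Pairwise identity distances build a UPGMA guide tree; profiles are then
    merged post-order with a profile-profile Needleman-Wunsch using the
    mean pairwise column score.  Fully deterministic.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    params = params or protein_params()
    labels = list(labels) if labels else [f"seq{i + 1}" for i in range(len(seqs))]
    guide = upgma(identity_matrix(seqs, labels, params))
    by_label = dict(zip(labels, seqs))

    def merge(node: TreeNode) -> list[tuple[str, str]]:
        if node.is_leaf:
            return [(node.name, by_label[node.name])]
        prof = merge(node.children[0])
        for child in node.children[1:]:
            prof = _align_profiles(prof, merge(child), params)
        return prof

    aligned = merge(guide)
    order = {lab: i for i, lab in enumerate(labels)}
    aligned.sort(key=lambda t: order[t[0]])
    return aligned


def _col_score(ca: Sequence[str], cb: Sequence[str], params: AlignParams) -> float:
    total = 0.0
    count = 0
    for x in ca:
        if x == "-":
            continue
        for y in cb:
            if y == "-":
                continue
            total += params.score(x, y)
            count += 1
    return total / count if count else 0.0


def _align_profiles(
    pa: list[tuple[str, str]], pb: list[tuple[str, str]], params: AlignParams
) -> list[tuple[str, str]]:
    rows_a = [s for _, s in pa]
    rows_b = [s for _, s in pb]
    cols_a = ["".join(r[i] for r in rows_a) for i in range(len(rows_a[0]))]
    cols_b = ["".join(r[i] for r in rows_b) for i in range(len(rows_b[0]))]
    n, m = len(cols_a), len(cols_b)
    go, ge = params.gap_open, params.gap_extend
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Y[0, j] = go + (j - 1) * ge
    S = np.zeros((n, m))
    for i in range(n):
        for j in range(m):
            S[i, j] = _col_score(cols_a[i], cols_b[j], params)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = S[i - 1, j - 1]
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] + go, X[i - 1, j] + ge, Y[i - 1, j] + go)
            Y[i, j] = max(M[i, j - 1] + go, X[i, j - 1] + go, Y[i, j - 1] + ge)
    # traceback (diagonal > up > left)
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    state = max((("M", M[n, m]), ("X", X[n, m]), ("Y", Y[n, m])),
                key=lambda t: (t[1], t[0] == "M", t[0] == "X"))[0]
    eps = 1e-9
    gap_a = "-" * len(rows_a)
    gap_b = "-" * len(rows_b)
    while i > 0 or j > 0:
        if state == "M" and i > 0 and j > 0:
            target = M[i, j] - S[i - 1, j - 1]
            if abs(M[i - 1, j - 1] - target) < eps:
                state_next = "M"
            elif abs(X[i - 1, j - 1] - target) < eps:
                state_next = "X"
            else:
                state_next = "Y"
            out_a.append(cols_a[i - 1])
            out_b.append(cols_b[j - 1])
            i, j = i - 1, j - 1
            state = state_next
        elif state == "X" and i > 0:
            if abs(M[i - 1, j] + go - X[i, j]) < eps:
                state_next = "M"
            elif abs(X[i - 1, j] + ge - X[i, j]) < eps:
                state_next = "X"
            else:
                state_next = "Y"
            out_a.append(cols_a[i - 1])
            out_b.append(gap_b)
            i -= 1
            state = state_next if i > 0 or j > 0 else "M"
        else:
            if abs(M[i, j - 1] + go - Y[i, j]) < eps:
                state_next = "M"
            elif abs(X[i, j - 1] + go - Y[i, j]) < eps:
                state_next = "X"
            else:
                state_next = "Y"
            out_a.append(gap_a)
            out_b.append(cols_b[j - 1])
            j -= 1
            state = state_next if i > 0 or j > 0 else "M"
    out_a.reverse()
    out_b.reverse()
    labels_a = [lab for lab, _ in pa]
    labels_b = [lab for lab, _ in pb]
    merged: list[tuple[str, str]] = []
    for r, lab in enumerate(labels_a):
        merged.append((lab, "".join(col[r] for col in out_a)))
    for r, lab in enumerate(labels_b):
        merged.append((lab, "".join(col[r] for col in out_b)))
    return merged
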