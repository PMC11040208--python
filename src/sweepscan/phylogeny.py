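"""Protein p-distances, Saitou–Nei neighbor joining and bootstrap supports.

Distances default to the proportion of differing residues with pairwise
deletion of gapped columns (the quick protein NJ default of common tree
software); a Poisson correction ``−ln(1 − p)`` is available behind a
flag.  NJ joins the pair minimising

    Q(i,j) = (r − 2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k)

with ties broken by the lowest (i, j) index pair for determinism, and
branch lengths from the standard NJ formulas with negatives clamped to
zero.  NJ is exact on additive matrices.  Bootstrap supports are the
fraction of column-resampled replicate trees containing each internal
bipartition of the original tree, compared as label sets so taxa input
order is irrelevant.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

GAP = "-"


@dataclass
class ProteinAlignment:
    """Aligned residue strings (gaps '-'), all the same length."""

    names: list[str]
    matrix: np.ndarray  # (n_seqs, n_cols) of single characters

    @classmethod
    def from_dict(cls, seqs: dict[str, str]) -> "ProteinAlignment":
        if not seqs:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in seqs.values()}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must all have equal length")
        if lengths == {0}:
            raise ValueError("alignment length must be >= 1")
        names = list(seqs)
        matrix = np.array([list(seqs[n]) for n in names], dtype="U1")
        return cls(names, matrix)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ProteinAlignment":
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls.from_dict(seqs)

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def resample_columns(self, rng: np.random.Generator) -> "ProteinAlignment":
        cols = rng.integers(0, self.n_columns, self.n_columns)
        return ProteinAlignment(list(self.names), self.matrix[:, cols])


@dataclass
class DistanceMatrix:
    names: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.names),) * 2:
            raise ValueError("matrix shape does not match taxa count")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(m), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        if (m < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.matrix = m


class TreeNode:
    """Minimal rooted representation of an unrooted tree (the root is the
    final trifurcation of NJ)."""

    __slots__ = ("name", "children", "branch_length", "support")

    def __init__(self, name: str | None = None,
                 children: list["TreeNode"] | None = None,
                 branch_length: float | None = None) -> None:
        self.name = name
        self.children = children or []
        self.branch_length = branch_length
        self.support: float | None = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits as canonical label sets (the side NOT
        containing the lexicographically smallest taxon)."""
        all_leaves = set(self.leaves())
        ref = min(all_leaves)
        out = set()
        for node in self.walk():
            if node is self or node.is_leaf():
                continue
            side = set(node.leaves())
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(frozenset(side))
        return out

    def newick(self, with_support: bool = False) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = ""
                if with_support and node.support is not None:
                    label = str(int(round(100 * node.support)))
                body = f"({inner}){label}"
            if node.branch_length is not None:
                body += f":{node.branch_length:.6g}"
            return body

        return fmt(self) + ";"


@dataclass
class DistanceTreeBundle:
    """NJ tree with bootstrap supports on its internal edges."""

    tree: TreeNode
    distances: DistanceMatrix
    supports: dict[frozenset[str], float]
    n_replicates: int
    n_dropped: int = 0


# ---------------------------------------------------------------------------


def p_distance(aln: ProteinAlignment, poisson: bool = False) -> DistanceMatrix:
    """Pairwise proportion of differing residues, deleting columns where
    either sequence has a gap.  ``poisson=True`` applies −ln(1 − p)."""
    n = len(aln)
    if n < 2:
        raise ValueError("need >= 2 sequences")
    ungapped = aln.matrix != GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = ungapped[i] & ungapped[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {aln.names[i]} and {aln.names[j]}"
                )
            p = float(np.sum(aln.matrix[i, both] != aln.matrix[j, both])) / m
            if poisson:
                if p >= 1.0:
                    raise ValueError("Poisson correction undefined at p = 1")
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(list(aln.names), d)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou–Nei NJ; exact (topology and lengths) on additive matrices.

    The final three lineages are joined at an unresolved root, giving
    the conventional unrooted (trifurcating) tree.
    """
    n = len(dm.names)
    if n < 3:
        raise ValueError("NJ needs >= 3 taxa")
    d = dm.matrix.copy()
    nodes: list[TreeNode] = [TreeNode(name) for name in dm.names]

    def clamp(x: float) -> float:
        if x < 0:
            logger.debug("negative branch length %.3g clamped to 0", x)
            return 0.0
        return x

    while len(nodes) > 3:
        r = len(nodes)
        row_sums = d.sum(axis=1)
        q = (r - 2) * d - row_sums[:, None] - row_sums[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) among minimisers: lexicographic over the upper triangle
        q_upper = np.where(np.triu(np.ones_like(q, dtype=bool), 1), q, np.inf)
        i, j = np.unravel_index(np.argmin(q_upper), q.shape)
        li = 0.5 * d[i, j] + (row_sums[i] - row_sums[j]) / (2 * (r - 2))
        lj = d[i, j] - li
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].branch_length = clamp(li)
        nodes[j].branch_length = clamp(lj)
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(r) if k not in (i, j)]
        d = np.pad(d[np.ix_(keep, keep)], ((0, 1), (0, 1)))
        d[-1, :-1] = d[:-1, -1] = new_d[keep]
        nodes = [nodes[k] for k in keep] + [parent]

    # root as trifurcation: the three-point formulas
    d01, d02, d12 = d[0, 1], d[0, 2], d[1, 2]
    l0 = 0.5 * (d01 + d02 - d12)
    l1 = 0.5 * (d01 + d12 - d02)
    l2 = 0.5 * (d02 + d12 - d01)
    root = TreeNode(children=list(nodes))
    for node, length in zip(nodes, (l0, l1, l2)):
        node.branch_length = clamp(length)
    return root


def bootstrap_support(aln: ProteinAlignment, B: int = 1000, seed: int = 0,
                      poisson: bool = False) -> DistanceTreeBundle:
    """NJ tree from the full alignment plus bootstrap supports.

    Each replicate resamples alignment columns with replacement, rebuilds
    the tree, and the support of an internal edge of the original tree is
    the fraction of replicate trees containing the same bipartition.
    Replicates where some pair has no comparable columns are dropped and
    logged.  Deterministic under a fixed seed.
    """
    dm = p_distance(aln, poisson=poisson)
    tree = neighbor_joining(dm)
    splits = tree.bipartitions()
    if B == 0:
        warnings.warn("B=0: tree has no bootstrap supports", stacklevel=2)
        return DistanceTreeBundle(tree, dm, {}, 0)

    rng = np.random.default_rng(seed)
    tally = {s: 0 for s in splits}
    dropped = 0
    used = 0
    for _ in range(B):
        rep = aln.resample_columns(rng)
        try:
            rep_dm = p_distance(rep, poisson=poisson)
        except ValueError:
            dropped += 1
            continue
        rep_splits = neighbor_joining(rep_dm).bipartitions()
        used += 1
        for s in splits:
            if s in rep_splits:
                tally[s] += 1
    if dropped:
        logger.info("dropped %d bootstrap replicates with incomputable distances", dropped)
    supports = {s: (tally[s] / used if used else float("nan")) for s in splits}

    # annotate internal nodes for Newick output
    all_leaves = set(tree.leaves())
    ref = min(all_leaves)
    for node in tree.walk():
        if node is tree or node.is_leaf():
            continue
        side = set(node.leaves())
        key = frozenset(all_leaves - side if ref in side else side)
        if key in supports:
            node.support = supports[key]
    return DistanceTreeBundle(tree, dm, supports, used, dropped)
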