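"""Shared fixtures and independent oracles.

The oracles here deliberately take the slow, enumerate-everything route
(pairwise Hamming distances, exhaustive label splits, path lengths on a
reference tree) so they stay independent of the vectorised
implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from sweepscan.io import MISSING, GeneModel, PopulationPanel, VariantRecord, VariantTable


# ---------------------------------------------------------------------------
# oracles


def hamming_window_pi_oracle(genotypes: np.ndarray, window_length: int) -> float:
    """Brute-force window π: per site, enumerate every pair of *called*
    alleles and count differing pairs; sum over sites and divide by
    window length.  ``genotypes`` is (n_sites, n_samples, 2) allele
    indices with -1 for missing."""
    total = 0.0
    for site in genotypes:
        alleles = site.reshape(-1)
        alleles = alleles[alleles >= 0]
        n = len(alleles)
        if n < 2:
            continue
        diff = sum(
            1 for a, b in itertools.combinations(alleles, 2) if a != b
        )
        total += diff / (n * (n - 1) / 2)
    return total / window_length


def anova_f_oracle(groups: list[list[float]]) -> float:
    """One-way F from first principles (explicit sums of squares)."""
    all_vals = [v for g in groups for v in g]
    n, k = len(all_vals), len(groups)
    grand = sum(all_vals) / n
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    return (ssb / (k - 1)) / (ssw / (n - k))


def exhaustive_two_group_pvalue(values: list[float], n1: int) -> float:
    """Exact permutation p-value for a two-group comparison: enumerate
    every split of the observations into groups of size n1 and n−n1."""
    idx = range(len(values))
    obs = anova_f_oracle([list(values[:n1]), list(values[n1:])])
    count = total = 0
    for combo in itertools.combinations(idx, n1):
        g1 = [values[i] for i in combo]
        g2 = [values[i] for i in idx if i not in combo]
        total += 1
        if anova_f_oracle([g1, g2]) >= obs - 1e-12:
            count += 1
    return count / total


class ReferenceTree:
    """Random binary tree on named leaves with positive branch lengths;
    yields additive distances by summing path lengths edge by edge."""

    def __init__(self, n_taxa: int, rng: np.random.Generator):
        self.names = [f"t{i}" for i in range(n_taxa)]
        # adjacency: node -> {neighbor: length}; leaves are names, internal
        # nodes ints
        self.adj: dict = {self.names[0]: {}, self.names[1]: {}, self.names[2]: {}}
        centre = 0
        self.adj[centre] = {}
        self._next_internal = 1
        for leaf in self.names[:3]:
            self._connect(centre, leaf, self._blen(rng))
        for leaf in self.names[3:]:
            edge = self._random_edge(rng)
            self._attach(leaf, edge, rng)

    def _blen(self, rng):
        return float(rng.uniform(0.1, 1.0))

    def _connect(self, a, b, length):
        self.adj.setdefault(a, {})[b] = length
        self.adj.setdefault(b, {})[a] = length

    def _random_edge(self, rng):
        edges = []
        for a, nbrs in self.adj.items():
            for b in nbrs:
                if str(a) < str(b):
                    edges.append((a, b))
        return edges[rng.integers(0, len(edges))]

    def _attach(self, leaf, edge, rng):
        a, b = edge
        old = self.adj[a].pop(b)
        self.adj[b].pop(a)
        mid = self._next_internal
        self._next_internal += 1
        split = float(rng.uniform(0.2, 0.8)) * old
        self._connect(a, mid, split)
        self._connect(mid, b, old - split)
        self._connect(mid, leaf, self._blen(rng))

    def distance_matrix(self) -> np.ndarray:
        n = len(self.names)
        d = np.zeros((n, n))
        for i, src in enumerate(self.names):
            dist = {src: 0.0}
            stack = [src]
            while stack:
                u = stack.pop()
                for v, w in self.adj[u].items():
                    if v not in dist:
                        dist[v] = dist[u] + w
                        stack.append(v)
            for j, dst in enumerate(self.names):
                d[i, j] = dist[dst]
        return (d + d.T) / 2  # exact symmetry despite float summation order

    def bipartitions(self) -> set[frozenset]:
        leaves = set(self.names)
        ref = min(leaves)
        out = set()
        for a, nbrs in self.adj.items():
            for b in nbrs:
                if not (isinstance(a, int) and isinstance(b, int)):
                    continue
                if not (str(a) < str(b)):
                    continue
                # leaves on b's side of edge (a, b)
                side = set()
                stack = [b]
                seen = {a, b}
                while stack:
                    u = stack.pop()
                    if isinstance(u, str):
                        side.add(u)
                    for v in self.adj[u]:
                        if v not in seen:
                            seen.add(v)
                            stack.append(v)
                if ref in side:
                    side = leaves - side
                if 2 <= len(side) <= len(leaves) - 2:
                    out.add(frozenset(side))
        return out


def tree_leaf_distances(tree, names: list[str]) -> np.ndarray:
    """Pairwise leaf path-length distances of a sweepscan TreeNode."""
    adj: dict = {}

    def build(node, parent_key):
        key = node.name if node.is_leaf() else id(node)
        if parent_key is not None:
            adj.setdefault(parent_key, {})[key] = node.branch_length
            adj.setdefault(key, {})[parent_key] = node.branch_length
        else:
            adj.setdefault(key, {})
        for c in node.children:
            build(c, key)

    build(tree, None)
    n = len(names)
    d = np.zeros((n, n))
    for i, src in enumerate(names):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(names):
            d[i, j] = dist[dst]
    return d


# ---------------------------------------------------------------------------
# random-instance builders


def random_variant_table(rng: np.random.Generator, n_samples: int, n_sites: int,
                         chrom: str = "chr1", span: int = 1000,
                         missing_rate: float = 0.05) -> VariantTable:
    samples = tuple(f"s{i}" for i in range(n_samples))
    positions = np.sort(rng.choice(span, size=n_sites, replace=False)) + 1
    records = []
    for pos in positions:
        geno = rng.integers(0, 2, (n_samples, 2)).astype(np.int16)
        miss = rng.random((n_samples, 2)) < missing_rate
        geno[miss] = MISSING
        records.append(VariantRecord(chrom, int(pos), "A", ("T",), geno))
    return VariantTable(records, samples)


# ---------------------------------------------------------------------------
# file fixtures


TOY_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr8,length=100000>
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta1\ta2\ta3\ta4
chr8\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t./.
chr8\t500\t.\tC\tT,G\t.\tPASS\t.\tGT\t0/0\t1/2\t2/2\t0|1
chr8\t900\t.\tG\tGA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1\t1/1
"""

TOY_VCF_WITH_SV = TOY_VCF + "chr8\t1500\t.\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL\tGT\t0/0\t0/0\t0/0\t0/0\n"


@pytest.fixture
def toy_vcf(tmp_path):
    p = tmp_path / "toy.vcf"
    p.write_text(TOY_VCF)
    return p


@pytest.fixture
def toy_vcf_sv(tmp_path):
    p = tmp_path / "toy_sv.vcf"
    p.write_text(TOY_VCF_WITH_SV)
    return p


@pytest.fixture
def toy_panel(tmp_path):
    p = tmp_path / "panel.tsv"
    p.write_text(
        "a1\tPIM\na2\tPIM\na3\tCER\na4\tCER\na5\tBIG\na6\tBIG\n"
    )
    return p


TOY_GFF = """\
##gff-version 3
chr8\ttest\tgene\t9000\t11000\t.\t+\t.\tID=geneA
chr8\ttest\tmRNA\t9000\t11000\t.\t+\t.\tID=geneA.1;Parent=geneA
chr8\ttest\tCDS\t10000\t10500\t.\t+\t0\tID=geneA.c;Parent=geneA.1
chr8\ttest\tgene\t8500\t10000\t.\t-\t.\tID=geneB
chr8\ttest\tmRNA\t8500\t10000\t.\t-\t.\tID=geneB.1;Parent=geneB
chr8\ttest\tCDS\t9000\t10000\t.\t-\t0\tID=geneB.c;Parent=geneB.1
chr8\ttest\tgene\t20000\t21000\t.\t+\t.\tID=geneC
chr8\ttest\tmRNA\t20000\t21000\t.\t+\t.\tID=geneC.1;Parent=geneC
"""


@pytest.fixture
def toy_gff(tmp_path):
    p = tmp_path / "genes.gff3"
    p.write_text(TOY_GFF)
    return p


def make_gene(strand: str = "+", atg: int = 10001, chrom: str = "chr8",
              span: int = 3000) -> GeneModel:
    if strand == "+":
        return GeneModel("g", chrom, "+", atg, atg + span, atg)
    return GeneModel("g", chrom, "-", atg - span, atg, atg)


def single_site_table(chrom: str, pos: int, ref: str, alt: tuple,
                      genotypes, samples) -> VariantTable:
    rec = VariantRecord(chrom, pos, ref, alt, np.asarray(genotypes, dtype=np.int16))
    return VariantTable([rec], tuple(samples))


@pytest.fixture(scope="session")
def default_sim():
    """One default-config simulation shared across read-only tests."""
    from sweepscan import simulate_dataset

    return simulate_dataset(seed=11)
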