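"""Forward-drift simulator producing panels with the structure the sweep
scan assumes.

The model: ``S`` unlinked segregating sites on one chromosome.  Ancestral
(wild-group) derived-allele frequencies follow the neutral folded SFS,
``P(count = i) ∝ 1/i`` over ``i ∈ {1..2n−1}``.  Domestication and
improvement are serial bottlenecks modelled as ``g`` generations of
Wright–Fisher binomial resampling at drift size ``N`` (``p' =
Binomial(2N, p)/2N``), which erodes heterozygosity by a factor of about
``(1 − 1/2N)^g`` per epoch and can fix or lose alleles — producing the
expected diversity ordering wild > domesticated > improved.  An
improvement sweep is injected by rescaling in-interval heterozygosity in
the improved group only: each frequency moves toward its nearer boundary
so that ``2p'(1−p') = λ·2p(1−p)`` (ties at p = 0.5 move toward 0).

A tag SNP with configured wild-allele frequencies per group, a phenotype
linear in the wild-allele dose, a toy gene model anchored so the tag sits
1903 bp upstream of the ATG, and a toy aligned protein family round out
the fixture.  Sites are independent given their frequencies (no
recombination model); genotypes are two Bernoulli(p) draws per accession.
Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MISSING, GeneModel, PhenotypeTable, PopulationPanel, VariantRecord, VariantTable

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-condition defaults for a desk-scale three-group panel.

    The three groups mirror a wild / domesticated / improved series with
    sample sizes 20/40/60, a 2-Mb chromosome with 4000 segregating
    sites, and a 200-kb improvement sweep retaining λ = 0.05 of
    heterozygosity.  Bottleneck epochs (N = 100 for 60 and 45
    generations) give expected heterozygosity retention ≈ 0.74 and 0.80,
    a moderate genome-wide diversity decline against which the localized
    sweep stands out.  Tag-SNP wild-allele target frequencies decline
    0.90 → 0.45 → 0.10 across groups, and the phenotype (survival rate,
    %) is μ + β·(wild-allele dose) + N(0, σ²) with μ = 40, β = 20,
    σ = 10, clipped to [0, 100].
    """

    chrom: str = "chr8"
    chrom_length: int = 2_000_000
    n_sites: int = 4000
    group_labels: tuple[str, str, str] = ("PIM", "CER", "BIG")
    group_sizes: tuple[int, int, int] = (20, 40, 60)
    bottleneck_n: tuple[int, int] = (100, 100)      # drift size: ->group2, ->group3
    bottleneck_g: tuple[int, int] = (60, 45)        # generations per epoch
    sweep_start: int = 900_000
    sweep_end: int = 1_100_000
    sweep_lambda: float = 0.05
    indel_fraction: float = 0.02
    gene_id: str = "SlSCaBP8"
    gene_atg_pos: int = 1_000_001                   # 1-based, + strand
    gene_end: int = 1_003_500
    tag_upstream_offset: int = 1903                 # tag SNP bp upstream of ATG
    tag_wild_base: str = "G"
    tag_cultivar_base: str = "A"
    tag_wild_freqs: tuple[float, float, float] = (0.90, 0.45, 0.10)
    pheno_mu: float = 40.0
    pheno_beta: float = 20.0
    pheno_sigma: float = 10.0
    seed: int = 7

    def __post_init__(self) -> None:
        if not (0 <= self.sweep_lambda <= 1):
            raise ValueError("sweep_lambda must be in [0, 1]")
        if not (0 <= self.sweep_start < self.sweep_end <= self.chrom_length):
            raise ValueError("sweep interval must lie within [0, chrom_length)")
        if any(not (0 <= f <= 1) for f in self.tag_wild_freqs):
            raise ValueError("tag frequencies must be in [0, 1]")
        if min(self.group_sizes) < 1 or self.n_sites < 1:
            raise ValueError("sizes must be >= 1")

    @property
    def tag_pos(self) -> int:
        """1-based tag-SNP position (upstream of the + strand ATG)."""
        return self.gene_atg_pos - self.tag_upstream_offset


@dataclass
class SimulationResult:
    """In-memory fixture plus the ground truth it realizes."""

    table: VariantTable
    panel: PopulationPanel
    gene: GeneModel
    phenotypes: PhenotypeTable
    alignment: dict[str, str]
    truth: dict
    config: SimulationConfig


# ---------------------------------------------------------------------------


def simulate_base_population(n_sites: int, chrom_length: int, n_diploid: int,
                             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Site positions (0-based, unique, sorted) and ancestral derived-allele
    frequencies drawn from the neutral SFS P(i) ∝ 1/i, i ∈ {1..2n−1}."""
    if n_sites > chrom_length:
        raise ValueError("more sites than base pairs")
    positions = np.sort(rng.choice(chrom_length, size=n_sites, replace=False))
    counts = np.arange(1, 2 * n_diploid)
    weights = 1.0 / counts
    weights /= weights.sum()
    freqs = rng.choice(counts, size=n_sites, p=weights) / (2 * n_diploid)
    return positions, freqs


def apply_bottleneck(freqs: np.ndarray, N: int, g: int,
                     rng: np.random.Generator) -> np.ndarray:
    """``g`` rounds of Wright–Fisher binomial resampling at population size
    ``N`` diploids; fixation and loss are absorbing; g = 0 is identity."""
    if N < 1 or g < 0:
        raise ValueError("need N >= 1 and g >= 0")
    p = np.asarray(freqs, dtype=float).copy()
    for _ in range(g):
        p = rng.binomial(2 * N, p) / (2 * N)
    return p


def inject_sweep(freqs: np.ndarray, positions: np.ndarray, start: int, end: int,
                 lam: float) -> np.ndarray:
    """Scale in-interval heterozygosity by λ, moving each frequency toward
    its nearer boundary (ties at 0.5 toward 0); sites outside untouched."""
    if not (0 <= lam <= 1):
        raise ValueError("lambda must be in [0, 1]")
    p = np.asarray(freqs, dtype=float).copy()
    if lam == 1.0:
        return p
    inside = (positions >= start) & (positions < end)
    h = lam * p[inside] * (1.0 - p[inside])        # target p'(1−p')
    root = np.sqrt(np.maximum(1.0 - 4.0 * h, 0.0))
    lower = 0.5 * (1.0 - root)
    upper = 0.5 * (1.0 + root)
    p[inside] = np.where(p[inside] <= 0.5, lower, upper)
    return p


def _draw_genotypes(freqs: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n_sites, n, 2) allele indices: two Bernoulli(p) draws per accession."""
    return (rng.random((len(freqs), n, 2)) < freqs[:, None, None]).astype(np.int16)


def _random_alleles(n: int, indel_fraction: float,
                    rng: np.random.Generator) -> tuple[list[str], list[str]]:
    refs = BASES[rng.integers(0, 4, n)].tolist()
    alts = []
    is_indel = rng.random(n) < indel_fraction
    for i in range(n):
        if is_indel[i]:
            alts.append(refs[i] + str(BASES[rng.integers(0, 4)]))
        else:
            alts.append(str(BASES[(BASES.tolist().index(refs[i]) + int(rng.integers(1, 4))) % 4]))
    return refs, alts


def simulate_dataset(config: SimulationConfig | None = None,
                     seed: int | None = None) -> SimulationResult:
    """Run the full generative model and return in-memory objects.

    ``seed`` overrides ``config.seed``; a fixed seed gives identical
    output on every platform (single Generator, documented draw order).
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    labels = cfg.group_labels
    sizes = cfg.group_sizes

    positions, p_wild = simulate_base_population(
        cfg.n_sites, cfg.chrom_length, sizes[0], rng
    )
    # the tag site is placed explicitly; collisions are resampled
    tag_pos0 = cfg.tag_pos - 1
    while np.any(positions == tag_pos0):
        idx = int(np.nonzero(positions == tag_pos0)[0][0])
        logger.info("simulated site collides with tag position %d; resampled", cfg.tag_pos)
        replacement = int(rng.integers(0, cfg.chrom_length))
        while replacement == tag_pos0 or np.any(positions == replacement):
            replacement = int(rng.integers(0, cfg.chrom_length))
        positions[idx] = replacement
        order = np.argsort(positions)
        positions, p_wild = positions[order], p_wild[order]

    p_dom = apply_bottleneck(p_wild, cfg.bottleneck_n[0], cfg.bottleneck_g[0], rng)
    p_imp = apply_bottleneck(p_dom, cfg.bottleneck_n[1], cfg.bottleneck_g[1], rng)
    p_imp = inject_sweep(p_imp, positions, cfg.sweep_start, cfg.sweep_end, cfg.sweep_lambda)

    group_freqs = {labels[0]: p_wild, labels[1]: p_dom, labels[2]: p_imp}
    genos = [
        _draw_genotypes(group_freqs[lab], n, rng) for lab, n in zip(labels, sizes)
    ]
    geno_all = np.concatenate(genos, axis=1)  # (S, n_total, 2)

    accessions = [
        f"{lab}{i + 1:03d}" for lab, n in zip(labels, sizes) for i in range(n)
    ]
    panel = PopulationPanel({a: lab for lab, n in zip(labels, sizes)
                             for a in [f"{lab}{i + 1:03d}" for i in range(n)]})

    refs, alts = _random_alleles(cfg.n_sites, cfg.indel_fraction, rng)

    # tag SNP: reference genome is cultivar-derived, so REF is the cultivated
    # base and the wild base is the ALT — classification must key on bases
    tag_wild_dose = np.concatenate([
        (rng.random((n, 2)) < f).astype(np.int16)
        for f, n in zip(cfg.tag_wild_freqs, sizes)
    ])  # (n_total, 2): 1 = wild allele (= ALT index 1)

    records = [
        VariantRecord(cfg.chrom, int(pos) + 1, refs[i], (alts[i],), geno_all[i])
        for i, pos in enumerate(positions)
    ]
    records.append(
        VariantRecord(cfg.chrom, cfg.tag_pos, cfg.tag_cultivar_base,
                      (cfg.tag_wild_base,), tag_wild_dose, id="tagSNP")
    )
    table = VariantTable(records, tuple(accessions))

    gene = GeneModel(
        gene_id=cfg.gene_id, chrom=cfg.chrom, strand="+",
        start=cfg.gene_atg_pos, end=cfg.gene_end,
        cds_start_codon_pos=cfg.gene_atg_pos,
    )

    n_wild = tag_wild_dose.sum(axis=1)
    survival = np.clip(
        cfg.pheno_mu + cfg.pheno_beta * n_wild + rng.normal(0, cfg.pheno_sigma, len(n_wild)),
        0.0, 100.0,
    )
    chlorophyll = 1.0 + 0.25 * n_wild + rng.normal(0, 0.3, len(n_wild))
    pheno = PhenotypeTable(pd.DataFrame(
        {"survival_rate": survival, "chlorophyll_content": chlorophyll},
        index=pd.Index(accessions, name="accession"),
    ))

    alignment = simulate_protein_alignment(rng)

    hap_call = np.where(n_wild == 2, "Hap1", np.where(n_wild == 0, "Hap2", "Het"))
    realized = {
        lab: _realized_freqs(geno, n) for (lab, n), geno in zip(zip(labels, sizes), genos)
    }
    truth = {
        "chrom": cfg.chrom,
        "sweep_interval": [cfg.sweep_start, cfg.sweep_end],
        "positions": (positions + 1).tolist(),
        "realized_alt_freqs": {lab: realized[lab].tolist() for lab in labels},
        "tag_pos": cfg.tag_pos,
        "tag_wild_base": cfg.tag_wild_base,
        "true_haplotype": dict(zip(accessions, hap_call.tolist())),
        "phenotype_mean": {
            a: float(cfg.pheno_mu + cfg.pheno_beta * d)
            for a, d in zip(accessions, n_wild.tolist())
        },
    }
    return SimulationResult(table, panel, gene, pheno, alignment, truth, cfg)


def _realized_freqs(geno: np.ndarray, n: int) -> np.ndarray:
    return geno.reshape(geno.shape[0], -1).mean(axis=1)


# ---------------------------------------------------------------------------
# toy protein family for the phylogeny module


_FAMILY_TAXA = (
    "AtCBL1", "AtCBL4", "AtSCaBP8", "AtCBL10",
    "SlCBL1", "SlCBL4", "SlSCaBP8", "SlCBL10",
)

AMINO = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def simulate_protein_alignment(rng: np.random.Generator, length: int = 150,
                               sub_rate: float = 0.08) -> dict[str, str]:
    """Evolve a calcineurin-B-like-style family down a fixed 8-taxon tree
    by per-branch random substitutions; returns id -> aligned string."""
    root = AMINO[rng.integers(0, 20, length)]

    def mutate(seq: np.ndarray, branch: float) -> np.ndarray:
        seq = seq.copy()
        hits = rng.random(length) < branch * sub_rate
        seq[hits] = AMINO[rng.integers(0, 20, int(hits.sum()))]
        return seq

    # ((At-clade),(Sl-clade)) with paired orthologs: each ortholog pair
    # (AtX, SlX) diverges from a shared subfamily ancestor
    seqs: dict[str, np.ndarray] = {}
    for k in range(4):
        subfamily = mutate(root, 3.0)
        seqs[_FAMILY_TAXA[k]] = mutate(subfamily, 1.0)
        seqs[_FAMILY_TAXA[k + 4]] = mutate(subfamily, 1.0)
    return {name: "".join(seqs[name]) for name in _FAMILY_TAXA}


# ---------------------------------------------------------------------------
# file emission


def _write_vcf(table: VariantTable, chrom_length: int, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = sorted({r.chrom for r in table.records})
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={chrom_length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for r in table.records:
            gts = []
            for a1, a2 in r.genotypes:
                s1 = "." if a1 == MISSING else str(int(a1))
                s2 = "." if a2 == MISSING else str(int(a2))
                gts.append(f"{s1}/{s2}")
            fh.write(
                f"{r.chrom}\t{r.pos}\t{r.id}\t{r.ref}\t{','.join(r.alt)}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def _write_gff3(gene: GeneModel, cds_end: int, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"{gene.chrom}\tsim\tgene\t{gene.start}\t{gene.end}\t.\t{gene.strand}\t.\t"
                 f"ID={gene.gene_id}\n")
        fh.write(f"{gene.chrom}\tsim\tmRNA\t{gene.start}\t{gene.end}\t.\t{gene.strand}\t.\t"
                 f"ID={gene.gene_id}.1;Parent={gene.gene_id}\n")
        if gene.strand == "+":
            c_start, c_end = gene.cds_start_codon_pos, cds_end
        else:
            c_start, c_end = cds_end, gene.cds_start_codon_pos
        fh.write(f"{gene.chrom}\tsim\tCDS\t{c_start}\t{c_end}\t.\t{gene.strand}\t0\t"
                 f"ID={gene.gene_id}.cds;Parent={gene.gene_id}.1\n")


def emit_fixture(config: SimulationConfig | None = None, outdir: str | Path = ".",
                 seed: int | None = None) -> dict[str, Path]:
    """Write the six-file fixture set and return the paths.

    Files: ``variants.vcf``, ``panel.tsv``, ``genes.gff3``,
    ``phenotypes.tsv``, ``alignment.faa``, ``truth.json`` — all plain
    text, byte-identical under a fixed seed.
    """
    cfg = config or SimulationConfig()
    sim = simulate_dataset(cfg, seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "variants.vcf",
        "panel": outdir / "panel.tsv",
        "gff3": outdir / "genes.gff3",
        "phenotypes": outdir / "phenotypes.tsv",
        "alignment": outdir / "alignment.faa",
        "truth": outdir / "truth.json",
    }
    _write_vcf(sim.table, cfg.chrom_length, paths["vcf"])
    with open(paths["panel"], "w") as fh:
        fh.write("accession\tgroup\n")
        for a, g in sim.panel.assignments.items():
            fh.write(f"{a}\t{g}\n")
    _write_gff3(sim.gene, min(cfg.gene_end, cfg.gene_atg_pos + 2999), paths["gff3"])
    sim.phenotypes.data.round(6).to_csv(paths["phenotypes"], sep="\t")
    with open(paths["alignment"], "w") as fh:
        for name, seq in sim.alignment.items():
            fh.write(f">{name}\n{seq}\n")
    with open(paths["truth"], "w") as fh:
        json.dump(sim.truth, fh, indent=1)
        fh.write("\n")
    return paths
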