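"""Promoter variant extraction, tag-SNP haplotype classification and
group-wise phenotype comparison.

The promoter is the strand-aware window immediately upstream of the
first base of the ATG start codon (default 3 kb).  Variant positions are
reported as signed distances ``rel_pos`` relative to the ATG, negative
upstream (a variant 1903 bp upstream of the ATG has rel_pos −1903).
Haplotypes are defined by one tag SNP: accessions homozygous for the
wild base form Hap1, homozygous for the cultivated base Hap2;
heterozygotes and missing calls are reported in their own classes rather
than folded into either haplotype.  Classification keys on nucleotide
identity, never on REF/ALT index, because a cultivar-derived reference
genome can make the wild allele the ALT.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import Window
from .io import (
    MISSING,
    GeneModel,
    PhenotypeTable,
    PopulationPanel,
    VariantRecord,
    VariantTable,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PromoterVariant:
    record: VariantRecord
    rel_pos: int  # signed bp relative to ATG; negative = upstream
    label: str    # SNP1..SNPk / InDel1..InDelm, most-upstream first

    def __post_init__(self) -> None:
        if self.rel_pos >= 0:
            raise ValueError("promoter variants lie strictly upstream of the ATG")


@dataclass
class HaplotypeAssignment:
    """Per-accession haplotype call at a tag SNP."""

    chrom: str
    pos: int
    allele_map: dict[str, str]          # e.g. {"Hap1": "G", "Hap2": "A"}
    calls: dict[str, str]               # accession -> Hap1|Hap2|Het|Missing

    def counts(self) -> dict[str, int]:
        out = {"Hap1": 0, "Hap2": 0, "Het": 0, "Missing": 0}
        for c in self.calls.values():
            out[c] += 1
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"accession": list(self.calls), "haplotype": list(self.calls.values())}
        )


@dataclass
class GroupFrequencyTable:
    """Per-group haplotype counts and fractions (fractions over the
    non-missing classes Hap1/Hap2/Het)."""

    table: pd.DataFrame  # index group; columns n_Hap1, n_Hap2, n_Het, n_Missing, f_*

    def to_dataframe(self) -> pd.DataFrame:
        return self.table.reset_index(names="group")


@dataclass
class GroupComparison:
    """One-way ANOVA F with a permutation p-value."""

    groups: tuple[str, ...]
    n: tuple[int, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    f_stat: float
    p_value: float
    n_perm: int
    seed: int
    measure: str

    def summary(self) -> str:
        lines = [
            f"One-way comparison of {self.measure!r} "
            f"(permutation p from {self.n_perm} shuffles, seed {self.seed})",
            f"{'group':<12}{'n':>5}{'mean':>12}{'sd':>12}",
        ]
        for g, n, m, s in zip(self.groups, self.n, self.means, self.sds):
            lines.append(f"{g:<12}{n:>5}{m:>12.4g}{s:>12.4g}")
        lines.append(f"F = {self.f_stat:.4g}   p = {self.p_value:.4g}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------


def promoter_window(gene: GeneModel, upstream_len: int = 3000,
                    chrom_length: int | None = None) -> Window:
    """Strand-aware 0-based half-open interval immediately upstream of the
    ATG, clipped at the chromosome boundary."""
    if upstream_len < 1:
        raise ValueError("upstream_len must be >= 1")
    atg0 = gene.cds_start_codon_pos - 1
    if gene.strand == "+":
        start, end = max(atg0 - upstream_len, 0), atg0
    else:
        start, end = atg0 + 1, atg0 + 1 + upstream_len
        if chrom_length is not None:
            end = min(end, chrom_length)
    if end <= start:
        raise ValueError("promoter window lies entirely off the chromosome")
    return Window(gene.chrom, start, end)


def extract_promoter_variants(table: VariantTable, gene: GeneModel,
                              upstream_len: int = 3000,
                              chrom_length: int | None = None) -> list[PromoterVariant]:
    """Variants in the promoter window with signed distances to the ATG.

    SNPs are labelled SNP1..SNPk from most-upstream to closest-to-ATG
    (a labelling convention, stable under strand mirroring); InDels are
    labelled InDel1.. separately in the same order.
    """
    win = promoter_window(gene, upstream_len, chrom_length)
    sub = table.subset_region(win.chrom, win.start, win.end)
    entries = []
    for rec in sub.records:
        if gene.strand == "+":
            rel = rec.pos - gene.cds_start_codon_pos
        else:
            rel = gene.cds_start_codon_pos - rec.pos
        entries.append((rel, rec))
    entries.sort(key=lambda t: t[0])
    out: list[PromoterVariant] = []
    n_snp = n_indel = 0
    for rel, rec in entries:
        if rec.vtype == "SNP":
            n_snp += 1
            label = f"SNP{n_snp}"
        else:
            n_indel += 1
            label = f"InDel{n_indel}"
        out.append(PromoterVariant(rec, rel, label))
    return out


def promoter_variants_dataframe(variants: list[PromoterVariant]) -> pd.DataFrame:
    return pd.DataFrame({
        "label": [v.label for v in variants],
        "chrom": [v.record.chrom for v in variants],
        "pos": [v.record.pos for v in variants],
        "rel_pos": [v.rel_pos for v in variants],
        "ref": [v.record.ref for v in variants],
        "alt": [",".join(v.record.alt) for v in variants],
        "type": [v.record.vtype for v in variants],
    })


def classify_haplotypes(table: VariantTable, chrom: str, pos: int,
                        allele_map: dict[str, str]) -> HaplotypeAssignment:
    """Call Hap1/Hap2/Het/Missing per accession at the tag site.

    ``allele_map`` maps haplotype label to its defining base, e.g.
    ``{"Hap1": "G", "Hap2": "A"}``.  Homozygotes for a defining base get
    that haplotype; anything else fully called is Het; any uncalled
    allele is Missing.
    """
    rec = table.find(chrom, pos)
    if rec is None:
        raise ValueError(f"tag site {chrom}:{pos} absent from variant table")
    alleles = rec.alleles
    for hap, base in allele_map.items():
        if base not in alleles:
            raise ValueError(
                f"{hap} base {base!r} not among alleles {alleles} at {chrom}:{pos}"
            )
    base_to_hap = {base: hap for hap, base in allele_map.items()}
    calls: dict[str, str] = {}
    for acc, (a1, a2) in zip(table.samples, rec.genotypes):
        if a1 == MISSING or a2 == MISSING:
            calls[acc] = "Missing"
        elif a1 == a2 and alleles[a1] in base_to_hap:
            calls[acc] = base_to_hap[alleles[a1]]
        else:
            calls[acc] = "Het"
    return HaplotypeAssignment(chrom, pos, dict(allele_map), calls)


def haplotype_distribution(assignment: HaplotypeAssignment,
                           panel: PopulationPanel) -> GroupFrequencyTable:
    """Per-group haplotype counts/fractions; Missing reported separately."""
    shared = set(assignment.calls) & set(panel.assignments)
    if not shared:
        raise ValueError("assignment and panel share no accessions")
    dropped = len(assignment.calls) - len(shared)
    if dropped:
        logger.info("%d classified accessions absent from panel", dropped)
    rows = {}
    classes = ("Hap1", "Hap2", "Het")
    for group in panel.groups:
        members = [a for a in panel.members(group) if a in shared]
        if not members:
            warnings.warn(f"group {group!r} has no classified accessions", stacklevel=2)
        counts = {c: 0 for c in (*classes, "Missing")}
        for a in members:
            counts[assignment.calls[a]] += 1
        total = sum(counts[c] for c in classes)
        row = {f"n_{c}": counts[c] for c in (*classes, "Missing")}
        for c in classes:
            row[f"f_{c}"] = counts[c] / total if total else 0.0
        rows[group] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "group"
    return GroupFrequencyTable(df)


# ---------------------------------------------------------------------------


def _anova_f(values: np.ndarray, sizes: np.ndarray) -> float:
    """One-way F from the sums-of-squares decomposition; ``values`` is
    ordered group-by-group with group lengths ``sizes``."""
    n = values.size
    k = sizes.size
    grand = values.mean()
    sst = float(np.sum((values - grand) ** 2))
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    ssb = 0.0
    for i in range(k):
        seg = values[bounds[i]:bounds[i + 1]]
        ssb += sizes[i] * (seg.mean() - grand) ** 2
    ssw = sst - ssb
    if ssw <= 0 and ssb <= 0:
        raise ValueError("all observations identical; F undefined")
    if ssw <= 0:
        raise ValueError("zero within-group variance; F undefined")
    return float((ssb / (k - 1)) / (ssw / (n - k)))


def compare_groups(pheno: PhenotypeTable, grouping: dict[str, str], measure: str,
                   n_perm: int = 10_000, seed: int = 0) -> GroupComparison:
    """One-way ANOVA across labelled groups with a permutation p-value.

    F is the classic between/within mean-square ratio; p is the fraction
    of label shuffles with F at least as large, with the +1/(n_perm+1)
    correction so p ∈ (0, 1].  Deterministic under a fixed seed.  The
    permutation test supplements the F test because group sizes in panel
    comparisons are typically small and unbalanced.
    """
    by_group: dict[str, list[float]] = {}
    for acc, label in grouping.items():
        if acc in pheno.data.index and pd.notna(pheno.data.at[acc, measure]):
            by_group.setdefault(label, []).append(float(pheno.data.at[acc, measure]))
    by_group = {g: v for g, v in by_group.items() if len(v) >= 2}
    if len(by_group) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    labels = tuple(sorted(by_group))
    sizes = np.array([len(by_group[g]) for g in labels])
    values = np.concatenate([np.asarray(by_group[g], dtype=float) for g in labels])
    f_obs = _anova_f(values, sizes)

    rng = np.random.default_rng(seed)
    n = values.size
    k = sizes.size
    grand = values.mean()
    sst = float(np.sum((values - grand) ** 2))
    bounds = np.concatenate([[0], np.cumsum(sizes)])
    # vectorised label shuffles: permute columns of a (n_perm, n) matrix
    count = 0
    chunk = 2000  # bound peak memory for large n_perm
    remaining = n_perm
    while remaining > 0:
        m = min(chunk, remaining)
        perm = np.argsort(rng.random((m, n)), axis=1)
        shuffled = values[perm]
        ssb = np.zeros(m)
        for i in range(k):
            seg = shuffled[:, bounds[i]:bounds[i + 1]]
            ssb += sizes[i] * (seg.mean(axis=1) - grand) ** 2
        ssw = sst - ssb
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = (ssb / (k - 1)) / (ssw / (n - k))
        f_perm = np.where(ssw <= 0, np.inf, f_perm)
        count += int(np.sum(f_perm >= f_obs - 1e-12))
        remaining -= m
    p = (count + 1) / (n_perm + 1)

    return GroupComparison(
        groups=labels,
        n=tuple(int(s) for s in sizes),
        means=tuple(float(np.mean(by_group[g])) for g in labels),
        sds=tuple(float(np.std(by_group[g], ddof=1)) for g in labels),
        f_stat=f_obs,
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        measure=measure,
    )
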