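"""Readers/writers for the standard formats the pipeline touches and the
shared domain types.

Coordinate convention: VCF and GFF3 are 1-based inclusive on disk; every
internal interval in this package is 0-based half-open.  Conversion
happens only here, at the I/O boundary.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel allele index for uncalled alleles


@dataclass(frozen=True)
class VariantRecord:
    """One variant site with diploid genotypes over the panel.

    ``pos`` is the 1-based reference position as printed in the VCF.
    ``genotypes`` is an ``(n_samples, 2)`` int array of allele indices
    (0 = REF, 1.. = ALT order), with :data:`MISSING` for uncalled
    alleles.  Phase is ignored; every statistic downstream is
    frequency-based.
    """

    chrom: str
    pos: int
    ref: str
    alt: tuple[str, ...]
    genotypes: np.ndarray
    id: str = "."

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or any(not a for a in self.alt):
            raise ValueError("ref and alt alleles must be non-empty")
        g = np.asarray(self.genotypes)
        if g.ndim != 2 or g.shape[1] != 2:
            raise ValueError("genotypes must have shape (n_samples, 2)")
        if g.size and (g.max() > len(self.alt) or g.min() < MISSING):
            raise ValueError("allele index out of range")

    @property
    def vtype(self) -> str:
        """"SNP" unless any allele length differs from REF ("InDel")."""
        if any(len(a) != len(self.ref) for a in self.alt):
            return "InDel"
        return "SNP"

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref, *self.alt)

    def allele_counts(self, sample_idx: Sequence[int] | None = None) -> np.ndarray:
        """Called-allele counts per allele index (REF first)."""
        g = self.genotypes if sample_idx is None else self.genotypes[list(sample_idx)]
        flat = g.reshape(-1)
        called = flat[flat >= 0]
        return np.bincount(called, minlength=len(self.alt) + 1)


@dataclass
class VariantTable:
    """Position-sorted variant records sharing one sample ordering."""

    records: list[VariantRecord]
    samples: tuple[str, ...]

    def __post_init__(self) -> None:
        keys = [(r.chrom, r.pos) for r in self.records]
        if keys != sorted(keys):
            self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos))
        for r in self.records:
            if r.genotypes.shape[0] != len(self.samples):
                raise ValueError(
                    f"record at {r.chrom}:{r.pos} has {r.genotypes.shape[0]} "
                    f"genotypes for {len(self.samples)} samples"
                )

    def __len__(self) -> int:
        return len(self.records)

    def positions(self, chrom: str | None = None) -> np.ndarray:
        """1-based positions, optionally restricted to one chromosome."""
        recs = self.records if chrom is None else [r for r in self.records if r.chrom == chrom]
        return np.array([r.pos for r in recs], dtype=np.int64)

    def subset_region(self, chrom: str, start: int, end: int) -> "VariantTable":
        """Records whose 0-based position falls in half-open [start, end)."""
        recs = [r for r in self.records if r.chrom == chrom and start <= r.pos - 1 < end]
        return VariantTable(recs, self.samples)

    def find(self, chrom: str, pos: int) -> VariantRecord | None:
        for r in self.records:
            if r.chrom == chrom and r.pos == pos:
                return r
        return None

    def sample_index(self, accessions: Iterable[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        return np.array([lookup[a] for a in accessions], dtype=np.intp)


@dataclass
class PopulationPanel:
    """Accession -> population group labels (e.g. PIM/CER/BIG strata)."""

    assignments: dict[str, str]

    @property
    def groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for g in self.assignments.values():
            seen.setdefault(g)
        return tuple(seen)

    def members(self, group: str) -> list[str]:
        return [a for a, g in self.assignments.items() if g == group]

    def intersect(self, samples: Sequence[str]) -> "PopulationPanel":
        """Restrict to accessions present in *samples*; log the dropped."""
        keep = {a: g for a, g in self.assignments.items() if a in set(samples)}
        dropped = len(self.assignments) - len(keep)
        if dropped:
            logger.warning("%d panel accessions absent from variant data", dropped)
        return PopulationPanel(keep)


@dataclass(frozen=True)
class GeneModel:
    """Gene span with the genomic position of the first base of the ATG.

    ``cds_start_codon_pos`` is 1-based: the min CDS start on the + strand,
    the max CDS end on the − strand.  Strand determines which direction is
    upstream.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    cds_start_codon_pos: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (self.start <= self.cds_start_codon_pos <= self.end):
            raise ValueError("cds_start_codon_pos outside gene span")


@dataclass
class PhenotypeTable:
    """Per-accession numeric measurements (e.g. survival rate in %)."""

    data: pd.DataFrame  # index: accession; columns: measures

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            raise ValueError("duplicated accession in phenotype table")
        if "survival_rate" in self.data.columns:
            sr = self.data["survival_rate"].dropna()
            if ((sr < 0) | (sr > 100)).any():
                raise ValueError("survival_rate outside [0, 100]")

    def values_for(self, accessions: Sequence[str], measure: str) -> np.ndarray:
        return self.data.loc[list(accessions), measure].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers


def _parse_region(region: str | tuple[str, int, int]) -> tuple[str, int, int]:
    """Accept "chrom:start-end" (1-based inclusive) or a (chrom, start0, end0)
    half-open tuple; return 0-based half-open."""
    if isinstance(region, tuple):
        return region
    chrom, _, span = region.partition(":")
    if not span:
        return chrom, 0, np.iinfo(np.int64).max
    lo, _, hi = span.partition("-")
    return chrom, int(lo) - 1, int(hi)


def read_vcf(path: str | Path, region: str | tuple[str, int, int] | None = None) -> VariantTable:
    """Read a multi-sample VCF into a :class:`VariantTable`.

    Structural variants (records with an SVTYPE INFO key or a symbolic
    ALT) and records without a GT field are skipped with a logged count.
    The file is scanned linearly — no tabix index is required — so plain
    uncompressed VCF works.  ``region`` uses 1-based inclusive
    "chrom:start-end" coordinates as on the command line of samtools.
    """
    vcf = pysam.VariantFile(str(path))
    samples = tuple(vcf.header.samples)
    want = _parse_region(region) if region is not None else None
    records: list[VariantRecord] = []
    n_skipped_sv = 0
    n_skipped_nogt = 0
    seen_chroms: set[str] = set()
    for rec in vcf:
        seen_chroms.add(rec.chrom)
        if want is not None:
            chrom, start0, end0 = want
            if rec.chrom != chrom or not (start0 <= rec.pos - 1 < end0):
                continue
        if "SVTYPE" in rec.info or any(a is None or a.startswith("<") for a in (rec.alts or ())):
            n_skipped_sv += 1
            continue
        if "GT" not in rec.format or not rec.alts:
            n_skipped_nogt += 1
            continue
        geno = np.full((len(samples), 2), MISSING, dtype=np.int16)
        for i, s in enumerate(samples):
            gt = rec.samples[s].get("GT")
            if gt is None:
                continue
            for j, a in enumerate(gt[:2]):
                if a is not None:
                    geno[i, j] = a
        records.append(
            VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref=rec.ref,
                alt=tuple(rec.alts),
                genotypes=geno,
                id=rec.id or ".",
            )
        )
    if n_skipped_sv:
        logger.info("skipped %d structural-variant records", n_skipped_sv)
    if n_skipped_nogt:
        logger.info("skipped %d records without usable GT/ALT", n_skipped_nogt)
    if want is not None and not records and want[0] not in seen_chroms:
        warnings.warn(f"chromosome {want[0]!r} not present in {path}", stacklevel=2)
    return VariantTable(records, samples)


def read_panel(path: str | Path) -> PopulationPanel:
    """Read a two-column TSV (accession, group); header row optional."""
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            rows.append((parts[0], parts[1]))
    # tolerate a header line like "accession<TAB>group"
    if rows and rows[0][0].lower() in ("accession", "sample", "id", "acc"):
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no assignments")
    assignments: dict[str, str] = {}
    for acc, grp in rows:
        if acc in assignments:
            raise ValueError(f"duplicate accession {acc!r} in panel")
        assignments[acc] = grp
    return PopulationPanel(assignments)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Parse gene + CDS features from a GFF3 into :class:`GeneModel` s.

    The start-codon anchor is the min CDS start (+ strand) or max CDS end
    (− strand).  Genes without any CDS child are skipped with a warning.
    """
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    out: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        cds = list(db.children(gene, featuretype="CDS"))
        if not cds:
            warnings.warn(f"gene {gene.id} has no CDS; skipped", stacklevel=2)
            continue
        if gene.strand == "+":
            atg = min(c.start for c in cds)
        else:
            atg = max(c.end for c in cds)
        out.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                cds_start_codon_pos=atg,
            )
        )
    return out


def read_phenotypes(path: str | Path) -> PhenotypeTable:
    """TSV with an ``accession`` column plus named numeric measures."""
    df = pd.read_csv(path, sep="\t")
    first = df.columns[0]
    df = df.set_index(first)
    df.index.name = "accession"
    return PhenotypeTable(df)


# ---------------------------------------------------------------------------
# writers


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with deterministic column order and
    floats at 6 significant digits."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _round_floats(obj):
    if isinstance(obj, float):
        return float(f"{obj:.6g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.6g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist())
    return obj


def write_json(obj: Mapping, path: str | Path) -> None:
    """Write a JSON result with floats rounded to 6 significant digits."""
    with open(path, "w") as fh:
        json.dump(_round_floats(dict(obj)), fh, indent=2, sort_keys=True)
        fh.write("\n")
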