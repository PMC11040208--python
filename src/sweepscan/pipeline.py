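"""End-to-end orchestration: scan → sweep calls → locus classification →
promoter/haplotype analysis → group comparison, with a merged report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._version import __version__
from .diversity import (
    DiversityTrack,
    SweepCallSet,
    call_sweeps,
    empirical_threshold,
    locate_locus,
    make_windows,
    pi_ratio,
    window_pi,
)
from .haplotypes import (
    classify_haplotypes,
    compare_groups,
    extract_promoter_variants,
    haplotype_distribution,
    promoter_variants_dataframe,
)
from .io import (
    GeneModel,
    PhenotypeTable,
    PopulationPanel,
    VariantTable,
    read_gene_models,
    read_panel,
    read_phenotypes,
    read_vcf,
    write_json,
    write_tsv,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and input fingerprint."""

    def __init__(self, stage: str, fingerprint: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed on input {fingerprint}: {cause}")
        self.stage = stage
        self.fingerprint = fingerprint
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    vcf: str
    panel: str
    gff3: str
    chrom: str
    chrom_length: int
    gene_id: str
    tag_pos: int
    phenotypes: str | None = None
    window: int = 100_000
    step: int = 10_000
    quantile: float = 0.95
    contrasts: tuple[tuple[str, str], ...] = (("PIM", "CER"), ("CER", "BIG"))
    upstream_len: int = 3000
    hap1_base: str = "G"
    hap2_base: str = "A"
    measure: str = "survival_rate"
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.quantile < 1):
            raise ValueError("quantile must be in (0, 1)")

    def fingerprint(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ReportBundle:
    """Every number traceable to a stage output."""

    thresholds: dict[str, float]
    sweeps: dict[str, SweepCallSet]
    locus_classification: dict[str, str]
    promoter_variants: "object"          # DataFrame
    haplotype_counts: dict[str, int]
    group_frequencies: "object"          # DataFrame
    comparison: "object | None"          # GroupComparison
    diversity: DiversityTrack
    provenance: dict

    def to_json_dict(self) -> dict:
        out = {
            "thresholds": self.thresholds,
            "sweep_intervals": {
                c: [list(iv) for iv in s.intervals] for c, s in self.sweeps.items()
            },
            "locus_classification": self.locus_classification,
            "promoter_variants": self.promoter_variants.to_dict(orient="records"),
            "haplotype_counts": self.haplotype_counts,
            "group_frequencies": self.group_frequencies.reset_index(names="group")
                                     .to_dict(orient="records"),
            "provenance": self.provenance,
        }
        if self.comparison is not None:
            c = self.comparison
            out["comparison"] = {
                "groups": list(c.groups), "n": list(c.n),
                "means": list(c.means), "sds": list(c.sds),
                "F": c.f_stat, "p": c.p_value,
                "n_perm": c.n_perm, "seed": c.seed, "measure": c.measure,
            }
        return out

    def to_markdown(self) -> str:
        lines = ["# Sweep-scan report", ""]
        for contrast, thr in self.thresholds.items():
            cls = self.locus_classification.get(contrast, "?")
            ivs = self.sweeps[contrast].intervals
            lines.append(
                f"- **{contrast}**: top-quantile threshold {thr:.4g}; "
                f"{len(ivs)} sweep interval(s); locus {cls}"
            )
        lines.append("")
        lines.append(f"- Promoter variants: {len(self.promoter_variants)}")
        hc = self.haplotype_counts
        lines.append(
            f"- Haplotypes: Hap1 n={hc.get('Hap1', 0)}, Hap2 n={hc.get('Hap2', 0)}, "
            f"Het n={hc.get('Het', 0)}, Missing n={hc.get('Missing', 0)}"
        )
        if self.comparison is not None:
            c = self.comparison
            lines.append(
                f"- {c.measure}: F = {c.f_stat:.4g}, permutation p = {c.p_value:.4g}"
            )
        return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> ReportBundle:
    """Run the full analysis; idempotent given seeds.

    Stages write their outputs to ``outdir`` (if given) as they complete,
    so a failure in a later stage leaves earlier results on disk; errors
    are re-raised as :class:`StageError` naming the stage.
    """
    fp = config.fingerprint()
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 — annotate and propagate
            raise StageError(name, fp, exc) from exc

    def _load():
        for p in (config.vcf, config.panel, config.gff3):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        table = read_vcf(config.vcf)
        panel = read_panel(config.panel).intersect(table.samples)
        genes = {g.gene_id: g for g in read_gene_models(config.gff3)}
        if config.gene_id not in genes:
            raise ValueError(f"gene {config.gene_id!r} not in {config.gff3}")
        pheno = read_phenotypes(config.phenotypes) if config.phenotypes else None
        return table, panel, genes[config.gene_id], pheno

    table, panel, gene, pheno = _stage("load", _load)

    def _scan():
        windows = make_windows(config.chrom, config.chrom_length,
                               config.window, config.step)
        groups = sorted({g for c in config.contrasts for g in c},
                        key=lambda g: list(panel.groups).index(g))
        return window_pi(table, panel, groups, windows)

    track = _stage("scan", _scan)
    if outdir is not None:
        write_tsv(track.to_dataframe(), outdir / "diversity.tsv")

    thresholds: dict[str, float] = {}
    sweeps: dict[str, SweepCallSet] = {}
    classification: dict[str, str] = {}

    def _sweeps():
        for num, den in config.contrasts:
            contrast = f"{num}/{den}"
            ratio = pi_ratio(track, num, den)
            thr = empirical_threshold(ratio, config.quantile)
            calls = call_sweeps(ratio, thr, quantile=config.quantile)
            thresholds[contrast] = thr
            sweeps[contrast] = calls
            classification[contrast] = locate_locus(calls, gene)
            if outdir is not None:
                safe = contrast.replace("/", "_")
                write_tsv(ratio.to_dataframe(), outdir / f"ratio_{safe}.tsv")
                calls.to_bed().to_csv(outdir / f"sweeps_{safe}.bed",
                                      sep="\t", index=False, header=False)

    _stage("sweeps", _sweeps)

    def _promoter():
        variants = extract_promoter_variants(
            table, gene, config.upstream_len, config.chrom_length
        )
        return promoter_variants_dataframe(variants)

    prom_df = _stage("promoter", _promoter)
    if outdir is not None:
        write_tsv(prom_df, outdir / "promoter_variants.tsv")

    def _haplotypes():
        assignment = classify_haplotypes(
            table, config.chrom, config.tag_pos,
            {"Hap1": config.hap1_base, "Hap2": config.hap2_base},
        )
        dist = haplotype_distribution(assignment, panel)
        return assignment, dist

    assignment, dist = _stage("haplotypes", _haplotypes)
    if outdir is not None:
        write_tsv(assignment.to_dataframe(), outdir / "haplotypes.tsv")
        write_tsv(dist.to_dataframe(), outdir / "group_frequencies.tsv")

    comparison = None
    if pheno is not None:
        def _compare():
            grouping = {a: c for a, c in assignment.calls.items()
                        if c in ("Hap1", "Hap2")}
            return compare_groups(pheno, grouping, config.measure,
                                  n_perm=config.n_perm, seed=config.seed)

        comparison = _stage("compare", _compare)

    provenance = {
        "config_hash": fp,
        "seed": config.seed,
        "version": __version__,
    }
    bundle = ReportBundle(
        thresholds=thresholds,
        sweeps=sweeps,
        locus_classification=classification,
        promoter_variants=prom_df,
        haplotype_counts=assignment.counts(),
        group_frequencies=dist.table,
        comparison=comparison,
        diversity=track,
        provenance=provenance,
    )
    if outdir is not None:
        write_json(bundle.to_json_dict(), outdir / "report.json")
        (outdir / "report.md").write_text(bundle.to_markdown())
    return bundle
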