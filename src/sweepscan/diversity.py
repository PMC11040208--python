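"""Windowed nucleotide diversity (π), π-ratio tracks and sweep calling.

π is estimated per site from allele frequencies with the small-sample
(Nei) correction::

    π_site = n/(n−1) · (1 − Σ_i p_i²)

with ``n`` called alleles and ``p_i`` the frequency of allele ``i``
(diploids contribute two alleles; missing alleles reduce ``n`` at that
site).  For a biallelic site with counts ``c`` and ``n−c`` this equals
``2c(n−c)/(n(n−1))``, the fraction of differing pairs among all C(n,2)
pairs of sequences.  Window π sums site π over the polymorphic sites in
the window and divides by window length in bp, so sites absent from the
VCF count as invariant.

The sweep statistic is the ratio of window π between two groups
(π_wild/π_domesticated for the domestication contrast,
π_domesticated/π_improved for improvement); windows above the empirical
top-quantile threshold of the ratio track are merged into candidate
sweep intervals.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GeneModel, PopulationPanel, VariantTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Window:
    """Genomic window, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


def make_windows(chrom: str, chrom_length: int, window: int = 100_000,
                 step: int = 10_000) -> list[Window]:
    """Sliding windows tiling ``[0, chrom_length)``; the trailing window is
    clipped at the chromosome end."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    out = []
    start = 0
    while start < chrom_length:
        out.append(Window(chrom, start, min(start + window, chrom_length)))
        start += step
    return out


@dataclass
class DiversityTrack:
    """Per-window π for one or more population groups."""

    windows: list[Window]
    pi: dict[str, np.ndarray]
    n_sites: np.ndarray  # variant records available per window

    def to_dataframe(self) -> pd.DataFrame:
        cols = {
            "chrom": [w.chrom for w in self.windows],
            "win_start": [w.start for w in self.windows],
            "win_end": [w.end for w in self.windows],
        }
        for g, v in self.pi.items():
            cols[f"pi_{g}"] = v
        cols["n_sites"] = self.n_sites
        return pd.DataFrame(cols)


@dataclass
class RatioTrack:
    """Per-window π ratio between two groups; undefined windows masked."""

    windows: list[Window]
    ratio: np.ndarray      # NaN where masked
    contrast: str
    mask: np.ndarray       # True where the ratio is undefined

    @property
    def defined(self) -> np.ndarray:
        return self.ratio[~self.mask]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom": [w.chrom for w in self.windows],
            "win_start": [w.start for w in self.windows],
            "win_end": [w.end for w in self.windows],
            "ratio": self.ratio,
            "masked": self.mask,
        })


@dataclass
class SweepCallSet:
    """Above-threshold windows merged into candidate sweep intervals."""

    threshold: float
    intervals: list[tuple[str, int, int]]  # (chrom, start, end), 0-based half-open
    contrast: str
    quantile: float | None = None

    def to_bed(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["chrom", "start", "end"])


# ---------------------------------------------------------------------------


def site_pi(allele_counts) -> float:
    """Per-site π from called-allele counts (any number of alleles).

    Equals the fraction of differing pairs among all C(n,2) pairs of
    sampled alleles.  Raises for n < 2 (callers skip such sites).
    """
    counts = np.asarray(allele_counts, dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("site_pi needs at least 2 called alleles")
    p = counts / n
    return float(n / (n - 1.0) * (1.0 - np.sum(p * p)))


def _per_site_pi_matrix(table: VariantTable, panel: PopulationPanel,
                        groups: list[str], chrom: str) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-site π for each group on one chromosome.

    Returns (positions0, pi) with positions 0-based and pi of shape
    (n_groups, n_sites).  Sites with < 2 called alleles in a group get
    π = 0 there (skipped, not fatal).
    """
    recs = [r for r in table.records if r.chrom == chrom]
    pos0 = np.array([r.pos - 1 for r in recs], dtype=np.int64)
    pi = np.zeros((len(groups), len(recs)))
    group_idx = []
    for g in groups:
        members = [a for a in panel.members(g) if a in set(table.samples)]
        if len(members) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 accessions with genotypes")
        group_idx.append(table.sample_index(members))
    for j, rec in enumerate(recs):
        for gi, idx in enumerate(group_idx):
            counts = rec.allele_counts(idx)
            n = counts.sum()
            if n < 2:
                continue
            p = counts / n
            pi[gi, j] = n / (n - 1.0) * (1.0 - np.sum(p * p))
    return pos0, pi


def window_pi(table: VariantTable, panel: PopulationPanel,
              groups, windows: list[Window]) -> DiversityTrack:
    """Sliding-window π per group: Σ site π over in-window sites / window
    length in bp.  ``groups`` may be one label or a list."""
    if isinstance(groups, str):
        groups = [groups]
    groups = list(groups)
    if not windows:
        raise ValueError("no windows given")
    chrom = windows[0].chrom
    if any(w.chrom != chrom for w in windows):
        raise ValueError("all windows must share one chromosome")

    pos0, pi_site_mat = _per_site_pi_matrix(table, panel, groups, chrom)
    order = np.argsort(pos0, kind="stable")
    pos0 = pos0[order]
    pi_site_mat = pi_site_mat[:, order]
    # prefix sums let each (possibly overlapping) window be a range query
    csum = np.concatenate([np.zeros((len(groups), 1)), np.cumsum(pi_site_mat, axis=1)], axis=1)

    starts = np.array([w.start for w in windows])
    ends = np.array([w.end for w in windows])
    lo = np.searchsorted(pos0, starts, side="left")
    hi = np.searchsorted(pos0, ends, side="left")
    lengths = (ends - starts).astype(float)

    pi = {}
    for gi, g in enumerate(groups):
        pi[g] = (csum[gi, hi] - csum[gi, lo]) / lengths
    n_sites = (hi - lo).astype(np.int64)
    return DiversityTrack(list(windows), pi, n_sites)


def pi_ratio(track: DiversityTrack, numerator: str, denominator: str) -> RatioTrack:
    """Per-window π ratio; windows with zero denominator π are masked."""
    for g in (numerator, denominator):
        if g not in track.pi:
            raise ValueError(f"group {g!r} not in diversity track")
    num = track.pi[numerator]
    den = track.pi[denominator]
    mask = den == 0
    ratio = np.full(len(num), np.nan)
    ratio[~mask] = num[~mask] / den[~mask]
    return RatioTrack(track.windows, ratio, f"{numerator}/{denominator}", mask)


def empirical_threshold(ratio, q: float = 0.95) -> float:
    """Nearest-rank empirical quantile of the defined ratios: the k-th
    smallest with k = ceil(q·m).  Interpolation-free, hence reproducible
    across numeric libraries."""
    values = ratio.defined if isinstance(ratio, RatioTrack) else np.asarray(ratio, dtype=float)
    values = values[~np.isnan(values)]
    m = len(values)
    if m == 0:
        raise ValueError("no defined windows to take a quantile over")
    if not (0 < q <= 1):
        raise ValueError("q must be in (0, 1]")
    if m < 20 and q >= 0.95:
        warnings.warn(
            f"only {m} defined windows for q={q}; threshold is unstable",
            stacklevel=2,
        )
    k = math.ceil(q * m)
    return float(np.sort(values)[k - 1])


def call_sweeps(ratio: RatioTrack, threshold: float, quantile: float | None = None,
                max_gap: int = 0) -> SweepCallSet:
    """Windows with defined ratio ≥ threshold, merged into intervals.

    Overlapping or abutting qualifying windows merge; ``max_gap`` allows
    up to that many bp of separation between merged windows (default 0:
    no gap tolerance).  Masked windows never qualify.
    """
    qualifying = (~ratio.mask) & (np.nan_to_num(ratio.ratio, nan=-np.inf) >= threshold)
    intervals: list[tuple[str, int, int]] = []
    cur: list | None = None
    for w, q_ in zip(ratio.windows, qualifying):
        if not q_:
            continue
        if cur is not None and w.chrom == cur[0] and w.start <= cur[2] + max_gap:
            cur[2] = max(cur[2], w.end)
        else:
            if cur is not None:
                intervals.append(tuple(cur))
            cur = [w.chrom, w.start, w.end]
    if cur is not None:
        intervals.append(tuple(cur))
    return SweepCallSet(float(threshold), intervals, ratio.contrast, quantile)


def interval_jaccard(calls: SweepCallSet, chrom: str, start: int, end: int) -> float:
    """Jaccard overlap (bp intersection / bp union) between the union of
    called intervals and one reference interval, all 0-based half-open."""
    if end <= start:
        raise ValueError("reference interval must be non-empty")
    ivs = sorted((s, e) for c, s, e in calls.intervals if c == chrom)
    inter = sum(max(0, min(e, end) - max(s, start)) for s, e in ivs)
    called_len = sum(e - s for s, e in ivs)  # call_sweeps merges, so disjoint
    union = called_len + (end - start) - inter
    return inter / union if union else 0.0


def locate_locus(calls: SweepCallSet, gene: GeneModel) -> str:
    """Classify a gene as ``within_sweep`` iff its span overlaps any sweep
    interval (half-open overlap on the same chromosome)."""
    g_start0, g_end0 = gene.start - 1, gene.end  # 1-based inclusive -> half-open
    on_chrom = [iv for iv in calls.intervals if iv[0] == gene.chrom]
    if calls.intervals and not on_chrom and all(iv[0] != gene.chrom for iv in calls.intervals):
        warnings.warn(
            f"gene {gene.gene_id} on {gene.chrom} but sweep calls on other chromosomes",
            stacklevel=2,
        )
    for _, s, e in on_chrom:
        if g_start0 < e and s < g_end0:
            return "within_sweep"
    return "outside_sweep"
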