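# Methods

This note documents the statistical models, numerical conventions and
design choices behind `sweepscan`, and what the synthetic panels do and
do not establish about behaviour on real resequencing data.

## Diversity estimation

Per-site nucleotide diversity is Nei's unbiased frequency estimator
π = n/(n−1)·(1 − Σ p_i²) over the called alleles at the site, which
equals the fraction of differing pairs among all C(n,2) pairs of
sampled alleles.  Conventions:

- Diploid genotypes contribute two alleles; missing alleles ("./.") are
  excluded per site rather than imputed, so n varies by site.  This
  keeps the estimator unbiased under missingness at the cost of
  site-to-site variance.
- Multiallelic sites enter through their full allele-frequency vector.
- InDels count as single polymorphic sites at their VCF position; their
  length does not weight π.  This is the simplest defensible treatment
  and is symmetric across groups, which is what the π *ratio* needs.
- Sites with fewer than two called alleles in a group contribute zero
  (skipped, not fatal).
- Phase is ignored; every statistic is frequency-based.

Window π is the sum of site π over the variants inside the window
divided by window length in bp — sites absent from the VCF are treated
as invariant.  Windows default to 100 kb with a 10-kb step.  No
published window/step accompanies the thresholds this scan emulates;
100 kb/10 kb is the conventional scale for tomato resequencing sweep
scans, and both are configurable precisely because empirical
top-quantile thresholds are sensitive to them.  There is no site-count
floor per window by default; `n_sites` is reported per window so users
can mask sparse windows themselves.

## Sweep calling

The ratio track divides window π of the ancestral-side group by the
derived-side group (wild/domesticated, domesticated/improved).  Windows
whose denominator π is zero are masked — excluded from both ratios and
quantiles — rather than stabilised with a pseudocount, because a
pseudocount would distort the empirical quantile that defines the
threshold.  The threshold is the nearest-rank quantile (k-th smallest,
k = ceil(q·m), over the m defined windows; default q = 0.95):
deterministic, interpolation-free, and exactly scale-equivariant.
Qualifying windows (ratio ≥ threshold) merge when they overlap or abut;
a configurable gap tolerance exists but defaults to zero.  A gene is
"within" a sweep iff its span overlaps a called interval under
half-open coordinates.  All internal intervals are 0-based half-open;
VCF/GFF3 coordinates are converted once at the I/O boundary.

## Promoter haplotypes

The promoter window is the `upstream_len` (default 3000 bp) interval
immediately upstream of the first base of the ATG start codon, oriented
by strand and clipped at the chromosome edge.  Relative positions are
signed distances to the ATG (−1 is the base adjacent to the A of ATG;
rel_pos 0 — the ATG itself — is excluded by the half-open window).
SNPs are labelled SNP1..k from most-upstream toward the ATG, InDels
separately in the same order; the labelling is a convention of this
package, chosen so that labels are invariant under strand mirroring.

Haplotype classification at the tag SNP is by base identity:
homozygotes for the configured wild base are Hap1, for the cultivated
base Hap2; anything else fully called is Het, any uncalled allele is
Missing.  Het and Missing are excluded from Hap1/Hap2 counts and
reported in their own classes — panel tallies in which Hap1 + Hap2 sums
to fewer accessions than the panel size imply exactly such exclusions,
but how a given study handled them is rarely stated, so the treatment
here is explicit and configurable downstream (group fractions are over
non-missing classes).

## Group comparison

`compare_groups` computes the classic one-way F from the
sums-of-squares decomposition and a permutation p-value: labels are
shuffled `n_perm` times (default 10 000), and
p = (#{F* ≥ F} + 1)/(n_perm + 1), so p ∈ (0, 1] and the test is exact
in expectation under exchangeability.  The permutation route is
preferred over the F reference distribution because haplotype groups in
panel phenotyping are small and unbalanced.  Degenerate inputs: zero
within-group variance everywhere makes F undefined and raises; two
groups with identical values give F = 0, p = 1.  The shuffle uses a
seeded generator and is fully deterministic; permuted F values are
compared with a 1e-12 slack so exact ties count as extreme.

## Phylogeny

Distances are p-distances with pairwise deletion of gapped columns —
the common quick default for protein NJ — with a Poisson correction
−ln(1−p) behind a flag; the substitution model behind the published
tree this module emulates is not stated, so exact reproduction of its
supports is not claimed.  NJ follows Saitou–Nei: join the pair
minimising Q(i,j) = (r−2)d(i,j) − Σd(i,·) − Σd(j,·), with ties broken
by the lowest (i,j) index pair, branch lengths from the standard
formulas, negatives clamped to zero (logged), and the final three
lineages joined at a trifurcating root by the three-point formulas.  On
additive matrices the algorithm recovers the generating tree exactly
(verified to 1e-9 against random reference trees, and cross-checked
against scikit-bio's NJ).  Bootstrap supports resample alignment
columns with replacement, rebuild the tree, and count how often each
internal bipartition of the original tree recurs; bipartitions are
compared as canonical label sets, so taxa order never matters.
Replicates with an incomputable pair distance (no shared ungapped
columns) are dropped and logged, and supports are fractions of the
replicates actually used.

## Synthetic panels

The generator produces the statistical structure the analysis assumes,
with these defaults as the study conditions:

| parameter | default | rationale |
|---|---|---|
| chromosome length L | 2 Mb | desk-scale stand-in for a chromosome |
| segregating sites S | 4000 | ≈ 2 variants/kb, typical resequencing density |
| group sizes | 20 / 40 / 60 | wild < domesticated < improved, desk scale |
| bottlenecks (N, g) | (100, 60), (100, 45) | heterozygosity retention ≈ e^(−g/2N): 0.74 then 0.80 |
| sweep interval, λ | [0.9, 1.1 Mb), 0.05 | 200-kb improvement sweep retaining 5% of heterozygosity |
| tag wild-allele freq | 0.90 / 0.45 / 0.10 | monotone decline of the wild allele across groups |
| phenotype | μ=40, β=20/allele, σ=10 (%) | wild homozygotes ≈ 80% survival vs ≈ 40%, clipped to [0,100] |

Ancestral frequencies are drawn from the neutral SFS (P(count=i) ∝ 1/i
over 1..2n−1); bottlenecks are g rounds of binomial resampling
(p′ = Binomial(2N, p)/2N), so Var(p′) = p(1−p)/2N per round and
fixation/loss are absorbing.  The sweep rescales in-interval
heterozygosity in the improved group only: p moves toward its nearer
boundary so that 2p′(1−p′) = λ·2p(1−p), with the p = 0.5 tie broken
toward 0 for determinism.  Genotypes are two Bernoulli(p) draws per
accession.  The toy gene model is a + strand gene whose ATG sits inside
the sweep with the tag SNP exactly 1903 bp upstream; the reference
(REF) base at the tag is the cultivated allele, mimicking a
cultivar-derived reference genome.  The protein fixture evolves an
8-member calcineurin-B-like-style family down a fixed 4-subfamily tree
with paired *Arabidopsis*/tomato orthologs.

Simplifications, hence limits of what passing tests show: sites are
independent given their frequencies (no recombination or linkage), there
is no migration, selection acts only through the imposed λ rescaling,
genotypes are in Hardy–Weinberg proportions within groups, and missing
data are absent from the generator (the readers and estimators handle
missingness, exercised by separate randomized tests).  Passing the
sweep-recovery checks therefore shows the scan detects a localized
diversity collapse against drift-induced background variation — not
that it is robust to linked selection, population structure within
groups, or call-rate artefacts in real panels.

## Problem sizes and determinism

The test suite and the acceptance script run the generator at its
default scale (2 Mb / 4000 sites / 120 accessions; about 0.4 s per
panel), 20 seeded panels for recovery rates, 200 random instances for
the exhaustive π oracle, 100 random trees for NJ exactness, and 200
null simulations at 999 permutations for calibration — sizes chosen so
the whole suite completes in well under a minute while keeping the
binomial error of every rate criterion small.  Every stochastic
component takes a `numpy` `Generator` seed; sub-seeds are derived via
`SeedSequence` so independent analyses never share streams.

## Known limitations

- Empirical thresholds depend on window/step and on the extent of the
  scanned region; published threshold values can only be reproduced
  with the original (often unstated) windowing, so thresholds here are
  always recomputed, never asserted.
- The π-ratio scan has no composite-likelihood or haplotype-based
  statistics (XP-CLR, Fst, Tajima's D are out of scope).
- Haplotypes are defined by one tag SNP; no LD-based phasing.
- NJ is distance-based only; no ML/Bayesian inference, and input
  protein alignments must be pre-aligned.
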