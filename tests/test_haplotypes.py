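"""Promoter geometry, tag-SNP haplotype calls and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from sweepscan import (
    classify_haplotypes,
    compare_groups,
    extract_promoter_variants,
    haplotype_distribution,
    promoter_window,
)
from sweepscan.io import (
    MISSING,
    PhenotypeTable,
    PopulationPanel,
    VariantRecord,
    VariantTable,
)

from conftest import anova_f_oracle, exhaustive_two_group_pvalue, make_gene


def _table(records, samples):
    return VariantTable(records, tuple(samples))


def _snp(chrom, pos, genotypes, ref="C", alt=("T",)):
    return VariantRecord(chrom, pos, ref, alt,
                         np.asarray(genotypes, dtype=np.int16))


class TestPromoterWindow:
    def test_plus_strand(self):
        win = promoter_window(make_gene("+", atg=10001))
        assert (win.start, win.end) == (7000, 10000)

    def test_minus_strand(self):
        win = promoter_window(make_gene("-", atg=10000))
        assert (win.start, win.end) == (10000, 13000)

    def test_clipped_at_chromosome_start(self):
        win = promoter_window(make_gene("+", atg=2001))
        assert (win.start, win.end) == (0, 2000)

    def test_fully_off_chromosome_rejected(self):
        gene = make_gene("+", atg=1, span=0)
        with pytest.raises(ValueError, match="off the chromosome"):
            promoter_window(gene)


class TestExtractPromoterVariants:
    def test_rel_pos_minus_1903_on_plus_strand(self):
        gene = make_gene("+", atg=10001)
        table = _table([_snp("chr8", 8098, [[0, 1]])], ["s1"])
        (var,) = extract_promoter_variants(table, gene)
        assert var.rel_pos == -1903
        assert var.label == "SNP1"

    def test_rel_pos_minus_1903_on_mirrored_minus_strand(self):
        # reflect the + strand fixture: ATG at 10000 on −, SNP downstream in
        # genome coordinates but 1903 bp upstream along the gene
        gene = make_gene("-", atg=10000)
        table = _table([_snp("chr8", 11903, [[0, 1]])], ["s1"])
        (var,) = extract_promoter_variants(table, gene)
        assert var.rel_pos == -1903
        assert var.label == "SNP1"

    def test_variant_at_atg_first_base_excluded(self):
        gene = make_gene("+", atg=10001)
        table = _table([_snp("chr8", 10001, [[0, 1]])], ["s1"])
        assert extract_promoter_variants(table, gene) == []

    def test_eight_snps_one_indel_in_window_two_outside(self):
        gene = make_gene("+", atg=10001)  # window [7000, 10000)
        records = [
            _snp("chr8", 7100 + 300 * i, [[0, 1]]) for i in range(8)
        ]
        records.append(_snp("chr8", 9600, [[0, 1]], ref="C", alt=("CAT",)))
        records.append(_snp("chr8", 6900, [[0, 1]]))    # upstream of window
        records.append(_snp("chr8", 10500, [[0, 1]]))   # inside the gene
        table = _table(records, ["s1"])
        variants = extract_promoter_variants(table, gene)
        assert len(variants) == 9
        snps = [v for v in variants if v.record.vtype == "SNP"]
        indels = [v for v in variants if v.record.vtype == "InDel"]
        assert [v.label for v in snps] == [f"SNP{i}" for i in range(1, 9)]
        assert [v.label for v in indels] == ["InDel1"]
        # most-upstream SNP gets label SNP1
        assert snps[0].rel_pos < snps[-1].rel_pos

    def test_labels_invariant_under_strand_mirroring(self):
        gene_f = make_gene("+", atg=10001)
        offsets = [-2500, -1903, -400]
        fwd = _table([_snp("chr8", 10001 + o, [[0, 1]]) for o in offsets], ["s1"])
        gene_r = make_gene("-", atg=10000)
        rev = _table([_snp("chr8", 10000 - o, [[0, 1]]) for o in offsets], ["s1"])
        vf = extract_promoter_variants(fwd, gene_f)
        vr = extract_promoter_variants(rev, gene_r)
        assert [(v.label, v.rel_pos) for v in vf] == [(v.label, v.rel_pos) for v in vr]


class TestClassifyHaplotypes:
    def _tag_table(self):
        # REF is the cultivated base A (cultivar-derived reference); the
        # wild base G is the ALT, so classification must key on bases
        geno = [[1, 1], [0, 0], [0, 1], [MISSING, MISSING]]
        rec = _snp("chr8", 8098, geno, ref="A", alt=("G",))
        return _table([rec], ["w1", "c1", "h1", "m1"])

    def test_homozygous_calls_and_het_and_missing(self):
        table = self._tag_table()
        asg = classify_haplotypes(table, "chr8", 8098, {"Hap1": "G", "Hap2": "A"})
        assert asg.calls == {"w1": "Hap1", "c1": "Hap2", "h1": "Het", "m1": "Missing"}
        assert sum(asg.counts().values()) == 4

    def test_classification_keys_on_base_not_allele_index(self):
        # same panel, wild-derived reference: G is now REF
        geno = [[0, 0], [1, 1], [0, 1], [MISSING, MISSING]]
        rec = _snp("chr8", 8098, geno, ref="G", alt=("A",))
        table = _table([rec], ["w1", "c1", "h1", "m1"])
        asg = classify_haplotypes(table, "chr8", 8098, {"Hap1": "G", "Hap2": "A"})
        assert asg.calls["w1"] == "Hap1" and asg.calls["c1"] == "Hap2"

    def test_absent_tag_site_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            classify_haplotypes(self._tag_table(), "chr8", 9999,
                                {"Hap1": "G", "Hap2": "A"})

    def test_allele_map_base_not_at_site_rejected(self):
        with pytest.raises(ValueError, match="not among alleles"):
            classify_haplotypes(self._tag_table(), "chr8", 8098,
                                {"Hap1": "T", "Hap2": "A"})


class TestHaplotypeDistribution:
    def _assignment(self, calls):
        from sweepscan.haplotypes import HaplotypeAssignment

        return HaplotypeAssignment("chr8", 8098, {"Hap1": "G", "Hap2": "A"}, calls)

    def test_fractions(self):
        calls = {f"p{i}": ("Hap1" if i < 8 else "Hap2") for i in range(10)}
        panel = PopulationPanel({a: "PIM" for a in calls})
        dist = haplotype_distribution(self._assignment(calls), panel)
        assert dist.table.at["PIM", "f_Hap1"] == pytest.approx(0.8)
        assert dist.table.at["PIM", "f_Hap2"] == pytest.approx(0.2)

    def test_group_without_classified_accessions_warns_zero_row(self):
        calls = {"a1": "Hap1", "a2": "Hap2"}
        panel = PopulationPanel({"a1": "PIM", "a2": "PIM", "b1": "CER"})
        with pytest.warns(UserWarning, match="CER"):
            dist = haplotype_distribution(self._assignment(calls), panel)
        assert dist.table.loc["CER", ["n_Hap1", "n_Hap2", "n_Het"]].sum() == 0

    def test_counts_conserved_across_classify_then_distribute(self, default_sim):
        cfg = default_sim.config
        asg = classify_haplotypes(default_sim.table, cfg.chrom, cfg.tag_pos,
                                  {"Hap1": "G", "Hap2": "A"})
        dist = haplotype_distribution(asg, default_sim.panel)
        count_cols = ["n_Hap1", "n_Hap2", "n_Het", "n_Missing"]
        assert dist.table[count_cols].to_numpy().sum() == len(asg.calls)
        assert sum(asg.counts().values()) == len(default_sim.table.samples)

    def test_empty_intersection_rejected(self):
        calls = {"a1": "Hap1"}
        panel = PopulationPanel({"zz": "PIM"})
        with pytest.raises(ValueError, match="no accessions"):
            haplotype_distribution(self._assignment(calls), panel)

    def test_fractions_sum_to_one_over_non_missing(self, default_sim):
        cfg = default_sim.config
        asg = classify_haplotypes(default_sim.table, cfg.chrom, cfg.tag_pos,
                                  {"Hap1": "G", "Hap2": "A"})
        dist = haplotype_distribution(asg, default_sim.panel)
        sums = dist.table[["f_Hap1", "f_Hap2", "f_Het"]].sum(axis=1)
        assert np.allclose(sums, 1.0)


def _pheno(values_by_acc, measure="survival_rate"):
    return PhenotypeTable(pd.DataFrame(
        {measure: pd.Series(values_by_acc)}
    ).rename_axis("accession"))


class TestCompareGroups:
    def test_identical_groups_f_zero_p_one(self):
        pheno = _pheno({"a": 1.0, "b": 2.0, "c": 3.0,
                        "d": 1.0, "e": 2.0, "f": 3.0})
        grouping = dict.fromkeys("abc", "Hap1") | dict.fromkeys("def", "Hap2")
        res = compare_groups(pheno, grouping, "survival_rate", n_perm=200, seed=0)
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_sums_of_squares(self):
        # {1,2,3} vs {4,5,6}: SSB = 13.5, SSW = 4, F = 13.5 / 1
        pheno = _pheno(dict(zip("abcdef", [1, 2, 3, 4, 5, 6])))
        grouping = dict.fromkeys("abc", "Hap1") | dict.fromkeys("def", "Hap2")
        res = compare_groups(pheno, grouping, "survival_rate", n_perm=100, seed=0)
        assert res.f_stat == pytest.approx(13.5, abs=1e-12)
        assert res.f_stat == pytest.approx(
            anova_f_oracle([[1, 2, 3], [4, 5, 6]]), abs=1e-12
        )

    def test_permutation_p_approximates_exhaustive_enumeration(self):
        values = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        exact = exhaustive_two_group_pvalue(values, 3)  # over all 20 splits
        pheno = _pheno(dict(zip("abcdef", values)))
        grouping = dict.fromkeys("abc", "Hap1") | dict.fromkeys("def", "Hap2")
        res = compare_groups(pheno, grouping, "survival_rate",
                             n_perm=20_000, seed=1)
        assert res.p_value == pytest.approx(exact, abs=0.01)

    def test_f_matches_oracle_on_random_unbalanced_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sizes = rng.integers(2, 8, size=int(rng.integers(2, 5)))
            groups = [list(rng.normal(rng.normal(0, 2), 1, s)) for s in sizes]
            accs = [f"g{i}_{j}" for i, g in enumerate(groups) for j in range(len(g))]
            vals = [v for g in groups for v in g]
            pheno = _pheno(dict(zip(accs, vals)), measure="trait")
            grouping = {f"g{i}_{j}": f"G{i}" for i, g in enumerate(groups)
                        for j in range(len(g))}
            res = compare_groups(pheno, grouping, "trait",
                                 n_perm=10, seed=0)
            assert res.f_stat == pytest.approx(anova_f_oracle(groups), rel=1e-10)

    def test_zero_total_variance_rejected(self):
        pheno = _pheno(dict.fromkeys("abcd", 5.0))
        grouping = dict.fromkeys("ab", "G1") | dict.fromkeys("cd", "G2")
        with pytest.raises(ValueError, match="undefined"):
            compare_groups(pheno, grouping, "survival_rate", n_perm=10, seed=0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(9)
        pheno = _pheno({f"a{i}": float(v) for i, v in
                        enumerate(rng.normal(size=12))}, measure="trait")
        grouping = {f"a{i}": ("G1" if i < 5 else "G2") for i in range(12)}
        r1 = compare_groups(pheno, grouping, "trait", n_perm=500, seed=4)
        r2 = compare_groups(pheno, grouping, "trait", n_perm=500, seed=4)
        assert r1.p_value == r2.p_value

    def test_fewer_than_two_groups_rejected(self):
        pheno = _pheno({"a": 1.0, "b": 2.0})
        with pytest.raises(ValueError, match=">= 2 groups"):
            compare_groups(pheno, {"a": "G1", "b": "G1"}, "survival_rate")

    def test_power_increases_with_effect_size(self):
        # rejection frequency at p < 0.05 grows with β/σ
        rates = []
        for beta in (0.0, 1.0, 3.0):
            hits = 0
            for seed in range(40):
                rng = np.random.default_rng(10_000 + seed)
                g1 = rng.normal(0, 1, 10)
                g2 = rng.normal(beta, 1, 10)
                accs = [f"x{i}" for i in range(20)]
                pheno = _pheno(dict(zip(accs, np.concatenate([g1, g2]))),
                               measure="trait")
                grouping = {a: ("G1" if i < 10 else "G2")
                            for i, a in enumerate(accs)}
                res = compare_groups(pheno, grouping, "trait",
                                     n_perm=199, seed=seed)
                hits += res.p_value < 0.05
            rates.append(hits / 40)
        assert rates[0] < rates[1] < rates[2]
        assert rates[2] > 0.9
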