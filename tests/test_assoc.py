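"""Genotype counting, Hardy-Weinberg tests, case-control tests and contrasts."""

from math import exp, lgamma, log

import numpy as np
import pandas as pd
import pytest

from snptrait.assoc import (
    GenotypeCounts,
    allele_freqs,
    case_control_test,
    count_genotypes,
    genotype_contrasts,
    genotype_stratified_table,
    hwe_exact_p,
    hwe_test,
)
from snptrait.io import DataError, SnpDef, geno_col

from conftest import cohort_from_counts


def hwe_exact_bruteforce(counts: GenotypeCounts) -> float:
    """Independent oracle: direct log-factorial enumeration of all het counts."""
    n = counts.total
    n_a, n_b = counts.allele_counts
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0

    def logprob(het: int) -> float:
        naa = (n_a - het) // 2
        nbb = (n_b - het) // 2
        return (
            lgamma(n + 1)
            - lgamma(naa + 1)
            - lgamma(het + 1)
            - lgamma(nbb + 1)
            + het * log(2.0)
            + lgamma(n_a + 1)
            + lgamma(n_b + 1)
            - lgamma(2 * n + 1)
        )

    hets = range(rare % 2, rare + 1, 2)
    lps = {h: logprob(h) for h in hets}
    m = max(lps.values())
    probs = {h: exp(lp - m) for h, lp in lps.items()}
    total = sum(probs.values())
    p_obs = probs[counts.n_het]
    return min(1.0, sum(v for v in probs.values() if v <= p_obs * (1 + 1e-10)) / total)


class TestCounting:
    def test_lepr_scale_counts_and_freqs(self):
        cohort = cohort_from_counts((190, 273, 154))
        counts = count_genotypes(cohort, "rs0")
        assert counts.as_tuple() == (190, 273, 154)
        assert counts.allele_counts == (653, 581)
        freqs = allele_freqs(counts)
        assert round(freqs.p, 2) == 0.53
        assert round(freqs.q, 2) == 0.47

    def test_allele_conservation(self):
        counts = GenotypeCounts(7, 11, 3)
        assert sum(counts.allele_counts) == 2 * counts.total

    def test_orientation_flip_swaps_homozygotes(self):
        cohort = cohort_from_counts((190, 273, 154))
        flipped = cohort.panel[0].flipped()
        cohort_flipped = type(cohort)([flipped], cohort.data)
        a = count_genotypes(cohort, "rs0")
        b = count_genotypes(cohort_flipped, "rs0")
        assert b.as_tuple() == (a.n_minor_homo, a.n_het, a.n_major_homo)

    def test_all_missing_group_errors(self):
        cohort = cohort_from_counts((3, 2, 1))
        cohort.data[geno_col("rs0")] = pd.NA
        with pytest.raises(DataError, match="no non-missing"):
            count_genotypes(cohort, "rs0")


class TestHwe:
    def test_perfect_hwe(self):
        res = hwe_test(GenotypeCounts(25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_chisq == pytest.approx(1.0)

    def test_chi_square_hand_computation(self):
        # expected counts 101.3 / 192.4 / 91.3 at p = 395/770
        res = hwe_test(GenotypeCounts(115, 165, 105))
        assert round(res.chi2, 2) == 7.79
        assert 0.004 < res.p_chisq < 0.006

    def test_monomorphic_exact_p_is_one(self):
        res = hwe_test(GenotypeCounts(80, 0, 0))
        assert res.p_exact == 1.0
        assert res.p_chisq == 1.0

    @pytest.mark.parametrize(
        "counts",
        [
            (115, 165, 105),
            (25, 50, 25),
            (10, 1, 10),
            (0, 7, 0),
            (1, 1, 1),
            (60, 10, 2),
            (3, 40, 3),
            (97, 2, 1),
        ],
    )
    def test_exact_matches_bruteforce(self, counts):
        gc = GenotypeCounts(*counts)
        assert hwe_exact_p(gc) == pytest.approx(hwe_exact_bruteforce(gc), abs=1e-12)


class TestCaseControl:
    def test_identical_proportions_null(self):
        g = GenotypeCounts(40, 40, 20)
        res = case_control_test(g, g, mode="allele")
        assert res.chi2 == pytest.approx(0.0, abs=1e-10)
        assert res.p == pytest.approx(1.0)

    def test_closed_form_2x2(self):
        case = GenotypeCounts(52, 86, 33)
        control = GenotypeCounts(115, 165, 105)
        res = case_control_test(case, control, mode="allele")
        a, b = case.allele_counts
        c, d = control.allele_counts
        N = a + b + c + d
        chi2 = N * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.chi2 == pytest.approx(chi2, abs=1e-10)

    def test_label_swap_invariance(self):
        case = GenotypeCounts(52, 86, 33)
        control = GenotypeCounts(115, 165, 105)
        assert case_control_test(case, control, "allele").p == pytest.approx(
            case_control_test(control, case, "allele").p, abs=1e-12
        )

    def test_genotype_mode_drops_empty_column(self):
        # no minor homozygotes in either group: 2x2 table, df = 1
        res = case_control_test(
            GenotypeCounts(120, 2, 0), GenotypeCounts(275, 7, 0), mode="genotype"
        )
        assert res.computable
        assert res.df == 1

    def test_degenerate_table_flagged(self):
        res = case_control_test(
            GenotypeCounts(120, 0, 0), GenotypeCounts(275, 0, 0), mode="genotype"
        )
        assert not res.computable


class TestContrasts:
    def test_identical_group_zero_difference(self):
        vals = np.arange(10, dtype=float)
        cohort = cohort_from_counts((10, 10, 10), phenotype_means=(0, 0, 0))
        cohort.data["pheno"] = np.concatenate([vals, vals, vals])
        results = genotype_contrasts(cohort, "rs0", "pheno")
        for r in results:
            assert r.difference == pytest.approx(0.0, abs=1e-12)
            assert r.ci_low <= 0 <= r.ci_high

    def test_unbiased_estimate_of_planted_shift(self):
        diffs = []
        for seed in range(500):
            cohort = cohort_from_counts(
                (100, 100, 0), phenotype_means=(0.0, 1.0, 0.0), noise_sd=1.0, seed=seed
            )
            (het, _) = genotype_contrasts(cohort, "rs0", "pheno")
            diffs.append(het.difference)
        assert abs(np.mean(diffs) - 1.0) < 0.03

    def test_small_class_not_computable(self):
        cohort = cohort_from_counts((10, 5, 1), phenotype_means=(0, 0, 0), noise_sd=1.0)
        het, minor = genotype_contrasts(cohort, "rs0", "pheno")
        assert het.computable
        assert not minor.computable
        assert minor.difference is None

    def test_bonferroni_across_computable_contrasts(self):
        cohort = cohort_from_counts(
            (50, 50, 50), phenotype_means=(0, 0.1, 0.2), noise_sd=1.0, seed=1
        )
        het, minor = genotype_contrasts(cohort, "rs0", "pheno")
        assert het.p_adj == pytest.approx(min(1.0, het.p_raw * 2), abs=1e-12)
        assert minor.p_adj >= minor.p_raw


class TestGenotypeStratifiedTable:
    def test_singleton_class_excluded_but_printed(self):
        cohort = cohort_from_counts((10, 5, 1), phenotype_means=(0, 0, 5), noise_sd=1.0)
        table = genotype_stratified_table(cohort, "rs0", ["pheno"], stratifier=None)
        minor = table[table["genotype_class"] == "minor_homo"].iloc[0]
        assert minor["n"] == 1
        assert not minor["in_comparison"]
        assert minor["letters"] == ""
        assert np.isfinite(minor["mean"])

    def test_identical_distributions_share_letter(self):
        cohort = cohort_from_counts((30, 30, 30), phenotype_means=(0, 0, 0), noise_sd=1.0)
        table = genotype_stratified_table(cohort, "rs0", ["pheno"], stratifier=None)
        assert set(table["letters"]) == {"a"}

    def test_power_planted_minor_homozygote_shift(self):
        # delta = 1 sd at n = 150 per class: Dunn-Bonferroni should separate
        # the minor homozygote in >= 80% of replicates
        hits = 0
        n_rep = 200
        for seed in range(n_rep):
            cohort = cohort_from_counts(
                (150, 150, 150), phenotype_means=(0.0, 0.0, 1.0), noise_sd=1.0, seed=seed
            )
            table = genotype_stratified_table(cohort, "rs0", ["pheno"], stratifier=None)
            letters = table.set_index("genotype_class")["letters"]
            shared_major = set(letters["minor_homo"]) & set(letters["major_homo"])
            shared_het = set(letters["minor_homo"]) & set(letters["het"])
            hits += int(not shared_major and not shared_het)
        assert hits / n_rep >= 0.80
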