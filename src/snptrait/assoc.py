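"""Single-locus association statistics.

Genotype/allele counting with declared or inferred major/minor
orientation, Hardy-Weinberg testing (Pearson chi-square with df = 1 and
the exact conditional test side by side), Pearson chi-square case-control
association in allele (2x2) or genotype (2x3) mode, and genotype-stratified
phenotype contrasts against the wild-type homozygote.

The exact Hardy-Weinberg test conditions on the observed allele counts and
sums the probabilities of all heterozygote configurations no more probable
than the observed one; it is computed with a probability recurrence over
heterozygote counts of fixed parity, so totals of a few hundred are exact
and overflow-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .anthro import dunn_pairwise
from .io import CohortTable, DataError, SnpDef, geno_col

__all__ = [
    "GenotypeCounts",
    "AlleleFreqs",
    "HweResult",
    "CaseControlResult",
    "ContrastResult",
    "count_genotypes",
    "allele_freqs",
    "hwe_exact_p",
    "hwe_test",
    "case_control_test",
    "genotype_contrasts",
    "genotype_stratified_table",
    "GENOTYPE_ORDER",
]

GENOTYPE_ORDER = ("major_homo", "het", "minor_homo")


@dataclass(frozen=True)
class GenotypeCounts:
    """(major-homozygote, heterozygote, minor-homozygote) counts for one group."""

    n_major_homo: int
    n_het: int
    n_minor_homo: int

    def __post_init__(self) -> None:
        if min(self.n_major_homo, self.n_het, self.n_minor_homo) < 0:
            raise DataError("genotype counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_major_homo + self.n_het + self.n_minor_homo

    @property
    def allele_counts(self) -> tuple[int, int]:
        """(major, minor) allele counts; always sums to 2 x total."""
        return (
            2 * self.n_major_homo + self.n_het,
            2 * self.n_minor_homo + self.n_het,
        )

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_major_homo, self.n_het, self.n_minor_homo)

    def flipped(self) -> "GenotypeCounts":
        return GenotypeCounts(self.n_minor_homo, self.n_het, self.n_major_homo)


@dataclass(frozen=True)
class AlleleFreqs:
    """Allele counts and relative frequencies; p is the major allele."""

    count_major: int
    count_minor: int

    @property
    def total(self) -> int:
        return self.count_major + self.count_minor

    @property
    def p(self) -> float:
        return self.count_major / self.total

    @property
    def q(self) -> float:
        return self.count_minor / self.total

    @classmethod
    def from_genotype_counts(cls, counts: GenotypeCounts) -> "AlleleFreqs":
        major, minor = counts.allele_counts
        return cls(major, minor)


@dataclass(frozen=True)
class HweResult:
    """Hardy-Weinberg test: Pearson chi-square (df=1) and exact conditional p."""

    chi2: float
    p_chisq: float
    p_exact: float
    df: int = 1


@dataclass(frozen=True)
class CaseControlResult:
    mode: str  # {"allele", "genotype"}
    chi2: float
    df: int
    p: float
    computable: bool = True


@dataclass(frozen=True)
class ContrastResult:
    """Mean difference of one genotype class vs the wild-type homozygote."""

    genotype: str  # "het" or "minor_homo", or a genotype string label
    phenotype: str
    n: int
    n_reference: int
    difference: float | None
    ci_low: float | None
    ci_high: float | None
    p_raw: float | None
    p_adj: float | None
    computable: bool = True


def _genotype_class(cell: str, snp: SnpDef) -> str:
    alleles = cell.split("/")
    extra = set(alleles) - snp.alleles
    if extra:
        raise DataError(f"SNP {snp.snp_id}: allele(s) {sorted(extra)} outside declared pair")
    n_minor = sum(a == snp.minor_allele for a in alleles)
    return GENOTYPE_ORDER[n_minor]


def genotype_classes(cohort: CohortTable, snp_id: str, group: str | None = None) -> pd.Series:
    """Per-sample genotype class ('major_homo'/'het'/'minor_homo'), NA dropped."""
    snp = cohort.snp(snp_id)
    df = cohort.data
    if group is not None:
        df = df[df["weight_category"] == group]
    calls = df[geno_col(snp_id)].dropna()
    return calls.map(lambda cell: _genotype_class(cell, snp))


def count_genotypes(cohort: CohortTable, snp_id: str, group: str | None = None) -> GenotypeCounts:
    """Genotype counts over non-missing calls, optionally within one weight category."""
    classes = genotype_classes(cohort, snp_id, group)
    if classes.empty:
        raise DataError(f"SNP {snp_id}: no non-missing calls" + (f" in group {group}" if group else ""))
    vc = classes.value_counts()
    counts = GenotypeCounts(*(int(vc.get(g, 0)) for g in GENOTYPE_ORDER))
    # conservation: allele counts are twice the genotype total by construction
    assert sum(counts.allele_counts) == 2 * counts.total
    return counts


def allele_freqs(counts: GenotypeCounts) -> AlleleFreqs:
    return AlleleFreqs.from_genotype_counts(counts)


def hwe_exact_p(counts: GenotypeCounts) -> float:
    """Exact conditional Hardy-Weinberg p-value.

    Given the observed allele counts, heterozygote counts share the parity
    of the minor-allele count; the p-value is the total probability of
    configurations with probability <= that of the observed one.
    Monomorphic samples return 1.
    """
    n = counts.total
    if n < 1:
        raise DataError("exact HWE test needs at least one genotype")
    n_major, n_minor = counts.allele_counts
    rare = min(n_major, n_minor)
    if rare == 0:
        return 1.0
    obs_het = counts.n_het

    # probability recurrence over het counts of fixed parity, anchored at
    # the (near-modal) expected het count to keep ratios well-scaled
    mid = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1 if mid < rare else -1
    probs: dict[int, float] = {mid: 1.0}
    het, hom_r = mid, (rare - mid) // 2
    hom_c = n - het - hom_r
    while het >= 2:
        probs[het - 2] = probs[het] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        het -= 2
        hom_r += 1
        hom_c += 1
    het, hom_r = mid, (rare - mid) // 2
    hom_c = n - het - hom_r
    while het <= rare - 2:
        probs[het + 2] = probs[het] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
        het += 2
        hom_r -= 1
        hom_c -= 1
    total = sum(probs.values())
    p_obs = probs[obs_het]
    p = sum(v for v in probs.values() if v <= p_obs * (1.0 + 1e-10)) / total
    return min(1.0, p)


def hwe_test(counts: GenotypeCounts) -> HweResult:
    """Pearson chi-square (df=1, no continuity correction) and exact HWE tests."""
    n = counts.total
    if n < 1:
        raise DataError("HWE test needs at least one genotype")
    freqs = allele_freqs(counts)
    p, q = freqs.p, freqs.q
    if p == 0.0 or q == 0.0:
        chi2 = 0.0
        p_chisq = 1.0
    else:
        expected = np.array([p * p, 2 * p * q, q * q]) * n
        observed = np.array(counts.as_tuple(), dtype=float)
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        p_chisq = float(stats.chi2.sf(chi2, 1))
    return HweResult(chi2=chi2, p_chisq=p_chisq, p_exact=hwe_exact_p(counts))


def case_control_test(
    case: GenotypeCounts, control: GenotypeCounts, mode: str = "allele"
) -> CaseControlResult:
    """Pearson chi-square on the case/control contingency table.

    ``mode="allele"`` tests the 2x2 allele-count table; ``mode="genotype"``
    the 2x3 genotype table, dropping genotype columns with zero total (df
    reduced accordingly). No continuity correction. A table degenerate to a
    single non-empty column yields a flagged not-computable result.
    """
    if mode == "allele":
        table = np.array([case.allele_counts, control.allele_counts], dtype=float)
    elif mode == "genotype":
        table = np.array([case.as_tuple(), control.as_tuple()], dtype=float)
    else:
        raise DataError(f"unknown case-control mode {mode!r}")
    if case.total == 0 or control.total == 0:
        raise DataError("case and control groups must both be non-empty")
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return CaseControlResult(mode=mode, chi2=np.nan, df=0, p=np.nan, computable=False)
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return CaseControlResult(mode=mode, chi2=float(chi2), df=int(df), p=float(p))


def _welch_ci(a: np.ndarray, b: np.ndarray, conf: float) -> tuple[float, float, float]:
    """(difference a-b, ci_low, ci_high) by Welch's approximation."""
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    se2 = va / na + vb / nb
    diff = ma - mb
    if se2 == 0:
        return diff, diff, diff
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    half = stats.t.ppf(0.5 + conf / 2.0, df) * np.sqrt(se2)
    return diff, diff - half, diff + half


def genotype_contrasts(
    cohort: CohortTable,
    snp_id: str,
    phenotype: str,
    group: str | None = None,
    conf: float = 0.95,
) -> list[ContrastResult]:
    """Heterozygote and minor-homozygote phenotype contrasts vs wild type.

    Differences of means with Welch confidence intervals; p-values are
    rank-based (Dunn z over the three genotype classes) and Bonferroni
    multiplied by the number of computable contrasts at this SNP. A class
    with < 2 non-missing values is returned flagged not-computable.
    """
    classes = genotype_classes(cohort, snp_id, group)
    df = cohort.data.loc[classes.index]
    values = df[phenotype]
    groups = {
        g: values[classes == g].dropna().to_numpy(dtype=float) for g in GENOTYPE_ORDER
    }
    ref = groups["major_homo"]
    if len(ref) < 2:
        raise DataError(
            f"SNP {snp_id}: wild-type homozygote class needs >= 2 non-missing {phenotype} values"
        )
    praw_matrix = dunn_pairwise([groups[g] for g in GENOTYPE_ORDER])
    candidates = [g for g in ("het", "minor_homo")]
    computable = [g for g in candidates if len(groups[g]) >= 2]
    n_comp = max(1, len(computable))
    results = []
    for g in candidates:
        if g not in computable:
            results.append(
                ContrastResult(
                    genotype=g,
                    phenotype=phenotype,
                    n=len(groups[g]),
                    n_reference=len(ref),
                    difference=None,
                    ci_low=None,
                    ci_high=None,
                    p_raw=None,
                    p_adj=None,
                    computable=False,
                )
            )
            continue
        diff, lo, hi = _welch_ci(groups[g], ref, conf)
        praw = float(praw_matrix[0, GENOTYPE_ORDER.index(g)])
        results.append(
            ContrastResult(
                genotype=g,
                phenotype=phenotype,
                n=len(groups[g]),
                n_reference=len(ref),
                difference=diff,
                ci_low=lo,
                ci_high=hi,
                p_raw=praw,
                p_adj=min(1.0, praw * n_comp),
            )
        )
    return results


def _letter_display(k: int, significant: np.ndarray, usable: Sequence[bool]) -> list[str]:
    """Compact letter display: groups share a letter iff not significantly different.

    Enumerates maximal cliques of the "not different" graph over the usable
    groups (k is tiny here) and assigns one letter per clique.
    """
    usable_idx = [i for i in range(k) if usable[i]]
    cliques: list[set[int]] = []
    from itertools import combinations as _comb

    for size in range(len(usable_idx), 0, -1):
        for subset in _comb(usable_idx, size):
            if any(significant[i, j] for i, j in _comb(subset, 2)):
                continue
            s = set(subset)
            if any(s <= c for c in cliques):
                continue
            cliques.append(s)
    cliques.sort(key=min)
    letters = ["" for _ in range(k)]
    for letter_i, clique in enumerate(cliques):
        ch = chr(ord("a") + letter_i)
        for i in clique:
            letters[i] += ch
    return letters


def genotype_stratified_table(
    cohort: CohortTable,
    snp_id: str,
    variables: Sequence[str],
    stratifier: str = "weight_category",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per genotype x stratum descriptives with Dunn-Bonferroni letter groups.

    For each stratum and variable: n, mean, sd per genotype class plus a
    compact letter display from the rank-based pairwise tests (Bonferroni
    within the genotype family). Genotype classes with < 2 observations are
    excluded from the comparisons but their descriptives are still printed
    (letter left blank).
    """
    snp = cohort.snp(snp_id)
    df = cohort.data
    rows = []
    strata = sorted(df[stratifier].dropna().unique()) if stratifier else [None]
    for stratum in strata:
        classes = genotype_classes(cohort, snp_id, stratum)
        sub = df.loc[classes.index]
        for var in variables:
            groups = [
                sub.loc[classes == g, var].dropna().to_numpy(dtype=float)
                for g in GENOTYPE_ORDER
            ]
            usable = [len(g) >= 2 for g in groups]
            praw = dunn_pairwise(groups)
            n_pairs = sum(1 for i, j in combinations(range(3), 2) if usable[i] and usable[j])
            padj = np.minimum(1.0, praw * max(1, n_pairs))
            significant = (padj < alpha) & ~np.isnan(praw)
            letters = _letter_display(3, significant, usable)
            genotype_labels = {
                "major_homo": snp.major_allele * 2,
                "het": snp.major_allele + snp.minor_allele,
                "minor_homo": snp.minor_allele * 2,
            }
            for g, vals, letter, ok in zip(GENOTYPE_ORDER, groups, letters, usable):
                rows.append(
                    {
                        "snp_id": snp_id,
                        "gene": snp.gene,
                        "stratum": stratum,
                        "genotype": genotype_labels[g],
                        "genotype_class": g,
                        "variable": var,
                        "n": len(vals),
                        "mean": vals.mean() if len(vals) else np.nan,
                        "sd": vals.std(ddof=1) if len(vals) > 1 else np.nan,
                        "letters": letter if ok else "",
                        "in_comparison": ok,
                    }
                )
    return pd.DataFrame(rows)
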