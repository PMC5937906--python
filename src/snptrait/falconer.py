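"""Falconer single-locus effect decomposition.

Given the three genotype phenotype means at a biallelic locus and the
allele frequencies, the classical quantitative-genetics decomposition is

    m     = (mean_major_homo + mean_minor_homo) / 2    homozygote midpoint
    a     = mean_minor_homo - m                        additive effect
    d     = mean_het - m                               dominance deviation
    alpha = a + d (p - q)                              average effect of an
                                                       allele substitution

with p the major- and q the minor-allele frequency, and the substitution
oriented toward the minor allele. The minor allele's average effect is
alpha_1 = p * alpha. The frequency-weighted population mean under
Hardy-Weinberg proportions is M = m + a (q - p) + 2 p q d; the headline
``population_mean`` field reports the homozygote midpoint m, with the
frequency-weighted value available separately as ``freq_weighted_mean``.

Dominance is typed by the ratio r = |d / a| (no dominance ~ 0, partial
< 1, complete ~ 1, overdominance > 1, with a configurable relative band
around 1), and the minor allele's effect on the standardized phenotype is
graded very weak / weak / medium / strong by |x| against the cutoffs
0.05, 0.2 and 0.8, boundaries assigned upward, with direction from the
sign of x.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .assoc import AlleleFreqs, GenotypeCounts, allele_freqs, count_genotypes
from .io import CohortTable, DataError

__all__ = [
    "EffectGradeCutoffs",
    "PooledGenotypeMeans",
    "FalconerEffects",
    "pool_stratum_means",
    "falconer_decompose",
    "classify_dominance",
    "grade_effect_size",
    "effects_table",
    "NO_DOMINANCE",
    "PARTIAL_DOMINANCE",
    "COMPLETE_DOMINANCE",
    "OVERDOMINANCE",
]

NO_DOMINANCE = "no_dominance"
PARTIAL_DOMINANCE = "partial_dominance"
COMPLETE_DOMINANCE = "complete_dominance"
OVERDOMINANCE = "overdominance"

#: minor-homozygote classes thinner than this are flagged as fragile
SMALL_CLASS_N = 5


@dataclass(frozen=True)
class EffectGradeCutoffs:
    """|x| thresholds (standardized phenotype units) separating effect grades."""

    very_weak_max: float = 0.05
    weak_max: float = 0.2
    medium_max: float = 0.8

    def __post_init__(self) -> None:
        if not 0 < self.very_weak_max < self.weak_max < self.medium_max:
            raise DataError("effect-grade cutoffs must be strictly increasing and positive")


@dataclass(frozen=True)
class PooledGenotypeMeans:
    """Per-genotype phenotype means and sample sizes (possibly pooled over strata)."""

    mean_major_homo: float
    mean_het: float
    mean_minor_homo: float
    n_major_homo: int
    n_het: int
    n_minor_homo: int


def pool_stratum_means(strata: Sequence[tuple[int, float]]) -> tuple[int, float]:
    """n-weighted pooled mean over strata given (n, mean) pairs."""
    if not strata:
        raise DataError("cannot pool an empty list of strata")
    ns = np.array([n for n, _ in strata], dtype=float)
    if np.any(ns < 1):
        raise DataError("every stratum must have n >= 1")
    means = np.array([m for _, m in strata], dtype=float)
    total = ns.sum()
    return int(total), float((ns * means).sum() / total)


def classify_dominance(a: float, d: float, tol: float = 0.25) -> str:
    """Dominance type from the additive effect a and dominance deviation d.

    Classifies by r = |d/a| with a relative band of width ``tol`` around
    the landmark ratios: |d| <= tol|a| is no dominance, |r - 1| <= tol is
    complete, r < 1 - tol partial, r > 1 + tol overdominance. a = 0 with
    d != 0 is overdominance (r infinite); a = d = 0 degenerates to no
    dominance.
    """
    if a == 0.0 and d == 0.0:
        return NO_DOMINANCE
    if a == 0.0:
        return OVERDOMINANCE
    r = abs(d / a)
    if r <= tol:
        return NO_DOMINANCE
    if abs(r - 1.0) <= tol:
        return COMPLETE_DOMINANCE
    if r < 1.0 - tol:
        return PARTIAL_DOMINANCE
    return OVERDOMINANCE


def grade_effect_size(x: float, cutoffs: EffectGradeCutoffs = EffectGradeCutoffs()) -> str:
    """Grade an effect on the standardized phenotype, e.g. ``"weak decrease"``.

    |x| is compared against the cutoffs with boundary values assigned to
    the higher grade (|x| = 0.05 is already "weak"). x = 0 grades as
    "very weak" with no direction.
    """
    if not np.isfinite(x):
        raise DataError("cannot grade a non-finite effect")
    mag = abs(x)
    if mag < cutoffs.very_weak_max:
        grade = "very weak"
    elif mag < cutoffs.weak_max:
        grade = "weak"
    elif mag < cutoffs.medium_max:
        grade = "medium"
    else:
        grade = "strong"
    if x == 0:
        return "very weak"
    return f"{grade} {'increase' if x > 0 else 'decrease'}"


@dataclass(frozen=True)
class FalconerEffects:
    """Full effect decomposition for one SNP x one phenotype."""

    phenotype: str
    midpoint: float
    additive: float
    dominance: float
    alpha: float
    minor_avg_effect: float
    aecme: float  # per-substitution effect toward the minor allele (= alpha)
    freq_weighted_mean: float
    p_major: float
    q_minor: float
    n_major_homo: int
    n_het: int
    n_minor_homo: int
    dominance_type: str
    effect_grade: str
    degenerate: bool = False
    small_minor_class: bool = False

    @property
    def population_mean(self) -> float:
        """Reported population mean: the homozygote midpoint m."""
        return self.midpoint

    @property
    def dominance_ratio(self) -> float:
        if self.additive == 0.0:
            return np.inf if self.dominance != 0.0 else 0.0
        return abs(self.dominance / self.additive)

    def genotype_means(self) -> tuple[float, float, float]:
        """Reconstruct (major-homo, het, minor-homo) means exactly."""
        return (
            self.midpoint - self.additive,
            self.midpoint + self.dominance,
            self.midpoint + self.additive,
        )


def falconer_decompose(
    means: PooledGenotypeMeans,
    freqs: AlleleFreqs,
    phenotype: str = "zbmi",
    dominance_tol: float = 0.25,
    cutoffs: EffectGradeCutoffs = EffectGradeCutoffs(),
    grade_source: str = "minor_avg_effect",
) -> FalconerEffects:
    """Decompose genotype means into Falconer effect components.

    ``grade_source`` names the quantity fed to :func:`grade_effect_size`
    (``"minor_avg_effect"``, ``"alpha"`` or ``"additive"``). All three
    genotype classes must be observed (n >= 1).
    """
    for name, n in (
        ("major homozygote", means.n_major_homo),
        ("heterozygote", means.n_het),
        ("minor homozygote", means.n_minor_homo),
    ):
        if n < 1:
            raise DataError(f"falconer_decompose: {name} class is empty")
    m = (means.mean_major_homo + means.mean_minor_homo) / 2.0
    a = means.mean_minor_homo - m
    d = means.mean_het - m
    p, q = freqs.p, freqs.q
    alpha = a + d * (p - q)
    alpha1 = p * alpha
    freq_weighted = m + a * (q - p) + 2.0 * p * q * d
    graded = {"minor_avg_effect": alpha1, "alpha": alpha, "additive": a}
    if grade_source not in graded:
        raise DataError(f"unknown grade_source {grade_source!r}")
    return FalconerEffects(
        phenotype=phenotype,
        midpoint=m,
        additive=a,
        dominance=d,
        alpha=alpha,
        minor_avg_effect=alpha1,
        aecme=alpha,
        freq_weighted_mean=freq_weighted,
        p_major=p,
        q_minor=q,
        n_major_homo=means.n_major_homo,
        n_het=means.n_het,
        n_minor_homo=means.n_minor_homo,
        dominance_type=classify_dominance(a, d, dominance_tol),
        effect_grade=grade_effect_size(graded[grade_source], cutoffs),
        degenerate=(a == 0.0 and d == 0.0),
        small_minor_class=means.n_minor_homo < SMALL_CLASS_N,
    )


def _se_additive(values_by_class: dict[str, np.ndarray]) -> float:
    """Standard error of the additive estimate from per-class samples."""
    var = 0.0
    for cls in ("major_homo", "minor_homo"):
        v = values_by_class[cls]
        if len(v) < 2:
            return np.nan
        var += v.var(ddof=1) / len(v) / 4.0
    return float(np.sqrt(var))


def effects_table(
    cohort: CohortTable,
    phenotypes: Sequence[str] = ("bmi", "zbmi"),
    dominance_tol: float = 0.25,
    cutoffs: EffectGradeCutoffs = EffectGradeCutoffs(),
    grade_source: str = "minor_avg_effect",
) -> tuple[pd.DataFrame, dict[tuple[str, str], FalconerEffects | None]]:
    """Per SNP x phenotype Falconer decomposition from individual-level data.

    Genotype means are computed directly from the cohort records; allele
    frequencies from the per-SNP genotype counts. SNPs with an empty
    genotype class yield a ``None`` entry (and an ``NA`` row) rather than
    an error; minor-homozygote classes below ``SMALL_CLASS_N`` are flagged.
    Returns (tidy table, {(snp_id, phenotype): FalconerEffects or None}).
    """
    from .assoc import genotype_classes  # local import to avoid cycle at module load

    if not cohort.has_derived:
        raise DataError("cohort lacks derived anthropometrics; run derive_anthropometrics first")
    rows = []
    results: dict[tuple[str, str], FalconerEffects | None] = {}
    for snp in cohort.panel:
        counts = count_genotypes(cohort, snp.snp_id)
        freqs = allele_freqs(counts)
        classes = genotype_classes(cohort, snp.snp_id)
        sub = cohort.data.loc[classes.index]
        for phenotype in phenotypes:
            by_class = {
                g: sub.loc[classes == g, phenotype].dropna().to_numpy(dtype=float)
                for g in ("major_homo", "het", "minor_homo")
            }
            ns = {g: len(v) for g, v in by_class.items()}
            if min(ns.values()) < 1:
                results[(snp.snp_id, phenotype)] = None
                rows.append(
                    {
                        "snp_id": snp.snp_id,
                        "gene": snp.gene,
                        "phenotype": phenotype,
                        "computable": False,
                        "n_major_homo": ns["major_homo"],
                        "n_het": ns["het"],
                        "n_minor_homo": ns["minor_homo"],
                        "q_minor": freqs.q,
                    }
                )
                continue
            means = PooledGenotypeMeans(
                mean_major_homo=by_class["major_homo"].mean(),
                mean_het=by_class["het"].mean(),
                mean_minor_homo=by_class["minor_homo"].mean(),
                n_major_homo=ns["major_homo"],
                n_het=ns["het"],
                n_minor_homo=ns["minor_homo"],
            )
            eff = falconer_decompose(
                means,
                freqs,
                phenotype=phenotype,
                dominance_tol=dominance_tol,
                cutoffs=cutoffs,
                grade_source=grade_source,
            )
            results[(snp.snp_id, phenotype)] = eff
            rows.append(
                {
                    "snp_id": snp.snp_id,
                    "gene": snp.gene,
                    "phenotype": phenotype,
                    "computable": True,
                    "dominant_effect": eff.dominance,
                    "additive_effect": eff.additive,
                    "additive_se": _se_additive(by_class),
                    "population_mean": eff.population_mean,
                    "freq_weighted_mean": eff.freq_weighted_mean,
                    "minor_avg_effect": eff.minor_avg_effect,
                    "aecme": eff.aecme,
                    "dominance_type": eff.dominance_type,
                    "effect_grade": eff.effect_grade,
                    "n_major_homo": eff.n_major_homo,
                    "n_het": eff.n_het,
                    "n_minor_homo": eff.n_minor_homo,
                    "q_minor": eff.q_minor,
                    "small_minor_class": eff.small_minor_class,
                }
            )
    return pd.DataFrame(rows), results
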