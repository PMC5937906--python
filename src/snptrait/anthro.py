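"""Derived phenotypes and stratified descriptive statistics.

BMI, LMS-standardized BMI z-scores (zBMI), IOTF-style weight-category
classification, circumference ratios, HOMA-IR, and the sex- or
weight-category-stratified summary tables with rank-based pairwise
comparisons (Dunn's z on mean ranks, Bonferroni-adjusted).

The LMS method maps a measured value X to SD units via the Box-Cox
parameters of a growth reference:

    z = ((X/M)^L - 1) / (L * S)     for |L| > 1e-8
    z = ln(X/M) / S                 in the L -> 0 limit

where L is the Box-Cox power, M the age/sex median and S the coefficient
of variation. L, M and S are interpolated linearly in age, each parameter
independently. Growth-reference and cutoff tables are pluggable inputs,
never embedded constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CohortTable, DataError, ConfigError

__all__ = [
    "DAYS_PER_MONTH",
    "compute_bmi",
    "lms_zscore",
    "lms_inverse",
    "lms_lookup",
    "iotf_classify",
    "homa_ir",
    "derive_anthropometrics",
    "StratifiedSummary",
    "stratified_summary",
    "dunn_pairwise",
    "welch_pairwise",
    "DEFAULT_SUMMARY_VARIABLES",
]

#: mean Gregorian month length, used to convert exact age in days to the
#: monthly grid of growth references
DAYS_PER_MONTH = 30.4375

NORMAL_WEIGHT = "normal_weight"
OVERWEIGHT_OBESE = "overweight_obese"


def compute_bmi(weight_kg, height_cm):
    """Body-mass index, kg/m^2. Heights below 50 are rejected as probable meters."""
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(weight_kg <= 0):
        raise DataError("weight must be positive")
    if np.any(height_cm <= 0):
        raise DataError("height must be positive")
    if np.any(height_cm < 50):
        raise DataError("height < 50 cm: value looks like meters, refusing to guess")
    out = weight_kg / (height_cm / 100.0) ** 2
    return float(out) if out.ndim == 0 else out


def lms_zscore(x, L, M, S):
    """LMS (Box-Cox) z-score of measurement ``x`` against reference (L, M, S)."""
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0):
        raise DataError("LMS z-score requires a positive measurement")
    if np.any(M <= 0) or np.any(S <= 0):
        raise DataError("LMS parameters require M > 0 and S > 0")
    general = np.divide(
        np.power(x / M, L) - 1.0,
        L * S,
        out=np.zeros(np.broadcast_shapes(x.shape, L.shape, M.shape, S.shape)),
        where=np.abs(L) > 1e-8,
    )
    log_form = np.log(x / M) / S
    out = np.where(np.abs(L) > 1e-8, general, log_form)
    return float(out) if out.ndim == 0 else out


def lms_inverse(z, L, M, S):
    """Measurement at z-score ``z``: the inverse of :func:`lms_zscore`."""
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    base = 1.0 + L * S * z
    if np.any(base[np.abs(L) > 1e-8] <= 0):
        raise DataError("z-score outside the domain of the Box-Cox reference")
    general = np.power(
        base, np.divide(1.0, L, out=np.ones_like(L), where=np.abs(L) > 1e-8)
    )
    out = M * np.where(np.abs(L) > 1e-8, general, np.exp(S * z))
    return float(out) if out.ndim == 0 else out


def _interp_column(table: pd.DataFrame, age_col: str, ages, value_col: str):
    xp = table[age_col].to_numpy(dtype=float)
    fp = table[value_col].to_numpy(dtype=float)
    return np.interp(ages, xp, fp)


def lms_lookup(sex: str, age_days, lms_table: pd.DataFrame):
    """Interpolate (L, M, S) at an exact age in days for one sex.

    Linear interpolation in age_months per parameter; ages are accepted up
    to one grid step beyond either end of the table (held constant there,
    matching ``np.interp``), anything further is an error naming the range.
    """
    block = lms_table[lms_table["sex"] == sex]
    if block.empty:
        raise DataError(f"LMS table has no rows for sex {sex!r}")
    age_months = np.asarray(age_days, dtype=float) / DAYS_PER_MONTH
    ages = block["age_months"].to_numpy(dtype=float)
    step = np.diff(ages).max() if len(ages) > 1 else 1.0
    lo, hi = ages[0] - step, ages[-1] + step
    if np.any(age_months < lo) or np.any(age_months > hi):
        raise DataError(
            f"age {np.atleast_1d(age_months).min():.1f}-{np.atleast_1d(age_months).max():.1f} months "
            f"outside LMS reference range [{ages[0]}, {ages[-1]}] (+/- one grid step)"
        )
    L = _interp_column(block, "age_months", age_months, "L")
    M = _interp_column(block, "age_months", age_months, "M")
    S = _interp_column(block, "age_months", age_months, "S")
    if np.ndim(age_days) == 0:
        return float(L), float(M), float(S)
    return L, M, S


def iotf_classify(bmi, sex: str, age_years, cutoffs: pd.DataFrame):
    """Dichotomous weight category from age/sex BMI cutoffs.

    Returns ``"overweight_obese"`` iff bmi >= the interpolated overweight
    cutoff (ties classify upward — the case group merges overweight and
    obese), else ``"normal_weight"``.
    """
    block = cutoffs[cutoffs["sex"] == sex]
    if block.empty:
        raise DataError(f"IOTF cutoff table has no rows for sex {sex!r}")
    ages = block["age_years"].to_numpy(dtype=float)
    step = np.diff(ages).max() if len(ages) > 1 else 1.0
    age_years = np.asarray(age_years, dtype=float)
    if np.any(age_years < ages[0] - step) or np.any(age_years > ages[-1] + step):
        raise DataError(
            f"age outside IOTF cutoff range [{ages[0]}, {ages[-1]}] years (+/- one grid step)"
        )
    threshold = _interp_column(block, "age_years", age_years, "bmi_overweight")
    out = np.where(np.asarray(bmi, dtype=float) >= threshold, OVERWEIGHT_OBESE, NORMAL_WEIGHT)
    return str(out) if out.ndim == 0 else out


def homa_ir(insulin_uU_ml, glucose_mg_dl):
    """HOMA insulin-resistance index: insulin (uU/ml) x glucose (mg/dl) / 405."""
    insulin = np.asarray(insulin_uU_ml, dtype=float)
    glucose = np.asarray(glucose_mg_dl, dtype=float)
    if np.any(insulin < 0) or np.any(glucose < 0):
        raise DataError("HOMA-IR inputs must be non-negative")
    out = insulin * glucose / 405.0
    return float(out) if out.ndim == 0 else out


def derive_anthropometrics(
    cohort: CohortTable, lms_table: pd.DataFrame, iotf_table: pd.DataFrame
) -> CohortTable:
    """Attach derived columns: bmi, zbmi, weight_category, whr, whtr, homa_ir.

    Ratio and index columns are left missing wherever an input is missing;
    bmi/zbmi/weight_category are computed for every record (weight, height
    and age are required fields).
    """
    df = cohort.data.copy()
    df["bmi"] = compute_bmi(df["weight_kg"].to_numpy(), df["height_cm"].to_numpy())
    zbmi = np.empty(len(df))
    category = np.empty(len(df), dtype=object)
    age_years = df["age_days"].to_numpy(dtype=float) / 365.25
    for sex in ("male", "female"):
        mask = (df["sex"] == sex).to_numpy()
        if not mask.any():
            continue
        L, M, S = lms_lookup(sex, df.loc[mask, "age_days"].to_numpy(dtype=float), lms_table)
        zbmi[mask] = lms_zscore(df.loc[mask, "bmi"].to_numpy(), L, M, S)
        category[mask] = iotf_classify(
            df.loc[mask, "bmi"].to_numpy(), sex, age_years[mask], iotf_table
        )
    df["zbmi"] = zbmi
    df["weight_category"] = category
    if "waist_cm" in df.columns and "hip_cm" in df.columns:
        df["whr"] = df["waist_cm"] / df["hip_cm"]
    if "waist_cm" in df.columns:
        df["whtr"] = df["waist_cm"] / df["height_cm"]
    if "insulin_uU_ml" in df.columns and "glucose_mg_dl" in df.columns:
        both = df["insulin_uU_ml"].notna() & df["glucose_mg_dl"].notna()
        df["homa_ir"] = np.nan
        df.loc[both, "homa_ir"] = homa_ir(
            df.loc[both, "insulin_uU_ml"].to_numpy(), df.loc[both, "glucose_mg_dl"].to_numpy()
        )
    return CohortTable(cohort.panel, df)


# ---------------------------------------------------------------------------
# pairwise comparisons


def dunn_pairwise(groups: Sequence[np.ndarray]) -> np.ndarray:
    """Dunn's rank-based pairwise z-test p-values (raw, unadjusted).

    Ranks all observations jointly, compares mean ranks of each group pair
    with the tie-corrected null variance N(N+1)/12 - sum(t^3-t)/(12(N-1)).
    Returns a symmetric matrix of two-sided p-values (NaN where a group has
    < 2 observations).
    """
    k = len(groups)
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups]) if k else np.array([])
    N = len(pooled)
    pvals = np.full((k, k), np.nan)
    np.fill_diagonal(pvals, 1.0)
    if N == 0:
        return pvals
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (N - 1))) if N > 1 else 0.0
    var0 = N * (N + 1) / 12.0 - tie_term
    mean_ranks, sizes = [], []
    start = 0
    for g in groups:
        n = len(g)
        mean_ranks.append(ranks[start : start + n].mean() if n else np.nan)
        sizes.append(n)
        start += n
    for i, j in combinations(range(k), 2):
        if sizes[i] < 2 or sizes[j] < 2:
            continue
        if var0 <= 0:  # every observation tied: no evidence of any difference
            pvals[i, j] = pvals[j, i] = 1.0
            continue
        z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var0 * (1.0 / sizes[i] + 1.0 / sizes[j]))
        p = 2.0 * stats.norm.sf(abs(z))
        pvals[i, j] = pvals[j, i] = min(1.0, p)
    return pvals


def welch_pairwise(groups: Sequence[np.ndarray]) -> np.ndarray:
    """Welch two-sample t-test p-values for every group pair (raw)."""
    k = len(groups)
    pvals = np.full((k, k), np.nan)
    np.fill_diagonal(pvals, 1.0)
    for i, j in combinations(range(k), 2):
        a, b = np.asarray(groups[i], dtype=float), np.asarray(groups[j], dtype=float)
        if len(a) < 2 or len(b) < 2:
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals[i, j] = pvals[j, i] = 1.0
            continue
        pvals[i, j] = pvals[j, i] = stats.ttest_ind(a, b, equal_var=False).pvalue
    return pvals


DEFAULT_SUMMARY_VARIABLES = (
    "age_days",
    "weight_kg",
    "height_cm",
    "bmi",
    "zbmi",
    "waist_cm",
    "hip_cm",
    "whr",
    "whtr",
    "muac_cm",
    "calf_cm",
    "body_fat_pct",
    "skeletal_muscle_pct",
    "rmr_kcal",
    "tc_mg_dl",
    "ldl_mg_dl",
    "hdl_mg_dl",
    "tg_mg_dl",
    "apoa1_g_l",
    "apob_g_l",
    "glucose_mg_dl",
    "creatinine_mg_dl",
    "total_protein_g_dl",
    "ferritin_ng_ml",
    "leptin_ng_ml",
    "insulin_uU_ml",
    "homa_ir",
)


@dataclass
class StratifiedSummary:
    """Per-stratum descriptives plus Bonferroni-adjusted pairwise comparisons."""

    stratifier: str
    strata: list[str]
    descriptives: pd.DataFrame  # variable, stratum, n, mean, sd
    comparisons: pd.DataFrame  # variable, stratum_a, stratum_b, p_raw, p_adj, significant, computable

    def to_tsv(self, path) -> None:
        merged = self.descriptives.copy()
        merged.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def stratified_summary(
    cohort: CohortTable,
    stratifier: str,
    variables: Sequence[str] | None = None,
    method: str = "dunn",
    alpha: float = 0.05,
) -> StratifiedSummary:
    """Descriptive table with pairwise between-stratum tests.

    ``method="dunn"`` (default) uses rank-based Dunn z-tests; ``"welch"``
    uses Welch t-tests. Raw p-values are multiplied by the number of
    stratum pairs (Bonferroni) and capped at 1. A comparison where either
    stratum has < 2 non-missing values is marked not-computable rather
    than raising.
    """
    if method not in ("dunn", "welch"):
        raise ConfigError(f"unknown comparison method {method!r}")
    df = cohort.data
    if stratifier not in df.columns:
        raise ConfigError(f"stratifier column {stratifier!r} not present (derive first?)")
    strata = sorted(df[stratifier].dropna().unique())
    if len(strata) < 2:
        raise DataError("stratified summary needs at least two non-empty strata")
    if variables is None:
        variables = [v for v in DEFAULT_SUMMARY_VARIABLES if v in df.columns]
    n_pairs = len(strata) * (len(strata) - 1) // 2
    test = dunn_pairwise if method == "dunn" else welch_pairwise

    desc_rows, comp_rows = [], []
    for var in variables:
        groups = [
            df.loc[df[stratifier] == s, var].dropna().to_numpy(dtype=float) for s in strata
        ]
        for s, g in zip(strata, groups):
            desc_rows.append(
                {
                    "variable": var,
                    "stratum": s,
                    "n": len(g),
                    "mean": g.mean() if len(g) else np.nan,
                    "sd": g.std(ddof=1) if len(g) > 1 else np.nan,
                }
            )
        praw = test(groups)
        for i, j in combinations(range(len(strata)), 2):
            raw = praw[i, j]
            computable = not np.isnan(raw)
            adj = min(1.0, raw * n_pairs) if computable else np.nan
            comp_rows.append(
                {
                    "variable": var,
                    "stratum_a": strata[i],
                    "stratum_b": strata[j],
                    "p_raw": raw,
                    "p_adj": adj,
                    "significant": bool(computable and adj < alpha),
                    "computable": computable,
                }
            )
    return StratifiedSummary(
        stratifier=stratifier,
        strata=list(strata),
        descriptives=pd.DataFrame(desc_rows),
        comparisons=pd.DataFrame(comp_rows),
    )
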