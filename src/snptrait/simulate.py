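"""Synthetic genotype-phenotype cohorts with planted single-locus effects.

The generator emulates the statistical structure the analysis assumes for
a prepubertal school cohort: biallelic genotypes drawn under
Hardy-Weinberg proportions at a configurable minor-allele frequency, a
standardized adiposity phenotype (zBMI) whose genotype-conditional means
follow the single-locus model (m - a, m + d, m + a) plus Gaussian noise,
anthropometry and fasting biochemistry generated by documented
correlated-normal recipes so that every downstream table has inputs, and a
dichotomous weight category derived from BMI through toy LMS/IOTF
reference tables that are internally consistent with the generated data.

All randomness flows from a single integer seed; equal parameters and
seed reproduce the cohort bit for bit. The generator makes no claim of
physiological realism beyond first moments loosely matched to a
school-age population.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .anthro import DAYS_PER_MONTH, lms_inverse, lms_lookup
from .io import CohortTable, SnpDef, join_cohort, write_genotypes, write_phenotypes

__all__ = [
    "SnpSpec",
    "SimulationParams",
    "DEFAULT_SNP_SPECS",
    "simulate_genotypes",
    "simulate_cohort",
    "toy_lms_table",
    "toy_iotf_table",
    "make_paper_fixture",
]


@dataclass(frozen=True)
class SnpSpec:
    """One simulated locus: allele labels, minor-allele frequency and planted effects.

    ``additive``/``dominance`` are the planted a and d on the standardized
    phenotype (zBMI units): genotype shifts are -a, +d, +a around the locus
    midpoint for major-homo, het, minor-homo.
    """

    snp_id: str
    gene: str
    major_allele: str
    minor_allele: str
    maf: float
    additive: float = 0.0
    dominance: float = 0.0
    call_rate: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError("maf must lie in [0, 0.5]")
        if not 0.0 < self.call_rate <= 1.0:
            raise ValueError("call_rate must lie in (0, 1]")

    @property
    def snpdef(self) -> SnpDef:
        return SnpDef(self.snp_id, self.gene, self.major_allele, self.minor_allele)

    def mean_shift(self) -> float:
        """Expected phenotype shift under HWE: a(q^2 - p^2) + 2pq d."""
        q = self.maf
        p = 1.0 - q
        return self.additive * (q * q - p * p) + 2.0 * p * q * self.dominance

    def var_shift(self) -> float:
        q = self.maf
        p = 1.0 - q
        mu = self.mean_shift()
        vals = np.array([-self.additive, self.dominance, self.additive])
        probs = np.array([p * p, 2 * p * q, q * q])
        return float((probs * (vals - mu) ** 2).sum())


#: study-scale defaults: the five loci of a candidate-gene childhood
#: obesity panel, at their reported minor-allele frequencies, with planted
#: zBMI effects set to the published point estimates (the rare MC4R coding
#: variant carries no planted effect and its maf of 0.01 deliberately
#: produces zero minor homozygotes in most cohorts of this size). Call
#: rates mirror the per-SNP genotyped fractions of the study population.
DEFAULT_SNP_SPECS = (
    SnpSpec("rs1137101", "LEPR", "A", "G", 0.47, additive=-0.15, dominance=0.28, call_rate=617 / 773),
    SnpSpec("rs9939609", "FTO", "T", "A", 0.46, additive=0.06, dominance=-0.07, call_rate=530 / 773),
    SnpSpec("rs2229616", "MC4R", "G", "A", 0.01, call_rate=437 / 773),
    SnpSpec("rs17782313", "MC4R", "T", "C", 0.21, additive=0.17, dominance=-0.16, call_rate=352 / 773),
    SnpSpec("rs1801282", "PPARG", "C", "G", 0.09, additive=-0.15, dominance=0.10, call_rate=272 / 773),
)


@dataclass(frozen=True)
class SimulationParams:
    """Cohort-level simulation settings; the seed is mandatory."""

    n: int = 773
    n_male: int | None = 381  # None: Binomial(n, 1/2)
    snps: tuple[SnpSpec, ...] = DEFAULT_SNP_SPECS
    zbmi_mean: float = 0.6  # baseline standardized adiposity, SD units
    noise_sd: float = 1.0  # residual zBMI noise
    case_fraction: float = 0.301  # target overweight/obese fraction
    missing_rate: float = 0.0  # extra missingness on optional phenotype cells
    age_days_range: tuple[int, int] = (3300, 3900)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    def zbmi_marginal(self) -> tuple[float, float]:
        """Analytic mean and SD of the simulated zBMI marginal."""
        mu = self.zbmi_mean + sum(s.mean_shift() for s in self.snps)
        var = self.noise_sd**2 + sum(s.var_shift() for s in self.snps)
        return mu, float(np.sqrt(var))

    def case_threshold(self) -> float:
        """zBMI cutoff putting ``case_fraction`` of the cohort in the case group."""
        mu, sd = self.zbmi_marginal()
        return mu + sd * stats.norm.ppf(1.0 - self.case_fraction)


def simulate_genotypes(n: int, maf: float, rng: np.random.Generator) -> np.ndarray:
    """Minor-allele dosage (0/1/2) per sample under Hardy-Weinberg proportions."""
    q = maf
    p = 1.0 - q
    return rng.choice(3, size=n, p=[p * p, 2 * p * q, q * q])


# toy growth reference: Box-Cox power held constant, median BMI rising
# gently with age, slightly different by sex
_TOY_L = -1.5
_TOY_S = 0.11


def toy_lms_table(age_lo_months: int = 60, age_hi_months: int = 156, step: int = 6) -> pd.DataFrame:
    rows = []
    for sex, m0, slope in (("male", 15.0, 0.030), ("female", 14.8, 0.032)):
        for age in range(age_lo_months, age_hi_months + 1, step):
            rows.append(
                {"sex": sex, "age_months": age, "L": _TOY_L, "M": m0 + slope * (age - 60), "S": _TOY_S}
            )
    return pd.DataFrame(rows)


def toy_iotf_table(z_overweight: float, z_obese: float, lms: pd.DataFrame) -> pd.DataFrame:
    """BMI cutoffs equivalent to fixed zBMI thresholds under the toy LMS reference."""
    rows = []
    for sex, block in lms.groupby("sex", sort=True):
        for _, r in block.iterrows():
            rows.append(
                {
                    "sex": sex,
                    "age_years": r["age_months"] * DAYS_PER_MONTH / 365.25,
                    "bmi_overweight": lms_inverse(z_overweight, r["L"], r["M"], r["S"]),
                    "bmi_obese": lms_inverse(z_obese, r["L"], r["M"], r["S"]),
                }
            )
    return pd.DataFrame(rows).sort_values(["sex", "age_years"]).reset_index(drop=True)


def _genotype_strings(dosage: np.ndarray, spec: SnpSpec) -> list[str]:
    gmap = {
        0: "/".join(sorted(spec.major_allele * 2)),
        1: "/".join(sorted(spec.major_allele + spec.minor_allele)),
        2: "/".join(sorted(spec.minor_allele * 2)),
    }
    return [gmap[int(g)] for g in dosage]


def simulate_cohort(
    params: SimulationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate (phenotypes, genotypes, lms_table, iotf_table).

    Phenotypes and genotypes come in the exact column schemas the readers
    in :mod:`snptrait.io` produce, so a simulated cohort can be written to
    disk and pushed through the pipeline unchanged.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n
    n_male = params.n_male if params.n_male is not None else int(rng.binomial(n, 0.5))
    sex = np.array(["male"] * n_male + ["female"] * (n - n_male))
    age_days = rng.integers(params.age_days_range[0], params.age_days_range[1] + 1, size=n)

    dosages = {spec.snp_id: simulate_genotypes(n, spec.maf, rng) for spec in params.snps}
    zbmi = params.zbmi_mean + rng.normal(0.0, params.noise_sd, size=n)
    for spec in params.snps:
        shift = np.array([-spec.additive, spec.dominance, spec.additive])
        zbmi += shift[dosages[spec.snp_id]]
    zbmi = np.clip(zbmi, -5.0, 5.0)  # stay inside the Box-Cox domain

    lms = toy_lms_table()
    z_ow = params.case_threshold()
    iotf = toy_iotf_table(z_ow, z_ow + 1.0, lms)

    bmi = np.empty(n)
    for s in ("male", "female"):
        mask = sex == s
        L, M, S = lms_lookup(s, age_days[mask].astype(float), lms)
        bmi[mask] = lms_inverse(zbmi[mask], L, M, S)

    height = np.where(sex == "male", 138.7, 137.7) + rng.normal(0.0, 6.5, size=n) + 1.4 * zbmi
    height = np.clip(height, 110.0, 175.0)
    weight = bmi * (height / 100.0) ** 2

    # ancillary measurements: documented linear recipes around the adiposity
    # signal, Gaussian residuals; coefficients chosen once to land near the
    # study population's first moments
    waist = 20.0 + 2.0 * bmi + 0.06 * height + rng.normal(0.0, 3.0, size=n)
    hip = 30.0 + 1.8 * bmi + 0.06 * height + rng.normal(0.0, 3.0, size=n)
    muac = 5.0 + 0.88 * bmi + rng.normal(0.0, 1.0, size=n)
    calf = 12.0 + 0.93 * bmi + rng.normal(0.0, 1.5, size=n)
    body_fat = np.clip(19.0 + 4.5 * zbmi + (sex == "female") * 1.5 + rng.normal(0, 3.5, n), 3, 55)
    skel_muscle = np.clip(31.9 - 0.4 * zbmi + (sex == "male") * 0.6 + rng.normal(0, 2.5, n), 20, 45)
    rmr = 1000.0 + 5.9 * weight + rng.normal(0.0, 60.0, size=n)

    glucose = 78.0 + 1.7 * (sex == "male") + 0.8 * zbmi + rng.normal(0.0, 10.0, size=n)
    glucose = np.clip(glucose, 45.0, 160.0)
    insulin = np.exp(rng.normal(1.45, 0.55, size=n)) + 1.2 * np.clip(zbmi, 0.0, None)
    leptin = np.exp(rng.normal(1.2, 0.8, size=n)) + 4.5 * np.clip(zbmi, 0.0, None) ** 2
    tc = np.clip(170.0 + rng.normal(0.0, 30.0, size=n), 80, 300)
    hdl = np.clip(55.5 - 1.8 * zbmi + rng.normal(0.0, 10.0, size=n), 20, 110)
    tg = np.clip(58.0 + 7.0 * np.clip(zbmi, 0, None) + rng.normal(0.0, 22.0, size=n), 20, 300)
    ldl = np.clip(tc - hdl - tg / 5.0, 25, None)  # Friedewald closure
    apoa1 = np.clip(0.55 + 0.0145 * hdl + rng.normal(0.0, 0.10, size=n), 0.6, 2.4)
    apob = np.clip(0.20 + 0.0059 * ldl + rng.normal(0.0, 0.07, size=n), 0.2, 1.8)
    creatinine = np.clip(0.60 + 0.02 * (sex == "male") + rng.normal(0, 0.09, n), 0.25, 1.2)
    total_protein = np.clip(7.43 + rng.normal(0.0, 0.7, size=n), 5.0, 10.0)
    ferritin = np.exp(rng.normal(3.5, 0.5, size=n))

    pheno = pd.DataFrame(
        {
            "sample_id": [f"S{i:04d}" for i in range(1, n + 1)],
            "sex": sex,
            "age_days": age_days.astype(int),
            "weight_kg": weight,
            "height_cm": height,
            "waist_cm": waist,
            "hip_cm": hip,
            "muac_cm": muac,
            "calf_cm": calf,
            "body_fat_pct": body_fat,
            "skeletal_muscle_pct": skel_muscle,
            "rmr_kcal": rmr,
            "tc_mg_dl": tc,
            "ldl_mg_dl": ldl,
            "hdl_mg_dl": hdl,
            "tg_mg_dl": tg,
            "apoa1_g_l": apoa1,
            "apob_g_l": apob,
            "glucose_mg_dl": glucose,
            "creatinine_mg_dl": creatinine,
            "total_protein_g_dl": total_protein,
            "ferritin_ng_ml": ferritin,
            "leptin_ng_ml": leptin,
            "insulin_uU_ml": insulin,
        }
    )
    if params.missing_rate > 0:
        optional = [c for c in pheno.columns if c not in ("sample_id", "sex", "age_days", "weight_kg", "height_cm")]
        mask = rng.random((n, len(optional))) < params.missing_rate
        for j, col in enumerate(optional):
            pheno.loc[mask[:, j], col] = np.nan

    geno = pd.DataFrame(index=pd.Index(pheno["sample_id"], name="sample_id"))
    for spec in params.snps:
        cells = pd.array(_genotype_strings(dosages[spec.snp_id], spec), dtype="string")
        if spec.call_rate < 1.0:
            drop = rng.random(n) >= spec.call_rate
            cells[drop] = pd.NA
        geno[spec.snp_id] = cells
    return pheno, geno, lms, iotf


def make_paper_fixture(
    seed: int = 0, outdir: str | Path | None = None, params: SimulationParams | None = None
) -> tuple[CohortTable, pd.DataFrame, pd.DataFrame]:
    """Study-scale fixture: n = 773 (381 male / 392 female), five SNPs.

    Minor-allele frequencies, per-SNP call rates and the ~30% case
    fraction match the study conditions; planted effects are the published
    per-SNP point estimates. Returns (cohort, lms_table, iotf_table) and,
    when ``outdir`` is given, writes phenotype/genotype/reference CSVs plus
    a JSON manifest of all parameters so the files regenerate bit-for-bit.
    """
    params = params or SimulationParams(seed=seed)
    pheno, geno, lms, iotf = simulate_cohort(params)
    cohort = join_cohort(pheno, geno, [s.snpdef for s in params.snps])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_phenotypes(pheno, outdir / "phenotypes.csv")
        write_genotypes(geno, outdir / "genotypes.csv")
        lms.to_csv(outdir / "lms_reference.csv", index=False, float_format="%.12g")
        iotf.to_csv(outdir / "iotf_cutoffs.csv", index=False, float_format="%.12g")
        manifest = {
            "seed": params.seed,
            "n": params.n,
            "n_male": params.n_male,
            "case_fraction": params.case_fraction,
            "zbmi_mean": params.zbmi_mean,
            "noise_sd": params.noise_sd,
            "snps": [
                {
                    "snp_id": s.snp_id,
                    "gene": s.gene,
                    "major": s.major_allele,
                    "minor": s.minor_allele,
                    "maf": s.maf,
                    "additive": s.additive,
                    "dominance": s.dominance,
                    "call_rate": s.call_rate,
                }
                for s in params.snps
            ],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return cohort, lms, iotf
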