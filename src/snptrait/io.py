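"""Cohort, genotype and reference-table I/O.

The package operates on three kinds of tabular input:

* a **phenotype table** — one row per child with sex, age (in days, or a
  birth/exam date pair), anthropometry, bioimpedance and fasting
  biochemistry;
* a **genotype table** — per-child genotype calls for a panel of named
  biallelic SNPs, either as a wide CSV/TSV with ``"A/G"``-style cells or as
  a biallelic-SNP subset of VCF v4.2;
* **growth references** — a sex/age-indexed LMS table and an IOTF-style
  BMI-cutoff table.

Tables are held as validated :class:`pandas.DataFrame` objects; the joined
per-child view consumed by every downstream stage is a :class:`CohortTable`.
Missing values are written with an explicit ``NA`` sentinel, never as ``0``
or an empty cell, because several biochemistry analytes are legitimately
close to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "ConfigError",
    "SnpDef",
    "GenotypeCall",
    "CohortTable",
    "MISSING",
    "REQUIRED_PHENOTYPE_COLUMNS",
    "OPTIONAL_PHENOTYPE_COLUMNS",
    "read_phenotypes",
    "write_phenotypes",
    "read_genotypes",
    "write_genotypes",
    "read_lms_table",
    "read_iotf_table",
    "infer_panel",
    "join_cohort",
    "geno_col",
]


class DataError(ValueError):
    """A record or file violates the data contract (bad value, duplicate id...)."""


class ConfigError(ValueError):
    """The input is structurally unusable (missing column, unknown format...)."""


#: sentinel written for missing cells; distinct from 0 and from ""
MISSING = "NA"

REQUIRED_PHENOTYPE_COLUMNS = ("sample_id", "sex", "weight_kg", "height_cm")

#: optional per-child measurements; unit is part of the column name
OPTIONAL_PHENOTYPE_COLUMNS = (
    "waist_cm",
    "hip_cm",
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
)

_SEXES = ("male", "female")


@dataclass(frozen=True)
class SnpDef:
    """A biallelic locus with a declared major (wild-type) and minor allele."""

    snp_id: str
    gene: str
    major_allele: str
    minor_allele: str

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ConfigError("snp_id must be non-empty")
        object.__setattr__(self, "major_allele", self.major_allele.upper())
        object.__setattr__(self, "minor_allele", self.minor_allele.upper())
        for allele in (self.major_allele, self.minor_allele):
            if len(allele) != 1:
                raise ConfigError(
                    f"{self.snp_id}: allele symbols must be single characters, got {allele!r}"
                )
        if self.major_allele == self.minor_allele:
            raise ConfigError(f"{self.snp_id}: major and minor allele must differ")

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset((self.major_allele, self.minor_allele))

    def flipped(self) -> "SnpDef":
        """Same locus with major/minor orientation swapped."""
        return SnpDef(self.snp_id, self.gene, self.minor_allele, self.major_allele)


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's genotype at one SNP; ``alleles`` is an unordered pair or None."""

    sample_id: str
    snp_id: str
    alleles: tuple[str, str] | None

    def __post_init__(self) -> None:
        if self.alleles is not None:
            a, b = (x.upper() for x in self.alleles)
            # canonical sorted order makes "A/G" == "G/A"
            object.__setattr__(self, "alleles", tuple(sorted((a, b))))

    @property
    def missing(self) -> bool:
        return self.alleles is None

    def as_string(self) -> str:
        if self.alleles is None:
            return MISSING
        return "/".join(self.alleles)


def geno_col(snp_id: str) -> str:
    """Column name under which a SNP's calls are stored in a cohort frame."""
    return f"geno_{snp_id}"


def normalize_genotype_cell(cell: object) -> str | None:
    """Canonicalize a genotype cell: 'g/a', 'AG', 'A/G' -> 'A/G'; blank/NA -> None."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return None
    text = str(cell).strip().upper()
    if text in ("", MISSING, "./.", ".", "-"):
        return None
    alleles = text.split("/") if "/" in text else list(text)
    if len(alleles) != 2 or any(len(a) != 1 for a in alleles):
        raise DataError(f"unparseable genotype cell {cell!r}")
    return "/".join(sorted(alleles))


def _detect_dialect(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        if dialect not in ("csv", "tsv"):
            raise ConfigError(f"unknown dialect {dialect!r}")
        return dialect
    return "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"


def _read_table(path: Path, dialect: str | None) -> pd.DataFrame:
    sep = "\t" if _detect_dialect(path, dialect) == "tsv" else ","
    return pd.read_csv(
        path, sep=sep, na_values=[MISSING, ""], keep_default_na=False, dtype={"sample_id": str}
    )


def read_phenotypes(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    """Read a phenotype table into a validated DataFrame (one row per child).

    Age is accepted either as an ``age_days`` column or as ``birth_date`` +
    ``exam_date`` ISO dates, converted by calendar-day subtraction. Required
    cells must parse; unparseable optional cells become missing.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"phenotype file not found: {path}")
    df = _read_table(path, dialect)

    for col in REQUIRED_PHENOTYPE_COLUMNS:
        if col not in df.columns:
            raise ConfigError(f"phenotype table missing required column {col!r}")
    if "age_days" not in df.columns and not {"birth_date", "exam_date"} <= set(df.columns):
        raise ConfigError(
            "phenotype table must provide 'age_days' or both 'birth_date' and 'exam_date'"
        )

    if df["sample_id"].isna().any():
        raise DataError("phenotype table has empty sample_id cells")
    dup = df["sample_id"].duplicated()
    if dup.any():
        raise DataError(f"duplicate sample_id(s): {sorted(df.loc[dup, 'sample_id'])}")

    sex = df["sex"].astype(str).str.strip().str.lower()
    bad_sex = ~sex.isin(_SEXES)
    if bad_sex.any():
        raise DataError(f"unrecognized sex value(s): {sorted(df.loc[bad_sex, 'sex'].unique())}")
    df["sex"] = sex

    if "age_days" not in df.columns or df["age_days"].isna().any():
        births = pd.to_datetime(df["birth_date"], format="%Y-%m-%d")
        exams = pd.to_datetime(df["exam_date"], format="%Y-%m-%d")
        age_days = (exams - births).dt.days
        if "age_days" in df.columns:
            df["age_days"] = df["age_days"].fillna(age_days)
        else:
            df["age_days"] = age_days
    df["age_days"] = pd.to_numeric(df["age_days"], errors="raise").astype(int)
    if (df["age_days"] <= 0).any():
        raise DataError("age_days must be positive")

    for col in ("weight_kg", "height_cm"):
        df[col] = pd.to_numeric(df[col], errors="raise")
        if df[col].isna().any() or (df[col] <= 0).any():
            raise DataError(f"{col} must be present and positive for every record")

    for col in OPTIONAL_PHENOTYPE_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")

    keep = [c for c in df.columns if c not in ("birth_date", "exam_date")]
    return df[keep].reset_index(drop=True)


def write_phenotypes(df: pd.DataFrame, path: str | Path, dialect: str | None = None) -> None:
    """Write a phenotype table; missing cells become the ``NA`` sentinel."""
    path = Path(path)
    sep = "\t" if _detect_dialect(path, dialect) == "tsv" else ","
    df.to_csv(path, sep=sep, index=False, na_rep=MISSING, float_format="%.12g")


def read_genotypes(
    path: str | Path, fmt: str | None = None
) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Read genotype calls from a wide table or a biallelic-SNP VCF.

    Returns ``(genotypes, observed_alleles)`` where *genotypes* is a
    DataFrame indexed by ``sample_id`` with one column per SNP holding
    canonical ``"A/G"`` strings (alphabetically ordered alleles) or NA, and
    *observed_alleles* maps each SNP to the allele symbols seen (for VCF,
    REF and ALT even if unobserved).

    Format is auto-detected from the extension (``.vcf`` vs table) and can
    be forced with ``fmt`` in ``{"wide_table", "vcf"}``.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"genotype file not found: {path}")
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "wide_table"
    if fmt == "wide_table":
        return _read_genotypes_wide(path)
    if fmt == "vcf":
        return _read_genotypes_vcf(path)
    raise ConfigError(f"unknown genotype format {fmt!r}")


def _read_genotypes_wide(path: Path) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    df = _read_table(path, None)
    if "sample_id" not in df.columns:
        raise ConfigError("genotype table missing required column 'sample_id'")
    if df["sample_id"].duplicated().any():
        raise DataError("duplicate sample_id in genotype table")
    snp_ids = [c for c in df.columns if c != "sample_id"]
    out = pd.DataFrame(index=pd.Index(df["sample_id"], name="sample_id"))
    observed: dict[str, set[str]] = {}
    for snp in snp_ids:
        cells = []
        seen: set[str] = set()
        for sample, cell in zip(df["sample_id"], df[snp]):
            try:
                norm = normalize_genotype_cell(cell)
            except DataError as exc:
                raise DataError(f"sample {sample}, SNP {snp}: {exc}") from None
            cells.append(norm)
            if norm is not None:
                seen.update(norm.split("/"))
        out[snp] = pd.array(cells, dtype="string")
        observed[snp] = seen
    return out, observed


def _read_genotypes_vcf(path: Path) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        columns: dict[str, list[str | None]] = {}
        observed: dict[str, set[str]] = {}
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise DataError(
                    f"VCF record {rec.id or rec.pos} is not biallelic; only biallelic SNPs are supported"
                )
            ref, alt = rec.ref.upper(), rec.alts[0].upper()
            if len(ref) != 1 or len(alt) != 1:
                raise DataError(f"VCF record {rec.id or rec.pos} is not a SNP (REF={ref}, ALT={alt})")
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            alleles = (ref, alt)
            cells: list[str | None] = []
            for sample in samples:
                gt = rec.samples[sample].get("GT")
                if gt is None or any(idx is None for idx in gt):
                    cells.append(None)
                    continue
                if len(gt) != 2 or any(idx not in (0, 1) for idx in gt):
                    raise DataError(f"sample {sample}, SNP {snp_id}: unsupported GT {gt}")
                cells.append("/".join(sorted(alleles[idx] for idx in gt)))
            columns[snp_id] = cells
            observed[snp_id] = {ref, alt}
    out = pd.DataFrame(
        {snp: pd.array(cells, dtype="string") for snp, cells in columns.items()},
        index=pd.Index(samples, name="sample_id"),
    )
    return out, observed


def write_genotypes(genotypes: pd.DataFrame, path: str | Path, dialect: str | None = None) -> None:
    """Write a wide genotype table with the ``NA`` sentinel for missing calls."""
    path = Path(path)
    sep = "\t" if _detect_dialect(path, dialect) == "tsv" else ","
    genotypes.to_csv(path, sep=sep, na_rep=MISSING)


def infer_panel(
    genotypes: pd.DataFrame,
    observed: dict[str, set[str]],
    declared: Sequence[SnpDef] | None = None,
    genes: dict[str, str] | None = None,
) -> list[SnpDef]:
    """Build the SNP panel, taking declared major/minor orientation when given.

    For undeclared SNPs the major allele is the more frequent one over all
    non-missing calls (ties broken lexicographically). Calls carrying an
    allele outside a declared pair raise :class:`DataError`.
    """
    declared_by_id = {s.snp_id: s for s in (declared or [])}
    genes = genes or {}
    panel: list[SnpDef] = []
    for snp in genotypes.columns:
        if snp in declared_by_id:
            snpdef = declared_by_id[snp]
            extra = observed.get(snp, set()) - snpdef.alleles
            if extra:
                bad = genotypes[snp].dropna()
                offender = next(
                    (str(idx) for idx, cell in bad.items() if set(cell.split("/")) - snpdef.alleles),
                    "?",
                )
                raise DataError(
                    f"sample {offender}, SNP {snp}: allele(s) {sorted(extra)} outside declared pair "
                    f"{{{snpdef.major_allele},{snpdef.minor_allele}}}"
                )
            panel.append(snpdef)
            continue
        counts: dict[str, int] = {}
        for cell in genotypes[snp].dropna():
            for allele in cell.split("/"):
                counts[allele] = counts.get(allele, 0) + 1
        symbols = sorted(observed.get(snp, set()) | set(counts))
        if len(symbols) != 2:
            raise DataError(f"SNP {snp}: expected exactly 2 alleles, saw {symbols}")
        # more frequent allele is major; lexicographic tie-break
        major = max(symbols, key=lambda s: (counts.get(s, 0), -ord(s)))
        minor = next(s for s in symbols if s != major)
        panel.append(SnpDef(snp, genes.get(snp, snp), major, minor))
    return panel


@dataclass
class CohortTable:
    """Joined per-child phenotype + genotype records plus derived fields.

    ``data`` has one row per sample_id; genotype calls live in
    ``geno_<snp_id>`` columns as canonical ``"A/G"`` strings (NA when the
    child was not genotyped for that SNP — the per-SNP analysis n is the
    number of non-missing calls, never the cohort size). Derived columns
    (``bmi``, ``zbmi``, ``weight_category``...) appear only after
    :func:`snptrait.anthro.derive_anthropometrics` has run.
    """

    panel: list[SnpDef]
    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data["sample_id"].duplicated().any():
            raise DataError("cohort table has duplicate sample_id")

    @property
    def n(self) -> int:
        return len(self.data)

    def snp(self, snp_id: str) -> SnpDef:
        for s in self.panel:
            if s.snp_id == snp_id:
                return s
        raise ConfigError(f"SNP {snp_id!r} not in panel")

    def genotype_series(self, snp_id: str) -> pd.Series:
        self.snp(snp_id)
        return self.data[geno_col(snp_id)]

    def n_genotyped(self, snp_id: str) -> int:
        return int(self.genotype_series(snp_id).notna().sum())

    @property
    def has_derived(self) -> bool:
        return "weight_category" in self.data.columns

    def write(self, path: str | Path, dialect: str | None = None) -> None:
        path = Path(path)
        sep = "\t" if _detect_dialect(path, dialect) == "tsv" else ","
        self.data.to_csv(path, sep=sep, index=False, na_rep=MISSING, float_format="%.12g")

    @classmethod
    def read(
        cls, path: str | Path, panel: Sequence[SnpDef], dialect: str | None = None
    ) -> "CohortTable":
        df = _read_table(Path(path), dialect)
        for s in panel:
            col = geno_col(s.snp_id)
            if col in df.columns:
                df[col] = df[col].astype("string")
        return cls(list(panel), df)


def join_cohort(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    panel: Sequence[SnpDef],
    policy: str = "strict",
) -> CohortTable:
    """Join phenotype and genotype tables on sample_id.

    ``policy="strict"`` requires every genotyped sample to have phenotypes;
    ``policy="intersect"`` keeps only samples present in both tables.
    Phenotyped samples without a call at a given SNP stay in the table with
    that call missing.
    """
    if policy not in ("strict", "intersect"):
        raise ConfigError(f"unknown join policy {policy!r}")
    pheno_ids = set(phenotypes["sample_id"])
    geno_ids = set(genotypes.index.astype(str))
    if policy == "strict" and not geno_ids <= pheno_ids:
        missing = sorted(geno_ids - pheno_ids)[:5]
        raise DataError(f"genotyped samples without phenotypes (strict join): {missing}")
    df = phenotypes.copy()
    if policy == "intersect":
        df = df[df["sample_id"].isin(geno_ids)].reset_index(drop=True)
    if df.empty:
        raise DataError("empty phenotype/genotype intersection")
    geno = genotypes.copy()
    geno.index = geno.index.astype(str)
    for s in panel:
        if s.snp_id not in geno.columns:
            raise ConfigError(f"panel SNP {s.snp_id!r} absent from genotype table")
        df[geno_col(s.snp_id)] = (
            df["sample_id"].map(geno[s.snp_id]).astype("string")
        )
    return CohortTable(list(panel), df)


def read_lms_table(path: str | Path) -> pd.DataFrame:
    """Read an LMS growth-reference table (sex, age_months, L, M, S)."""
    df = _read_table(Path(path), None)
    required = {"sex", "age_months", "L", "M", "S"}
    if not required <= set(df.columns):
        raise ConfigError(f"LMS table must have columns {sorted(required)}")
    df["sex"] = df["sex"].str.strip().str.lower()
    if not df["sex"].isin(_SEXES).all():
        raise DataError("LMS table has unrecognized sex values")
    if (df["M"] <= 0).any() or (df["S"] <= 0).any():
        raise DataError("LMS table requires M > 0 and S > 0")
    for sex, block in df.groupby("sex"):
        if not block["age_months"].is_monotonic_increasing or block["age_months"].duplicated().any():
            raise DataError(f"LMS ages must be strictly increasing within sex ({sex})")
    return df


def read_iotf_table(path: str | Path) -> pd.DataFrame:
    """Read an IOTF-style BMI cutoff table (sex, age_years, bmi_overweight, bmi_obese)."""
    df = _read_table(Path(path), None)
    required = {"sex", "age_years", "bmi_overweight", "bmi_obese"}
    if not required <= set(df.columns):
        raise ConfigError(f"IOTF cutoff table must have columns {sorted(required)}")
    df["sex"] = df["sex"].str.strip().str.lower()
    if not df["sex"].isin(_SEXES).all():
        raise DataError("IOTF table has unrecognized sex values")
    if not ((df["bmi_obese"] > df["bmi_overweight"]) & (df["bmi_overweight"] > 0)).all():
        raise DataError("IOTF cutoffs require bmi_obese > bmi_overweight > 0")
    for sex, block in df.groupby("sex"):
        if not block["age_years"].is_monotonic_increasing or block["age_years"].duplicated().any():
            raise DataError(f"IOTF ages must be strictly increasing within sex ({sex})")
    return df
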