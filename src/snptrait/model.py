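"""Study-level model object and fitted results.

:class:`SnpStudy` wraps a joined cohort table plus analysis configuration;
``fit()`` runs the full single-locus analysis — allele/genotype
frequencies, Hardy-Weinberg testing, case-control association, stratified
descriptives, genotype-stratified contrasts, and the Falconer effect
decomposition — and returns a :class:`SnpStudyResults` holding every
table, with ``summary()`` and ``save()``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import anthro, assoc, falconer
from .io import CohortTable, SnpDef, join_cohort

__all__ = ["SnpStudy", "SnpStudyResults"]


class SnpStudy:
    """Single-locus association study over a genotyped pediatric cohort.

    Parameters
    ----------
    cohort:
        Joined cohort table. If derived anthropometrics (bmi, zbmi,
        weight_category) are absent, ``lms_table`` and ``iotf_table`` must
        be supplied so they can be computed at fit time.
    contrast_method:
        "dunn" (rank-based, default) or "welch" for the stratified
        descriptive comparisons.
    dominance_tol:
        relative band around |d/a| = 1 for dominance typing.
    grade_source:
        which quantity is graded for the effect-size label
        ("minor_avg_effect", "alpha" or "additive").
    """

    def __init__(
        self,
        cohort: CohortTable,
        lms_table: pd.DataFrame | None = None,
        iotf_table: pd.DataFrame | None = None,
        contrast_method: str = "dunn",
        dominance_tol: float = 0.25,
        grade_source: str = "minor_avg_effect",
        effect_phenotypes: Sequence[str] = ("bmi", "zbmi"),
        contrast_variables: Sequence[str] | None = None,
    ) -> None:
        self.cohort = cohort
        self.lms_table = lms_table
        self.iotf_table = iotf_table
        self.contrast_method = contrast_method
        self.dominance_tol = dominance_tol
        self.grade_source = grade_source
        self.effect_phenotypes = tuple(effect_phenotypes)
        self.contrast_variables = contrast_variables

    @classmethod
    def from_dataframes(
        cls,
        phenotypes: pd.DataFrame,
        genotypes: pd.DataFrame,
        panel: Sequence[SnpDef],
        lms_table: pd.DataFrame,
        iotf_table: pd.DataFrame,
        join_policy: str = "strict",
        **kwargs: Any,
    ) -> "SnpStudy":
        cohort = join_cohort(phenotypes, genotypes, panel, policy=join_policy)
        return cls(cohort, lms_table=lms_table, iotf_table=iotf_table, **kwargs)

    def fit(self) -> "SnpStudyResults":
        cohort = self.cohort
        if not cohort.has_derived:
            if self.lms_table is None or self.iotf_table is None:
                raise ValueError(
                    "cohort lacks derived anthropometrics and no LMS/IOTF tables were given"
                )
            cohort = anthro.derive_anthropometrics(cohort, self.lms_table, self.iotf_table)

        freq_rows = []
        hwe: dict[tuple[str, str], assoc.HweResult] = {}
        case_control: dict[tuple[str, str], assoc.CaseControlResult] = {}
        for snp in cohort.panel:
            for group_label, group in (
                ("overall", None),
                ("case", anthro.OVERWEIGHT_OBESE),
                ("control", anthro.NORMAL_WEIGHT),
            ):
                counts = assoc.count_genotypes(cohort, snp.snp_id, group)
                freqs = assoc.allele_freqs(counts)
                res = assoc.hwe_test(counts)
                hwe[(snp.snp_id, group_label)] = res
                freq_rows.append(
                    {
                        "snp_id": snp.snp_id,
                        "gene": snp.gene,
                        "group": group_label,
                        "n": counts.total,
                        "n_major_homo": counts.n_major_homo,
                        "n_het": counts.n_het,
                        "n_minor_homo": counts.n_minor_homo,
                        "count_major": freqs.count_major,
                        "count_minor": freqs.count_minor,
                        "freq_major": freqs.p,
                        "freq_minor": freqs.q,
                        "hwe_p_exact": res.p_exact,
                        "hwe_p_chisq": res.p_chisq,
                    }
                )
            case_counts = assoc.count_genotypes(cohort, snp.snp_id, anthro.OVERWEIGHT_OBESE)
            control_counts = assoc.count_genotypes(cohort, snp.snp_id, anthro.NORMAL_WEIGHT)
            for mode in ("allele", "genotype"):
                case_control[(snp.snp_id, mode)] = assoc.case_control_test(
                    case_counts, control_counts, mode=mode
                )

        freq_table = pd.DataFrame(freq_rows)
        cc_rows = [
            {"snp_id": snp_id, "mode": mode, "chi2": r.chi2, "df": r.df, "p": r.p, "computable": r.computable}
            for (snp_id, mode), r in case_control.items()
        ]
        effects_df, effects = falconer.effects_table(
            cohort,
            phenotypes=self.effect_phenotypes,
            dominance_tol=self.dominance_tol,
            grade_source=self.grade_source,
        )

        by_sex = anthro.stratified_summary(cohort, "sex", method=self.contrast_method)
        by_category = anthro.stratified_summary(
            cohort, "weight_category", method=self.contrast_method
        )

        contrast_vars = list(
            self.contrast_variables
            if self.contrast_variables is not None
            else [v for v in ("bmi", "zbmi", "body_fat_pct") if v in cohort.data.columns]
        )
        genotype_tables = {
            snp.snp_id: assoc.genotype_stratified_table(cohort, snp.snp_id, contrast_vars)
            for snp in cohort.panel
        }
        contrasts = {
            (snp.snp_id, var): assoc.genotype_contrasts(cohort, snp.snp_id, var)
            for snp in cohort.panel
            for var in contrast_vars
        }

        return SnpStudyResults(
            model=self,
            cohort=cohort,
            freq_table=freq_table,
            hwe=hwe,
            case_control=case_control,
            case_control_table=pd.DataFrame(cc_rows),
            effects_table=effects_df,
            effects=effects,
            summary_by_sex=by_sex,
            summary_by_category=by_category,
            genotype_tables=genotype_tables,
            contrasts=contrasts,
        )


@dataclass
class SnpStudyResults:
    """Fitted study: every table of the single-locus analysis."""

    model: SnpStudy
    cohort: CohortTable
    freq_table: pd.DataFrame
    hwe: dict[tuple[str, str], assoc.HweResult]
    case_control: dict[tuple[str, str], assoc.CaseControlResult]
    case_control_table: pd.DataFrame
    effects_table: pd.DataFrame
    effects: dict[tuple[str, str], falconer.FalconerEffects | None]
    summary_by_sex: anthro.StratifiedSummary
    summary_by_category: anthro.StratifiedSummary
    genotype_tables: dict[str, pd.DataFrame]
    contrasts: dict[tuple[str, str], list[assoc.ContrastResult]]

    @property
    def n(self) -> int:
        return self.cohort.n

    @property
    def n_case(self) -> int:
        return int((self.cohort.data["weight_category"] == anthro.OVERWEIGHT_OBESE).sum())

    def summary(self) -> str:
        lines = [
            "Single-locus SNP-trait association study",
            f"  samples: {self.n}  (case {self.n_case} / control {self.n - self.n_case})",
            f"  SNPs: {len(self.cohort.panel)}",
            "",
            "  SNP          gene   n    q_minor  HWE p(exact)  allele p  genotype p",
        ]
        overall = self.freq_table[self.freq_table["group"] == "overall"].set_index("snp_id")
        for snp in self.cohort.panel:
            row = overall.loc[snp.snp_id]
            pa = self.case_control[(snp.snp_id, "allele")]
            pg = self.case_control[(snp.snp_id, "genotype")]
            pg_txt = f"{pg.p:9.3g}" if pg.computable else "      n/c"
            lines.append(
                f"  {snp.snp_id:<12} {snp.gene:<6} {int(row['n']):<4} "
                f"{row['freq_minor']:.3f}    {row['hwe_p_exact']:<13.3g} {pa.p:<9.3g} {pg_txt}"
            )
        lines.append("")
        lines.append("  Effect decomposition (zBMI):")
        lines.append("  SNP          a        d        midpoint alpha1   dominance        grade")
        for snp in self.cohort.panel:
            eff = self.effects.get((snp.snp_id, "zbmi"))
            if eff is None:
                lines.append(f"  {snp.snp_id:<12} not computable (empty genotype class)")
                continue
            note = "  [minor n<5]" if eff.small_minor_class else ""
            lines.append(
                f"  {snp.snp_id:<12} {eff.additive:+.3f}   {eff.dominance:+.3f}   "
                f"{eff.midpoint:7.3f}  {eff.minor_avg_effect:+.3f}   "
                f"{eff.dominance_type:<16} {eff.effect_grade}{note}"
            )
        return "\n".join(lines)

    def to_report(self) -> dict[str, Any]:
        """Full-precision JSON-serializable report of every statistic."""
        report: dict[str, Any] = {
            "n": self.n,
            "n_case": self.n_case,
            "snps": {},
        }
        for snp in self.cohort.panel:
            sid = snp.snp_id
            entry: dict[str, Any] = {"gene": snp.gene}
            entry["frequencies"] = (
                self.freq_table[self.freq_table["snp_id"] == sid]
                .drop(columns=["snp_id", "gene"])
                .to_dict(orient="records")
            )
            entry["case_control"] = {
                mode: {
                    "chi2": _nan_to_none(self.case_control[(sid, mode)].chi2),
                    "df": self.case_control[(sid, mode)].df,
                    "p": _nan_to_none(self.case_control[(sid, mode)].p),
                    "computable": self.case_control[(sid, mode)].computable,
                }
                for mode in ("allele", "genotype")
            }
            entry["effects"] = {}
            for phenotype in self.model.effect_phenotypes:
                eff = self.effects.get((sid, phenotype))
                if eff is None:
                    entry["effects"][phenotype] = None
                    continue
                entry["effects"][phenotype] = {
                    "midpoint": eff.midpoint,
                    "additive": eff.additive,
                    "dominance": eff.dominance,
                    "alpha": eff.alpha,
                    "minor_avg_effect": eff.minor_avg_effect,
                    "aecme": eff.aecme,
                    "freq_weighted_mean": eff.freq_weighted_mean,
                    "dominance_type": eff.dominance_type,
                    "effect_grade": eff.effect_grade,
                    "n_genotypes": [eff.n_major_homo, eff.n_het, eff.n_minor_homo],
                    "small_minor_class": eff.small_minor_class,
                }
            entry["contrasts"] = {
                var: [
                    {
                        "genotype": c.genotype,
                        "n": c.n,
                        "difference": c.difference,
                        "ci": [c.ci_low, c.ci_high],
                        "p_adj": c.p_adj,
                        "computable": c.computable,
                    }
                    for c in self.contrasts[(sid, var)]
                ]
                for (s2, var) in self.contrasts
                if s2 == sid
            }
            report["snps"][sid] = entry
        return report

    def save(self, outdir: str | Path) -> None:
        """Write every table (TSV) plus the full-precision JSON report."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.freq_table.to_csv(outdir / "frequencies_hwe.tsv", sep="\t", index=False, na_rep="NA")
        self.case_control_table.to_csv(
            outdir / "case_control.tsv", sep="\t", index=False, na_rep="NA"
        )
        self.effects_table.to_csv(outdir / "effects.tsv", sep="\t", index=False, na_rep="NA")
        self.summary_by_sex.descriptives.to_csv(
            outdir / "descriptives_by_sex.tsv", sep="\t", index=False, na_rep="NA"
        )
        self.summary_by_sex.comparisons.to_csv(
            outdir / "comparisons_by_sex.tsv", sep="\t", index=False, na_rep="NA"
        )
        self.summary_by_category.descriptives.to_csv(
            outdir / "descriptives_by_category.tsv", sep="\t", index=False, na_rep="NA"
        )
        self.summary_by_category.comparisons.to_csv(
            outdir / "comparisons_by_category.tsv", sep="\t", index=False, na_rep="NA"
        )
        genotype_frames = [df for df in self.genotype_tables.values() if not df.empty]
        if genotype_frames:
            pd.concat(genotype_frames, ignore_index=True).to_csv(
                outdir / "genotype_stratified.tsv", sep="\t", index=False, na_rep="NA"
            )
        (outdir / "report.json").write_text(json.dumps(self.to_report(), indent=2) + "\n")


def _nan_to_none(x: float) -> float | None:
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else x
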