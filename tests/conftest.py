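import numpy as np
import pandas as pd
import pytest

from snptrait.io import CohortTable, SnpDef, geno_col
from snptrait.simulate import make_paper_fixture


@pytest.fixture(scope="session")
def paper_fixture():
    """Study-scale synthetic cohort (n=773, five SNPs) plus reference tables."""
    return make_paper_fixture(seed=7)


@pytest.fixture(scope="session")
def fitted_study(paper_fixture):
    from snptrait.model import SnpStudy

    cohort, lms, iotf = paper_fixture
    return SnpStudy(cohort, lms_table=lms, iotf_table=iotf).fit()


def cohort_from_counts(
    counts: tuple[int, int, int],
    snp: SnpDef = SnpDef("rs0", "GENE", "A", "G"),
    phenotype_means: tuple[float, float, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CohortTable:
    """Build a minimal cohort whose genotype class sizes equal ``counts``.

    Optionally attaches a ``pheno`` column with per-class means plus
    Gaussian noise (deterministic via ``seed``).
    """
    rng = np.random.default_rng(seed)
    cells, values = [], []
    genotype_strings = (
        "/".join(sorted(snp.major_allele * 2)),
        "/".join(sorted(snp.major_allele + snp.minor_allele)),
        "/".join(sorted(snp.minor_allele * 2)),
    )
    for cls, n in enumerate(counts):
        cells.extend([genotype_strings[cls]] * n)
        if phenotype_means is not None:
            values.extend(phenotype_means[cls] + rng.normal(0.0, noise_sd, n))
    df = pd.DataFrame({"sample_id": [f"S{i}" for i in range(sum(counts))]})
    df[geno_col(snp.snp_id)] = pd.array(cells, dtype="string")
    if phenotype_means is not None:
        df["pheno"] = values
    return CohortTable([snp], df)


@pytest.fixture
def tiny_phenotypes(tmp_path):
    path = tmp_path / "pheno.csv"
    path.write_text(
        "sample_id,sex,age_days,weight_kg,height_cm,waist_cm,hip_cm,ferritin_ng_ml,"
        "insulin_uU_ml,glucose_mg_dl\n"
        "A1,male,3592,31.4,136.9,61.2,67.4,37.2,5.29,77.7\n"
        "A2,female,3650,45.39,141.3,76.6,80.0,NA,9.84,79.8\n"
        "A3,female,3500,35.6,138.2,65.7,71.0,40.29,,78.5\n"
    )
    return path
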