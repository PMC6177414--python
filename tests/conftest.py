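"""Shared fixtures: small deterministic simulations reused across modules."""
import numpy as np
import pandas as pd
import pytest

from psapred import synthdata
from psapred.core import GenotypeMatrix, PhenotypeTable


@pytest.fixture(scope="session")
def small_sim():
    """Two cohorts, planted subtype loci; used by select/ensemble tests."""
    cfg = synthdata.SimConfig(
        n_cohorts=2, n_control=600, n_psa=600, n_psc=600, n_markers=100,
        n_shared_loci=3, n_psa_loci=2, n_psc_loci=2,
        effect_size_shared=0.3, effect_size_subtype=0.6, mhc_effect=0.9,
        maf_range=(0.15, 0.5), imputation_r2_range=(0.8, 1.0), seed=3,
    )
    return synthdata.simulate(cfg)


@pytest.fixture(scope="session")
def null_sim():
    """No genetic effects at all: pure noise cohorts."""
    cfg = synthdata.SimConfig(
        n_cohorts=2, n_control=400, n_psa=400, n_psc=400, n_markers=120,
        n_shared_loci=0, n_psa_loci=0, n_psc_loci=0,
        effect_size_shared=0.0, effect_size_subtype=0.0, mhc_effect=0.0,
        seed=9,
    )
    return synthdata.simulate(cfg)


def make_genotypes(dosages, genotyped=False, r2=None, chrom=None, pos=None):
    """Hand-build a GenotypeMatrix from a dosage array."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    markers = pd.DataFrame({
        "marker_id": [f"mk{j}" for j in range(m)],
        "chrom": chrom if chrom is not None else ["1"] * m,
        "pos": pos if pos is not None else (1000 + 10 * np.arange(m)),
        "risk_allele": ["A"] * m,
        "nonrisk_allele": ["G"] * m,
        "imputation_r2": r2 if r2 is not None else [1.0] * m,
        "genotyped": ([genotyped] * m if isinstance(genotyped, bool) else genotyped),
    })
    ids = [f"s{i}" for i in range(n)]
    return GenotypeMatrix(dosages, markers, ids)


def make_phenotypes(statuses, cohort="c0", covariates=None):
    df = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(len(statuses))],
        "cohort": cohort,
        "status": list(statuses),
    })
    names = ()
    if covariates:
        for k, v in covariates.items():
            df[k] = v
        names = tuple(covariates)
    return PhenotypeTable(df, names)
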