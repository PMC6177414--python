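"""Multi-cohort case-control genotype simulator.

Generates dosage matrices and phenotype tables with the statistical
structure the downstream analysis assumes: shared disease loci, subtype
specific loci, one strong MHC-like locus, population-structure covariates,
per-marker imputation quality, and (optionally) a cohort containing PsA
cases only.

The generative model is an additive-logistic liability:

* case vs. control:   ``logit P(case) = a0 + sum_j b_j (g_j - 2 f_j) + c * z``
* PsA vs. PsC (cases): ``logit P(PsA)  = a1 + sum_j s_j (g_j - 2 f_j)``

where ``g_j`` are true allele counts, ``f_j`` ancestral allele frequencies,
``z`` the subpopulation indicator, ``b`` loads on the shared loci and ``s``
on the subtype loci (positive for PsA-specific, negative for PsC-specific,
with a large positive loading on the MHC-like locus).

Emitted dosages mimic posterior-mean imputed genotypes:
``d = r2 * g + (1 - r2) * 2f + e`` with Gaussian jitter ``e`` scaled so
``corr^2(d, g)`` matches the target imputation quality, then clipped to
``[0, 2]``.  Markers flagged as genotyped are emitted as exact hard calls.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    CONTROL,
    PSA,
    PSC,
    UNKNOWN_SUBTYPE,
    Cohort,
    ConfigurationError,
    GenotypeMatrix,
    MHC_REGION,
    PhenotypeTable,
)

logger = logging.getLogger(__name__)

CountSpec = "int | Sequence[int]"


@dataclass
class SimConfig:
    """Parameters of the multi-cohort simulation.

    Per-cohort counts may be a single int (applied to every cohort) or a
    sequence of length ``n_cohorts``.  When ``psa_only_last`` is set, the
    last cohort's PsC and unknown-subtype counts are forced to zero,
    mirroring a PsA-only GWAS cohort.
    """

    n_cohorts: int = 2
    n_control: CountSpec = 500
    n_psa: CountSpec = 500
    n_psc: CountSpec = 500
    n_unknown_subtype: CountSpec = 0
    n_markers: int = 200
    maf_range: tuple = (0.05, 0.5)
    n_shared_loci: int = 5
    n_psa_loci: int = 2
    n_psc_loci: int = 2
    effect_size_shared: float = 0.3
    effect_size_subtype: float = 0.4
    mhc_effect: float = 0.8
    n_subpops: int = 2
    fst_like_shift: float = 0.01
    subpop_effect: float = 0.0
    imputation_r2_range: tuple = (0.7, 1.0)
    genotyped_frac: float = 0.1
    psa_only_last: bool = False
    seed: int = 0

    def counts(self, which: str) -> np.ndarray:
        v = getattr(self, which)
        if np.isscalar(v):
            arr = np.full(self.n_cohorts, int(v), dtype=int)
        else:
            arr = np.asarray(v, dtype=int)
            if arr.shape != (self.n_cohorts,):
                raise ConfigurationError(
                    f"{which} must be scalar or length n_cohorts={self.n_cohorts}"
                )
        if self.psa_only_last and which in ("n_psc", "n_unknown_subtype"):
            arr = arr.copy()
            arr[-1] = 0
        return arr

    def validate(self) -> None:
        if self.n_cohorts < 1:
            raise ConfigurationError("n_cohorts must be >= 1")
        for which in ("n_control", "n_psa", "n_psc", "n_unknown_subtype"):
            if (self.counts(which) < 0).any():
                raise ConfigurationError(f"{which} must be >= 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        lo, hi = self.imputation_r2_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("imputation_r2_range must lie within (0, 1]")
        n_causal = self.n_shared_loci + self.n_psa_loci + self.n_psc_loci + 1
        if n_causal > self.n_markers:
            raise ConfigurationError("locus counts (plus MHC) exceed n_markers")
        if not 0.0 <= self.genotyped_frac <= 1.0:
            raise ConfigurationError("genotyped_frac must lie in [0, 1]")
        if self.n_subpops < 1:
            raise ConfigurationError("n_subpops must be >= 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        known = {f for f in cls.__dataclass_fields__}
        extra = set(d) - known
        if extra:
            raise ConfigurationError(f"unknown SimConfig fields: {sorted(extra)}")
        cfg = cls(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in d.items()})
        cfg.validate()
        return cfg


@dataclass
class SimTruth:
    """Generating values recorded for downstream oracle checks."""

    maf: np.ndarray
    beta_case: np.ndarray
    beta_subtype: np.ndarray
    shared_idx: np.ndarray
    psa_idx: np.ndarray
    psc_idx: np.ndarray
    mhc_idx: int
    subpop_freqs: np.ndarray  # (n_subpops, n_markers)
    true_genotypes: dict = field(default_factory=dict)  # cohort -> int8 matrix
    unknown_true_subtype: dict = field(default_factory=dict)  # cohort -> {id: PSA|PSC}


@dataclass
class SimResult:
    cohorts: "dict[str, Cohort]"
    truth: SimTruth
    config: SimConfig


def _marker_table(cfg: SimConfig, rng, mhc_idx: int, r2: np.ndarray,
                  genotyped: np.ndarray) -> pd.DataFrame:
    alleles = np.array(list("ACGT"))
    risk = rng.choice(alleles, size=cfg.n_markers)
    shift = rng.integers(1, 4, size=cfg.n_markers)
    nonrisk = alleles[(np.searchsorted(alleles, risk) + shift) % 4]
    chrom = np.full(cfg.n_markers, "1", dtype=object)
    pos = 1_000_000 + 5_000 * np.arange(cfg.n_markers, dtype=np.int64)
    chrom[mhc_idx] = MHC_REGION[0]
    pos[mhc_idx] = (MHC_REGION[1] + MHC_REGION[2]) // 2
    return pd.DataFrame(
        {
            "marker_id": [f"m{j:05d}" for j in range(cfg.n_markers)],
            "chrom": chrom,
            "pos": pos,
            "risk_allele": risk,
            "nonrisk_allele": nonrisk,
            "imputation_r2": r2,
            "genotyped": genotyped,
        }
    )


def _subpop_freqs(maf: np.ndarray, n_subpops: int, fst: float, rng) -> np.ndarray:
    """Balding-Nichols style per-subpopulation allele frequencies."""
    if fst <= 0 or n_subpops == 1:
        return np.tile(maf, (n_subpops, 1))
    a = maf * (1.0 - fst) / fst
    b = (1.0 - maf) * (1.0 - fst) / fst
    freqs = rng.beta(a, b, size=(n_subpops, maf.size))
    return np.clip(freqs, 1e-4, 1.0 - 1e-4)


def _emit_dosages(g: np.ndarray, maf: np.ndarray, r2: np.ndarray,
                  genotyped: np.ndarray, rng) -> np.ndarray:
    """Noisy posterior-mean-like dosages with corr^2(d, g) ~= r2."""
    var_g = 2.0 * maf * (1.0 - maf)
    # d = r2*g + (1-r2)*2f + e,  Var(e) = r2*(1-r2)*Var(g)  =>  corr^2(d,g)=r2
    tau = np.sqrt(np.maximum(r2 * (1.0 - r2) * var_g, 0.0))
    d = r2 * g + (1.0 - r2) * 2.0 * maf + tau * rng.standard_normal(g.shape)
    d = np.clip(d, 0.0, 2.0)
    exact = genotyped | (r2 >= 1.0)
    d[:, exact] = g[:, exact]
    return d


def simulate(config: SimConfig) -> SimResult:
    """Draw per-cohort genotype/phenotype data under the liability model.

    Deterministic given ``config.seed``.  Returns the cohorts together with
    the generating truth (causal indices, effect vectors, true genotypes).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = config.n_markers

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    # causal architecture: disjoint shared/PsA/PsC sets plus one MHC-like
    # locus that differentiates the subtypes with a strong effect
    perm = rng.permutation(m)
    k = 0
    shared_idx = perm[k:k + config.n_shared_loci]; k += config.n_shared_loci
    psa_idx = perm[k:k + config.n_psa_loci]; k += config.n_psa_loci
    psc_idx = perm[k:k + config.n_psc_loci]; k += config.n_psc_loci
    mhc_idx = int(perm[k])

    beta_case = np.zeros(m)
    beta_case[shared_idx] = config.effect_size_shared
    beta_subtype = np.zeros(m)
    beta_subtype[psa_idx] = config.effect_size_subtype
    beta_subtype[psc_idx] = -config.effect_size_subtype
    beta_subtype[mhc_idx] = config.mhc_effect

    n_geno = int(round(config.genotyped_frac * m))
    genotyped = np.zeros(m, dtype=bool)
    genotyped[rng.choice(m, size=n_geno, replace=False)] = True
    r2 = rng.uniform(*config.imputation_r2_range, size=m)
    r2[genotyped] = 1.0

    markers = _marker_table(config, rng, mhc_idx, r2, genotyped)
    subpop_freqs = _subpop_freqs(maf, config.n_subpops, config.fst_like_shift, rng)

    truth = SimTruth(
        maf=maf, beta_case=beta_case, beta_subtype=beta_subtype,
        shared_idx=np.sort(shared_idx), psa_idx=np.sort(psa_idx),
        psc_idx=np.sort(psc_idx), mhc_idx=mhc_idx, subpop_freqs=subpop_freqs,
    )

    cohorts: dict[str, Cohort] = {}
    quotas = {w: config.counts(w) for w in
              ("n_control", "n_psa", "n_psc", "n_unknown_subtype")}

    for c in range(config.n_cohorts):
        name = f"cohort{c}"
        need = {
            CONTROL: int(quotas["n_control"][c]),
            PSA: int(quotas["n_psa"][c]),
            PSC: int(quotas["n_psc"][c]),
            UNKNOWN_SUBTYPE: int(quotas["n_unknown_subtype"][c]),
        }
        total = sum(need.values())
        if total == 0:
            raise ConfigurationError(f"{name}: zero samples requested")
        mix = rng.dirichlet(np.full(config.n_subpops, 5.0))

        rows_g, rows_z, rows_status, rows_true = [], [], [], []
        for _ in range(1000):
            if total == 0:
                break
            batch = max(4 * total, 256)
            z = rng.choice(config.n_subpops, size=batch, p=mix)
            g = rng.binomial(2, subpop_freqs[z], size=(batch, m)).astype(np.int8)
            centered = g - 2.0 * maf
            eta_case = centered @ beta_case
            if config.subpop_effect:
                eta_case = eta_case + config.subpop_effect * (z - z.mean())
            is_case = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta_case))
            eta_sub = centered @ beta_subtype
            is_psa = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta_sub))
            for i in range(batch):
                if total == 0:
                    break
                if not is_case[i]:
                    status, true_sub = CONTROL, None
                else:
                    true_sub = PSA if is_psa[i] else PSC
                    status = true_sub
                if need.get(status, 0) > 0:
                    pass
                elif is_case[i] and need[UNKNOWN_SUBTYPE] > 0:
                    status = UNKNOWN_SUBTYPE
                else:
                    continue
                need[status] -= 1
                total -= 1
                rows_g.append(g[i])
                rows_z.append(z[i])
                rows_status.append(status)
                rows_true.append(true_sub)
        if total != 0:  # pragma: no cover - would need degenerate config
            raise ConfigurationError(f"{name}: could not fill sample quotas")

        gtrue = np.array(rows_g, dtype=np.int8)
        dosages = _emit_dosages(gtrue.astype(float), maf, r2, genotyped, rng)
        sample_ids = np.array([f"{name}_s{i:05d}" for i in range(len(rows_g))],
                              dtype=object)
        pheno = PhenotypeTable(
            pd.DataFrame(
                {
                    "sample_id": sample_ids,
                    "cohort": name,
                    "status": rows_status,
                    "subpop": np.asarray(rows_z, dtype=float),
                }
            ),
            covariate_names=("subpop",),
        )
        gm = GenotypeMatrix(dosages, markers.copy(), sample_ids)
        cohorts[name] = Cohort(name, gm, pheno)
        truth.true_genotypes[name] = gtrue
        truth.unknown_true_subtype[name] = {
            sid: ts
            for sid, st, ts in zip(sample_ids, rows_status, rows_true)
            if st == UNKNOWN_SUBTYPE
        }
        logger.info("%s: simulated %d samples x %d markers", name, len(rows_g), m)

    return SimResult(cohorts=cohorts, truth=truth, config=config)
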