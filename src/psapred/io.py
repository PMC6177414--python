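"""File formats and run configuration.

VCF v4.2 carries dosages in the per-genotype ``DS`` FORMAT field with
imputation quality in INFO ``R2``; genotyped (hard-call) markers carry a
``TYPED`` INFO flag and no ``R2``.  Phenotype/covariate tables are
tab-separated text with a header.  All coordinates follow VCF (1-based).
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .core import Cohort, GenotypeMatrix, PhenotypeTable

logger = logging.getLogger(__name__)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality (squared correlation)">
##INFO=<ID=TYPED,Number=0,Type=Flag,Description="Directly genotyped marker">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Expected alternate allele dosage">
"""


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------
def write_vcf_dosages(g: GenotypeMatrix, path) -> None:
    """Write a dosage VCF; risk allele is ALT, nonrisk is REF."""
    path = Path(path)
    m = g.markers
    order = np.lexsort((m["pos"].to_numpy(), m["chrom"].astype(str).to_numpy()))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in g.sample_ids) + "\n")
        for j in order:
            row = m.iloc[j]
            genotyped = bool(row["genotyped"])
            info = "TYPED" if genotyped else f"R2={row['imputation_r2']:.4f}"
            fields = [
                str(row["chrom"]), str(int(row["pos"])), str(row["marker_id"]),
                str(row["nonrisk_allele"]), str(row["risk_allele"]),
                ".", "PASS", info, "GT:DS",
            ]
            d = g.dosages[:, j]
            cells = []
            for v in d:
                if np.isnan(v):
                    cells.append("./.:.")
                elif genotyped:
                    k = int(round(v))
                    gt = ("0/0", "0/1", "1/1")[k]
                    cells.append(f"{gt}:{k}")
                else:
                    cells.append(f"./.:{v:.3f}")
            fh.write("\t".join(fields + cells) + "\n")


def read_vcf_dosages(path) -> GenotypeMatrix:
    """Read dosages from ``DS`` (falling back to GT allele counts).

    ``imputation_r2`` comes from INFO ``R2`` when present, else 1.0 with
    ``genotyped=True``.  Multi-allelic records are skipped with a warning;
    malformed records raise with the record number.
    """
    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    dosage_cols, rows = [], []
    for i, variant in enumerate(vcf, start=1):
        try:
            if len(variant.ALT) != 1:
                logger.warning("skipping multi-allelic record %d (%s)",
                               i, variant.ID or f"{variant.CHROM}:{variant.POS}")
                continue
            try:
                ds = variant.format("DS")
            except KeyError:  # DS not declared in the header at all
                ds = None
            if ds is not None:
                d = np.asarray(ds, dtype=float).reshape(-1)
                d = np.where((d < 0) | (d > 2), np.nan, d)
            else:
                gt_map = {0: 0.0, 1: 1.0, 3: 2.0, 2: np.nan}
                d = np.array([gt_map[t] for t in variant.gt_types], dtype=float)
            r2 = variant.INFO.get("R2")
            typed = variant.INFO.get("TYPED") is not None
            rows.append({
                "marker_id": variant.ID or f"{variant.CHROM}:{variant.POS}",
                "chrom": str(variant.CHROM),
                "pos": int(variant.POS),
                "risk_allele": variant.ALT[0],
                "nonrisk_allele": variant.REF,
                "imputation_r2": float(r2) if r2 is not None else 1.0,
                "genotyped": typed or r2 is None,
            })
            dosage_cols.append(d)
        except Exception as exc:
            raise ValueError(f"malformed VCF record {i} in {path}: {exc}") from exc
    if not rows:
        raise ValueError(f"no usable records in {path}")
    dosages = np.column_stack(dosage_cols)
    return GenotypeMatrix(dosages, pd.DataFrame(rows), samples)


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------
def write_phenotypes(ph: PhenotypeTable, path) -> None:
    ph.df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, covariate_names: Optional[Sequence[str]] = None
                    ) -> PhenotypeTable:
    """Read a tab-separated phenotype table; covariates default to every
    column beyond sample_id/cohort/status."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cohort": str})
    if covariate_names is None:
        covariate_names = [c for c in df.columns
                           if c not in ("sample_id", "cohort", "status")]
    return PhenotypeTable(df, tuple(covariate_names))


def read_cohort(name: str, vcf_path, pheno_path) -> Cohort:
    return Cohort(name, read_vcf_dosages(vcf_path), read_phenotypes(pheno_path))


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------
@dataclass
class RunConfig:
    """Stage parameters, cohort declarations, and a single master seed.

    Stage-specific seeds, when not given explicitly, derive deterministically
    from ``seed``.  Round-trips unchanged through YAML.
    """

    seed: int = 0
    cohorts: list = field(default_factory=list)  # {name, vcf, pheno, contains_psc}
    params: dict = field(default_factory=dict)   # stage name -> parameter dict

    def stage_params(self, stage: str) -> dict:
        return dict(self.params.get(stage, {}))

    def stage_seed(self, stage: str) -> int:
        p = self.params.get(stage, {})
        if "seed" in p:
            return int(p["seed"])
        digest = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(digest[:4], "little") % (2**31 - 1)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "cohorts": self.cohorts, "params": self.params}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(seed=int(d.get("seed", 0)),
                   cohorts=list(d.get("cohorts", [])),
                   params=dict(d.get("params", {})))


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def write_runlog(path, **payload) -> None:
    """Machine-readable run log (parameters, seeds, counts, versions)."""
    from . import __version__

    payload.setdefault("psapred_version", __version__)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
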