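"""Shared data containers: dosage matrices, phenotype tables, cohort bundles.

Coordinate conventions used throughout the package:

* marker positions are 1-based (VCF convention);
* BED-style intervals are 0-based half-open and converted on read.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Phenotype status labels.
CONTROL = "CONTROL"
PSA = "PSA"
PSC = "PSC"
UNKNOWN_SUBTYPE = "UNKNOWN_SUBTYPE"
STATUSES = (CONTROL, PSA, PSC, UNKNOWN_SUBTYPE)
CASE_STATUSES = (PSA, PSC, UNKNOWN_SUBTYPE)

#: Columns every marker-metadata frame must carry.
MARKER_COLUMNS = (
    "marker_id",
    "chrom",
    "pos",
    "risk_allele",
    "nonrisk_allele",
    "imputation_r2",
    "genotyped",
)

#: Conventional extended MHC window (chrom, start, end), 1-based inclusive.
MHC_REGION = ("6", 25_000_000, 34_000_000)


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so ``chr6`` and ``6`` compare equal."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


def in_mhc(chrom, pos) -> np.ndarray:
    """Element-wise test whether 1-based positions fall in the extended MHC."""
    chrom = np.asarray([normalize_chrom(c) for c in np.atleast_1d(chrom)])
    pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
    mchrom, lo, hi = MHC_REGION
    return (chrom == mchrom) & (pos >= lo) & (pos <= hi)


class ConfigurationError(ValueError):
    """Raised for inconsistent run or simulation configuration."""


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with per-marker metadata.

    Parameters
    ----------
    dosages
        Float array of shape ``(n_samples, n_markers)``; entries in ``[0, 2]``
        or NaN for missing.
    markers
        Data frame with one row per marker and at least :data:`MARKER_COLUMNS`.
    sample_ids
        One identifier per dosage row.
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    sample_ids: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x markers)")
        if self.dosages.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length does not match dosage rows")
        if self.dosages.shape[1] != len(self.markers):
            raise ValueError("marker table length does not match dosage columns")
        missing = [c for c in MARKER_COLUMNS if c not in self.markers.columns]
        if missing:
            raise ValueError(f"marker table lacks columns: {missing}")
        self.markers = self.markers.reset_index(drop=True)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def marker_ids(self) -> np.ndarray:
        return self.markers["marker_id"].to_numpy()

    def marker_index(self, marker_ids: Iterable[str]) -> np.ndarray:
        """Column indices of the given marker ids (order preserved)."""
        lookup = {m: i for i, m in enumerate(self.marker_ids)}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"unknown marker id {exc.args[0]!r}") from None

    def dosage_for(self, marker_id: str) -> np.ndarray:
        return self.dosages[:, self.marker_index([marker_id])[0]]

    # -- derived per-marker statistics ------------------------------------
    def alt_freq(self) -> np.ndarray:
        """Mean dosage / 2 per marker (risk-allele frequency), NaN-aware."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        af = self.alt_freq()
        return np.minimum(af, 1.0 - af)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    # -- subsetting --------------------------------------------------------
    def subset_markers(self, mask_or_ids) -> "GenotypeMatrix":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            idx = self.marker_index(arr)
        return GenotypeMatrix(
            self.dosages[:, idx], self.markers.iloc[idx], self.sample_ids
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in sample_ids], dtype=np.intp)
        return GenotypeMatrix(self.dosages[idx], self.markers, self.sample_ids[idx])

    def validate(self) -> None:
        """Enforce dosage-range and hard-call invariants; raises on violation."""
        d = self.dosages
        ok = np.isnan(d) | ((d >= 0.0) & (d <= 2.0))
        if not ok.all():
            raise ValueError("dosage entries outside [0, 2]")
        geno = self.markers["genotyped"].to_numpy(dtype=bool)
        if geno.any():
            sub = d[:, geno]
            present = ~np.isnan(sub)
            if not np.isin(sub[present], (0.0, 1.0, 2.0)).all():
                raise ValueError("genotyped markers must have hard-call dosages")
        r2 = self.markers["imputation_r2"].to_numpy(dtype=float)
        if ((r2 <= 0) | (r2 > 1)).any():
            raise ValueError("imputation_r2 must lie in (0, 1]")


@dataclass
class PhenotypeTable:
    """Per-sample cohort, status, and covariates.

    ``df`` must contain columns ``sample_id``, ``cohort``, ``status``; any
    declared covariate columns hold real values.
    """

    df: pd.DataFrame
    covariate_names: tuple = ()

    def __post_init__(self):
        required = {"sample_id", "cohort", "status"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"phenotype table lacks columns: {sorted(missing)}")
        self.covariate_names = tuple(self.covariate_names)
        for c in self.covariate_names:
            if c not in self.df.columns:
                raise ValueError(f"declared covariate {c!r} not in table")
        bad = set(self.df["status"]) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown status values: {sorted(bad)}")
        self.df = self.df.reset_index(drop=True)

    def validate(self) -> None:
        for cohort, grp in self.df.groupby("cohort"):
            if grp["sample_id"].duplicated().any():
                raise ValueError(f"duplicate sample ids within cohort {cohort!r}")

    @property
    def sample_ids(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy()

    def status_of(self, sample_ids: Sequence[str]) -> np.ndarray:
        lut = dict(zip(self.df["sample_id"], self.df["status"]))
        return np.array([lut[s] for s in sample_ids], dtype=object)

    def ids_with_status(self, *statuses: str) -> np.ndarray:
        mask = self.df["status"].isin(statuses)
        return self.df.loc[mask, "sample_id"].to_numpy()

    def covariates_for(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Covariate matrix aligned to the given sample order."""
        if not self.covariate_names:
            return np.empty((len(list(sample_ids)), 0))
        sub = self.df.set_index("sample_id").loc[list(sample_ids)]
        return sub[list(self.covariate_names)].to_numpy(dtype=float)


@dataclass
class Cohort:
    """A named cohort: one genotype matrix plus its phenotype table."""

    name: str
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable

    def __post_init__(self):
        g_ids = set(self.genotypes.sample_ids)
        p_ids = set(self.phenotypes.sample_ids)
        if g_ids != p_ids:
            raise ValueError(
                f"cohort {self.name!r}: genotype and phenotype sample ids differ"
            )

    def has_status(self, status: str) -> bool:
        return bool((self.phenotypes.df["status"] == status).any())


CohortMap = Mapping[str, Cohort]
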