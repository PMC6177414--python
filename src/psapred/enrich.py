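"""Overlap of association markers with regulatory-element intervals,
stratified by p-value bin and reported relative to the baseline bin.

Markers are treated as single 1-based positions (converted to 0-based for
interval testing); intervals are BED-style 0-based half-open and are
merged on load.  Bins may be defined on the p scale (default; edges
``1, 0.05, 1e-2, ..., 0``) or on the -log10(p) scale, where the baseline
"0-0.05" bin covers -log10(p) in [0, 0.05).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import in_mhc, normalize_chrom

logger = logging.getLogger(__name__)

#: Default bin edges on the p scale, most significant last.
DEFAULT_P_EDGES = (1.0, 0.05, 1e-2, 1e-3, 1e-4, 1e-5, 0.0)
#: Default bin edges on the -log10(p) scale.
DEFAULT_LOG10_EDGES = (0.0, 0.05, 1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass
class PeakSet:
    """Named set of genomic intervals (0-based half-open), merged and sorted."""

    name: str
    intervals: pd.DataFrame  # chrom, start, end

    def __post_init__(self):
        df = self.intervals.copy()
        if not {"chrom", "start", "end"} <= set(df.columns):
            raise ValueError("intervals need chrom/start/end columns")
        if (df["start"] >= df["end"]).any():
            raise ValueError(f"peak set {self.name!r}: start must be < end")
        df["chrom"] = df["chrom"].map(normalize_chrom)
        before = len(df)
        self.intervals = merge_intervals(df)
        if len(self.intervals) != before:
            logger.info("peak set %s: merged %d -> %d intervals",
                        self.name, before, len(self.intervals))

    @property
    def is_empty(self) -> bool:
        return len(self.intervals) == 0

    def contains(self, chroms, pos0) -> np.ndarray:
        """Membership of 0-based points via binary search on merged intervals."""
        chroms = np.asarray([normalize_chrom(c) for c in np.atleast_1d(chroms)])
        pos0 = np.atleast_1d(np.asarray(pos0, dtype=np.int64))
        out = np.zeros(len(pos0), dtype=bool)
        for chrom, grp in self.intervals.groupby("chrom"):
            mask = chroms == chrom
            if not mask.any():
                continue
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            idx = np.searchsorted(starts, pos0[mask], side="right") - 1
            hit = (idx >= 0) & (pos0[mask] < ends[np.clip(idx, 0, None)])
            out[mask] = hit
        return out


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/adjacent intervals per chromosome; sorted output."""
    rows = []
    for chrom, grp in df.sort_values(["chrom", "start", "end"]).groupby("chrom"):
        cur_s = cur_e = None
        for s, e in zip(grp["start"], grp["end"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                rows.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        if cur_s is not None:
            rows.append((chrom, cur_s, cur_e))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"]).reset_index(drop=True)


def read_bed(path, name: Optional[str] = None) -> PeakSet:
    """Load a 3+ column BED file into a merged :class:`PeakSet`."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return PeakSet(name or str(path), df)


def bin_by_p(
    p_values,
    edges: Optional[Sequence[float]] = None,
    scale: str = "p",
) -> pd.Series:
    """Assign each finite p-value to exactly one significance bin.

    ``scale='p'`` bins p directly with edges descending from 1 to 0;
    ``scale='log10'`` bins -log10(p) with ascending edges (last bin open
    above the largest edge).  A value exactly on an edge goes to the more
    significant bin.  Bin 0 is always the baseline (least significant).
    """
    p = np.asarray(p_values, dtype=float)
    if scale == "p":
        e = np.asarray(edges if edges is not None else DEFAULT_P_EDGES, dtype=float)
        if not np.all(np.diff(e) < 0):
            raise ValueError("p-scale edges must be strictly decreasing")
        asc = e[::-1]  # ascending: 0 ... 1
        # bins: (asc[i], asc[i+1]]; boundary value joins the lower (more
        # significant) interval via side='left'
        idx = np.searchsorted(asc, p, side="left") - 1
        idx = np.clip(idx, 0, len(asc) - 2)
        n_bins = len(asc) - 1
        bin_num = (n_bins - 1) - idx  # 0 = baseline (least significant)
        labels = [f"({asc[i]:g},{asc[i + 1]:g}]" for i in range(n_bins)][::-1]
    elif scale == "log10":
        e = np.asarray(edges if edges is not None else DEFAULT_LOG10_EDGES, dtype=float)
        if not np.all(np.diff(e) > 0):
            raise ValueError("log10-scale edges must be strictly increasing")
        with np.errstate(divide="ignore"):
            lp = -np.log10(p)
        # bins: [e[i], e[i+1]) plus a final open bin [e[-1], inf); an exact
        # edge joins the higher (more significant) interval
        bin_num = np.searchsorted(e, lp, side="right") - 1
        bin_num = np.clip(bin_num, 0, len(e) - 1)
        labels = [f"[{e[i]:g},{e[i + 1]:g})" for i in range(len(e) - 1)]
        labels.append(f"[{e[-1]:g},inf)")
    else:
        raise ValueError("scale must be 'p' or 'log10'")

    cats = pd.Categorical.from_codes(
        np.where(np.isfinite(p), bin_num, -1), categories=labels, ordered=True
    )
    return pd.Series(cats, name="p_bin")


def overlap_fractions(
    markers: pd.DataFrame,
    peaks: Sequence[PeakSet],
    edges: Optional[Sequence[float]] = None,
    scale: str = "p",
    exclude_mhc: bool = False,
) -> pd.DataFrame:
    """Per (cell type, p-bin) overlap fractions relative to the baseline bin.

    ``markers`` needs columns ``chrom``, ``pos`` (1-based), ``p_value``.
    ``relative_fraction`` is NaN when the baseline fraction is 0 (e.g. no
    peaks at all).  With ``exclude_mhc`` the extended MHC window is removed
    before binning.
    """
    df = markers.loc[np.isfinite(markers["p_value"].astype(float))].copy()
    if exclude_mhc:
        df = df.loc[~in_mhc(df["chrom"].to_numpy(), df["pos"].to_numpy())]
    bins = bin_by_p(df["p_value"].to_numpy(), edges=edges, scale=scale)
    df = df.assign(p_bin=bins.array)  # keep categorical dtype (bin order)
    baseline = bins.cat.categories[0]

    pos0 = df["pos"].to_numpy(dtype=np.int64) - 1  # 1-based point -> 0-based
    chroms = df["chrom"].to_numpy()

    rows = []
    for ps in peaks:
        hit = ps.contains(chroms, pos0) if not ps.is_empty else np.zeros(len(df), bool)
        sub = df.assign(hit=hit)
        agg = sub.groupby("p_bin", observed=False)["hit"].agg(["size", "sum"])
        base_frac = np.nan
        if agg.loc[baseline, "size"] > 0:
            base_frac = agg.loc[baseline, "sum"] / agg.loc[baseline, "size"]
        for p_bin, row in agg.iterrows():
            frac = row["sum"] / row["size"] if row["size"] > 0 else np.nan
            rel = frac / base_frac if base_frac and base_frac > 0 else np.nan
            rows.append({
                "cell_type": ps.name,
                "p_bin": p_bin,
                "n_markers": int(row["size"]),
                "n_overlapping": int(row["sum"]),
                "fraction": frac,
                "relative_fraction": rel,
            })
    return pd.DataFrame(rows)
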