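"""Per-SNP fixation index from two pools' allele read counts.

The estimator is the plain heterozygosity ratio

    F_ST = (H_T - H_S) / H_T

with allele frequencies taken as raw read-count ratios in each pool,
``H_i = 2 p_i (1 - p_i)``, ``H_S`` the unweighted mean of the two
within-pool heterozygosities and ``H_T = 2 p_bar (1 - p_bar)`` at the
unweighted mean frequency.  No pool-size or read-depth correction is
applied; pool-size-aware estimators (Karlsson, PoPoolation2) are a
deliberate extension point, not implemented here.

Sites where ``H_T = 0`` (monomorphic across both pools, or one pool has
zero depth) are retained with ``defined = False`` so that window SNP
counts remain auditable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

COUNT_COLUMNS = [
    "chrom",
    "pos",
    "ref_count_1",
    "alt_count_1",
    "ref_count_2",
    "alt_count_2",
]

FST_COLUMNS = ["chrom", "pos", "p1", "p2", "h_s", "h_t", "fst", "defined"]


@dataclass(frozen=True)
class SnpCount:
    """One biallelic site's ref/alt read counts in each of two pools."""

    chrom: str
    pos: int  # 1-based
    ref_count_1: int
    alt_count_1: int
    ref_count_2: int
    alt_count_2: int


@dataclass(frozen=True)
class FstRecord:
    chrom: str
    pos: int
    p1: float
    p2: float
    h_s: float
    h_t: float
    fst: float  # NaN when undefined
    defined: bool


def snp_fst(site: SnpCount) -> FstRecord:
    """Compute F_ST for a single site.

    Raises ``ValueError`` if both pools have zero depth.  A site with one
    zero-depth pool, or monomorphic in both pools, yields ``defined=False``
    and ``fst=NaN``.
    """
    for c in (site.ref_count_1, site.alt_count_1, site.ref_count_2, site.alt_count_2):
        if c < 0:
            raise ValueError(f"negative read count at {site.chrom}:{site.pos}")
    d1 = site.ref_count_1 + site.alt_count_1
    d2 = site.ref_count_2 + site.alt_count_2
    if d1 == 0 and d2 == 0:
        raise ValueError(f"zero depth in both pools at {site.chrom}:{site.pos}")
    if d1 == 0 or d2 == 0:
        p1 = site.alt_count_1 / d1 if d1 else float("nan")
        p2 = site.alt_count_2 / d2 if d2 else float("nan")
        return FstRecord(site.chrom, site.pos, p1, p2, float("nan"), float("nan"), float("nan"), False)
    p1 = site.alt_count_1 / d1
    p2 = site.alt_count_2 / d2
    h1 = 2.0 * p1 * (1.0 - p1)
    h2 = 2.0 * p2 * (1.0 - p2)
    h_s = 0.5 * (h1 + h2)
    pbar = 0.5 * (p1 + p2)
    h_t = 2.0 * pbar * (1.0 - pbar)
    if h_t > 0.0:
        return FstRecord(site.chrom, site.pos, p1, p2, h_s, h_t, (h_t - h_s) / h_t, True)
    return FstRecord(site.chrom, site.pos, p1, p2, h_s, h_t, float("nan"), False)


def _check_sorted(df: pd.DataFrame) -> None:
    by_chrom = df.groupby("chrom", sort=False)["pos"]
    if not bool(by_chrom.apply(lambda s: s.is_monotonic_increasing).all()):
        raise ValueError("input sites must be sorted by (chrom, pos); sort upstream")


def fst_table(sites: pd.DataFrame) -> pd.DataFrame:
    """Vectorised per-site F_ST over a (chrom, pos)-sorted count table.

    One output row per input row, order preserved; undefined sites are
    retained with ``defined=False`` and ``fst=NaN``.  Raises on unsorted
    input (sorting is the caller's job, to keep streaming semantics) and
    on any site with zero depth in both pools.
    """
    if sites.empty:
        return pd.DataFrame(columns=FST_COLUMNS)
    _check_sorted(sites)
    r1 = sites["ref_count_1"].to_numpy(float)
    a1 = sites["alt_count_1"].to_numpy(float)
    r2 = sites["ref_count_2"].to_numpy(float)
    a2 = sites["alt_count_2"].to_numpy(float)
    if min(r1.min(), a1.min(), r2.min(), a2.min()) < 0:
        raise ValueError("negative read counts")
    d1 = r1 + a1
    d2 = r2 + a2
    if np.any((d1 == 0) & (d2 == 0)):
        i = int(np.argmax((d1 == 0) & (d2 == 0)))
        row = sites.iloc[i]
        raise ValueError(f"zero depth in both pools at {row['chrom']}:{row['pos']}")
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(d1 > 0, a1 / np.where(d1 > 0, d1, 1), np.nan)
        p2 = np.where(d2 > 0, a2 / np.where(d2 > 0, d2, 1), np.nan)
        h_s = p1 * (1.0 - p1) + p2 * (1.0 - p2)  # = (H1+H2)/2 with H=2pq
        pbar = 0.5 * (p1 + p2)
        h_t = 2.0 * pbar * (1.0 - pbar)
        fst = (h_t - h_s) / h_t
    defined = np.isfinite(h_t) & (h_t > 0.0)
    fst = np.where(defined, fst, np.nan)
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "p1": p1,
            "p2": p2,
            "h_s": h_s,
            "h_t": h_t,
            "fst": fst,
            "defined": defined,
        }
    )
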