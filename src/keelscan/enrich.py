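"""Candidate-gene annotation and gene-set over-representation.

Genes overlapping candidate sweep regions by at least one base pair (on
0-based half-open coordinates) become the candidate list; each gene-set
term is then tested with the one-sided hypergeometric upper tail
(equivalently Fisher's exact test on the 2x2 table) and
Benjamini-Hochberg FDR adjustment across terms.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

ENRICH_COLUMNS = ["term", "term_size", "overlap", "p_value", "p_adjusted"]


def genes_in_regions(genes: pd.DataFrame, regions: pd.DataFrame) -> pd.DataFrame:
    """Genes with >= 1 bp overlap with any candidate region.

    *genes*: gene_id, chrom, start, end (0-based half-open).  *regions*:
    chrom, start, end and optionally ``max_window_fst``.  Each gene is
    reported once with the best (max) F_ST among its overlapping
    regions.  Regions on chromosomes absent from the annotation are
    skipped with a warning.
    """
    known = set(genes["chrom"].unique())
    best: dict[str, float] = {}
    for _, reg in regions.iterrows():
        if reg["chrom"] not in known:
            warnings.warn(
                f"region {reg['chrom']}:{reg['start']}-{reg['end']} is on a "
                "chromosome absent from the gene annotation; skipped"
            )
            continue
        g = genes[genes["chrom"] == reg["chrom"]]
        hit = (g["start"].to_numpy() < reg["end"]) & (g["end"].to_numpy() > reg["start"])
        fst = float(reg["max_window_fst"]) if "max_window_fst" in reg else np.nan
        for gid in g.loc[hit, "gene_id"]:
            if gid not in best or not (best[gid] >= fst):
                best[gid] = fst
    if not best:
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end", "best_fst"])
    out = genes[genes["gene_id"].isin(best)][["gene_id", "chrom", "start", "end"]].copy()
    out["best_fst"] = out["gene_id"].map(best)
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


def fisher_enrich(
    candidates: list[str],
    universe: list[str],
    gene_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH adjustment.

    For a term of size K in a universe of size M with n candidates and
    observed overlap k, the raw p value is P[X >= k] for
    X ~ Hypergeometric(M, K, n); terms are intersected with the universe
    first and results are sorted by raw p ascending.
    """
    uni = set(universe)
    cand = set(candidates)
    if not uni:
        raise ValueError("empty gene universe")
    if not cand:
        raise ValueError("empty candidate gene list")
    stray = cand - uni
    if stray:
        raise ValueError(f"candidate genes not in universe: {sorted(stray)[:5]}")
    M, n = len(uni), len(cand)
    rows = []
    for term, members in gene_sets.items():
        in_uni = set(members) & uni
        K = len(in_uni)
        k = len(in_uni & cand)
        p = float(hypergeom.sf(k - 1, M, K, n))  # P[X >= k]
        rows.append((term, K, k, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p_value"])
    out["p_adjusted"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values("p_value", kind="stable").reset_index(drop=True)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values (step-up FDR)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
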