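"""Phenotype-level tests: cage-tier association and production traits.

Two report generators: a Pearson chi-square test of independence between
cage tier (3 rows) and keel-bend level (4 columns), and per-trait
one-way ANOVA across keel-bend levels with Tukey HSD pairwise
comparisons summarised as a compact letter display (groups sharing a
letter are not significantly different).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.sandbox.stats.multicomp import MultiComparison


@dataclass
class ChisqResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray


@dataclass
class AnovaReport:
    trait: str
    groups: pd.DataFrame  # kb_level, n, mean, sem, letters
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group1, group2, p_adjusted, reject


def chisq_cage(table) -> ChisqResult:
    """Pearson chi-square of independence on a cage-tier x KB-level table.

    For the designed 3x4 table df = (3-1)(4-1) = 6.  No continuity
    correction is applied.  Raises on an all-zero row or column margin.
    """
    tbl = np.asarray(table, dtype=float)
    if tbl.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if np.any(tbl < 0):
        raise ValueError("counts must be non-negative")
    if np.any(tbl.sum(axis=0) == 0) or np.any(tbl.sum(axis=1) == 0):
        raise ValueError("zero row or column margin; drop the empty category first")
    res = stats.chi2_contingency(tbl, correction=False)
    return ChisqResult(
        statistic=float(res.statistic),
        df=int(res.dof),
        p_value=float(res.pvalue),
        expected=res.expected_freq,
    )


def compact_letter_display(
    groups: list, nonsig_pairs: set[tuple]
) -> dict:
    """Insert-and-absorb compact letter display.

    Groups connected by a non-significant pairwise difference share at
    least one letter; significantly different groups never do.  Letter
    assignments are canonical in the given group order, so relabelling
    the order never changes which pairs share letters.
    """
    nonsig = {frozenset(p) for p in nonsig_pairs}
    sig = [
        (a, b)
        for i, a in enumerate(groups)
        for b in groups[i + 1 :]
        if frozenset((a, b)) not in nonsig
    ]

    # Piepho insert-and-absorb: start from one letter covering everything,
    # split every letter that joins a significantly different pair.
    letters: list[set] = [set(groups)]
    for a, b in sig:
        for ls in [s for s in letters if a in s and b in s]:
            letters.remove(ls)
            for split in (ls - {a}, ls - {b}):
                if split and not any(split <= other for other in letters):
                    letters.append(split)
        letters = [
            s for i, s in enumerate(letters)
            if not any(s < o or (s == o and i > j) for j, o in enumerate(letters))
        ]
    kept = letters
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, ls in zip(alphabet, kept):
        for g in groups:
            if g in ls:
                out[g] += letter
    return out


def anova_by_level(
    df: pd.DataFrame,
    trait: str,
    group_col: str = "kb_level",
    alpha: float = 0.05,
    method: str = "tukey",
) -> AnovaReport:
    """One-way ANOVA of *trait* across KB levels with pairwise letters.

    Levels with fewer than 2 observations are dropped with a warning.
    ``method`` is "tukey" (HSD, default) or "bonferroni".  Raises on
    degenerate data with zero within- and between-group variance.
    """
    sub = df[[group_col, trait]].dropna()
    sizes = sub.groupby(group_col)[trait].size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"dropping {group_col} groups with < 2 observations: {small}")
        sub = sub[~sub[group_col].isin(small)]
    levels = sorted(sub[group_col].unique())
    if len(levels) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations each")
    arrays = [sub.loc[sub[group_col] == g, trait].to_numpy(float) for g in levels]
    if np.ptp(sub[trait].to_numpy(float)) == 0:
        raise ValueError("all trait values identical: F statistic undefined")
    f_stat, p = stats.f_oneway(*arrays)

    mc = MultiComparison(sub[trait].to_numpy(float), sub[group_col].to_numpy())
    if method == "tukey":
        tk = mc.tukeyhsd(alpha=alpha)
        i1, i2 = mc.pairindices
        pw = pd.DataFrame(
            {
                "group1": mc.groupsunique[np.asarray(i1)],
                "group2": mc.groupsunique[np.asarray(i2)],
                "p_adjusted": tk.pvalues,
                "reject": tk.reject,
            }
        )
    elif method == "bonferroni":
        res = mc.allpairtest(stats.ttest_ind, alpha=alpha, method="bonf")[0]
        pw = pd.DataFrame(res.data[1:], columns=[str(c).strip() for c in res.data[0]])
        pw = pw.rename(columns={"pval_corr": "p_adjusted"})[
            ["group1", "group2", "p_adjusted", "reject"]
        ]
        pw["reject"] = pw["reject"].astype(bool)
    else:
        raise ValueError("method must be 'tukey' or 'bonferroni'")

    nonsig = {
        (g1, g2)
        for g1, g2, rej in zip(pw["group1"], pw["group2"], pw["reject"])
        if not rej
    }
    letters = compact_letter_display(levels, nonsig)
    grp = (
        sub.groupby(group_col)[trait]
        .agg(n="size", mean="mean", sem="sem")
        .reset_index()
    )
    grp["letters"] = grp[group_col].map(letters)
    return AnovaReport(
        trait=trait,
        groups=grp,
        f_statistic=float(f_stat),
        p_value=float(p),
        pairwise=pw,
    )
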