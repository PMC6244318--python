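"""Phenotype handling: divergent-group selection by BLUP and group statistics.

Animals are ranked by their best linear unbiased prediction (BLUP) of additive
genetic merit for residual feed intake (RFI, kg/day); the lowest tail is the
feed-efficient group and the highest tail the feed-inefficient group.  Group
means and a two-sample Student's t-test reproduce the descriptive comparison
of phenotypes (RFI, intramuscular fat, ribeye area) between the two groups.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

FEED_EFFICIENT = "feed_efficient"
FEED_INEFFICIENT = "feed_inefficient"

PHENOTYPE_COLUMNS = ["animal_id", "group", "blup", "rfi", "imf", "rea"]


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype table (TSV; empty cells are missing values).

    Expected columns: ``animal_id`` plus any of ``group``, ``blup``, ``rfi``,
    ``imf``, ``rea``.  ``animal_id`` must be unique.
    """
    df = pd.read_csv(path, sep="\t", dtype={"animal_id": str})
    if "animal_id" not in df.columns:
        raise ValueError("phenotype table must have an 'animal_id' column")
    if df["animal_id"].duplicated().any():
        dup = df.loc[df["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise ValueError(f"duplicate animal_id: {dup!r}")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def select_divergent_by_blup(table: pd.DataFrame, n_per_tail: int) -> pd.DataFrame:
    """Select the two divergent RFI tails by BLUP of genetic merit.

    Returns the ``n_per_tail`` lowest-BLUP animals labelled ``feed_efficient``
    and the ``n_per_tail`` highest-BLUP animals labelled ``feed_inefficient``.
    Ties are broken by ``animal_id`` ascending, so the split is deterministic.
    """
    if n_per_tail < 1:
        raise ValueError("n_per_tail must be >= 1")
    if "blup" not in table.columns or table["blup"].isna().any():
        raise ValueError("blup must be present for every animal")
    n = len(table)
    if n_per_tail > n // 2:
        raise ValueError(
            f"cannot select {n_per_tail} per tail from {n} animals"
        )
    ranked = table.sort_values(["blup", "animal_id"], kind="mergesort")
    eff = ranked.iloc[:n_per_tail].copy()
    ineff = ranked.iloc[n - n_per_tail :].copy()
    # highest BLUP first within the inefficient tail (descending rank)
    ineff = ineff.iloc[::-1]
    eff["group"] = FEED_EFFICIENT
    ineff["group"] = FEED_INEFFICIENT
    return pd.concat([eff, ineff], ignore_index=True)


def group_mean(values) -> float:
    """Arithmetic mean over non-missing values; raises if all are missing."""
    arr = np.asarray(pd.Series(values, dtype=float))
    ok = ~np.isnan(arr)
    if not ok.any():
        raise ValueError("group_mean: all values missing")
    return float(arr[ok].mean())


def two_sample_t_test(group_a, group_b, equal_variance: bool = True):
    """Two-sample t-test between two groups, dropping missing values.

    By default this is Student's pooled-variance test; ``equal_variance=False``
    gives Welch's test.  Returns ``(t, df, p_two_sided)``.  Degenerate inputs
    with zero variance return ``t=0, p=1`` when the means are equal, and the
    smallest representable p when they differ.
    """
    a = np.asarray(pd.Series(group_a, dtype=float))
    b = np.asarray(pd.Series(group_b, dtype=float))
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 non-missing values per group")
    if equal_variance:
        df = len(a) + len(b) - 2
    else:
        va, vb = a.var(ddof=1), b.var(ddof=1)
        na, nb = len(a), len(b)
        denom = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        df = (va / na + vb / nb) ** 2 / denom if denom > 0 else na + nb - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, float(df), 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), float(df), float(
            np.finfo(float).tiny
        )
    res = stats.ttest_ind(a, b, equal_var=equal_variance)
    return float(res.statistic), float(df), float(res.pvalue)


def group_summary(table: pd.DataFrame, columns=("blup", "rfi", "imf", "rea")) -> pd.DataFrame:
    """Per-group mean / n / missing count for the phenotype columns present."""
    rows = []
    for grp, sub in table.groupby("group", sort=True):
        for col in columns:
            if col not in sub.columns:
                continue
            vals = pd.Series(sub[col], dtype=float)
            rows.append(
                {
                    "group": grp,
                    "variable": col,
                    "mean": group_mean(vals) if vals.notna().any() else np.nan,
                    "n": int(vals.notna().sum()),
                    "n_missing": int(vals.isna().sum()),
                }
            )
    return pd.DataFrame(rows)
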