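"""Count filtering, median-of-ratios normalization, and network input transform.

Count matrices are pandas DataFrames with unique feature ids as the index and
unique sample ids as columns; all entries are nonnegative.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd


def read_counts(path) -> pd.DataFrame:
    """Read a counts TSV (first column feature id, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_counts(df)
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="feature_id")


def validate_counts(m: pd.DataFrame) -> None:
    if m.index.duplicated().any():
        raise ValueError("duplicate feature ids")
    if m.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    if (m.to_numpy() < 0).any():
        raise ValueError("negative counts")


def filter_counts(m: pd.DataFrame, max_zero_fraction: float = 0.2, report: bool = False):
    """Drop features that are all zero or have too many zero-count samples.

    A feature is removed if (i) every sample is zero, or (ii) the fraction of
    samples with a zero count exceeds ``max_zero_fraction`` (default 1/5, so a
    feature with zeros in more than 20% of samples is dropped).  Feature order
    is preserved.  With ``report=True`` also returns a DataFrame of dropped
    features and the reason.
    """
    if not 0.0 <= max_zero_fraction <= 1.0:
        raise ValueError("max_zero_fraction must be in [0, 1]")
    validate_counts(m)
    arr = m.to_numpy()
    zero_frac = (arr == 0).mean(axis=1)
    all_zero = (arr == 0).all(axis=1)
    too_many_zeros = zero_frac > max_zero_fraction
    keep = ~(all_zero | too_many_zeros)
    out = m.loc[keep]
    if out.shape[0] == 0:
        warnings.warn("filter_counts: no features pass the zero-count filter")
    if report:
        reason = np.where(all_zero, "all_zero", "zero_fraction")
        rep = pd.DataFrame(
            {
                "feature_id": m.index[~keep],
                "reason": reason[~keep],
                "zero_fraction": zero_frac[~keep],
            }
        )
        return out, rep
    return out


def size_factors(m: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (the standard scheme for NB count data).

    Reference features are those with strictly positive counts in every
    sample; for each sample the size factor is the median across reference
    features of count / geometric mean of that feature's row.
    """
    validate_counts(m)
    arr = m.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no feature with positive counts in all samples; filter first or "
            "use a pseudo-reference"
        )
    ref = arr[positive]
    log_geo = np.log(ref).mean(axis=1, keepdims=True)
    ratios = ref / np.exp(log_geo)
    s = np.median(ratios, axis=0)
    if not np.all(np.isfinite(s)) or (s <= 0).any():
        raise ValueError("degenerate size factors")
    return pd.Series(s, index=m.columns, name="size_factor")


def normalize_counts(m: pd.DataFrame, s: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its size factor."""
    if not m.columns.equals(pd.Index(s.index)):
        raise ValueError("size factor index does not match sample ids")
    return m.div(s, axis=1)


def log_transform_for_network(normalized: pd.DataFrame, pseudocount: float = 1.0):
    """log2(x + pseudocount) transform for network construction.

    Returns ``(transformed, kept_mask)`` where features with zero variance
    across samples are flagged False in ``kept_mask``; such features carry no
    correlation information and must be excluded from network construction.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    logged = np.log2(normalized + pseudocount)
    variances = logged.var(axis=1, ddof=0)
    kept = variances > 1e-24
    if (~kept).any():
        warnings.warn(
            f"log_transform_for_network: {int((~kept).sum())} zero-variance "
            "features excluded from network input"
        )
    return logged, kept
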