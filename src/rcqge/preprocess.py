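"""Cleaning of raw peak-area frequency tables before titration fitting.

Three rules, applied in order:

1. drop "bad" points — no signal detected for either product (missing
   frequency);
2. collapse printing replicates to their median;
3. exclude boundary frequencies (exactly 0 or 1) from fitting, since the
   decadic logit is undefined there.  They are logged, not clamped:
   clamping would silently bias the fitted slope.

The cleaned table keeps the input schema (minus the replicate column) and
gains ``log10_conc`` and ``logit`` columns.  A QC report records every
dropped point with a reason code.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import inv_logit10, logit10

__all__ = [
    "drop_bad_points",
    "median_replicates",
    "logit_transform",
    "preprocess",
    "MIN_POINTS",
]

#: minimum usable titration points for a fittable ladder: two define the
#: line, one more leaves a residual degree of freedom
MIN_POINTS = 3

_KEY_COLS = ["sample_id", "breed", "group", "assay", "point_index", "competitor_conc_M"]


def _keys(df: pd.DataFrame) -> list[str]:
    keys = [c for c in _KEY_COLS if c in df.columns]
    if "allele" in df.columns:
        keys.append("allele")
    return keys


def drop_bad_points(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove points where no signal was detected for either product.

    Missing (NaN) frequency encodes "no peak for cDNA nor competitor".
    Returns the filtered table and a QC frame of dropped rows with a
    ``reason`` column.
    """
    bad = df["frequency"].isna()
    qc = df.loc[bad].copy()
    qc["reason"] = "no_signal"
    return df.loc[~bad].copy(), qc


def median_replicates(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse printing replicates to one frequency per titration point.

    The per-point value is the median over non-missing replicates; a point
    whose replicates are all missing stays missing (and then falls to the
    no-signal rule).  Any ``replicate`` column is dropped.
    """
    keys = _keys(df)
    out = (
        df.groupby(keys, sort=False, dropna=False)["frequency"]
        .median()
        .reset_index()
    )
    return out


def logit_transform(f):
    """Decadic logit ``y = log10(f/(1-f))``; domain error outside (0, 1)."""
    return logit10(f)


def _drop_boundary(df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    bad = (df["frequency"] <= 0.0) | (df["frequency"] >= 1.0)
    qc = df.loc[bad].copy()
    qc["reason"] = "boundary_frequency"
    return df.loc[~bad].copy(), qc


def preprocess(df: pd.DataFrame, min_points: int = MIN_POINTS) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full cleaning pass: drop bad points, median replicates, logit column.

    Returns ``(clean, qc)``.  ``clean`` has one row per (sample, assay,
    point[, allele]) with ``log10_conc`` and ``logit`` columns; ladders
    left with fewer than ``min_points`` usable points are removed entirely
    and reported in ``qc`` with reason ``short_ladder`` (the assay is then
    reported-but-unfit downstream, never a crash).

    Idempotent: running the output through again changes nothing.
    """
    work = df.copy()
    if "replicate" in work.columns:
        work = median_replicates(work)
    work, qc_signal = drop_bad_points(work)
    work, qc_boundary = _drop_boundary(work)

    ladder_keys = [c for c in ["sample_id", "breed", "group", "assay"] if c in work.columns]
    if "allele" in work.columns:
        ladder_keys.append("allele")
    sizes = work.groupby(ladder_keys, sort=False)["frequency"].transform("size")
    short = sizes < min_points
    qc_short = work.loc[short].copy()
    qc_short["reason"] = "short_ladder"
    work = work.loc[~short].copy()

    work["log10_conc"] = np.log10(work["competitor_conc_M"])
    work["logit"] = np.log10(work["frequency"] / (1.0 - work["frequency"]))
    qc_cols = _keys(df) + ["frequency", "reason"]
    qc = pd.concat([qc_signal, qc_boundary, qc_short], ignore_index=True)
    qc = qc[[c for c in qc_cols if c in qc.columns]]
    return work.reset_index(drop=True), qc


def inverse_logit_transform(y):
    """Inverse decadic logit; round-trips with :func:`logit_transform`."""
    return inv_logit10(y)
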