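"""Library-size normalization of siRNA locus counts.

Two scalings are provided. Total count scaling (TCS) rescales every library
to the largest one:

    R' = R * M / T,            M = max(T_1, ..., T_n)

Knockdown-corrected scaling (KDCS) first removes the feeding-associated
reads K from each library size, so that the massive primary-siRNA signal of
a feeding library does not masquerade as global depletion of everything
else:

    R' = R * M / (T - K),      M = max(T_1-K_1, ..., T_n-K_n)

Libraries are normalized within a batch (by default one serotype's
libraries, since serotypes are analysed separately).
"""

from __future__ import annotations

import pandas as pd


def _check_meta(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    meta = meta.set_index("library_id") if "library_id" in meta.columns else meta
    missing = [c for c in matrix.columns if c not in meta.index]
    if missing:
        raise ValueError(f"library metadata missing for {missing}")
    return meta.loc[list(matrix.columns)]


def total_count_scaling(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """TCS: scale each library to the largest total read count M = max(T)."""
    meta = _check_meta(matrix, meta)
    t = meta["T"].astype(float)
    if (t <= 0).any():
        bad = t.index[t <= 0].tolist()
        raise ValueError(f"total count scaling requires T > 0; offending: {bad}")
    m = t.max()
    return matrix * (m / t)


def kdcs(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Knockdown-corrected scaling: R' = R * M / (T - K), M = max(T - K)."""
    meta = _check_meta(matrix, meta)
    corrected = meta["T"].astype(float) - meta["K"].astype(float)
    if (corrected <= 0).any():
        bad = corrected.index[corrected <= 0].tolist()
        raise ValueError(
            f"KDCS requires T - K > 0 for every library; offending: {bad}"
        )
    m = corrected.max()
    return matrix * (m / corrected)


def normalize_by_batch(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    method: str = "kdcs",
    batch_column: str = "serotype",
) -> pd.DataFrame:
    """Apply TCS or KDCS separately within each batch (default: serotype)."""
    if method not in ("kdcs", "tcs"):
        raise ValueError(f"unknown normalization method {method!r}")
    fn = kdcs if method == "kdcs" else total_count_scaling
    meta_ix = meta.set_index("library_id") if "library_id" in meta.columns else meta
    parts = []
    for _, group in meta_ix.loc[list(matrix.columns)].groupby(batch_column, sort=False):
        libs = [c for c in matrix.columns if c in group.index]
        parts.append(fn(matrix[libs], group))
    return pd.concat(parts, axis=1)[matrix.columns]
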