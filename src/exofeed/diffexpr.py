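"""Negative-binomial differential expression for count matrices.

A transparent two-group procedure in the DESeq2 mould, applied to raw
counts: median-of-ratios size factors, per-feature method-of-moments
dispersion, and a Wald test on the group coefficient of an NB log-linear
model, followed by Benjamini-Hochberg correction. Dispersion shrinkage,
Cook's distance filtering and independent filtering are deliberately not
replicated; every step here has a closed form or a simple Newton iteration.

The NB model for feature *i* in library *j* with size factor ``s_j`` and
dispersion ``alpha`` is ``y_ij ~ NB(mean = s_j * mu_g(j), var = mean +
alpha * mean^2)`` with one mean per group. The group log-mean MLE solves
``sum_j (y_ij - s_j mu) / (1 + alpha s_j mu) = 0`` and its variance is the
inverse Fisher information ``sum_j s_j mu / (1 + alpha s_j mu)``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: numerical floor for a group mean, as if half a read had been observed
_HALF_READ = 0.5


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    For each feature expressed in every library, the ratio of its count to
    the feature's geometric mean is taken; a library's factor is the median
    of these ratios.
    """
    x = counts.to_numpy(dtype=float)
    all_pos = (x > 0).all(axis=1)
    if not all_pos.any():
        raise ValueError(
            "no feature has positive counts in every library; "
            "filter features or libraries before size-factor estimation"
        )
    logs = np.log(x[all_pos])
    log_geomean = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def estimate_dispersion(counts: pd.DataFrame, size_factors: pd.Series) -> pd.Series:
    """Per-feature method-of-moments NB dispersion on scaled counts.

    ``alpha = max(0, (var - mean) / mean^2)`` with the sample variance
    (ddof=1) of size-factor-scaled counts. Features with zero mean get NaN
    and are excluded from testing.
    """
    if counts.shape[1] < 2:
        raise ValueError("dispersion estimation needs at least 2 libraries")
    scaled = counts.to_numpy(dtype=float) / size_factors.loc[counts.columns].to_numpy()
    mean = scaled.mean(axis=1)
    var = scaled.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(mean > 0, np.maximum(0.0, (var - mean) / mean**2), np.nan)
    return pd.Series(alpha, index=counts.index, name="dispersion")


def _nb_group_fit(
    y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-feature NB mean MLE for one group.

    ``y`` is features x libraries, ``s`` the group's size factors, ``alpha``
    per-feature dispersions. Returns (log mu, Fisher information). Groups
    with zero total count are floored at half a read.
    """
    s = s[None, :]
    alpha = alpha[:, None]
    tot = y.sum(axis=1)
    mu = np.maximum(tot, _HALF_READ) / s.sum()
    beta = np.log(mu)
    for _ in range(n_iter):
        m = s * np.exp(beta[:, None])
        denom = 1.0 + alpha * m
        score = ((y - m) / denom).sum(axis=1)
        info = (m / denom).sum(axis=1)
        step = np.clip(score / np.maximum(info, 1e-12), -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-10:
            break
    # do not let an all-zero group drive beta to -inf
    floor = np.log(_HALF_READ / s.sum())
    beta = np.maximum(beta, floor)
    m = s * np.exp(beta[:, None])
    info = (m / (1.0 + alpha * m)).sum(axis=1)
    return beta, info


def nb_wald_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    dispersion: pd.Series,
    group_labels: pd.Series,
    test_group: str,
    reference_group: str = "WT",
) -> pd.DataFrame:
    """Wald test of ``test_group`` vs ``reference_group`` per feature.

    Returns a frame with baseMean (mean of scaled counts), log2FoldChange
    (test over reference), lfcSE (log2 units), stat and pvalue. Features
    with zero counts in both groups are reported as NA.
    """
    labels = group_labels.loc[counts.columns]
    in_test = (labels == test_group).to_numpy()
    in_ref = (labels == reference_group).to_numpy()
    if not in_test.any() or not in_ref.any():
        raise ValueError(
            f"both groups must be non-empty ({test_group} vs {reference_group})"
        )
    s = size_factors.loc[counts.columns].to_numpy(dtype=float)
    y = counts.to_numpy(dtype=float)
    alpha = dispersion.loc[counts.index].to_numpy(dtype=float)

    base_mean = (y / s).mean(axis=1)
    testable = (y[:, in_test | in_ref].sum(axis=1) > 0) & np.isfinite(alpha)

    ln2 = np.log(2.0)
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FoldChange": np.nan,
            "lfcSE": np.nan,
            "stat": np.nan,
            "pvalue": np.nan,
        },
        index=counts.index,
    )
    if testable.any():
        yt = y[testable]
        at = alpha[testable]
        b_test, i_test = _nb_group_fit(yt[:, in_test], s[in_test], at)
        b_ref, i_ref = _nb_group_fit(yt[:, in_ref], s[in_ref], at)
        lfc = b_test - b_ref
        se = np.sqrt(1.0 / np.maximum(i_test, 1e-12) + 1.0 / np.maximum(i_ref, 1e-12))
        z = lfc / se
        p = 2.0 * stats.norm.sf(np.abs(z))
        out.loc[testable, "log2FoldChange"] = lfc / ln2
        out.loc[testable, "lfcSE"] = se / ln2
        out.loc[testable, "stat"] = z
        out.loc[testable, "pvalue"] = p
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, preserving input order.

    NaN entries (untested features) stay NaN and do not count towards m.
    """
    p = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(p)
    if ((p[mask] < 0) | (p[mask] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full(p.shape, np.nan)
    if mask.any():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def moderated_within_group_dispersion(
    counts: pd.DataFrame, size_factors: pd.Series, labels: pd.Series
) -> tuple[pd.Series, int]:
    """Within-group MoM dispersion with an across-feature median floor.

    The all-library estimate absorbs any real between-group difference into
    alpha, making large effects untestable; the per-group estimate avoids
    that but is wildly noisy at 2-3 replicates (its truncation at zero makes
    naive normal-reference tests anti-conservative). This combines both
    remedies: per feature, a degrees-of-freedom-weighted average of each
    group's raw (untruncated) MoM estimate, floored at the across-feature
    median — no feature is allowed to look quieter than the experiment's
    typical dispersion. Returns (alpha, residual degrees of freedom); the
    caller should refer the Wald statistic to a t distribution with that df
    to account for the estimated dispersion.
    """
    scaled = counts.to_numpy(dtype=float) / size_factors.loc[counts.columns].to_numpy()
    raw = np.zeros(len(counts))
    den = 0
    for group in labels.unique():
        idx = (labels == group).to_numpy()
        if idx.sum() < 2:
            continue
        m = scaled[:, idx].mean(axis=1)
        v = scaled[:, idx].var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(m > 0, (v - m) / m**2, 0.0)
        raw += a * (idx.sum() - 1)
        den += idx.sum() - 1
    if den == 0:
        raise ValueError("need at least one group with >= 2 libraries")
    raw /= den
    floor = float(np.quantile(np.maximum(raw, 0.0), 0.5))
    return pd.Series(np.maximum(raw, floor), index=counts.index), den


def run_de(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    test_group: str,
    reference_group: str = "WT",
    alpha_threshold: float = 0.05,
    size_factor_features: pd.Index | None = None,
) -> pd.DataFrame:
    """Full DE pass: size factors, dispersion, Wald test, BH, significance.

    ``meta`` needs library_id and condition columns. ``size_factor_features``
    optionally restricts size-factor estimation (e.g. to exclude
    feeding-region features from feeding libraries, or to anchor on a
    stable feature set when a genome-wide shift is expected). Dispersion is
    the moderated within-group estimate and the Wald statistic is referred
    to a t distribution with the residual degrees of freedom, which keeps
    the false-positive rate controlled at 2-3 replicates.
    """
    meta_ix = meta.set_index("library_id") if "library_id" in meta.columns else meta
    labels = meta_ix.loc[list(counts.columns), "condition"]
    libs = labels[(labels == test_group) | (labels == reference_group)].index
    sub = counts[list(libs)]
    sub_labels = labels.loc[libs]
    sf_input = sub if size_factor_features is None else sub.loc[size_factor_features]
    sf = size_factors_median_of_ratios(sf_input)
    try:
        disp, resid_df = moderated_within_group_dispersion(sub, sf, sub_labels)
    except ValueError:
        disp, resid_df = estimate_dispersion(sub, sf), max(len(libs) - 2, 1)
    res = nb_wald_test(sub, sf, disp, labels, test_group, reference_group)
    tested = res["stat"].notna()
    res.loc[tested, "pvalue"] = 2.0 * stats.t.sf(
        np.abs(res.loc[tested, "stat"]), resid_df
    )
    res["padj"] = bh_adjust(res["pvalue"])
    res["significant"] = res["padj"] < alpha_threshold
    return res


def de_set_intersections(significant_sets: dict[str, set], universe: set) -> dict:
    """Exclusive-membership (UpSet-style) intersection counts.

    ``significant_sets`` maps a contrast name to its significant feature
    set; every set must be a subset of ``universe``. The result maps a
    tuple of member set names (sorted) to the number of features belonging
    to exactly those sets; features in no set are omitted.
    """
    for name, s in significant_sets.items():
        extra = s - universe
        if extra:
            raise ValueError(
                f"set {name!r} contains features outside the universe: "
                f"{sorted(extra)[:5]}"
            )
    names = sorted(significant_sets)
    regions: dict[tuple[str, ...], int] = {}
    for feature in universe:
        members = tuple(n for n in names if feature in significant_sets[n])
        if members:
            regions[members] = regions.get(members, 0) + 1
    return regions
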