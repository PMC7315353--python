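"""Expression summaries: TPM, knockdown efficiency, group comparisons,
phased/unphased fold-change dissection, and library clustering.

mRNA abundance is reported in transcripts per million (TPM) on gene-level
counts. When quantifying a knocked-down gene in its own feeding condition,
the feeding-associated region (padded by 100 bp on both sides to absorb
alignment edge effects) is excluded from the transcript, so that the
massive primary-siRNA-covered segment does not distort the estimate; TPM
then uses the effective (remaining) length.

All rank comparisons are unpaired two-sided Wilcoxon rank-sum tests: exact
enumeration for small tie-free samples, normal approximation with tie
correction otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript with optional excluded segments (transcript coordinates,
    0-based half-open)."""

    gene_id: str
    length: int
    excluded: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("transcript length must be >= 1")
        for a, b in self.excluded:
            if not 0 <= a < b <= self.length:
                raise ValueError(f"excluded interval ({a}, {b}) outside transcript")

    @property
    def effective_length(self) -> int:
        """Transcript length minus excluded bases (intervals merged), floor 1."""
        if not self.excluded:
            return self.length
        ivs = sorted(self.excluded)
        merged = [list(ivs[0])]
        for a, b in ivs[1:]:
            if a <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], b)
            else:
                merged.append([a, b])
        removed = sum(b - a for a, b in merged)
        return max(1, self.length - removed)


def exclude_feeding_region(
    model: TranscriptModel, feeding_start: int, feeding_end: int, pad: int = 100
) -> TranscriptModel:
    """Exclude the feeding span (transcript coordinates) plus ``pad`` bp on
    each side, clipped to the transcript.

    Idempotent: re-excluding the same span changes nothing. If the exclusion
    covers the whole transcript the effective length is floored at 1 with a
    warning.
    """
    if not 0 <= feeding_start < feeding_end <= model.length:
        raise ValueError(
            f"feeding span ({feeding_start}, {feeding_end}) does not map into "
            f"transcript {model.gene_id} of length {model.length}"
        )
    a = max(0, feeding_start - pad)
    b = min(model.length, feeding_end + pad)
    new = replace(model, excluded=tuple(sorted(set(model.excluded) | {(a, b)})))
    if new.effective_length == 1 and new.length > 1:
        warnings.warn(
            f"exclusion covers transcript {model.gene_id} almost entirely; "
            "effective length floored at 1",
            stacklevel=2,
        )
    return new


def compute_tpm(counts: pd.Series, effective_lengths: pd.Series) -> pd.Series:
    """Transcripts per million from gene counts and effective lengths."""
    lengths = effective_lengths.loc[counts.index].astype(float)
    if (lengths < 1).any():
        raise ValueError("effective lengths must be >= 1")
    rate = counts.astype(float) / lengths
    total = rate.sum()
    if total == 0:
        warnings.warn("all counts zero; TPM undefined, returning zeros", stacklevel=2)
        return rate * 0.0
    return rate / total * 1e6


def tpm_matrix(
    counts: pd.DataFrame, effective_lengths: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Per-library TPM; ``effective_lengths`` may vary by library (a frame
    with one column per library) or be shared (a series)."""
    cols = {}
    for lib in counts.columns:
        lens = (
            effective_lengths[lib]
            if isinstance(effective_lengths, pd.DataFrame)
            else effective_lengths
        )
        cols[lib] = compute_tpm(counts[lib], lens)
    return pd.DataFrame(cols)


def knockdown_efficiency(tpm_kd: float, tpm_wt: float) -> tuple[float, float]:
    """(fold change, reduction) of a target gene; NA when the WT TPM is 0."""
    if tpm_wt == 0:
        return float("nan"), float("nan")
    fc = tpm_kd / tpm_wt
    return fc, 1.0 - fc


def wilcoxon_compare(group_a, group_b) -> float:
    """Two-sided unpaired rank-sum p-value.

    Exact enumeration when the pooled sample has at most 25 observations
    and no ties; normal approximation with tie correction otherwise.
    Constant pooled data yields p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 25 and no_ties) else "asymptotic"
    return float(
        sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def log2_fold_changes(
    values_kd: pd.Series, values_wt: pd.Series, pseudocount: float = 1.0
) -> pd.Series:
    """Per-feature log2((kd + c) / (wt + c)) on normalized values."""
    kd = values_kd.astype(float) + pseudocount
    wt = values_wt.loc[values_kd.index].astype(float) + pseudocount
    return np.log2(kd / wt)


def fold_change_by_phasing(
    values_kd: pd.Series,
    values_wt: pd.Series,
    phased: pd.Series,
    pseudocount: float = 1.0,
) -> dict:
    """Dissect per-locus log2 fold changes into phased vs unphased groups.

    ``phased`` is a boolean series labelling every locus. Returns the two
    fold-change vectors, their medians, and the two-sided rank-sum p-value
    between the groups (NA if a group is empty).
    """
    missing = values_kd.index.difference(phased.index)
    if len(missing):
        raise ValueError(f"phasing label missing for loci: {list(missing[:5])}")
    lfc = log2_fold_changes(values_kd, values_wt, pseudocount)
    is_phased = phased.loc[lfc.index].astype(bool)
    grp_p = lfc[is_phased]
    grp_u = lfc[~is_phased]
    p = (
        wilcoxon_compare(grp_p, grp_u)
        if len(grp_p) and len(grp_u)
        else float("nan")
    )
    return {
        "phased": grp_p,
        "unphased": grp_u,
        "median_phased": float(grp_p.median()) if len(grp_p) else float("nan"),
        "median_unphased": float(grp_u.median()) if len(grp_u) else float("nan"),
        "pvalue": p,
    }


def condition_means(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns per condition (replicate merging)."""
    meta_ix = meta.set_index("library_id") if "library_id" in meta.columns else meta
    cond = meta_ix.loc[list(matrix.columns), "condition"]
    return matrix.T.groupby(cond).mean().T


def hierarchical_clustering(matrix: pd.DataFrame):
    """Complete-linkage clustering of library columns on Euclidean distance.

    Columns are sorted lexicographically first so the result is
    deterministic regardless of input order. Returns (linkage matrix,
    leaf labels in the sorted order).
    """
    if matrix.shape[1] < 2:
        raise ValueError("clustering needs at least 2 libraries")
    if matrix.isna().any().any():
        raise ValueError("matrix contains NaN cells")
    ordered = matrix[sorted(matrix.columns)]
    z = hierarchy.linkage(pdist(ordered.T.to_numpy()), method="complete")
    return z, list(ordered.columns)


def clades(linkage: np.ndarray, labels: list[str]) -> list[frozenset]:
    """Leaf sets of every internal node of a linkage tree."""
    tree = hierarchy.to_tree(linkage)
    out: list[frozenset] = []

    def walk(node):
        if node.is_leaf():
            return frozenset([labels[node.id]])
        leaves = walk(node.left) | walk(node.right)
        out.append(leaves)
        return leaves

    walk(tree)
    return out


def forms_exclusive_clade(
    linkage: np.ndarray, labels: list[str], members: set[str]
) -> bool:
    """True if ``members`` appear as exactly one internal node's leaf set."""
    target = frozenset(members)
    return target in clades(linkage, labels)


def to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Render a linkage tree as a Newick string with merge-height branch
    lengths."""
    tree = hierarchy.to_tree(linkage)

    def walk(node, parent_height: float) -> str:
        bl = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{bl:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{bl:.6g}"

    return walk(tree, tree.dist) + ";"
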