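"""Presence calling, specificity classes, UExp sets and profile summaries.

A polypeptide is *detected* in a context (tissue, cell line, cohort) when it
has a non-missing abundance in at least one sample of that context.  Over a
panel of contexts this yields a boolean presence matrix, from which each
polypeptide is labelled context-specific (exactly one context), shared
(more than one but not all), or ubiquitous (all contexts).  Polypeptides
ubiquitous in both the tissue and the cell-line panel are universally
expressed (UExp).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .evidence_io import SampleAnnotation


@dataclass(frozen=True)
class SpecificityCall:
    group_id: str
    n_contexts_detected: int
    label: str  # specific | shared | ubiquitous
    uexp: bool = False


def detect_presence(
    abundance: pd.DataFrame,
    annotation: list[SampleAnnotation],
    min_samples: int = 1,
) -> pd.DataFrame:
    """Boolean group-by-context detection matrix.

    A group counts as detected in a context when it is quantified in at
    least ``min_samples`` samples of that context.
    """
    by_context: dict[str, list[str]] = {}
    for a in annotation:
        if a.sample_id in abundance.columns:
            by_context.setdefault(a.context, []).append(a.sample_id)
    for ctx, samples in by_context.items():
        if not samples:
            raise ValueError(f"context {ctx!r} has no samples")
    if not by_context:
        raise ValueError("no annotated samples present in the abundance matrix")
    presence = pd.DataFrame(
        {
            ctx: abundance[samples].notna().sum(axis=1) >= min_samples
            for ctx, samples in by_context.items()
        }
    )
    presence.index.name = "group_id"
    return presence


def classify_specificity(presence: pd.DataFrame) -> list[SpecificityCall]:
    """Label every group specific / shared / ubiquitous from its presence row."""
    n_contexts = presence.shape[1]
    if n_contexts < 1:
        raise ValueError("need at least one context")
    calls = []
    for gid, row in presence.iterrows():
        n = int(row.sum())
        if n == n_contexts:
            label = "ubiquitous"
        elif n == 1:
            label = "specific"
        else:
            label = "shared"
        calls.append(SpecificityCall(group_id=gid, n_contexts_detected=n, label=label))
    return calls


def specificity_counts(calls: list[SpecificityCall]) -> dict[str, int]:
    out = {"specific": 0, "shared": 0, "ubiquitous": 0}
    for c in calls:
        out[c.label] += 1
    return out


def ubiquitous_set(calls: list[SpecificityCall]) -> set[str]:
    return {c.group_id for c in calls if c.label == "ubiquitous"}


def universal_expressed(
    tissue_ubiquitous: set[str], cellline_ubiquitous: set[str]
) -> set[str]:
    """UExp polypeptides: ubiquitous in both the tissue and cell-line panels."""
    return set(tissue_ubiquitous) & set(cellline_ubiquitous)


def fraction_of_proteome(n_lnc_polypeptides: int, n_proteins: int) -> float:
    """lncRNA-peptidome size as a fraction of the quantified proteome."""
    if n_proteins <= 0:
        raise ValueError("n_proteins must be positive")
    return n_lnc_polypeptides / n_proteins


def zscore_log2(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score of log2 intensities over non-missing cells.

    Rows with zero variance become all-zero with a warning; missing cells
    stay missing.
    """
    log2 = np.log2(matrix)
    mean = log2.mean(axis=1, skipna=True)
    sd = log2.std(axis=1, ddof=1, skipna=True)
    degenerate = (sd == 0) | sd.isna()
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant row(s) z-scored to zeros",
            stacklevel=2,
        )
    safe_sd = sd.mask(degenerate, 1.0)
    out = log2.sub(mean, axis=0).div(safe_sd, axis=0)
    if degenerate.any():
        sub = log2.loc[degenerate]
        out.loc[degenerate] = sub.where(sub.isna(), 0.0)
    return out


def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Spearman or Pearson correlation with pairwise-complete deletion.

    p-value from the t-transform with n-2 df; NaN below three complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        return math.nan, math.nan
    if method == "spearman":
        r, p = sps.spearmanr(x, y)
    elif method == "pearson":
        r, p = sps.pearsonr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def impute_row_min(matrix: pd.DataFrame) -> pd.DataFrame:
    """Replace missing cells with the row minimum (low-abundance semantics)."""
    return matrix.apply(lambda row: row.fillna(row.min()), axis=1)


def hcluster(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "average",
    axis: str = "rows",
) -> dict:
    """Agglomerative clustering of rows or columns.

    Missing cells must be imputed first (see :func:`impute_row_min`).
    Returns the linkage matrix, ordered leaf labels and a newick string.
    ``distance='correlation'`` uses 1 - Pearson r.
    """
    data = matrix if axis == "rows" else matrix.T
    if data.shape[0] < 2:
        raise ValueError("need at least two items to cluster")
    if data.isna().any().any():
        raise ValueError("missing cells: impute before clustering")
    if distance not in ("euclidean", "correlation"):
        raise ValueError(f"unknown distance {distance!r}")
    if linkage not in ("average", "complete"):
        raise ValueError(f"unknown linkage {linkage!r}")
    d = pdist(data.to_numpy(dtype=float), metric=distance)
    z = hierarchy.linkage(d, method=linkage)
    leaves = hierarchy.leaves_list(z)
    labels = [str(data.index[i]) for i in leaves]
    tree = hierarchy.to_tree(z)

    def newick(node) -> str:
        if node.is_leaf():
            return str(data.index[node.id])
        return f"({newick(node.left)},{newick(node.right)})"

    return {"linkage": z, "leaf_order": labels, "newick": newick(tree) + ";"}


def plasma_rank(
    candidate_ids: list[str], plasma_abundance: pd.Series
) -> pd.DataFrame:
    """Rank candidates within a plasma abundance profile.

    Rank 1 is the most abundant entry; ties share the average rank.  The
    percentile is the rank expressed as a fraction of the profile size
    (from the top).  Absent candidates are reported unranked (NaN).
    """
    profile = plasma_abundance.dropna()
    ranks = pd.Series(
        sps.rankdata(-profile.to_numpy(), method="average"), index=profile.index
    )
    n = len(profile)
    rows = []
    for cid in candidate_ids:
        if cid in ranks.index:
            r = float(ranks[cid])
            rows.append({"group_id": cid, "rank": r, "percentile": 100.0 * r / n})
        else:
            rows.append({"group_id": cid, "rank": math.nan, "percentile": math.nan})
    return pd.DataFrame(rows).set_index("group_id")
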