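"""Metabolomics significance filtering, overlap counts and clustering.

Downstream of the per-comparison statistics: combine p/q/fold-change/
annotation-level criteria into feature sets (all strict inequalities),
count Venn overlaps between comparisons, and hierarchically cluster the
final significant metabolites with Pearson distance (1 - r) and average
(UPGMA) linkage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, leaves_list, linkage
from scipy.spatial.distance import pdist

from .io_tables import AbundanceMatrix, MetaboliteTable, ValidationError


@dataclass
class SignificanceFilter:
    """Conjunction of optional criteria; ``None`` disables a criterion.

    ``min_abs_log2fc`` filters on |log2fc| when ``two_sided`` (the default,
    both increased and decreased metabolites) or on signed log2fc otherwise.
    ``levels`` restricts to a set of annotation confidence levels.
    """

    p_max: float | None = None
    q_max: float | None = None
    min_abs_log2fc: float | None = None
    levels: frozenset[str] | None = None
    two_sided: bool = True

    def __post_init__(self) -> None:
        if (
            self.p_max is None
            and self.q_max is None
            and self.min_abs_log2fc is None
            and self.levels is None
        ):
            raise ValidationError("SignificanceFilter needs at least one criterion")
        if self.levels is not None:
            self.levels = frozenset(self.levels)


def significant_metabolites(
    res: pd.DataFrame,
    table: MetaboliteTable | None,
    filt: SignificanceFilter,
) -> set[str]:
    """Features of ``res`` satisfying every active criterion (strictly)."""
    mask = np.ones(len(res), dtype=bool)
    if filt.p_max is not None:
        mask &= res["p"].to_numpy() < filt.p_max
    if filt.q_max is not None:
        mask &= res["q"].to_numpy() < filt.q_max
    if filt.min_abs_log2fc is not None:
        fc = res["log2fc"].to_numpy()
        fc = np.abs(fc) if filt.two_sided else fc
        mask &= fc > filt.min_abs_log2fc
    selected = set(res.loc[mask, "feature_id"])
    if filt.levels is not None:
        if table is None:
            raise ValidationError("annotation-level filter needs a MetaboliteTable")
        lv = table.annotations["annotation_level"]
        allowed = set(lv.index[lv.isin(filt.levels)])
        selected &= allowed
    return selected


def overlap_counts(set_a: set, set_b: set) -> tuple[int, int, int]:
    """Venn cardinalities: (|A|, |B|, |A & B|)."""
    return len(set_a), len(set_b), len(set_a & set_b)


def zscore_rows(m: AbundanceMatrix) -> AbundanceMatrix:
    """Center each row to mean 0 and scale to sd 1 over non-missing entries.

    Display convention for heatmaps.  A zero-variance row is an error.
    """
    if m.scale != "log2":
        raise ValidationError("zscore_rows expects a log2-scale matrix")
    vals = m.data.to_numpy(copy=True)
    n = (~np.isnan(vals)).sum(axis=1)
    if np.any(n < 2):
        bad = m.data.index[n < 2].tolist()
        raise ValidationError(f"row(s) with < 2 non-missing values: {bad}")
    mean = np.nanmean(vals, axis=1, keepdims=True)
    sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        bad = m.data.index[(sd == 0).ravel()].tolist()
        raise ValidationError(f"zero-variance row(s): {bad}")
    out = (vals - mean) / sd
    return AbundanceMatrix(
        pd.DataFrame(out, index=m.data.index, columns=m.data.columns),
        scale="log2",
    )


@dataclass
class ClusterResult:
    """Average-linkage tree over Pearson distances.

    ``merges`` is the scipy-style linkage matrix: each row (i, j, height,
    size) joins clusters i and j (indices >= n refer to earlier merges).
    """

    labels: list[str]
    merges: np.ndarray
    leaf_order: list[str]
    distance: str = "pearson"
    linkage_method: str = "average"

    def cophenetic_matrix(self) -> np.ndarray:
        """Condensed matrix of heights at which each pair first joins."""
        return cophenet(self.merges)

    def to_newick(self) -> str:
        """Serialize the merge tree as a Newick string with branch lengths."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: self.labels[i] for i in range(n)}
        for k, (i, j, h, _) in enumerate(self.merges):
            i, j = int(i), int(j)
            bi = h - heights[i]
            bj = h - heights[j]
            nodes[n + k] = f"({nodes[i]}:{bi:g},{nodes[j]}:{bj:g})"
            heights[n + k] = h
        root = n + len(self.merges) - 1 if len(self.merges) else 0
        return nodes[root] + ";"


def pearson_average_linkage(
    m: AbundanceMatrix, axis: str = "features"
) -> ClusterResult:
    """UPGMA tree on d = 1 - Pearson r between rows (or columns).

    Vectors must be complete (no missing values) and have nonzero variance.
    scipy's agglomeration is deterministic; exact ties are resolved by its
    fixed scan order.
    """
    if axis == "features":
        X = m.data.to_numpy()
        labels = m.feature_ids
    elif axis == "samples":
        X = m.data.to_numpy().T
        labels = m.sample_ids
    else:
        raise ValidationError(f"unknown axis {axis!r}")
    if X.shape[0] < 2:
        raise ValidationError("clustering needs >= 2 vectors")
    if np.isnan(X).any():
        raise ValidationError("clustering requires complete data (no missing)")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = [labels[i] for i in np.nonzero(sd == 0)[0]]
        raise ValidationError(f"zero-variance vector(s): {bad}")
    d = pdist(X, metric="correlation")  # 1 - Pearson r
    d = np.clip(d, 0.0, None)  # guard tiny negative rounding
    Z = linkage(d, method="average")
    order = [labels[i] for i in leaves_list(Z)]
    return ClusterResult(labels=list(labels), merges=Z, leaf_order=order)
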