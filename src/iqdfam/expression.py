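"""Relative qPCR expression via the Livak 2^-ddCt method, plus clustering.

Replicate Ct values are averaged per (gene, condition); dCt subtracts the
reference gene, ddCt subtracts the control condition, and the fold change
is 2^-ddCt, so the control column is exactly 1 for every gene.  Gene rows
(log2 fold) are ordered for heatmap display by average-linkage hierarchical
clustering on Euclidean distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .io import IqdfamError

CT_COLUMNS = ["gene", "condition", "replicate", "ct"]


@dataclass
class CtTable:
    """Long-format Ct table with a named reference gene and control condition."""

    data: pd.DataFrame
    reference_gene: str
    control_condition: str

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise IqdfamError(f"Ct table missing columns: {missing}")
        if self.reference_gene not in set(self.data["gene"]):
            raise IqdfamError(f"reference gene {self.reference_gene!r} absent from table")
        if self.control_condition not in set(self.data["condition"]):
            raise IqdfamError(
                f"control condition {self.control_condition!r} absent from table"
            )


def read_ct_table(path, reference_gene: str, control_condition: str) -> CtTable:
    return CtTable(pd.read_csv(path, sep="\t"), reference_gene, control_condition)


def aggregate_ct(table: CtTable) -> pd.DataFrame:
    """Mean Ct (and SD, replicate count) per (gene, condition).

    Every gene must be measured in every condition; missing cells are an
    error naming the (gene, condition) pairs.
    """
    agg = (
        table.data.groupby(["gene", "condition"])["ct"]
        .agg(mean_ct="mean", sd_ct="std", n="count")
        .reset_index()
    )
    agg["sd_ct"] = agg["sd_ct"].fillna(0.0)
    genes = sorted(set(table.data["gene"]))
    conditions = sorted(set(table.data["condition"]))
    have = set(zip(agg["gene"], agg["condition"]))
    missing = [(g, c) for g in genes for c in conditions if (g, c) not in have]
    if missing:
        raise IqdfamError(f"missing Ct cells: {missing}")
    return agg


@dataclass
class ExpressionMatrix:
    fold: pd.DataFrame        # genes x conditions, control column == 1
    log2fold: pd.DataFrame
    reference_gene: str
    control_condition: str


def relative_expression(table: CtTable) -> ExpressionMatrix:
    """2^-ddCt fold changes against the reference gene and control condition."""
    agg = aggregate_ct(table)
    mean = agg.pivot(index="gene", columns="condition", values="mean_ct")
    ref = mean.loc[table.reference_gene]
    dct = mean.subtract(ref, axis=1)
    ddct = dct.subtract(dct[table.control_condition], axis=0)
    fold = np.power(2.0, -ddct)
    fold = fold.drop(index=table.reference_gene)
    log2fold = -ddct.drop(index=table.reference_gene)
    return ExpressionMatrix(
        fold=fold, log2fold=log2fold,
        reference_gene=table.reference_gene,
        control_condition=table.control_condition,
    )


def classify_response(
    matrix: ExpressionMatrix, threshold_fold: float = 2.0
) -> dict[str, str]:
    """Per-gene label over the non-control conditions.

    up if any fold >= threshold and none <= 1/threshold; down mirrored;
    both present -> mixed; neither -> flat.
    """
    if threshold_fold <= 1:
        raise IqdfamError("threshold_fold must exceed 1")
    cols = [c for c in matrix.fold.columns if c != matrix.control_condition]
    if not cols:
        raise IqdfamError("no non-control conditions")
    out: dict[str, str] = {}
    for gene, row in matrix.fold[cols].iterrows():
        up = bool((row >= threshold_fold).any())
        down = bool((row <= 1.0 / threshold_fold).any())
        out[gene] = (
            "mixed" if up and down else "upregulated" if up
            else "downregulated" if down else "flat"
        )
    return out


@dataclass
class Dendrogram:
    linkage: np.ndarray
    leaf_order: list[str]
    heights: list[float] = field(default_factory=list)


def cluster_heatmap(matrix: ExpressionMatrix) -> tuple[Dendrogram, pd.DataFrame]:
    """Average-linkage clustering of log2-fold gene rows for heatmap order.

    Rows are pre-sorted by gene label so equal-distance merges break ties
    deterministically; a constant matrix degenerates to all-zero heights.
    """
    log2 = matrix.log2fold.sort_index()
    if log2.shape[0] < 2:
        raise IqdfamError("need at least 2 genes to cluster")
    dists = pdist(log2.to_numpy(), metric="euclidean")
    Z = average(dists)
    order = [log2.index[i] for i in leaves_list(Z)]
    dend = Dendrogram(linkage=Z, leaf_order=order, heights=[float(h) for h in Z[:, 2]])
    return dend, log2.loc[order]
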