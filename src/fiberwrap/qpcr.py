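"""Relative copy numbers and cluster differentiation indices from qPCR Cq tables.

Expression of a target gene is reported as the relative copy number

    RCN = 2^(-ΔCq) × 100,   ΔCq = Cq(target) - Cq(reference),

where the reference is the median Cq of four endogenous control genes
measured in the same sample (replicate Cq values are averaged first).  For
time-course experiments each gene's RCN at time t is normalized to its
baseline RCN (cells before transfer onto the scaffold, t = 0) as a percent
change, then averaged across the genes of a cluster to give a differentiation
index with its SD.  Two gene clusters are compared per timepoint with a
Welch (unequal-variance) two-sample t-test.

The default 21-gene panel groups ten endothelial-function genes as Cluster 1,
ten endothelial-indifferent/primitive genes as Cluster 2, MKI67 as the
proliferation marker, and four housekeeping genes as endogenous controls.
Any other panel can be supplied as a gene → group mapping.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "QpcrTable",
    "DEFAULT_CLUSTER_MAP",
    "reference_cq",
    "compute_rcn",
    "rcn_table",
    "cluster_index",
    "intercluster_test",
]

CLUSTER1 = "CLUSTER1"
CLUSTER2 = "CLUSTER2"
PROLIFERATION = "PROLIFERATION"
CONTROL = "CONTROL"

# 21-gene endothelial differentiation panel; Cluster 1 = endothelial
# function-relevant genes (defined by expression covariation), Cluster 2 =
# the remaining primitive / endothelial-indifferent genes.
DEFAULT_CLUSTER_MAP: dict[str, str] = {
    **{g: CLUSTER1 for g in
       ("CD31", "CAV3", "CDH5", "CNN1", "FSHR", "KDR", "NES", "NOS3", "TEK", "VWF")},
    **{g: CLUSTER2 for g in
       ("ABCG2", "CD117", "CD133", "CD34", "GATA4", "NKX2-5", "POU5F1",
        "ACTA2", "ALPL", "COL1A1")},
    "MKI67": PROLIFERATION,
    **{g: CONTROL for g in ("B2M", "CAP1", "GAPDH", "RPL13")},
}


@dataclasses.dataclass
class QpcrTable:
    """Long-format Cq measurements plus a gene → cluster map.

    ``data`` columns: ``sample_id``, ``timepoint`` (days), ``gene``, ``cq``
    — one row per replicate well.  Every Cq must lie in (0, 45) and every
    non-control gene must belong to exactly one cluster.
    """

    data: pd.DataFrame
    cluster_map: Mapping[str, str] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_MAP)
    )

    REQUIRED = ("sample_id", "timepoint", "gene", "cq")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        cq = self.data["cq"]
        if not ((cq > 0) & (cq < 45)).all():
            raise ValueError("Cq values must be in (0, 45)")
        unmapped = set(self.data["gene"]) - set(self.cluster_map)
        if unmapped:
            raise ValueError(f"genes without cluster assignment: {sorted(unmapped)}")

    @classmethod
    def from_csv(cls, path: str | Path,
                 cluster_map: Mapping[str, str] | None = None) -> "QpcrTable":
        df = pd.read_csv(path)
        return cls(df, cluster_map or dict(DEFAULT_CLUSTER_MAP))

    def genes(self, cluster: str) -> list[str]:
        return sorted(g for g, c in self.cluster_map.items() if c == cluster)

    def replicate_means(self) -> pd.DataFrame:
        """Replicate-averaged Cq per (sample, timepoint, gene)."""
        return (self.data
                .groupby(["sample_id", "timepoint", "gene"], as_index=False)["cq"]
                .mean())


def reference_cq(table: QpcrTable, sample_id: str) -> float:
    """Median of the endogenous controls' replicate-averaged Cq in one sample."""
    means = table.replicate_means()
    rows = means[(means["sample_id"] == sample_id)
                 & means["gene"].map(table.cluster_map.get).eq(CONTROL)]
    if rows.empty:
        raise InsufficientDataError(f"no control genes measured in sample {sample_id!r}")
    return float(rows["cq"].median())


def compute_rcn(cq_target: float, cq_reference: float) -> float:
    """RCN = 2^-(Cq_target - Cq_reference) × 100; strictly positive."""
    if not (np.isfinite(cq_target) and np.isfinite(cq_reference)):
        raise ValueError("Cq values must be finite")
    return float(2.0 ** -(cq_target - cq_reference) * 100.0)


def rcn_table(table: QpcrTable) -> pd.DataFrame:
    """RCN per (sample, timepoint, gene) for all non-control genes."""
    means = table.replicate_means()
    refs = {s: reference_cq(table, s) for s in means["sample_id"].unique()}
    rows = means[~means["gene"].map(table.cluster_map.get).eq(CONTROL)].copy()
    rows["rcn"] = [
        compute_rcn(cq, refs[s]) for s, cq in zip(rows["sample_id"], rows["cq"])
    ]
    return rows[["sample_id", "timepoint", "gene", "rcn"]]


def cluster_index(
    table: QpcrTable,
    cluster: str,
    baseline_timepoint: float = 0.0,
) -> pd.DataFrame:
    """Per-timepoint differentiation index of a gene cluster.

    For each gene, percent change = 100 · RCN(t) / RCN(baseline); the index
    is the mean ± SD of these percent changes across the cluster's genes
    (per-gene normalization first, then averaging).  Genes missing at
    baseline are excluded with a warning.  Returns columns ``timepoint``,
    ``mean_pct``, ``sd_pct``, ``n_genes``.
    """
    rcn = rcn_table(table)
    rcn = rcn[rcn["gene"].map(table.cluster_map.get).eq(cluster)]
    if rcn.empty:
        raise InsufficientDataError(f"no measurements for cluster {cluster!r}")
    # average RCN over samples at the same timepoint
    per_tp = rcn.groupby(["timepoint", "gene"], as_index=False)["rcn"].mean()
    base = per_tp[per_tp["timepoint"] == baseline_timepoint].set_index("gene")["rcn"]
    measured = set(per_tp["gene"])
    dropped = sorted(measured - set(base.index))
    if dropped:
        warnings.warn(f"genes missing at baseline excluded: {dropped}")
        per_tp = per_tp[~per_tp["gene"].isin(dropped)]
    if per_tp.empty:
        raise InsufficientDataError("no genes with a baseline measurement")
    if (base <= 0).any():
        raise ValueError("baseline RCN must be > 0 for every gene")
    per_tp = per_tp.assign(
        pct=100.0 * per_tp["rcn"] / per_tp["gene"].map(base).to_numpy()
    )
    out = per_tp.groupby("timepoint").agg(
        mean_pct=("pct", "mean"),
        sd_pct=("pct", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0),
        n_genes=("pct", "size"),
    ).reset_index()
    return out


def intercluster_test(
    values1: Sequence[float], values2: Sequence[float]
) -> tuple[float, float]:
    """Welch two-sample t-test (two-sided) between per-gene cluster values."""
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >= 2 values per cluster")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
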