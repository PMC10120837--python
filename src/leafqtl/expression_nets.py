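"""Expression clustering, thresholded co-expression network, and qPCR fold change.

Clustering operates on log2(FPKM + 1) rows standardized per gene (z-score), so
genes cluster by tissue profile rather than absolute abundance; the dendrogram
is agglomerative with average linkage and Euclidean distance and is cut to a
requested number of clusters. The co-expression network keeps gene pairs with
|r| >= 0.95 and p < 0.001 by default — a deliberately strict conjunction: with
only five or six tissue samples the p-value condition dominates the
correlation floor. Relative expression from qPCR uses the 2^-ΔΔCt method
against a reference gene and a calibrator sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy as sch

from .core_io import ExpressionMatrix, NetworkEdge, ValidationError, get_logger

__all__ = [
    "ClusterAssignment",
    "DdctInput",
    "cluster_expression",
    "coexpression_network",
    "ddct_fold_change",
    "plot_heatmap",
]


@dataclass
class ClusterAssignment:
    """Gene-to-cluster labels plus the clustering configuration that made them."""

    labels: dict[str, str]
    linkage_method: str
    distance_metric: str
    k: int
    leaf_order: list[str] = field(default_factory=list)

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, name="cluster")


def _transform(fpkm: pd.DataFrame) -> pd.DataFrame:
    """log2(FPKM+1) then per-gene z-score; constant genes map to all-zero rows."""
    logx = np.log2(fpkm + 1.0)
    mu = logx.mean(axis=1)
    sd = logx.std(axis=1, ddof=0)
    z = logx.sub(mu, axis=0).div(sd.replace(0.0, 1.0), axis=0)
    return z


def cluster_expression(
    expr: ExpressionMatrix,
    k: int = 3,
    linkage_method: str = "average",
    distance_metric: str = "euclidean",
) -> ClusterAssignment:
    """Hierarchical clustering of transformed expression rows, cut to k clusters.

    Genes are processed in lexicographic id order so ties break
    deterministically (lowest gene id first). Cluster labels C1, C2, ... are
    assigned in order of first appearance along the sorted gene list.
    """
    genes = sorted(expr.genes)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k > len(genes):
        raise ValidationError(f"k = {k} exceeds the number of genes ({len(genes)})")
    if len(expr.samples) < 2:
        raise ValidationError("need >= 2 samples to cluster expression profiles")
    z = _transform(expr.fpkm.loc[genes])
    if k == 1:
        return ClusterAssignment({g: "C1" for g in genes}, linkage_method, distance_metric, 1, genes)
    link = sch.linkage(z.to_numpy(), method=linkage_method, metric=distance_metric)
    flat = sch.fcluster(link, t=k, criterion="maxclust")
    relabel: dict[int, str] = {}
    labels: dict[str, str] = {}
    for g, c in zip(genes, flat):
        if c not in relabel:
            relabel[c] = f"C{len(relabel) + 1}"
        labels[g] = relabel[c]
    leaf_order = [genes[i] for i in sch.leaves_list(link)]
    return ClusterAssignment(labels, linkage_method, distance_metric, k, leaf_order)


def coexpression_network(
    expr: ExpressionMatrix,
    r_min: float = 0.95,
    p_max: float = 0.001,
    top_hubs: int = 10,
) -> tuple[list[NetworkEdge], pd.DataFrame]:
    """Thresholded Pearson co-expression network across tissue samples.

    Edges require |r| >= ``r_min`` AND p < ``p_max`` (two-sided t transform
    with n−2 degrees of freedom). Genes with constant expression are skipped
    with a warning. Returns the edge list and a hub table of node degrees,
    sorted by decreasing degree (gene id breaks ties).
    """
    x = expr.fpkm.to_numpy(dtype=float)
    genes = expr.genes
    n = x.shape[1]
    if n < 4:
        raise ValidationError(f"need >= 4 samples, got {n}")
    sd = x.std(axis=1)
    constant = sd == 0.0
    if constant.any():
        skipped = [g for g, c in zip(genes, constant) if c]
        warnings.warn(f"constant-expression gene(s) skipped: {skipped[:5]}")
        get_logger().warning("coexpression_network: %d constant gene(s) skipped", len(skipped))
    keep_idx = np.flatnonzero(~constant)
    r = np.corrcoef(x[keep_idx])
    if r.ndim == 0:  # single gene
        r = np.atleast_2d(r)
    np.clip(r, -1.0, 1.0, out=r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)

    edges: list[NetworkEdge] = []
    for ii, jj in combinations(range(len(keep_idx)), 2):
        if abs(r[ii, jj]) >= r_min and p[ii, jj] < p_max:
            a, b = genes[keep_idx[ii]], genes[keep_idx[jj]]
            edges.append(NetworkEdge(*sorted((a, b)), r=float(r[ii, jj]), p=float(p[ii, jj])))
    degree: dict[str, int] = {}
    for e in edges:
        degree[e.node_a] = degree.get(e.node_a, 0) + 1
        degree[e.node_b] = degree.get(e.node_b, 0) + 1
    hubs = pd.DataFrame(sorted(degree.items(), key=lambda kv: (-kv[1], kv[0])),
                        columns=["gene", "degree"]).head(top_hubs)
    return edges, hubs


@dataclass
class DdctInput:
    """qPCR cycle thresholds per sample for one target and one reference gene.

    ``samples`` is indexed by sample id with columns ``ct_target`` and
    ``ct_reference``; ``calibrator`` names the baseline sample.
    """

    samples: pd.DataFrame
    calibrator: str

    def __post_init__(self) -> None:
        required = {"ct_target", "ct_reference"}
        missing = required - set(self.samples.columns)
        if missing:
            raise ValidationError(f"DdctInput missing column(s): {sorted(missing)}")
        if self.calibrator not in self.samples.index:
            raise ValidationError(f"calibrator sample {self.calibrator!r} not present")
        vals = self.samples[list(required)].to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            raise ValidationError("Ct values must be finite (missing reference or target Ct)")


def ddct_fold_change(inputs: DdctInput, sample: str) -> float:
    """Relative expression of ``sample`` vs the calibrator by the 2^-ΔΔCt method.

    ΔCt = Ct_target − Ct_reference per sample; ΔΔCt subtracts the calibrator's
    ΔCt; the fold change is 2^(−ΔΔCt) (1.0 when sample == calibrator).
    """
    if sample not in inputs.samples.index:
        raise ValidationError(f"unknown sample {sample!r}")
    dct = inputs.samples["ct_target"] - inputs.samples["ct_reference"]
    ddct = float(dct.loc[sample] - dct.loc[inputs.calibrator])
    return float(2.0 ** (-ddct))


def plot_heatmap(expr: ExpressionMatrix, assignment: ClusterAssignment, path) -> None:
    """Heat map of transformed expression, rows in dendrogram leaf order."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = assignment.leaf_order or sorted(expr.genes)
    z = _transform(expr.fpkm.loc[order])
    fig, ax = plt.subplots(figsize=(6, max(3, 0.08 * len(order))))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2.5, vmax=2.5)
    ax.set_xticks(range(len(expr.samples)), expr.samples, rotation=45, ha="right", fontsize=8)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="z(log2 FPKM+1)")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
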