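"""Gene-body 5hmC clustering, expression summaries and differentiation dynamics.

Genes are clustered on log2-transformed gene-body 5hmC levels across
cell types with Euclidean distance and complete linkage. A two-stage
protocol is supported: cluster all genes, select the uniformly-high
cluster, then re-cluster it (default k = 6). Cluster expression is
summarised as mean log2 FPKM with a t-based 95 % CI over genes with
FPKM > 1. Differentiation dynamics relate the change in expression
(log2 fold change, with |LFC| >= 2 defining increase/loss) to the
change in gene-body 5hmC between a progenitor and a mature cell type.
A simple joint state classifier labels genes by promoter methylation,
gene-body 5hmC and expression (primed / expressed / repressed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage

from .profiles import SpearmanResult, spearman_perm

__all__ = [
    "GeneBodyMatrix",
    "ClusterAssignment",
    "cluster_genes",
    "select_high_cluster",
    "cluster_expression_summary",
    "delta_analysis",
    "BivalentState",
    "bivalent_state",
]


@dataclass
class GeneBodyMatrix:
    """Genes x cell types matrix of gene-body 5hmC levels."""

    values: pd.DataFrame           # index gene_id, columns cell types
    log2_transformed: bool = False

    @classmethod
    def from_level_tables(cls, tables: dict[str, pd.DataFrame]) -> "GeneBodyMatrix":
        """Combine per-cell-type gene-body level tables (replicates averaged).

        ``tables`` maps cell type -> level table(s); a list means
        biological replicates whose levels are averaged per gene.
        """
        cols = {}
        for ct, tab in tables.items():
            tabs = tab if isinstance(tab, list) else [tab]
            per = [t.set_index("gene_id")["level"] for t in tabs]
            cols[ct] = pd.concat(per, axis=1).mean(axis=1)
        return cls(pd.DataFrame(cols))

    def log2(self) -> "GeneBodyMatrix":
        """log2(x+1); missing levels are imputed as 0 first."""
        if self.log2_transformed:
            return self
        vals = self.values.fillna(0.0)
        if (vals.to_numpy() < 0).any():
            raise ValueError("negative 5hmC levels")
        return GeneBodyMatrix(np.log2(vals + 1.0), log2_transformed=True)


@dataclass
class ClusterAssignment:
    labels: pd.Series               # gene_id -> 1..k
    k: int
    method: str = "complete"
    metric: str = "euclidean"

    def members(self, cluster: int) -> pd.Index:
        return self.labels.index[self.labels == cluster]


def cluster_genes(matrix: GeneBodyMatrix, k: int) -> ClusterAssignment:
    """Complete-linkage Euclidean clustering of log2 gene-body 5hmC."""
    m = matrix.log2()
    if k > len(m.values):
        raise ValueError(f"k={k} exceeds {len(m.values)} genes")
    z = linkage(m.values.to_numpy(), method="complete", metric="euclidean")
    labels = fcluster(z, t=k, criterion="maxclust")
    return ClusterAssignment(pd.Series(labels, index=m.values.index, name="cluster"), k=k)


def select_high_cluster(matrix: GeneBodyMatrix, assign: ClusterAssignment) -> int:
    """The cluster with the highest mean log2 level across all cell types."""
    m = matrix.log2().values
    means = m.groupby(assign.labels).mean().mean(axis=1)
    return int(means.idxmax())


def cluster_expression_summary(
    assign: ClusterAssignment,
    expr_tables: dict[str, pd.DataFrame],
    min_fpkm: float = 1.0,
) -> pd.DataFrame:
    """Mean log2 FPKM +/- 95 % CI per cluster and cell type.

    Genes at or below ``min_fpkm`` are excluded per cell type (strict
    FPKM > 1 by default); empty cluster/cell pairs yield NaN rows.
    """
    rows = []
    for ct, expr in expr_tables.items():
        fpkm = expr.set_index("gene_id")["fpkm"]
        for cl in sorted(assign.labels.unique()):
            vals = fpkm.reindex(assign.members(cl)).dropna()
            vals = vals[vals > min_fpkm]
            if len(vals) == 0:
                rows.append((ct, cl, 0, np.nan, np.nan, np.nan))
                continue
            logv = np.log2(vals.to_numpy())
            mean = float(np.mean(logv))
            if len(logv) > 1:
                half = float(stats.t.ppf(0.975, len(logv) - 1) * stats.sem(logv))
            else:
                half = np.nan
            rows.append((ct, cl, len(logv), mean, mean - half, mean + half))
    return pd.DataFrame(rows, columns=["cell_type", "cluster", "n_genes",
                                       "mean_log2_fpkm", "ci_low", "ci_high"])


def delta_analysis(
    expr_prog: pd.DataFrame,
    expr_mat: pd.DataFrame,
    hmc_prog: pd.DataFrame,
    hmc_mat: pd.DataFrame,
    lfc_threshold: float = 2.0,
    strict_both: bool = False,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, SpearmanResult | None]:
    """Per-gene expression vs gene-body 5hmC changes, progenitor -> mature.

    Genes must have FPKM > 1 and gene-body 5hmC > 1 in at least one of
    the two cell types (both, when ``strict_both``). LFC is
    log2(mature/progenitor) FPKM; |LFC| >= ``lfc_threshold`` labels a
    gene increase or loss, else unchanged. Returns the records plus a
    permutation-tested Spearman correlation of delta-5hmC vs LFC (None
    when either vector is constant).
    """
    def _series(df, col):
        return df.set_index("gene_id")[col]

    fp = _series(expr_prog, "fpkm")
    fm = _series(expr_mat, "fpkm")
    hp = _series(hmc_prog, "level")
    hm = _series(hmc_mat, "level")
    genes = fp.index.intersection(fm.index).intersection(hp.index).intersection(hm.index)
    df = pd.DataFrame({
        "fpkm_progenitor": fp.reindex(genes),
        "fpkm_mature": fm.reindex(genes),
        "hmc_progenitor": hp.reindex(genes),
        "hmc_mature": hm.reindex(genes),
    }).dropna()
    comb = np.logical_and if strict_both else np.logical_or
    keep = comb(df["fpkm_progenitor"] > 1, df["fpkm_mature"] > 1) & comb(
        df["hmc_progenitor"] > 1, df["hmc_mature"] > 1)
    df = df[keep]
    if len(df) == 0:
        raise ValueError("no genes pass the FPKM > 1 and 5hmC > 1 filter")
    df["lfc"] = np.log2(df["fpkm_mature"] / df["fpkm_progenitor"])
    df["delta_hmc"] = df["hmc_mature"] - df["hmc_progenitor"]
    df["category"] = np.select(
        [df["lfc"] >= lfc_threshold, df["lfc"] <= -lfc_threshold],
        ["increase", "loss"], default="unchanged")
    rho = None
    if df["lfc"].nunique() > 1 and df["delta_hmc"].nunique() > 1 and len(df) >= 3:
        rho = spearman_perm(df["delta_hmc"].to_numpy(), df["lfc"].to_numpy(),
                            n_perm=n_perm, seed=seed)
    return df.reset_index(names="gene_id"), rho


@dataclass(frozen=True)
class BivalentState:
    gene_id: str
    state: str                     # primed | expressed | repressed | unknown
    meth_percent: float | None
    hmc_level: float | None
    fpkm: float | None
    thresholds: tuple              # (meth_high, hmc_high, fpkm_expressed)


def bivalent_state(
    meth_percent: float | None,
    hmc_level: float | None,
    fpkm: float | None,
    meth_high: float = 50.0,
    hmc_high: float | None = None,
    fpkm_expressed: float = 1.0,
    gene_id: str = "",
) -> BivalentState:
    """Joint promoter-5mC / gene-body-5hmC / expression state of one gene.

    primed: methylated promoter with high gene-body 5hmC (poised for
    activation); expressed: unmethylated promoter with high 5hmC;
    repressed: low gene-body 5hmC. ``hmc_high`` is typically the
    cell-type median gene-body level and must be supplied. Missing
    measurements yield state "unknown", never a guess.
    """
    thr = (meth_high, hmc_high, fpkm_expressed)
    if meth_percent is None or hmc_level is None or fpkm is None or hmc_high is None:
        return BivalentState(gene_id, "unknown", meth_percent, hmc_level, fpkm, thr)
    if not 0 <= meth_percent <= 100:
        raise ValueError("methylation percentage outside [0, 100]")
    if hmc_level <= hmc_high:
        state = "repressed"
    else:
        state = "primed" if meth_percent >= meth_high else "expressed"
    return BivalentState(gene_id, state, meth_percent, hmc_level, fpkm, thr)
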