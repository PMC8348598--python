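"""PCA, hierarchical clustering, correlation structure and the paired
left/right comparison.

All multivariate views run on the transformed (ln or lnPQN), Pareto-scaled
and mean-centred study matrix.  Cluster recovery is scored as purity
against the individual: the fraction of individuals whose six samples land
in a single cluster when the dendrogram is cut at k = 10.  Pearson
correlations between lipids carry an analytic significance threshold
derived from the t distribution.  The left/right comparison is a paired
t-test over the 30 (individual, day) pairs with Benjamini–Hochberg control
of the false discovery rate and a log2 fold-change of medians.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.decomposition import PCA as _SkPCA
from statsmodels.stats.multitest import multipletests

from .normalization import pqn, scale_matrix
from .peaktable import PeakTable

__all__ = [
    "PcaResult",
    "HcaResult",
    "PairedComparison",
    "pca",
    "hca",
    "critical_r",
    "correlation_matrix",
    "bh_reject",
    "paired_compare",
    "network_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    mean: pd.Series

    def reconstruct(self) -> pd.DataFrame:
        return self.scores.to_numpy() @ self.loadings.to_numpy().T + self.mean.to_numpy()


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """Principal component analysis of a samples × lipids matrix.

    The matrix is centred internally; explained variance fractions are the
    covariance eigenvalues over the total variance.  ``n_components``
    beyond what the data support is truncated with a warning.
    """
    max_comp = min(matrix.shape)
    if n_components is None:
        n_components = max_comp
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} exceeds min(n, p)={max_comp}; truncated",
            stacklevel=2,
        )
        n_components = max_comp
    model = _SkPCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(matrix.to_numpy(dtype=float))
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(model.components_.T, index=matrix.columns,
                              columns=comp_names),
        explained_variance_ratio=model.explained_variance_ratio_,
        mean=pd.Series(model.mean_, index=matrix.columns),
    )


@dataclass
class HcaResult:
    labels: pd.Series                # cluster id per sample
    merge_heights: np.ndarray        # linkage heights
    linkage_matrix: np.ndarray
    purity: float | None = None      # vs individual, when groups provided


def hca(matrix: pd.DataFrame, k: int, method: str = "ward",
        metric: str = "euclidean",
        groups: pd.Series | None = None) -> HcaResult:
    """Agglomerative clustering of samples; optional purity vs a grouping.

    Purity = fraction of groups (individuals) whose samples all fall in a
    single cluster at the ``k``-cluster cut.
    """
    n = matrix.shape[0]
    if n < 2:
        raise ValueError("clustering needs at least 2 samples")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    Z = linkage(matrix.to_numpy(dtype=float), method=method, metric=metric)
    labels = pd.Series(fcluster(Z, t=k, criterion="maxclust"),
                       index=matrix.index, name="cluster")
    purity = None
    if groups is not None:
        groups = groups.loc[matrix.index]
        pure = sum(labels.loc[ids].nunique() == 1
                   for _, ids in groups.groupby(groups).groups.items())
        purity = pure / groups.nunique()
    return HcaResult(labels=labels, merge_heights=Z[:, 2],
                     linkage_matrix=Z, purity=purity)


def critical_r(n: int, alpha: float = 0.05, tails: int = 2) -> float:
    """Smallest |Pearson r| significant at ``alpha`` for sample size ``n``.

    r* = sqrt(t² / (t² + n − 2)) with t the critical Student-t value at
    n − 2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("need n >= 3 samples")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    t = stats.t.ppf(1.0 - alpha / tails, df=n - 2)
    return float(np.sqrt(t ** 2 / (t ** 2 + n - 2)))


def correlation_matrix(matrix: pd.DataFrame, alpha: float = 0.05,
                       order_by_class: bool = True
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation over lipids + significance mask.

    Columns are grouped by lipid class (stable within class) when
    ``order_by_class``.  The mask flags |r| at or above the analytic
    threshold for the number of samples; the diagonal is always True and
    zero-variance lipids give missing correlations.
    """
    n = matrix.shape[0]
    if n < 3:
        raise ValueError("correlation needs at least 3 samples")
    cols = list(matrix.columns)
    if order_by_class:
        from .library import parse_label
        cols = sorted(cols, key=lambda c: (parse_label(c).class_code,
                                           cols.index(c)))
    ordered = matrix[cols]
    zero_var = ordered.std(axis=0, ddof=1) == 0
    r = ordered.corr(method="pearson", min_periods=2)
    r.loc[zero_var, :] = np.nan
    r.loc[:, zero_var] = np.nan
    np.fill_diagonal(r.to_numpy(), 1.0)
    threshold = critical_r(n, alpha)
    mask = r.abs() >= threshold
    np.fill_diagonal(mask.to_numpy(), True)
    return r, mask


def bh_reject(pvalues, q: float = 0.25) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at FDR ``q``."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, alpha=q, method="fdr_bh")[0]


@dataclass
class PairedComparison:
    results: pd.DataFrame  # per lipid: t, p, p_adjusted, significant, log2_fc
    q: float
    n_pairs: int

    @property
    def n_significant(self) -> int:
        return int(self.results["significant"].sum())


def paired_compare(table: PeakTable, q: float = 0.25,
                   condition: str = "lnPQN") -> PairedComparison:
    """Paired left-vs-right t-test per lipid with BH correction.

    Samples are paired on (individual, day); pairs missing a side are
    dropped.  The t-test runs on log-transformed (ln or lnPQN) intensities;
    the fold-change is log2 of the ratio of linear-scale medians (left over
    right).
    """
    study = table.study_areas
    if condition == "lnPQN":
        study = pqn(study).matrix
    elif condition != "ln":
        raise ValueError("condition must be 'ln' or 'lnPQN'")
    man = table.manifest.loc[table.study_ids]
    left, right = [], []
    for (ind, day), ids in man.groupby(["individual", "day"]).groups.items():
        sides = man.loc[ids, "side"]
        l_ids = sides.index[sides == "L"]
        r_ids = sides.index[sides == "R"]
        if len(l_ids) == 1 and len(r_ids) == 1:
            left.append(l_ids[0])
            right.append(r_ids[0])
        else:
            logger.warning("pair (%s, day %s) incomplete; dropped", ind, day)
    if len(left) < 2:
        raise ValueError("paired comparison needs >=2 complete L/R pairs")
    L = study.loc[left]
    R = study.loc[right]
    logL = scale_matrix(L, "ln")
    logR = scale_matrix(R, "ln")
    diffs = logL.to_numpy() - logR.to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_rel(logL.to_numpy(), logR.to_numpy(), axis=0,
                                nan_policy="omit")
    tvals = np.asarray(t_res.statistic, dtype=float)
    pvals = np.asarray(t_res.pvalue, dtype=float)
    # exactly equal sides: no evidence of a difference, not an undefined test
    degenerate = (np.nanstd(diffs, axis=0) == 0) & (np.nanmean(diffs, axis=0) == 0)
    tvals[degenerate] = 0.0
    pvals[degenerate] = 1.0
    log2_fc = np.log2(L.median(axis=0) / R.median(axis=0))
    usable = ~np.isnan(pvals)
    significant = np.zeros(len(pvals), dtype=bool)
    if usable.any():
        significant[usable] = bh_reject(pvals[usable], q=q)
    p_adj = np.full(len(pvals), np.nan)
    if usable.any():
        p_adj[usable] = multipletests(pvals[usable], alpha=q, method="fdr_bh")[1]
    results = pd.DataFrame({
        "t": tvals, "p": pvals, "p_adjusted": p_adj,
        "significant": significant, "log2_fc": log2_fc.to_numpy(),
    }, index=study.columns)
    return PairedComparison(results=results, q=q, n_pairs=len(left))


def network_summary(comparison: PairedComparison,
                    variability: "pd.DataFrame | None" = None) -> dict:
    """Node-link summary (one node per lipid) for network visualization.

    Node attributes: class, p, adjusted p, log2 fold-change and, when a
    per-lipid variability frame is given, the CVs.  The returned dict is
    JSON-serializable (Cytoscape-style node-link format via networkx).
    """
    import networkx as nx

    from .library import parse_label

    g = nx.Graph()
    for lipid, row in comparison.results.iterrows():
        attrs = {
            "lipid_class": parse_label(lipid).class_code,
            "p": None if np.isnan(row["p"]) else float(row["p"]),
            "p_adjusted": (None if np.isnan(row["p_adjusted"])
                           else float(row["p_adjusted"])),
            "log2_fc": None if np.isnan(row["log2_fc"]) else float(row["log2_fc"]),
            "significant": bool(row["significant"]),
        }
        if variability is not None and lipid in variability.index:
            for col in ("CVi", "CVg", "CVqc"):
                val = variability.loc[lipid, col]
                attrs[col] = None if pd.isna(val) else float(val)
        g.add_node(lipid, **attrs)
    return nx.node_link_data(g, edges="links")
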