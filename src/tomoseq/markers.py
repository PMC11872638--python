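"""Cluster-enriched gene (spatial marker) detection, one cluster vs the rest.

For each gene the in-cluster and out-of-cluster normalized values are
compared by a two-sided Wilcoxon rank-sum test (a t-test is selectable), with
Benjamini-Hochberg adjustment across genes, and a pseudocounted fold change

    log2FC = log2((mean_in + c) / (mean_out + c)),   c = pseudocount.

A gene is called enriched when log2FC > log2fc_min (strict) AND adjusted
p < alpha (strict); the defaults 0.5 / 0.05 are the thresholds used for the
stress-domain ("cluster 4") gene list in the study this pipeline mirrors.

The choice of test is the largest inferential gap in the source analysis,
which reports only "adjusted p"; the rank-sum test is the field-standard
cluster-vs-rest marker test and is the default here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterAssignment
from .normalize import NormalizedMatrix


@dataclass
class MarkerTable:
    table: pd.DataFrame  # gene, cluster, mean_in, mean_out, log2fc, p_value, adj_p, enriched
    cluster_id: int
    pseudocount: float
    test: str
    alpha: float
    log2fc_min: float

    @property
    def enriched_genes(self) -> list:
        t = self.table
        return list(t.loc[t["enriched"], "gene"])


def _ranksum_p(x_in: np.ndarray, x_out: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p per gene (rows).

    Exact null distribution for small groups without ties (scipy's 'auto'
    policy), vectorized normal approximation with tie correction otherwise.
    Genes whose values are all identical get p = 1.
    """
    n_in, n_out = x_in.shape[1], x_out.shape[1]
    if max(n_in, n_out) <= 8:
        p = np.empty(x_in.shape[0])
        for i in range(x_in.shape[0]):
            p[i] = scipy.stats.mannwhitneyu(
                x_in[i], x_out[i], alternative="two-sided", method="auto"
            ).pvalue
    else:
        p = scipy.stats.mannwhitneyu(
            x_in, x_out, alternative="two-sided", method="asymptotic", axis=1
        ).pvalue
    # all-tied genes: no evidence of difference
    flat = (x_in == x_in[:, [0]]).all(axis=1) & (x_out == x_in[:, [0]]).all(axis=1)
    p = np.where(flat | ~np.isfinite(p), 1.0, p)
    return np.clip(p, 0.0, 1.0)


def cluster_markers(
    nm: NormalizedMatrix,
    ca: ClusterAssignment,
    cluster_id: int,
    pseudocount: float = 1.0,
    log2fc_min: float = 0.5,
    alpha: float = 0.05,
    test: str = "wilcoxon",
) -> MarkerTable:
    """One-vs-rest enrichment test of every gene for one spatial cluster."""
    if cluster_id not in set(ca.labels.unique()):
        raise ValueError(f"cluster {cluster_id} not present in assignment")
    in_cols = [s for s in nm.sections if ca.labels.get(s) == cluster_id]
    out_cols = [s for s in nm.sections if ca.labels.get(s) != cluster_id]
    if len(in_cols) < 2 or len(out_cols) < 2:
        raise ValueError(
            f"cluster {cluster_id} needs >= 2 sections on each side "
            f"(got {len(in_cols)} vs {len(out_cols)})"
        )
    x_in = nm.values[in_cols].to_numpy(dtype=float)
    x_out = nm.values[out_cols].to_numpy(dtype=float)
    mean_in = x_in.mean(axis=1)
    mean_out = x_out.mean(axis=1)
    log2fc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))

    if test == "wilcoxon":
        p = _ranksum_p(x_in, x_out)
    elif test == "ttest":
        p = scipy.stats.ttest_ind(x_in, x_out, axis=1, equal_var=False).pvalue
        p = np.where(np.isfinite(p), p, 1.0)
    else:
        raise ValueError("test must be 'wilcoxon' or 'ttest'")

    adj_p = multipletests(p, method="fdr_bh")[1]
    enriched = (log2fc > log2fc_min) & (adj_p < alpha)
    table = pd.DataFrame(
        {
            "gene": nm.genes,
            "cluster": cluster_id,
            "mean_in": mean_in,
            "mean_out": mean_out,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": adj_p,
            "enriched": enriched,
        }
    ).sort_values(["adj_p", "log2fc"], ascending=[True, False], kind="mergesort")
    table = table.reset_index(drop=True)
    return MarkerTable(
        table=table,
        cluster_id=cluster_id,
        pseudocount=pseudocount,
        test=test,
        alpha=alpha,
        log2fc_min=log2fc_min,
    )


def marker_overlap_report(detected, truth_markers) -> tuple[float, float]:
    """(sensitivity, FDR) of a detected marker list vs a ground-truth set.

    ``detected`` may be a MarkerTable or any iterable of gene IDs.
    FDR uses max(|detected|, 1) in the denominator so an empty detection is
    (0, 0) rather than undefined.
    """
    if isinstance(detected, MarkerTable):
        detected = detected.enriched_genes
    det = set(detected)
    truth = set(truth_markers)
    sens = len(det & truth) / len(truth) if truth else 0.0
    fdr = len(det - truth) / max(len(det), 1)
    return sens, fdr


def write_markers(mt: MarkerTable, path) -> None:
    mt.table.to_csv(path, sep="\t", index=False)


class ClusterMarkerDetector(BaseEstimator):
    """Estimator wrapper: ``fit(nm, assignment)`` stores ``table_`` and
    ``enriched_genes_`` for the configured cluster."""

    def __init__(
        self,
        cluster_id: int = 1,
        pseudocount: float = 1.0,
        log2fc_min: float = 0.5,
        alpha: float = 0.05,
        test: str = "wilcoxon",
    ):
        self.cluster_id = cluster_id
        self.pseudocount = pseudocount
        self.log2fc_min = log2fc_min
        self.alpha = alpha
        self.test = test

    def fit(self, X: NormalizedMatrix, y: ClusterAssignment):
        self.result_ = cluster_markers(
            X,
            y,
            cluster_id=self.cluster_id,
            pseudocount=self.pseudocount,
            log2fc_min=self.log2fc_min,
            alpha=self.alpha,
            test=self.test,
        )
        self.table_ = self.result_.table
        self.enriched_genes_ = self.result_.enriched_genes
        return self
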