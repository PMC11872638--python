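"""Correlation of section transcriptomes and hierarchical spatial clustering.

Sections are compared by the Pearson correlation r(s, t) of their normalized
gene-expression vectors; agglomerative clustering on the distance
d = 1 - r, cut to exactly k clusters, groups sections into transcriptional
domains.  Labels are renumbered deterministically by the physical position of
each cluster's first section (epicardial side first), and a run-length
contiguity summary records which stretches of the section axis each cluster
occupies (contiguity is reported, never enforced: a domain may flank another
on both sides).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .normalize import NormalizedMatrix, ZScoreMatrix

LINKAGES = {"complete": "complete", "average": "average", "ward-on-distance": "ward"}


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame  # sections x sections, physical order
    method: str = "pearson"
    flagged_sections: tuple = ()

    @property
    def sections(self) -> pd.Index:
        return self.r.index


@dataclass
class ClusterAssignment:
    labels: pd.Series  # section -> label in 1..k, physical order
    k: int
    linkage_method: str
    runs: tuple  # ((label, start_pos, end_pos), ...) 1-based, tiling the axis

    def sections_of(self, label: int) -> list:
        return list(self.labels.index[self.labels.to_numpy() == label])

    @classmethod
    def from_labels(cls, labels: pd.Series, linkage_method: str = "manual"):
        """Wrap an externally produced per-section labeling (physical order)."""
        arr = labels.to_numpy()
        return cls(
            labels=labels,
            k=int(len(np.unique(arr))),
            linkage_method=linkage_method,
            runs=_contiguity_runs(arr),
        )


def correlation_matrix(nm, use: str = "normalized") -> CorrelationMatrix:
    """Pairwise Pearson correlation between section profiles.

    ``use='normalized'`` expects a NormalizedMatrix (the default input space);
    ``use='zscore'`` a ZScoreMatrix.  Sections whose profile has zero
    variance across genes have undefined correlations: their rows/columns are
    NaN and they are flagged.
    """
    if use == "normalized":
        values = nm.values if isinstance(nm, NormalizedMatrix) else pd.DataFrame(nm)
    elif use == "zscore":
        values = nm.z if isinstance(nm, ZScoreMatrix) else pd.DataFrame(nm)
    else:
        raise ValueError("use must be 'normalized' or 'zscore'")
    if values.shape[0] < 2 or values.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 sections")
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=0)
    flagged = tuple(values.columns[sd == 0])
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(arr, rowvar=False)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    if flagged:
        idx = [values.columns.get_loc(s) for s in flagged]
        r[idx, :] = np.nan
        r[:, idx] = np.nan
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=values.columns, columns=values.columns),
        flagged_sections=flagged,
    )


def _contiguity_runs(labels: np.ndarray) -> tuple:
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((int(labels[start]), start + 1, i))  # 1-based inclusive
            start = i
    return tuple(runs)


def cluster_sections(
    cm: CorrelationMatrix, k: int, linkage: str = "complete"
) -> ClusterAssignment:
    """Cut the hierarchical tree on d = 1 - r into exactly k clusters."""
    n = cm.r.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {sorted(LINKAGES)}")
    if np.isnan(cm.r.to_numpy()).any():
        raise ValueError(
            f"correlation matrix has missing values (flagged sections "
            f"{list(cm.flagged_sections)}); remove them before clustering"
        )
    d = 1.0 - cm.r.to_numpy(dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)  # enforce exact symmetry
    condensed = squareform(d, checks=False)
    Z = sch.linkage(condensed, method=LINKAGES[linkage])
    raw = sch.fcluster(Z, t=k, criterion="maxclust")
    # renumber 1..k by first occurrence along the epi->endo axis
    order = {}
    for lab in raw:
        if lab not in order:
            order[lab] = len(order) + 1
    labels = np.array([order[lab] for lab in raw], dtype=int)
    series = pd.Series(labels, index=cm.sections, name="cluster")
    return ClusterAssignment(
        labels=series,
        k=int(labels.max()),
        linkage_method=linkage,
        runs=_contiguity_runs(labels),
    )


def cluster_mean_profiles(nm: NormalizedMatrix, ca: ClusterAssignment) -> pd.DataFrame:
    """Per-(gene, cluster) mean of normalized expression."""
    missing = [s for s in nm.sections if s not in ca.labels.index]
    if missing:
        raise ValueError(f"sections without cluster label: {missing}")
    out = {}
    for lab in sorted(ca.labels.unique()):
        cols = [s for s in nm.sections if ca.labels[s] == lab]
        out[lab] = nm.values[cols].mean(axis=1)
    return pd.DataFrame(out)


def write_assignment(ca: ClusterAssignment, path) -> None:
    df = pd.DataFrame(
        {
            "section_id": ca.labels.index,
            "position": np.arange(1, len(ca.labels) + 1),
            "cluster": ca.labels.to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


class SectionClusterer(ClusterMixin, BaseEstimator):
    """Hierarchical clustering of ordered sections on 1 - Pearson r.

    Parameters
    ----------
    k : number of clusters to cut the tree into (the fine clustering in a
        diseased-heart Tomo-seq study used 5; the coarse two-area split 2).
    linkage : 'complete' (default), 'average' or 'ward-on-distance'.
    use : input space for the correlations, 'normalized' or 'zscore'.
    """

    def __init__(self, k: int = 5, linkage: str = "complete", use: str = "normalized"):
        self.k = k
        self.linkage = linkage
        self.use = use

    def fit(self, X, y=None):
        self.correlation_ = correlation_matrix(X, use=self.use)
        self.assignment_ = cluster_sections(self.correlation_, self.k, self.linkage)
        self.labels_ = self.assignment_.labels.to_numpy()
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
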