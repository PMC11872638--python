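"""Median-of-totals depth normalization and per-gene spatial Z-scores.

Normalization: with raw counts C_gs, per-slice totals R_s = sum_g C_gs and
median m = median_s R_s over retained slices, the normalized value is

    N_gs = C_gs / R_s * m

so every slice's normalized total equals m and within-slice gene ranking is
unchanged.  Z-scores standardize each gene across sections,

    z_gs = (N_gs - mean_s N_gs) / sd_s N_gs,

making spatial traces comparable across genes of different absolute
abundance.  Sample (n-1) standard deviation by default; zero-variance genes
are kept as flagged all-zero rows so shapes stay aligned downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CountMatrix
from .qc import QCResult


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame  # genes x sections, non-negative reals
    scale_constant: float

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sections(self) -> pd.Index:
        return self.values.columns


@dataclass
class ZScoreMatrix:
    z: pd.DataFrame  # genes x sections
    flags: pd.Series = field(default=None)  # type: ignore[assignment]  # True = zero variance

    def __post_init__(self) -> None:
        if self.flags is None:
            self.flags = pd.Series(False, index=self.z.index)

    @property
    def sections(self) -> pd.Index:
        return self.z.columns


def _as_counts_frame(source) -> pd.DataFrame:
    if isinstance(source, QCResult):
        return source.filtered_matrix.counts
    if isinstance(source, CountMatrix):
        return source.counts
    return pd.DataFrame(source)


def normalize_counts(source) -> NormalizedMatrix:
    """Scale each slice to the median of per-slice totals.

    ``source`` may be a QCResult (its filtered matrix is used), a
    CountMatrix, or a plain genes x sections DataFrame.
    """
    counts = _as_counts_frame(source).astype(float)
    if counts.size == 0:
        raise ValueError("empty count matrix")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero-total slice(s): {bad}; run QC first")
    # even-count median = midpoint of the two central values (numpy default)
    scale = float(np.median(totals.to_numpy()))
    values = counts.div(totals, axis=1) * scale
    return NormalizedMatrix(values=values, scale_constant=scale)


def zscore(nm, ddof: int = 1) -> ZScoreMatrix:
    """Standardize each gene across sections; flag zero-variance genes."""
    values = nm.values if isinstance(nm, NormalizedMatrix) else pd.DataFrame(nm).astype(float)
    if values.shape[1] < 2:
        raise ValueError("Z-scores need at least 2 sections")
    arr = values.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=ddof, keepdims=True)
    flat = sd[:, 0] == 0
    sd[flat] = 1.0
    z = (arr - mean) / sd
    z[flat, :] = 0.0
    return ZScoreMatrix(
        z=pd.DataFrame(z, index=values.index, columns=values.columns),
        flags=pd.Series(flat, index=values.index, name="zero_variance"),
    )


def spatial_profile(zm: ZScoreMatrix, genes) -> pd.DataFrame:
    """Long-format (gene, section_id, position, z) traces in physical order."""
    genes = [genes] if isinstance(genes, str) else list(genes)
    missing = [g for g in genes if g not in zm.z.index]
    if missing:
        raise KeyError(f"unknown gene(s): {missing}")
    rows = []
    for g in genes:
        for pos, s in enumerate(zm.sections, start=1):
            rows.append(
                (g, s, pos, float(zm.z.at[g, s]), bool(zm.flags[g]))
            )
    return pd.DataFrame(
        rows, columns=["gene", "section_id", "position", "z", "zero_variance"]
    )


class MedianOfTotalsNormalizer(TransformerMixin, BaseEstimator):
    """Estimator wrapper: ``fit`` records ``scale_constant_``, ``transform``
    returns the :class:`NormalizedMatrix`."""

    def fit(self, X, y=None):
        self.result_ = normalize_counts(X)
        self.scale_constant_ = self.result_.scale_constant
        return self

    def transform(self, X) -> NormalizedMatrix:
        return normalize_counts(X)


class SpatialZScorer(TransformerMixin, BaseEstimator):
    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        self.result_ = zscore(X, ddof=self.ddof)
        self.zero_variance_genes_ = list(
            self.result_.flags.index[self.result_.flags]
        )
        return self

    def transform(self, X) -> ZScoreMatrix:
        return zscore(X, ddof=self.ddof)
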