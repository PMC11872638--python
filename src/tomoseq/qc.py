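"""Slice- and gene-level quality control for ordered-section count matrices.

Order of operations is fixed:

1. exclude mitochondrial and spike-in genes (their reads are technical /
   organelle signal, not informative for spatial domain structure);
2. drop sections whose post-exclusion total read count is below
   ``slice_min_reads`` (strict ``<``);
3. drop genes that do not reach a count strictly greater than
   ``gene_min_count`` in at least ``gene_min_slices`` of the sections that
   survived step 2.

The slice totals used in step 2 are post-exclusion by default; ``totals="pre"``
switches to raw totals (spike-ins and mitochondrial reads included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import CountMatrix


class QCError(ValueError):
    pass


@dataclass
class QCResult:
    """Outcome of slice/gene filtering plus per-slice QC metrics.

    All per-slice series are indexed by the *input* section IDs so a QC
    report can show why each section was kept or dropped.
    """

    per_slice_total_raw: pd.Series
    per_slice_total_postexclusion: pd.Series
    mito_fraction: pd.Series  # percent of raw reads
    zero_total_sections: list
    retained_sections: list
    retained_genes: list
    filtered_matrix: CountMatrix
    slice_min_reads: int
    gene_min_count: int
    gene_min_slices: int
    totals: str = "post"


def compute_slice_qc(m: CountMatrix) -> QCResult:
    """Per-slice totals and mitochondrial read percentage (no filtering).

    ``mito_fraction`` is 100 x (mitochondrial reads / all raw reads, spike-ins
    included in the denominator).  Slices with zero raw total get 0% and are
    flagged in ``zero_total_sections`` with a warning.
    """
    raw_tot = m.counts.sum(axis=0).astype(float)
    mito = m.genes_of_class("mitochondrial")
    mito_tot = m.counts.loc[mito].sum(axis=0).astype(float)
    spike = m.genes_of_class("spikein")
    post_tot = raw_tot - mito_tot - m.counts.loc[spike].sum(axis=0).astype(float)

    zero = list(m.sections[raw_tot.to_numpy() == 0])
    if zero:
        warnings.warn(f"sections with zero total reads: {zero}")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(raw_tot.to_numpy() > 0, 100.0 * mito_tot.to_numpy() / raw_tot.to_numpy(), 0.0)
    return QCResult(
        per_slice_total_raw=raw_tot,
        per_slice_total_postexclusion=post_tot,
        mito_fraction=pd.Series(frac, index=m.sections, name="mito_pct"),
        zero_total_sections=zero,
        retained_sections=list(m.sections),
        retained_genes=list(m.genes),
        filtered_matrix=m,
        slice_min_reads=0,
        gene_min_count=0,
        gene_min_slices=0,
    )


def apply_filters(
    m: CountMatrix,
    slice_min_reads: int = 3000,
    gene_min_count: int = 5,
    gene_min_slices: int = 3,
    totals: str = "post",
) -> QCResult:
    """Apply the fixed-order slice and gene filters; returns a full QCResult."""
    if totals not in ("pre", "post"):
        raise ValueError("totals must be 'pre' or 'post'")
    base = compute_slice_qc(m)

    bio = m.drop_classes()  # step 1: remove mito + spike-in genes
    slice_tot = (
        base.per_slice_total_raw if totals == "pre" else base.per_slice_total_postexclusion
    )
    keep_sections = [s for s in m.sections if slice_tot[s] >= slice_min_reads]
    if not keep_sections:
        raise QCError(
            f"all {m.n_sections} sections fall below slice_min_reads={slice_min_reads}"
        )
    sub = bio.counts[keep_sections]

    n_ok = (sub.to_numpy() > gene_min_count).sum(axis=1)
    keep_genes = list(bio.genes[n_ok >= gene_min_slices])
    if not keep_genes:
        raise QCError(
            f"all genes fail the gene filter (> {gene_min_count} in >= {gene_min_slices} slices)"
        )
    filtered = CountMatrix(
        sub.loc[keep_genes].copy(), bio.gene_classes.loc[keep_genes].copy()
    )
    return QCResult(
        per_slice_total_raw=base.per_slice_total_raw,
        per_slice_total_postexclusion=base.per_slice_total_postexclusion,
        mito_fraction=base.mito_fraction,
        zero_total_sections=base.zero_total_sections,
        retained_sections=keep_sections,
        retained_genes=keep_genes,
        filtered_matrix=filtered,
        slice_min_reads=slice_min_reads,
        gene_min_count=gene_min_count,
        gene_min_slices=gene_min_slices,
        totals=totals,
    )


def write_qc_report(qc: QCResult, path) -> None:
    """One row per input section: totals, mito %, retained flag."""
    retained = set(qc.retained_sections)
    rep = pd.DataFrame(
        {
            "raw_total": qc.per_slice_total_raw.astype(int),
            "postexclusion_total": qc.per_slice_total_postexclusion.astype(int),
            "mito_pct": qc.mito_fraction.round(4),
            "retained": [int(s in retained) for s in qc.per_slice_total_raw.index],
        }
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rep.to_csv(path, sep="\t", index_label="section")


class SliceQC(TransformerMixin, BaseEstimator):
    """Estimator wrapper around :func:`apply_filters`.

    ``fit`` computes the QC result (``result_``); ``transform`` returns the
    filtered :class:`CountMatrix`.
    """

    def __init__(
        self,
        slice_min_reads: int = 3000,
        gene_min_count: int = 5,
        gene_min_slices: int = 3,
        totals: str = "post",
    ):
        self.slice_min_reads = slice_min_reads
        self.gene_min_count = gene_min_count
        self.gene_min_slices = gene_min_slices
        self.totals = totals

    def fit(self, X: CountMatrix, y=None):
        self.result_ = apply_filters(
            X,
            slice_min_reads=self.slice_min_reads,
            gene_min_count=self.gene_min_count,
            gene_min_slices=self.gene_min_slices,
            totals=self.totals,
        )
        self.retained_sections_ = self.result_.retained_sections
        self.retained_genes_ = self.result_.retained_genes
        return self

    def transform(self, X: CountMatrix) -> CountMatrix:
        if not hasattr(self, "result_"):
            self.fit(X)
        return self.result_.filtered_matrix
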