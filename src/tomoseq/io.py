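"""Count-matrix container and TSV / MatrixMarket I/O.

The central object is :class:`CountMatrix`: a genes x ordered-sections table
of raw transcript counts from consecutive cryosections of one tissue block.
Section (column) order is the physical order along the sectioning axis, from
epicardium (first) to endocardium (last), and every downstream operation
preserves it.  Genes carry a class flag (``regular`` / ``mitochondrial`` /
``spikein``) inferred from the community naming conventions ``MT-`` and
``ERCC-`` unless an explicit class table is supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

GENE_CLASSES = ("regular", "mitochondrial", "spikein")

MITO_PREFIX = "MT-"
SPIKEIN_PREFIX = "ERCC-"


class CountMatrixError(ValueError):
    """Raised when a counts table fails validation or parsing."""


def infer_gene_classes(gene_ids) -> pd.Series:
    """Classify genes by name prefix: ``MT-`` mitochondrial, ``ERCC-`` spike-in."""
    ids = pd.Index(gene_ids)

    def _cls(g: str) -> str:
        gu = str(g).upper()
        if gu.startswith(MITO_PREFIX):
            return "mitochondrial"
        if gu.startswith(SPIKEIN_PREFIX):
            return "spikein"
        return "regular"

    return pd.Series([_cls(g) for g in ids], index=ids, name="gene_class")


@dataclass
class CountMatrix:
    """Raw integer counts, genes x sections, in physical section order.

    Parameters
    ----------
    counts
        DataFrame of non-negative integers; rows are genes, columns are
        section IDs ordered epicardium -> endocardium.
    gene_classes
        Per-gene class flag; inferred from name prefixes when omitted.
    """

    counts: pd.DataFrame
    gene_classes: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.gene_classes is None:
            self.gene_classes = infer_gene_classes(self.counts.index)
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        idx, cols = self.counts.index, self.counts.columns
        for axis_name, labels in (("gene", idx), ("section", cols)):
            dup = labels[labels.duplicated()]
            if len(dup):
                raise CountMatrixError(
                    f"duplicate {axis_name} ID(s): {sorted(set(map(str, dup)))}"
                )
        vals = self.counts.to_numpy()
        if vals.size:
            if np.isnan(vals.astype(float)).any():
                bad = int(np.argwhere(np.isnan(vals.astype(float)))[0, 0])
                raise CountMatrixError(
                    f"missing/ragged value in row for gene {idx[bad]!r}"
                )
            if (vals.astype(float) < 0).any():
                bad = idx[np.argwhere(vals.astype(float) < 0)[0, 0]]
                raise CountMatrixError(f"negative count for gene {bad!r}")
            if not np.allclose(vals.astype(float) % 1, 0):
                bad = idx[np.argwhere(vals.astype(float) % 1 != 0)[0, 0]]
                raise CountMatrixError(f"non-integer count for gene {bad!r}")
        self.counts = self.counts.astype(np.int64)
        self.gene_classes = self.gene_classes.reindex(idx)
        if self.gene_classes.isna().any():
            missing = list(idx[self.gene_classes.isna()])
            raise CountMatrixError(f"genes without class flag: {missing}")
        bad_cls = set(self.gene_classes.unique()) - set(GENE_CLASSES)
        if bad_cls:
            raise CountMatrixError(f"unknown gene class(es): {sorted(bad_cls)}")

    # -- accessors ----------------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def sections(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_sections(self) -> int:
        return self.counts.shape[1]

    def genes_of_class(self, cls: str) -> pd.Index:
        return self.genes[self.gene_classes.to_numpy() == cls]

    def subset(self, genes=None, sections=None) -> "CountMatrix":
        """Restrict to the given genes/sections, preserving input order."""
        sub = self.counts
        if genes is not None:
            sub = sub.loc[[g for g in self.genes if g in set(genes)]]
        if sections is not None:
            keep = set(sections)
            sub = sub[[s for s in self.sections if s in keep]]
        return CountMatrix(sub.copy(), self.gene_classes.loc[sub.index].copy())

    def drop_classes(self, classes=("mitochondrial", "spikein")) -> "CountMatrix":
        keep = ~self.gene_classes.isin(classes)
        return CountMatrix(
            self.counts.loc[keep.to_numpy()].copy(),
            self.gene_classes[keep.to_numpy()].copy(),
        )


# -- file I/O ---------------------------------------------------------------

def _sidecar_paths(path: Path) -> tuple[Path, Path]:
    base = path.with_suffix("")
    return base.with_suffix(".rownames.txt"), base.with_suffix(".colnames.txt")


def read_counts(path, format: str = "tsv", class_file=None) -> CountMatrix:
    """Read a genes x sections counts table.

    ``tsv``: first column gene symbols, header section IDs in physical order.
    ``mtx``: MatrixMarket integer coordinate file with ``.rownames.txt`` /
    ``.colnames.txt`` sidecars next to it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.ParserError as exc:  # ragged rows carry line numbers
            raise CountMatrixError(f"parse error in {path}: {exc}") from exc
        if df.isna().any().any():
            row = int(np.argwhere(df.isna().any(axis=1).to_numpy())[0, 0])
            raise CountMatrixError(
                f"ragged/missing values at line {row + 2} of {path}"
            )
        df.index.name = None
    elif format == "mtx":
        rows_p, cols_p = _sidecar_paths(path)
        mat = scipy.io.mmread(path)
        genes = rows_p.read_text().split()
        sections = cols_p.read_text().split()
        df = pd.DataFrame(
            np.asarray(scipy.sparse.coo_matrix(mat).todense()),
            index=genes,
            columns=sections,
        )
    else:
        raise ValueError(f"unknown counts format {format!r}")

    classes = None
    if class_file is not None:
        tab = pd.read_csv(class_file, sep="\t", index_col=0, header=None)
        classes = tab.iloc[:, 0].rename("gene_class")
        classes.index = classes.index.astype(str)
        classes = classes.reindex(df.index.astype(str))
    return CountMatrix(df, classes)


def write_counts(m: CountMatrix, path, format: str = "tsv") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "tsv":
        m.counts.to_csv(path, sep="\t", index_label="gene")
    elif format == "mtx":
        rows_p, cols_p = _sidecar_paths(path)
        scipy.io.mmwrite(
            path, scipy.sparse.coo_matrix(m.counts.to_numpy()), field="integer"
        )
        rows_p.write_text("\n".join(map(str, m.genes)) + "\n")
        cols_p.write_text("\n".join(map(str, m.sections)) + "\n")
    else:
        raise ValueError(f"unknown counts format {format!r}")


def warn(msg: str) -> None:
    warnings.warn(msg, stacklevel=2)
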