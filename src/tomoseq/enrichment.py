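"""Gene-set / motif-target over-representation (upstream-regulator discovery).

Given a query gene list (e.g. the markers of a stressed spatial cluster) and
an annotation mapping terms to gene sets over a background universe, each
term is tested with the one-sided Fisher exact test: with the 2x2 table

                 in term   not in term
    in query        a          b
    not in query    c          d

the p-value is the hypergeometric upper tail P(X >= a) with X ~
Hypergeom(N = a+b+c+d, K = a+c, n = a+b).  Odds ratios use a 0.5
continuity (Haldane) correction when any cell is zero.  BH adjustment is
applied across terms; ``rank_regulators`` orders significant terms for
candidate-regulator reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetAnnotation:
    """term -> gene-set mapping restricted to a background universe.

    Genes outside the universe are dropped with a warning; terms empty after
    intersection are removed.
    """

    sets: dict
    universe: set

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        cleaned = {}
        for term, genes in self.sets.items():
            genes = set(genes)
            outside = genes - self.universe
            if outside:
                warnings.warn(
                    f"term {term}: {len(outside)} gene(s) outside universe dropped"
                )
            inside = genes & self.universe
            if inside:
                cleaned[term] = inside
            else:
                warnings.warn(f"term {term}: empty after universe intersection; removed")
        self.sets = cleaned


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # term_id, k_in_set, n_set, K_in_universe, N_universe, odds_ratio, p_value, adj_p


def hypergeom_upper_tail(a, n_query, K, N):
    """P(X >= a) for X ~ Hypergeom(N, K, n_query); vectorized over arrays.

    Degenerate margins (e.g. an empty universe), where X is deterministic at
    the lower support bound max(0, n_query + K - N), are handled explicitly.
    """
    a, n_query, K, N = np.broadcast_arrays(
        np.asarray(a), np.asarray(n_query), np.asarray(K), np.asarray(N)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        p = scipy.stats.hypergeom.sf(a - 1, N, K, n_query)
    lower = np.maximum(0, n_query + K - N)
    p = np.where(np.isnan(p), np.where(a <= lower, 1.0, 0.0), p)
    return p if p.ndim else float(p)


def overrepresentation(query, annot: GeneSetAnnotation) -> EnrichmentResult:
    """One-sided Fisher over-representation of every term in the query list."""
    query = set(query)
    outside = query - annot.universe
    if outside:
        warnings.warn(f"{len(outside)} query gene(s) outside universe dropped")
    query &= annot.universe
    if not query:
        raise ValueError("query empty after intersection with universe")
    N = len(annot.universe)
    n_q = len(query)
    rows = []
    for term, genes in annot.sets.items():
        K = len(genes)
        a = len(query & genes)
        b = n_q - a
        c = K - a
        d = N - K - b
        p = float(hypergeom_upper_tail(a, n_q, K, N))
        if min(a, b, c, d) == 0:
            orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            orr = (a * d) / (b * c)
        rows.append((term, a, K, K, N, orr, p))
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "k_in_set", "n_set", "K_in_universe", "N_universe",
            "odds_ratio", "p_value",
        ],
    )
    df["adj_p"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    df = df.sort_values("p_value", kind="mergesort").reset_index(drop=True)
    return EnrichmentResult(table=df)


def rank_regulators(er: EnrichmentResult, alpha: float = 0.05) -> list:
    """Terms with adj_p < alpha, ordered by p asc, then odds ratio desc, then ID."""
    t = er.table
    sig = t.loc[t["adj_p"] < alpha].copy()
    sig = sig.sort_values(
        ["p_value", "odds_ratio", "term_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return list(sig["term_id"])


# -- GMT I/O ----------------------------------------------------------------

def read_gmt(path, universe) -> GeneSetAnnotation:
    """Read GMT (term <tab> description <tab> gene...) into an annotation."""
    sets = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"GMT line {ln}: need term, description, >=1 gene")
            sets[parts[0]] = set(g for g in parts[2:] if g)
    return GeneSetAnnotation(sets=sets, universe=set(universe))


def write_gmt(annot: GeneSetAnnotation, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(annot.sets):
            genes = "\t".join(sorted(annot.sets[term]))
            fh.write(f"{term}\t-\t{genes}\n")


def write_enrichment(er: EnrichmentResult, path) -> None:
    er.table.to_csv(path, sep="\t", index=False)
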