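"""One-vs-rest cluster marker detection: fold change, rank-sum test, BH."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from tomoseq import ClusterMarkerDetector, cluster_markers, marker_overlap_report
from tomoseq.cluster import ClusterAssignment
from tomoseq.normalize import NormalizedMatrix


def _nm(df: pd.DataFrame) -> NormalizedMatrix:
    return NormalizedMatrix(values=df.astype(float), scale_constant=1.0)


def _assignment(labels, columns) -> ClusterAssignment:
    return ClusterAssignment.from_labels(pd.Series(labels, index=columns))


def _toy(seed=0, n_in=5, n_out=9, n_genes=6):
    rng = np.random.default_rng(seed)
    cols = [f"S{i:02d}" for i in range(n_in + n_out)]
    df = pd.DataFrame(rng.random((n_genes, n_in + n_out)) * 10,
                      index=[f"G{i}" for i in range(n_genes)], columns=cols)
    labels = [1] * n_in + [2] * n_out
    return df, _assignment(labels, cols)


def test_constant_gene_is_null():
    df, ca = _toy()
    df.loc["G0"] = 3.0
    mt = cluster_markers(_nm(df), ca, 1)
    row = mt.table.set_index("gene").loc["G0"]
    assert row["log2fc"] == 0.0
    assert row["p_value"] == 1.0
    assert not row["enriched"]


def test_log2fc_threshold_is_strict():
    # in-cluster constant 1, out-cluster 0 => log2fc exactly 1.0
    cols = [f"S{i}" for i in range(12)]
    df = pd.DataFrame(0.0, index=["M", "F"], columns=cols)
    df.loc["M", cols[:6]] = 1.0
    rng = np.random.default_rng(1)
    df.loc["F"] = rng.random(12)  # filler so BH has >1 gene
    ca = _assignment([1] * 6 + [2] * 6, cols)
    strict = cluster_markers(_nm(df), ca, 1, log2fc_min=1.0)
    row = strict.table.set_index("gene").loc["M"]
    assert row["log2fc"] == pytest.approx(1.0)
    assert not row["enriched"]  # log2fc must EXCEED the threshold
    loose = cluster_markers(_nm(df), ca, 1, log2fc_min=0.999)
    assert "M" in loose.enriched_genes


def test_swap_symmetry():
    df, ca = _toy(seed=5)
    a = cluster_markers(_nm(df), ca, 1)
    b = cluster_markers(_nm(df), ca, 2)
    ta = a.table.set_index("gene").loc[df.index]
    tb = b.table.set_index("gene").loc[df.index]
    assert np.allclose(ta["log2fc"], -tb["log2fc"])
    assert np.allclose(ta["p_value"], tb["p_value"])


def test_small_cluster_is_error():
    df, _ = _toy()
    ca = _assignment([1] + [2] * 13, df.columns)
    with pytest.raises(ValueError, match=">= 2 sections"):
        cluster_markers(_nm(df), ca, 1)


def exact_permutation_p(x, y):
    """Two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n, N = len(x), len(pooled)
    ranks = rankdata(pooled)
    obs = ranks[:n].sum() - n * (n + 1) / 2
    stats = np.array([
        ranks[list(c)].sum() - n * (n + 1) / 2
        for c in itertools.combinations(range(N), n)
    ])
    p = 2 * min((stats <= obs).mean(), (stats >= obs).mean())
    return min(1.0, p)


def test_ranksum_matches_exhaustive_permutation():
    rng = np.random.default_rng(2)
    cols = [f"S{i:02d}" for i in range(12)]
    df = pd.DataFrame(rng.normal(size=(4, 12)), index=list("ABCD"), columns=cols)
    ca = _assignment([1] * 6 + [2] * 6, cols)
    mt = cluster_markers(_nm(df - df.min().min()), ca, 1)
    shifted = (df - df.min().min()).to_numpy()
    for i, g in enumerate("ABCD"):
        expected = exact_permutation_p(shifted[i, :6], shifted[i, 6:])
        got = float(mt.table.set_index("gene").at[g, "p_value"])
        assert got == pytest.approx(expected, abs=1e-10)


def bh_stepup_oracle(p):
    """Independent Benjamini-Hochberg step-up implementation."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


def test_bh_adjustment_matches_stepup_oracle():
    rng = np.random.default_rng(9)
    df, ca = _toy(seed=9, n_genes=40)
    mt = cluster_markers(_nm(df), ca, 1)
    t = mt.table
    assert np.allclose(
        t["adj_p"].to_numpy(), bh_stepup_oracle(t["p_value"].to_numpy()), atol=1e-12
    )
    assert (t["adj_p"] >= t["p_value"] - 1e-15).all()


def test_planted_marker_detected():
    rng = np.random.default_rng(4)
    cols = [f"S{i:03d}" for i in range(150)]
    base = rng.gamma(2.0, 5.0, size=(30, 150))
    df = pd.DataFrame(base, index=[f"G{i}" for i in range(30)], columns=cols)
    df.iloc[0, :25] *= 4  # fold-4 marker in a 25-section cluster
    ca = _assignment([1] * 25 + [2] * 125, cols)
    mt = cluster_markers(_nm(df), ca, 1)
    assert "G0" in mt.enriched_genes


@pytest.mark.parametrize(
    "detected,truth,expected",
    [
        ({"A", "B"}, {"A", "B"}, (1.0, 0.0)),
        (set(), {"A"}, (0.0, 0.0)),  # max(|detected|, 1) convention
        ({f"X{i}" for i in range(20)}, {"A", "B"}, (0.0, 1.0)),
    ],
)
def test_overlap_report_conventions(detected, truth, expected):
    assert marker_overlap_report(detected, truth) == expected


def test_ttest_option_and_estimator():
    df, ca = _toy(seed=6)
    mt = cluster_markers(_nm(df), ca, 1, test="ttest")
    assert ((mt.table["p_value"] >= 0) & (mt.table["p_value"] <= 1)).all()
    det = ClusterMarkerDetector(cluster_id=1).fit(_nm(df), ca)
    assert list(det.table_["gene"]) == list(
        cluster_markers(_nm(df), ca, 1).table["gene"]
    )
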