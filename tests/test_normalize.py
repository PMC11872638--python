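"""Median-of-totals normalization and per-gene spatial Z-scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tomoseq import (
    MedianOfTotalsNormalizer,
    SpatialZScorer,
    TissueDesign,
    apply_filters,
    normalize_counts,
    simulate_tissue,
    spatial_profile,
    zscore,
)


def test_worked_example_direct_arithmetic():
    # totals 20, 20, 10; median 20 -> each column scaled to 20
    c = pd.DataFrame([[10, 0, 5], [10, 20, 5]], index=["A", "B"], columns=["S1", "S2", "S3"])
    nm = normalize_counts(c)
    assert nm.scale_constant == 20
    expected = pd.DataFrame(
        [[10.0, 0.0, 10.0], [10.0, 20.0, 10.0]], index=["A", "B"], columns=c.columns
    )
    pd.testing.assert_frame_equal(nm.values, expected)


def test_equal_totals_is_identity():
    c = pd.DataFrame([[1, 2], [3, 2]], index=["A", "B"], columns=["S1", "S2"])
    nm = normalize_counts(c)
    pd.testing.assert_frame_equal(nm.values, c.astype(float))


@settings(max_examples=50, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_column_sums_equal_median_and_ranks_preserved(seed):
    rng = np.random.default_rng(seed)
    c = pd.DataFrame(
        rng.integers(0, 50, size=(6, 5)) + 1,  # +1 avoids zero-total slices
        index=[f"G{i}" for i in range(6)],
        columns=[f"S{j}" for j in range(5)],
    )
    nm = normalize_counts(c)
    colsums = nm.values.sum(axis=0).to_numpy()
    assert np.allclose(colsums, nm.scale_constant, rtol=1e-9)
    # positive per-column scaling preserves within-slice gene ranking
    for s in c.columns:
        pd.testing.assert_series_equal(
            c[s].rank(), nm.values[s].rank(), check_names=False
        )


def test_zero_total_slice_is_error():
    c = pd.DataFrame({"S1": [1], "S2": [0]}, index=["A"])
    with pytest.raises(ValueError, match="S2"):
        normalize_counts(c)


def test_zscore_example_and_moments():
    c = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["A", "B"],
                     columns=["S1", "S2", "S3"])
    zm = zscore(pd.DataFrame(c))
    assert np.allclose(zm.z.loc["A"], [-1, 0, 1])  # sample sd of (1,2,3) is 1
    assert np.allclose(zm.z.loc["B"], 0.0) and bool(zm.flags["B"])
    assert not zm.flags["A"]
    assert zm.z.loc["A"].mean() == pytest.approx(0, abs=1e-12)
    assert zm.z.loc["A"].std(ddof=1) == pytest.approx(1, abs=1e-12)


def test_zscore_population_sd_option():
    zm = zscore(pd.DataFrame([[1.0, 2.0, 3.0]], index=["A"]), ddof=0)
    assert np.allclose(zm.z.loc["A"], np.array([-1, 0, 1]) / np.sqrt(2 / 3))


def test_zscore_single_section_error():
    with pytest.raises(ValueError, match="2 sections"):
        zscore(pd.DataFrame({"S1": [1.0, 2.0]}))


def test_zscore_moments_on_random_input():
    rng = np.random.default_rng(3)
    zm = zscore(pd.DataFrame(rng.random((40, 25))))
    ok = ~zm.flags.to_numpy()
    assert np.abs(zm.z.to_numpy()[ok].mean(axis=1)).max() < 1e-9
    assert np.abs(zm.z.to_numpy()[ok].std(axis=1, ddof=1) - 1).max() < 1e-9


def test_spatial_profile_shape_and_flags(default_sim):
    m, _ = default_sim
    nm = normalize_counts(apply_filters(m))
    zm = zscore(nm)
    prof = spatial_profile(zm, ["NPPA"])
    assert len(prof) == len(nm.sections)
    assert list(prof["position"]) == list(range(1, len(nm.sections) + 1))
    with pytest.raises(KeyError, match="NOT_A_GENE"):
        spatial_profile(zm, ["NPPA", "NOT_A_GENE"])


def test_flagged_gene_trace_is_zero():
    values = pd.DataFrame([[2.0, 2.0, 2.0]], index=["FLAT"], columns=["S1", "S2", "S3"])
    zm = zscore(values)
    prof = spatial_profile(zm, "FLAT")
    assert (prof["z"] == 0).all() and prof["zero_variance"].all()


def test_planted_marker_elevated_in_its_domain():
    """Generative fold >= 4 must show up in the spatial Z trace (10 seeds)."""
    for seed in range(10):
        m, truth = simulate_tissue(TissueDesign(seed=seed))
        qc = apply_filters(m)
        zm = zscore(normalize_counts(qc))
        marker = next(
            g for g in truth.markers_of_domain["stress"] if g in zm.z.index
        )
        in_dom = [s for s in zm.sections if truth.domain_of_section[s] == "stress"]
        out_dom = [s for s in zm.sections if truth.domain_of_section[s] != "stress"]
        assert zm.z.loc[marker, in_dom].mean() > zm.z.loc[marker, out_dom].mean()


def test_estimator_wrappers(default_sim):
    m, _ = default_sim
    qc = apply_filters(m)
    norm = MedianOfTotalsNormalizer().fit(qc)
    nm = norm.transform(qc)
    assert norm.scale_constant_ == nm.scale_constant
    zs = SpatialZScorer(ddof=1).fit(nm)
    assert set(zs.zero_variance_genes_) == set(zs.result_.flags.index[zs.result_.flags])
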