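"""Synthetic layered-tissue generator: determinism, mean model, ground truth."""

import numpy as np
import pytest

from tomoseq import GroundTruth, TissueDesign, read_truth, simulate_tissue, write_truth
from tomoseq.simulate import DesignError, make_motif_annotation, simulate_promoters


def test_seeded_determinism():
    d = TissueDesign(seed=5, n_genes=200, n_sections=40,
                     domain_layout=[("fatty", 10), ("myocardial", 20), ("stress", 10)],
                     n_markers_per_domain=10, n_low_depth_slices=0)
    m1, t1 = simulate_tissue(d)
    m2, t2 = simulate_tissue(TissueDesign(**{**d.__dict__}))
    assert m1.counts.equals(m2.counts)
    assert t1.domain_of_section == t2.domain_of_section
    assert t1.motif_positive_genes == t2.motif_positive_genes


def test_default_design_geometry(default_sim):
    m, truth = default_sim
    assert m.n_sections == 173
    assert len(set(truth.domain_of_section.values())) == 5
    assert len(truth.markers_of_domain) == 5
    marker_sets = [set(v) for v in truth.markers_of_domain.values()]
    assert all(len(s) == 50 for s in marker_sets)
    for i, a in enumerate(marker_sets):  # disjoint across domains
        for b in marker_sets[i + 1:]:
            assert not (a & b)
    # canonical symbols land in their domains
    assert "PLIN1" in truth.markers_of_domain["fatty"]
    assert "NPPA" in truth.markers_of_domain["stress"]
    assert "EPAS1" in truth.markers_of_domain["stress"]
    # every truth gene/section exists in the matrix
    genes = set(m.genes)
    assert all(set(v) <= genes for v in truth.markers_of_domain.values())
    assert truth.motif_positive_genes <= genes
    assert set(truth.domain_of_section) == set(m.sections)


def test_gene_classes_from_names(default_sim):
    m, _ = default_sim
    assert len(m.genes_of_class("mitochondrial")) == 13
    assert len(m.genes_of_class("spikein")) == 92


def test_low_depth_slices_straddle_threshold(default_sim):
    m, truth = default_sim
    bio_totals = m.drop_classes().counts.sum(axis=0)
    low = set(truth.expected_low_depth_slices)
    assert len(low) == 20
    assert all(bio_totals[s] < 3000 for s in low)
    assert all(bio_totals[s] >= 3000 for s in m.sections if s not in low)


def test_marker_fold_monte_carlo():
    """Empirical in/out-domain mean ratio of a marker ~ marker_fold (10%)."""
    d = TissueDesign(
        seed=3, n_sections=500, n_genes=100,
        domain_layout=[("a", 250), ("b", 250)],
        n_markers_per_domain=10, marker_fold=4.0,
        depth_log_sigma=0.0, n_low_depth_slices=0,
        n_mito_genes=0, n_spikein_genes=0, mito_fraction_mean=0.0,
    )
    m, truth = simulate_tissue(d)
    marker = truth.markers_of_domain["a"][0]
    in_s = [s for s, dom in truth.domain_of_section.items() if dom == "a"]
    out_s = [s for s, dom in truth.domain_of_section.items() if dom == "b"]
    ratio = m.counts.loc[marker, in_s].mean() / m.counts.loc[marker, out_s].mean()
    assert ratio == pytest.approx(4.0, rel=0.10)


def test_generative_mean_recovery():
    """Empirical per-gene means track the NB mean model (>= 200 sections)."""
    d = TissueDesign(
        seed=8, n_sections=300, n_genes=150,
        domain_layout=[("a", 300)], n_markers_per_domain=0,
        depth_log_sigma=0.0, n_low_depth_slices=0,
        n_mito_genes=0, n_spikein_genes=0, mito_fraction_mean=0.0,
        baseline_mean_log_mu=1.5, baseline_mean_log_sigma=1.0, nb_dispersion=0.3,
    )
    m, _ = simulate_tissue(d)
    # recover the baseline means the generator drew (same seeded stream)
    rng = np.random.default_rng(np.random.SeedSequence([8, 0]))
    mu = rng.lognormal(1.5, 1.0, 150)
    emp = m.counts.mean(axis=1).to_numpy()
    se = np.sqrt((mu + 0.3 * mu**2) / 300)
    z = (emp - mu) / se
    # standardized errors are calibrated: centred, unit scale, thin tails
    assert abs(z.mean()) < 0.2
    assert 0.7 < (z**2).mean() < 1.3
    assert (np.abs(z) < 3).mean() >= 0.97
    assert np.abs(z).max() < 5


@pytest.mark.parametrize(
    "kwargs,field",
    [
        (dict(domain_layout=[("a", 10)], n_sections=20), "domain_layout"),
        (dict(marker_fold=1.0), "marker_fold"),
        (dict(mito_fraction_mean=1.5), "mito_fraction_mean"),
        (dict(n_low_depth_slices=173), "n_low_depth_slices"),
        (dict(n_genes=100, n_markers_per_domain=50), "n_markers_per_domain"),
        (dict(motif_positive_frac_stress=-0.1), "motif_positive_frac_stress"),
    ],
)
def test_invalid_design_names_field(kwargs, field):
    with pytest.raises(DesignError, match=field):
        TissueDesign(**kwargs)


def test_truth_roundtrip(tmp_path, default_sim):
    _, truth = default_sim
    p = tmp_path / "truth.json"
    write_truth(truth, p)
    again = read_truth(p)
    assert again.domain_of_section == {
        k: str(v) for k, v in truth.domain_of_section.items()
    }
    assert {d: set(v) for d, v in again.markers_of_domain.items()} == {
        d: set(v) for d, v in truth.markers_of_domain.items()
    }
    assert again.motif_positive_genes == truth.motif_positive_genes
    assert again.expected_low_depth_slices == truth.expected_low_depth_slices


def test_truth_roundtrip_preserves_empty_marker_set(tmp_path):
    truth = GroundTruth(
        domain_of_section={"S1": "a"},
        markers_of_domain={"a": [], "b": ["G1"]},
        motif_positive_genes=set(),
        expected_low_depth_slices=[],
    )
    p = tmp_path / "t.json"
    write_truth(truth, p)
    again = read_truth(p)
    assert again.markers_of_domain["a"] == []


def test_motif_positive_rates(default_sim):
    _, truth = default_sim
    stress = set(truth.markers_of_domain["stress"])
    pos = truth.motif_positive_genes
    stress_rate = len(pos & stress) / len(stress)
    bg = {g for g in truth.motif_positive_genes if g not in stress}
    # planted 0.5 vs 0.1: binomial slack on 50 / ~1950 genes
    assert 0.3 <= stress_rate <= 0.7
    assert len(bg) / 1950 < 0.15


def test_motif_annotation_and_promoters(default_sim):
    from tomoseq import PWM

    _, truth = default_sim
    universe = sorted(set().union(*truth.markers_of_domain.values()))
    annot = make_motif_annotation(truth, universe, n_decoys=3, seed=1)
    assert set(annot.sets) == {"EPAS1", "DECOY001", "DECOY002", "DECOY003"}
    assert annot.sets["EPAS1"] == truth.motif_positive_genes & set(universe)

    counts = np.zeros((4, 10))
    counts[0] = 12  # poly-A consensus
    pwm = PWM("M", "TEST", counts)
    seqs = simulate_promoters(truth, universe[:20], pwm, length=60, seed=2)
    for g in universe[:20]:
        assert len(seqs[g]) == 60
        if g in truth.motif_positive_genes:
            assert pwm.consensus in seqs[g]
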