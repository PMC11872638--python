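"""Synthetic layered-tissue Tomo-seq data with ground truth.

Emulates a 1D cryosection series through a diseased ventricular wall: ~173
ordered 100 um sections spanning epi- to endocardium, organised into five
contiguous transcriptional domains (epicardial fatty tissue, working
myocardium, a mitochondrial-stress cardiomyocyte domain, a thin endocardial
domain, and a fibroblast-rich domain), with mitochondrial genes, ERCC
spike-ins, per-slice sequencing-depth variation including sub-3000-read
slices, and a motif-positive gene subset concentrated among the
stress-domain markers.

Counts are negative binomial (gamma-Poisson) with

    mean(g, s) = baseline(g) * fold(g, domain(s)) * depth(s)
    var = mean + dispersion * mean^2

Marker genes of a domain are elevated ``marker_fold``-fold inside it.  In
the fatty domain, non-fatty-marker genes are additionally damped by
``fatty_baseline_factor``, reflecting the shift in tissue composition away
from myocardium; this makes the fibro-fatty area the transcriptionally most
distinct region, as in the tissue the generator imitates.  Mitochondrial
genes track each slice's biological signal so that they contribute about
``mito_fraction_mean`` of its reads; spike-ins have depth-independent means
(a fixed amount of control RNA is added per section).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, infer_gene_classes

# QC read threshold the engineered low-depth slices must undercut
LOW_DEPTH_QC_THRESHOLD = 3000

DEFAULT_DOMAIN_LAYOUT = (
    ("fatty", 40),
    ("myocardial", 55),
    ("stress", 30),
    ("endocardial", 10),
    ("fibroblast", 38),
)

# recognisable markers seeded into each domain's marker set
CANONICAL_MARKERS = {
    "fatty": ["PLIN1", "ADIPOQ", "CD36"],
    "myocardial": ["TTN", "MYH7", "MYBPC3"],
    "stress": ["NPPA", "SOD2", "BNIP3L", "EPAS1", "CRYAB", "GADD45A", "ADM"],
    "endocardial": ["PECAM1", "NPR3", "VWF"],
    "fibroblast": ["COL1A1", "COL3A1", "POSTN"],
}

MT_GENE_NAMES = [
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CYB", "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8",
]


class DesignError(ValueError):
    pass


@dataclass
class TissueDesign:
    """Parameters of the synthetic layered tissue (see module docstring)."""

    n_sections: int = 173
    domain_layout: tuple = None  # type: ignore[assignment]  # ((domain_id, n_sections), ...)
    n_genes: int = 2000
    n_markers_per_domain: int = 50
    marker_fold: float = 4.0
    baseline_mean_log_mu: float = 1.5
    baseline_mean_log_sigma: float = 1.0
    nb_dispersion: float = 0.3
    depth_log_mu: float = 0.0
    depth_log_sigma: float = 0.25
    n_low_depth_slices: int = 20
    low_depth_target_reads: float = 1000.0
    mito_fraction_mean: float = 0.30
    n_mito_genes: int = 13
    n_spikein_genes: int = 92
    motif_positive_frac_stress: float = 0.5
    motif_positive_frac_background: float = 0.1
    fatty_baseline_factor: float = 0.5
    split_stress_domain: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.domain_layout is None:
            if self.split_stress_domain:
                self.domain_layout = (
                    ("fatty", 40), ("stress", 15), ("myocardial", 55),
                    ("stress", 15), ("endocardial", 10), ("fibroblast", 38),
                )
            else:
                self.domain_layout = DEFAULT_DOMAIN_LAYOUT
        self.domain_layout = tuple((str(d), int(n)) for d, n in self.domain_layout)
        self.validate()

    def validate(self) -> None:
        total = sum(n for _, n in self.domain_layout)
        if total != self.n_sections:
            raise DesignError(
                f"domain_layout: block lengths sum to {total}, not n_sections={self.n_sections}"
            )
        if any(n <= 0 for _, n in self.domain_layout):
            raise DesignError("domain_layout: block lengths must be positive")
        for name in (
            "motif_positive_frac_stress",
            "motif_positive_frac_background",
            "mito_fraction_mean",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DesignError(f"{name}: must be in [0, 1], got {v}")
        if self.marker_fold <= 1:
            raise DesignError(f"marker_fold: must be > 1, got {self.marker_fold}")
        if not 0 <= self.n_low_depth_slices < self.n_sections:
            raise DesignError(
                f"n_low_depth_slices: must be in [0, n_sections), got {self.n_low_depth_slices}"
            )
        if self.n_genes <= 0:
            raise DesignError(f"n_genes: must be positive, got {self.n_genes}")
        n_domains = len(self.domains)
        if self.n_markers_per_domain * n_domains > self.n_genes:
            raise DesignError(
                "n_markers_per_domain: marker sets exceed n_genes "
                f"({self.n_markers_per_domain} x {n_domains} > {self.n_genes})"
            )
        if self.nb_dispersion < 0:
            raise DesignError(f"nb_dispersion: must be >= 0, got {self.nb_dispersion}")
        if self.baseline_mean_log_sigma < 0 or self.depth_log_sigma < 0:
            raise DesignError("log-normal sigma fields must be >= 0")
        if not 0 < self.fatty_baseline_factor <= 1:
            raise DesignError(
                f"fatty_baseline_factor: must be in (0, 1], got {self.fatty_baseline_factor}"
            )

    @property
    def domains(self) -> list:
        seen = []
        for d, _ in self.domain_layout:
            if d not in seen:
                seen.append(d)
        return seen


@dataclass
class GroundTruth:
    """Planted structure of a simulated tissue (test oracle)."""

    domain_of_section: dict  # section_id -> domain_id
    markers_of_domain: dict  # domain_id -> list of gene IDs (disjoint sets)
    motif_positive_genes: set
    expected_low_depth_slices: list
    metadata: dict = field(default_factory=dict)

    def fatty_partition(self) -> dict:
        """Binary section labeling: fatty vs everything else (coarse truth)."""
        return {
            s: ("fatty" if d == "fatty" else "other")
            for s, d in self.domain_of_section.items()
        }


def _section_ids(n: int) -> list:
    width = max(3, len(str(n)))
    return [f"S{i:0{width}d}" for i in range(1, n + 1)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mean + dispersion * mean^2."""
    mean = np.clip(mean, 1e-12, None)
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
    return rng.poisson(lam)


def _build_gene_names(design: TissueDesign, marker_idx: dict) -> list:
    names = [f"G{i:04d}" for i in range(1, design.n_genes + 1)]
    for domain, idxs in marker_idx.items():
        for name, i in zip(CANONICAL_MARKERS.get(domain, []), idxs):
            names[i] = name
    return names


def _simulate_once(design: TissueDesign, attempt: int):
    rng = np.random.default_rng(np.random.SeedSequence([int(design.seed), attempt]))
    sections = _section_ids(design.n_sections)

    domain_of_pos = []
    for d, n in design.domain_layout:
        domain_of_pos.extend([d] * n)
    domain_of_pos = np.array(domain_of_pos)

    baseline = rng.lognormal(
        design.baseline_mean_log_mu, design.baseline_mean_log_sigma, design.n_genes
    )
    perm = rng.permutation(design.n_genes)
    marker_idx = {}
    off = 0
    for d in design.domains:
        marker_idx[d] = np.sort(perm[off : off + design.n_markers_per_domain])
        off += design.n_markers_per_domain

    fold = np.ones((design.n_genes, design.n_sections))
    for d, idxs in marker_idx.items():
        in_domain = domain_of_pos == d
        fold[np.ix_(idxs, in_domain)] = design.marker_fold
    # fatty composition shift: damp every non-fatty-marker gene in the fat
    fatty_cols = domain_of_pos == "fatty"
    if fatty_cols.any() and design.fatty_baseline_factor < 1:
        non_fatty_marker = np.ones(design.n_genes, dtype=bool)
        if "fatty" in marker_idx:
            non_fatty_marker[marker_idx["fatty"]] = False
        fold[np.ix_(non_fatty_marker, fatty_cols)] *= design.fatty_baseline_factor

    bio_mean = baseline[:, None] * fold
    bio_total_mean = bio_mean.sum(axis=0)

    depth = rng.lognormal(design.depth_log_mu, design.depth_log_sigma, design.n_sections)
    low_idx = np.sort(
        rng.choice(design.n_sections, size=design.n_low_depth_slices, replace=False)
    )
    depth[low_idx] = design.low_depth_target_reads / bio_total_mean[low_idx]

    mean_bio = bio_mean * depth[None, :]

    f = design.mito_fraction_mean
    w = rng.lognormal(0.0, 0.5, design.n_mito_genes)
    w = w / w.sum() if design.n_mito_genes else w
    mean_mito = (
        w[:, None] * (f / (1.0 - f)) * (bio_total_mean * depth)[None, :]
        if design.n_mito_genes
        else np.zeros((0, design.n_sections))
    )
    mu_spike = rng.lognormal(2.0, 1.0, design.n_spikein_genes)
    mean_spike = np.repeat(mu_spike[:, None], design.n_sections, axis=1)

    mean_all = np.vstack([mean_bio, mean_mito, mean_spike])
    counts = _nb_draw(rng, mean_all, design.nb_dispersion)

    gene_names = _build_gene_names(design, marker_idx)
    mito_names = (MT_GENE_NAMES * (design.n_mito_genes // 13 + 1))[: design.n_mito_genes]
    if design.n_mito_genes > 13:
        mito_names = [f"MT-G{i:03d}" for i in range(1, design.n_mito_genes + 1)]
    spike_names = [f"ERCC-{i:05d}" for i in range(1, design.n_spikein_genes + 1)]
    all_names = gene_names + mito_names + spike_names

    df = pd.DataFrame(counts, index=all_names, columns=sections)
    matrix = CountMatrix(df, infer_gene_classes(all_names))

    markers_of_domain = {
        d: [gene_names[i] for i in idxs] for d, idxs in marker_idx.items()
    }
    stress_markers = set(markers_of_domain.get("stress", []))
    motif_pos = set()
    for g, name in enumerate(gene_names):
        rate = (
            design.motif_positive_frac_stress
            if name in stress_markers
            else design.motif_positive_frac_background
        )
        if rng.random() < rate:
            motif_pos.add(name)

    truth = GroundTruth(
        domain_of_section=dict(zip(sections, domain_of_pos)),
        markers_of_domain=markers_of_domain,
        motif_positive_genes=motif_pos,
        expected_low_depth_slices=[sections[i] for i in low_idx],
        metadata={"seed": design.seed, "attempt": attempt},
    )
    return matrix, truth


def simulate_tissue(design: TissueDesign) -> tuple[CountMatrix, GroundTruth]:
    """Simulate counts + truth; bit-identical for identical (design, seed).

    When low-depth slices are engineered, the draw is checked against the
    3000-read QC threshold (post mito/spike-in exclusion): engineered slices
    must fall below it and all others clear it.  A violating draw is
    rejected and deterministically redrawn (recorded in truth.metadata).
    """
    design.validate()
    max_attempts = 20
    for attempt in range(max_attempts):
        matrix, truth = _simulate_once(design, attempt)
        if design.n_low_depth_slices == 0:
            return matrix, truth
        bio = matrix.drop_classes()
        totals = bio.counts.sum(axis=0)
        low = set(truth.expected_low_depth_slices)
        ok_low = all(totals[s] < LOW_DEPTH_QC_THRESHOLD for s in low)
        ok_high = all(
            totals[s] >= LOW_DEPTH_QC_THRESHOLD for s in matrix.sections if s not in low
        )
        if ok_low and ok_high:
            if attempt:
                truth.metadata["rejected_draws"] = attempt
                warnings.warn(
                    f"depth draw rejected {attempt} time(s) before satisfying "
                    "the low-depth slice invariant"
                )
            return matrix, truth
    raise RuntimeError(
        "could not generate a dataset satisfying the low-depth slice invariant "
        f"in {max_attempts} attempts; the design's depth/mean settings leave "
        "slices too close to the 3000-read threshold"
    )


# -- truth I/O --------------------------------------------------------------

def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "domain_of_section": dict(truth.domain_of_section),
        "markers_of_domain": {d: sorted(g) for d, g in truth.markers_of_domain.items()},
        "motif_positive_genes": sorted(truth.motif_positive_genes),
        "expected_low_depth_slices": list(truth.expected_low_depth_slices),
        "metadata": truth.metadata,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        domain_of_section=payload["domain_of_section"],
        markers_of_domain={d: list(g) for d, g in payload["markers_of_domain"].items()},
        motif_positive_genes=set(payload["motif_positive_genes"]),
        expected_low_depth_slices=list(payload["expected_low_depth_slices"]),
        metadata=payload.get("metadata", {}),
    )


# -- companion fixtures for the enrichment stage ----------------------------

def make_motif_annotation(
    truth: GroundTruth,
    universe,
    motif_name: str = "EPAS1",
    n_decoys: int = 19,
    decoy_rate: float = 0.1,
    seed: int = 0,
):
    """Annotation with the planted motif term plus random decoy terms.

    Decoy terms contain each universe gene independently with probability
    ``decoy_rate``, emulating unrelated transcription-factor target sets.
    """
    from .enrichment import GeneSetAnnotation

    rng = np.random.default_rng(seed)
    universe = sorted(set(universe))
    sets = {motif_name: set(truth.motif_positive_genes) & set(universe)}
    for i in range(1, n_decoys + 1):
        mask = rng.random(len(universe)) < decoy_rate
        sets[f"DECOY{i:03d}"] = {g for g, m in zip(universe, mask) if m}
    return GeneSetAnnotation(sets=sets, universe=set(universe))


def simulate_promoters(
    truth: GroundTruth,
    genes,
    pwm,
    length: int = 500,
    seed: int = 0,
) -> dict:
    """Random promoter sequences with the motif consensus embedded in the
    promoters of motif-positive genes."""
    rng = np.random.default_rng(seed)
    consensus = pwm.consensus
    seqs = {}
    for g in genes:
        seq = "".join(rng.choice(list("ACGT"), size=length))
        if g in truth.motif_positive_genes:
            pos = int(rng.integers(0, length - len(consensus) + 1))
            seq = seq[:pos] + consensus + seq[pos + len(consensus):]
        seqs[g] = seq
    return seqs


def write_design(design: TissueDesign, path) -> None:
    Path(path).write_text(json.dumps(asdict(design), indent=1, sort_keys=True) + "\n")
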