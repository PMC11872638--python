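"""End-to-end orchestration: simulate -> QC -> normalize -> cluster ->
markers -> enrichment, driven by one YAML config, with a run manifest.

The manifest records the config snapshot, software version, per-stage output
files with SHA-256 hashes, and per-stage row/column counts (sections in /
retained, genes in / retained, markers found, terms tested / significant).
All stage outputs are plain TSV/JSON, and for a fixed seed and config the
stage outputs are byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cluster import (
    cluster_mean_profiles,
    cluster_sections,
    correlation_matrix,
    write_assignment,
)
from .enrichment import (
    overrepresentation,
    rank_regulators,
    read_gmt,
    write_enrichment,
)
from .io import read_counts, write_counts
from .markers import cluster_markers, write_markers
from .motifs import read_pwm_jaspar, scan_promoters
from .normalize import normalize_counts, zscore
from .qc import apply_filters, write_qc_report
from .simulate import (
    TissueDesign,
    make_motif_annotation,
    simulate_tissue,
    write_truth,
)

log = logging.getLogger("tomoseq")


class ConfigError(ValueError):
    pass


DESIGN_FIELDS = {f.name for f in dataclasses.fields(TissueDesign)} - {"seed"}

DEFAULTS = {
    "seed": 0,
    "outdir": "tomoseq_run",
    "log_level": "INFO",
    "figures": False,
    "simulate": {"enabled": True, "design": {}},
    "counts": {"path": None, "format": "tsv", "class_file": None},
    "qc": {
        "slice_min_reads": 3000,
        "gene_min_count": 5,
        "gene_min_slices": 3,
        "totals": "post",
    },
    "normalize": {"zscore_ddof": 1, "zscore_on": "normalized"},
    "cluster": {"k": 5, "linkage": "complete", "use": "normalized"},
    "markers": {
        "cluster_id": "stress",
        "pseudocount": 1.0,
        "log2fc_min": 0.5,
        "alpha": 0.05,
        "test": "wilcoxon",
    },
    "enrichment": {
        "mode": "auto",  # auto | gmt | pwm | none
        "gmt": None,
        "pwm": None,
        "promoters": None,
        "threshold_fraction": 0.8,
        "alpha": 0.05,
        "n_decoy_terms": 19,
        "decoy_rate": 0.1,
    },
}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "tomoseq_run"
    log_level: str = "INFO"
    figures: bool = False
    simulate: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    normalize: dict = field(default_factory=dict)
    cluster: dict = field(default_factory=dict)
    markers: dict = field(default_factory=dict)
    enrichment: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# nested mappings whose keys are validated elsewhere, not against DEFAULTS
_PASSTHROUGH = {"simulate.design"}


def _merge(defaults: dict, user: dict, prefix: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        uval = user.get(key, None)
        if f"{prefix}{key}" in _PASSTHROUGH:
            out[key] = {**dval, **(uval or {})}
        elif isinstance(dval, dict):
            out[key] = _merge(dval, uval or {}, f"{prefix}{key}.")
        else:
            out[key] = dval if uval is None else uval
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown config key(s): {sorted(prefix + k for k in unknown)}")
    return out


def _check_ranges(cfg: dict) -> None:
    def bad(key, msg):
        raise ConfigError(f"config key {key}: {msg}")

    if cfg["qc"]["slice_min_reads"] < 0:
        bad("qc.slice_min_reads", "must be >= 0")
    if cfg["qc"]["gene_min_count"] < 0:
        bad("qc.gene_min_count", "must be >= 0")
    if cfg["qc"]["gene_min_slices"] < 0:
        bad("qc.gene_min_slices", "must be >= 0")
    if cfg["qc"]["totals"] not in ("pre", "post"):
        bad("qc.totals", "must be 'pre' or 'post'")
    if cfg["cluster"]["k"] < 1:
        bad("cluster.k", "must be >= 1")
    if cfg["cluster"]["linkage"] not in ("complete", "average", "ward-on-distance"):
        bad("cluster.linkage", "unknown linkage")
    if not 0 < cfg["markers"]["alpha"] < 1:
        bad("markers.alpha", "must be in (0, 1)")
    if cfg["markers"]["pseudocount"] < 0:
        bad("markers.pseudocount", "must be >= 0")
    if cfg["markers"]["test"] not in ("wilcoxon", "ttest"):
        bad("markers.test", "must be 'wilcoxon' or 'ttest'")
    if not 0 < cfg["enrichment"]["threshold_fraction"] <= 1:
        bad("enrichment.threshold_fraction", "must be in (0, 1]")
    if not 0 < cfg["enrichment"]["alpha"] < 1:
        bad("enrichment.alpha", "must be in (0, 1)")
    if cfg["enrichment"]["mode"] not in ("auto", "gmt", "pwm", "none"):
        bad("enrichment.mode", "must be auto|gmt|pwm|none")
    unknown_design = set(cfg["simulate"]["design"]) - DESIGN_FIELDS
    if unknown_design:
        bad("simulate.design", f"unknown design field(s): {sorted(unknown_design)}")
    if not cfg["simulate"]["enabled"] and not cfg["counts"]["path"]:
        bad("counts.path", "required when simulate.enabled is false")
    for key in ("gmt", "pwm", "promoters"):
        p = cfg["enrichment"][key]
        if p is not None and not Path(p).exists():
            bad(f"enrichment.{key}", f"file not found: {p}")
    if cfg["counts"]["path"] is not None and not cfg["simulate"]["enabled"]:
        if not Path(cfg["counts"]["path"]).exists():
            bad("counts.path", f"file not found: {cfg['counts']['path']}")


def validate_config(source) -> PipelineConfig:
    """Load + validate a YAML config (path, mapping, or None for defaults)."""
    if source is None:
        user = {}
    elif isinstance(source, dict):
        user = source
    else:
        text = Path(source).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError("config file must contain a YAML mapping")
    cfg = _merge(DEFAULTS, user)
    _check_ranges(cfg)
    return PipelineConfig(**cfg)


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict          # stage -> {"outputs": {path: sha256}, "counts": {...}}
    started: float
    finished: float = 0.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _record(stages: dict, stage: str, outdir: Path, files: list, **counts) -> None:
    stages[stage] = {
        "outputs": {f.name: _sha256(f) for f in files},
        "counts": counts,
    }


def _resolve_marker_cluster(cfg_cluster_id, assignment, truth):
    """'stress' -> the cluster with the largest overlap with the planted
    stress domain (needs simulated truth); integers pass through."""
    if isinstance(cfg_cluster_id, int):
        return cfg_cluster_id
    if cfg_cluster_id != "stress":
        raise ConfigError(
            f"markers.cluster_id must be an integer or 'stress', got {cfg_cluster_id!r}"
        )
    if truth is None:
        raise ConfigError(
            "markers.cluster_id='stress' requires simulated data with ground "
            "truth; set an integer cluster id for real data"
        )
    stress = {s for s, d in truth.domain_of_section.items() if d == "stress"}
    best, best_ov = None, -1
    for lab in sorted(assignment.labels.unique()):
        ov = len(stress & set(assignment.sections_of(lab)))
        if ov > best_ov:
            best, best_ov = int(lab), ov
    return best


def run_all(config: PipelineConfig) -> RunManifest:
    """Execute every stage; returns the manifest (also written to outdir)."""
    cfg = config.to_dict()
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg["log_level"])
    stages: dict = {}
    started = time.time()

    # -- simulate -----------------------------------------------------------
    truth = None
    try:
        if cfg["simulate"]["enabled"]:
            design = TissueDesign(**cfg["simulate"]["design"], seed=cfg["seed"])
            matrix, truth = simulate_tissue(design)
            counts_path = outdir / "counts.tsv"
            write_counts(matrix, counts_path)
            truth_path = outdir / "truth.json"
            write_truth(truth, truth_path)
            _record(
                stages, "simulate", outdir, [counts_path, truth_path],
                genes=matrix.n_genes, sections=matrix.n_sections,
            )
        else:
            matrix = read_counts(
                cfg["counts"]["path"],
                format=cfg["counts"]["format"],
                class_file=cfg["counts"]["class_file"],
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/load' failed: {exc}") from exc

    # -- qc ------------------------------------------------------------------
    try:
        qc = apply_filters(
            matrix,
            slice_min_reads=cfg["qc"]["slice_min_reads"],
            gene_min_count=cfg["qc"]["gene_min_count"],
            gene_min_slices=cfg["qc"]["gene_min_slices"],
            totals=cfg["qc"]["totals"],
        )
        log.info(
            "QC: %d/%d sections retained, %d/%d genes retained",
            len(qc.retained_sections), matrix.n_sections,
            len(qc.retained_genes), matrix.n_genes,
        )
        qc_path = outdir / "qc_report.tsv"
        write_qc_report(qc, qc_path)
        filt_path = outdir / "counts_filtered.tsv"
        write_counts(qc.filtered_matrix, filt_path)
        _record(
            stages, "qc", outdir, [qc_path, filt_path],
            sections_in=matrix.n_sections,
            sections_retained=len(qc.retained_sections),
            genes_in=matrix.n_genes,
            genes_retained=len(qc.retained_genes),
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'qc' failed: {exc}") from exc

    # -- normalize -----------------------------------------------------------
    try:
        nm = normalize_counts(qc)
        zm = zscore(nm, ddof=cfg["normalize"]["zscore_ddof"])
        nm_path = outdir / "normalized.tsv"
        nm.values.to_csv(nm_path, sep="\t", index_label="gene", float_format="%.6g")
        z_path = outdir / "zscores.tsv"
        zm.z.to_csv(z_path, sep="\t", index_label="gene", float_format="%.6g")
        _record(
            stages, "normalize", outdir, [nm_path, z_path],
            scale_constant=nm.scale_constant,
            zero_variance_genes=int(zm.flags.sum()),
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'normalize' failed: {exc}") from exc

    # -- cluster -------------------------------------------------------------
    try:
        cm = correlation_matrix(
            zm if cfg["cluster"]["use"] == "zscore" else nm, use=cfg["cluster"]["use"]
        )
        assignment = cluster_sections(
            cm, k=cfg["cluster"]["k"], linkage=cfg["cluster"]["linkage"]
        )
        corr_path = outdir / "correlation.tsv"
        cm.r.to_csv(corr_path, sep="\t", index_label="section", float_format="%.6g")
        asg_path = outdir / "clusters.tsv"
        write_assignment(assignment, asg_path)
        prof_path = outdir / "cluster_mean_profiles.tsv"
        cluster_mean_profiles(nm, assignment).to_csv(
            prof_path, sep="\t", index_label="gene", float_format="%.6g"
        )
        files = [corr_path, asg_path, prof_path]
        if cfg["figures"]:
            from .plotting import correlation_heatmap

            fig_path = outdir / "correlation_heatmap.png"
            correlation_heatmap(cm, assignment, fig_path)
            files.append(fig_path)
        _record(
            stages, "cluster", outdir, files,
            k=assignment.k, runs=len(assignment.runs),
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'cluster' failed: {exc}") from exc

    # -- markers -------------------------------------------------------------
    try:
        target = _resolve_marker_cluster(
            cfg["markers"]["cluster_id"], assignment, truth
        )
        mt = cluster_markers(
            nm,
            assignment,
            cluster_id=target,
            pseudocount=cfg["markers"]["pseudocount"],
            log2fc_min=cfg["markers"]["log2fc_min"],
            alpha=cfg["markers"]["alpha"],
            test=cfg["markers"]["test"],
        )
        mk_path = outdir / "markers.tsv"
        write_markers(mt, mk_path)
        genes_path = outdir / "enriched_genes.txt"
        genes_path.write_text("\n".join(mt.enriched_genes) + "\n")
        _record(
            stages, "markers", outdir, [mk_path, genes_path],
            cluster_id=target, markers_found=len(mt.enriched_genes),
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'markers' failed: {exc}") from exc

    # -- enrichment ----------------------------------------------------------
    try:
        ecfg = cfg["enrichment"]
        universe = list(nm.genes)
        annot = None
        if ecfg["mode"] in ("gmt",) or (ecfg["mode"] == "auto" and ecfg["gmt"]):
            annot = read_gmt(ecfg["gmt"], universe)
        elif ecfg["mode"] in ("pwm",) or (
            ecfg["mode"] == "auto" and ecfg["pwm"] and ecfg["promoters"]
        ):
            pwms = read_pwm_jaspar(ecfg["pwm"])
            annot = scan_promoters(
                pwms,
                ecfg["promoters"],
                threshold_fraction=ecfg["threshold_fraction"],
                universe=universe,
            )
        elif ecfg["mode"] == "auto" and truth is not None:
            annot = make_motif_annotation(
                truth,
                universe,
                n_decoys=ecfg["n_decoy_terms"],
                decoy_rate=ecfg["decoy_rate"],
                seed=cfg["seed"],
            )
        if annot is not None and mt.enriched_genes:
            er = overrepresentation(mt.enriched_genes, annot)
            en_path = outdir / "enrichment.tsv"
            write_enrichment(er, en_path)
            regs = rank_regulators(er, alpha=ecfg["alpha"])
            reg_path = outdir / "regulators.txt"
            reg_path.write_text("\n".join(map(str, regs)) + "\n")
            _record(
                stages, "enrich", outdir, [en_path, reg_path],
                terms_tested=len(er.table), terms_significant=len(regs),
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'enrich' failed: {exc}") from exc

    manifest = RunManifest(
        config=cfg, version=__version__, stages=stages,
        started=started, finished=time.time(),
    )
    (outdir / "manifest.json").write_text(
        json.dumps(manifest.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    return manifest
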