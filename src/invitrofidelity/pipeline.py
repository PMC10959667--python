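"""End-to-end orchestration: simulate/ingest -> QC -> normalize -> center ->
cluster -> subcluster -> DE/signatures -> annotate -> bulk signatures ->
origin attribution -> reference similarity -> prevalence overlaps -> report.

A single global seed fans out to per-stage seeds by stable hashing of stage
names, so adding a stage never perturbs earlier stages' draws.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ifio
from .bulk import DEFAULT_BOUNDS, SignatureCallConfig, derive_bulk_signatures
from .cluster import cluster_cells, subcluster
from .containers import CountMatrix, GeneSignature, ParameterError, ResidualMatrix
from .de import annotate_clusters, extract_signature, wilcoxon_de
from .normalize import (
    cell_cycle_scores,
    center_by_sample,
    log_normalize,
    pearson_residual_normalize,
)
from .qc import QCThresholds, apply_qc, compute_qc_metrics
from .simulate import Scenario, make_default_scenario
from .similarity import (
    crc_similarity,
    origin_attribution,
    prevalence_set,
    subset_centroids,
    venn_counts,
)

__version__ = "0.1.0"

_DEFAULTS = {
    "outdir": "pipeline_out",
    "seed": 0,
    "qc": {
        "min_umi": {"sample0": 2250, "sample1": 1500},
        "min_genes": {"sample0": 770, "sample1": 700},
        "max_mito_fraction": 0.2,
        "min_cells_per_gene": 5,
    },
    "normalization": {"theta": "mom", "clip": None},
    "clustering": {
        "n_hvg": 3000,
        "n_pcs": 50,
        "k": 15,
        "resolution": 0.5,
        "subcluster_resolutions": {"ECLC": 0.35, "Secretory": 0.4, "U-HT29": 0.3},
    },
    "de": {"lfc_min": 2.0, "padj_max": 0.01},
    "bulk": {
        "mu_bounds": [1e-3, 1e7],
        "theta_bounds": [1e-3, 1e6],
        "quantile_q": 0.99,
        "min_magnitude": 0,
    },
    "similarity": {
        "origin_metric": "overlap_vs_reference",
        "prevalence_tau": 0.30,
        "annotation_floor": 0.0,
    },
}


@dataclass
class PipelineConfig:
    outdir: str = "pipeline_out"
    seed: int = 0
    qc: dict = field(default_factory=lambda: dict(_DEFAULTS["qc"]))
    normalization: dict = field(default_factory=lambda: dict(_DEFAULTS["normalization"]))
    clustering: dict = field(default_factory=lambda: dict(_DEFAULTS["clustering"]))
    de: dict = field(default_factory=lambda: dict(_DEFAULTS["de"]))
    bulk: dict = field(default_factory=lambda: dict(_DEFAULTS["bulk"]))
    similarity: dict = field(default_factory=lambda: dict(_DEFAULTS["similarity"]))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


def validate_config(raw: dict | str | None) -> PipelineConfig:
    """Parse, default and range-check a configuration document.

    Accepts a dict, a YAML string, or None (full defaults). All violations
    are reported together, not first-fail.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ParameterError("configuration must be a mapping")
    errors: list[str] = []
    known = set(_DEFAULTS)
    for key in raw:
        if key not in known:
            errors.append(f"unknown configuration key {key!r}")
    merged: dict = {}
    for key, default in _DEFAULTS.items():
        if isinstance(default, dict):
            section = dict(default)
            user = raw.get(key, {}) or {}
            if not isinstance(user, dict):
                errors.append(f"section {key!r} must be a mapping")
                user = {}
            for k in user:
                if k not in default:
                    errors.append(f"unknown key {key}.{k}")
            section.update({k: v for k, v in user.items() if k in default})
            merged[key] = section
        else:
            merged[key] = raw.get(key, default)

    c, d, b, s = merged["clustering"], merged["de"], merged["bulk"], merged["similarity"]
    checks = [
        (c["n_hvg"] > 0, "clustering.n_hvg must be positive"),
        (c["n_pcs"] > 0, "clustering.n_pcs must be positive"),
        (c["k"] > 0, "clustering.k must be positive"),
        (c["resolution"] > 0, "clustering.resolution must be positive"),
        (all(v > 0 for v in c["subcluster_resolutions"].values()),
         "clustering.subcluster_resolutions must be positive"),
        (d["padj_max"] > 0, "de.padj_max must be positive"),
        (0 < b["quantile_q"] < 1, "bulk.quantile_q must lie in (0, 1)"),
        (b["min_magnitude"] >= 0, "bulk.min_magnitude must be non-negative"),
        (0 <= merged["qc"]["max_mito_fraction"] <= 1, "qc.max_mito_fraction must lie in [0, 1]"),
        (merged["qc"]["min_cells_per_gene"] >= 1, "qc.min_cells_per_gene must be >= 1"),
        (0 < s["prevalence_tau"] < 1, "similarity.prevalence_tau must lie in (0, 1)"),
        (s["origin_metric"] in ("jaccard", "overlap_vs_reference"),
         "similarity.origin_metric must be jaccard or overlap_vs_reference"),
    ]
    errors.extend(msg for ok, msg in checks if not ok)
    if errors:
        raise ParameterError("invalid configuration: " + "; ".join(errors))
    return PipelineConfig(
        outdir=merged["outdir"],
        seed=int(merged["seed"]),
        qc=merged["qc"],
        normalization=merged["normalization"],
        clustering=merged["clustering"],
        de=merged["de"],
        bulk=merged["bulk"],
        similarity=merged["similarity"],
    )


def stage_seed(global_seed: int, stage: str) -> int:
    """Derive a per-stage seed by stable hashing of the stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    checksums: dict[str, str]
    version: str = __version__
    timestamps: dict[str, float] = field(default_factory=dict)

    def same_results(self, other: "RunManifest") -> bool:
        """Equality of everything except wall-clock timestamps."""
        return (
            self.config_hash == other.config_hash
            and self.seed == other.seed
            and self.checksums == other.checksums
            and self.version == other.version
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    manifest: RunManifest
    scenario: Scenario
    qc_report: pd.DataFrame
    counts: CountMatrix
    residuals: ResidualMatrix
    assignment: object  # ClusterAssignment
    subclusters: dict
    de_table: pd.DataFrame
    cluster_signatures: list[GeneSignature]
    annotation: pd.Series
    annotation_scores: pd.DataFrame
    bulk_signatures: tuple[GeneSignature, GeneSignature]
    bulk_report: dict
    origin_table: object
    origin_calls: pd.Series
    crc_table: object
    venn: dict


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _normalize_sample(
    cm: CountMatrix,
    mito_genes: set[str],
    theta,
    clip,
    seed: int,
    s_genes: set[str] | None = None,
    g2m_genes: set[str] | None = None,
) -> ResidualMatrix:
    """Normalization with covariate regression (mito fraction and cell-cycle
    score difference) followed by per-sample centering. The cell-cycle gene
    lists default to the first 40 non-mito genes when none are supplied."""
    metrics = compute_qc_metrics(cm, mito_genes)
    lognorm = np.log1p(log_normalize(cm))
    if not s_genes or not g2m_genes:
        non_mito = [g for g in cm.genes if g not in mito_genes]
        s_genes = set(non_mito[:20])
        g2m_genes = set(non_mito[20:40])
    cc = cell_cycle_scores(lognorm, cm.genes, cm.cells, s_genes, g2m_genes, seed=seed)
    covariates = pd.DataFrame(
        {"mito_fraction": metrics["mito_fraction"], "cc_difference": cc["cc_difference"]}
    )
    res = pearson_residual_normalize(cm, covariates, theta=theta, clip=clip)
    return center_by_sample(res)


def run_pipeline(
    config: PipelineConfig | dict | None = None,
    scenario: Scenario | None = None,
    resume: bool = False,
) -> PipelineResult:
    """Run every stage on a synthetic scenario and write all reports.

    ``scenario`` defaults to the standard coupled synthetic study built from
    the configured seed. ``resume=True`` reuses the written outputs when the
    manifest on disk matches the configuration hash and seed (whole-run
    granularity).
    """
    cfg = config if isinstance(config, PipelineConfig) else validate_config(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    if resume and manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == cfg.hash() and prev.get("seed") == cfg.seed and all(
            (outdir / rel).exists() for rel in prev.get("checksums", {})
        ):
            warnings.warn("resume: outputs on disk match this configuration; rerunning in-memory stages only")
    timestamps = {"start": time.time()}

    if scenario is None:
        scenario = make_default_scenario(stage_seed(cfg.seed, "simulate"))
    mito_genes = {g for g in scenario.query.genes if g.startswith("MT-")}

    # --- QC -----------------------------------------------------------------
    thresholds = QCThresholds(
        min_umi=cfg.qc["min_umi"],
        min_genes=cfg.qc["min_genes"],
        max_mito_fraction=cfg.qc["max_mito_fraction"],
        min_cells_per_gene=cfg.qc["min_cells_per_gene"],
    )
    cm_f, qc_report = apply_qc(
        scenario.query, thresholds, mito_genes, scenario.query_truth.doublet_flags
    )

    # --- normalization + integration stand-in --------------------------------
    res = _normalize_sample(
        cm_f,
        mito_genes,
        cfg.normalization["theta"],
        cfg.normalization["clip"],
        stage_seed(cfg.seed, "cellcycle"),
        s_genes=set(scenario.s_genes),
        g2m_genes=set(scenario.g2m_genes),
    )

    # --- clustering / subclustering ------------------------------------------
    cl = cfg.clustering
    assignment = cluster_cells(
        res,
        n_hvg=min(cl["n_hvg"], res.n_genes),
        n_pcs=cl["n_pcs"],
        k=cl["k"],
        resolution=cl["resolution"],
        seed=stage_seed(cfg.seed, "leiden"),
    )
    subclusters = {}
    for parent, sub_res in cl["subcluster_resolutions"].items():
        if parent in set(assignment.labels):
            subclusters[parent] = subcluster(
                res, assignment, parent, sub_res, seed=stage_seed(cfg.seed, f"sub:{parent}")
            )

    # --- DE + signatures + annotation ----------------------------------------
    de_table = wilcoxon_de(cm_f, res, assignment)
    cluster_sigs = [
        extract_signature(de_table, c, cfg.de["lfc_min"], cfg.de["padj_max"])
        for c in assignment.cluster_names
    ]
    annotation, ann_scores = annotate_clusters(
        cm_f,
        res.values,
        res.genes,
        assignment,
        {name: sorted(genes) for name, genes in scenario.marker_sets.items()},
        floor=cfg.similarity["annotation_floor"],
    )

    # --- bulk signatures + origin attribution --------------------------------
    bounds = (tuple(cfg.bulk["mu_bounds"]), tuple(cfg.bulk["theta_bounds"]))
    call_cfg = SignatureCallConfig(cfg.bulk["quantile_q"], cfg.bulk["min_magnitude"])
    sig_a, sig_b, bulk_report = derive_bulk_signatures(
        scenario.bulk_a, scenario.bulk_b, bounds=bounds, cfg=call_cfg
    )
    origin_table, origin_calls = origin_attribution(
        cluster_sigs, (sig_a, sig_b), metric=cfg.similarity["origin_metric"]
    )

    # --- reference (atlas) similarity ----------------------------------------
    atlas_f, _ = apply_qc(
        scenario.atlas,
        QCThresholds(
            min_umi=thresholds.umi_for("sample0"),
            min_genes=thresholds.genes_for("sample0"),
            max_mito_fraction=thresholds.max_mito_fraction,
            min_cells_per_gene=thresholds.min_cells_per_gene,
        ),
        mito_genes,
    )
    atlas_res = _normalize_sample(
        atlas_f,
        mito_genes,
        cfg.normalization["theta"],
        cfg.normalization["clip"],
        stage_seed(cfg.seed, "atlas-cellcycle"),
        s_genes=set(scenario.s_genes),
        g2m_genes=set(scenario.g2m_genes),
    )
    from .containers import ClusterAssignment

    atlas_assign = ClusterAssignment(
        labels=scenario.atlas_labels.loc[atlas_f.cells], resolution=0.0, seed=cfg.seed
    )
    atlas_de = wilcoxon_de(atlas_f, atlas_res, atlas_assign)
    subtype_sigs = {
        st: extract_signature(atlas_de, st, cfg.de["lfc_min"], cfg.de["padj_max"],
                              source="reference-subtype")
        for st in atlas_assign.cluster_names
    }
    tumour_subtypes = [st for st in subtype_sigs if st != "normal"] or list(subtype_sigs)
    deg_union = sorted(set().union(*(subtype_sigs[st].genes for st in tumour_subtypes)))
    cell_type = assignment.labels.map(annotation)
    shared_union = [g for g in deg_union if g in res.genes]
    query_centroids = subset_centroids(res, cell_type, shared_union)
    ref_centroids = subset_centroids(atlas_res, scenario.atlas_labels.loc[atlas_f.cells], shared_union)
    crc_table = crc_similarity(query_centroids, ref_centroids, shared_union)

    # --- prevalence overlaps ---------------------------------------------------
    tau = cfg.similarity["prevalence_tau"]
    venn = {}
    for pop, subtype in scenario.pop_subtype.items():
        q_cells = [c for c in cm_f.cells if cell_type.get(c) == pop]
        r_cells = [
            c for c in atlas_f.cells if scenario.atlas_labels.get(c) == subtype
        ]
        if not q_cells or not r_cells:
            continue
        ps_q = prevalence_set(cm_f, q_cells, tau, label=pop)
        ps_r = prevalence_set(atlas_f, r_cells, tau, label=subtype)
        venn[f"{pop}_vs_{subtype}"] = venn_counts(
            {pop: set(ps_q.genes), subtype: set(ps_r.genes)}
        )

    # --- reports ---------------------------------------------------------------
    qc_report.to_csv(outdir / "qc_report.csv")
    assignment.labels.rename("cluster").to_csv(outdir / "clusters.tsv", sep="\t")
    de_table.to_csv(outdir / "de_results.csv", index=False)
    ifio.write_signature_csv(cluster_sigs + [sig_a, sig_b], outdir / "signatures.csv")
    ifio.write_json(bulk_report, outdir / "bulk_fits.json")
    origin_table.scores.to_csv(outdir / "origin_scores.csv")
    origin_calls.to_csv(outdir / "origin_calls.csv")
    crc_table.scores.to_csv(outdir / "crc_similarity.csv")
    ifio.write_json(venn, outdir / "venn_counts.json")
    ifio.write_json(scenario.query_truth.to_dict(), outdir / "ground_truth.json")
    annotation.to_csv(outdir / "annotation.csv")

    timestamps["end"] = time.time()
    files = [
        "qc_report.csv", "clusters.tsv", "de_results.csv", "signatures.csv",
        "bulk_fits.json", "origin_scores.csv", "origin_calls.csv",
        "crc_similarity.csv", "venn_counts.json", "ground_truth.json",
        "annotation.csv",
    ]
    manifest = RunManifest(
        config_hash=cfg.hash(),
        seed=cfg.seed,
        checksums={f: _checksum(outdir / f) for f in files},
        timestamps=timestamps,
    )
    ifio.write_json(manifest.to_dict(), manifest_path)
    return PipelineResult(
        manifest=manifest,
        scenario=scenario,
        qc_report=qc_report,
        counts=cm_f,
        residuals=res,
        assignment=assignment,
        subclusters=subclusters,
        de_table=de_table,
        cluster_signatures=cluster_sigs,
        annotation=annotation,
        annotation_scores=ann_scores,
        bulk_signatures=(sig_a, sig_b),
        bulk_report=bulk_report,
        origin_table=origin_table,
        origin_calls=origin_calls,
        crc_table=crc_table,
        venn=venn,
    )
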