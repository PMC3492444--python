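"""End-to-end orchestration of the two analysis contrasts.

The *pathology* contrast (CP-AD + P-AD vs. N) runs differential expression
(FDR < 0.05 attempted first, raw permutation alpha as fallback), category
over-representation, hierarchical clustering with bootstrap support on the
stricter DEG set, and the interactome differential-correlation signature.
The *manifestation* contrast (CP-AD vs. P-AD) runs differential expression
and — because a handful of small-sample DEGs is not statistically reliable
— the bolstered-error triplet classifier search over SVM-preselected genes.

Every stage writes its table into the run directory and is declared in a
JSON manifest together with the seeds used, so single stages can be re-run
from cached upstream outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clustering as _clustering
from . import cohort as _cohort
from . import diffexpr as _diffexpr
from . import enrichment as _enrichment
from . import network as _network
from . import classifier as _classifier
from . import preprocessing as _pre
from . import synthetic as _syn

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run (YAML-loadable)."""

    out_dir: str = "run"
    contrast: str = "both"  # pathology | manifestation | both
    seed: int = 0
    alpha: float = 0.01
    alpha_cluster: float = 0.005
    fdr_alpha: float = 0.05
    n_perm: int = 1000
    n_boot: int = 1000
    span: float = 0.4
    collapse: str = "arrays"
    ad_pathology_rule: str = "or"
    target_count: int = 200
    top_k: int = 10
    # data sources: either paths to existing inputs ...
    spot_dir: str | None = None
    manifest_path: str | None = None
    subjects_path: str | None = None
    matrix_path: str | None = None  # pre-normalized matrix (skips preprocessing)
    interactome_path: str | None = None
    annotation_path: str | None = None
    # ... or a synthetic experiment specification
    synthetic: dict | None = None

    def __post_init__(self):
        for name in ("alpha", "alpha_cluster", "fdr_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.contrast not in ("pathology", "manifestation", "both"):
            raise ValueError(f"unknown contrast {self.contrast!r}")
        for name in ("spot_dir", "manifest_path", "subjects_path", "matrix_path",
                     "interactome_path", "annotation_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"{name} does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _seed_for(config: RunConfig, stage: int) -> int:
    return int(np.random.SeedSequence(entropy=config.seed, spawn_key=(100 + stage,))
               .generate_state(1)[0] % (2**31))


def _default_signal(n_genes: int) -> _syn.PlantedSignal:
    """Planted structure of the default synthetic run, scaled to platform
    size: up to 40 DEGs at 2-fold effect, up to 5 differential-correlation
    hubs with 4 interactors each, one 3-gene class signature."""
    ids = _syn.gene_ids(n_genes)
    n_de = min(40, max(2, n_genes // 8))
    n_hubs = min(5, max(1, n_genes // 60))
    while n_de + n_hubs * 5 + 3 > n_genes:  # hubs consume 4 free interactors each
        n_de = max(2, n_de // 2)
        n_hubs = max(0, n_hubs - 1)
    de = tuple((ids[i], 1.0, "up" if i % 2 == 0 else "down") for i in range(n_de))
    hubs = tuple((ids[n_de + h], 4, 0.9, -0.1) for h in range(n_hubs))
    triplet = tuple(ids[n_de + n_hubs:n_de + n_hubs + 3])
    return _syn.PlantedSignal(de_genes=de, diffcorr_hubs=hubs,
                              triplet_signature=triplet, triplet_offset=1.5,
                              noise_sd=0.5)


def _load_inputs(config: RunConfig, out: Path, files: dict):
    """Resolve the expression matrix, interactome and annotation inputs."""
    interactome = annotation = None
    truth = None
    if config.matrix_path:
        manifest = pd.read_csv(config.manifest_path, sep="\t").set_index("array_id")
        matrix = _pre.ExpressionMatrix.read_tsv(config.matrix_path, manifest)
    elif config.spot_dir:
        arrays = _pre.read_spot_dir(config.spot_dir)
        manifest = pd.read_csv(config.manifest_path, sep="\t")
        matrix, reports = _pre.preprocess_experiment(
            arrays, manifest, span=config.span, collapse=config.collapse)
        _write_json(out / "normalization_report.json",
                    {k: r.as_dict() for k, r in reports.items()}, files)
    else:
        syn = dict(config.synthetic or {})
        spec = _syn.SyntheticCohortSpec(
            n_cpad=syn.get("n_cpad", 9), n_pad=syn.get("n_pad", 4),
            n_control=syn.get("n_control", 10),
            n_genes=syn.get("n_genes", 1000),
            dye_swap=syn.get("dye_swap", True), seed=config.seed)
        signal = _default_signal(spec.n_genes)
        exp = _syn.generate_expression(spec, signal)
        truth = exp.truth
        _write_json(out / "truth.json", truth, files)
        exp.subjects.to_csv(out / "subjects.tsv", sep="\t", index=False)
        files["subjects"] = "subjects.tsv"
        matrix, reports = _pre.preprocess_experiment(
            exp.arrays, exp.manifest, span=config.span, collapse=config.collapse)
        _write_json(out / "normalization_report.json",
                    {k: r.as_dict() for k, r in reports.items()}, files)
        ids = list(matrix.values.index)
        interactome = _syn.generate_interactome(
            spec.n_genes, syn.get("mean_degree", 4.0), config.seed, ids=ids,
            extra_edges=_syn.truth_edges(truth))
        planted_cat = {"C_planted": [d["gene"] for d in truth["de_genes"]]}
        annotation = _syn.generate_annotation(
            spec.n_genes, syn.get("n_categories", 20), config.seed, ids=ids,
            planted=planted_cat)
    if config.interactome_path:
        interactome = read_interactome(config.interactome_path)
    if config.annotation_path:
        annotation = pd.read_csv(config.annotation_path, sep="\t")
    return matrix, interactome, annotation, truth


def read_interactome(path) -> pd.DataFrame:
    """2-column TSV edge list, or a PSI-MITAB subset (first two id columns)."""
    df = pd.read_csv(path, sep="\t", comment=None)
    if df.shape[1] >= 15 or str(df.columns[0]).startswith("#ID"):
        # PSI-MITAB: take the interactor A/B identifier columns
        ids_a = df.iloc[:, 0].astype(str).str.split(":").str[-1]
        ids_b = df.iloc[:, 1].astype(str).str.split(":").str[-1]
        return pd.DataFrame({"gene_a": ids_a, "gene_b": ids_b})
    return df.iloc[:, :2].set_axis(["gene_a", "gene_b"], axis=1)


def _write_json(path: Path, obj, files: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
    files[path.stem] = path.name


def _mask_for(matrix: _pre.ExpressionMatrix, contrast: str):
    """Relabel columns onto the two contrast sides; error on empty side."""
    side_a, side_b = _cohort.contrast_groups(contrast)
    g = matrix.groups
    lab = pd.Series(
        np.where(g.isin(side_a), "A", np.where(g.isin(side_b), "B", "")),
        index=g.index)
    for side, names in (("A", side_a), ("B", side_b)):
        if (lab == side).sum() == 0:
            raise ValueError(f"group empty: no {'/'.join(names)} samples for contrast {contrast!r}")
    return lab


def _run_de(matrix, lab, config: RunConfig, out: Path, prefix: str, files: dict, report: list):
    res = _diffexpr.permutation_ttest(
        matrix.values, lab, "A", "B", n_perm=config.n_perm,
        seed=_seed_for(config, 1))
    res.to_csv(out / f"{prefix}_ttest.tsv", sep="\t", index_label="gene_id")
    files[f"{prefix}_ttest"] = f"{prefix}_ttest.tsv"
    degs_fdr, counts_fdr = _diffexpr.select_degs(res, config.fdr_alpha, use_fdr=True)
    report.append(f"[{prefix}] FDR<{config.fdr_alpha}: {counts_fdr['n_total']} genes")
    if counts_fdr["n_total"] > 0:
        degs, counts = degs_fdr, counts_fdr
        report.append(f"[{prefix}] using the FDR criterion")
    else:
        degs, counts = _diffexpr.select_degs(res, config.alpha, use_fdr=False)
        report.append(
            f"[{prefix}] fallback P<={config.alpha} (no FDR): "
            f"{counts['n_total']} genes ({counts['n_up']} up / {counts['n_down']} down)")
    degs.to_csv(out / f"{prefix}_degs.tsv", sep="\t", index_label="gene_id")
    files[f"{prefix}_degs"] = f"{prefix}_degs.tsv"
    return res, degs


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured contrasts end-to-end; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    report: list[str] = []
    t0 = time.time()

    matrix, interactome, annotation, truth = _load_inputs(config, out, files)
    matrix.write_tsv(out / "matrix.tsv")
    files["matrix"] = "matrix.tsv"
    matrix.manifest.to_csv(out / "manifest.tsv", sep="\t", index_label="array_id")
    files["manifest"] = "manifest.tsv"
    report.append(f"matrix: {matrix.values.shape[0]} genes x {matrix.values.shape[1]} columns")

    contrasts = [config.contrast] if config.contrast != "both" else ["pathology", "manifestation"]
    for contrast in contrasts:
        logger.info("stage %s: differential expression", contrast)
        lab = _mask_for(matrix, contrast)
        res, degs = _run_de(matrix, lab, config, out, contrast, files, report)

        if contrast == "pathology":
            if annotation is not None and len(degs):
                enr = _enrichment.overrepresentation(
                    degs.index, annotation, matrix.values.index)
                enr.to_csv(out / "pathology_enrichment.tsv", sep="\t", index=False)
                files["pathology_enrichment"] = "pathology_enrichment.tsv"
                report.append(
                    f"[pathology] enrichment: {(enr['p'] <= 0.05).sum()} categories at P<=0.05")
            strict, _ = _diffexpr.select_degs(res, config.alpha_cluster, use_fdr=False)
            if len(strict) >= 2:
                dend, support = _clustering.bootstrap_support(
                    matrix.values, strict.index, n_boot=config.n_boot,
                    seed=_seed_for(config, 2))
                (out / "pathology_dendrogram.nwk").write_text(dend.to_newick(support.support))
                files["pathology_dendrogram"] = "pathology_dendrogram.nwk"
                cut = _clustering.cut_to_k(dend, 2)
                pd.Series(cut, name="cluster").rename_axis("column").to_csv(
                    out / "pathology_clusters.tsv", sep="\t")
                files["pathology_clusters"] = "pathology_clusters.tsv"
                report.append(
                    f"[pathology] clustering on {len(strict)} genes at P<={config.alpha_cluster}")
            if interactome is not None and len(degs):
                seeds = list(strict.index if len(strict) else degs.index)
                subnet = _network.build_subnetwork(seeds, interactome, matrix.values.index)
                scores = _network.diffcorr_signature(
                    subnet, matrix.values, lab, "A", "B",
                    n_perm=config.n_perm, seed=_seed_for(config, 3))
                scores.genes.to_csv(out / "network_scores.tsv", sep="\t", index=False)
                files["network_scores"] = "network_scores.tsv"
                paths = _network.export_network(
                    scores, subnet, out, deg_genes=degs.index)
                for k, p in paths.items():
                    files[f"network_{k}"] = p.name
                n_sig = int(scores.genes["significant"].sum())
                report.append(f"[pathology] network signature: {n_sig} genes at P<=0.05")
        else:  # manifestation: DE is unreliable at this n; classifier search
            used = lab.index[lab != ""]
            complete = matrix.values[used].dropna(axis=0, how="any")
            cand = _classifier.preselect_features(
                complete, lab[used], target_count=config.target_count)
            cands = _classifier.search_triplets(
                complete, lab[used], candidate_genes=cand, top_k=config.top_k)
            table = _classifier.candidates_table(cands)
            table.to_csv(out / "manifestation_triplets.tsv", sep="\t", index=False)
            files["manifestation_triplets"] = "manifestation_triplets.tsv"
            n_sep = int((table["resubstitution_error"] == 0).sum())
            report.append(
                f"[manifestation] triplet search over {len(cand)} preselected genes: "
                f"{n_sep}/{len(table)} returned classifiers separate all samples")

    manifest = {
        "config": asdict(config),
        "seed": config.seed,
        "stage_seeds": {f"stage_{i}": _seed_for(config, i) for i in (1, 2, 3)},
        "files": files,
        "elapsed_s": round(time.time() - t0, 2),
    }
    _write_json(out / "run_manifest.json", manifest, files)
    (out / "report.txt").write_text("\n".join(report) + "\n")
    return out
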