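"""End-to-end orchestration: qc -> scoring -> CNV -> malignant call ->
origin typing -> cohort projection/survival, with independent
metabolomics and spatial branches.

Every run writes a manifest (config echo, per-stage counts, warnings,
output checksums) whether it succeeds or fails, so runs are auditable
and same-seed reruns can be checked for bitwise identity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as aio
from ._utils import lognorm_cp10k
from .malignancy import call_malignant, cnv_burden, infer_cnv_profile, qc_filter
from .metabolism import (
    FluxMatrices,
    PairedMetaboliteTable,
    da_score,
    da_table,
    differential_metabolites,
    metabolite_flux,
    zscore_flux,
)
from .origin import assign_origin, build_reference_centroids, classify_cohort, similarity_scores
from .signatures import derive_signature_from_bulk, ucell_score
from .spatial import annotate_spots, build_signature_matrix, compare_group_fractions, deconvolve_spots
from .survival import km_curve, logrank_test, optimal_cutoff
from .synthetic import (
    REF_SITES,
    SimConfig,
    generate_cohort,
    generate_flux_inputs,
    generate_metabolome,
    generate_paired_bulk,
    generate_reference_sets,
    generate_scrna,
    generate_spots,
)

logger = logging.getLogger(__name__)

_LABEL_TO_TYPE = {
    "AEG-like": "Malignant_AEG",
    "EAC-like": "Malignant_EAC",
    "GAC-like": "Malignant_GAC",
}


@dataclass
class PipelineConfig:
    """All stage toggles, parameters and input paths for one run."""

    outdir: str = "results/pipeline"
    seed: int = 0
    log_level: str = "INFO"
    simulate: bool = True
    # stage toggles
    run_qc: bool = True
    run_scoring: bool = True
    run_cnv: bool = True
    run_malignant: bool = True
    run_origin: bool = True
    run_cohort: bool = True
    run_metabolism: bool = True
    run_spatial: bool = True
    # stage parameters
    r_max: int = 1500
    fc_min: float = 1.2
    top_n: int = 50
    cnv_window: int = 101
    cnv_clamp: float = 3.0
    alpha: float = 0.05
    qrange: tuple = (0.10, 0.90)
    n_markers: int = 50
    threshold_method: str = "kmeans2"
    max_mito: float = 0.20
    min_genes: int = 1000
    reference_celltypes: tuple = ("Tcell", "Bcell")
    # external inputs, used when simulate is false
    matrix_path: str | None = None
    annotation_path: str | None = None
    celltype_path: str | None = None
    cluster_path: str | None = None
    bulk_tumor_path: str | None = None
    bulk_nat_path: str | None = None
    ref_paths: dict = field(default_factory=dict)  # class -> {matrix, meta}
    cohort_matrix_path: str | None = None
    cohort_survival_path: str | None = None
    metab_tumor_path: str | None = None
    metab_normal_path: str | None = None
    pathways_path: str | None = None
    flux_r_path: str | None = None
    flux_s_path: str | None = None
    spots_path: str | None = None
    sim: SimConfig | None = None

    def __post_init__(self) -> None:
        if self.sim is None:
            self.sim = SimConfig(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in raw and raw["sim"] is not None and not isinstance(raw["sim"], SimConfig):
            sim_known = {f.name for f in dataclasses.fields(SimConfig)}
            sim_unknown = set(raw["sim"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            raw = dict(raw)
            raw["sim"] = SimConfig(**raw["sim"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _preflight(cfg: PipelineConfig) -> None:
    """Fail before any computation if an enabled stage lacks its input."""
    if cfg.run_malignant and not (cfg.run_cnv and cfg.run_scoring):
        raise ValueError("run_malignant requires run_cnv and run_scoring")
    if cfg.run_origin and not cfg.run_malignant:
        raise ValueError("run_origin requires run_malignant")
    if cfg.run_cohort and not cfg.run_origin:
        raise ValueError("run_cohort requires run_origin (centroids, signature)")
    if cfg.simulate:
        return
    need: list[tuple[str, str | None]] = []
    if cfg.run_qc or cfg.run_scoring or cfg.run_cnv:
        need += [("matrix_path", cfg.matrix_path), ("annotation_path", cfg.annotation_path)]
    if cfg.run_scoring:
        need += [("bulk_tumor_path", cfg.bulk_tumor_path), ("bulk_nat_path", cfg.bulk_nat_path)]
    if cfg.run_cnv:
        need += [("celltype_path", cfg.celltype_path)]
    if cfg.run_origin:
        need += [("cluster_path", cfg.cluster_path)]
        if not cfg.ref_paths:
            need += [("ref_paths", None)]
    if cfg.run_cohort:
        need += [
            ("cohort_matrix_path", cfg.cohort_matrix_path),
            ("cohort_survival_path", cfg.cohort_survival_path),
        ]
    if cfg.run_metabolism:
        need += [
            ("metab_tumor_path", cfg.metab_tumor_path),
            ("metab_normal_path", cfg.metab_normal_path),
            ("pathways_path", cfg.pathways_path),
            ("flux_r_path", cfg.flux_r_path),
            ("flux_s_path", cfg.flux_s_path),
        ]
    if cfg.run_spatial:
        need += [("spots_path", cfg.spots_path)]
    missing = [name for name, val in need if not val]
    if missing:
        raise ValueError(f"enabled stages need inputs: {sorted(set(missing))}")


def _load_inputs(cfg: PipelineConfig) -> dict:
    """Gather all stage inputs, from the generators or from disk."""
    if cfg.simulate:
        counts, annotation, truth = generate_scrna(cfg.sim)
        refs = generate_reference_sets(cfg.sim)
        bulk_t, bulk_n, _ = generate_paired_bulk(cfg.sim)
        cohort_expr, cohort_surv, _ = generate_cohort(cfg.sim)
        mt, mn, pathways, _ = generate_metabolome(cfg.sim)
        flux_r, flux_s, _ = generate_flux_inputs(cfg.sim)
        spots, _ = generate_spots(cfg.sim)
        return {
            "counts": counts,
            "annotation": annotation,
            "cell_type": truth.cell_type,
            "cluster": truth.cluster,
            "refs": refs,
            "ref_keep": {cls: list(REF_SITES[cls]["keep"]) for cls in refs},
            "bulk": (bulk_t, bulk_n),
            "cohort": (cohort_expr, cohort_surv),
            "metab": (mt, mn, pathways),
            "flux": (flux_r, flux_s),
            "spots": spots,
        }
    out: dict = {"refs": {}, "ref_keep": {}}
    if cfg.matrix_path:
        out["counts"] = aio.read_matrix(cfg.matrix_path)
    if cfg.annotation_path:
        out["annotation"] = aio.read_gene_annotation(cfg.annotation_path)
    if cfg.celltype_path:
        out["cell_type"] = pd.read_csv(cfg.celltype_path, index_col=0).iloc[:, 0]
    if cfg.cluster_path:
        out["cluster"] = pd.read_csv(cfg.cluster_path, index_col=0).iloc[:, 0]
    if cfg.bulk_tumor_path:
        out["bulk"] = (aio.read_matrix(cfg.bulk_tumor_path), aio.read_matrix(cfg.bulk_nat_path))
    for cls, paths in cfg.ref_paths.items():
        counts = aio.read_matrix(paths["matrix"])
        meta = pd.read_csv(paths["meta"], index_col=0)
        out["refs"][cls] = (counts, meta)
        out["ref_keep"][cls] = paths.get("keep_sites", sorted(meta["site"].unique()))
    if cfg.cohort_matrix_path:
        out["cohort"] = (
            aio.read_matrix(cfg.cohort_matrix_path),
            aio.read_survival_csv(cfg.cohort_survival_path),
        )
    if cfg.metab_tumor_path:
        out["metab"] = (
            pd.read_csv(cfg.metab_tumor_path, index_col=0),
            pd.read_csv(cfg.metab_normal_path, index_col=0),
            aio.read_gmt(cfg.pathways_path),
        )
    if cfg.flux_r_path:
        out["flux"] = (
            pd.read_csv(cfg.flux_r_path, index_col=0),
            pd.read_csv(cfg.flux_s_path, index_col=0),
        )
    if cfg.spots_path:
        out["spots"] = aio.read_matrix(cfg.spots_path)
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "aegmap",
        "version": __version__,
        "config": json.loads(json.dumps(dataclasses.asdict(cfg), default=str)),
        "stages": {},
        "results": {},
        "warnings": [],
        "status": "running",
    }
    written: list[Path] = []

    def save(df: pd.DataFrame, name: str) -> None:
        p = outdir / name
        df.to_csv(p)
        written.append(p)

    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _preflight(cfg)
            data = _load_inputs(cfg)
            _run_stages(cfg, data, manifest, save)
        manifest["warnings"] = sorted({str(w.message) for w in caught})
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _finalize(manifest, outdir, written)
        raise
    _finalize(manifest, outdir, written)
    return manifest


def _finalize(manifest: dict, outdir: Path, written: list[Path]) -> None:
    extra = [Path(p) for p in manifest.pop("_extra_files", [])]
    manifest["checksums"] = {
        p.name: _sha256(p) for p in written + [p for p in extra if p.exists()]
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)


def _run_stages(cfg: PipelineConfig, data: dict, manifest: dict, save) -> None:
    counts = data.get("counts")
    annotation = data.get("annotation")
    cell_scores = None

    if cfg.run_qc and counts is not None:
        counts, report = qc_filter(
            counts, annotation, max_mito=cfg.max_mito, min_genes=cfg.min_genes
        )
        manifest["stages"]["qc"] = dataclasses.asdict(report)

    aeg_sig = None
    if cfg.run_scoring:
        bulk_t, bulk_n = data["bulk"]
        aeg_sig = derive_signature_from_bulk(
            bulk_t, bulk_n, fc_min=cfg.fc_min, top_n=cfg.top_n, r_max=cfg.r_max
        )
        p = Path(cfg.outdir) / "aeg_signature.tsv"
        aio.write_signature_tsv(aeg_sig, p)
        manifest.setdefault("_extra_files", []).append(str(p))
        aeg_scores = ucell_score(counts, aeg_sig)
        # unfloored signed score: no point mass at 0, better two-means substrate
        aeg_raw = ucell_score(counts, aeg_sig, floor_at_zero=False)
        cell_scores = pd.DataFrame({"aeg_score": aeg_scores, "aeg_score_raw": aeg_raw})
        manifest["stages"]["scoring"] = {
            "n_positive": len(aeg_sig.positive),
            "n_negative": len(aeg_sig.negative),
            "n_cells_scored": int(len(aeg_scores)),
        }

    if cfg.run_cnv:
        cell_type = data["cell_type"].reindex(counts.index)
        ref_cells = counts.index[cell_type.isin(cfg.reference_celltypes)]
        profile = infer_cnv_profile(
            counts, annotation, ref_cells, k=cfg.cnv_window, clamp=cfg.cnv_clamp
        )
        burden = cnv_burden(profile)
        if cell_scores is None:
            cell_scores = pd.DataFrame(index=counts.index)
        cell_scores["cnv_score"] = burden
        cell_scores["cell_type"] = cell_type
        manifest["stages"]["cnv"] = {
            "n_reference": int(len(ref_cells)),
            "n_genes_profiled": int(profile.values.shape[1]),
            "window": cfg.cnv_window,
        }

    mal_cells = None
    if cfg.run_malignant:
        epi = cell_scores.index[cell_scores["cell_type"] == "Epithelial"]
        call = call_malignant(
            cell_scores.loc[epi, "cnv_score"],
            cell_scores.loc[epi, "aeg_score_raw"],
            method=cfg.threshold_method,
        )
        cell_scores["is_malignant"] = False
        cell_scores.loc[epi, "is_malignant"] = call.is_malignant
        mal_cells = cell_scores.index[cell_scores["is_malignant"]]
        manifest["stages"]["malignant"] = {
            "n_epithelial": int(len(epi)),
            "n_malignant": int(len(mal_cells)),
            "cnv_threshold": call.cnv_threshold,
            "score_threshold": call.score_threshold,
        }

    centroids = None
    if cfg.run_origin:
        centroids = build_reference_centroids(data["refs"], data["ref_keep"])
        sim_scores = similarity_scores(counts.loc[mal_cells], centroids)
        clusters = data["cluster"].reindex(mal_cells)
        assignment = assign_origin(
            sim_scores, cell_scores.loc[mal_cells, "aeg_score"], clusters
        )
        save(assignment, "origin_assignments.csv")
        cell_scores.loc[mal_cells, ["EAC_score", "GAC_score"]] = sim_scores.to_numpy()
        cell_scores.loc[mal_cells, "origin_label"] = clusters.map(assignment["label"]).to_numpy()
        manifest["stages"]["origin"] = {
            "n_clusters": int(assignment.shape[0]),
            "labels": assignment["label"].value_counts().to_dict(),
        }

    if cell_scores is not None:
        save(cell_scores, "cell_scores.csv")

    if cfg.run_cohort:
        cohort_expr, cohort_surv = data["cohort"]
        cohort_assign = classify_cohort(cohort_expr, centroids, aeg_sig)
        merged = cohort_assign.join(cohort_surv)
        save(merged, "cohort_assignments.csv")
        lr = logrank_test(merged["time"], merged["event"], merged["label"])
        medians = {
            lab: km_curve(sub["time"], sub["event"]).median
            for lab, sub in merged.groupby("label")
        }
        cut = optimal_cutoff(
            merged["AEG_z"], merged["time"], merged["event"], qrange=tuple(cfg.qrange)
        )
        manifest["stages"]["cohort"] = {
            "groups": merged["label"].value_counts().to_dict(),
            "logrank_chi2": lr.statistic,
            "logrank_df": lr.df,
            "logrank_p": lr.p_value,
            "km_median_by_group": medians,
            "aeg_cutoff": cut.cutoff,
            "aeg_cutoff_p_selection_biased": cut.p_min,
        }
        manifest["results"]["cohort_logrank_p"] = lr.p_value

    if cfg.run_metabolism:
        mt, mn, pathways = data["metab"]
        table = PairedMetaboliteTable(tumor=mt, normal=mn)
        up, down, res = differential_metabolites(table, alpha=cfg.alpha)
        save(res, "metabolites.csv")
        das = da_score(up, down, pathways, set(res.index))
        save(da_table(das), "da_scores.csv")
        flux_r, flux_s = data["flux"]
        m = metabolite_flux(FluxMatrices(reaction_flux=flux_r, stoichiometry=flux_s))
        save(m, "metabolite_flux.csv")
        save(zscore_flux(m), "metabolite_flux_z.csv")
        manifest["stages"]["metabolism"] = {
            "n_up": len(up),
            "n_down": len(down),
            "n_pathways_scored": len(das),
        }

    if cfg.run_spatial:
        labels = data["cell_type"].reindex(counts.index).copy()
        if mal_cells is not None and cell_scores is not None and "origin_label" in cell_scores.columns:
            mapped = cell_scores.loc[mal_cells, "origin_label"].map(_LABEL_TO_TYPE)
            labels.loc[mal_cells] = mapped.fillna("Malignant_GAC")
        sigmat = build_signature_matrix(counts, labels, n_markers=cfg.n_markers)
        props = deconvolve_spots(data["spots"], sigmat)
        save(props, "spot_proportions.csv")
        ann = annotate_spots(props)
        save(ann.to_frame(), "spot_annotations.csv")
        manifest["stages"]["spatial"] = {
            "n_spots": int(props.shape[0]),
            "spot_types": ann.value_counts().to_dict(),
        }
        groups = ann[ann.isin(["Malignant_AEG", "Malignant_GAC"])]
        if groups.nunique() == 2:
            tests = compare_group_fractions(props.loc[groups.index], groups)
            save(tests, "spot_fraction_tests.csv")
            manifest["stages"]["spatial"]["n_fraction_tests"] = int(tests.shape[0])
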