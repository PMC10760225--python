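"""End-to-end orchestration of the phenotype-learning workflow.

``run_pipeline`` executes the stages in dependency order on a synthetic
cohort — synthesize, encode (Barlow-Twins training + embedding, or the
Gaussian-mixture bypass), the over-clustering artifact pass, artifact
filtering, final clustering, compositional representation, cross-validated
outcome models, and interpretation outputs — writing every artifact into a
run directory with provenance (config hash, seed, package version).  A
completed stage whose provenance matches the current config is skipped on
rerun, so a run can resume after any stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, clustering, composition, encoder, interpret, models, synthetic

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "validate_manifest"]


@dataclass
class PipelineConfig:
    out_dir: str = "runs/demo"
    seed: int = 0
    cohort: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    embedding_mode: str = "bypass"  # "bypass" (Gaussian mixture) or "train"
    encoder: encoder.EncoderConfig = field(default_factory=encoder.EncoderConfig)
    embedding_dim: int = 128
    artifact_resolution: float = 7.0
    final_resolution: float | None = None  # None -> sweep + presence-based selection
    resolution_grid: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0)
    k_neighbors: int = 50
    knn_metric: str = "cosine"
    artifact_filter: bool = True
    artifact_luminance_threshold: float = 215.0
    n_folds: int = 3
    km_tolerance: float = 0.15
    logistic_alpha: float = 0.25
    logistic_l1_ratio: float = 0.5
    cox_alpha: float = 0.35
    cox_l1_ratio: float = 0.01
    clr_pseudocount: float = 1.0
    write_heatmaps: bool = True
    version_tag: str = __version__

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage_done(run: Path, stage: str, cfg_hash: str) -> bool:
    marker = run / f"{stage}.done.json"
    if not marker.exists():
        return False
    try:
        meta = json.loads(marker.read_text())
    except json.JSONDecodeError:
        return False
    return meta.get("config_hash") == cfg_hash


def _mark_done(run: Path, stage: str, config: PipelineConfig) -> None:
    marker = run / f"{stage}.done.json"
    marker.write_text(
        json.dumps(
            {
                "stage": stage,
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "version": config.version_tag,
            },
            indent=1,
        )
    )


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory."""
    run = Path(config.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    (run / "pipeline_config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=1, default=str)
    )

    # -- synthesize ---------------------------------------------------------
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    need_images = config.embedding_mode == "train"
    manifest, store, truth = synthetic.generate_cohort(
        cohort_cfg, tiles="images" if need_images else "none"
    )
    if not _stage_done(run, "synthesize", cfg_hash):
        synthetic.write_manifest(manifest, run / "manifest.tsv")
        synthetic.write_ground_truth(
            truth, run / "ground_truth_tiles.tsv", run / "ground_truth_compositions.tsv"
        )
        _mark_done(run, "synthesize", config)
    tile_meta = truth.tile_phenotype.merge(
        manifest[["slide_id", "institution"]].drop_duplicates(), on="slide_id"
    )

    # -- embed --------------------------------------------------------------
    if config.embedding_mode == "train":
        enc_cfg = dataclasses.replace(config.encoder, seed=config.seed)
        state, trace = encoder.train_encoder(store, manifest, enc_cfg)
        state.save(run / "encoder_state.npz")
        pd.DataFrame(
            {
                "epoch": range(len(trace)),
                "on_diag": [r.on_diag_term for r in trace],
                "off_diag": [r.off_diag_term for r in trace],
                "total": [r.total for r in trace],
            }
        ).to_csv(run / "ssl_loss_trace.tsv", sep="\t", index=False)
        encoder.embed(store, state)
        embeddings, emb_table = store.embedding_matrix(kept_only=True)
        store.provenance = {"config_hash": cfg_hash, "seed": config.seed}
        store.save(run / "tiles.h5")
        tile_order = emb_table["tile_id"].to_numpy()
    else:
        order = tile_meta.sort_values("tile_id", ignore_index=True)
        embeddings = synthetic.sample_embeddings(
            order["phenotype"].to_numpy(),
            dim=config.embedding_dim,
            seed=config.seed,
        )
        tile_order = order["tile_id"].to_numpy()
    _mark_done(run, "embed", config)

    meta = tile_meta.set_index("tile_id").loc[tile_order].reset_index()

    # -- artifact pass ------------------------------------------------------
    graph = clustering.build_knn_graph(embeddings, config.k_neighbors, config.knn_metric)
    over = clustering.leiden_cluster(
        graph, config.artifact_resolution, seed=config.seed, tile_ids=tile_order
    )
    over.to_tsv(run / "assignment_artifact_pass.tsv")
    if config.artifact_filter:
        if config.embedding_mode == "train":
            lum = clustering.tile_luminance(
                np.stack(
                    [
                        store[sid].images[_tile_index(store, sid, tid)]
                        for sid, tid in zip(meta["slide_id"], tile_order)
                    ]
                )
            )
        else:
            # image-free bypass: ground-truth artifact flag plays the role of
            # the visual inspection (white-glass luminance) step
            lum = np.where(meta["is_artifact"], 255.0, 0.0)
        proposal = clustering.propose_artifact_clusters(
            over, lum, config.artifact_luminance_threshold
        )
        proposal.to_csv(run / "artifact_candidates.tsv", sep="\t", index=False)
        artifact_ids = proposal.loc[proposal["artifact_candidate"], "hpc_id"].tolist()
        keep = clustering.filter_artifact_hpcs(over, artifact_ids)
    else:
        keep = np.ones(len(tile_order), bool)
    retained = meta[keep].reset_index(drop=True)
    emb_retained = embeddings[keep]
    _mark_done(run, "artifact_filter", config)

    # -- final clustering ---------------------------------------------------
    if config.final_resolution is None:
        sweep = clustering.resolution_sweep(
            emb_retained,
            retained,
            list(config.resolution_grid),
            k_neighbors=config.k_neighbors,
            metric=config.knn_metric,
            seed=config.seed,
        )
        sweep.to_csv(run / "resolution_sweep.tsv", sep="\t", index=False)
        resolution = clustering.select_resolution(sweep)
    else:
        resolution = config.final_resolution
    graph2 = clustering.build_knn_graph(emb_retained, config.k_neighbors, config.knn_metric)
    assignment = clustering.leiden_cluster(
        graph2, resolution, seed=config.seed, tile_ids=retained["tile_id"].to_numpy()
    )
    assignment.to_tsv(run / "assignment_final.tsv", tile_table=retained)
    _mark_done(run, "cluster", config)

    # -- represent ----------------------------------------------------------
    counts = composition.composition_matrix(assignment, retained, "patient_id", as_counts=True)
    comps = counts.div(counts.sum(axis=1), axis=0)
    clr = composition.clr_matrix(counts, pseudocount=config.clr_pseudocount)
    comps.to_csv(run / "patient_compositions.tsv", sep="\t")
    clr.to_csv(run / "patient_clr.tsv", sep="\t")
    _mark_done(run, "represent", config)

    # -- model --------------------------------------------------------------
    patients = manifest.drop_duplicates("patient_id").reset_index(drop=True)
    patients = patients[patients["patient_id"].isin(clr.index)]
    folds = models.make_folds(
        patients, n_folds=config.n_folds, seed=config.seed, km_tolerance=config.km_tolerance
    )
    clr_p = clr.loc[patients["patient_id"]]
    logit_report = models.cross_validate(
        clr_p, patients, folds, "logistic", config.logistic_alpha, config.logistic_l1_ratio
    )
    cox_report = models.cross_validate(
        clr_p, patients, folds, "cox", config.cox_alpha, config.cox_l1_ratio
    )
    cv_summary = {"logistic": logit_report.summary(), "cox": cox_report.summary()}
    (run / "cv_report.json").write_text(json.dumps(cv_summary, indent=1))
    logit_report.fold_metrics.to_csv(run / "cv_logistic_folds.tsv", sep="\t")
    cox_report.fold_metrics.to_csv(run / "cv_cox_folds.tsv", sep="\t")
    _write_km(run, cox_report)
    _mark_done(run, "model", config)

    # -- interpret ----------------------------------------------------------
    fold0 = cox_report.fold_fits[0]
    test0 = folds.patients(0, "test")
    train0 = folds.patients(0, "train")
    background = clr_p.loc[train0].mean(axis=0).to_numpy()
    shap = interpret.linear_shap(
        fold0.coef, 0.0, clr_p.loc[test0], background, model_ref="cox_fold0"
    )
    shap.values.to_csv(run / "shap_cox_fold0.tsv", sep="\t")
    forest = interpret.forest_summary(cox_report, counts)
    forest.to_csv(run / "forest_summary.tsv", sep="\t", index=False)
    interactions = interpret.adjacency_interactions(
        assignment.to_frame().merge(retained, on="tile_id"), n_clusters=assignment.n_clusters
    )
    interactions.to_csv(run / "interactions.tsv", sep="\t")
    subtype = patients.set_index("patient_id")["outcome_subtype"]
    lr_vs_met = subtype[subtype.isin(["LR", "NM", "DM"])].map(
        {"LR": 0, "NM": 1, "DM": 1}  # overall metastases: nodal + distant
    )
    if lr_vs_met.nunique() > 1 and len(lr_vs_met) >= 3:
        enrich = interpret.spearman_enrichment(comps.loc[lr_vs_met.index], lr_vs_met)
        enrich.to_csv(run / "spearman_lr_vs_metastasis.tsv", sep="\t", index=False)
    if config.write_heatmaps:
        heat_dir = run / "heatmaps"
        heat_dir.mkdir(exist_ok=True)
        tiles_df = assignment.to_frame().merge(retained, on="tile_id")
        for sid in sorted(tiles_df["slide_id"].unique())[:3]:
            img, legend = interpret.hpc_heatmap(tiles_df, sid, assignment.n_clusters)
            interpret.save_heatmap_png(img, heat_dir / f"{sid}.png")
            legend.to_csv(heat_dir / f"{sid}_legend.tsv", sep="\t", index=False)
    _mark_done(run, "interpret", config)
    logger.info("pipeline complete: %s", run)
    return run


def _tile_index(store, sid: str, tid: str) -> int:
    s = store[sid]
    ids = s.tile_ids()
    return ids.index(tid)


def _write_km(run: Path, cox_report: models.CVReport) -> None:
    rows = []
    for f, rg in enumerate(cox_report.risk_groups or []):
        for group, km in (("low", rg.km_low), ("high", rg.km_high)):
            if km is None:
                continue
            for t, s in zip(*km):
                rows.append({"fold": f, "group": group, "time": t, "survival": s})
    if rows:
        pd.DataFrame(rows).to_csv(run / "km_risk_groups.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# manifest validation


def validate_manifest(path: str | Path) -> dict:
    """Schema and consistency checks on a cohort manifest TSV.

    Returns ``{"n_rows": ..., "violations": [...]}``; an empty violations
    list means the manifest is usable.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ValueError(f"cannot read manifest {path}: {exc}") from exc
    violations: list[str] = []
    required = [
        "patient_id",
        "institution",
        "slide_id",
        "outcome",
        "outcome_subtype",
        "dfs_months",
        "event",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        return {"n_rows": len(df), "violations": [f"missing columns: {missing}"]}
    dup = df[df.duplicated(["patient_id", "slide_id"], keep=False)]
    for _, row in dup.drop_duplicates(["patient_id", "slide_id"]).iterrows():
        violations.append(f"duplicated row: patient {row['patient_id']} slide {row['slide_id']}")
    multi_pat = df.groupby("slide_id")["patient_id"].nunique()
    for sid in multi_pat[multi_pat > 1].index:
        violations.append(f"slide {sid} assigned to multiple patients")
    bad_outcome = ~df["outcome"].isin(["good", "poor"])
    if bad_outcome.any():
        violations.append(f"{int(bad_outcome.sum())} rows with outcome outside good/poor")
    bad_sub = ~df["outcome_subtype"].isin(list(synthetic.ARTIFACT_SUBTYPES))
    if bad_sub.any():
        violations.append(f"{int(bad_sub.sum())} rows with unknown outcome_subtype")
    event = pd.to_numeric(df["event"], errors="coerce")
    dfs = pd.to_numeric(df["dfs_months"], errors="coerce")
    if event.isna().any():
        violations.append(f"{int(event.isna().sum())} rows with non-numeric event flag")
    bad_time = (event == 1) & dfs.isna()
    if bad_time.any():
        violations.append(f"{int(bad_time.sum())} rows with event=1 but missing dfs_months")
    if (dfs < 0).any():
        violations.append(f"{int((dfs < 0).sum())} rows with negative dfs_months")
    inconsistent = df.groupby("patient_id")["outcome"].nunique()
    for pid in inconsistent[inconsistent > 1].index:
        violations.append(f"patient {pid} has conflicting outcomes across slides")
    return {"n_rows": len(df), "violations": violations}
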