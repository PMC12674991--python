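"""One-command end-to-end run with a structured config and report bundle.

``run_pipeline`` drives the full analysis — preprocessing, per-model PCA,
human projection, the four stability-selection runs, per-PC GLMs, the
mouse-vs-human variance table, GSEA on the significant PCs and the
sex-stratified comparisons — and writes every stage artifact as TSV plus
a JSON manifest recording seeds, thresholds, orientation flips and
dropped-gene counts.  With ``synthetic: true`` the inputs are generated
in-process and a truth-vs-found recovery summary is added.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    GeneSetCollection,
    read_expression_matrix,
    read_gmt,
    read_homolog_map,
    read_sample_table,
    write_expression_matrix,
    write_gmt,
    write_sample_table,
    write_homolog_map,
    HomologMap,
)
from .model import TransCompR, TransCompRResults
from .simulate import (
    SimConfig,
    SyntheticTruth,
    generate_paired_datasets,
    match_translatable_pc,
    truth_report,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serializable to/from YAML."""

    out_dir: str = "transcompr_run"
    synthetic: bool = True
    sim: dict = field(default_factory=dict)   # SimConfig overrides
    mouse: str | None = None
    human: str | None = None
    mouse_meta: str | None = None
    human_meta: str | None = None
    homologs: str | None = None
    gmt: list[str] = field(default_factory=list)
    skip_log2: bool = False  # inputs already on log scale
    cum_var_threshold: float = 0.80
    frequency_threshold: float = 50.0
    glm_alpha: float = 0.05
    gsea_fdr: float = 0.25
    sexdiff_alpha: float = 0.05
    min_age: float | None = 65.0
    region: str | None = "hippocampus"
    log2_offset: float = 1.0
    rounds: int = 100
    folds: int = 5
    nperm: int = 2000
    heatmap_k: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cum_var_threshold", "glm_alpha", "gsea_fdr", "sexdiff_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name}={v} must lie in (0, 1)")
        if not self.synthetic:
            missing = [
                n
                for n in ("mouse", "human", "mouse_meta", "human_meta", "homologs")
                if getattr(self, n) is None
            ]
            if missing:
                raise ValueError(f"non-synthetic run needs paths for {missing}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class ReportBundle:
    """In-memory handles plus the on-disk artifact directory."""

    out_dir: Path
    results: TransCompRResults
    enrichment: dict[str, dict[str, object]]
    sexdiff: dict[str, object]
    manifest: dict
    truth: SyntheticTruth | None = None
    recovery: pd.DataFrame | None = None


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %-12s %.2fs", name, t1 - t0)
    return t1


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis described by ``config``.

    The master seed is deterministically split into independent per-stage
    streams (simulation, selection, GSEA), so e.g. changing ``nperm``
    does not perturb the LASSO folds.  Any stage failure propagates with
    the stage name; artifacts written before the failure remain on disk.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    sim_ss, fit_ss, gsea_ss = ss.spawn(3)
    seeds = {
        "master": config.seed,
        "simulate": int(sim_ss.generate_state(1)[0] % 2**31),
        "fit": int(fit_ss.generate_state(1)[0] % 2**31),
        "gsea": int(gsea_ss.generate_state(1)[0] % 2**31),
    }
    t0 = time.perf_counter()

    stage = "load"
    truth = None
    collections: list[GeneSetCollection] = []
    try:
        if config.synthetic:
            stage = "simulate"
            sim_cfg = SimConfig(**{"seed": seeds["simulate"], **config.sim})
            mouse, mouse_meta, human, human_meta, truth = generate_paired_datasets(sim_cfg)
            collections = [truth.gene_sets]
            write_expression_matrix(mouse, out / "mouse_expression.tsv")
            write_expression_matrix(human, out / "human_expression.tsv")
            write_sample_table(mouse_meta, out / "mouse_samples.tsv")
            write_sample_table(human_meta, out / "human_samples.tsv")
            homologs = HomologMap(
                list(zip(mouse.genes, human.genes))
            )
            write_homolog_map(homologs, out / "homologs.tsv")
            write_gmt(truth.gene_sets, out / "gene_sets.gmt")
        else:
            mouse = read_expression_matrix(config.mouse, species="mouse")
            human = read_expression_matrix(config.human, species="human")
            if config.skip_log2:
                mouse.state = human.state = "log2"
            mouse_meta = read_sample_table(config.mouse_meta)
            human_meta = read_sample_table(config.human_meta)
            homologs = read_homolog_map(config.homologs)
            collections = [read_gmt(p) for p in config.gmt]
        t0 = _stage(stage, t0)

        stage = "fit"
        model = TransCompR(
            mouse,
            human,
            mouse_meta,
            human_meta,
            homologs,
            cum_var_threshold=config.cum_var_threshold,
            min_age=config.min_age,
            region=config.region,
            log2_offset=config.log2_offset,
        )
        results = model.fit(
            rounds=config.rounds,
            folds=config.folds,
            seed=seeds["fit"],
            frequency_threshold=config.frequency_threshold,
            glm_alpha=config.glm_alpha,
        )
        t0 = _stage(stage, t0)

        stage = "write-fit"
        for name, table in results.frequency_tables.items():
            table.to_csv(out / f"lasso_frequency_{name.replace('+', '_')}.tsv", sep="\t")
        results.selection.to_csv(out / "selection_summary.tsv", sep="\t")
        results.glm_results.to_csv(out / "glm_table.tsv", sep="\t", index=False)
        results.variance_table.to_csv(out / "variance_table.tsv", sep="\t", index=False)
        results.human_scores.scores.to_csv(out / "human_scores.tsv", sep="\t")
        if results.collinearity is not None:
            results.collinearity.to_csv(out / "collinearity.tsv", sep="\t", index=False)
        t0 = _stage(stage, t0)

        stage = "gsea"
        enrichment: dict[str, dict[str, object]] = {}
        for pc in results.significant_pcs:
            enrichment[pc] = {}
        for ci, coll in enumerate(collections):
            per_pc = results.gsea(
                coll, nperm=config.nperm, seed=seeds["gsea"] + ci
            )
            cname = Path(str(coll.source)).stem or f"collection{ci}"
            for pc, res in per_pc.items():
                enrichment.setdefault(pc, {})[cname] = res
                tbl = res.table.copy()
                tbl["leading_edge"] = tbl["leading_edge"].map(",".join)
                safe = pc.replace(" ", "_")
                tbl.to_csv(out / f"gsea_{safe}_{cname}.tsv", sep="\t", index=False)
        t0 = _stage(stage, t0)

        stage = "posthoc"
        sexdiff = results.sex_stratified(alpha=config.sexdiff_alpha)
        for pc, res in sexdiff.items():
            safe = pc.replace(" ", "_")
            res.table.to_csv(out / f"sexdiff_{safe}.tsv", sep="\t", index=False)
            res.group_summary.to_csv(
                out / f"sexdiff_groups_{safe}.tsv", sep="\t", index=False
            )
            mat, col_order = results.heatmap_matrix(pc, k=config.heatmap_k)
            mat.to_csv(out / f"heatmap_{safe}.tsv", sep="\t", index_label="gene")
        t0 = _stage(stage, t0)
    except Exception as exc:  # noqa: BLE001 - annotate and re-raise
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc

    recovery = None
    if truth is not None:
        recovery = _recovery_summary(results, truth, enrichment, config)
        recovery.to_csv(out / "recovery_summary.tsv", sep="\t", index=False)
        truth_report(truth).to_csv(out / "truth_report.tsv", sep="\t", index=False)

    manifest = {
        "seeds": seeds,
        "spec_seeds": results.params["spec_seeds"],
        "thresholds": {
            "cum_var": config.cum_var_threshold,
            "frequency": config.frequency_threshold,
            "glm_alpha": config.glm_alpha,
            "gsea_fdr": config.gsea_fdr,
            "sexdiff_alpha": config.sexdiff_alpha,
        },
        "rounds": config.rounds,
        "folds": config.folds,
        "nperm": config.nperm,
        "orientation_flips": results.orientation,
        "n_genes_aligned": len(results.aligned.gene_index),
        "n_human_subjects": len(results.human_scores.subjects),
        "k_retained": {m: p.k_retained for m, p in results.pcas.items()},
        "carried_pcs": results.carried_pcs,
        "significant_pcs": results.significant_pcs,
    }
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)

    return ReportBundle(
        out_dir=out,
        results=results,
        enrichment=enrichment,
        sexdiff=sexdiff,
        manifest=manifest,
        truth=truth,
        recovery=recovery,
    )


def _recovery_summary(
    results: TransCompRResults,
    truth: SyntheticTruth,
    enrichment: dict[str, dict[str, object]],
    config: RunConfig,
) -> pd.DataFrame:
    """Truth-vs-found table: was each planted signal recovered?"""
    expected = truth_report(truth).set_index("disease_model")
    rows = []
    for model, pca in results.pcas.items():
        pc_idx = match_translatable_pc(pca, truth)
        label = f"{model} PC{pc_idx}"
        selected = (
            bool(results.selection.loc[label, "selected_any"])
            if label in results.selection.index
            else False
        )
        simple = results.glm_results
        sig = False
        if not simple.empty:
            m = simple[(simple["pc"] == label) & (simple["covariates"] == "pcs")]
            sig = bool(m["significant"].iloc[0]) if len(m) else False
        planted_hit = False
        if label in enrichment:
            for res in enrichment[label].values():
                tbl = res.table
                hit = tbl[
                    (tbl["set"] == truth.planted_set_name)
                    & (tbl["padj"] < config.gsea_fdr)
                ]
                planted_hit = planted_hit or len(hit) > 0
        rows.append(
            {
                "disease_model": model,
                "expected_translatable": bool(expected.loc[model, "translatable"]),
                "matched_pc": label,
                "lasso_selected": selected,
                "glm_significant": sig,
                "planted_set_enriched": planted_hit,
            }
        )
    return pd.DataFrame(rows)
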