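"""End-to-end orchestration: classify -> collapse -> cluster -> enrich.

One :class:`PipelineConfig` (usually loaded from YAML) drives every stage
with a single master seed; all outputs are TSVs carrying a run-metadata
header (seed, version, config hash) so a finished report directory is fully
reproducible and self-describing.  A rerun into a directory produced by a
*different* configuration refuses to overwrite unless forced.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import ClassifyConfig, anova_table, classify, overlap_shares, summarize_categories
from .cluster import DEFAULT_K, build_profiles, kmeans_cluster
from .collapse import collapse
from .enrichment import enrich_sets, overlap_analysis
from .io import (
    ExpressionBundle,
    GeneMap,
    config_hash,
    read_expression,
    read_fasta_promoters,
    read_gene_list,
    read_gene_map,
    read_gmt,
    read_jaspar_pfm,
    write_results,
)
from .motifs import build_motif_model, motif_enrich
from .simulate import SimConfig, simulate_bound_list, simulate_expression, simulate_gene_sets, simulate_promoters

__all__ = ["PipelineConfig", "PipelineError", "run_all", "report_overlap_shares"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Inputs plus every tunable of the analysis.

    Either ``synth`` holds a :class:`~crossfactor.simulate.SimConfig` (the
    bundle is generated in memory) or the path fields point at files on
    disk.  Defaults mirror the conventional settings of a factorial
    knock-down study: FDR 0.01, 2-fold filter, k map {A:2, B:2, C:4, D:8},
    promoter window -1000/+500, score cut-off 8.0, alpha 0.05.
    """

    out_dir: str = "crossfactor_out"
    seed: int = 17
    synth: SimConfig | None = None
    matrix_path: str | None = None
    sample_sheet_path: str | None = None
    gene_map_path: str | None = None
    gmt_path: str | None = None
    promoters_path: str | None = None
    pfm_path: str | None = None
    bound_list_path: str | None = None
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    k_map: dict = field(default_factory=lambda: dict(DEFAULT_K))
    alpha_sets: float = 0.05
    alpha_motifs: float = 0.05
    score_cutoff: float = 8.0
    kmeans_restarts: int = 50
    force: bool = False

    def __post_init__(self) -> None:
        missing = {"A", "B", "C", "D"} - set(self.k_map)
        if missing:
            raise ValueError(f"k map must cover all four categories; missing {sorted(missing)}")

    def hash(self) -> str:
        d = asdict(self)
        # destination and overwrite policy are not part of the analysis
        d.pop("force", None)
        d.pop("out_dir", None)
        return config_hash(d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "synth" in raw and raw["synth"] is not None:
            raw["synth"] = SimConfig(**raw["synth"])
        if "classify" in raw and raw["classify"] is not None:
            raw["classify"] = ClassifyConfig(**raw["classify"])
        return cls(**raw)


def _load_inputs(config: PipelineConfig):
    if config.synth is not None:
        sim = config.synth
        bundle, gene_map, truth = simulate_expression(sim)
        promoters, pfms = simulate_promoters(sim, truth)
        bound = simulate_bound_list(sim, truth)
        genesets = simulate_gene_sets(sim, truth)
        return bundle, gene_map, genesets, promoters, pfms, bound, truth
    if not config.matrix_path or not config.sample_sheet_path:
        raise ValueError("need either a synth block or matrix + sample sheet paths")
    bundle = read_expression(config.matrix_path, config.sample_sheet_path)
    gene_map = read_gene_map(config.gene_map_path) if config.gene_map_path else GeneMap(
        mapping={}
    )
    genesets = read_gmt(config.gmt_path) if config.gmt_path else None
    promoters = read_fasta_promoters(config.promoters_path) if config.promoters_path else None
    pfms = read_jaspar_pfm(config.pfm_path) if config.pfm_path else []
    bound = read_gene_list(config.bound_list_path) if config.bound_list_path else []
    return bundle, gene_map, genesets, promoters, pfms, bound, None


def report_overlap_shares(summary: pd.DataFrame) -> pd.DataFrame:
    """Overlap-share statistics at both cut-offs from a category summary.

    For each cut-off row, reports the share of factor-2-responsive probesets
    that also respond to factor 1, (C+D)/(B+C+D), and the factor-1 analogue
    (C+D)/(A+C+D).  Zero denominators give NaN ("undefined").
    """
    rows = []
    for _, row in summary.iterrows():
        shares = overlap_shares(row["n_B"], row["n_C"], row["n_D"], n_A=row["n_A"])
        rows.append(
            {
                "cutoff": row["cutoff"],
                "factor2_overlap_pct": 100.0 * shares["factor2_overlap"],
                "factor1_overlap_pct": 100.0 * shares["factor1_overlap"],
                "both_responsive": shares["both_responsive"],
                "factor2_responsive": shares["factor2_responsive"],
                "factor1_responsive": shares["factor1_responsive"],
            }
        )
    return pd.DataFrame(rows)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - reraised with stage context
            raise PipelineError(name, exc) from exc
        logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
        return result

    return wrap


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage in order and write the report directory.

    Returns the output directory path.  Stages: ANOVA classification,
    gene collapse, per-category K-means, gene-set enrichment per category
    and cluster, bound-list overlap, and motif enrichment (each enrichment
    stage runs only when its inputs were supplied).
    """
    out = Path(config.out_dir)
    cfg_hash = config.hash()
    marker = out / "run_config_hash.txt"
    if marker.exists() and marker.read_text().strip() != cfg_hash and not config.force:
        raise PipelineError(
            "setup",
            RuntimeError(
                f"{out} holds results from a different configuration; rerun with force"
            ),
        )
    out.mkdir(parents=True, exist_ok=True)
    metadata = {"seed": config.seed, "version": __version__, "config_hash": cfg_hash}

    bundle, gene_map, genesets, promoters, pfms, bound, truth = _stage("load")(
        _load_inputs, config
    )

    anova = _stage("classify")(anova_table, bundle)
    calls = _stage("classify")(classify, anova, config.classify)
    summary = summarize_categories(calls)
    shares = report_overlap_shares(summary)
    tables = {"anova": anova, "calls": calls, "summary": summary, "overlap_shares": shares}

    mean_intensity = bundle.values.mean(axis=1)
    if len(gene_map):
        gene_calls, dropped = _stage("collapse")(collapse, calls, gene_map, mean_intensity)
        tables["gene_calls"] = gene_calls
        tables["dropped_genes"] = dropped
    else:
        gene_calls = calls.rename(columns={"probeset_id": "gene_id"}).assign(
            representative_probeset=calls["probeset_id"]
        )
        dropped = pd.DataFrame()

    assignment_frames = []
    centroid_frames = []
    for cat in "ABCD":
        k = int(config.k_map[cat])
        profiles = build_profiles(bundle, gene_calls, cat, id_column="gene_id")
        if profiles.empty:
            continue
        if len(profiles) < k:
            raise PipelineError(
                "cluster",
                ValueError(f"category {cat} has {len(profiles)} members, fewer than k={k}"),
            )
        model = _stage("cluster")(
            kmeans_cluster, profiles, k, seed=config.seed, n_restarts=config.kmeans_restarts,
            category=cat,
        )
        assignment_frames.append(
            pd.DataFrame(
                {
                    "gene_id": model.assignments.index,
                    "category": cat,
                    "cluster": model.assignments.to_numpy() + 1,
                }
            )
        )
        cf = pd.DataFrame(model.centroids, columns=[f"z_cell{j + 1}" for j in range(4)])
        cf.insert(0, "category", cat)
        cf.insert(1, "cluster", range(1, k + 1))
        centroid_frames.append(cf)
    clusters = (
        pd.concat(assignment_frames, ignore_index=True)
        if assignment_frames
        else pd.DataFrame(columns=["gene_id", "category", "cluster"])
    )
    tables["clusters"] = clusters
    if centroid_frames:
        tables["centroids"] = pd.concat(centroid_frames, ignore_index=True)

    universe = sorted(set(gene_calls["gene_id"]))
    if genesets is not None:
        rows = []
        for cat in "ABCD":
            target = gene_calls.loc[gene_calls["category"] == cat, "gene_id"]
            if target.empty:
                continue
            res = _stage("enrich")(
                enrich_sets, target, genesets, universe, config.alpha_sets
            )
            res.insert(0, "target", f"category_{cat}")
            rows.append(res)
        for (cat, cl), grp in clusters.groupby(["category", "cluster"]):
            res = _stage("enrich")(
                enrich_sets, grp["gene_id"], genesets, universe, config.alpha_sets
            )
            res.insert(0, "target", f"category_{cat}_cluster_{cl}")
            rows.append(res)
        if rows:
            tables["set_enrichment"] = pd.concat(rows, ignore_index=True)

    if bound:
        responsive = gene_calls.loc[
            gene_calls["category"].isin(["A", "C", "D"]), "gene_id"
        ]
        bound_in_universe = [g for g in bound if g in set(universe)]
        res = _stage("overlap")(
            overlap_analysis, bound_in_universe, sorted(responsive), universe
        )
        tables["bound_overlap"] = pd.DataFrame([{k: (v if not isinstance(v, tuple) else str(v)) for k, v in res.items()}])

    if promoters is not None and pfms:
        models = [
            build_motif_model(p, threshold=config.score_cutoff) for p in pfms
        ]
        target_genes = [
            g
            for g in gene_calls.loc[gene_calls["category"].isin(["A", "C", "D"]), "gene_id"]
            if g in promoters.sequences
        ]
        if target_genes:
            res = _stage("motifs")(
                motif_enrich,
                promoters.subset(target_genes),
                promoters,
                models,
                config.alpha_motifs,
            )
            tables["motif_enrichment"] = res

    _stage("write")(write_results, tables, out, metadata)
    marker.write_text(cfg_hash + "\n")
    if truth is not None:
        truth.reset_index().to_csv(out / "truth.tsv", sep="\t", index=False)
    return out
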