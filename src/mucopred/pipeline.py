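"""End-to-end orchestration of the analysis stages with a run manifest.

One :func:`run` call executes, per selected cohort, the stages
simulate -> preprocess -> cohort stats -> alpha diversity -> ordination ->
response model, writing each stage's tables under the output directory and a
JSON manifest recording the configuration echo, seeds, per-stage wall time
and warnings. Stages only ever write their own outputs, so later stages can
be re-run alone against earlier results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import beta, cohort_stats, diversity, model, preprocess, simulate


@dataclasses.dataclass
class RunConfig:
    """Declarative configuration of one full run.

    Either ``simulation`` is present (a :class:`~mucopred.simulate.
    SimulationConfig`) or all four input paths are; stage toggles and numeric
    parameters default to the study's settings except the permutation count,
    which callers running at desk scale should reduce.
    """

    outdir: str = "results/run"
    simulation: simulate.SimulationConfig | None = None
    counts_path: str | None = None
    taxonomy_path: str | None = None
    tree_path: str | None = None
    metadata_path: str | None = None
    response_col: str = "response"
    min_reads: int = 4
    stages: tuple[str, ...] = ("preprocess", "stats", "diversity",
                               "ordination", "model")
    permanova_permutations: int = 999
    envfit_permutations: int = 999
    pipeline: model.PipelineConfig = dataclasses.field(
        default_factory=model.PipelineConfig)
    run_permutation_test: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.simulation is None:
            paths = [self.counts_path, self.taxonomy_path, self.tree_path,
                     self.metadata_path]
            if any(p is None for p in paths):
                raise ValueError("without a simulation block, all four input "
                                 "paths are required")
            for p in paths:
                if not Path(p).exists():
                    raise FileNotFoundError(p)
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")


def _sha1(path: Path) -> str:
    return hashlib.sha1(path.read_bytes()).hexdigest()[:12]


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def _load_inputs(config: RunConfig, outdir: Path
                 ) -> tuple[pd.DataFrame, pd.DataFrame, TreeNode, pd.DataFrame]:
    if config.simulation is not None:
        cohort = simulate.generate_cohort(config.simulation)
        cohort.write(outdir / "simulated")
        return cohort.counts, cohort.taxonomy, cohort.tree, cohort.metadata
    counts = simulate.read_counts(config.counts_path)
    taxonomy = simulate.read_taxonomy(config.taxonomy_path)
    tree = TreeNode.read(config.tree_path, convert_underscores=False)
    metadata = simulate.read_metadata(config.metadata_path)
    return counts, taxonomy, tree, metadata


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config": _jsonable(config),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
    }
    t0 = time.perf_counter()

    counts, taxonomy, tree, metadata = _load_inputs(config, outdir)
    y = metadata.loc[counts.index, config.response_col]

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        def stage_done(name: str, started: float) -> None:
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - started, 3)}

        t = time.perf_counter()
        filtered = preprocess.filter_min_reads(counts, config.min_reads)
        bacterial, report = preprocess.exclude_nonbacterial(filtered, taxonomy)
        relabund = preprocess.relative_abundance(bacterial)
        if "preprocess" in config.stages:
            bacterial.to_csv(outdir / "counts_filtered.tsv", sep="\t",
                             index_label="sample_id")
            relabund.to_csv(outdir / "relative_abundance.tsv", sep="\t",
                            index_label="sample_id")
            report.to_json(outdir / "filter_report.json")
        stage_done("preprocess", t)

        if "stats" in config.stages:
            t = time.perf_counter()
            table = cohort_stats.summarize_cohort(
                metadata.loc[counts.index], group_col=config.response_col)
            table.to_csv(outdir / "cohort_table.tsv", sep="\t", index=False)
            stage_done("stats", t)

        if "diversity" in config.stages:
            t = time.perf_counter()
            alpha = diversity.alpha_diversity(bacterial)
            alpha.to_csv(outdir / "alpha_diversity.tsv", sep="\t",
                         index_label="sample_id")
            groups = sorted(y.unique(), key=str)
            comparisons = {}
            for metric in alpha.columns:
                a = alpha.loc[(y == groups[0]).values, metric].dropna()
                b = alpha.loc[(y == groups[1]).values, metric].dropna()
                u, p = diversity.compare_alpha(a, b)
                comparisons[metric] = {"U": u, "p": p}
            (outdir / "alpha_comparison.json").write_text(
                json.dumps(_jsonable(comparisons), indent=2))
            stage_done("diversity", t)

        if "ordination" in config.stages:
            t = time.perf_counter()
            seeds = np.random.SeedSequence(config.seed).generate_state(2) % (2**31)
            ordination_report = {}
            for name, dm in (("bray_curtis", beta.bray_curtis(relabund)),
                             ("unweighted_unifrac",
                              beta.unweighted_unifrac(bacterial, tree)),
                             ("weighted_unifrac",
                              beta.weighted_unifrac(bacterial, tree))):
                pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
                    outdir / f"distance_{name}.tsv", sep="\t")
                ordn = beta.pcoa(dm, n_axes=2)
                ordn.coordinates.to_csv(outdir / f"pcoa_{name}.tsv", sep="\t",
                                        index_label="sample_id")
                perm = beta.permanova(dm, y, config.permanova_permutations,
                                      seed=int(seeds[0]))
                ordination_report[name] = {
                    "eigenvalues": ordn.eigenvalues[:5],
                    "proportion_explained": ordn.proportion_explained,
                    "permanova": perm,
                }
                if name == "bray_curtis":
                    centroids = beta.centroid_distances(ordn, y)
                    centroids.to_csv(outdir / "centroid_distances.tsv",
                                     sep="\t")
                    flags = [c for c in ("prior_anti_tnfa", "prior_vdz",
                                         "prior_uste")
                             if c in metadata.columns
                             and metadata.loc[counts.index, c].nunique() > 1]
                    if flags:
                        env = beta.envfit_vectors(
                            ordn, metadata.loc[counts.index, flags],
                            config.envfit_permutations, seed=int(seeds[1]))
                        ordination_report["envfit"] = {
                            "arrows": env.arrows.to_dict(),
                            "r2": env.r2.to_dict(), "p": env.p.to_dict()}
            (outdir / "ordination_report.json").write_text(
                json.dumps(_jsonable(ordination_report), indent=2))
            stage_done("ordination", t)

        if "model" in config.stages:
            t = time.perf_counter()
            selection, cv = model.run_pipeline(relabund, y, config.pipeline,
                                               seed=config.seed)
            biomarkers = model.rank_biomarkers(cv, relabund, y,
                                               taxonomy=taxonomy)
            biomarkers.to_csv(outdir / "biomarkers.tsv", sep="\t", index=False)
            selection.selection_counts.sort_values(ascending=False).to_csv(
                outdir / "stability_scores.tsv", sep="\t",
                index_label="asv_id")
            report_m: dict[str, Any] = {
                "outer_split_aucs": cv.outer_split_aucs,
                "mean_auc": cv.mean_auc,
                "best_hyperparameters": cv.best_hyperparameters,
                "selected_features": selection.selected_features,
            }
            if config.run_permutation_test:
                perm_res = model.permutation_test(relabund, y, config.pipeline,
                                                  seed=config.seed,
                                                  observed=cv)
                report_m["permutation_p"] = perm_res.p
                report_m["null_aucs"] = perm_res.null_aucs
            (outdir / "model_report.json").write_text(
                json.dumps(_jsonable(report_m), indent=2))
            stage_done("model", t)

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    manifest["total_seconds"] = round(time.perf_counter() - t0, 3)
    manifest["input_checksums"] = {
        p.name: _sha1(p) for p in sorted(outdir.glob("simulated/*"))}
    (outdir / "manifest.json").write_text(json.dumps(_jsonable(manifest),
                                                     indent=2, sort_keys=True))
    return manifest
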