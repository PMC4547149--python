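"""The load -> filter -> predict -> visualize pipeline as a library call.

Each stage is a plain function over the domain types; :func:`run_pipeline`
wires them together from a :class:`PipelineConfig` (typically parsed from
YAML by the CLI) and writes every intermediate product to the output
directory, returning a manifest of artifact paths and row counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

from . import assoc, diffexp, netviz
from .data_io import (
    DataKind,
    DiffStatsTable,
    ExpressionDataset,
    SequenceTargetDB,
    TWO_SAMPLE_KINDS,
)
from .genmir import GenMiRConfig, genmir_fit
from .interactions import (
    DEFAULT_ORDERING,
    DirectionOption,
    InteractionTable,
    PredictionResult,
    SelectionSpec,
    apply_direction_filter,
    combine_results,
)

logger = logging.getLogger(__name__)

EXPRESSION_ALGORITHMS = ("pearson", "spearman", "mutual_information", "mic", "genmir")
SEQUENCE_ALGORITHMS = ("targetscan", "microrna_org")
VALID_ALGORITHMS = EXPRESSION_ALGORITHMS + SEQUENCE_ALGORITHMS


class PipelineError(ValueError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class AlgorithmSpec:
    name: str
    params: dict = dc_field(default_factory=dict)
    selection: Optional[SelectionSpec] = None

    def __post_init__(self) -> None:
        if self.name not in VALID_ALGORITHMS:
            raise PipelineError("config", f"unknown algorithm {self.name!r}")
        if self.selection is None and self.name in EXPRESSION_ALGORITHMS:
            self.selection = SelectionSpec(
                mode="top_n", n=100, ordering=DEFAULT_ORDERING.get(
                    "correlation" if self.name in ("pearson", "spearman") else self.name,
                    "descending",
                )
            )


@dataclass
class PipelineConfig:
    algorithms: list[AlgorithmSpec]
    p_max: float = 0.05
    min_abs_fc: float = 1.0
    min_mean: float = 0.0
    direction: DirectionOption = DirectionOption.ALL
    combine: str = "intersection"
    combine_over: Optional[list[str]] = None  # algorithm names; default: all
    layout: str = "isom_modified"
    canvas: tuple[float, float] = (400.0, 300.0)
    fc_cap: float = 4.0
    seed: int = 0
    genmir: GenMiRConfig = dc_field(default_factory=GenMiRConfig)
    output_dir: Optional[Path] = None


def filter_stage(
    dataset: ExpressionDataset, config: PipelineConfig
) -> tuple[set[str], Optional[DiffStatsTable]]:
    """Differential filter for two-sample data, expression filter otherwise."""
    if dataset.data_kind in TWO_SAMPLE_KINDS or dataset.data_kind is DataKind.STATS_ONLY:
        stats = diffexp.two_sample_stats(dataset)
        keep = diffexp.filter_two_sample(stats, config.p_max, config.min_abs_fc)
        return keep, stats
    return diffexp.filter_multisample(dataset, config.min_mean), None


def _algo_label(name: str) -> str:
    if name in ("pearson", "spearman"):
        return "correlation"
    if name == "mic":
        return "mine"
    return name


def predict_stage(
    mirna_ds: ExpressionDataset,
    mrna_ds: ExpressionDataset,
    mirna_keep: set[str],
    mrna_keep: set[str],
    config: PipelineConfig,
    mirna_stats: Optional[DiffStatsTable] = None,
    mrna_stats: Optional[DiffStatsTable] = None,
    candidate_db: Optional[SequenceTargetDB] = None,
) -> dict[str, PredictionResult]:
    """Score, direction-filter and select pairs for every configured algorithm.

    The direction filter runs before threshold/top-N selection, so a top-N
    request returns the N best pairs among those in the requested direction.
    """
    mirna_sub = mirna_ds.subset(sorted(mirna_keep))
    mrna_sub = mrna_ds.subset(sorted(mrna_keep))
    universe = {(m, g) for m in mirna_sub.entity_ids for g in mrna_sub.entity_ids}
    if config.direction is not DirectionOption.ALL:
        universe = apply_direction_filter(
            universe, mirna_stats, mrna_stats, config.direction
        )
    logger.info("predict: %d candidate pairs after direction filter", len(universe))

    results: dict[str, PredictionResult] = {}
    for spec in config.algorithms:
        label = _algo_label(spec.name)
        if spec.name in SEQUENCE_ALGORITHMS:
            if candidate_db is None:
                raise PipelineError(
                    "predict", f"{spec.name} requires a sequence candidate database"
                )
            pairs = sorted(candidate_db.pairs() & universe)
            results[label] = PredictionResult(
                algorithm=spec.name, pairs=[(m, g, None) for m, g in pairs]
            )
        elif spec.name == "genmir":
            if candidate_db is not None:
                pair_pool = candidate_db.pairs() & universe
            else:
                pair_pool = universe
            candidates: dict[str, set[str]] = {}
            for m, g in pair_pool:
                candidates.setdefault(g, set()).add(m)
            fit = genmir_fit(mirna_sub, mrna_sub, candidates, config.genmir)
            from .interactions import select_interactions

            results[label] = select_interactions(fit, spec.selection, algorithm="genmir")
        else:
            table = assoc.score_pairs(
                mirna_sub,
                mrna_sub,
                method=spec.name,
                params=spec.params,
                candidates=sorted(universe),
            )
            from .interactions import select_interactions

            results[label] = select_interactions(table, spec.selection)
        logger.info("predict: %s selected %d pairs", label, len(results[label].pairs))
    return results


def run_pipeline(
    config: PipelineConfig,
    mirna_ds: ExpressionDataset,
    mrna_ds: ExpressionDataset,
    candidate_db: Optional[SequenceTargetDB] = None,
) -> dict:
    """Execute all stages and (when an output dir is set) write artifacts.

    Returns a manifest: per-stage row counts, the per-algorithm selections,
    the combined interaction table and, when configured, the written paths.
    """
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"outputs": {}, "counts": {}}

    def _emit(name: str, writer, count: int) -> None:
        manifest["counts"][name] = count
        if outdir:
            path = outdir / name
            writer(path)
            manifest["outputs"][name] = str(path)

    try:
        mirna_keep, mirna_stats = filter_stage(mirna_ds, config)
        mrna_keep, mrna_stats = filter_stage(mrna_ds, config)
    except Exception as exc:  # noqa: BLE001 - stage-tagged rethrow
        raise PipelineError("filter", str(exc)) from exc
    logger.info("filter: kept %d miRNAs, %d mRNAs", len(mirna_keep), len(mrna_keep))
    if mirna_stats is not None:
        _emit("mirna_stats.tsv", mirna_stats.to_tsv, len(mirna_stats.entity_ids))
    if mrna_stats is not None:
        _emit("mrna_stats.tsv", mrna_stats.to_tsv, len(mrna_stats.entity_ids))

    try:
        results = predict_stage(
            mirna_ds,
            mrna_ds,
            mirna_keep,
            mrna_keep,
            config,
            mirna_stats,
            mrna_stats,
            candidate_db,
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("predict", str(exc)) from exc
    for label, result in results.items():
        frame_writer = lambda path, r=result: _write_result(r, path)
        _emit(f"selection_{label}.tsv", frame_writer, len(result.pairs))

    try:
        combine_over = config.combine_over or list(results)
        table = combine_results(
            list(results.values()),
            mode=config.combine,
            selected=combine_over,
            mirna_stats=mirna_stats,
            mrna_stats=mrna_stats,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("combine", str(exc)) from exc
    _emit("interactions.tsv", table.to_tsv, len(table))
    manifest["selections"] = results
    manifest["interactions"] = table

    if len(table):
        try:
            network = netviz.build_network(table)
            layout = netviz.layout_network(network, config.layout, seed=config.seed)
            treemap = netviz.treemap_layout(network, *config.canvas)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("visualize", str(exc)) from exc
        manifest["network"] = network
        manifest["layout"] = layout
        manifest["treemap"] = treemap
        manifest["counts"]["network_edges"] = len(network.edges)
        if outdir:
            netviz.export_graphml(network, outdir / "network.graphml")
            netviz.export_tsv(network, outdir / "nodes.tsv", outdir / "edges.tsv")
            treemap.to_frame().to_csv(outdir / "treemap.tsv", sep="\t", index=False)
            netviz.render_node_link(
                network, layout, outdir / "network.svg", fc_cap=config.fc_cap
            )
            netviz.render_treemap(
                network, treemap, outdir / "treemap.svg", fc_cap=config.fc_cap
            )
            for name in ("network.graphml", "nodes.tsv", "edges.tsv", "treemap.tsv",
                         "network.svg", "treemap.svg"):
                manifest["outputs"][name] = str(outdir / name)
    else:
        logger.warning("combine produced no interactions; skipping visualization")
    return manifest


def _write_result(result: PredictionResult, path) -> None:
    import pandas as pd

    pd.DataFrame(
        result.pairs, columns=["mirna_id", "mrna_id", "score"]
    ).to_csv(path, sep="\t", index=False)
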