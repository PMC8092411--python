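"""End-to-end orchestration of the two workflows.

``run_recovery`` drives the time-course analysis: log-normalization and
per-day deregulation calling for every provided omic layer, PCA, the
temporal similarity graph over deregulated transcripts, the Markov-time
stability scan with robust partition selection, cluster mean profiles,
optional single-sample enrichment and supernatant exchange rates, plus a
JSON manifest of summary counts.

``run_dependency`` drives the dependency-signature workflow: extreme-group
selection, signature derivation, and tumor projection with the
strictly-greater-than match threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, dependency, enrichment, exchange, network, stability
from .io import write_manifest
from .synthetic import (
    DependencyCohort,
    SyntheticStudy,
)

logger = logging.getLogger("stressrec")


def _setup_logging(out_dir: Path, verbose: bool) -> None:
    logger.setLevel(logging.DEBUG)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    stream = logging.StreamHandler()
    stream.setLevel(logging.INFO if verbose else logging.WARNING)
    stream.setFormatter(fmt)
    logger.addHandler(stream)
    filehandler = logging.FileHandler(out_dir / "pipeline.log")
    filehandler.setFormatter(fmt)
    logger.addHandler(filehandler)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RecoveryConfig:
    """Knobs of the recovery workflow; validated before any computation."""

    q_max: float = 0.05
    lfc_min_transcript: float = 1.0
    k_neighbors: int = 5
    t_grid: np.ndarray | None = None
    n_restarts: int = 20
    vi_max: float | None = None
    alpha: float = 0.0
    n_pc: int = 2
    seed: int = 0
    out_dir: str | Path = "results"
    verbose: bool = False

    def validate(self) -> None:
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must be in (0, 1]")
        if self.lfc_min_transcript < 0:
            raise ValueError("lfc_min_transcript must be >= 0")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.n_pc < 1:
            raise ValueError("n_pc must be >= 1")
        if self.t_grid is not None:
            grid = np.asarray(self.t_grid, float)
            if len(grid) == 0 or not np.all(np.diff(grid) > 0):
                raise ValueError("t_grid must be non-empty and strictly increasing")
        if self.vi_max is not None and self.vi_max < 0:
            raise ValueError("vi_max must be >= 0")


@dataclass
class DependencyConfig:
    """Knobs of the dependency-signature workflow."""

    n_top: int = 61
    n_bottom: int = 60
    signature_size: int = 56
    q_max: float = 0.05
    match_thr: float = 0.8
    prob_threshold: float = 0.5
    seed: int = 0
    out_dir: str | Path = "results"
    verbose: bool = False

    def validate(self) -> None:
        if self.n_top < 3 or self.n_bottom < 3:
            raise ValueError("extreme groups need >= 3 lines")
        if self.signature_size < 1:
            raise ValueError("signature_size must be >= 1")
        if not 0 < self.q_max <= 1:
            raise ValueError("q_max must be in (0, 1]")
        if self.match_thr < 0:
            raise ValueError("match_thr must be >= 0")
        if not 0 < self.prob_threshold < 1:
            raise ValueError("prob_threshold must be in (0, 1)")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(name, exc) from exc
            logger.info("stage %s: done", name)
            return out

        return wrapped

    return deco


def run_recovery(
    study: SyntheticStudy | dict,
    config: RecoveryConfig | None = None,
    supernatant=None,
    cells=None,
    gene_sets: enrichment.GeneSetCollection | None = None,
) -> dict:
    """Run the full recovery workflow and write results to ``out_dir``.

    ``study`` is a :class:`SyntheticStudy` or a dict of
    ``{omic: OmicsMatrix}`` with at least a ``transcript`` entry.  Returns a
    result bundle (tables, graph, scan, partition, manifest).
    """
    config = config or RecoveryConfig()
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir, config.verbose)

    if isinstance(study, SyntheticStudy):
        layers = {
            "transcript": study.transcripts,
            "protein": study.proteins,
            "metabolite": study.metabolites,
        }
    else:
        layers = dict(study)
    if "transcript" not in layers:
        raise ValueError("a transcript matrix is mandatory")

    bundle: dict = {"tables": {}, "counts": {}}

    @_stage("differential")
    def _differential():
        for omic, matrix in layers.items():
            if matrix is None:
                continue
            lfc_min = config.lfc_min_transcript if omic == "transcript" else 0.0
            table = differential.differential_table(
                matrix, q_max=config.q_max, lfc_min=lfc_min
            )
            bundle["tables"][omic] = table
            counts = differential.deregulation_counts(table)
            bundle["counts"][omic] = counts
            table.to_csv(out_dir / f"differential_{omic}.tsv", sep="\t", index=False)
            counts.to_csv(out_dir / f"deregulation_counts_{omic}.tsv", sep="\t", index=False)

    _differential()

    @_stage("pca")
    def _pca():
        bundle["pca"] = {}
        for omic, matrix in layers.items():
            if matrix is None:
                continue
            log_m = matrix if matrix.log_scale else differential.normalize_log(matrix)
            n_pc = min(config.n_pc, log_m.values.shape[1] - 1, len(log_m.values.index))
            scores, evf = differential.pca_scores(log_m, n_pc=n_pc)
            bundle["pca"][omic] = (scores, evf)
            scores.rename_axis("sample_id").to_csv(out_dir / f"pca_{omic}.tsv", sep="\t")

    _pca()

    @_stage("network")
    def _network():
        tx_table = bundle["tables"]["transcript"]
        called = network.deregulated_features(tx_table)
        if len(called) < 3:
            raise ValueError("too few deregulated transcripts to build a network")
        profiles = network.standardize_profiles(tx_table, feature_subset=called)
        graph = network.similarity_graph(profiles, k=config.k_neighbors)
        network.write_edge_list(graph, out_dir / "feature_graph.tsv")
        bundle["profiles"] = profiles
        bundle["graph"] = graph

    _network()

    @_stage("stability_scan")
    def _scan():
        scan = stability.scan_markov_times(
            bundle["graph"],
            t_grid=config.t_grid,
            n_restarts=config.n_restarts,
            seed=config.seed,
        )
        partition, selection = stability.select_robust_partition(scan, vi_max=config.vi_max)
        scan.summary().to_csv(out_dir / "stability_scan.tsv", sep="\t", index=False)
        partition.as_series().rename_axis("feature_id").to_csv(out_dir / "partition.csv")
        means = stability.cluster_mean_profiles(partition, bundle["profiles"])
        means.to_csv(out_dir / "cluster_mean_profiles.tsv", sep="\t")
        bundle["scan"] = scan
        bundle["partition"] = partition
        bundle["selection"] = selection
        bundle["cluster_means"] = means

    _scan()

    if gene_sets is not None:

        @_stage("enrichment")
        def _enrichment():
            tx = layers["transcript"]
            log_m = tx if tx.log_scale else differential.normalize_log(tx)
            scores = enrichment.sample_set_scores(log_m, gene_sets, alpha=config.alpha)
            scaled = enrichment.scale_scores(scores)
            scaled.scores.rename_axis("gene_set").to_csv(
                out_dir / "enrichment_scaled.tsv", sep="\t"
            )
            bundle["enrichment"] = scaled

        _enrichment()

    if supernatant is not None and cells is not None:

        @_stage("exchange_rates")
        def _exchange():
            frames = []
            rates = {}
            for met, series in supernatant.items():
                rate = exchange.exchange_rates(series, cells)
                rates[met] = rate
                frame = rate.as_frame()
                frame.insert(0, "metabolite", met)
                frames.append(frame)
            pd.concat(frames, ignore_index=True).to_csv(
                out_dir / "exchange_rates.csv", index=False
            )
            bundle["exchange"] = rates

        _exchange()

    manifest = {
        "workflow": "recovery",
        "seed": config.seed,
        "n_clusters_selected": bundle["partition"].n_clusters,
        "selection": bundle["selection"],
        "deregulated_per_day": {
            omic: counts.set_index("day")["total"].to_dict()
            for omic, counts in bundle["counts"].items()
        },
        "n_network_features": len(bundle["graph"]),
    }
    write_manifest(manifest, out_dir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle


def run_dependency(
    cohort: DependencyCohort | dict,
    config: DependencyConfig | None = None,
) -> dict:
    """Run the dependency-signature workflow and write results."""
    config = config or DependencyConfig()
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir, config.verbose)

    if isinstance(cohort, DependencyCohort):
        scores = cohort.scores
        probabilities = cohort.probabilities
        expression = cohort.expression
        tissues = cohort.tissues
        tumors = cohort.tumor_expression
        target = cohort.config.target_gene
    else:
        scores = cohort["scores"]
        probabilities = cohort.get("probabilities")
        expression = cohort["expression"]
        tissues = cohort["tissues"]
        tumors = cohort["tumor_expression"]
        target = cohort["target_gene"]
    if tissues is None:
        raise ValueError("tissue labels are required before any computation")

    bundle: dict = {}

    @_stage("select_extremes")
    def _select():
        top, bottom, shortfall = dependency.select_extreme_lines(
            scores.loc[target], tissues, config.n_top, config.n_bottom
        )
        pd.DataFrame(
            {"line": top + bottom, "group": ["dependent"] * len(top) + ["independent"] * len(bottom)}
        ).to_csv(out_dir / "extreme_groups.csv", index=False)
        bundle["groups"] = (top, bottom)
        bundle["shortfall"] = shortfall

    _select()

    @_stage("derive_signature")
    def _derive():
        top, bottom = bundle["groups"]
        sig = dependency.derive_signature(
            expression, top, bottom, target_gene=target,
            size=config.signature_size, q_max=config.q_max,
        )
        sig.to_json(out_dir / "signature.json")
        bundle["signature"] = sig

    _derive()

    @_stage("project")
    def _project():
        result = dependency.project_signature(
            bundle["signature"], tumors, match_thr=config.match_thr
        )
        pd.DataFrame(
            {
                "match_fraction": result.match_fraction,
                "dependent": result.dependent,
            }
        ).rename_axis("tumor").to_csv(out_dir / "projections.tsv", sep="\t")
        bundle["projection"] = result

    _project()

    n_dep = int(bundle["projection"].dependent.sum())
    manifest = {
        "workflow": "dependency",
        "seed": config.seed,
        "target_gene": target,
        "n_dependent_lines_prob": (
            dependency.count_dependent(probabilities, target, config.prob_threshold)
            if probabilities is not None
            else None
        ),
        "signature_size": len(bundle["signature"]),
        "n_tumors": int(len(bundle["projection"].dependent)),
        "n_dependent_tumors": n_dep,
        "dependent_fraction": n_dep / len(bundle["projection"].dependent),
        "tissue_shortfall": bundle["shortfall"],
    }
    write_manifest(manifest, out_dir / "manifest.json")
    bundle["manifest"] = manifest
    return bundle
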