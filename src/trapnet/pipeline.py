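"""End-to-end pipeline: census -> control filter -> replicate summation ->
one-hit removal -> extensive network -> dynamics -> reference annotation ->
lean network, with every intermediate written to disk and a JSON report of
all checkpoint counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as tio
from .counts import CountMatrix, census
from .fdr import aggregate_fdr, read_psm_tsv
from .filters import (
    ONE_HIT_PER_CONDITION,
    control_filter,
    drop_one_hit_wonders,
    sum_replicates,
)
from .network import (
    DEGREE_GRAPH_STRONG,
    LEAN_ORDER_SELFLOOP_FIRST,
    ReferenceInteractionSet,
    annotate_known,
    build_extensive,
    build_lean,
    classify_dynamics,
    dynamics_counts,
    overlap_counts,
)

logger = logging.getLogger("trapnet")

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Paths, filter switches and provenance knobs of one pipeline run."""

    counts_path: str = ""
    meta_path: str = ""
    reference_path: str | None = None
    reference_format: str = "tsv"  # "tsv" | "biogrid"
    psm_path: str | None = None
    out_dir: str = "trapnet_out"
    decoy_prefix: str = "REV_"
    conditions: tuple[str, str] = ("untreated", "TNF")
    weak_value: int = 2
    strong_min: int = 3
    one_hit_mode: str = ONE_HIT_PER_CONDITION
    keep_one_hit_presence: bool = True
    degree_threshold: int = 3
    lean_order: str = LEAN_ORDER_SELFLOOP_FIRST
    degree_graph: str = DEGREE_GRAPH_STRONG
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.weak_value < 1 or self.strong_min < 1:
            raise ValueError("strength thresholds must be positive integers")
        if self.strong_min <= self.weak_value:
            raise ValueError("strong_min must exceed weak_value")
        if self.degree_threshold < 1:
            raise ValueError("degree_threshold must be a positive integer")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in data:
            data["conditions"] = tuple(data["conditions"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def run_pipeline(
    config: PipelineConfig,
    matrix: CountMatrix | None = None,
    reference: ReferenceInteractionSet | None = None,
) -> dict:
    """Execute all stages and return the checkpoint report.

    Inputs are loaded from the configured paths unless ``matrix`` /
    ``reference`` are passed directly (library use). All intermediate
    tables, network exports and the JSON report land in ``out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "tool": {"name": "trapnet", "version": __version__},
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            report["failed_stage"] = name
            (out / "report.json").write_text(json.dumps(report, indent=2))
            raise PipelineError(name, exc) from exc

    if matrix is None:
        matrix = stage("load_counts", tio.read_counts_tsv, config.counts_path, config.meta_path)
    if reference is None and config.reference_path:
        if config.reference_format == "biogrid":
            reference = stage("load_reference", tio.read_biogrid_tab, config.reference_path)
        else:
            reference = stage("load_reference", tio.read_reference_tsv, config.reference_path)
    if reference is None:
        reference = ReferenceInteractionSet([], version_label="empty")

    if config.psm_path:
        psms = stage("load_psms", read_psm_tsv, config.psm_path, config.decoy_prefix)
        report["psm_fdr"] = aggregate_fdr([psms])

    n_proteins, n_interactions = stage("census", census, matrix)
    report["prefilter"] = {"proteins": n_proteins, "interactions": n_interactions}

    filtered = stage("control_filter", control_filter, matrix)
    pc_proteins, pc_interactions = census(filtered)
    report["post_control"] = {"proteins": pc_proteins, "interactions": pc_interactions}
    tio.write_counts_tsv(filtered, out / "counts_control_filtered.tsv")

    cands = stage("sum_replicates", sum_replicates, filtered,
                  config.weak_value, config.strong_min)
    cands = stage("drop_one_hit_wonders", drop_one_hit_wonders, cands,
                  config.one_hit_mode, config.keep_one_hit_presence)
    tio.write_candidates_tsv(cands, out / "candidates_filtered.tsv")

    net = stage("build_extensive", build_extensive, cands, config.conditions)
    net = stage("classify_dynamics", classify_dynamics, net)
    net = stage("annotate_known", annotate_known, net, reference)
    known, novel = overlap_counts(net)
    report["extensive"] = {
        "proteins": net.number_of_nodes(),
        "interactions": net.number_of_edges(),
        "known": known,
        "novel": novel,
        "dynamics": dynamics_counts(net),
    }
    tio.write_edge_table(net, out / "extensive_edges.tsv")
    tio.write_node_table(net, out / "extensive_nodes.tsv")
    if net.number_of_edges():
        tio.write_graphml(net, out / "extensive.graphml")
        tio.write_sif(net, out / "extensive.sif")
        tio.write_mitab25(net, out / "extensive.mitab25.txt")

    lean, lean_report = stage("build_lean", build_lean, net,
                              config.degree_threshold, config.lean_order,
                              config.degree_graph)
    lk, ln = overlap_counts(lean)
    report["lean"] = {
        "proteins": lean_report.n_nodes,
        "interactions": lean_report.n_edges,
        "rescued_proteins": lean_report.rescued_nodes,
        "rescued_interactions": lean_report.rescued_edges,
        "self_loops_removed": lean_report.self_loops_removed,
        "known_self_loops_removed": lean_report.known_self_loops_removed,
        "known": lk,
        "novel": ln,
        "dynamics": dynamics_counts(lean),
    }
    tio.write_edge_table(lean, out / "lean_edges.tsv")
    tio.write_node_table(lean, out / "lean_nodes.tsv")
    if lean.number_of_edges():
        tio.write_graphml(lean, out / "lean.graphml")
        tio.write_sif(lean, out / "lean.sif")

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    logger.info("run_pipeline: report written to %s", out / "report.json")
    return report
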