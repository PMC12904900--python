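"""End-to-end orchestration with a config file and a run manifest.

Stages: load (or simulate) -> network summary -> centralities -> power
detection -> backbone -> hemisphere/homology -> motif census + QAP.
Every convention flag, seed, and load count is echoed into
``manifest.json`` so a run can be reproduced bit-for-bit; per-stage seeds
are derived from one master seed by fixed offsets so stages can be rerun
in isolation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pnio
from .hemisphere import (
    group_side_distribution,
    hemisphere_table,
    infer_homologs,
    intergroup_graph,
)
from .metrics import CentralityConventions, compute_centralities, summarize
from .model import ValidationError
from .motifs import census_to_frame, filter_frequent, mean_connections_frame, motif_census, qap_test, sensitivity_scan
from .power import backbone_report, backbone_subnetwork, detect_power_neurons, degree_comparison_table, rich_club_set
from .synthetic import SyntheticConfig, generate_connectome

STAGE_SEED_OFFSETS = {"simulate": 0, "qap": 101}


@dataclass
class PipelineConfig:
    # input: either a pair of CSV paths or "synthetic"
    arcs_path: str | None = None
    nodes_path: str | None = None
    stage_label: str = "synthetic"
    synthetic: dict = field(default_factory=dict)
    strict_load: bool = True
    # analysis parameters
    q: float = 0.20
    min_count: int = 4
    qap_permutations: int = 1000
    alpha: float = 0.05
    rich_club_threshold: int = 37
    include_boundary_ties: bool = False
    homolog_strategy: str = "explicit_column"
    intergroup_mode: str = "at_least_one"
    qap_shuffle_scope: str = "all"
    scan_thresholds: list[int] = field(default_factory=list)
    conventions: CentralityConventions = field(default_factory=CentralityConventions)
    seed: int = 0
    out_dir: str = "run"

    def __post_init__(self) -> None:
        if isinstance(self.conventions, dict):
            self.conventions = CentralityConventions(**self.conventions)
        if not 0 < self.q < 1:
            raise ValidationError(f"q must lie in (0,1), got {self.q}")
        if self.qap_permutations < 1:
            raise ValidationError("qap_permutations must be >= 1")
        if (self.arcs_path is None) != (self.nodes_path is None):
            raise ValidationError("arcs_path and nodes_path must be given together")
        for path in (self.arcs_path, self.nodes_path):
            if path is not None and not Path(path).exists():
                raise ValidationError(f"input file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def stage_seed(self, stage: str) -> int:
        return (self.seed + STAGE_SEED_OFFSETS[stage]) % (2**31)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage, writing tables, graphs, and the manifest.

    Returns the run directory. A stage failure leaves a ``FAILED`` marker
    naming the stage; outputs of completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "powerneurons 0.1.0",
        "config": {
            **{k: v for k, v in asdict(config).items() if k != "conventions"},
            "conventions": config.conventions.to_dict(),
        },
        "stages_completed": [],
    }
    stage = "load"
    try:
        if config.arcs_path is not None:
            connectome, report = pnio.read_connectome(
                config.arcs_path,
                config.nodes_path,
                config.stage_label,
                strict=config.strict_load,
            )
            truth = None
        else:
            stage = "simulate"
            syn = SyntheticConfig(**{**config.synthetic, "seed": config.stage_seed("simulate")})
            connectome, truth = generate_connectome(syn)
            truth.to_json(out / "ground_truth.json")
            from .model import LoadReport

            report = LoadReport()
        manifest["load_report"] = report.to_dict()
        manifest["stages_completed"].append(stage)

        stage = "summarize"
        summary = summarize(connectome, config.conventions)
        pnio.write_table(summary.to_frame(), out / "network_summary.csv")
        manifest["stages_completed"].append(stage)

        stage = "centralities"
        centralities = compute_centralities(connectome, config.conventions)
        pnio.write_table(centralities.reset_index(), out / "centralities.csv")
        manifest["stages_completed"].append(stage)

        stage = "power"
        top, power = detect_power_neurons(
            centralities, config.q, config.include_boundary_ties
        )
        pnio.write_table(
            pd.DataFrame({"id": sorted(power.power_ids)}), out / "power_neurons.csv"
        )
        pnio.write_table(power.to_frame(), out / "top_set_overlaps.csv")
        pnio.write_table(
            degree_comparison_table(centralities, power.power_ids),
            out / "degree_comparison.csv",
        )
        rich = rich_club_set(connectome, config.rich_club_threshold)
        manifest["n_power_neurons"] = len(power.power_ids)
        manifest["n_rich_club"] = len(rich)
        manifest["four_way_overlap_pct"] = power.four_way_overlap_pct
        manifest["stages_completed"].append(stage)

        stage = "backbone"
        if power.power_ids:
            report_bb = backbone_report(connectome, power.power_ids, config.conventions)
            pnio.write_table(
                report_bb.to_frame().reset_index(names="measure"),
                out / "backbone_report.csv",
            )
            manifest["backbone_density_ratio"] = report_bb.ratios["density"]
        manifest["stages_completed"].append(stage)

        stage = "hemisphere"
        pairing = infer_homologs(connectome, config.homolog_strategy)
        table, excluded = hemisphere_table(power, pairing, connectome)
        pnio.write_table(table.reset_index(), out / "hemisphere_table.csv")
        manifest["power_excluded_unknown_side"] = excluded
        pnio.write_table(
            group_side_distribution(power, connectome), out / "group_side.csv"
        )
        for mode in ("at_least_one", "both"):
            ig = intergroup_graph(connectome, power.power_ids, mode)
            export = ig.graph.copy()
            relabel = {node: f"{node[0]}|{node[1]}" for node in export.nodes}
            import networkx as nx

            pnio.write_graphml(
                nx.relabel_nodes(export, relabel), out / f"intergroup_{mode}.graphml"
            )
        manifest["stages_completed"].append(stage)

        stage = "motifs"
        census = motif_census(connectome, power.power_ids)
        qap = qap_test(
            connectome,
            power.power_ids,
            census,
            n_permutations=config.qap_permutations,
            seed=config.stage_seed("qap"),
            shuffle_scope=config.qap_shuffle_scope,
        )
        pnio.write_table(census_to_frame(census, qap), out / "motif_census.csv")
        frequent = filter_frequent(census, qap, config.min_count, config.alpha)
        pnio.write_table(census_to_frame(frequent), out / "motifs_frequent.csv")
        pnio.write_table(mean_connections_frame(frequent), out / "motif_mean_connections.csv")
        if config.scan_thresholds:
            pnio.write_table(
                sensitivity_scan(census, qap, config.scan_thresholds, config.alpha),
                out / "motif_sensitivity.csv",
            )
        manifest["n_motifs"] = len(census)
        manifest["n_frequent_significant"] = len(frequent)
        manifest["stages_completed"].append(stage)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\nerror={exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    pnio.write_manifest(manifest, out / "manifest.json")
    return out
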