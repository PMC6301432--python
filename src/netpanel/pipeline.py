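"""End-to-end orchestration: simulate/load -> validate -> dynamics ->
structure -> compare -> report.

Every stage consumes and produces only documented files under the run's
output directory, logs record counts to stderr, and the whole run is a
deterministic function of the configuration and master seed (no
wall-clock or locale dependence). A stage failure leaves completed
stages' outputs intact; ``manifest.json`` records per-stage status.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

import netpanel
from netpanel import io as npio
from netpanel.dynamics import cohort_dynamics
from netpanel.roster import Dataset, from_simulation, validate_dataset
from netpanel.simulate import SimulationConfig, simulate_cohort
from netpanel.stats import baseline_table, ego_composition, network_or_table
from netpanel.structure import (
    EDGE_KINDS,
    assemble_graph,
    group_structure_comparison,
    node_metrics,
)

log = logging.getLogger("netpanel")


class PipelineError(RuntimeError):
    """A stage failed; the manifest names it."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Run configuration: exactly one of ``inputs`` or ``simulation``."""

    out_dir: str = "netpanel-run"
    seed: int = 0
    inputs: Optional[dict] = None  # paths to respondents/rosters/... csv files
    simulation: Optional[dict] = None  # SimulationConfig field overrides
    edge_kinds: tuple = EDGE_KINDS
    waves: Optional[tuple] = None
    ttest: str = "welch"
    or_direction: str = "auto"
    retained_rule: str = "strict"
    closeness: str = "corrected"
    verbosity: str = "info"

    def __post_init__(self):
        if (self.inputs is None) == (self.simulation is None):
            raise ValueError("exactly one of 'inputs' or 'simulation' is required")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "edge_kinds" in raw and raw["edge_kinds"] is not None:
            raw["edge_kinds"] = tuple(raw["edge_kinds"])
        if "waves" in raw and raw["waves"] is not None:
            raw["waves"] = tuple(raw["waves"])
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        over = dict(self.simulation or {})
        over.setdefault("rng_seed", self.seed)
        if "retain_prob" in over:
            over["retain_prob"] = {(k if isinstance(k, tuple) else tuple(k.split(":"))): v
                                   for k, v in over["retain_prob"].items()}
        if "new_tie_rate" in over:
            over["new_tie_rate"] = {(k if isinstance(k, tuple) else tuple(k.split(":"))): v
                                    for k, v in over["new_tie_rate"].items()}
        if "mixing" in over:
            over["mixing"] = tuple(tuple(row) for row in over["mixing"])
        return SimulationConfig(**over)


def _stage(manifest: dict, out_dir: Path, name: str):
    class _Ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            manifest["stages"][name] = "ok" if exc is None else f"failed: {exc}"
            npio.write_results_json(manifest, out_dir / "manifest.json")
            if exc is not None:
                log.error("stage %s: failed (%s)", name, exc)
                raise PipelineError(name, str(exc)) from exc
            log.info("stage %s: ok", name)
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns a machine-readable summary dict.

    The summary (also written to ``summary.json``) records the package
    version, seed, every statistical flag, and per-stage record counts.
    """
    logging.basicConfig(level=getattr(logging, config.verbosity.upper(), 20),
                        format="%(levelname)s %(name)s: %(message)s")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}}
    summary: dict = {
        "package": "netpanel",
        "version": netpanel.__version__,
        "seed": config.seed,
        "flags": {
            "edge_kinds": list(config.edge_kinds),
            "waves": list(config.waves) if config.waves else None,
            "ttest": config.ttest,
            "or_direction": config.or_direction,
            "retained_rule": config.retained_rule,
            "closeness": config.closeness,
        },
        "counts": {},
    }

    dataset: Dataset
    dataset_tables: dict = {}
    ground_truth = None
    if config.simulation is not None:
        with _stage(manifest, out_dir, "simulate"):
            sim = simulate_cohort(config.simulation_config())
            npio.write_dataset(sim, out_dir / "dataset")
            dataset_tables = sim.tables()
            ground_truth = sim.ground_truth
            for name, df in dataset_tables.items():
                summary["counts"][name] = int(len(df))

    with _stage(manifest, out_dir, "validate"):
        if config.simulation is None:
            required = ("respondents", "rosters", "matches", "attendance")
            missing = [k for k in required if k not in (config.inputs or {})]
            if missing:
                raise FileNotFoundError(f"input paths missing for tables: {missing}")
            for name in required:
                path = Path(config.inputs[name])
                if not path.exists():
                    raise FileNotFoundError(f"missing input table file: {path}")
                dataset_tables[name] = npio.read_table(path, name)
                summary["counts"][name] = int(len(dataset_tables[name]))
        dataset = validate_dataset(
            dataset_tables["respondents"], dataset_tables["rosters"],
            dataset_tables["matches"], dataset_tables["attendance"],
            ground_truth=ground_truth,
        )
        summary["counts"]["violations"] = len(dataset.violations)
        if dataset.violations:
            npio.write_results_table(
                pd.DataFrame([vars(v) for v in dataset.violations]),
                out_dir / "violations.csv",
            )

    with _stage(manifest, out_dir, "dynamics"):
        summaries, comparisons, exclusions = cohort_dynamics(
            dataset, retained_rule=config.retained_rule, ttest=config.ttest
        )
        npio.write_results_table(summaries, out_dir / "tie_change_summaries.csv")
        npio.write_results_table(comparisons, out_dir / "ratio_comparisons.csv")
        summary["counts"]["tie_change_summaries"] = int(len(summaries))
        summary["counts"]["dynamics_exclusions"] = len(exclusions)
        summary["ratio_comparisons"] = comparisons.to_dict(orient="records")

    with _stage(manifest, out_dir, "structure"):
        graph = assemble_graph(dataset, edge_kinds=config.edge_kinds,
                               waves=config.waves)
        metrics = node_metrics(graph, closeness=config.closeness)
        comparison = group_structure_comparison(metrics, dataset.respondents,
                                                ttest=config.ttest)
        npio.graph_to_graphml(graph, out_dir / "composite_network.graphml")
        npio.write_edge_list(graph, out_dir / "composite_edges.csv")
        npio.write_results_table(metrics.reset_index(), out_dir / "node_metrics.csv")
        npio.write_results_table(comparison, out_dir / "structure_comparison.csv")
        summary["counts"]["nodes"] = graph.number_of_nodes()
        summary["counts"]["edges"] = graph.number_of_edges()
        summary["structure_comparison"] = comparison.to_dict(orient="records")

    with _stage(manifest, out_dir, "compare"):
        composition = ego_composition(dataset, wave=1)
        baseline = baseline_table(dataset)
        ors = network_or_table(dataset, wave=1, direction=config.or_direction)
        npio.write_results_table(composition, out_dir / "ego_composition.csv")
        npio.write_results_table(baseline, out_dir / "baseline_table.csv")
        npio.write_results_table(ors, out_dir / "network_odds_ratios.csv")
        summary["counts"]["ego_composition"] = int(len(composition))
        summary["baseline_table"] = baseline.to_dict(orient="records")
        summary["network_odds_ratios"] = ors.to_dict(orient="records")

    with _stage(manifest, out_dir, "report"):
        npio.write_results_json(summary, out_dir / "summary.json")

    return summary
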