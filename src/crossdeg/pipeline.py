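"""End-to-end orchestration: simulate/load -> DE per species -> sample
clustering -> ortholog quadrants -> enrichment -> hub ranking -> report.

Given one config (YAML or JSON) and a seed, every output byte is
determined.  Outputs land in the configured directory under fixed names;
the run report (JSON) echoes the config and summarizes every stage's
counts.  Each stage can also be run standalone through the CLI on the
orchestrator's intermediate files and reproduces the same outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .diffexp import (
    call_degs,
    cluster_samples,
    estimate_dispersions,
    nb_wald_test,
    size_factors,
)
from .enrichment import fisher_enrich, top_terms
from .errors import ConfigError, CrossDEGError
from .io import (
    AnnotationSet,
    CountMatrix,
    EdgeList,
    OrthologMap,
    read_count_table,
    read_edge_list,
    read_gmt,
    read_ortholog_map,
    write_count_table,
    write_edge_list,
    write_gmt,
    write_ortholog_map,
    write_table,
)
from .ppi import build_graph, hub_table, rank_hubs
from .quadrants import join_orthologs, quadrant_partition, species_specific_sets
from .simulate import (
    GroundTruth,
    SynthConfig,
    simulate_annotations,
    simulate_counts,
    simulate_ppi,
)

log = logging.getLogger(__name__)

_INPUT_KEYS_REQUIRED = ("counts_a", "meta_a", "counts_b", "meta_b", "orthologs")
_INPUT_KEYS_OPTIONAL = ("gmt_a", "gmt_b", "edges")


class PipelineStageError(CrossDEGError):
    """Raised when a stage fails; names the stage, chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Fully-resolved pipeline configuration."""

    out_dir: Path
    seed: int = 0
    alpha: float = 0.05
    min_fc: float = 1.5
    top_terms: int = 10
    top_hubs: int = 5
    keep_isolated: bool = False
    dispersion_method: str = "auto"
    simulate: SynthConfig | None = None
    inputs: dict[str, Path] = field(default_factory=dict)

    def validate(self) -> None:
        problems = []
        if not (0.0 < self.alpha < 1.0):
            problems.append("alpha must lie in (0, 1)")
        if self.min_fc < 1.0:
            problems.append("min_fc must be >= 1")
        if self.top_terms < 1:
            problems.append("top_terms must be >= 1")
        if self.top_hubs < 1:
            problems.append("top_hubs must be >= 1")
        if self.dispersion_method not in ("auto", "trend", "genewise"):
            problems.append(f"unknown dispersion_method {self.dispersion_method!r}")
        if self.simulate is None and not self.inputs:
            problems.append("either 'simulate' or 'inputs' must be given")
        if self.inputs:
            missing = [k for k in _INPUT_KEYS_REQUIRED if k not in self.inputs]
            if missing:
                problems.append(f"inputs lacks required key(s): {missing}")
            for key, p in self.inputs.items():
                if not Path(p).exists():
                    problems.append(f"inputs.{key}: path {p} does not exist")
        if self.simulate is not None:
            try:
                self.simulate.validate()
            except ConfigError as exc:
                problems.append(f"simulate.{exc}")
        if problems:
            raise ConfigError("; ".join(problems))


def validate_config(path: str | Path) -> PipelineConfig:
    """Load, default and validate a YAML/JSON pipeline config.

    Unknown keys are rejected; all problems are reported at once.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    problems: list[str] = []
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    for key in sorted(unknown):
        problems.append(f"unknown key {key!r}")
    sim = None
    if "simulate" in raw and raw["simulate"] is not None:
        sim_raw = raw["simulate"]
        if not isinstance(sim_raw, dict):
            problems.append("'simulate' must be a mapping")
        else:
            sim_known = {f.name for f in dataclasses.fields(SynthConfig)}
            for key in sorted(set(sim_raw) - sim_known):
                problems.append(f"unknown key simulate.{key!r}")
            try:
                sim = SynthConfig(**{k: v for k, v in sim_raw.items() if k in sim_known})
            except TypeError as exc:
                problems.append(f"simulate: {exc}")
    inputs = {}
    if "inputs" in raw and raw["inputs"] is not None:
        if not isinstance(raw["inputs"], dict):
            problems.append("'inputs' must be a mapping")
        else:
            allowed = set(_INPUT_KEYS_REQUIRED) | set(_INPUT_KEYS_OPTIONAL)
            for key in sorted(set(raw["inputs"]) - allowed):
                problems.append(f"unknown key inputs.{key!r}")
            inputs = {
                k: Path(v) for k, v in raw["inputs"].items() if k in allowed
            }
    if "out_dir" not in raw:
        problems.append("missing required key 'out_dir'")
    cfg = None
    try:
        cfg = PipelineConfig(
            out_dir=Path(raw.get("out_dir", ".")),
            seed=int(raw.get("seed", 0)),
            alpha=float(raw.get("alpha", 0.05)),
            min_fc=float(raw.get("min_fc", 1.5)),
            top_terms=int(raw.get("top_terms", 10)),
            top_hubs=int(raw.get("top_hubs", 5)),
            keep_isolated=bool(raw.get("keep_isolated", False)),
            dispersion_method=str(raw.get("dispersion_method", "auto")),
            simulate=sim,
            inputs=inputs,
        )
        cfg.validate()
    except (TypeError, ValueError) as exc:
        problems.append(str(exc))
    if problems:
        raise ConfigError(f"{path}: " + "; ".join(problems))
    assert cfg is not None
    return cfg


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def run_de(
    cm: CountMatrix, alpha: float, min_fc: float, dispersion_method: str = "auto"
):
    """Size factors, dispersions and Wald table for one species."""
    s = size_factors(cm, fallback=True)
    disp = estimate_dispersions(cm, s, method=dispersion_method)
    table = nb_wald_test(cm, s, disp, alpha=alpha, min_fc=min_fc)
    return s, disp, table


def _write_de(table, path):
    out = table.copy()
    out = out.reset_index().sort_values(
        ["padj", "gene_id"], kind="stable", na_position="last"
    )
    write_table(out.set_index("gene_id"), path, index_label="gene_id")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _config_echo(config),
    }

    stage = "inputs"
    try:
        truth: GroundTruth | None = None
        anno_a: AnnotationSet | None = None
        anno_b: AnnotationSet | None = None
        edges: EdgeList | None = None
        graph_from_sim = None
        if config.simulate is not None:
            sim = dataclasses.replace(config.simulate, seed=config.seed)
            cm_a, cm_b, omap, truth = simulate_counts(sim)
            anno_b = simulate_annotations(sim, truth, cm_b.gene_ids)
            anno_a = simulate_annotations(
                sim, GroundTruth(), cm_a.gene_ids, planted_set=set()
            )
            # the interaction network covers the species-B-specific planted
            # DEGs (the network stage consumes B-specific sets downstream)
            b_spec_planted = sorted(
                (truth.up_b | truth.down_b)
                - {b for (a, b) in truth.quadrants}
            )
            sim_graph = dataclasses.replace(
                sim, graph_n_nodes=min(sim.graph_n_nodes, len(b_spec_planted))
            )
            if sim_graph.graph_n_nodes >= 2:
                graph_from_sim, hub = simulate_ppi(
                    sim_graph, b_spec_planted, hub_candidates=sorted(truth.up_b)
                )
                truth.hub = hub
                edges = EdgeList.from_pairs(graph_from_sim.edges())
            write_count_table(cm_a, out / "counts_A.tsv", out / "meta_A.tsv")
            write_count_table(cm_b, out / "counts_B.tsv", out / "meta_B.tsv")
            write_ortholog_map(omap, out / "orthologs.tsv")
            write_gmt(anno_a, out / "annotations_A.gmt")
            write_gmt(anno_b, out / "annotations_B.gmt")
            if edges is not None:
                write_edge_list(edges, out / "edges.tsv")
            truth.to_json(out / "ground_truth.json")
        else:
            cm_a = read_count_table(config.inputs["counts_a"], config.inputs["meta_a"])
            cm_b = read_count_table(config.inputs["counts_b"], config.inputs["meta_b"])
            omap = read_ortholog_map(config.inputs["orthologs"])
            if "gmt_a" in config.inputs:
                anno_a = read_gmt(config.inputs["gmt_a"])
            if "gmt_b" in config.inputs:
                anno_b = read_gmt(config.inputs["gmt_b"])
            if "edges" in config.inputs:
                edges = read_edge_list(config.inputs["edges"])
        report["genes_tested"] = {"A": len(cm_a.gene_ids), "B": len(cm_b.gene_ids)}
        report["orthologs"] = len(omap)

        stage = "diffexp"
        _, _, de_a = run_de(cm_a, config.alpha, config.min_fc, config.dispersion_method)
        _, _, de_b = run_de(cm_b, config.alpha, config.min_fc, config.dispersion_method)
        _write_de(de_a, out / "de_A.tsv")
        _write_de(de_b, out / "de_B.tsv")
        degs_a = call_degs(de_a, config.alpha, config.min_fc)
        degs_b = call_degs(de_b, config.alpha, config.min_fc)
        report["degs"] = {
            "A_up": len(degs_a[0]), "A_down": len(degs_a[1]),
            "B_up": len(degs_b[0]), "B_down": len(degs_b[1]),
        }

        stage = "clustering"
        for label, cm in (("A", cm_a), ("B", cm_b)):
            s = size_factors(cm, fallback=True)
            tree = cluster_samples(cm, s)
            (out / f"tree_{label}.nwk").write_text(tree.to_newick() + "\n")

        stage = "quadrants"
        overlap = join_orthologs(degs_a, degs_b, omap, de_a, de_b)
        part = quadrant_partition(overlap)
        write_table(overlap, out / "overlap.tsv")
        for q, t in part.tables.items():
            write_table(t, out / f"quadrant_{q}.tsv")
        report["overlap"] = int(part.total)
        report["quadrants"] = part.counts
        (out / "quadrant_summary.json").write_text(
            json.dumps(part.counts | {"total": part.total}, sort_keys=True, indent=2)
        )

        stage = "enrichment"
        runs: dict[str, tuple[set, AnnotationSet | None, set]] = {}
        bg_a, bg_b = set(cm_a.gene_ids), set(cm_b.gene_ids)
        runs["A_up"] = (degs_a[0], anno_a, bg_a)
        runs["A_down"] = (degs_a[1], anno_a, bg_a)
        runs["B_up"] = (degs_b[0], anno_b, bg_b)
        runs["B_down"] = (degs_b[1], anno_b, bg_b)
        for q in ("Q1", "Q2", "Q3", "Q4"):
            genes_q = {b for (_, b) in part.pairs(q)}
            runs[q] = (genes_q, anno_b, bg_b)
        report["enrichment"] = {}
        top_term_by_run = {}
        for name, (genes, anno, bg) in runs.items():
            if anno is None or not genes:
                continue
            res = fisher_enrich(genes, anno, bg)
            write_table(res, out / f"enrich_{name}.tsv")
            sig = int((res["fdr"] < 0.05).sum()) if len(res) else 0
            report["enrichment"][name] = {"terms_tested": len(res), "fdr_lt_05": sig}
            if len(res):
                top_term_by_run[name] = str(top_terms(res, 1).iloc[0]["term_id"])
        report["top_term"] = top_term_by_run

        stage = "network"
        spec_a, spec_b = species_specific_sets(degs_a, degs_b, omap)
        report["specific_degs"] = {"A": len(spec_a), "B": len(spec_b)}
        (out / "specific_A.txt").write_text("".join(g + "\n" for g in sorted(spec_a)))
        (out / "specific_B.txt").write_text("".join(g + "\n" for g in sorted(spec_b)))
        report["network"] = {"nodes": 0, "edges": 0}
        report["top_hubs"] = {"up": [], "down": []}
        if edges is not None:
            g = build_graph(edges, restrict_to=spec_b, keep_isolated=config.keep_isolated)
            direction_of = {n: "up" for n in degs_b[0]} | {
                n: "down" for n in degs_b[1]
            }
            records = hub_table(g, {n: d for n, d in direction_of.items() if n in g})
            write_table(records.sort_values(
                ["score", "degree", "node"], ascending=[False, False, True],
                kind="stable").reset_index(drop=True), out / "hubs.tsv")
            report["network"] = {
                "nodes": g.number_of_nodes(), "edges": g.number_of_edges()
            }
            for direction in ("up", "down"):
                ranked = rank_hubs(records, direction, top=config.top_hubs)
                write_table(ranked, out / f"top_hubs_{direction}.tsv")
                report["top_hubs"][direction] = list(ranked["node"])
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineStageError(stage, exc) from exc

    assert sum(report["quadrants"].values()) == report["overlap"]
    (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=2))
    return report


def _config_echo(config: PipelineConfig) -> dict:
    echo = dataclasses.asdict(config)
    echo["out_dir"] = str(echo["out_dir"])
    echo["inputs"] = {k: str(v) for k, v in echo["inputs"].items()}
    if echo["simulate"] is not None:
        echo["simulate"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in echo["simulate"].items()
        }
    return echo
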