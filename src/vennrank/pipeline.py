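"""End-to-end orchestration: load -> partition -> seed -> propagate -> rank.

This is the library-level entry point the command-line wrapper calls.  It
writes three artifacts into the output directory: ``regions.tsv`` (the
Venn-region summary), ``ranked.tsv`` (the prioritized gene table), and
``run.log`` (every count and parameter of the run, each recomputable from
the intermediate artifacts).  The whole pipeline is deterministic, so
identical inputs yield byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import deg_io, ppi_network, propagation, ranking, venn_partition
from .errors import AnalysisError


@dataclass
class RunConfig:
    """All knobs of one pipeline run; defaults follow the standard workflow
    (high-confidence cutoff 700, restart rate 0.5, L1 tolerance 1e-4)."""

    deg_paths: list[str | Path]
    ppi_path: str | Path
    seed_expression: str
    labels: list[str] | None = None
    alias_path: str | Path | None = None
    restrict_expression: str | None = None
    threshold: int = ppi_network.DEFAULT_THRESHOLD
    r: float = 0.5
    tol: float = 1e-4
    max_iter: int = 10_000
    delimiter: str = "\t"
    header: str = "auto"
    case_insensitive: bool = False
    output_dir: str | Path = "."


@dataclass
class RunResult:
    """Artifacts of one run, in memory."""

    experiments: list[deg_io.Experiment]
    regionmap: venn_partition.RegionMap
    graph: ppi_network.PpiGraph
    scores: propagation.ScoreVector
    table: pd.DataFrame
    seed_genes: set[str]
    log_lines: list[str] = field(default_factory=list)


def run(config: RunConfig) -> RunResult:
    """Execute the four-step workflow and write artifacts to ``output_dir``."""
    log_lines: list[str] = []

    def note(msg: str) -> None:
        log_lines.append(msg)

    # Step 1: load DEG lists
    experiments = deg_io.load_experiments(
        config.deg_paths,
        config.labels,
        delimiter=config.delimiter,
        header=config.header,
        case_insensitive=config.case_insensitive,
    )
    n = len(experiments)
    note(f"n_experiments\t{n}")
    for exp in experiments:
        note(f"experiment\t{exp.name}\trows={len(exp.records)}\tgenes={len(exp.genes)}")

    # Step 2: Venn partition
    regionmap = venn_partition.partition(experiments)
    deg_union = regionmap.union
    note(f"deg_union\t{len(deg_union)}")
    for i in sorted(regionmap.regions):
        note(f"region\tC{i}\t{len(regionmap.regions[i])}")

    # Step 3: seed selection
    seed_indices = venn_partition.parse_region_expression(config.seed_expression, n)
    seed_genes = venn_partition.genes_of(regionmap, seed_indices)
    note(f"seed_expression\t{config.seed_expression}\tseed_genes={len(seed_genes)}")
    if not seed_genes:
        raise AnalysisError("no seed genes present in network")
    restrict_to = None
    if config.restrict_expression:
        restrict_to = venn_partition.parse_region_expression(config.restrict_expression, n)
        note(f"restrict_expression\t{config.restrict_expression}")

    # Step 4: network instantiation and propagation
    ppi_text = Path(config.ppi_path).read_text(encoding="utf-8")
    all_edges = ppi_network.load_edges(ppi_text, threshold=-1)
    retained = ppi_network.load_edges(ppi_text, threshold=config.threshold)
    note(f"edges_loaded\t{len(all_edges)}")
    note(f"edges_over_threshold_{config.threshold}\t{len(retained)}")
    if config.alias_path is not None:
        alias = ppi_network.load_alias(Path(config.alias_path))
        retained, dropped = ppi_network.apply_alias(retained, alias)
        note(f"edges_dropped_unmapped\t{dropped}")
    graph = ppi_network.induce_subgraph(retained, deg_union)
    note(f"network_nodes\t{len(graph.nodes)}")
    note(f"network_edges\t{graph.n_edges}")

    A_prime = ppi_network.column_normalize(graph)
    seed = propagation.make_seed_vector(graph, seed_genes)
    note(f"seeds_in_network\t{len(seed.seed_genes)}")
    note(f"seeds_absent\t{len(seed.dropped)}")
    params = propagation.PropagationParams(r=config.r, tol=config.tol, max_iter=config.max_iter)
    scores = propagation.propagate(A_prime, seed, params)
    note(f"restart_rate\t{params.r}")
    note(f"tolerance\t{params.tol}")
    note(f"iterations\t{scores.iterations}")
    note(f"converged\t{scores.converged}")

    table = ranking.rank_genes(scores, graph, regionmap, seed_genes, restrict_to)
    note(f"ranked_genes\t{len(table)}")

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "regions.tsv", "w", encoding="utf-8") as fh:
        venn_partition.write_region_summary(regionmap, [e.name for e in experiments], fh)
    with open(out / "ranked.tsv", "w", encoding="utf-8") as fh:
        ranking.write_ranked_table(table, fh)
    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")

    return RunResult(
        experiments=experiments,
        regionmap=regionmap,
        graph=graph,
        scores=scores,
        table=table,
        seed_genes=seed_genes,
        log_lines=log_lines,
    )
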