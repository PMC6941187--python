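"""Synthetic DEG lists and STRING-dialect edge lists with planted structure.

The generator emulates the three pipeline inputs — per-experiment DEG
files, a scored protein-interaction edge list keyed by opaque protein IDs,
and the ID→symbol alias table — with a known ground truth:

* each gene in a fixed-size universe is assigned to one Venn region (or to
  the non-DEG background) by the region weight distribution, and appears in
  exactly the DEG files its region's membership bits dictate, under one to
  three synthetic transcript IDs;
* the interaction graph is a planted-partition model: a chosen fraction of
  the target region's genes ("linked" genes) attach to the seed region's
  genes with an elevated within-module probability, while every other pair
  uses a low background probability.  The default within-module probability
  is set so a linked gene's expected module degree roughly equals its
  background degree: seed proximity, not raw degree, is what distinguishes
  linked genes, so the planted signal is recoverable by propagation from the
  right seeds but not by degree alone.  Scores are drawn so that the >700
  high-confidence filter keeps roughly half of the module edges and a
  quarter of the background ones, exercising the threshold nontrivially.

Everything is reproducible from a single integer seed, and the returned
truth object is sufficient to recompute every intermediate count exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import UsageError
from .venn_partition import region_bits

#: score range for planted module edges: half exceed the 700 cutoff
_WITHIN_SCORE_RANGE = (400, 1000)
#: score range for background edges
_BETWEEN_SCORE_RANGE = (0, 1000)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    Defaults give two experiments over a 300-gene universe with a clear but
    not trivial enrichment signal: the seed region is C2 (genes only in
    experiment 2), the target region C1, and half of C1 is planted as
    functionally linked to the seeds.
    """

    n_experiments: int = 2
    universe_size: int = 300
    region_weights: dict[int, float] = field(
        default_factory=lambda: {1: 0.30, 2: 0.25, 3: 0.20}
    )
    module_edge_prob_within: float = 0.08
    module_edge_prob_between: float = 0.02
    seed_region: int = 2
    target_region: int = 1
    linked_fraction: float = 0.5
    rng_seed: int = 0

    def validate(self) -> None:
        max_region = 2**self.n_experiments - 1
        if self.n_experiments < 2:
            raise UsageError("need at least 2 experiments")
        total = sum(self.region_weights.values())
        if total > 1.0 + 1e-12:
            raise UsageError(f"region weights sum to {total} > 1")
        for i, w in self.region_weights.items():
            if not 1 <= i <= max_region:
                raise UsageError(f"region weight key C{i} invalid for n={self.n_experiments}")
            if not 0.0 <= w <= 1.0:
                raise UsageError(f"region weight {w} for C{i} outside [0, 1]")
        for name in ("module_edge_prob_within", "module_edge_prob_between", "linked_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise UsageError(f"{name}={v} outside [0, 1]")
        for name in ("seed_region", "target_region"):
            v = getattr(self, name)
            if not 1 <= v <= max_region:
                raise UsageError(f"{name}=C{v} invalid for n={self.n_experiments}")


@dataclass
class FixtureTruth:
    """Planted ground truth for one generated dataset."""

    region_of: dict[str, int]  # DEG genes only; background genes absent
    linked: set[str]  # target-region genes given module edges to the seeds
    protein_id: dict[str, str]  # gene symbol -> opaque network identifier
    deg_rows: dict[str, int]  # per-label row count (transcript lines)
    distinct_symbols: dict[str, int]  # per-label distinct gene count
    n_unique_pairs: int  # unordered edges drawn (any score)
    n_retained_edges: int  # unordered edges with score > 700

    def expected_region_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for region in self.region_of.values():
            counts[region] = counts.get(region, 0) + 1
        return counts


@dataclass
class Fixture:
    """In-memory fixture files plus their planted truth."""

    deg_texts: dict[str, str]  # label -> file content
    edge_text: str
    alias_text: str
    truth: FixtureTruth

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Materialize the fixture as a ready-to-run example directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for label, text in self.deg_texts.items():
            paths[label] = out / f"{label}.tsv"
            paths[label].write_text(text, encoding="utf-8")
        paths["edges"] = out / "edges.txt"
        paths["edges"].write_text(self.edge_text, encoding="utf-8")
        paths["alias"] = out / "alias.tsv"
        paths["alias"].write_text(self.alias_text, encoding="utf-8")
        return paths

    @property
    def deg_labels(self) -> list[str]:
        return list(self.deg_texts)


def expected_region_counts(truth: FixtureTruth) -> dict[int, int]:
    return truth.expected_region_counts()


def generate(spec: FixtureSpec = FixtureSpec()) -> Fixture:
    """Generate DEG files, edge list, alias table, and their ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_experiments
    max_region = 2**n - 1

    genes = [f"GENE{i:04d}" for i in range(1, spec.universe_size + 1)]

    # region assignment: index 0 = background (non-DEG)
    regions_list = sorted(spec.region_weights)
    probs = np.array([spec.region_weights[i] for i in regions_list])
    background = 1.0 - probs.sum()
    choice_pool = np.array([0] + regions_list)
    choice_probs = np.concatenate(([max(background, 0.0)], probs))
    choice_probs = choice_probs / choice_probs.sum()
    assignment = rng.choice(choice_pool, size=len(genes), p=choice_probs)
    region_of = {g: int(r) for g, r in zip(genes, assignment) if r != 0}

    # planted linked subset of the target region
    target_genes = sorted(g for g, r in region_of.items() if r == spec.target_region)
    seed_genes = sorted(g for g, r in region_of.items() if r == spec.seed_region)
    n_linked = int(round(spec.linked_fraction * len(target_genes)))
    linked = (
        {str(g) for g in rng.choice(target_genes, size=n_linked, replace=False)}
        if n_linked
        else set()
    )

    # DEG files: gene g appears in file j iff bit b_j of its region is set,
    # under 1-3 transcript IDs; rows shuffled within each file
    tx_count = {g: int(rng.integers(1, 4)) for g in genes if g in region_of}
    labels = [f"exp{j}" for j in range(1, n + 1)]
    deg_texts: dict[str, str] = {}
    deg_rows: dict[str, int] = {}
    distinct: dict[str, int] = {}
    for j, label in enumerate(labels, start=1):
        members = [g for g in genes if g in region_of and region_bits(region_of[g], n)[j - 1] == 1]
        rows = [
            f"{g}.t{k}\t{g}"
            for g in members
            for k in range(1, tx_count[g] + 1)
        ]
        order = rng.permutation(len(rows))
        shuffled = [rows[i] for i in order]
        deg_texts[label] = "transcript_id\tgene_symbol\n" + "\n".join(shuffled) + "\n"
        deg_rows[label] = len(rows)
        distinct[label] = len(members)

    # planted-partition edge list over opaque protein IDs
    protein_id = {g: f"SYN.P{i:05d}" for i, g in enumerate(genes, start=1)}
    is_linked = np.array([g in linked for g in genes])
    is_seed = np.array([region_of.get(g) == spec.seed_region for g in genes])
    iu, ju = np.triu_indices(len(genes), k=1)
    within = (is_linked[iu] & is_seed[ju]) | (is_seed[iu] & is_linked[ju])
    p_edge = np.where(within, spec.module_edge_prob_within, spec.module_edge_prob_between)
    drawn = rng.random(len(iu)) < p_edge
    s_within = rng.integers(_WITHIN_SCORE_RANGE[0], _WITHIN_SCORE_RANGE[1] + 1, size=len(iu))
    s_between = rng.integers(_BETWEEN_SCORE_RANGE[0], _BETWEEN_SCORE_RANGE[1] + 1, size=len(iu))
    scores = np.where(within, s_within, s_between)

    edge_lines = ["protein1 protein2 combined_score"]
    n_retained = 0
    for a, b, s in zip(iu[drawn], ju[drawn], scores[drawn]):
        pa, pb = protein_id[genes[a]], protein_id[genes[b]]
        edge_lines.append(f"{pa} {pb} {s}")
        edge_lines.append(f"{pb} {pa} {s}")  # STRING lists both directions
        if s > 700:
            n_retained += 1
    edge_text = "\n".join(edge_lines) + "\n"

    alias_text = "".join(f"{protein_id[g]}\t{g}\n" for g in genes)

    truth = FixtureTruth(
        region_of=region_of,
        linked=linked,
        protein_id=protein_id,
        deg_rows=deg_rows,
        distinct_symbols=distinct,
        n_unique_pairs=int(drawn.sum()),
        n_retained_edges=n_retained,
    )
    return Fixture(deg_texts=deg_texts, edge_text=edge_text, alias_text=alias_text, truth=truth)
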