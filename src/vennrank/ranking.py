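"""Turning converged propagation scores into the ranked DEG table.

Seed genes are always excluded from the ranking (they trivially score
highest and are the hypothesis, not the answer).  Optionally the table is
restricted to a set of target regions, mirroring the "discard everything
but the region of interest" reading of the workflow; by default every
non-seed DEG is ranked.  Unreachable isolates keep their (zero) score and
sit at the bottom rather than vanishing, so the table always covers the
whole candidate set.
"""

from __future__ import annotations

from typing import Iterable, TextIO

import pandas as pd

from .errors import AnalysisError
from .ppi_network import PpiGraph
from .propagation import ScoreVector
from .venn_partition import RegionMap

#: ranked-table column order
COLUMNS = ["rank", "gene", "score", "region", "is_seed", "degree"]


def rank_genes(
    scores: ScoreVector,
    graph: PpiGraph,
    regionmap: RegionMap,
    seed_genes: set[str],
    restrict_to: set[int] | None = None,
) -> pd.DataFrame:
    """Rank non-seed DEGs by descending propagation score.

    Ties break lexicographically on the gene symbol; ranks are strict
    ordinals 1..m with no gaps.  With ``restrict_to``, only genes whose
    Venn region is in the given set are ranked.
    """
    rows = []
    for i, gene in enumerate(graph.nodes):
        if gene in seed_genes:
            continue
        region = regionmap.region_of(gene)
        if restrict_to is not None and region not in restrict_to:
            continue
        rows.append(
            {
                "gene": gene,
                "score": float(scores.p[i]),
                "region": f"C{region}" if region is not None else "",
                "is_seed": False,
                "degree": graph.degree(gene),
            }
        )
    if not rows:
        raise AnalysisError("no candidate genes")
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    table.insert(0, "rank", range(1, len(table) + 1))
    return table[COLUMNS]


def write_ranked_table(table: pd.DataFrame, stream: TextIO) -> None:
    """Write the ranked table as TSV with scores at 6 significant digits."""
    stream.write("\t".join(COLUMNS) + "\n")
    for row in table.itertuples(index=False):
        stream.write(
            f"{row.rank}\t{row.gene}\t{row.score:.6g}\t{row.region}\t"
            f"{str(row.is_seed).lower()}\t{row.degree}\n"
        )


def read_ranked_table(stream: TextIO | str) -> pd.DataFrame:
    """Re-read a written table (round-trip checks, downstream tooling)."""
    table = pd.read_csv(stream, sep="\t")
    table["is_seed"] = table["is_seed"].astype(bool)
    return table
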