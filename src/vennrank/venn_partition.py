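"""Disjoint Venn-region partition of n gene sets.

With n experiments E_1..E_n there are 2^n − 1 non-empty membership
combinations.  Region C_i is indexed by the binary expansion of i with b_1
as the *least-significant* bit: b_j = 1 means "member of E_j", b_j = 0 means
"member of E_j's complement".  So for n = 3, C_1 = 001 holds genes found
only in E_1, and C_7 = 111 holds E_1 ∩ E_2 ∩ E_3.  Every gene appearing in
any experiment lands in exactly one region; the regions partition the union.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

from .deg_io import Experiment
from .errors import UsageError

_TOKEN_RE = re.compile(r"^[Cc](\d+)$")


def region_bits(i: int, n: int) -> tuple[int, ...]:
    """Binary digits (b_1, ..., b_n) of region index ``i``, b_1 = LSB."""
    return tuple((i >> (j - 1)) & 1 for j in range(1, n + 1))


def region_members(i: int, n: int) -> tuple[int, ...]:
    """1-based experiment indices j with b_j = 1."""
    return tuple(j for j in range(1, n + 1) if (i >> (j - 1)) & 1)


@dataclass
class RegionMap:
    """The 2^n − 1 disjoint regions, all materialized (possibly empty)."""

    n: int
    regions: dict[int, set[str]]

    def __post_init__(self) -> None:
        expected = set(range(1, 2**self.n))
        missing = expected - set(self.regions)
        for i in missing:
            self.regions[i] = set()

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for genes in self.regions.values():
            out |= genes
        return out

    def region_of(self, gene: str) -> int | None:
        """Region index of ``gene``, or None if it is in no experiment."""
        return self._gene_index().get(gene)

    def _gene_index(self) -> dict[str, int]:
        if not hasattr(self, "_cached_index"):
            self._cached_index = {
                g: i for i, genes in self.regions.items() for g in genes
            }
        return self._cached_index


def partition(experiments: Sequence[Experiment]) -> RegionMap:
    """Assign every gene in any experiment to its unique membership region.

    A gene's region index is the bitmask over experiments containing it:
    ``i = Σ_j 2^(j−1) [gene ∈ E_j]``.
    """
    n = len(experiments)
    if n < 2:
        raise UsageError("partition requires at least 2 experiments")
    gene_sets = [exp.genes for exp in experiments]
    regions: dict[int, set[str]] = {i: set() for i in range(1, 2**n)}
    universe: set[str] = set()
    for s in gene_sets:
        universe |= s
    for gene in universe:
        idx = 0
        for j, s in enumerate(gene_sets, start=1):
            if gene in s:
                idx |= 1 << (j - 1)
        regions[idx].add(gene)
    return RegionMap(n=n, regions=regions)


def parse_region_expression(expr: str, n: int) -> set[int]:
    """Parse a '+'-joined union of region tokens, e.g. ``"C2+C4"`` -> {2, 4}.

    Only union is supported: regions are pairwise disjoint, so intersection
    or difference of regions is always empty or redundant.
    """
    if not expr or not expr.strip():
        raise UsageError("empty region expression")
    max_index = 2**n - 1
    indices: set[int] = set()
    for token in expr.split("+"):
        token = token.strip()
        m = _TOKEN_RE.match(token)
        if not m:
            raise UsageError(
                f"malformed region token {token!r} (expected C<k>, e.g. C2+C4)"
            )
        k = int(m.group(1))
        if not 1 <= k <= max_index:
            raise UsageError(
                f"region token {token!r} out of range: valid indices are "
                f"C1..C{max_index} for {n} experiments"
            )
        indices.add(k)
    return indices


def genes_of(regionmap: RegionMap, indices: Iterable[int]) -> set[str]:
    """Union of the selected regions' gene sets (a disjoint union)."""
    indices = set(indices)
    if not indices:
        raise UsageError("no regions selected")
    out: set[str] = set()
    for i in indices:
        if i not in regionmap.regions:
            raise UsageError(f"region C{i} does not exist for n={regionmap.n}")
        out |= regionmap.regions[i]
    return out


def write_region_summary(
    regionmap: RegionMap,
    labels: Sequence[str],
    stream: TextIO,
) -> None:
    """Write the per-region report, sorted by descending gene count.

    ``code_b1_first`` prints digits b_1..b_n left to right (so C_1 of n=3 is
    ``100``); ``code_msb_first`` is the conventional binary literal (``001``).
    """
    stream.write(
        "# region code legend: code_b1_first lists b_1..b_n left-to-right; "
        "b_j=1 means member of experiment j\n"
    )
    stream.write(
        "region_index\tcode_b1_first\tcode_msb_first\tmember_experiments\t"
        "gene_count\tgenes\n"
    )
    order = sorted(
        regionmap.regions,
        key=lambda i: (-len(regionmap.regions[i]), i),
    )
    for i in order:
        bits = region_bits(i, regionmap.n)
        members = ",".join(labels[j - 1] for j in region_members(i, regionmap.n))
        genes = ",".join(sorted(regionmap.regions[i]))
        stream.write(
            f"C{i}\t{''.join(map(str, bits))}\t"
            f"{''.join(map(str, reversed(bits)))}\t{members}\t"
            f"{len(regionmap.regions[i])}\t{genes}\n"
        )
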