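import io
import itertools

import numpy as np
import pytest

import vennrank as vr
from vennrank.errors import UsageError
from vennrank.venn_partition import (
    genes_of,
    parse_region_expression,
    partition,
    region_bits,
    region_members,
    write_region_summary,
)

from conftest import random_experiments


def brute_force_regions(experiments):
    """Independent oracle: classify each gene by testing membership in every
    experiment and summing 2^(j-1) over memberships."""
    n = len(experiments)
    universe = set().union(*(e.genes for e in experiments))
    regions = {i: set() for i in range(1, 2**n)}
    for g in universe:
        mask = sum(2 ** (j - 1) for j, e in enumerate(experiments, 1) if g in e.genes)
        regions[mask].add(g)
    return regions


def exp_from_genes(name, genes):
    return vr.Experiment(name, [vr.DegRecord(f"{name}.{g}", g) for g in genes])


class TestBitEncoding:
    def test_bit_one_is_least_significant(self):
        # region C1 of three sets means "in E1 only": bits (1, 0, 0)
        assert region_bits(1, 3) == (1, 0, 0)
        assert region_bits(2, 3) == (0, 1, 0)
        assert region_bits(7, 3) == (1, 1, 1)
        assert region_members(5, 3) == (1, 3)


class TestPartition:
    def test_three_sets_give_seven_regions(self):
        # every membership combination occupied -> all 2^3 - 1 regions non-empty
        exps = [
            exp_from_genes("E1", {"a", "ab", "ac", "abc"}),
            exp_from_genes("E2", {"b", "ab", "bc", "abc"}),
            exp_from_genes("E3", {"c", "ac", "bc", "abc"}),
        ]
        rm = partition(exps)
        assert len(rm.regions) == 7
        assert all(len(g) > 0 for g in rm.regions.values())
        assert rm.regions[7] == exps[0].genes & exps[1].genes & exps[2].genes == {"abc"}
        assert rm.regions[1] == {"a"}
        assert rm.regions[3] == {"ab"}  # E1 and E2, not E3

    def test_full_overlap_two_sets(self):
        rm = partition([exp_from_genes("E1", {"a"}), exp_from_genes("E2", {"a"})])
        assert rm.regions[3] == {"a"}
        assert rm.regions[1] == set() and rm.regions[2] == set()

    def test_empty_regions_materialized(self):
        rm = partition([exp_from_genes("E1", {"x"}), exp_from_genes("E2", {"y"})])
        assert set(rm.regions) == {1, 2, 3}

    def test_single_experiment_rejected(self):
        with pytest.raises(UsageError):
            partition([exp_from_genes("E1", {"a"})])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = int(rng.integers(2, 7))
            exps = random_experiments(rng, n, int(rng.integers(1, 201)))
            rm = partition(exps)
            assert rm.regions == brute_force_regions(exps)

    def test_disjointness_coverage_cardinality(self):
        rng = np.random.default_rng(42)
        exps = random_experiments(rng, 4, 150)
        rm = partition(exps)
        union = set().union(*(e.genes for e in exps))
        assert rm.union == union
        assert sum(len(g) for g in rm.regions.values()) == len(union)
        for i, j in itertools.combinations(rm.regions, 2):
            assert not (rm.regions[i] & rm.regions[j])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(7)
        exps = random_experiments(rng, 3, 80)
        rm = partition(exps)
        perm = [2, 0, 1]  # new position k holds old experiment perm[k]
        rm_p = partition([exps[p] for p in perm])
        for i in range(1, 8):
            bits = region_bits(i, 3)
            permuted_bits = tuple(bits[p] for p in perm)
            j = sum(b << k for k, b in enumerate(permuted_bits))
            assert rm.regions[i] == rm_p.regions[j]


class TestRegionExpression:
    @pytest.mark.parametrize(
        "expr,n,expected",
        [
            ("C2+C4", 3, {2, 4}),
            ("C1", 2, {1}),
            ("c1 + C3", 2, {1, 3}),
            ("C2+C2", 3, {2}),
            ("C3+C12+C192", 8, {3, 12, 192}),
        ],
    )
    def test_valid_expressions(self, expr, n, expected):
        assert parse_region_expression(expr, n) == expected

    @pytest.mark.parametrize("expr,n", [("C9", 3), ("C0", 2), ("C", 2), ("X1", 2), ("", 2), ("C1-C2", 3)])
    def test_invalid_expressions(self, expr, n):
        with pytest.raises(UsageError):
            parse_region_expression(expr, n)

    def test_error_names_the_token(self):
        with pytest.raises(UsageError, match="C9"):
            parse_region_expression("C1+C9", 3)


class TestGenesOf:
    def test_all_regions_cover_union(self):
        rng = np.random.default_rng(3)
        exps = random_experiments(rng, 3, 100)
        rm = partition(exps)
        assert genes_of(rm, set(rm.regions)) == set().union(*(e.genes for e in exps))

    def test_top_region_is_full_intersection(self):
        exps = [
            exp_from_genes("E1", {"a", "abc"}),
            exp_from_genes("E2", {"b", "abc"}),
            exp_from_genes("E3", {"abc"}),
        ]
        assert genes_of(partition(exps), {7}) == {"abc"}

    def test_union_matches_oracle(self):
        rng = np.random.default_rng(11)
        exps = random_experiments(rng, 4, 60)
        rm = partition(exps)
        oracle = brute_force_regions(exps)
        sel = {1, 5, 9}
        assert genes_of(rm, sel) == oracle[1] | oracle[5] | oracle[9]

    def test_empty_selection_rejected(self):
        rm = partition([exp_from_genes("E1", {"a"}), exp_from_genes("E2", {"b"})])
        with pytest.raises(UsageError):
            genes_of(rm, set())


def test_region_summary_report_is_sorted_and_complete():
    exps = [exp_from_genes("tumor", {"a", "ab"}), exp_from_genes("normal", {"b", "ab"})]
    rm = partition(exps)
    buf = io.StringIO()
    write_region_summary(rm, ["tumor", "normal"], buf)
    lines = buf.getvalue().splitlines()
    assert lines[1].startswith("region_index\t")
    body = [l.split("\t") for l in lines[2:]]
    assert len(body) == 3
    counts = [int(row[4]) for row in body]
    assert counts == sorted(counts, reverse=True)
    c3 = next(row for row in body if row[0] == "C3")
    assert c3[1] == "11" and c3[3] == "tumor,normal" and c3[5] == "ab"
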