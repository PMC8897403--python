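"""Covering rough-set primitives: granulation, approximations,
neighbourhoods, effective blocks, related family and exhaustive reducts."""

import pytest

from phedkit.covering import (
    Covering,
    CoveringDecisionTable,
    DecisionPartition,
    InconsistentTableError,
    Universe,
    all_reducts,
    approximation_pair,
    brute_force_reducts,
    descriptions,
    effective_blocks,
    granulate,
    neighborhood,
    positive_region,
    related_family,
)
from phedkit.datagen import SynthSpec, synth_table

OBJS = ("x1", "x2", "x3", "x4", "x5", "x6")


def fs(*names):
    return frozenset(names)


class TestGranulate:
    def test_symbolic_equal_value_partition(self):
        cov = granulate(OBJS, ["A", "A", "B", "B", "C", "C"], "symbolic", "a")
        assert set(cov.blocks) == {fs("x1", "x2"), fs("x3", "x4"), fs("x5", "x6")}

    def test_numeric_delta_neighborhoods(self):
        # range 5, delta 0.2 -> tolerance 1
        cov = granulate(OBJS, [1, 2, 3, 4, 5, 6], "numeric", "a", delta=0.2)
        by_center = {}
        for block, meta in zip(cov.blocks, cov.block_meta):
            for pred in meta:
                by_center[(pred[1] + pred[2]) / 2] = block
        assert by_center[1.0] == fs("x1", "x2")
        assert by_center[3.0] == fs("x2", "x3", "x4")

    def test_numeric_zero_range_degenerates_to_universe(self):
        cov = granulate(OBJS, [7] * 6, "numeric", "a", delta=0.5)
        assert cov.blocks == (frozenset(OBJS),)

    def test_duplicate_blocks_merged(self):
        cov = granulate(("a", "b"), [0.0, 0.1], "numeric", "a", delta=1.0)
        assert cov.blocks == (fs("a", "b"),)
        assert len(cov.block_meta[0]) == 2  # both generators retained

    @pytest.mark.parametrize("delta", [0.0, -0.1, 1.5, None])
    def test_invalid_delta_rejected(self, delta):
        with pytest.raises(ValueError):
            granulate(OBJS, [1, 2, 3, 4, 5, 6], "numeric", "a", delta=delta)

    def test_empty_values_rejected(self):
        with pytest.raises(ValueError):
            granulate((), [], "symbolic", "a")


class TestApproximations:
    U = Universe(OBJS)
    PARTITION = (fs("x1", "x2"), fs("x3", "x4"), fs("x5", "x6"))

    def test_lower_and_upper_bracket_target(self):
        lower, upper = approximation_pair(self.PARTITION, fs("x1", "x2", "x3"), self.U)
        assert lower == fs("x1", "x2")
        assert upper == fs("x1", "x2", "x3", "x4")

    @pytest.mark.parametrize(
        "target", [frozenset(), frozenset(OBJS), fs("x1"), fs("x2", "x5")]
    )
    def test_duality_lower_equals_complement_of_upper(self, target):
        lower, _ = approximation_pair(self.PARTITION, target, self.U)
        _, upper_c = approximation_pair(
            self.PARTITION, frozenset(OBJS) - target, self.U
        )
        assert lower == frozenset(OBJS) - upper_c

    def test_extremes(self):
        full = frozenset(OBJS)
        assert approximation_pair(self.PARTITION, full, self.U) == (full, full)
        assert approximation_pair(self.PARTITION, frozenset(), self.U) == (
            frozenset(),
            frozenset(),
        )

    def test_unknown_object_rejected(self):
        with pytest.raises(ValueError):
            approximation_pair(self.PARTITION, fs("zz"), self.U)


class TestNeighborhoodAndDescriptions:
    def test_neighborhood_intersects_containing_blocks(self, worked_table):
        c5 = worked_table.covering("C5")
        assert neighborhood(c5, "x1") == fs("x1")
        c1 = worked_table.covering("C1")
        assert neighborhood(c1, "x1") == fs("x1", "x2")

    def test_neighborhood_contains_object_and_within_blocks(self, worked_table):
        for cov in worked_table.coverings:
            for x in worked_table.universe.objects:
                n = neighborhood(cov, x)
                assert x in n
                for b in cov.blocks_containing(x):
                    assert n <= b

    def test_min_max_descriptions(self, worked_table):
        c5 = worked_table.covering("C5")
        minimal, maximal = descriptions(c5, "x1")
        assert minimal == frozenset({fs("x1", "x2"), fs("x1", "x3")})
        assert maximal == frozenset({fs("x1", "x2", "x3")})
        c2 = worked_table.covering("C2")
        assert descriptions(c2, "x3") == (
            frozenset({fs("x3")}),
            frozenset({fs("x3")}),
        )

    def test_partition_covering_min_equals_max(self, worked_table):
        c1 = worked_table.covering("C1")
        for x in worked_table.universe.objects:
            minimal, maximal = descriptions(c1, x)
            assert minimal == maximal
            (block,) = minimal
            assert x in block


class TestPositiveRegion:
    def test_consistent_covering_certifies_all(self, worked_table):
        pos = positive_region(
            worked_table.covering("C5"), worked_table.decision, worked_table.universe
        )
        assert pos == frozenset(OBJS)

    def test_straddling_covering_loses_objects(self, worked_table):
        pos = positive_region(
            worked_table.covering("C4"), worked_table.decision, worked_table.universe
        )
        assert pos < frozenset(OBJS)

    def test_single_class_decision_gives_universe(self, worked_table):
        single = DecisionPartition.from_dict({"D": OBJS})
        pos = positive_region(worked_table.covering("C4"), single, worked_table.universe)
        assert pos == frozenset(OBJS)


class TestEffectiveBlocksAndFamily:
    def test_effective_blocks_per_covering(self, worked_table):
        eff = effective_blocks(worked_table)
        by_cov = {}
        for e in eff:
            by_cov.setdefault(e.covering_id, set()).add(e.block)
        assert "C4" not in by_cov
        assert by_cov["C2"] == {fs("x3"), fs("x4", "x5"), fs("x6")}
        assert by_cov["C1"] == {fs("x1", "x2"), fs("x5", "x6")}

    def test_every_effective_block_inside_one_class(self, worked_table):
        for e in effective_blocks(worked_table):
            containing = [
                lab
                for lab, mem in worked_table.decision.classes
                if e.block <= mem
            ]
            assert containing == [e.decision_label]

    def test_related_family_matches_worked_example(self, worked_table):
        fam = related_family(worked_table)
        assert fam.r("x1") == fs("C1", "C3", "C5")
        assert fam.r("x2") == fs("C1", "C5")
        assert fam.r("x3") == fs("C2", "C5")
        assert fam.r("x4") == fs("C2", "C5")
        assert fam.r("x5") == fs("C1", "C2", "C3", "C5")
        assert fam.r("x6") == fs("C1", "C2", "C3", "C5")
        assert fam.family == frozenset(
            {
                fs("C1", "C3", "C5"),
                fs("C1", "C5"),
                fs("C2", "C5"),
                fs("C1", "C2", "C3", "C5"),
            }
        )
        assert fam.uncovered == ()

    def test_uncovered_objects_reported_not_dropped(self):
        # one covering whose only block straddles both classes
        table = CoveringDecisionTable(
            Universe(("a", "b")),
            (Covering("C1", (fs("a", "b"),)),),
            DecisionPartition.from_dict({"d1": ("a",), "d2": ("b",)}),
        )
        fam = related_family(table)
        assert fam.family == frozenset()
        assert set(fam.uncovered) == {"a", "b"}


class TestAllReducts:
    def test_worked_example_reducts(self, worked_table):
        formula = all_reducts(worked_table)
        assert formula.dnf_minimal == frozenset(
            {fs("C1", "C2"), fs("C5")}
        )

    def test_single_covering_table(self):
        table = CoveringDecisionTable(
            Universe(("a", "b")),
            (Covering("C1", (fs("a"), fs("b"))),),
            DecisionPartition.from_dict({"d1": ("a",), "d2": ("b",)}),
        )
        assert all_reducts(table).dnf_minimal == frozenset({fs("C1")})

    def test_inconsistent_table_raises(self):
        table = CoveringDecisionTable(
            Universe(("a", "b")),
            (Covering("C1", (fs("a", "b"),)),),
            DecisionPartition.from_dict({"d1": ("a",), "d2": ("b",)}),
        )
        with pytest.raises(InconsistentTableError):
            all_reducts(table)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_power_set_oracle_on_random_tables(self, seed):
        spec = SynthSpec(
            n_objects=10,
            n_coverings=5,
            n_classes=2,
            planted_reduct_size=2,
            seed=seed,
        )
        table, _ = synth_table(spec)
        formula = all_reducts(table)
        assert formula.dnf_minimal == brute_force_reducts(table)
        # every DNF term hits every clause, minimally
        for term in formula.dnf_minimal:
            assert all(term & clause for clause in formula.cnf)
            for v in term:
                assert not all((term - {v}) & clause for clause in formula.cnf)


class TestInvariantValidation:
    def test_blocks_must_cover_universe(self):
        with pytest.raises(ValueError, match="does not cover"):
            CoveringDecisionTable(
                Universe(("a", "b")),
                (Covering("C1", (fs("a"),)),),
                DecisionPartition.from_dict({"d": ("a", "b")}),
            )

    def test_decision_must_partition_universe(self):
        with pytest.raises(ValueError):
            CoveringDecisionTable(
                Universe(("a", "b")),
                (Covering("C1", (fs("a", "b"),)),),
                DecisionPartition.from_dict({"d1": ("a",), "d2": ("a", "b")}),
            )

    def test_nonpositive_cost_rejected(self):
        with pytest.raises(ValueError):
            Covering("C1", (fs("a"),), cost=0.0)

    def test_duplicate_objects_rejected(self):
        with pytest.raises(ValueError):
            Universe(("a", "a"))
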