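"""Fold-change thresholding and DEG set operations."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from immunoscreen import (
    Culture,
    DEGSet,
    Direction,
    FoldChangeRecord,
    common_degs,
    deg_select,
    unique_degs,
    venn_counts,
)
from immunoscreen.errors import DuplicationError, ValidationError
from immunoscreen.expression_sets import read_fold_changes


def fc(gene, value, culture=Culture.CANCER_MONO, dose=10.0):
    return FoldChangeRecord(gene, culture, dose, value)


class TestFoldChangeRecord:
    @pytest.mark.parametrize("bad", [0.5, -0.5, 0.0, 0.99])
    def test_signed_linear_gap_rejected(self, bad):
        with pytest.raises(ValidationError):
            fc("G", bad)

    @pytest.mark.parametrize("ok", [1.0, -1.0, 2.5, -3.0])
    def test_valid_values(self, ok):
        assert fc("G", ok).fold_change == ok


class TestDegSelect:
    def test_threshold_rule(self):
        sets = deg_select([fc("up", 2.5), fc("down", -2.5), fc("mid", 1.8)])
        s = sets["CANCER_MONO@10uM"]
        assert s.genes_up == {"up"}
        assert s.genes_down == {"down"}

    def test_boundary_inclusive(self):
        sets = deg_select([fc("edge", 2.0), fc("neg", -2.0)])
        s = sets["CANCER_MONO@10uM"]
        assert "edge" in s.genes_up and "neg" in s.genes_down

    def test_empty_table(self):
        assert deg_select([]) == {}

    def test_duplicate_rows_rejected(self):
        with pytest.raises(DuplicationError):
            deg_select([fc("G", 2.5), fc("G", 3.0)])

    def test_idempotent_reselection(self):
        records = [fc("a", 4.0), fc("b", -2.0), fc("c", 1.5)]
        first = deg_select(records)
        again = deg_select([r for r in records if abs(r.fold_change) >= 2])
        assert first == again

    def test_threshold_must_exceed_one(self):
        with pytest.raises(ValidationError):
            deg_select([fc("G", 2.0)], threshold=1.0)


class TestCommonAndUnique:
    A = DEGSet("A", genes_up={"a", "b", "c"})
    B = DEGSet("B", genes_up={"b", "c"}, genes_down={"x"})

    def test_common_up(self):
        assert common_degs([self.A, self.B], Direction.UP) == {"b", "c"}

    def test_discordant_any_vs_concordant(self):
        one = DEGSet("one", genes_up={"s100a14"})
        two = DEGSet("two", genes_down={"s100a14"})
        assert common_degs([one, two], Direction.ANY) == {"s100a14"}
        assert common_degs([one, two], Direction.CONCORDANT) == frozenset()

    def test_disjoint_sets(self):
        c = DEGSet("C", genes_up={"q"})
        assert common_degs([self.A, c], Direction.ANY) == frozenset()

    def test_unique_excludes_any_direction(self):
        target = DEGSet("T", genes_up={"a", "b"})
        other = DEGSet("O", genes_down={"a"})
        assert unique_degs(target, [other], Direction.UP) == {"b"}

    def test_unique_against_empty_others(self):
        target = DEGSet("T", genes_up={"a", "b"})
        assert unique_degs(target, [DEGSet("O")], Direction.ANY) == {"a", "b"}

    def test_unique_of_subset_is_empty(self):
        assert unique_degs(self.B, [self.B]) == frozenset()

    def test_self_identities(self):
        assert common_degs([self.B, self.B]) == self.B.select(Direction.ANY)


deg_set_strategy = st.builds(
    lambda label, up, down: DEGSet(label, frozenset(up) - frozenset(down), down),
    label=st.just(""),
    up=st.sets(st.integers(0, 199).map(str), max_size=80),
    down=st.sets(st.integers(0, 199).map(str), max_size=80),
)


class TestVennCounts:
    def test_two_set_regions(self):
        a = DEGSet("A", genes_up={"a", "b"})
        b = DEGSet("B", genes_up={"b", "c"})
        counts = venn_counts([a, b])
        assert counts[frozenset({"A"})] == 1
        assert counts[frozenset({"B"})] == 1
        assert counts[frozenset({"A", "B"})] == 1

    def test_identical_sets_all_in_core(self):
        a = DEGSet("A", genes_up={"x", "y"})
        b = DEGSet("B", genes_up={"x", "y"})
        counts = venn_counts([a, b])
        assert counts[frozenset({"A", "B"})] == 2
        assert counts[frozenset({"A"})] == 0

    def test_three_disjoint_sets(self):
        sets = [DEGSet(l, genes_up={f"{l}{i}" for i in range(3)}) for l in "ABC"]
        counts = venn_counts(sets)
        for region, n in counts.items():
            assert n == (3 if len(region) == 1 else 0)

    def test_arity_limits(self):
        sets = [DEGSet(l, genes_up={"x"}) for l in "ABCD"]
        with pytest.raises(ValidationError):
            venn_counts(sets)
        with pytest.raises(ValidationError):
            venn_counts(sets[:1])

    @settings(max_examples=50, deadline=None)
    @given(
        raw=st.lists(deg_set_strategy, min_size=3, max_size=3),
        direction=st.sampled_from([Direction.ANY, Direction.UP, Direction.DOWN]),
    )
    def test_matches_brute_force_enumeration(self, raw, direction):
        """Region counts agree with per-gene membership enumeration,
        and sum to the union size."""
        sets = [
            DEGSet(label, s.genes_up, s.genes_down)
            for label, s in zip("ABC", raw)
        ]
        counts = venn_counts(sets, direction)
        union = set().union(*(s.select(direction) for s in sets))
        brute = {k: 0 for k in counts}
        for gene in union:
            labs = frozenset(
                s.condition for s in sets if gene in s.select(direction)
            )
            brute[labs] += 1
        assert counts == brute
        assert sum(counts.values()) == len(union)

        # common/unique agree with direct set algebra on the same fixture
        assert common_degs(sets, direction) == frozenset(
            set.intersection(*(set(s.select(direction)) for s in sets))
        )
        assert unique_degs(sets[0], sets[1:], direction) == frozenset(
            set(sets[0].select(direction))
            - set(sets[1].select(Direction.ANY))
            - set(sets[2].select(Direction.ANY))
        )


class TestIO:
    def test_read_linear_and_log2(self, tmp_path):
        path = tmp_path / "fc.tsv"
        path.write_text(
            "gene\tculture\tdose_uM\tfold_change\n"
            "CCL20\tCOCULTURE\t10\t4.0\n"
            "KLF2\tCANCER_MONO\t1\t-2.5\n"
        )
        records = read_fold_changes(path)
        assert records[0].fold_change == 4.0
        assert records[1].fold_change == -2.5

        log_path = tmp_path / "fc_log2.tsv"
        log_path.write_text(
            "gene\tculture\tdose_uM\tfold_change\n"
            "CCL20\tCOCULTURE\t10\t2.0\n"
            "KLF2\tCANCER_MONO\t1\t-1.0\n"
        )
        records = read_fold_changes(log_path, log2=True)
        assert records[0].fold_change == pytest.approx(4.0)
        assert records[1].fold_change == pytest.approx(-2.0)
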