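"""Alias resolution, cross-caller merging, and k-of-n consensus selection."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from fusemble.errors import ContractError, ValidationError
from fusemble.harmonize import (
    AliasTable,
    canonical_pair,
    consensus_select,
    merge_calls,
    merge_cohort,
)
from fusemble.model import Breakpoint, CALLERS, RawCall


def make_call(caller="arriba", sample="S", g5="KMT2A", g3="AFF1",
              pos5=1000, pos3=2000, split=5, spanning=3, frame="unknown"):
    return RawCall(
        caller=caller,
        sample_id=sample,
        bp5=Breakpoint("11", pos5, "+", g5),
        bp3=Breakpoint("4", pos3, "+", g3),
        split_reads=split,
        spanning_reads=spanning,
        frame=frame,
    )


class TestAliasTable:
    def test_alias_substitution(self):
        aliases = AliasTable({"MLL": "KMT2A"})
        assert canonical_pair(make_call(g5="MLL", g3="AFF1"), aliases) == ("KMT2A", "AFF1")

    def test_identity_with_empty_table(self):
        assert canonical_pair(make_call(), AliasTable()) == ("KMT2A", "AFF1")

    def test_chain_resolves_to_fixed_point(self):
        aliases = AliasTable({"A": "B", "B": "B"})
        assert aliases.resolve("A") == "B"
        chained = AliasTable({"A": "B", "B": "C"})
        assert chained.resolve("A") == "C" and chained.resolve("B") == "C"

    def test_cycle_is_rejected(self):
        with pytest.raises(ValidationError):
            AliasTable({"A": "B", "B": "A"})

    def test_empty_symbol_is_an_error(self):
        bad = RawCall("arriba", "S", Breakpoint("1", 1, "+", ""), make_call().bp3, 1, 1)
        with pytest.raises(ValidationError):
            canonical_pair(bad, AliasTable())

    def test_bundled_table_maps_leukemia_synonyms(self):
        aliases = AliasTable.bundled()
        assert aliases.resolve("MLL") == "KMT2A"
        assert aliases.resolve("NKX2.5") == "NKX2-5"


class TestMergeCalls:
    def test_same_pair_two_callers_breakpoints_apart(self):
        calls = [
            make_call("arriba", pos5=1000, pos3=2000),
            make_call("starfusion", pos5=1012, pos3=2005),
        ]
        (event,) = merge_calls(calls, AliasTable())
        assert event.caller_count == 2
        assert event.pair_key == ("KMT2A", "AFF1")

    def test_same_caller_two_junctions_one_event(self):
        calls = [make_call(pos5=1000), make_call(pos5=5000)]
        (event,) = merge_calls(calls, AliasTable())
        assert event.caller_count == 1
        assert len(event.evidence["arriba"]) == 2

    def test_all_five_callers_one_event(self):
        calls = [make_call(c) for c in CALLERS]
        (event,) = merge_calls(calls, AliasTable())
        assert event.caller_count == 5

    def test_aliases_unify_symbol_vocabularies(self):
        calls = [make_call("arriba", g5="KMT2A"), make_call("fusioncatcher", g5="MLL")]
        events = merge_calls(calls, AliasTable({"MLL": "KMT2A"}))
        assert len(events) == 1 and events[0].caller_count == 2

    def test_mixed_samples_rejected(self):
        with pytest.raises(ContractError):
            merge_calls([make_call(sample="A"), make_call("cicero", sample="B")], AliasTable())

    def test_merge_is_order_independent_over_all_permutations(self):
        """Permutation oracle: brute force over every ordering of 4 calls."""
        base = [
            make_call("arriba", pos5=1000, pos3=2000, split=9),
            make_call("starfusion", pos5=1000, pos3=2000, split=2),
            make_call("cicero", pos5=1500, pos3=2600, split=30),
            make_call("defuse", g5="BCR", g3="ABL1", pos5=7000, pos3=8000),
        ]
        reference = None
        for perm in itertools.permutations(base):
            events = merge_calls(list(perm), AliasTable())
            view = [(e.standard_view(), sorted(map(id, e.all_calls))) for e in events]
            if reference is None:
                reference = view
            assert view == reference

    def test_representative_junction_prefers_caller_majority(self):
        calls = [
            make_call("arriba", pos5=1000, pos3=2000, split=1, spanning=0),
            make_call("starfusion", pos5=1000, pos3=2000, split=1, spanning=0),
            make_call("cicero", pos5=5000, pos3=9000, split=50, spanning=50),
        ]
        (event,) = merge_calls(calls, AliasTable())
        assert (event.bp5.pos, event.bp3.pos) == (1000, 2000)

    def test_representative_junction_tie_breaks_on_support_then_coordinate(self):
        calls = [
            make_call("arriba", pos5=5000, pos3=9000, split=50),
            make_call("starfusion", pos5=1000, pos3=2000, split=2),
        ]
        (event,) = merge_calls(calls, AliasTable())
        assert (event.bp5.pos, event.bp3.pos) == (5000, 9000)  # higher support wins
        equal = [
            make_call("arriba", pos5=5000, pos3=9000, split=5, spanning=0),
            make_call("starfusion", pos5=1000, pos3=2000, split=5, spanning=0),
        ]
        (event,) = merge_calls(equal, AliasTable())
        assert (event.bp5.pos, event.bp3.pos) == (1000, 2000)  # lowest coordinate

    def test_reciprocal_orientations_distinct_by_default(self):
        calls = [make_call("arriba"), make_call("cicero", g5="AFF1", g3="KMT2A")]
        events = merge_calls(calls, AliasTable())
        assert len(events) == 2
        collapsed = merge_calls(calls, AliasTable(), collapse_reciprocal=True)
        assert len(collapsed) == 1 and collapsed[0].caller_count == 2

    def test_frame_consensus_is_optimistic(self):
        calls = [make_call("arriba", frame="out-of-frame"), make_call("cicero", frame="in-frame")]
        (event,) = merge_calls(calls, AliasTable())
        assert event.frame == "in-frame"
        calls = [make_call("arriba", frame="out-of-frame"), make_call("cicero")]
        (event,) = merge_calls(calls, AliasTable())
        assert event.frame == "out-of-frame"


@st.composite
def call_lists(draw):
    pairs = [("KMT2A", "AFF1"), ("BCR", "ABL1"), ("ETV6", "RUNX1")]
    n = draw(st.integers(min_value=1, max_value=12))
    calls = []
    for _ in range(n):
        g5, g3 = pairs[draw(st.integers(0, len(pairs) - 1))]
        calls.append(
            make_call(
                caller=CALLERS[draw(st.integers(0, 4))],
                g5=g5, g3=g3,
                pos5=draw(st.integers(1, 10_000)),
                pos3=draw(st.integers(1, 10_000)),
                split=draw(st.integers(0, 50)),
                spanning=draw(st.integers(0, 50)),
            )
        )
    return calls


class TestMergeProperties:
    @settings(derandomize=True, max_examples=60)
    @given(call_lists())
    def test_conservation_every_call_in_exactly_one_event(self, calls):
        events = merge_calls(calls, AliasTable())
        merged = [c for e in events for c in e.all_calls]
        assert sorted(map(id, merged)) == sorted(map(id, calls))

    @settings(derandomize=True, max_examples=60)
    @given(call_lists())
    def test_caller_count_matches_evidence(self, calls):
        for e in merge_calls(calls, AliasTable()):
            assert e.caller_count == len(e.evidence)
            assert all(e.evidence[c] for c in e.evidence)

    @settings(derandomize=True, max_examples=30)
    @given(call_lists(), st.randoms(use_true_random=False))
    def test_shuffling_input_does_not_change_output(self, calls, rnd):
        before = [e.standard_view() for e in merge_calls(calls, AliasTable())]
        shuffled = list(calls)
        rnd.shuffle(shuffled)
        after = [e.standard_view() for e in merge_calls(shuffled, AliasTable())]
        assert before == after


class TestConsensusSelect:
    def _events(self, counts):
        events = []
        for i, n in enumerate(counts):
            calls = [make_call(c, g5=f"G{i}", g3="ABL1") for c in CALLERS[:n]]
            events.extend(merge_calls(calls, AliasTable()))
        return events

    def test_boundary_inclusion(self):
        events = self._events([3])
        assert len(consensus_select(events, 3)) == 1
        assert consensus_select(events, 3)[0].status == "consensus"
        assert consensus_select(events, 4) == []

    def test_nesting_and_monotonicity(self):
        events = self._events([1, 2, 3, 3, 4, 5, 5])
        keys = lambda evs: {e.pair_key for e in evs}
        k5, k4, k3 = (keys(consensus_select(events, k)) for k in (5, 4, 3))
        assert k5 <= k4 <= k3
        sizes = [len(consensus_select(events, k)) for k in range(1, 6)]
        assert sizes == sorted(sizes, reverse=True)

    @pytest.mark.parametrize("k", [0, 6, -1])
    def test_k_out_of_range_rejected(self, k):
        with pytest.raises(ValidationError):
            consensus_select([], k)


def test_merge_cohort_partitions_by_sample():
    calls = [make_call(sample="A"), make_call("cicero", sample="B")]
    events = merge_cohort(calls, AliasTable())
    assert {e.sample_id for e in events} == {"A", "B"}
    assert all(e.caller_count == 1 for e in events)
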