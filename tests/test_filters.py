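"""The artifact-filter cascade: predicates, whitelist rescue, invariants."""

import itertools
import random

import pytest

from fusemble.annotation import GeneAnnotation, GeneModel
from fusemble.errors import ContractError
from fusemble.filters import (
    CallerRule,
    FilterConfig,
    breakpoint_site_class,
    evidence_filter,
    flag_promiscuous,
    is_read_through,
    run_filter_cascade,
)
from fusemble.harmonize import AliasTable, merge_calls
from fusemble.model import Breakpoint, RawCall


def make_call(caller="arriba", sample="S", g5="GENEA", g3="GENEB",
              chrom5="1", pos5=1000, chrom3="2", pos3=2000,
              split=5, spanning=3, confidence=None, frame="unknown"):
    return RawCall(
        caller=caller,
        sample_id=sample,
        bp5=Breakpoint(chrom5, pos5, "+", g5),
        bp3=Breakpoint(chrom3, pos3, "+", g3),
        split_reads=split,
        spanning_reads=spanning,
        confidence=confidence,
        frame=frame,
    )


def make_event(calls=None, **kwargs):
    calls = calls or [make_call(**kwargs)]
    return merge_calls(calls, AliasTable())[0]


def toy_gene(symbol, chrom, start, strand="+", length=999, biotype="protein_coding"):
    third = length // 3
    return GeneModel(
        symbol=symbol, chrom=chrom, start=start, end=start + length, strand=strand,
        biotype=biotype,
        exons=[(start, start + third), (start + 2 * third, start + length)],
    )


class TestEvidenceFilter:
    def test_low_confidence_label_fails(self):
        cfg = FilterConfig()
        call = make_call(confidence="low", split=10)
        assert evidence_filter(call, cfg) == (False, "low_confidence")

    def test_zero_support_fails(self):
        call = make_call(split=0, spanning=0)
        assert evidence_filter(call, FilterConfig()) == (False, "low_support")

    def test_exactly_at_threshold_passes(self):
        call = make_call(split=2, spanning=1)  # total 3 == default minimum
        assert evidence_filter(call, FilterConfig()) == (True, None)

    def test_defuse_probability_threshold(self):
        cfg = FilterConfig()
        assert evidence_filter(make_call("defuse", confidence="0.69"), cfg)[1] == "low_confidence"
        assert evidence_filter(make_call("defuse", confidence="0.70"), cfg) == (True, None)

    def test_absent_confidence_gets_benefit_of_the_doubt(self):
        assert evidence_filter(make_call(confidence=None), FilterConfig()) == (True, None)

    def test_unconfigured_caller_is_a_contract_error(self):
        cfg = FilterConfig(caller_rules={"arriba": CallerRule()})
        with pytest.raises(ContractError):
            evidence_filter(make_call("cicero"), cfg)


class TestReadThrough:
    def test_adjacent_same_strand_within_distance(self, annotation):
        ev = make_event(g5="MTAP", g3="CDKN2B-AS1")
        assert is_read_through(ev, annotation, 1_000_000)

    def test_different_chromosomes_false(self, annotation):
        ev = make_event(g5="BCR", g3="ABL1")
        assert not is_read_through(ev, annotation, 10**9)

    def test_opposite_strands_false(self):
        ann = GeneAnnotation([toy_gene("A", "1", 1000, "+"), toy_gene("B", "1", 3000, "-")])
        assert not is_read_through(make_event(g5="A", g3="B"), ann, 10**9)

    def test_minus_strand_orientation_respected(self, annotation):
        # SYNRTDA/SYNRTDB are a minus-strand adjacent pair: the 5' partner
        # sits genomically downstream, so only that orientation reads through
        assert is_read_through(make_event(g5="SYNRTDA", g3="SYNRTDB"), annotation, 1_000_000)
        assert not is_read_through(make_event(g5="SYNRTDB", g3="SYNRTDA"), annotation, 1_000_000)

    def test_unannotated_partner_never_true(self, annotation):
        assert not is_read_through(make_event(g5="NOSUCH", g3="TAL1"), annotation, 10**9)

    def test_exhaustive_enumeration_on_toy_annotation(self):
        """Enumeration oracle: brute-force geometry over all ordered pairs."""
        genes = [
            toy_gene("A", "1", 1_000, "+"),
            toy_gene("B", "1", 3_000, "+"),   # A->B gap 1001
            toy_gene("C", "1", 300_000, "+"),  # far downstream
            toy_gene("D", "1", 5_000, "-"),
            toy_gene("E", "2", 1_000, "+"),
            toy_gene("F", "1", 7_000, "-"),   # D->F? F is downstream genomically
        ]
        ann = GeneAnnotation(genes)
        by_symbol = {g.symbol: g for g in genes}
        max_d = 100_000

        def oracle(g5, g3):
            a, b = by_symbol[g5], by_symbol[g3]
            if a.chrom != b.chrom or a.strand != b.strand:
                return False
            gap = (b.start - a.end) if a.strand == "+" else (a.start - b.end)
            return 0 < gap <= max_d

        for g5, g3 in itertools.permutations(by_symbol, 2):
            ev = make_event(g5=g5, g3=g3)
            assert is_read_through(ev, ann, max_d) == oracle(g5, g3), (g5, g3)


class TestBreakpointSiteClass:
    def test_exon_boundary_is_splice_site(self, annotation):
        g = annotation.gene("KMT2A")
        bp = Breakpoint(g.chrom, g.exons[1][1], "+", "KMT2A")
        assert breakpoint_site_class(bp, annotation) == "splice_site"

    def test_position_outside_all_genes_is_intergenic(self, annotation):
        assert breakpoint_site_class(Breakpoint("1", 5, "+", "X"), annotation) == "intergenic"

    def test_randomized_positions_match_linear_scan_oracle(self):
        genes = [toy_gene("A", "1", 1_000), toy_gene("B", "1", 2_500), toy_gene("C", "2", 1_000)]
        ann = GeneAnnotation(genes)
        rng = random.Random(42)

        def oracle(chrom, pos):
            hit_gene = False
            in_exon = False
            for g in genes:
                if g.chrom != chrom or not (g.start <= pos <= g.end):
                    continue
                hit_gene = True
                for s, e in g.exons:
                    if pos in (s, e):
                        return "splice_site"
                    if s < pos < e:
                        in_exon = True
            if not hit_gene:
                return "intergenic"
            return "exonic" if in_exon else "intronic"

        for _ in range(300):
            chrom = rng.choice(["1", "2", "3"])
            pos = rng.randint(1, 4_500)
            bp = Breakpoint(chrom, pos, "+", "X")
            assert breakpoint_site_class(bp, ann) == oracle(chrom, pos), (chrom, pos)


class TestPromiscuity:
    def _ev(self, g5, g3, sample="S"):
        return make_event(g5=g5, g3=g3, sample=sample)

    def test_two_partners_flagged(self):
        events = [self._ev("G", "A"), self._ev("G", "B")]
        assert flag_promiscuous(events, 2) == {"G"}

    def test_single_partner_not_flagged(self):
        assert flag_promiscuous([self._ev("G", "A")], 2) == frozenset()

    def test_partner_side_agnostic(self):
        events = [self._ev("A", "G"), self._ev("B", "G")]
        assert flag_promiscuous(events, 2) == {"G"}

    def test_mixed_samples_rejected(self):
        with pytest.raises(ContractError):
            flag_promiscuous([self._ev("G", "A"), self._ev("G", "B", sample="T")], 2)


class TestCascade:
    def test_out_of_frame_whitelisted_event_rescued(self, annotation, default_config):
        calls = [make_call(g5="KMT2A", g3="AFF1", frame="out-of-frame")]
        # place breakpoints off splice sites too: rescue covers all structural steps
        retained, verdicts = run_filter_cascade(
            [make_event(calls)], annotation, default_config
        )
        assert len(retained) == 1
        assert verdicts[0].reasons == ["whitelist_rescue"]
        assert retained[0].status == "retained"

    def test_read_through_without_whitelist_discarded(self, annotation, default_config):
        g5, g3 = "MTAP", "CDKN2B-AS1"
        a5, a3 = annotation.gene(g5), annotation.gene(g3)
        calls = [make_call(g5=g5, g3=g3, chrom5=a5.chrom, pos5=a5.exons[1][1],
                           chrom3=a3.chrom, pos3=a3.exons[1][0])]
        retained, verdicts = run_filter_cascade([make_event(calls)], annotation, default_config)
        assert retained == []
        assert "read_through" in verdicts[0].reasons

    def test_event_survives_if_any_call_passes_evidence(self, annotation, default_config):
        g = annotation.gene("SYNFP1A")
        h = annotation.gene("SYNFP1B")
        weak = make_call("cicero", g5="SYNFP1A", g3="SYNFP1B", split=0, spanning=0,
                         chrom5=g.chrom, pos5=g.exons[1][1], chrom3=h.chrom, pos3=h.exons[1][0])
        strong = make_call("arriba", g5="SYNFP1A", g3="SYNFP1B", split=10, spanning=5,
                           chrom5=g.chrom, pos5=g.exons[1][1], chrom3=h.chrom, pos3=h.exons[1][0],
                           confidence="high", frame="in-frame")
        event = make_event([weak, strong])
        retained, verdicts = run_filter_cascade([event], annotation, default_config)
        assert len(retained) == 1 and verdicts[0].status == "retained"

    def test_all_calls_below_evidence_discarded_even_if_whitelisted(self, annotation, default_config):
        calls = [make_call(g5="KMT2A", g3="AFF1", split=1, spanning=0)]
        retained, verdicts = run_filter_cascade([make_event(calls)], annotation, default_config)
        assert retained == []
        assert verdicts[0].reasons == ["low_support"]

    def test_unannotated_partner_passes_with_warning(self, annotation, default_config):
        calls = [make_call(g5="SYNFP2A", g3="UNKNOWNGENE", frame="in-frame")]
        retained, verdicts = run_filter_cascade([make_event(calls)], annotation, default_config)
        assert len(retained) == 1
        assert verdicts[0].reasons == ["unannotated_gene"]

    def test_partition_is_exhaustive_and_disjoint(self, annotation, default_config):
        events = [
            make_event(g5="KMT2A", g3="AFF1"),
            make_event(g5="MTAP", g3="CDKN2B-AS1"),
            make_event([make_call(g5="SYNLS1A", g3="SYNLS1B", split=0, spanning=0)]),
        ]
        retained, verdicts = run_filter_cascade(events, annotation, default_config)
        assert len(verdicts) == len(events)
        n_discarded = sum(1 for v in verdicts if v.status == "discarded")
        assert len(retained) + n_discarded == len(events)

    def test_retained_set_stable_under_input_reordering(self, annotation, default_config, cell_cohort, cohort_annotation):
        import fusemble.pipeline as pipeline

        _, paths = cell_cohort
        import os
        cohort_dir = os.path.dirname(paths["truth"])
        res = pipeline.run_integration(cohort_dir, cohort_annotation, default_config, k=3)
        reordered = list(reversed(res.consensus))
        r1, _ = run_filter_cascade(res.consensus, cohort_annotation, default_config)
        r2, _ = run_filter_cascade(reordered, cohort_annotation, default_config)
        assert {e.standard_view() for e in r1} == {e.standard_view() for e in r2}

    def test_relaxing_thresholds_never_shrinks_retained_set(self, annotation, default_config, cell_cohort, cohort_annotation):
        import os
        import fusemble.pipeline as pipeline
        from dataclasses import replace

        _, paths = cell_cohort
        cohort_dir = os.path.dirname(paths["truth"])
        res = pipeline.run_integration(cohort_dir, cohort_annotation, default_config, k=3)
        strict, _ = run_filter_cascade(res.consensus, cohort_annotation, default_config)
        relaxed_rules = {c: CallerRule(min_reads_total=0) for c in default_config.caller_rules}
        relaxed = replace(default_config, caller_rules=relaxed_rules)
        loose, _ = run_filter_cascade(res.consensus, cohort_annotation, relaxed)
        assert {e.standard_view() for e in strict} <= {e.standard_view() for e in loose}

    def test_whitelist_dominance_over_structural_filters(self, annotation):
        """A whitelisted partner shields an event from every structural step."""
        structural_offenders = [
            # blacklisted 5' partner AND out-of-frame, but AFF1 is whitelisted
            make_event([make_call(g5="KMT2A", g3="AFF1", frame="out-of-frame")]),
            make_event([make_call(g5="STIL", g3="TAL1")]),  # read-through geometry
        ]
        cfg = FilterConfig(whitelist=frozenset({"AFF1", "TAL1"}), blacklist=frozenset({"KMT2A"}))
        retained, verdicts = run_filter_cascade(structural_offenders, annotation, cfg)
        assert len(retained) == 2
        assert all(v.status == "retained" for v in verdicts)


class TestFilterConfigYaml:
    def test_round_trip_of_overrides(self, tmp_path):
        doc = """
callers:
  arriba:
    min_reads_total: 5
    accepted_confidence: [high]
  defuse:
    min_probability: 0.9
read_through_max_distance: 500000
discard_out_of_frame: false
promiscuity_threshold: 3
whitelist: [KMT2A, AFF1]
blacklist: [HLA-DRB5]
"""
        path = tmp_path / "filters.yaml"
        path.write_text(doc)
        cfg = FilterConfig.from_yaml(path)
        assert cfg.caller_rules["arriba"].min_reads_total == 5
        assert cfg.caller_rules["arriba"].accepted_confidence == {"high"}
        assert cfg.caller_rules["defuse"].min_probability == 0.9
        assert cfg.caller_rules["cicero"].min_reads_total == 3  # untouched default
        assert cfg.read_through_max_distance == 500_000
        assert not cfg.discard_out_of_frame
        assert cfg.whitelist == {"KMT2A", "AFF1"}
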