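"""The artifact-filter cascade.

RNA-seq fusion calling produces far more candidates than real
rearrangements; most are technical artifacts (library chimeras, mapping
errors) or biological noise (read-through transcription between adjacent
genes).  This module turns the manual curation pass a molecular
diagnostics analyst would perform into an ordered, configurable, fully
audited cascade:

1. evidence filter — per supporting call: minimum read support and
   caller-specific confidence (an event survives if at least one of its
   calls passes);
2. read-through removal — same chromosome, same strand, small intergenic
   gap in transcriptional orientation;
3. out-of-frame removal (optional);
4. splice-site/coding-exon requirement on both breakpoints (optional);
5. blacklist removal (repeat regions, paralogs, pseudogenes);
6. promiscuous-gene removal (a gene fused to several partners in one
   sample is an artifact signature).

A fusion touching a clinically relevant leukemia gene (the whitelist) is
never discarded by the structural steps 2-6 — such rearrangements are kept
for human review regardless of their structural class — but it still needs
read evidence to survive step 1.

Every event receives exactly one :class:`~fusemble.model.FilterVerdict`;
the verdict table is the audit trail that replaces manual curation notes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
import yaml

from .annotation import GeneAnnotation
from .errors import ContractError, ValidationError
from .model import CALLERS, FilterVerdict, FusionEvent, RawCall

STRUCTURAL_ORDER = (
    "read_through",
    "out_of_frame",
    "non_splice_breakpoint",
    "blacklisted_gene",
    "promiscuous_gene",
)


@dataclass
class CallerRule:
    """Evidence thresholds for one caller.

    ``min_reads_total`` applies to split + spanning reads.  Exactly one of
    ``accepted_confidence`` (label set) or ``min_probability`` (numeric
    lower bound, for deFuse's classifier output) is typically set; a call
    with an absent or unparseable confidence gets the benefit of the doubt
    and is judged on read support alone.
    """

    min_reads_total: int = 3
    min_split: int = 0
    min_spanning: int = 0
    accepted_confidence: frozenset = None
    min_probability: float = None

    def __post_init__(self) -> None:
        if min(self.min_reads_total, self.min_split, self.min_spanning) < 0:
            raise ValidationError("evidence thresholds must be non-negative")
        if self.accepted_confidence is not None:
            self.accepted_confidence = frozenset(self.accepted_confidence)


def _default_rules() -> dict:
    rules = {c: CallerRule() for c in CALLERS}
    rules["arriba"] = CallerRule(accepted_confidence=frozenset({"high", "medium"}))
    rules["defuse"] = CallerRule(min_probability=0.7)
    return rules


def _read_gene_list(path) -> frozenset:
    symbols = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                symbols.add(line)
    return frozenset(symbols)


def _bundled_list(name: str) -> frozenset:
    ref = resources.files("fusemble.data").joinpath(name)
    with resources.as_file(ref) as path:
        return _read_gene_list(path)


@dataclass
class FilterConfig:
    """Tunable knobs of the filter cascade.

    Defaults are the package's own conventions for short-read leukemia
    RNA-seq, not values prescribed elsewhere: at least 3 supporting reads
    per call, Arriba confidence high/medium, deFuse probability >= 0.7,
    read-through gap up to 1 Mb, and both breakpoints on splice sites or
    inside coding exons.  All are overridable per run (YAML).
    """

    caller_rules: dict = field(default_factory=_default_rules)
    read_through_max_distance: int = 1_000_000
    require_splice_site: bool = True
    discard_out_of_frame: bool = True
    blacklist: frozenset = field(default_factory=frozenset)
    promiscuity_threshold: int = 2
    whitelist: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.read_through_max_distance < 0:
            raise ValidationError("read_through_max_distance must be >= 0")
        if self.promiscuity_threshold < 2:
            raise ValidationError("promiscuity_threshold must be >= 2")
        self.blacklist = frozenset(self.blacklist)
        self.whitelist = frozenset(self.whitelist)

    @classmethod
    def default(cls) -> "FilterConfig":
        """Defaults plus the bundled leukemia whitelist and artifact blacklist."""
        return cls(
            blacklist=_bundled_list("blacklist.txt"),
            whitelist=_bundled_list("whitelist.txt"),
        )

    @classmethod
    def from_yaml(cls, path) -> "FilterConfig":
        """Load a config from YAML; keys mirror the dataclass fields.

        Per-caller sections live under ``callers:``; ``blacklist`` /
        ``whitelist`` may be inline symbol lists or ``file:`` paths.
        """
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        rules = _default_rules()
        for caller, section in (doc.get("callers") or {}).items():
            if caller not in CALLERS:
                raise ValidationError(f"unknown caller {caller!r} in filter config")
            kwargs = dict(section or {})
            if "accepted_confidence" in kwargs and kwargs["accepted_confidence"] is not None:
                kwargs["accepted_confidence"] = frozenset(kwargs["accepted_confidence"])
            rules[caller] = CallerRule(**kwargs)
        kwargs = {"caller_rules": rules}
        for key in ("read_through_max_distance", "require_splice_site",
                    "discard_out_of_frame", "promiscuity_threshold"):
            if key in doc:
                kwargs[key] = doc[key]
        for key in ("blacklist", "whitelist"):
            if key in doc:
                val = doc[key]
                if isinstance(val, dict) and "file" in val:
                    kwargs[key] = _read_gene_list(val["file"])
                else:
                    kwargs[key] = frozenset(val or ())
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Individual predicates
# ---------------------------------------------------------------------------


def evidence_filter(call: RawCall, cfg: FilterConfig):
    """Judge one raw call's read support and confidence.

    Returns ``(True, None)`` on pass, or ``(False, reason)`` with reason
    ``low_support`` or ``low_confidence``.  Thresholds are minima: a call
    exactly at threshold passes.  Absent or unrecognized confidence passes
    (the benefit of the doubt; other filters still apply).
    """
    rule = cfg.caller_rules.get(call.caller)
    if rule is None:
        raise ContractError(f"no filter rule configured for caller {call.caller!r}")
    if (
        call.total_reads < rule.min_reads_total
        or call.split_reads < rule.min_split
        or call.spanning_reads < rule.min_spanning
    ):
        return False, "low_support"
    if rule.accepted_confidence is not None and call.confidence is not None:
        if call.confidence not in rule.accepted_confidence:
            return False, "low_confidence"
    if rule.min_probability is not None and call.confidence is not None:
        try:
            prob = float(call.confidence)
        except ValueError:
            prob = None  # non-numeric label: benefit of the doubt
        if prob is not None and prob < rule.min_probability:
            return False, "low_confidence"
    return True, None


def is_read_through(event: FusionEvent, ann: GeneAnnotation, max_distance: int) -> bool:
    """Whether the event looks like read-through (conjoined) transcription.

    True iff both partners are annotated on the same chromosome and strand,
    the 5' gene ends upstream of the 3' gene's start *in transcriptional
    orientation*, and the intergenic gap is at most ``max_distance``.
    An unannotated partner never yields True (the cascade flags the event
    ``unannotated_gene`` instead and lets it pass).
    """
    g5 = ann.gene(event.pair_key[0])
    g3 = ann.gene(event.pair_key[1])
    if g5 is None or g3 is None:
        return False
    if g5.chrom != g3.chrom or g5.strand != g3.strand or g5.strand not in "+-":
        return False
    if g5.strand == "+":
        gap = g3.start - g5.end
    else:  # transcription runs towards decreasing coordinates
        gap = g5.start - g3.end
    return 0 < gap <= max_distance


def breakpoint_site_class(bp, ann: GeneAnnotation) -> str:
    """Classify a breakpoint against the annotation.

    ``splice_site`` if the position equals an exon boundary of a gene at
    that locus; ``exonic`` if strictly inside an exon; ``intronic`` if
    inside a gene body but outside every exon; ``intergenic`` otherwise.
    """
    genes = ann.genes_at(bp.chrom, bp.pos)
    if not genes:
        return "intergenic"
    in_exon = False
    for g in genes:
        for s, e in g.exons:
            if bp.pos == s or bp.pos == e:
                return "splice_site"
            if s < bp.pos < e:
                in_exon = True
    return "exonic" if in_exon else "intronic"


def flag_promiscuous(events, threshold: int = 2) -> frozenset:
    """Genes fused to >= ``threshold`` distinct partners within one sample.

    Partner-side agnostic: a gene counts whether it appears as the 5' or
    the 3' member.  Promiscuity is a within-sample artifact signature, so
    all events must share one sample.
    """
    if threshold < 2:
        raise ValidationError("promiscuity threshold must be >= 2")
    samples = {ev.sample_id for ev in events}
    if len(samples) > 1:
        raise ContractError(f"flag_promiscuous is per-sample; got {sorted(samples)}")
    partners: dict = {}
    for ev in events:
        g5, g3 = ev.pair_key
        partners.setdefault(g5, set()).add(g3)
        partners.setdefault(g3, set()).add(g5)
    return frozenset(g for g, ps in partners.items() if len(ps) >= threshold)


# ---------------------------------------------------------------------------
# The cascade
# ---------------------------------------------------------------------------


def _structural_failures(event, ann, cfg, promiscuous) -> tuple:
    """All structural reasons the event fails, plus warnings, in cascade order."""
    failures = []
    warnings = []
    g5 = ann.gene(event.pair_key[0])
    g3 = ann.gene(event.pair_key[1])
    unannotated = g5 is None or g3 is None
    if unannotated:
        warnings.append("unannotated_gene")
    if not unannotated and is_read_through(event, ann, cfg.read_through_max_distance):
        failures.append("read_through")
    if cfg.discard_out_of_frame and event.frame == "out-of-frame":
        failures.append("out_of_frame")
    if cfg.require_splice_site and not unannotated:
        ok5 = breakpoint_site_class(event.bp5, ann) in ("splice_site", "exonic")
        ok3 = breakpoint_site_class(event.bp3, ann) in ("splice_site", "exonic")
        if not (ok5 and ok3):
            failures.append("non_splice_breakpoint")
    if cfg.blacklist & set(event.pair_key):
        failures.append("blacklisted_gene")
    if promiscuous & set(event.pair_key):
        failures.append("promiscuous_gene")
    return failures, warnings


def run_filter_cascade(events, ann: GeneAnnotation, cfg: FilterConfig):
    """Apply the full cascade; return ``(retained_events, verdicts)``.

    Every input event receives exactly one verdict (the partition is
    exhaustive and disjoint) and the retained set is invariant to the
    input ordering.  Promiscuity is assessed per sample on the cascade's
    input events, so it does not depend on the evidence thresholds —
    relaxing any threshold can only grow the retained set.
    """
    promiscuous_by_sample: dict = {}
    by_sample: dict = {}
    for ev in events:
        by_sample.setdefault(ev.sample_id, []).append(ev)
    for sample, sample_events in by_sample.items():
        promiscuous_by_sample[sample] = flag_promiscuous(
            sample_events, cfg.promiscuity_threshold
        )

    retained = []
    verdicts = []
    for ev in events:
        verdict = _judge(ev, ann, cfg, promiscuous_by_sample[ev.sample_id])
        verdicts.append(verdict)
        if verdict.status == "retained":
            retained.append(verdict.event)
    return retained, verdicts


def _judge(event, ann, cfg, promiscuous) -> FilterVerdict:
    # step 1: evidence — the event survives if any supporting call passes
    fail_reasons = []
    passed = False
    for call in event.all_calls:
        ok, reason = evidence_filter(call, cfg)
        if ok:
            passed = True
            break
        if reason not in fail_reasons:
            fail_reasons.append(reason)
    if not passed:
        return FilterVerdict(event.with_status("discarded"), "discarded", fail_reasons)

    # steps 2-6: structural/annotation filters, with whitelist rescue
    failures, warnings = _structural_failures(event, ann, cfg, promiscuous)
    if failures:
        if cfg.whitelist & set(event.pair_key):
            return FilterVerdict(
                event.with_status("retained"), "retained", ["whitelist_rescue"]
            )
        return FilterVerdict(
            event.with_status("discarded"), "discarded", failures
        )
    return FilterVerdict(event.with_status("retained"), "retained", warnings)


def write_audit(verdicts, path) -> None:
    """Export the verdicts as a TSV audit file for human curation."""
    rows = [
        {
            "sample": v.event.sample_id,
            "gene5": v.event.pair_key[0],
            "gene3": v.event.pair_key[1],
            "caller_count": v.event.caller_count,
            "callers": ",".join(v.event.callers),
            "status": v.status,
            "reasons": ",".join(v.reasons),
        }
        for v in verdicts
    ]
    df = pd.DataFrame(
        rows,
        columns=["sample", "gene5", "gene3", "caller_count", "callers", "status", "reasons"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
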