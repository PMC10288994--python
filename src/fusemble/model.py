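"""Core domain records shared by every stage of the pipeline.

The unit of information flowing through fusemble is a gene-fusion
prediction.  A :class:`RawCall` is one prediction exactly as one caller
reported it; a :class:`FusionEvent` is the merged, caller-agnostic view of
one fusion in one sample, carrying every supporting raw call as evidence.
Benchmarking vocabulary (:class:`TruthEntry`, :class:`BenchmarkResult`)
lives here too so the evaluate module stays purely computational.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

from .errors import ValidationError

#: The five supported fusion callers, by their canonical lower-case names.
CALLERS = ("arriba", "cicero", "defuse", "fusioncatcher", "starfusion")

#: Recognized strand labels.  ``unknown`` covers callers that omit strand.
STRANDS = ("+", "-", "unknown")

#: Recognized reading-frame labels for the fused transcript.
FRAMES = ("in-frame", "out-of-frame", "unknown")

#: Lifecycle tags for a FusionEvent as it moves through the pipeline.
STATUSES = ("raw", "consensus", "retained", "discarded")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix; both dialects are accepted on input."""
    chrom = chrom.strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    return chrom


@dataclass(frozen=True)
class Breakpoint:
    """One side of a fusion junction: a genomic coordinate plus gene symbol.

    Coordinates are 1-based inclusive as emitted by all five supported
    callers; no conversion is applied anywhere in the package.
    """

    chrom: str
    pos: int
    strand: str = "unknown"
    gene_symbol: str = ""

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("breakpoint chromosome must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"breakpoint position must be >= 1, got {self.pos}")
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")


@dataclass
class RawCall:
    """One fusion prediction from one caller for one sample, pre-harmonization.

    ``annotations`` is an open key->text map preserving caller-specific
    columns (e.g. FusionCatcher's fusion description flags) so that no
    information is lost before filtering.
    """

    caller: str
    sample_id: str
    bp5: Breakpoint
    bp3: Breakpoint
    split_reads: int
    spanning_reads: int
    confidence: Optional[str] = None
    frame: str = "unknown"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.caller not in CALLERS:
            raise ValidationError(f"unknown caller {self.caller!r}; expected one of {CALLERS}")
        if self.split_reads < 0 or self.spanning_reads < 0:
            raise ValidationError("read counts must be non-negative")
        if self.frame not in FRAMES:
            raise ValidationError(f"invalid frame label {self.frame!r}")

    @property
    def total_reads(self) -> int:
        return self.split_reads + self.spanning_reads


@dataclass
class FusionEvent:
    """A harmonized fusion: one (sample, ordered gene pair) with evidence.

    ``pair_key`` is the canonical (5' gene, 3' gene) symbol pair after alias
    resolution.  Fusion direction is biologically meaningful (KMT2A::AFF1 is
    not AFF1::KMT2A), so the pair is ordered.  ``evidence`` maps caller name
    to the raw calls that caller contributed; ``caller_count`` always equals
    the number of distinct callers in that map.
    """

    sample_id: str
    pair_key: tuple
    bp5: Breakpoint
    bp3: Breakpoint
    evidence: dict
    caller_count: int
    frame: str = "unknown"
    status: str = "raw"

    def __post_init__(self) -> None:
        if self.caller_count != len(self.evidence):
            raise ValidationError(
                f"caller_count {self.caller_count} != distinct evidence callers {len(self.evidence)}"
            )
        if not 1 <= self.caller_count <= len(CALLERS):
            raise ValidationError(f"caller_count must be in 1..{len(CALLERS)}")
        if self.status not in STATUSES:
            raise ValidationError(f"invalid status {self.status!r}")

    @property
    def callers(self) -> list:
        """Detecting caller names, sorted alphabetically."""
        return sorted(self.evidence)

    @property
    def all_calls(self) -> list:
        return [c for caller in sorted(self.evidence) for c in self.evidence[caller]]

    @property
    def max_split(self) -> int:
        return max(c.split_reads for c in self.all_calls)

    @property
    def max_spanning(self) -> int:
        return max(c.spanning_reads for c in self.all_calls)

    def with_status(self, status: str) -> "FusionEvent":
        return replace(self, status=status)

    def standard_view(self) -> tuple:
        """The event's projection onto the standardized-table columns.

        Two events are interchangeable for reporting purposes iff their
        standard views are equal; this is the round-trip equality contract
        of ``write_standard_table``/``read_standard_table``.
        """
        return (
            self.sample_id,
            self.pair_key[0],
            self.pair_key[1],
            self.bp5.chrom,
            self.bp5.pos,
            self.bp5.strand,
            self.bp3.chrom,
            self.bp3.pos,
            self.bp3.strand,
            self.caller_count,
            tuple(self.callers),
            self.max_split,
            self.max_spanning,
            self.frame,
            self.status,
        )


#: Machine-readable reason codes a FilterVerdict may carry.
REASON_CODES = (
    "low_confidence",
    "low_support",
    "read_through",
    "out_of_frame",
    "non_splice_breakpoint",
    "blacklisted_gene",
    "promiscuous_gene",
    "whitelist_rescue",
    "unannotated_gene",
)


@dataclass
class FilterVerdict:
    """Retained/discarded decision for one event, with its audit trail.

    ``reasons`` is ordered as the cascade evaluated them.  A discarded event
    always has at least one reason; ``whitelist_rescue`` appears only on
    retained events; ``unannotated_gene`` is a warning, not a failure.
    """

    event: FusionEvent
    status: str
    reasons: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status not in ("retained", "discarded"):
            raise ValidationError(f"invalid verdict status {self.status!r}")
        if self.status == "discarded" and not self.reasons:
            raise ValidationError("discarded verdict must carry at least one reason")
        for r in self.reasons:
            if r not in REASON_CODES:
                raise ValidationError(f"unknown reason code {r!r}")
        if self.status == "discarded" and "whitelist_rescue" in self.reasons:
            raise ValidationError("whitelist_rescue can only appear on retained events")


@dataclass(frozen=True)
class TruthEntry:
    """An expected rearrangement confirmed by an orthogonal clinical method.

    The unit of TP/FN accounting: a (sample, canonical ordered gene pair),
    with the confirming methodology (karyotype, FISH, RT-qPCR, panel) kept
    as free text.
    """

    sample_id: str
    gene5: str
    gene3: str
    method: str = ""

    @property
    def pair(self) -> tuple:
        return (self.gene5, self.gene3)


@dataclass
class BenchmarkResult:
    """TP/FP/FN counts and derived metrics for one method on one dataset.

    Sensitivity and precision are percentages rounded to one decimal;
    F1 is on the 0-1 scale rounded to two decimals.
    """

    method: str
    dataset: str
    tp: int
    fp: int
    fn: int
    total_identified: int
    sensitivity: float
    precision: float
    f1: float

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValidationError("tp/fp/fn must be non-negative")
        if self.total_identified != self.tp + self.fp:
            raise ValidationError("total_identified must equal tp + fp")
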