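"""End-to-end integration: parse -> harmonize -> consensus -> filter.

This is the library-level engine behind the ``integrate`` CLI command and
the benchmarking scripts.  A cohort directory contains one sub-directory
per sample holding that sample's native caller files (see
``caller_io.NATIVE_FILENAMES``); a missing caller file produces a warning
and the run proceeds with the remaining callers — the k-of-5 agreement
denominator intentionally stays at five, since consensus semantics are
defined against the full caller panel.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from . import caller_io
from .annotation import GeneAnnotation
from .errors import FusembleError
from .filters import FilterConfig, run_filter_cascade
from .harmonize import AliasTable, consensus_select, merge_cohort
from .model import CALLERS

log = logging.getLogger("fusemble")


@dataclass
class PipelineResult:
    """Counts and artifacts of one integrate run, stage by stage."""

    raw_calls: list
    events: list
    consensus: list
    retained: list
    verdicts: list
    missing_files: list = field(default_factory=list)

    @property
    def funnel(self) -> dict:
        """Event counts at each stage (raw calls -> merged -> consensus -> retained)."""
        return {
            "raw_calls": len(self.raw_calls),
            "merged_events": len(self.events),
            "consensus_events": len(self.consensus),
            "retained_events": len(self.retained),
        }


def discover_samples(cohort_dir) -> list:
    """Sample sub-directories of a cohort directory, sorted."""
    return sorted(
        d
        for d in os.listdir(cohort_dir)
        if os.path.isdir(os.path.join(cohort_dir, d))
    )


def parse_sample(sample_dir, sample_id=None):
    """Parse every caller file present in one sample directory.

    Returns ``(calls, missing)`` where ``missing`` lists callers whose
    native file was absent (warned, not fatal).
    """
    sample_id = sample_id or os.path.basename(os.path.normpath(sample_dir))
    calls = []
    missing = []
    for caller in CALLERS:
        path = os.path.join(sample_dir, caller_io.NATIVE_FILENAMES[caller])
        if not os.path.exists(path):
            missing.append((sample_id, caller))
            log.warning(
                "sample %s: no %s output (%s); proceeding with remaining callers "
                "(k-of-5 denominator unchanged)",
                sample_id, caller, caller_io.NATIVE_FILENAMES[caller],
            )
            continue
        calls.extend(caller_io.PARSERS[caller](path, sample_id=sample_id))
    return calls, missing


def run_integration(
    cohort_dir,
    annotation: GeneAnnotation,
    cfg: FilterConfig = None,
    k: int = 3,
    aliases: AliasTable = None,
    bp_tolerance: int = 100,
    collapse_reciprocal: bool = False,
) -> PipelineResult:
    """Run the full integration pipeline over a cohort directory."""
    cfg = cfg or FilterConfig.default()
    aliases = aliases or AliasTable.bundled()
    samples = discover_samples(cohort_dir)
    if not samples:
        raise FusembleError(f"no sample directories found under {cohort_dir}")
    raw_calls = []
    missing = []
    for sample in samples:
        calls, miss = parse_sample(os.path.join(cohort_dir, sample), sample)
        raw_calls.extend(calls)
        missing.extend(miss)
    events = merge_cohort(raw_calls, aliases, bp_tolerance, collapse_reciprocal)
    consensus = consensus_select(events, k)
    retained, verdicts = run_filter_cascade(consensus, annotation, cfg)
    log.info(
        "integration funnel: %d raw calls -> %d merged events -> %d consensus (k=%d) -> %d retained",
        len(raw_calls), len(events), len(consensus), k, len(retained),
    )
    return PipelineResult(
        raw_calls=raw_calls,
        events=events,
        consensus=consensus,
        retained=retained,
        verdicts=verdicts,
        missing_files=missing,
    )
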