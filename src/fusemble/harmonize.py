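"""Harmonization: gene-symbol aliasing, cross-caller merging, and k-of-n
consensus selection.

Callers emit different symbol vocabularies for the same gene (MLL vs
KMT2A), and they rarely agree on exact junction coordinates because they
use different aligners and breakpoint conventions.  Merging therefore keys
on the canonical ordered gene pair per sample; breakpoint proximity
(``bp_tolerance``) only decides which reported junction represents the
merged event, never whether two same-pair calls are the same event.
"""

from __future__ import annotations

from dataclasses import replace
from importlib import resources

import pandas as pd

from .errors import ContractError, ValidationError
from .model import CALLERS, FusionEvent, RawCall


class AliasTable:
    """Mapping from gene-symbol alias to canonical symbol.

    The table is closed under resolution at construction: chains (A->B,
    B->C) collapse so that every stored value is a fixed point, and
    canonical symbols always resolve to themselves.
    """

    def __init__(self, mapping=None) -> None:
        raw = dict(mapping or {})
        self._map: dict = {}
        for alias in raw:
            seen = [alias]
            target = raw[alias]
            while target in raw and raw[target] != target:
                target = raw[target]
                if target in seen:
                    raise ValidationError(f"alias cycle involving {alias!r}")
                seen.append(target)
            self._map[alias] = target

    @classmethod
    def from_tsv(cls, path) -> "AliasTable":
        """Load a two-column (alias, canonical) TSV; '#' lines are comments."""
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#", header=None,
                         names=["alias", "canonical"], keep_default_na=False)
        return cls(dict(zip(df["alias"], df["canonical"])))

    @classmethod
    def bundled(cls) -> "AliasTable":
        """The alias table shipped with the package (leukemia-relevant synonyms)."""
        ref = resources.files("fusemble.data").joinpath("aliases.tsv")
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def resolve(self, symbol: str) -> str:
        if not symbol:
            raise ValidationError("cannot resolve an empty gene symbol")
        return self._map.get(symbol, symbol)

    def __len__(self) -> int:
        return len(self._map)


def canonical_pair(call: RawCall, aliases: AliasTable) -> tuple:
    """The call's (5' gene, 3' gene) pair with canonical symbols.

    5'->3' order is preserved: fusion direction is biologically meaningful
    (KMT2A::AFF1 drives leukemia; AFF1::KMT2A is a different transcript).
    """
    g5 = call.bp5.gene_symbol
    g3 = call.bp3.gene_symbol
    if not g5 or not g3:
        raise ValidationError("call is missing a partner gene symbol")
    return (aliases.resolve(g5), aliases.resolve(g3))


def _sort_key(call: RawCall) -> tuple:
    return (
        call.caller,
        call.bp5.chrom,
        call.bp5.pos,
        call.bp3.chrom,
        call.bp3.pos,
        call.split_reads,
        call.spanning_reads,
        str(call.confidence),
    )


def _cluster_junctions(calls, bp_tolerance: int):
    """Group calls into junction clusters (both coordinates within tolerance).

    Clusters are formed greedily over junctions sorted by coordinate, so the
    result does not depend on input order.
    """
    clusters: list = []  # each: {"bp5":…, "bp3":…, "calls": […]}
    for call in sorted(calls, key=_sort_key):
        home = None
        for cl in clusters:
            if (
                call.bp5.chrom == cl["bp5"].chrom
                and call.bp3.chrom == cl["bp3"].chrom
                and abs(call.bp5.pos - cl["bp5"].pos) <= bp_tolerance
                and abs(call.bp3.pos - cl["bp3"].pos) <= bp_tolerance
            ):
                home = cl
                break
        if home is None:
            clusters.append({"bp5": call.bp5, "bp3": call.bp3, "calls": [call]})
        else:
            home["calls"].append(call)
    return clusters


def _representative_junction(calls, bp_tolerance: int):
    """Pick the representative (bp5, bp3) for a merged event.

    The junction reported by the most distinct callers wins; ties break by
    highest total read support, then lowest coordinates — deterministic and
    favoring consensus evidence.
    """
    clusters = _cluster_junctions(calls, bp_tolerance)

    def score(cl):
        n_callers = len({c.caller for c in cl["calls"]})
        support = sum(c.total_reads for c in cl["calls"])
        return (-n_callers, -support, cl["bp5"].pos, cl["bp3"].pos, cl["bp5"].chrom, cl["bp3"].chrom)

    best = min(clusters, key=score)
    # within the winning cluster, the exact junction reported most often
    exact: dict = {}
    for c in best["calls"]:
        key = (c.bp5.chrom, c.bp5.pos, c.bp3.chrom, c.bp3.pos)
        exact.setdefault(key, []).append(c)
    best_key = min(
        exact,
        key=lambda k: (-len({c.caller for c in exact[k]}),
                       -sum(c.total_reads for c in exact[k]),
                       k[1], k[3], k[0], k[2]),
    )
    pick = sorted(exact[best_key], key=_sort_key)[0]
    return pick.bp5, pick.bp3


def _consensus_frame(calls) -> str:
    """Optimistic frame consensus: in-frame if any caller says so, then
    out-of-frame, else unknown.  Caller frame annotation quality varies;
    the final decision belongs to the frame filter."""
    frames = {c.frame for c in calls}
    if "in-frame" in frames:
        return "in-frame"
    if "out-of-frame" in frames:
        return "out-of-frame"
    return "unknown"


def merge_calls(calls, aliases: AliasTable, bp_tolerance: int = 100,
                collapse_reciprocal: bool = False) -> list:
    """Merge equivalent per-sample calls across callers into FusionEvents.

    Calls with the same canonical ordered gene pair in the same sample
    become one event regardless of breakpoint coordinates.  With
    ``collapse_reciprocal`` the two orientations A::B / B::A of one sample
    count as a single event keyed by the orientation reported by more
    callers (tie: lexicographically smaller pair).

    The merge is deterministic and independent of input order, and every
    input call appears in exactly one event's evidence.
    """
    if not calls:
        return []
    samples = {c.sample_id for c in calls}
    if len(samples) > 1:
        raise ContractError(f"merge_calls is per-sample; got samples {sorted(samples)}")
    sample = samples.pop()

    by_pair: dict = {}
    for call in sorted(calls, key=_sort_key):
        by_pair.setdefault(canonical_pair(call, aliases), []).append(call)

    if collapse_reciprocal:
        by_pair = _collapse_reciprocal_pairs(by_pair)

    events = []
    for pair in sorted(by_pair):
        group = by_pair[pair]
        bp5, bp3 = _representative_junction(group, bp_tolerance)
        evidence: dict = {}
        for call in group:
            evidence.setdefault(call.caller, []).append(call)
        events.append(
            FusionEvent(
                sample_id=sample,
                pair_key=pair,
                bp5=replace(bp5, gene_symbol=pair[0]),
                bp3=replace(bp3, gene_symbol=pair[1]),
                evidence=evidence,
                caller_count=len(evidence),
                frame=_consensus_frame(group),
                status="raw",
            )
        )
    return events


def _collapse_reciprocal_pairs(by_pair: dict) -> dict:
    collapsed: dict = {}
    for pair in sorted(by_pair):
        flipped = (pair[1], pair[0])
        if flipped in collapsed:
            collapsed[flipped].extend(by_pair[pair])
        else:
            collapsed[pair] = list(by_pair[pair])
    # re-key each group by the orientation with more distinct callers
    out: dict = {}
    for pair, group in collapsed.items():
        flipped = (pair[1], pair[0])
        fwd = {c.caller for c in group if (c.bp5.gene_symbol, c.bp3.gene_symbol) != flipped}
        rev = {c.caller for c in group} - fwd
        key = pair
        if len(rev) > len(fwd) or (len(rev) == len(fwd) and flipped < pair):
            key = flipped
        out[key] = group
    return out


def merge_cohort(calls, aliases: AliasTable, bp_tolerance: int = 100,
                 collapse_reciprocal: bool = False) -> list:
    """Merge a multi-sample list of calls, partitioning by sample first."""
    by_sample: dict = {}
    for call in calls:
        by_sample.setdefault(call.sample_id, []).append(call)
    events = []
    for sample in sorted(by_sample):
        events.extend(
            merge_calls(by_sample[sample], aliases, bp_tolerance, collapse_reciprocal)
        )
    return events


def consensus_select(events, k: int) -> list:
    """Events called by at least ``k`` of the five callers.

    Returns exactly the events with ``caller_count >= k``, tagged
    ``status='consensus'``.  Results nest: k=5 is a subset of k=4 is a
    subset of k=3.
    """
    if not isinstance(k, int) or not 1 <= k <= len(CALLERS):
        raise ValidationError(f"consensus threshold k must be in 1..{len(CALLERS)}, got {k!r}")
    return [ev.with_status("consensus") for ev in events if ev.caller_count >= k]
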