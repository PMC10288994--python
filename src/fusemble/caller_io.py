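"""Readers for the five callers' native output dialects, plus the two
standardized integration outputs.

Each parser is total over syntactically valid rows: every data row yields
exactly one :class:`~fusemble.model.RawCall`, rows are never silently
dropped, and no filtering is applied here — raw read counts and confidence
labels are preserved verbatim for the filters module to act on.  Column
layouts follow each tool's published output documentation; columns a parser
does not interpret land in ``RawCall.annotations``.

Numeric fields that fail to parse raise :class:`~fusemble.errors.FormatError`
naming the offending row (fail fast, never silent zeros).
"""

from __future__ import annotations

import os
from typing import Optional

import pandas as pd

from .errors import FormatError
from .model import Breakpoint, FusionEvent, RawCall, normalize_chrom

#: Canonical per-sample file name for each caller's output.
NATIVE_FILENAMES = {
    "arriba": "fusions.tsv",
    "starfusion": "star-fusion.fusion_predictions.tsv",
    "fusioncatcher": "final-list_candidate-fusion-genes.txt",
    "defuse": "results.filtered.tsv",
    "cicero": "final_fusions.txt",
}

#: Fixed column order of the standardized fusion table.
STANDARD_COLUMNS = [
    "sample",
    "gene5",
    "gene3",
    "chrom5",
    "pos5",
    "strand5",
    "chrom3",
    "pos3",
    "strand3",
    "caller_count",
    "callers",
    "max_split",
    "max_spanning",
    "frame",
    "status",
]


def _read_table(path) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file has no header row")
    return df


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")


def _int(value: str, column: str, row: int, path) -> int:
    try:
        return int(value)
    except (TypeError, ValueError):
        raise FormatError(f"{path}: row {row}: cannot parse {column}={value!r} as integer")


def _split_locus(value: str, column: str, row: int, path):
    """Parse 'chr:pos' or 'chr:pos:strand' into (chrom, pos, strand)."""
    parts = str(value).split(":")
    if len(parts) < 2:
        raise FormatError(f"{path}: row {row}: malformed breakpoint {column}={value!r}")
    chrom = normalize_chrom(parts[0])
    pos = _int(parts[1], column, row, path)
    strand = parts[2] if len(parts) > 2 and parts[2] in "+-" else "unknown"
    return chrom, pos, strand


def _strand(value: str) -> str:
    """Normalize a strand token; Arriba's 'gene/fusion' pairs use the fusion strand."""
    value = str(value).strip()
    if "/" in value:
        value = value.split("/")[-1]
    return value if value in ("+", "-") else "unknown"


def _frame_label(value: str) -> str:
    v = str(value).strip().lower().replace("_", "-")
    if v in ("in-frame", "inframe"):
        return "in-frame"
    if v in ("out-of-frame", "frameshift", "out-frame"):
        return "out-of-frame"
    return "unknown"


def _infer_sample_id(path, sample_id: Optional[str]) -> str:
    """Default sample id: the name of the directory holding the file."""
    if sample_id is not None:
        return sample_id
    return os.path.basename(os.path.dirname(os.path.abspath(path))) or "sample"


def _annotations(row, used) -> dict:
    return {k: v for k, v in row.items() if k not in used and v != ""}


# ---------------------------------------------------------------------------
# Arriba — fusions.tsv
# ---------------------------------------------------------------------------

_ARRIBA_MANDATORY = [
    "#gene1",
    "gene2",
    "strand1(gene/fusion)",
    "strand2(gene/fusion)",
    "breakpoint1",
    "breakpoint2",
    "split_reads1",
    "split_reads2",
    "discordant_mates",
    "confidence",
]


def parse_arriba(path, sample_id: Optional[str] = None) -> list:
    """Parse an Arriba ``fusions.tsv``.

    Arriba reports junction support in two columns (``split_reads1``,
    ``split_reads2``, one per breakpoint); they are summed into
    ``split_reads`` so every caller exposes a single comparable support
    scalar.  ``discordant_mates`` maps to ``spanning_reads`` and the
    ``confidence`` label (high/medium/low) is preserved verbatim.
    """
    df = _read_table(path)
    _require(df, _ARRIBA_MANDATORY, path)
    sample = _infer_sample_id(path, sample_id)
    calls = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        c1, p1, _ = _split_locus(row["breakpoint1"], "breakpoint1", i, path)
        c2, p2, _ = _split_locus(row["breakpoint2"], "breakpoint2", i, path)
        calls.append(
            RawCall(
                caller="arriba",
                sample_id=sample,
                bp5=Breakpoint(c1, p1, _strand(row["strand1(gene/fusion)"]), row["#gene1"]),
                bp3=Breakpoint(c2, p2, _strand(row["strand2(gene/fusion)"]), row["gene2"]),
                split_reads=_int(row["split_reads1"], "split_reads1", i, path)
                + _int(row["split_reads2"], "split_reads2", i, path),
                spanning_reads=_int(row["discordant_mates"], "discordant_mates", i, path),
                confidence=row["confidence"] or None,
                frame=_frame_label(row.get("reading_frame", "")),
                annotations=_annotations(row, set(_ARRIBA_MANDATORY)),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# STAR-Fusion — star-fusion.fusion_predictions.tsv
# ---------------------------------------------------------------------------

_STARFUSION_MANDATORY = [
    "#FusionName",
    "JunctionReadCount",
    "SpanningFragCount",
    "LeftBreakpoint",
    "RightBreakpoint",
]


def parse_starfusion(path, sample_id: Optional[str] = None) -> list:
    """Parse a STAR-Fusion predictions table.

    ``JunctionReadCount`` maps to ``split_reads`` and ``SpanningFragCount``
    to ``spanning_reads``; the ``#FusionName`` "A--B" is split into the 5'
    and 3' partner symbols.  Breakpoints are "chr:pos:strand" triplets.
    """
    df = _read_table(path)
    _require(df, _STARFUSION_MANDATORY, path)
    sample = _infer_sample_id(path, sample_id)
    calls = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        name = row["#FusionName"]
        if "--" not in name:
            raise FormatError(f"{path}: row {i}: malformed #FusionName {name!r}")
        g5, g3 = name.split("--", 1)
        c5, p5, s5 = _split_locus(row["LeftBreakpoint"], "LeftBreakpoint", i, path)
        c3, p3, s3 = _split_locus(row["RightBreakpoint"], "RightBreakpoint", i, path)
        calls.append(
            RawCall(
                caller="starfusion",
                sample_id=sample,
                bp5=Breakpoint(c5, p5, s5, g5),
                bp3=Breakpoint(c3, p3, s3, g3),
                split_reads=_int(row["JunctionReadCount"], "JunctionReadCount", i, path),
                spanning_reads=_int(row["SpanningFragCount"], "SpanningFragCount", i, path),
                confidence=None,
                frame=_frame_label(row.get("PROT_FUSION_TYPE", "")),
                annotations=_annotations(row, set(_STARFUSION_MANDATORY)),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# FusionCatcher — final-list_candidate-fusion-genes.txt
# ---------------------------------------------------------------------------

_FC_G5 = "Gene_1_symbol(5end_fusion_partner)"
_FC_G3 = "Gene_2_symbol(3end_fusion_partner)"
_FC_BP5 = "Fusion_point_for_gene_1(5end_fusion_partner)"
_FC_BP3 = "Fusion_point_for_gene_2(3end_fusion_partner)"
_FC_MANDATORY = [_FC_G5, _FC_G3, "Spanning_pairs", "Spanning_unique_reads", _FC_BP5, _FC_BP3]


def parse_fusioncatcher(path, sample_id: Optional[str] = None) -> list:
    """Parse a FusionCatcher final candidate list.

    ``Spanning_unique_reads`` (reads crossing the junction) maps to
    ``split_reads`` and ``Spanning_pairs`` to ``spanning_reads``.  The
    ``Fusion_description`` flags (e.g. known-artifact tags such as
    ``readthrough``) and ``Counts_of_common_mapping_reads`` are retained in
    ``annotations`` for downstream filtering and audit.
    """
    df = _read_table(path)
    _require(df, _FC_MANDATORY, path)
    sample = _infer_sample_id(path, sample_id)
    calls = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        c5, p5, s5 = _split_locus(row[_FC_BP5], _FC_BP5, i, path)
        c3, p3, s3 = _split_locus(row[_FC_BP3], _FC_BP3, i, path)
        calls.append(
            RawCall(
                caller="fusioncatcher",
                sample_id=sample,
                bp5=Breakpoint(c5, p5, s5, row[_FC_G5]),
                bp3=Breakpoint(c3, p3, s3, row[_FC_G3]),
                split_reads=_int(row["Spanning_unique_reads"], "Spanning_unique_reads", i, path),
                spanning_reads=_int(row["Spanning_pairs"], "Spanning_pairs", i, path),
                confidence=None,
                frame=_frame_label(row.get("Predicted_effect", "")),
                annotations=_annotations(row, set(_FC_MANDATORY)),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# deFuse — results.filtered.tsv
# ---------------------------------------------------------------------------

_DEFUSE_MANDATORY = [
    "gene_name1",
    "gene_name2",
    "gene_chromosome1",
    "gene_chromosome2",
    "genomic_break_pos1",
    "genomic_break_pos2",
    "gene_strand1",
    "gene_strand2",
    "splitr_count",
    "span_count",
    "probability",
]


def parse_defuse(path, sample_id: Optional[str] = None) -> list:
    """Parse a deFuse filtered results table.

    ``splitr_count``/``span_count`` map to split/spanning reads; the
    classifier ``probability`` is retained as the call's confidence label
    (interpreted numerically by the evidence filter).
    """
    df = _read_table(path)
    _require(df, _DEFUSE_MANDATORY, path)
    sample = _infer_sample_id(path, sample_id)
    calls = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        calls.append(
            RawCall(
                caller="defuse",
                sample_id=sample,
                bp5=Breakpoint(
                    normalize_chrom(row["gene_chromosome1"]),
                    _int(row["genomic_break_pos1"], "genomic_break_pos1", i, path),
                    _strand(row["gene_strand1"]),
                    row["gene_name1"],
                ),
                bp3=Breakpoint(
                    normalize_chrom(row["gene_chromosome2"]),
                    _int(row["genomic_break_pos2"], "genomic_break_pos2", i, path),
                    _strand(row["gene_strand2"]),
                    row["gene_name2"],
                ),
                split_reads=_int(row["splitr_count"], "splitr_count", i, path),
                spanning_reads=_int(row["span_count"], "span_count", i, path),
                confidence=row["probability"] or None,
                frame="unknown",
                annotations=_annotations(row, set(_DEFUSE_MANDATORY)),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# CICERO — final_fusions.txt
# ---------------------------------------------------------------------------

_CICERO_MANDATORY = [
    "geneA",
    "chrA",
    "posA",
    "ortA",
    "readsA",
    "geneB",
    "chrB",
    "posB",
    "ortB",
    "readsB",
    "rating",
]


def parse_cicero(path, sample_id: Optional[str] = None) -> list:
    """Parse a CICERO final fusions table.

    CICERO reports per-side soft-clip read evidence (``readsA``/``readsB``)
    rather than a split/spanning split; readsA maps to ``split_reads`` and
    readsB to ``spanning_reads`` as an approximation so the shared evidence
    filter applies uniformly.  The quality ``rating`` (e.g. HQ/LQ) is the
    confidence label; the numeric ``score`` stays in annotations.
    """
    df = _read_table(path)
    _require(df, _CICERO_MANDATORY, path)
    sample = sample_id
    calls = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        this_sample = sample or row.get("sample") or _infer_sample_id(path, None)
        calls.append(
            RawCall(
                caller="cicero",
                sample_id=this_sample,
                bp5=Breakpoint(
                    normalize_chrom(row["chrA"]),
                    _int(row["posA"], "posA", i, path),
                    _strand(row["ortA"]),
                    row["geneA"],
                ),
                bp3=Breakpoint(
                    normalize_chrom(row["chrB"]),
                    _int(row["posB"], "posB", i, path),
                    _strand(row["ortB"]),
                    row["geneB"],
                ),
                split_reads=_int(row["readsA"], "readsA", i, path),
                spanning_reads=_int(row["readsB"], "readsB", i, path),
                confidence=row["rating"] or None,
                frame=_frame_label(row.get("frame", "")),
                annotations=_annotations(row, set(_CICERO_MANDATORY) | {"sample"}),
            )
        )
    return calls


#: Parser dispatch by caller name.
PARSERS = {
    "arriba": parse_arriba,
    "starfusion": parse_starfusion,
    "fusioncatcher": parse_fusioncatcher,
    "defuse": parse_defuse,
    "cicero": parse_cicero,
}


# ---------------------------------------------------------------------------
# Integration outputs
# ---------------------------------------------------------------------------


def write_standard_table(events, path) -> None:
    """Write the standardized fusion table: one row per event, fixed columns.

    Re-parsing with :func:`read_standard_table` reproduces the event list up
    to ``FusionEvent.standard_view`` equality (evidence read counts beyond
    the per-event maxima are not representable in the table).
    """
    rows = []
    for ev in events:
        rows.append(
            {
                "sample": ev.sample_id,
                "gene5": ev.pair_key[0],
                "gene3": ev.pair_key[1],
                "chrom5": ev.bp5.chrom,
                "pos5": ev.bp5.pos,
                "strand5": ev.bp5.strand,
                "chrom3": ev.bp3.chrom,
                "pos3": ev.bp3.pos,
                "strand3": ev.bp3.strand,
                "caller_count": ev.caller_count,
                "callers": ",".join(ev.callers),
                "max_split": ev.max_split,
                "max_spanning": ev.max_spanning,
                "frame": ev.frame,
                "status": ev.status,
            }
        )
    df = pd.DataFrame(rows, columns=STANDARD_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_standard_table(path) -> list:
    """Read a standardized fusion table back into FusionEvents.

    The per-caller evidence lists cannot be reconstructed from the table;
    each listed caller gets a single synthetic evidence call carrying the
    event's maxima, which is exactly what ``standard_view`` exposes.
    """
    df = _read_table(path)
    _require(df, STANDARD_COLUMNS, path)
    events = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        callers = [c for c in row["callers"].split(",") if c]
        bp5 = Breakpoint(row["chrom5"], _int(row["pos5"], "pos5", i, path), row["strand5"], row["gene5"])
        bp3 = Breakpoint(row["chrom3"], _int(row["pos3"], "pos3", i, path), row["strand3"], row["gene3"])
        evidence = {
            caller: [
                RawCall(
                    caller=caller,
                    sample_id=row["sample"],
                    bp5=bp5,
                    bp3=bp3,
                    split_reads=_int(row["max_split"], "max_split", i, path),
                    spanning_reads=_int(row["max_spanning"], "max_spanning", i, path),
                )
            ]
            for caller in callers
        }
        events.append(
            FusionEvent(
                sample_id=row["sample"],
                pair_key=(row["gene5"], row["gene3"]),
                bp5=bp5,
                bp3=bp3,
                evidence=evidence,
                caller_count=_int(row["caller_count"], "caller_count", i, path),
                frame=row["frame"],
                status=row["status"],
            )
        )
    return events


def write_summary(events, path) -> None:
    """Write the caller-summary file: which callers detected each fusion.

    One row per event with the gene pair, the number of detecting callers,
    and the comma-joined caller names sorted alphabetically.
    """
    rows = [
        {
            "sample": ev.sample_id,
            "gene5": ev.pair_key[0],
            "gene3": ev.pair_key[1],
            "caller_count": ev.caller_count,
            "callers": ",".join(ev.callers),
        }
        for ev in events
    ]
    df = pd.DataFrame(rows, columns=["sample", "gene5", "gene3", "caller_count", "callers"])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
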