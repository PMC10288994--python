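"""Benchmarking call sets against a truth list.

The truth list holds rearrangements previously confirmed by orthogonal
clinical methods (karyotype, FISH, RT-qPCR, targeted panel).  A retained
call is a true positive iff its (sample, canonical gene pair) matches a
truth entry; each truth entry counts at most once toward TP, unmatched
truth entries are false negatives, and unmatched calls are false
positives.  Metrics:

    sensitivity = 100 * TP / (TP + FN)        (percent, one decimal)
    precision   = 100 * TP / (TP + FP)        (percent, one decimal)
    F1          = 2 * S * P / (S + P) / 100   (0-1 scale, two decimals)

Rounding is half away from zero, matching how such tables are printed
(14/19 -> 73.7).
"""

from __future__ import annotations

import math

import pandas as pd

from .errors import UndefinedMetricError, ValidationError
from .model import BenchmarkResult, TruthEntry


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (unlike banker's rounding)."""
    factor = 10 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def sensitivity(tp: int, fn: int) -> float:
    """100 * tp / (tp + fn), one decimal."""
    if tp + fn <= 0:
        raise UndefinedMetricError("sensitivity undefined: tp + fn = 0")
    return round_half_away(100.0 * tp / (tp + fn), 1)


def precision(tp: int, fp: int) -> float:
    """100 * tp / (tp + fp), one decimal."""
    if tp + fp <= 0:
        raise UndefinedMetricError("precision undefined: tp + fp = 0")
    return round_half_away(100.0 * tp / (tp + fp), 1)


def f1(sens: float, prec: float) -> float:
    """Harmonic mean of sensitivity and precision on the 0-1 scale, two decimals.

    Inputs are percentages (the printed values); the harmonic mean is
    scale-invariant so computing on percents and dividing by 100 is exact.
    """
    if sens + prec <= 0:
        raise UndefinedMetricError("F1 undefined: sensitivity + precision = 0")
    return round_half_away(2.0 * sens * prec / (sens + prec) / 100.0, 2)


def read_truth(path) -> list:
    """Read a truth TSV (sample_id, gene5, gene3, method) into TruthEntries."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["sample_id", "gene5", "gene3"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: truth file missing column(s): {', '.join(missing)}")
    entries = [
        TruthEntry(r["sample_id"], r["gene5"], r["gene3"], r.get("method", ""))
        for r in df.to_dict("records")
    ]
    return entries


def match_truth(calls, truth, aliases=None, orientation_insensitive: bool = False):
    """Partition calls and truth into (TP entries, FP calls, FN entries).

    ``calls`` are FusionEvents (typically the retained set); ``truth`` is a
    list of TruthEntry restricted to the same dataset.  With
    ``orientation_insensitive`` a call matches a truth entry regardless of
    which partner is 5'.  Multiple calls matching one truth entry count the
    entry once and produce no FP (they report the same true fusion).
    Duplicate truth entries are a validation error.
    """

    def _resolve(sym: str) -> str:
        return aliases.resolve(sym) if aliases is not None else sym

    def _key(sample, g5, g3):
        pair = (_resolve(g5), _resolve(g3))
        if orientation_insensitive:
            pair = tuple(sorted(pair))
        return (sample, pair)

    truth_by_key: dict = {}
    for entry in truth:
        key = _key(entry.sample_id, entry.gene5, entry.gene3)
        if key in truth_by_key:
            raise ValidationError(
                f"duplicate truth entry {entry.sample_id}: {entry.gene5}::{entry.gene3}"
            )
        truth_by_key[key] = entry

    tp_entries = set()
    fp_calls = []
    for ev in calls:
        key = _key(ev.sample_id, ev.pair_key[0], ev.pair_key[1])
        entry = truth_by_key.get(key)
        if entry is not None:
            tp_entries.add(entry)
        else:
            fp_calls.append(ev)
    fn_entries = {e for e in truth_by_key.values() if e not in tp_entries}
    return tp_entries, fp_calls, fn_entries


def benchmark(call_sets, truth_sets, aliases=None, orientation_insensitive: bool = False):
    """Score every method on every dataset, plus a pooled global row.

    ``call_sets`` maps method label -> dataset label -> list of retained
    FusionEvents; ``truth_sets`` maps dataset label -> list of TruthEntry.
    Returns ``(results, matrix)`` where ``results`` is a list of
    :class:`~fusemble.model.BenchmarkResult` (one per method x dataset and,
    when there are several datasets, one ``global`` row per method pooling
    tp/fp/fn) and ``matrix`` is a :class:`DetectionMatrix`.
    """
    if not truth_sets or all(len(t) == 0 for t in truth_sets.values()):
        raise UndefinedMetricError("benchmark requires a non-empty truth set")
    datasets = sorted(truth_sets)
    methods = list(call_sets)
    results = []
    detected: dict = {}
    for method in methods:
        pooled = {"tp": 0, "fp": 0, "fn": 0}
        for dataset in datasets:
            truth = truth_sets[dataset]
            calls = call_sets[method].get(dataset, [])
            tp_set, fp_calls, fn_set = match_truth(
                calls, truth, aliases, orientation_insensitive
            )
            for entry in truth:
                detected[(entry, method)] = entry in tp_set
            results.append(_result(method, dataset, len(tp_set), len(fp_calls), len(fn_set)))
            pooled["tp"] += len(tp_set)
            pooled["fp"] += len(fp_calls)
            pooled["fn"] += len(fn_set)
        if len(datasets) > 1:
            results.append(_result(method, "global", pooled["tp"], pooled["fp"], pooled["fn"]))
    truth_rows = [e for d in datasets for e in truth_sets[d]]
    return results, DetectionMatrix(truth_rows, methods, detected)


def _result(method, dataset, tp, fp, fn) -> BenchmarkResult:
    sens = sensitivity(tp, fn)
    # a method that identified nothing has no defined precision; report 0
    # so the table still carries the (0-sensitivity) row
    prec = precision(tp, fp) if tp + fp > 0 else 0.0
    f1_val = f1(sens, prec) if sens + prec > 0 else 0.0
    return BenchmarkResult(
        method=method,
        dataset=dataset,
        tp=tp,
        fp=fp,
        fn=fn,
        total_identified=tp + fp,
        sensitivity=sens,
        precision=prec,
        f1=f1_val,
    )


class DetectionMatrix:
    """Truth entries x methods grid of detected flags.

    A cell is true iff the method's call set contained a match for that
    truth entry (i.e. the entry is in the method's TP set).
    """

    def __init__(self, truth_rows, methods, detected) -> None:
        self.truth_rows = list(truth_rows)
        self.methods = list(methods)
        self._detected = dict(detected)

    def detected(self, entry: TruthEntry, method: str) -> bool:
        return self._detected.get((entry, method), False)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for entry in self.truth_rows:
            row = {
                "sample_id": entry.sample_id,
                "fusion": f"{entry.gene5}::{entry.gene3}",
            }
            for m in self.methods:
                row[m] = int(self.detected(entry, m))
            rows.append(row)
        return pd.DataFrame(rows, columns=["sample_id", "fusion"] + self.methods)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def results_to_frame(results) -> pd.DataFrame:
    """Benchmark results as a report table (one row per method x dataset)."""
    rows = [
        {
            "method": r.method,
            "dataset": r.dataset,
            "total_identified": r.total_identified,
            "tp": r.tp,
            "fp": r.fp,
            "fn": r.fn,
            "sensitivity": r.sensitivity,
            "precision": r.precision,
            "f1": r.f1,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "method", "dataset", "total_identified", "tp", "fp", "fn",
            "sensitivity", "precision", "f1",
        ],
    )


def write_report(results, path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, lineterminator="\n")
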