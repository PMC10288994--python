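"""Synthetic cohorts: annotation, truth sets, and native caller outputs.

Real benchmarking of fusion callers needs RNA-seq libraries and five
external tools; this module replaces that stack with fully synthetic,
seeded cohorts so every pipeline stage is testable on a laptop.  It emits:

* a toy GRCh38-labeled gene annotation (GTF) containing the leukemia
  whitelist genes, adjacent same-strand gene pairs for read-through
  geometry, blacklisted repeat/pseudogene loci, and filler genes — each
  with exon structures whose boundaries are the known splice sites;
* a truth TSV of expected rearrangements per sample;
* per-sample output files in all five callers' native dialects, with
  planted true fusions and artifacts from a defined taxonomy
  (read-through, out-of-frame, non-splice breakpoints, blacklisted,
  low support, low confidence, promiscuous, clean false positives).

Two canned scenarios (:func:`scenario_cell_lines`, :func:`scenario_patients`)
encode caller-detection patterns as deterministic flags — which fusions all
five callers find, which only four or three, and which none — so that the
end-to-end consensus metrics are exact by construction.  Generic cohorts
(:func:`random_cohort_spec`) sample detection per caller instead, for
property testing.  Same seed, same bytes.
"""

from __future__ import annotations

import os
import random
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
import yaml

from .annotation import GeneAnnotation, GeneModel, write_gtf
from .caller_io import NATIVE_FILENAMES
from .errors import ValidationError
from .model import CALLERS, TruthEntry

# ---------------------------------------------------------------------------
# Gene catalogue and deterministic layout
# ---------------------------------------------------------------------------

_GENE_LEN = 9_999  # start..start+_GENE_LEN, i.e. 10 kb genes
_EXON_OFFSETS = ((0, 1_999), (4_000, 5_999), (8_000, 9_999))
_SPACING = 3_000_000  # between unrelated genes on one chromosome
_CHROM_START = 1_000_000

#: Real leukemia-relevant genes (symbol -> chromosome), placed 3 Mb apart.
_REAL_GENES = {
    "ETV6": "12", "RUNX1": "21", "BCR": "22", "ABL1": "9", "KMT2A": "11",
    "AFF1": "4", "MLLT3": "9", "MLLT1": "19", "MLLT10": "10", "ELL": "19",
    "PML": "15", "RARA": "17", "RUNX1T1": "8", "CBFB": "16", "MYH11": "16",
    "TCF3": "19", "PBX1": "1", "HLF": "17", "NKX2-5": "5", "BCL11B": "14",
    "TLX3": "5", "LMO1": "11", "TRD": "14", "SET": "9", "NUP214": "9",
    "DEK": "6", "NUP98": "11", "KDM5A": "12", "FUS": "16", "ERG": "21",
    "EP300": "22", "ZNF384": "12", "PAX5": "9", "JAK2": "9",
    "MEF2D": "1", "BCL9": "1",
}

#: Blacklisted repeat/paralog/pseudogene loci (must be annotated too).
_BLACK_GENES = {
    "HLA-DRB5": "6", "GOLGA8A": "15", "GOLGA8B": "15", "PABPC1P2": "2",
    "NBPF10": "1", "POTEE": "2", "LINC00969": "3",
}

_BIOTYPES = {"CDKN2B-AS1": "lncRNA", "LINC00969": "lncRNA", "PABPC1P2": "pseudogene"}

#: Adjacent same-strand gene pairs: (genomic-left, genomic-right, chrom,
#: strand, intergenic gap).  These create read-through geometry.  STIL/TAL1
#: and P2RY8/CRLF2 are the two clinically relevant intrachromosomal
#: deletions that *look* like read-throughs; the whitelist rescues them.
_ADJACENT = [
    ("STIL", "TAL1", "1", "+", 16_000),
    ("P2RY8", "CRLF2", "X", "+", 300_000),
    ("MTAP", "CDKN2B-AS1", "9", "+", 60_000),
    ("RAG1", "IFTAP", "11", "+", 40_000),
    ("SYNRTAA", "SYNRTAB", "2", "+", 50_000),
    ("SYNRTBA", "SYNRTBB", "3", "+", 50_000),
    ("SYNRTCA", "SYNRTCB", "7", "+", 50_000),
    ("SYNRTDB", "SYNRTDA", "8", "-", 50_000),  # minus strand: 5' gene downstream
    ("SYNRTEA", "SYNRTEB", "13", "+", 50_000),
    ("SYNRTFA", "SYNRTFB", "20", "+", 50_000),
]

#: Artifact pools: fixed gene couples per artifact class.  Each couple's
#: genes appear in no other couple, so planting one event per (sample,
#: couple) never creates accidental promiscuity.
RT_POOL = [
    ("MTAP", "CDKN2B-AS1"), ("RAG1", "IFTAP"),
    ("SYNRTAA", "SYNRTAB"), ("SYNRTBA", "SYNRTBB"), ("SYNRTCA", "SYNRTCB"),
    ("SYNRTDA", "SYNRTDB"), ("SYNRTEA", "SYNRTEB"), ("SYNRTFA", "SYNRTFB"),
]
OOF_POOL = [(f"SYNOF{i}A", f"SYNOF{i}B") for i in range(1, 7)]
NSP_POOL = [(f"SYNNS{i}A", f"SYNNS{i}B") for i in range(1, 7)]
BLK_POOL = [(g, f"SYNBL{i}") for i, g in enumerate(sorted(_BLACK_GENES), start=1)]
LS_POOL = [(f"SYNLS{i}A", f"SYNLS{i}B") for i in range(1, 7)]
LC_POOL = [(f"SYNLC{i}A", f"SYNLC{i}B") for i in range(1, 5)]
FP_POOL = [(f"SYNFP{i}A", f"SYNFP{i}B") for i in range(1, 7)]
PG_HUBS = [(f"SYNPGH{i}", (f"SYNPGH{i}P1", f"SYNPGH{i}P2")) for i in range(1, 4)]

_CLASS_POOLS = {
    "read_through": RT_POOL,
    "out_of_frame": OOF_POOL,
    "non_splice": NSP_POOL,
    "blacklisted": BLK_POOL,
    "low_support": LS_POOL,
    "low_confidence": LC_POOL,
    "random_fp": FP_POOL,
}

_SYN_CHROMS = ("2", "3", "6", "7", "8", "10", "13", "15", "18", "20")


def _catalogue() -> list:
    """All gene placements, fully deterministic (no randomness involved)."""
    cursor: dict = {}

    def place(symbol: str, chrom: str, strand: str = "+", at: Optional[int] = None) -> GeneModel:
        start = cursor.get(chrom, _CHROM_START) if at is None else at
        gene = GeneModel(
            symbol=symbol,
            chrom=chrom,
            start=start,
            end=start + _GENE_LEN,
            strand=strand,
            biotype=_BIOTYPES.get(symbol, "protein_coding"),
            exons=[(start + a, start + b) for a, b in _EXON_OFFSETS],
        )
        cursor[chrom] = gene.end + _SPACING
        return gene

    genes = []
    for left, right, chrom, strand, gap in _ADJACENT:
        g_left = place(left, chrom, strand)
        g_right = place(right, chrom, strand, at=g_left.end + gap)
        genes.extend([g_left, g_right])

    placed = {g.symbol for g in genes}
    for symbol in sorted(_REAL_GENES):
        if symbol not in placed:
            genes.append(place(symbol, _REAL_GENES[symbol]))
    for symbol in sorted(_BLACK_GENES):
        if symbol not in placed:
            genes.append(place(symbol, _BLACK_GENES[symbol]))

    synthetic = sorted(
        {g for pool in (OOF_POOL, NSP_POOL, LS_POOL, LC_POOL, FP_POOL) for pair in pool for g in pair}
        | {s for pair in BLK_POOL for s in pair if s.startswith("SYNBL")}
        | {hub for hub, _ in PG_HUBS}
        | {p for _, partners in PG_HUBS for p in partners}
    )
    for i, symbol in enumerate(synthetic):
        genes.append(place(symbol, _SYN_CHROMS[i % len(_SYN_CHROMS)]))
    return genes


def generate_annotation(gtf_path=None) -> GeneAnnotation:
    """The deterministic toy annotation; optionally written as GTF.

    Contains every whitelist gene exactly once, the adjacent same-strand
    pairs used for read-through tests, and exon structures whose boundary
    coordinates are the planted splice sites.  Output is byte-identical
    across runs (the layout involves no randomness).
    """
    genes = _catalogue()
    if gtf_path is not None:
        write_gtf(genes, gtf_path)
    return GeneAnnotation(genes)


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

ARTIFACT_CLASSES = (
    "read_through", "out_of_frame", "non_splice", "blacklisted",
    "low_support", "low_confidence", "promiscuous", "random_fp",
)


@dataclass
class FusionPlan:
    """One fusion to plant: a (sample, gene pair) with its detection set.

    ``kind`` is ``truth`` or an artifact class.  ``callers`` is the exact
    set of callers that report it (deterministic scenarios); ``None`` means
    detection is sampled per caller from the cohort's ``detect_p`` at
    generation time.  An empty tuple plants nothing (a guaranteed FN).
    """

    sample_id: str
    gene5: str
    gene3: str
    kind: str = "truth"
    callers: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.kind != "truth" and self.kind not in ARTIFACT_CLASSES:
            raise ValidationError(f"unknown fusion kind {self.kind!r}")
        if self.callers is not None:
            bad = set(self.callers) - set(CALLERS)
            if bad:
                raise ValidationError(f"unknown caller(s) {sorted(bad)}")


@dataclass
class CohortSpec:
    """Everything needed to materialize one synthetic cohort.

    ``detect_p`` gives each caller's probability of reporting a truth
    fusion whose plan leaves detection unspecified.  Read-support ranges
    separate true calls (always above the default evidence thresholds)
    from low-support artifacts (always below, by construction).
    """

    name: str
    samples: list
    plans: list
    detect_p: dict = field(default_factory=lambda: {c: 1.0 for c in CALLERS})
    true_split: tuple = (8, 40)
    true_spanning: tuple = (4, 20)
    low_split: tuple = (0, 1)
    low_spanning: tuple = (0, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        for c, p in self.detect_p.items():
            if c not in CALLERS:
                raise ValidationError(f"unknown caller {c!r} in detect_p")
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"detect_p[{c}]={p} outside [0, 1]")
        known = {g.symbol for g in _catalogue()}
        for plan in self.plans:
            for g in (plan.gene5, plan.gene3):
                if g not in known:
                    raise ValidationError(
                        f"gene {g!r} in plan {plan.sample_id}:{plan.gene5}::{plan.gene3} "
                        "is absent from the annotation catalogue"
                    )

    @property
    def truth(self) -> list:
        methods = ("karyotype", "FISH", "RT-qPCR", "NGS-panel")
        return [
            TruthEntry(p.sample_id, p.gene5, p.gene3, methods[i % len(methods)])
            for i, p in enumerate(pl for pl in self.plans if pl.kind == "truth")
        ]


# ---------------------------------------------------------------------------
# Scenario specs: deterministic detection patterns
# ---------------------------------------------------------------------------

_A, _C, _D, _F, _S = CALLERS
_ALL5 = CALLERS

#: Cell-line cohort: 14 samples, 19 expected rearrangements.  Three fusions
#: (NKX2-5::BCL11B, TLX3::BCL11B, LMO1::TRD) are detected by no caller;
#: FusionCatcher reports all 16 remaining fusions.
_CELL_TRUTH = [
    ("CL01", "ETV6", "RUNX1", _ALL5),
    ("CL02", "BCR", "ABL1", _ALL5),
    ("CL03", "KMT2A", "AFF1", _ALL5),
    ("CL04", "KMT2A", "MLLT3", _ALL5),
    ("CL05", "PML", "RARA", _ALL5),
    ("CL06", "RUNX1", "RUNX1T1", _ALL5),
    ("CL07", "CBFB", "MYH11", _ALL5),
    ("CL08", "TCF3", "PBX1", _ALL5),
    ("CL09", "SET", "NUP214", _ALL5),
    ("CL10", "DEK", "NUP214", _ALL5),
    ("CL11", "KMT2A", "MLLT1", _ALL5),
    ("CL12", "KMT2A", "MLLT10", _ALL5),
    ("CL13", "TCF3", "HLF", _ALL5),
    ("CL14", "P2RY8", "CRLF2", (_A, _C, _F, _S)),
    ("CL09", "STIL", "TAL1", (_A, _C, _F)),
    ("CL10", "FUS", "ERG", (_D, _F, _S)),
    ("CL11", "NKX2-5", "BCL11B", ()),
    ("CL12", "TLX3", "BCL11B", ()),
    ("CL13", "LMO1", "TRD", ()),
]

#: Patient cohort: 15 samples, 22 expected rearrangements.  Twelve are
#: called by all five callers, six by exactly four, four (including
#: STIL::TAL1 and P2RY8::CRLF2) by exactly three.
_PATIENT_TRUTH = [
    ("P01", "ETV6", "RUNX1", _ALL5),
    ("P02", "BCR", "ABL1", _ALL5),
    ("P03", "KMT2A", "AFF1", _ALL5),
    ("P04", "PML", "RARA", _ALL5),
    ("P05", "RUNX1", "RUNX1T1", _ALL5),
    ("P06", "CBFB", "MYH11", _ALL5),
    ("P07", "TCF3", "PBX1", _ALL5),
    ("P08", "KMT2A", "MLLT1", _ALL5),
    ("P09", "KMT2A", "MLLT3", _ALL5),
    ("P10", "ETV6", "ABL1", _ALL5),
    ("P11", "PAX5", "JAK2", _ALL5),
    ("P12", "EP300", "ZNF384", _ALL5),
    ("P13", "KMT2A", "MLLT10", (_A, _C, _F, _S)),
    ("P14", "TCF3", "HLF", (_A, _D, _F, _S)),
    ("P15", "SET", "NUP214", (_A, _C, _D, _F)),
    ("P01", "MEF2D", "BCL9", (_A, _C, _F, _S)),
    ("P02", "DEK", "NUP214", (_A, _D, _F, _S)),
    ("P04", "KMT2A", "ELL", (_A, _C, _D, _F)),
    ("P05", "STIL", "TAL1", (_A, _C, _F)),
    ("P06", "P2RY8", "CRLF2", (_A, _F, _S)),
    ("P07", "NUP98", "KDM5A", (_C, _F, _S)),
    ("P08", "TCF3", "ZNF384", (_A, _D, _F)),
]

_K4_SUBSETS = [
    (_A, _C, _D, _F), (_A, _C, _F, _S), (_A, _D, _F, _S), (_C, _D, _F, _S), (_A, _C, _D, _S),
]
_K3_SUBSETS = [
    (_A, _C, _F), (_A, _F, _S), (_C, _D, _F), (_A, _C, _D), (_D, _F, _S), (_C, _F, _S),
]
_K5_SUBSETS = [_ALL5]
_SUBSETS = {5: _K5_SUBSETS, 4: _K4_SUBSETS, 3: _K3_SUBSETS}

#: Discarded-artifact classes cycled through when planning funnels.
_FUNNEL_CLASSES = ("read_through", "out_of_frame", "non_splice", "blacklisted", "low_support")


def _plan_artifacts(samples, discard_counts: dict, fp_counts: dict) -> list:
    """Deterministically plan artifact events with exact per-k counts.

    ``discard_counts`` maps caller-agreement level k -> number of artifact
    events (each built so the default cascade discards it); ``fp_counts``
    maps k -> number of clean false positives (built to survive).
    """
    plans = []
    used = set()  # (sample, gene5, gene3)
    pool_pos = {klass: 0 for klass in _CLASS_POOLS}

    def next_pair(klass: str, sample: str) -> tuple:
        pool = _CLASS_POOLS[klass]
        for step in range(len(pool)):
            pair = pool[(pool_pos[klass] + step) % len(pool)]
            if (sample, pair[0], pair[1]) not in used:
                pool_pos[klass] = (pool_pos[klass] + step + 1) % len(pool)
                used.add((sample, pair[0], pair[1]))
                return pair
        raise ValidationError(f"artifact pool for {klass!r} exhausted in sample {sample}")

    idx = 0
    for k in (5, 4, 3):
        subsets = _SUBSETS[k]
        for j in range(discard_counts.get(k, 0)):
            klass = _FUNNEL_CLASSES[idx % len(_FUNNEL_CLASSES)]
            sample = samples[idx % len(samples)]
            pair = next_pair(klass, sample)
            plans.append(FusionPlan(sample, pair[0], pair[1], kind=klass, callers=subsets[j % len(subsets)]))
            idx += 1
    for k in (5, 4, 3):
        subsets = _SUBSETS[k]
        for j in range(fp_counts.get(k, 0)):
            sample = samples[idx % len(samples)]
            pair = next_pair("random_fp", sample)
            plans.append(FusionPlan(sample, pair[0], pair[1], kind="random_fp", callers=subsets[j % len(subsets)]))
            idx += 1
    return plans


def scenario_cell_lines(seed: int = 0) -> CohortSpec:
    """The 14-cell-line cohort with its 19-entry truth set.

    Caller agreement among detected truth fusions: 13 at 5/5, one at 4/5,
    two at 3/5, three undetected.  Planted artifacts give pre-filter
    consensus candidate counts of 28 (5/5), 49 (>=4/5) and 100 (>=3/5),
    of which one, two and four clean false positives survive the cascade.
    """
    samples = [f"CL{i:02d}" for i in range(1, 15)]
    plans = [FusionPlan(s, g5, g3, kind="truth", callers=det) for s, g5, g3, det in _CELL_TRUTH]
    plans += _plan_artifacts(
        samples,
        discard_counts={5: 14, 4: 19, 3: 47},
        fp_counts={5: 1, 4: 1, 3: 2},
    )
    return CohortSpec(name="cell_lines", samples=samples, plans=plans, seed=seed)


def scenario_patients(seed: int = 0) -> CohortSpec:
    """The 15-patient cohort with its 22-entry truth set.

    Twelve truth fusions reach 5/5 agreement, eighteen reach >=4/5 and all
    22 reach >=3/5.  Pre-filter consensus candidate counts are 23 (5/5),
    43 (>=4/5) and 74 (>=3/5); exactly one clean false positive (at 3/5
    agreement) survives the cascade.
    """
    samples = [f"P{i:02d}" for i in range(1, 16)]
    plans = [FusionPlan(s, g5, g3, kind="truth", callers=det) for s, g5, g3, det in _PATIENT_TRUTH]
    plans += _plan_artifacts(
        samples,
        discard_counts={5: 11, 4: 14, 3: 26},
        fp_counts={3: 1},
    )
    return CohortSpec(name="patients", samples=samples, plans=plans, seed=seed)


#: Truth pairs available to random cohorts.
TRUTH_PAIR_POOL = [(g5, g3) for _, g5, g3, _ in _CELL_TRUTH] + [
    (g5, g3) for _, g5, g3, _ in _PATIENT_TRUTH
]


def random_cohort_spec(
    n_samples: int = 4,
    fusions_per_sample: int = 2,
    detect_p=0.8,
    artifact_mix: Optional[dict] = None,
    seed: int = 0,
) -> CohortSpec:
    """A sampled cohort for property tests.

    Truth pairs are drawn without replacement per sample from the known
    leukemia fusion pool; detection is left unspecified so each caller
    reports each truth fusion with probability ``detect_p`` at generation
    time.  ``artifact_mix`` maps artifact class -> count across the cohort
    (``promiscuous`` plants two hub events per count unit).
    """
    rng = random.Random(seed)
    if not isinstance(detect_p, dict):
        detect_p = {c: float(detect_p) for c in CALLERS}
    samples = [f"S{i:02d}" for i in range(1, n_samples + 1)]
    plans = []
    for sample in samples:
        pairs = rng.sample(sorted(set(TRUTH_PAIR_POOL)), fusions_per_sample)
        seen_genes: set = set()
        for g5, g3 in pairs:
            if {g5, g3} & seen_genes:
                continue  # keep truth genes sample-unique (no accidental promiscuity)
            seen_genes |= {g5, g3}
            plans.append(FusionPlan(sample, g5, g3, kind="truth", callers=None))
    for klass, count in sorted((artifact_mix or {}).items()):
        if klass == "promiscuous":
            for i in range(count):
                hub, partners = PG_HUBS[i % len(PG_HUBS)]
                sample = samples[rng.randrange(n_samples)]
                callers = tuple(sorted(rng.sample(CALLERS, 3)))
                for p in partners:
                    plans.append(FusionPlan(sample, hub, p, kind="promiscuous", callers=callers))
            continue
        pool = _CLASS_POOLS[klass]
        for i in range(count):
            pair = pool[i % len(pool)]
            sample = samples[rng.randrange(n_samples)]
            if klass == "low_confidence":
                callers = ("arriba", "defuse")
            else:
                callers = tuple(sorted(rng.sample(CALLERS, rng.randint(1, 5))))
            plans.append(FusionPlan(sample, pair[0], pair[1], kind=klass, callers=callers))
    return CohortSpec(
        name=f"random-{seed}", samples=samples, plans=plans, detect_p=detect_p, seed=seed
    )


# ---------------------------------------------------------------------------
# Rendering native caller files
# ---------------------------------------------------------------------------

#: Symbols FusionCatcher reports under a legacy alias, to exercise
#: harmonization (the alias table maps them back).
_FC_ALIASES = {"KMT2A": "MLL", "ETV6": "TEL", "RUNX1": "AML1"}

_CLEAN_CONFIDENCE = {"arriba": "high", "cicero": "HQ"}
_LOW_CONFIDENCE = {"arriba": "low", "cicero": "LQ"}


def _junction(ann: GeneAnnotation, plan: FusionPlan):
    """Breakpoints for a planted fusion: exon boundaries (splice sites),
    except the ``non_splice`` class which lands in the 5' gene's intron."""
    g5 = ann.gene(plan.gene5)
    g3 = ann.gene(plan.gene3)
    pos5 = g5.start + 2_500 if plan.kind == "non_splice" else g5.exons[1][1]
    pos3 = g3.exons[1][0]
    return (g5.chrom, pos5, g5.strand), (g3.chrom, pos3, g3.strand)


def _support(spec: CohortSpec, plan: FusionPlan, rng: random.Random):
    if plan.kind == "low_support":
        return rng.randint(*spec.low_split), rng.randint(*spec.low_spanning)
    return rng.randint(*spec.true_split), rng.randint(*spec.true_spanning)


def _frame_words(plan: FusionPlan):
    if plan.kind == "out_of_frame":
        return "out-of-frame", "FRAMESHIFT"
    return "in-frame", "INFRAME"


def _render_rows(spec: CohortSpec, ann: GeneAnnotation, plan: FusionPlan,
                 callers, rng: random.Random, cluster_id: int) -> dict:
    """One row dict per detecting caller, in that caller's native dialect."""
    (c5, p5, s5), (c3, p3, s3) = _junction(ann, plan)
    frame_word, sf_frame = _frame_words(plan)
    low_conf = plan.kind == "low_confidence"
    rows: dict = {}
    for caller in callers:
        split, spanning = _support(spec, plan, rng)
        if caller == "arriba":
            rows[caller] = {
                "#gene1": plan.gene5, "gene2": plan.gene3,
                "strand1(gene/fusion)": f"{s5}/{s5}", "strand2(gene/fusion)": f"{s3}/{s3}",
                "breakpoint1": f"{c5}:{p5}", "breakpoint2": f"{c3}:{p3}",
                "site1": "splice-site", "site2": "splice-site", "type": "translocation",
                "split_reads1": split // 2, "split_reads2": split - split // 2,
                "discordant_mates": spanning,
                "coverage1": split * 3, "coverage2": split * 3,
                "confidence": _LOW_CONFIDENCE["arriba"] if low_conf else _CLEAN_CONFIDENCE["arriba"],
                "reading_frame": frame_word, "tags": ".",
            }
        elif caller == "starfusion":
            rows[caller] = {
                "#FusionName": f"{plan.gene5}--{plan.gene3}",
                "JunctionReadCount": split, "SpanningFragCount": spanning,
                "SpliceType": "ONLY_REF_SPLICE",
                "LeftGene": f"{plan.gene5}^ENSG00000000000",
                "LeftBreakpoint": f"chr{c5}:{p5}:{s5}",
                "RightGene": f"{plan.gene3}^ENSG00000000001",
                "RightBreakpoint": f"chr{c3}:{p3}:{s3}",
                "LargeAnchorSupport": "YES_LDAS", "FFPM": "1.5",
                "PROT_FUSION_TYPE": sf_frame,
            }
        elif caller == "fusioncatcher":
            desc = "readthrough" if plan.kind == "read_through" else "known"
            rows[caller] = {
                "Gene_1_symbol(5end_fusion_partner)": _FC_ALIASES.get(plan.gene5, plan.gene5),
                "Gene_2_symbol(3end_fusion_partner)": _FC_ALIASES.get(plan.gene3, plan.gene3),
                "Fusion_description": desc,
                "Counts_of_common_mapping_reads": rng.randint(0, 3),
                "Spanning_pairs": spanning, "Spanning_unique_reads": split,
                "Longest_anchor_found": 30, "Fusion_finding_method": "BOWTIE;STAR",
                "Fusion_point_for_gene_1(5end_fusion_partner)": f"{c5}:{p5}:{s5}",
                "Fusion_point_for_gene_2(3end_fusion_partner)": f"{c3}:{p3}:{s3}",
                "Predicted_effect": frame_word,
            }
        elif caller == "defuse":
            prob = "0.35" if low_conf else f"0.{rng.randint(75, 99)}"
            rows[caller] = {
                "cluster_id": cluster_id,
                "gene_name1": plan.gene5, "gene_name2": plan.gene3,
                "gene_chromosome1": c5, "gene_chromosome2": c3,
                "genomic_break_pos1": p5, "genomic_break_pos2": p3,
                "gene_strand1": s5, "gene_strand2": s3,
                "splitr_count": split, "span_count": spanning,
                "probability": prob,
            }
        elif caller == "cicero":
            rows[caller] = {
                "sample": plan.sample_id,
                "geneA": plan.gene5, "chrA": c5, "posA": p5, "ortA": s5, "readsA": split,
                "geneB": plan.gene3, "chrB": c3, "posB": p3, "ortB": s3, "readsB": spanning,
                "type": "CTX",
                "rating": _LOW_CONFIDENCE["cicero"] if low_conf else _CLEAN_CONFIDENCE["cicero"],
                "score": rng.randint(60, 100), "frame": frame_word,
            }
    return rows


_CALLER_COLUMNS = {
    "arriba": ["#gene1", "gene2", "strand1(gene/fusion)", "strand2(gene/fusion)",
               "breakpoint1", "breakpoint2", "site1", "site2", "type",
               "split_reads1", "split_reads2", "discordant_mates",
               "coverage1", "coverage2", "confidence", "reading_frame", "tags"],
    "starfusion": ["#FusionName", "JunctionReadCount", "SpanningFragCount", "SpliceType",
                   "LeftGene", "LeftBreakpoint", "RightGene", "RightBreakpoint",
                   "LargeAnchorSupport", "FFPM", "PROT_FUSION_TYPE"],
    "fusioncatcher": ["Gene_1_symbol(5end_fusion_partner)", "Gene_2_symbol(3end_fusion_partner)",
                      "Fusion_description", "Counts_of_common_mapping_reads",
                      "Spanning_pairs", "Spanning_unique_reads", "Longest_anchor_found",
                      "Fusion_finding_method",
                      "Fusion_point_for_gene_1(5end_fusion_partner)",
                      "Fusion_point_for_gene_2(3end_fusion_partner)", "Predicted_effect"],
    "defuse": ["cluster_id", "gene_name1", "gene_name2", "gene_chromosome1", "gene_chromosome2",
               "genomic_break_pos1", "genomic_break_pos2", "gene_strand1", "gene_strand2",
               "splitr_count", "span_count", "probability"],
    "cicero": ["sample", "geneA", "chrA", "posA", "ortA", "readsA",
               "geneB", "chrB", "posB", "ortB", "readsB", "type", "rating", "score", "frame"],
}

def _write_caller_file(caller: str, rows: list, path) -> None:
    df = pd.DataFrame(rows, columns=_CALLER_COLUMNS[caller])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def generate_cohort(spec: CohortSpec, out_dir, seed: Optional[int] = None) -> dict:
    """Materialize a cohort on disk; returns the paths written.

    Layout: ``annotation.gtf``, ``truth.tsv``, ``cohort.yaml`` at the top
    level and one directory per sample holding the five native caller
    files (a file is always written, header-only when that caller reports
    nothing).  Identical (spec, seed) pairs produce byte-identical trees.
    """
    seed = spec.seed if seed is None else seed
    rng = random.Random(seed)
    os.makedirs(out_dir, exist_ok=True)
    ann = generate_annotation(os.path.join(out_dir, "annotation.gtf"))

    # decide detection for sampled plans, in plan order (reproducible)
    resolved = []
    for plan in spec.plans:
        callers = plan.callers
        if callers is None:
            callers = tuple(c for c in CALLERS if rng.random() < spec.detect_p[c])
        resolved.append((plan, tuple(c for c in CALLERS if c in callers)))

    rows_by_sample: dict = {s: {c: [] for c in CALLERS} for s in spec.samples}
    cluster_id = 0
    for plan, callers in resolved:
        if plan.sample_id not in rows_by_sample:
            raise ValidationError(f"plan references unknown sample {plan.sample_id!r}")
        cluster_id += 1
        for caller, row in _render_rows(spec, ann, plan, callers, rng, cluster_id).items():
            rows_by_sample[plan.sample_id][caller].append(row)

    paths = {"annotation": os.path.join(out_dir, "annotation.gtf"), "samples": {}}
    for sample in spec.samples:
        sdir = os.path.join(out_dir, sample)
        os.makedirs(sdir, exist_ok=True)
        paths["samples"][sample] = {}
        for caller in CALLERS:
            fpath = os.path.join(sdir, NATIVE_FILENAMES[caller])
            _write_caller_file(caller, rows_by_sample[sample][caller], fpath)
            paths["samples"][sample][caller] = fpath

    truth_path = os.path.join(out_dir, "truth.tsv")
    pd.DataFrame(
        [
            {"sample_id": t.sample_id, "gene5": t.gene5, "gene3": t.gene3, "method": t.method}
            for t in spec.truth
        ],
        columns=["sample_id", "gene5", "gene3", "method"],
    ).to_csv(truth_path, sep="\t", index=False, lineterminator="\n")
    paths["truth"] = truth_path

    meta = {
        "name": spec.name,
        "seed": seed,
        "samples": list(spec.samples),
        "n_truth": len(spec.truth),
        "n_artifact_plans": sum(1 for p in spec.plans if p.kind != "truth"),
        "detect_p": {c: float(p) for c, p in sorted(spec.detect_p.items())},
    }
    yaml_path = os.path.join(out_dir, "cohort.yaml")
    with open(yaml_path, "w", encoding="utf-8", newline="\n") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    paths["config"] = yaml_path
    return paths


def write_random_caller_file(caller: str, n_rows: int, path, seed: int = 0,
                             sample_id: str = "SAMPLE") -> None:
    """A single native-format file with ``n_rows`` synthetic clean calls.

    Used for parser stress tests (row counts, dialect coverage); pairs are
    drawn with replacement from the truth pool so symbols repeat.
    """
    rng = random.Random(seed)
    ann = generate_annotation()
    pool = sorted(set(TRUTH_PAIR_POOL))
    spec = CohortSpec(name="stress", samples=[sample_id], plans=[], seed=seed)
    rows = []
    for i in range(n_rows):
        g5, g3 = pool[rng.randrange(len(pool))]
        plan = FusionPlan(sample_id, g5, g3, kind="truth", callers=(caller,))
        rows.append(_render_rows(spec, ann, plan, (caller,), rng, i + 1)[caller])
    _write_caller_file(caller, rows, path)
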