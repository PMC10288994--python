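# Methods

## Problem and approach

Gene fusions drive a large fraction of pediatric acute leukemias
(ETV6::RUNX1, BCR::ABL1, KMT2A rearrangements, …), and RNA-seq is the
broadest single assay for finding them. No single fusion caller is
reliable alone: each misses real events and reports many artifacts.
fusemble implements the post-calling half of an ensemble workflow. It
consumes the native output files of five callers — Arriba, CICERO,
deFuse, FusionCatcher and STAR-Fusion — and performs:

1. **Harmonization.** Each caller's dialect is parsed into a common
   `RawCall` record (5'/3' breakpoints, split reads, spanning reads,
   confidence, frame). Gene symbols are canonicalized through an alias
   table (MLL → KMT2A, …). Calls with the same canonical ordered gene
   pair in the same sample merge into one `FusionEvent`, whatever their
   breakpoint coordinates: callers systematically disagree on exact
   junctions (different aligners and conventions), and fusions are
   counted at gene-pair granularity.
2. **Consensus (k of 5).** An event is a consensus call if at least k
   distinct callers report it. k = 5, 4, 3 trade precision against
   sensitivity; results nest by construction (k=5 ⊆ k=4 ⊆ k=3).
3. **Filter cascade.** Evidence thresholds, read-through geometry,
   reading frame, splice-site placement, blacklist, and within-sample
   gene promiscuity, with whitelist rescue for clinically relevant
   leukemia genes. Every event gets a machine-readable verdict; the
   audit TSV is the hand-off to human curation (IGV review, BLAST,
   literature — deliberately out of scope).
4. **Benchmarking.** Retained calls are scored against a truth list of
   rearrangements previously confirmed by orthogonal clinical methods:
   sensitivity = 100·TP/(TP+FN), precision = 100·TP/(TP+FP), and their
   harmonic mean F1 on the 0–1 scale.

## Merging details

- The merge key is `(sample, canonical 5' gene, canonical 3' gene)`.
  Fusion direction is meaningful, so A::B and B::A stay distinct by
  default; `collapse_reciprocal` folds them into the orientation
  reported by more callers (tie: lexicographic).
- The representative breakpoint pair is chosen by clustering reported
  junctions (both coordinates within `bp_tolerance`, default 100 bp,
  chosen to cover caller-to-caller junction jitter at one exon boundary)
  and picking the cluster backed by the most distinct callers; ties
  break by total read support, then lowest coordinate. Deterministic
  and order-independent; verified by brute-force permutation tests.
- Frame consensus is optimistic: "in-frame" if any caller says so, then
  "out-of-frame", else "unknown". Caller frame annotations vary in
  quality; the final decision belongs to the frame filter, and the
  whitelist protects known out-of-frame drivers.

## Filter cascade: parameters and rationale

| knob | default | why |
| --- | --- | --- |
| min reads per call (split+spanning) | 3 | below ~3 supporting fragments a chimeric alignment is indistinguishable from ligation/mapping noise |
| Arriba accepted confidence | {high, medium} | Arriba's "low" tier is dominated by artifacts |
| deFuse minimum probability | 0.7 | conventional operating point of its classifier |
| read-through max gap | 1 Mb | conjoined transcripts arise between close same-strand neighbors; 1 Mb is deliberately permissive (whitelist rescues real deletions) |
| require splice site | on | both breakpoints must classify as splice-site or exonic (coding-exon containment); genomic rearrangements expressed as fusion transcripts splice at annotated boundaries |
| discard out-of-frame | on | out-of-frame products are rarely drivers, and whitelisted genes are exempt |
| promiscuity threshold | 2 partners | one gene fused to several partners in one sample is a mapping-artifact signature |

These defaults are this package's conventions for short-read leukemia
RNA-seq; every one is overridable per caller and per run via YAML.

The order is fixed (evidence → read-through → frame → splice →
blacklist → promiscuity): cheap per-call checks first, annotation-
dependent checks later. An event survives the evidence step if **any**
of its supporting calls passes — caller agreement should not be undone
by one caller's weak reporting. Whitelist rescue applies to the
structural steps only: a clinically relevant fusion is kept regardless
of its structural class, but read evidence is always required.
Promiscuity is computed per sample on the cascade's input events, not
on the survivors at that step, so that relaxing any threshold can never
shrink the retained set (a property the test suite asserts).

Events with an unannotated partner are passed through the structural
filters with an `unannotated_gene` warning rather than discarded: an
incomplete annotation must not silently delete candidates.

Intrachromosomal deletions such as STIL::TAL1 and P2RY8::CRLF2 are
geometrically indistinguishable from read-through transcription; the
cascade flags them, and the whitelist rescue is what keeps them. This
is intended behavior, not a loophole — it mirrors how a clinical
analyst treats known drivers.

## Benchmark conventions

- Matching is at (sample, canonical ordered gene pair) granularity;
  orientation-insensitive matching is available via a flag.
- Each truth entry counts once toward TP; additional calls matching the
  same entry are not false positives.
- Sensitivity and precision are printed as percentages to one decimal,
  F1 on 0–1 to two decimals, rounding half away from zero.
- A method that retains no calls at all gets precision 0.0 rather than
  an error, so the report row still shows its zero sensitivity.
- With several datasets, a pooled "global" row per method sums TP/FP/FN
  across datasets; its truth denominator is the sum of the per-dataset
  truth-set sizes (19 + 22 = 41 for the two bundled scenarios).

## The synthetic cohorts

The fixtures module replaces RNA-seq plus five external callers with
seeded synthetic cohorts.

**Annotation.** A deterministic toy annotation uses real chromosome
names and real leukemia gene symbols, 10 kb gene bodies with three
exons each (so splice-site coordinates are known), adjacent same-strand
pairs for read-through geometry (including MTAP/CDKN2B-AS1 and a
minus-strand pair to exercise orientation logic), blacklisted
repeat/pseudogene loci, and synthetic filler genes. Unrelated genes on
one chromosome sit 3 Mb apart so no accidental read-through geometry
arises.

**Cohorts.** A `CohortSpec` lists planted fusions: truth events and
artifacts from a taxonomy (read-through, out-of-frame, non-splice
breakpoint, blacklisted, low support, low confidence, promiscuous,
clean false positive). Each planted event is rendered into the native
dialect of each detecting caller, with breakpoints at annotated exon
boundaries (except the non-splice class), read support drawn from
class-specific ranges (true calls 8–40 split / 4–20 spanning, always
above the default thresholds; low-support artifacts 0–1/0–1, always
below), and caller-appropriate confidence labels. FusionCatcher emits
legacy symbols (MLL, TEL, AML1) to exercise alias resolution, and
STAR-Fusion emits `chr`-prefixed coordinates to exercise chromosome
normalization. Same seed ⇒ byte-identical trees.

**Scenarios.** Two canned cohorts encode fixed detection patterns as
deterministic flags rather than sampled probabilities, so end-to-end
metrics are exact by construction:

- *cell lines*: 14 samples, 19 truth fusions — 13 called by all five
  callers, one by four, two by three, and three (NKX2-5::BCL11B,
  TLX3::BCL11B, LMO1::TRD) by none; FusionCatcher reports all 16
  detected fusions. Planted artifacts bring the pre-filter consensus
  candidate counts to 28 (5/5), 49 (≥4/5) and 100 (≥3/5), of which 1,
  2 and 4 clean false positives survive the cascade.
- *patients*: 15 samples, 22 truth fusions — 12 at 5/5 agreement, 6 at
  exactly 4, 4 at exactly 3 (including STIL::TAL1 and P2RY8::CRLF2).
  Pre-filter consensus counts are 23/43/74; exactly one clean false
  positive (at 3/5) survives.

The scenarios pin the *consensus-level* detection pattern. The
per-caller curation that an individual pipeline's analyst would apply
is not modeled, so single-caller precision figures from these cohorts
are not meaningful — only single-caller sensitivity (which the tests
use for FusionCatcher) and all consensus-level metrics are.

**What passing these tests does and does not show.** The generator
produces structurally valid caller files with the planted detection
pattern; it does not simulate reads, expression levels, alignment
ambiguity, or caller-internal scoring. Passing therefore demonstrates
that the harmonization, consensus, filtering and scoring machinery is
correct and deterministic — not that any particular sensitivity will be
achieved on new biological samples.

## Numerical and degenerate-input choices

- All coordinates are 1-based inclusive as emitted by the callers; no
  conversion anywhere.
- Unparseable numeric fields are fail-fast format errors, never silent
  zeros; parse errors name file, row and column.
- Zero-denominator metrics raise (`sensitivity(0,0)` etc.), except the
  benchmark-table convenience above.
- Merging, filtering and reporting are pure functions of their inputs;
  randomness exists only in the fixture generator and is fully seeded.

## Known limitations

- Only gene-pair-level consensus: no breakpoint-level reconciliation,
  transcript-isoform resolution, or ITD handling.
- The five supported dialects track current public output formats of
  the tools; other versions may need column-name overrides.
- Whitelist/blacklist are flat symbol lists; no per-disease ontology.
- The k-of-5 denominator stays at five when a caller's file is missing
  (with a warning), since consensus semantics are defined against the
  full panel; use `--callers`-style re-runs with a different k if a
  caller is permanently absent.
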