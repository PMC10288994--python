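"""Gene annotation: a minimal per-gene model backed by a GTF file.

The structural filters need three things per gene: its genomic extent (for
read-through geometry and locus lookup), its strand, and the set of exon
boundary coordinates (splice sites).  A GTF is ingested once with gffutils
and held in memory; locus queries go through per-chromosome interval trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree

from .errors import ValidationError
from .model import normalize_chrom


@dataclass
class GeneModel:
    """One gene: extent, strand, biotype, and splice-site coordinates."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str = "protein_coding"
    exons: list = field(default_factory=list)  # list of (start, end), 1-based inclusive

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.symbol}: gene start > end")
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValidationError(f"{self.symbol}: exon ({s},{e}) outside gene body")

    @property
    def splice_sites(self) -> frozenset:
        """All exon boundary coordinates (both ends of every exon)."""
        return frozenset(c for s, e in self.exons for c in (s, e))


class GeneAnnotation:
    """In-memory gene annotation with symbol and locus lookup."""

    def __init__(self, genes) -> None:
        self.genes: dict = {}
        self._trees: dict = {}
        for g in genes:
            if g.symbol in self.genes:
                raise ValidationError(f"duplicate gene symbol {g.symbol!r} in annotation")
            self.genes[g.symbol] = g
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            tree[g.start : g.end + 1] = g.symbol

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    def gene(self, symbol: str):
        """The GeneModel for ``symbol``, or None if unannotated."""
        return self.genes.get(symbol)

    def genes_at(self, chrom: str, pos: int) -> list:
        """Genes whose body overlaps (chrom, pos), sorted by symbol."""
        tree = self._trees.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted(self.genes[iv.data] for iv in tree[pos])


def read_gtf(path) -> GeneAnnotation:
    """Ingest a GTF into a :class:`GeneAnnotation`.

    Gene extents come from ``gene`` features; splice sites from ``exon``
    features grouped by their ``gene_name`` (falling back to ``gene_id``)
    attribute.  Chromosome names are normalized (``chr`` prefix stripped).
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    exons_by_gene: dict = {}
    for exon in db.features_of_type("exon"):
        sym = _symbol_of(exon)
        exons_by_gene.setdefault(sym, []).append((exon.start, exon.end))
    genes = []
    for feat in db.features_of_type("gene"):
        sym = _symbol_of(feat)
        biotype = (feat.attributes.get("gene_biotype") or ["protein_coding"])[0]
        genes.append(
            GeneModel(
                symbol=sym,
                chrom=normalize_chrom(feat.seqid),
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "unknown",
                biotype=biotype,
                exons=sorted(exons_by_gene.get(sym, [])),
            )
        )
    return GeneAnnotation(genes)


def _symbol_of(feature) -> str:
    for key in ("gene_name", "gene_id"):
        vals = feature.attributes.get(key)
        if vals:
            return vals[0]
    raise ValidationError(f"GTF feature at {feature.seqid}:{feature.start} lacks gene_name/gene_id")


def write_gtf(genes, path) -> None:
    """Write gene + exon GTF lines for a list of GeneModel (UTF-8, Unix EOL)."""
    lines = []
    for g in genes:
        attrs = (
            f'gene_id "{g.symbol}"; gene_name "{g.symbol}"; gene_biotype "{g.biotype}";'
        )
        lines.append(
            f"{g.chrom}\tfusemble\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}"
        )
        for i, (s, e) in enumerate(g.exons, start=1):
            exon_attrs = attrs + f' transcript_id "{g.symbol}-T1"; exon_number "{i}";'
            lines.append(
                f"{g.chrom}\tfusemble\texon\t{s}\t{e}\t.\t{g.strand}\t.\t{exon_attrs}"
            )
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(lines) + "\n")
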