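"""Reference annotation: map genomic positions to gene/CDS context.

GFF3 and FASTA coordinates are 1-based inclusive; the spliced-CDS offsets
used internally are 0-based.  One transcript is used per gene (the longest
total CDS when several overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree


@dataclass(frozen=True)
class SiteAnnotation:
    """Annotation context of one genomic position."""

    location: str                     # intergenic | genic_noncoding | coding
    gene_id: str | None = None
    transcript_id: str | None = None
    strand: str | None = None
    codon: str | None = None          # reference codon on the coding strand
    codon_position: int | None = None  # 1..3 within the codon
    cds_offset: int | None = None      # 0-based offset in the (phase-trimmed) CDS


class _Transcript:
    __slots__ = ("tid", "gene_id", "strand", "segments", "phase0", "cds_seq")

    def __init__(self, tid: str, gene_id: str, strand: str,
                 segments: list[tuple[int, int, int]], contig_seq: str):
        # segments: (start, end, phase), 1-based inclusive, genomic order
        self.tid = tid
        self.gene_id = gene_id
        self.strand = strand
        self.segments = sorted(segments)
        spliced = "".join(contig_seq[s - 1:e] for s, e, _ in self.segments)
        if strand == "-":
            spliced = str(Seq(spliced).reverse_complement())
            first = max(self.segments, key=lambda seg: seg[1])
        else:
            first = min(self.segments)
        self.phase0 = first[2]
        self.cds_seq = spliced[self.phase0:]

    @property
    def cds_len(self) -> int:
        return len(self.cds_seq)

    def spliced_offset(self, pos: int) -> int | None:
        """0-based offset of a genomic position in the phase-trimmed CDS."""
        off = 0
        if self.strand == "+":
            for s, e, _ in self.segments:
                if s <= pos <= e:
                    return off + (pos - s) - self.phase0
                off += e - s + 1
        else:
            for s, e, _ in reversed(self.segments):
                if s <= pos <= e:
                    return off + (e - pos) - self.phase0
                off += e - s + 1
        return None


class Annotation:
    """Indexed gene/CDS annotation over a reference sequence."""

    def __init__(self, seqs: dict[str, str]):
        self.seqs = seqs
        self._genes: dict[str, IntervalTree] = {}
        self._cds: dict[str, IntervalTree] = {}
        self.transcripts: dict[str, _Transcript] = {}
        self.gene_strand: dict[str, str] = {}

    # -- construction ------------------------------------------------------

    def add_gene(self, gene_id: str, contig: str, start: int, end: int, strand: str) -> None:
        self._genes.setdefault(contig, IntervalTree())[start:end + 1] = gene_id
        self.gene_strand[gene_id] = strand

    def add_transcript(self, tr: _Transcript, contig: str) -> None:
        self.transcripts[tr.tid] = tr
        tree = self._cds.setdefault(contig, IntervalTree())
        for s, e, _ in tr.segments:
            tree[s:e + 1] = tr.tid

    # -- queries -----------------------------------------------------------

    def classify(self, contig: str, pos: int) -> SiteAnnotation:
        """Classify a 1-based position as intergenic / genic-noncoding / coding."""
        if contig not in self.seqs:
            raise KeyError(f"contig {contig!r} absent from reference FASTA")
        if not (1 <= pos <= len(self.seqs[contig])):
            raise IndexError(f"position {contig}:{pos} outside the reference sequence")
        cds_hits = sorted(self._cds.get(contig, IntervalTree())[pos],
                          key=lambda iv: self.transcripts[iv.data].cds_len,
                          reverse=True)
        for hit in cds_hits:
            tr = self.transcripts[hit.data]
            off = tr.spliced_offset(pos)
            if off is None or off < 0 or off >= 3 * (tr.cds_len // 3):
                continue  # in the phase-trimmed margin or an incomplete tail codon
            codon_idx = off // 3
            codon = tr.cds_seq[3 * codon_idx: 3 * codon_idx + 3]
            return SiteAnnotation(
                location="coding", gene_id=tr.gene_id, transcript_id=tr.tid,
                strand=tr.strand, codon=codon, codon_position=off % 3 + 1,
                cds_offset=off,
            )
        gene_hits = self._genes.get(contig, IntervalTree())[pos]
        if gene_hits:
            gene_id = sorted(iv.data for iv in gene_hits)[0]
            return SiteAnnotation(location="genic_noncoding", gene_id=gene_id,
                                  strand=self.gene_strand.get(gene_id))
        return SiteAnnotation(location="intergenic")

    def ref_base(self, contig: str, pos: int) -> str:
        return self.seqs[contig][pos - 1]


def load_annotation(gff_path: str, fasta_path: str) -> Annotation:
    """Build an :class:`Annotation` from GFF3 gene/mRNA/CDS features and a FASTA.

    Transcripts whose total CDS length is not a multiple of 3, or whose CDS
    extends beyond its contig, are kept but flagged with a warning.  When a
    gene carries several transcripts only the longest CDS is indexed.
    """
    import gffutils

    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    ann = Annotation(seqs)
    db = gffutils.create_db(str(gff_path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")

    for gene in db.features_of_type("gene"):
        if gene.seqid not in seqs:
            raise KeyError(f"GFF3 contig {gene.seqid!r} absent from FASTA")
        ann.add_gene(gene.id, gene.seqid, gene.start, gene.end, gene.strand)

    by_gene: dict[str, list[tuple[_Transcript, str]]] = {}
    for mrna in db.features_of_type("mRNA"):
        contig = mrna.seqid
        if contig not in seqs:
            raise KeyError(f"GFF3 contig {contig!r} absent from FASTA")
        segs = []
        for cds in db.children(mrna, featuretype="CDS"):
            phase = 0 if cds.frame in (None, ".") else int(cds.frame)
            segs.append((cds.start, cds.end, phase))
            if cds.end > len(seqs[contig]) or cds.start < 1:
                warnings.warn(f"CDS of {mrna.id} extends beyond contig {contig}")
        if not segs:
            continue
        gene_id = mrna.attributes.get("Parent", [mrna.id])[0]
        tr = _Transcript(mrna.id, gene_id, mrna.strand, segs, seqs[contig])
        if (sum(e - s + 1 for s, e, _ in segs) - tr.phase0) % 3 != 0:
            warnings.warn(f"CDS length of {mrna.id} is not a multiple of 3")
        by_gene.setdefault(gene_id, []).append((tr, contig))

    for gene_id, trs in by_gene.items():
        best, contig = max(trs, key=lambda t: t[0].cds_len)
        ann.add_transcript(best, contig)
    return ann
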