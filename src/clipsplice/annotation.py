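"""Genome annotation model and the unique non-overlapping intron set.

All internal coordinates are 0-based half-open; GTF input/output converts
at the boundary (GTF is 1-based closed), BED output is pass-through.

The central product is the per-gene *unique non-overlapping intron set*:
candidate introns are the gaps between consecutive exons of each
transcript; identical candidates across isoforms are emitted once; any
candidate overlapping an exon of any isoform of the same gene is dropped;
residual overlapping candidates are resolved deterministically in favour
of the lexicographically smallest transcript id.  Ordinal indices are
1-based and counted from the 5' end of the gene on its strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Gene",
    "Transcript",
    "GenomeAnnotation",
    "Intron",
    "IntronSet",
    "SpliceSites",
    "AnnotationError",
    "load_annotation",
    "write_gtf",
    "build_unique_intron_set",
    "splice_sites",
    "classify_intron_context",
]


class AnnotationError(ValueError):
    pass


@dataclass
class Transcript:
    id: str
    gene_id: str
    exons: list  # [(start, end)] 0-based half-open, sorted by genomic start
    cds: list = field(default_factory=list)  # [(start, end)], may be empty

    def introns(self) -> list:
        """Gaps between consecutive exons, genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]


@dataclass
class Gene:
    id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str  # "protein_coding" | "noncoding"
    transcripts: list = field(default_factory=list)

    def exon_union(self) -> list:
        """Merged exon intervals over all transcripts."""
        ivs = sorted(iv for t in self.transcripts for iv in t.exons)
        merged = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged


@dataclass
class GenomeAnnotation:
    genes: list
    contigs: dict  # name -> length (bp)

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def validate(self) -> None:
        for g in self.genes:
            if g.strand not in "+-":
                raise AnnotationError(f"{g.id}: bad strand {g.strand!r}")
            for t in g.transcripts:
                prev_end = None
                for s, e in t.exons:
                    if e <= s:
                        raise AnnotationError(f"{t.id}: exon end <= start ({s}, {e})")
                    if not (g.start <= s and e <= g.end):
                        raise AnnotationError(f"{t.id}: exon [{s},{e}) outside gene span")
                    if prev_end is not None and s < prev_end:
                        raise AnnotationError(f"{t.id}: overlapping exons")
                    prev_end = e


SpliceSites = tuple  # (donor, acceptor) genomic positions


@dataclass
class Intron:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    ordinal: int  # 1-based, from the 5' end of the gene
    host_biotype: str
    transcript_id: str = ""

    @property
    def name(self) -> str:
        return f"{self.gene_id}|{self.ordinal}"


@dataclass
class IntronSet:
    introns: list
    provenance: str = (
        "transcript gaps; identical candidates deduplicated; "
        "exon-overlapping candidates dropped; ties to smallest transcript id"
    )

    def __iter__(self):
        return iter(self.introns)

    def __len__(self):
        return len(self.introns)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": i.gene_id,
                    "chrom": i.chrom,
                    "strand": i.strand,
                    "start": i.start,
                    "end": i.end,
                    "intron_index": i.ordinal,
                    "host_biotype": i.host_biotype,
                }
                for i in self.introns
            ]
        )

    def write_bed(self, path) -> None:
        df = self.to_frame()
        bed = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": df["gene_id"] + "|" + df["intron_index"].astype(str),
                "score": 0,
                "strand": df["strand"],
            }
        )
        bed.to_csv(path, sep="\t", header=False, index=False)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF I/O


def _biotype_class(raw: str | None) -> str:
    return "protein_coding" if raw == "protein_coding" else "noncoding"


def _prevalidate_gtf(path) -> None:
    """Cheap line-level checks so parse errors carry a line number."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationError(f"line {lineno}: expected 9 tab-separated fields")
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise AnnotationError(f"line {lineno}: non-integer coordinates") from None
            if end < start:
                raise AnnotationError(f"line {lineno}: end < start ({start}, {end})")
            if fields[6] not in "+-":
                raise AnnotationError(f"line {lineno}: bad strand {fields[6]!r}")


def load_annotation(path, contigs: dict | None = None) -> GenomeAnnotation:
    """Load a GTF (gencode/ensembl dialect) into a :class:`GenomeAnnotation`.

    ``contigs`` maps contig names to lengths; when given, genes on absent
    contigs are skipped with a warning.  When omitted, contig lengths are
    taken as the maximum annotated end per contig.
    """
    _prevalidate_gtf(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes = []
    for grec in db.features_of_type("gene"):
        chrom = grec.seqid
        if contigs is not None and chrom not in contigs:
            logger.warning("gene %s on absent contig %s: skipped", grec.id, chrom)
            continue
        raw_bt = (grec.attributes.get("gene_biotype") or grec.attributes.get("gene_type") or [None])[0]
        gene = Gene(
            id=grec.id,
            chrom=chrom,
            strand=grec.strand,
            start=grec.start - 1,
            end=grec.end,
            biotype=_biotype_class(raw_bt),
        )
        for trec in db.children(grec, featuretype="transcript", order_by="start"):
            exons = sorted(
                (e.start - 1, e.end) for e in db.children(trec, featuretype="exon")
            )
            cds = sorted((c.start - 1, c.end) for c in db.children(trec, featuretype="CDS"))
            gene.transcripts.append(Transcript(id=trec.id, gene_id=gene.id, exons=exons, cds=cds))
        genes.append(gene)
    if contigs is None:
        contigs = {}
        for g in genes:
            contigs[g.chrom] = max(contigs.get(g.chrom, 0), g.end)
    ann = GenomeAnnotation(genes=genes, contigs=dict(contigs))
    ann.validate()
    return ann


def write_gtf(annotation: GenomeAnnotation, path) -> None:
    """Write gene/transcript/exon (and CDS) features, converting to 1-based closed."""
    with open(path, "w") as out:
        for g in annotation.genes:
            attrs = f'gene_id "{g.id}"; gene_biotype "{g.biotype}";'
            out.write(
                f"{g.chrom}\tclipsplice\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                tattrs = f'gene_id "{g.id}"; transcript_id "{t.id}"; gene_biotype "{g.biotype}";'
                out.write(
                    f"{g.chrom}\tclipsplice\ttranscript\t{t.exons[0][0] + 1}\t{t.exons[-1][1]}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in t.exons:
                    out.write(
                        f"{g.chrom}\tclipsplice\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n"
                    )
                for s, e in t.cds:
                    out.write(
                        f"{g.chrom}\tclipsplice\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t{tattrs}\n"
                    )


# ---------------------------------------------------------------------------
# Intron set construction


def _overlaps(a, b) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def build_unique_intron_set(annotation: GenomeAnnotation) -> IntronSet:
    """Per-gene unique, non-overlapping introns with strand-aware ordinals.

    Single-exon genes contribute no introns.  See module docstring for the
    redundancy rules.
    """
    out = []
    for gene in annotation.genes:
        candidates = {}  # (start, end) -> smallest transcript id
        for t in sorted(gene.transcripts, key=lambda t: t.id):
            for iv in t.introns():
                candidates.setdefault(iv, t.id)
        union = gene.exon_union()
        clean = [
            (iv, tid)
            for iv, tid in candidates.items()
            if not any(_overlaps(iv, ex) for ex in union)
        ]
        # residual overlaps between candidates: smallest transcript id wins
        kept = []
        for iv, tid in sorted(clean, key=lambda c: (c[1], c[0])):
            if not any(_overlaps(iv, kv) for kv, _ in kept):
                kept.append((iv, tid))
        kept.sort(key=lambda c: c[0])
        n = len(kept)
        for pos, (iv, tid) in enumerate(kept):
            ordinal = pos + 1 if gene.strand == "+" else n - pos
            out.append(
                Intron(
                    gene_id=gene.id,
                    chrom=gene.chrom,
                    strand=gene.strand,
                    start=iv[0],
                    end=iv[1],
                    ordinal=ordinal,
                    host_biotype=gene.biotype,
                    transcript_id=tid,
                )
            )
    return IntronSet(introns=out)


def splice_sites(intron: Intron) -> SpliceSites:
    """(donor, acceptor) genomic positions, strand-aware.

    The donor is the boundary adjacent to the upstream exon in transcript
    orientation; on the minus strand that is the genomic end.
    """
    if intron.strand == "+":
        return (intron.start, intron.end)
    return (intron.end, intron.start)


def classify_intron_context(intron_set: IntronSet, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Label each intron by its host gene's biotype class.

    Returns the intron table with a ``context`` column in
    {protein_coding_intron, noncoding_intron} plus per-class counts in
    ``df.attrs['class_counts']``.
    """
    biotypes = {g.id: g.biotype for g in annotation.genes}
    rows = intron_set.to_frame()
    missing = set(rows["gene_id"]) - set(biotypes)
    if missing:
        raise AnnotationError(f"introns with unknown host gene: {sorted(missing)[:5]}")
    rows["context"] = rows["gene_id"].map(
        lambda g: "protein_coding_intron" if biotypes[g] == "protein_coding" else "noncoding_intron"
    )
    rows.attrs["class_counts"] = rows["context"].value_counts().to_dict()
    return rows
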