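"""Genome annotation model, window tiling and gene-feature geometry.

All coordinates are internally 0-based half-open.  GFF3 input (1-based,
inclusive) is converted on ingest; BED input is passed through unchanged.
Derived gene features follow the conventions of plant epigenomics surveys:
the promoter is the 2 kb immediately upstream of the transcription start
site (strand-aware, truncated at chromosome edges), the gene body is the
annotated transcribed region, introns are the gene body minus exons, and
intergenic space is the complement of gene bodies and promoters, tiled
into 1 kb windows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: precedence used when a single context label must be reported for an
#: interval overlapping several features (highest first); gene_body is a
#: composite label and is never chosen as the single label.
CONTEXT_PRECEDENCE = (
    "promoter",
    "utr5",
    "exon",
    "intron",
    "utr3",
    "repeat",
    "intergenic",
)

_ORGANELLE_HINTS = ("chloroplast", "mitochond", "plastid")


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass
class GeneModel:
    """A single gene model (one splice variant).

    ``exons`` are non-overlapping, sorted (start, end) pairs within
    ``[tx_start, tx_end)``; UTRs, when annotated, likewise.
    """

    id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: tuple[int, int] | None = None
    utr3: tuple[int, int] | None = None
    splice_variant_index: int = 0

    def validate(self, chrom_length: int | None = None) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.id}: strand must be + or -")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"gene {self.id}: tx_start >= tx_end")
        if self.tx_start < 0:
            raise ValueError(f"gene {self.id}: negative tx_start")
        if chrom_length is not None and self.tx_end > chrom_length:
            raise ValueError(
                f"gene {self.id}: interval [{self.tx_start},{self.tx_end}) "
                f"exceeds {self.chrom} length {chrom_length}"
            )
        prev_end = None
        for s, e in sorted(self.exons):
            if prev_end is not None and s < prev_end:
                raise ValueError(f"gene {self.id}: overlapping exons")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"gene {self.id}: exon outside gene body")
            prev_end = e
        for name, utr in (("utr5", self.utr5), ("utr3", self.utr3)):
            if utr is not None and (utr[0] < self.tx_start or utr[1] > self.tx_end):
                raise ValueError(f"gene {self.id}: {name} outside gene body")
        self.exons = sorted(self.exons)

    @property
    def body(self) -> tuple[int, int]:
        return (self.tx_start, self.tx_end)

    def introns(self) -> list[tuple[int, int]]:
        """Gene body minus exons (empty when the gene has no exons)."""
        if not self.exons:
            return []
        out = []
        prev = self.exons[0][1]
        for s, e in self.exons[1:]:
            if s > prev:
                out.append((prev, s))
            prev = max(prev, e)
        return out


@dataclass
class RepeatElement:
    chrom: str
    start: int
    end: int
    class_label: str

    def validate(self, chrom_length: int | None = None) -> None:
        if not self.start < self.end:
            raise ValueError(f"repeat {self.chrom}:{self.start}-{self.end}: empty")
        if not self.class_label:
            raise ValueError("repeat with empty class label")
        if chrom_length is not None and self.end > chrom_length:
            raise ValueError(
                f"repeat {self.chrom}:{self.start}-{self.end} exceeds "
                f"chromosome length {chrom_length}"
            )


@dataclass
class GenomeAnnotation:
    """Chromosomes, gene models and repeats of one genome assembly."""

    chrom_lengths: dict[str, int]
    genes: list[GeneModel] = field(default_factory=list)
    repeats: list[RepeatElement] = field(default_factory=list)
    organelle_names: set[str] = field(default_factory=set)
    sequences: dict[str, str] | None = None

    def nuclear_chroms(self) -> dict[str, int]:
        return {
            c: n for c, n in self.chrom_lengths.items()
            if c not in self.organelle_names
        }

    def validate(self) -> None:
        for g in self.genes:
            if g.chrom not in self.chrom_lengths:
                raise ValueError(f"gene {g.id}: unknown chromosome {g.chrom}")
            g.validate(self.chrom_lengths[g.chrom])
        for r in self.repeats:
            if r.chrom not in self.chrom_lengths:
                raise ValueError(f"repeat on unknown chromosome {r.chrom}")
            r.validate(self.chrom_lengths[r.chrom])


@dataclass
class FeatureCatalog:
    """Derived gene-associated features plus intergenic windows.

    ``per_gene`` maps gene id -> dict with keys promoter, utr5, utr3,
    exons, introns, gene_body (intervals or interval lists, or None).
    """

    per_gene: dict[str, dict]
    intergenic: list[GenomicInterval]
    chrom_lengths: dict[str, int]
    _trees: dict[str, dict[str, IntervalTree]] = field(default_factory=dict, repr=False)

    def label_tree(self, chrom: str, label: str) -> IntervalTree:
        return self._trees.get(chrom, {}).get(label, IntervalTree())


def detect_organelles(names) -> set[str]:
    """Flag sequence names that look like organelle genomes."""
    return {
        n for n in names
        if any(h in n.lower() for h in _ORGANELLE_HINTS)
    }


# ---------------------------------------------------------------------------
# ingest

def _first_variant_models(db) -> list[GeneModel]:
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if gene.strand not in {"+", "-"}:
            warnings.warn(f"gene {gene.id}: missing strand, record rejected")
            continue
        if mrnas:
            # only the first splice variant represents the gene
            mrna = mrnas[0]
            exons = [
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="exon", order_by="start")
            ]
            utr5s = [
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="five_prime_UTR", order_by="start")
            ]
            utr3s = [
                (f.start - 1, f.end)
                for f in db.children(mrna, featuretype="three_prime_UTR", order_by="start")
            ]
        else:
            exons, utr5s, utr3s = [], [], []
        model = GeneModel(
            id=gene.id,
            chrom=gene.seqid,
            strand=gene.strand,
            tx_start=gene.start - 1,
            tx_end=gene.end,
            exons=exons,
            utr5=(utr5s[0][0], utr5s[-1][1]) if utr5s else None,
            utr3=(utr3s[0][0], utr3s[-1][1]) if utr3s else None,
            splice_variant_index=0,
        )
        genes.append(model)
    return genes


def load_annotation(
    genome_fasta_path,
    gff3_path,
    repeat_bed_path=None,
    organelle_names: set[str] | None = None,
    keep_sequences: bool = True,
) -> GenomeAnnotation:
    """Load genome FASTA + GFF3 gene models (+ optional repeat BED).

    GFF3 coordinates (1-based inclusive) are converted to 0-based
    half-open.  When several mRNAs are annotated for a gene, only the
    first is used.  Records violating chromosome bounds raise; records
    without a strand are rejected with a warning.
    """
    import gffutils

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(genome_fasta_path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    chrom_lengths = {name: len(s) for name, s in seqs.items()}
    if organelle_names is None:
        organelle_names = detect_organelles(chrom_lengths)

    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", keep_order=True,
        merge_strategy="create_unique",
    )
    genes = _first_variant_models(db)

    repeats: list[RepeatElement] = []
    if repeat_bed_path is not None:
        with open(repeat_bed_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                repeats.append(
                    RepeatElement(f[0], int(f[1]), int(f[2]),
                                  f[3] if len(f) > 3 else "repeat")
                )

    ann = GenomeAnnotation(
        chrom_lengths=chrom_lengths,
        genes=genes,
        repeats=repeats,
        organelle_names=organelle_names,
        sequences=seqs if keep_sequences else None,
    )
    ann.validate()
    return ann


# ---------------------------------------------------------------------------
# tiling

def tile_windows(annotation: GenomeAnnotation, window_size: int = 1000,
                 nuclear_only: bool = True) -> list[GenomicInterval]:
    """Tile every chromosome end-to-end with fixed-size windows.

    The final window of each chromosome may be shorter; its true width is
    used downstream (e.g. as the RPKM length term).
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    lengths = annotation.nuclear_chroms() if nuclear_only else annotation.chrom_lengths
    out: list[GenomicInterval] = []
    for chrom, length in lengths.items():
        for start in range(0, length, window_size):
            out.append(GenomicInterval(chrom, start, min(start + window_size, length)))
    return out


class WindowGrid:
    """Fast placement -> window-index arithmetic for a uniform tiling."""

    def __init__(self, chrom_lengths: dict[str, int], size: int = 1000):
        self.size = size
        self.chrom_lengths = dict(chrom_lengths)
        self.offsets: dict[str, int] = {}
        self.intervals: list[GenomicInterval] = []
        off = 0
        for chrom, length in self.chrom_lengths.items():
            self.offsets[chrom] = off
            n = -(-length // size)
            for start in range(0, length, size):
                self.intervals.append(
                    GenomicInterval(chrom, start, min(start + size, length)))
            off += n
        self.n = off

    def locate(self, chrom: str, pos: int) -> int:
        if chrom not in self.offsets:
            raise KeyError(f"unknown chromosome {chrom}")
        if not 0 <= pos < self.chrom_lengths[chrom]:
            raise ValueError(f"position {pos} beyond {chrom}")
        return self.offsets[chrom] + pos // self.size

    def widths(self):
        import numpy as np
        return np.array([iv.width for iv in self.intervals])


# ---------------------------------------------------------------------------
# feature derivation

def promoter_interval(gene: GeneModel, chrom_length: int,
                      promoter_len: int = 2000) -> tuple[int, int] | None:
    """Strand-aware promoter upstream of the TSS, truncated at edges."""
    if gene.strand == "+":
        s, e = max(0, gene.tx_start - promoter_len), gene.tx_start
    else:
        s, e = gene.tx_end, min(chrom_length, gene.tx_end + promoter_len)
    return (s, e) if s < e else None


def _complement(segments: list[tuple[int, int]], length: int) -> list[tuple[int, int]]:
    """Gaps of [0, length) not covered by the (possibly overlapping) segments."""
    out = []
    pos = 0
    for s, e in sorted(segments):
        if s > pos:
            out.append((pos, s))
        pos = max(pos, e)
    if pos < length:
        out.append((pos, length))
    return out


def derive_features(annotation: GenomeAnnotation, promoter_len: int = 2000,
                    intergenic_window: int = 1000) -> FeatureCatalog:
    """Derive promoters, UTRs, introns, gene bodies and intergenic windows."""
    per_gene: dict[str, dict] = {}
    occupied: dict[str, list[tuple[int, int]]] = {
        c: [] for c in annotation.nuclear_chroms()
    }
    trees: dict[str, dict[str, IntervalTree]] = {}

    def add(chrom: str, label: str, s: int, e: int, payload=None):
        if s >= e:
            return
        trees.setdefault(chrom, {}).setdefault(label, IntervalTree()).addi(s, e, payload)

    for gene in annotation.genes:
        clen = annotation.chrom_lengths[gene.chrom]
        prom = promoter_interval(gene, clen, promoter_len)
        introns = gene.introns()
        per_gene[gene.id] = {
            "chrom": gene.chrom,
            "strand": gene.strand,
            "promoter": prom,
            "utr5": gene.utr5,
            "utr3": gene.utr3,
            "exons": list(gene.exons),
            "introns": introns,
            "gene_body": gene.body,
        }
        if gene.chrom in occupied:
            occupied[gene.chrom].append(gene.body)
            if prom:
                occupied[gene.chrom].append(prom)
        if prom:
            add(gene.chrom, "promoter", *prom, gene.id)
        if gene.utr5:
            add(gene.chrom, "utr5", *gene.utr5, gene.id)
        if gene.utr3:
            add(gene.chrom, "utr3", *gene.utr3, gene.id)
        for s, e in gene.exons:
            add(gene.chrom, "exon", s, e, gene.id)
        for s, e in introns:
            add(gene.chrom, "intron", s, e, gene.id)
        add(gene.chrom, "gene_body", *gene.body, gene.id)

    for rep in annotation.repeats:
        add(rep.chrom, "repeat", rep.start, rep.end, rep.class_label)

    intergenic: list[GenomicInterval] = []
    for chrom, length in annotation.nuclear_chroms().items():
        for gap_s, gap_e in _complement(occupied.get(chrom, []), length):
            for s in range(gap_s, gap_e, intergenic_window):
                e = min(s + intergenic_window, gap_e)
                intergenic.append(GenomicInterval(chrom, s, e))
                add(chrom, "intergenic", s, e)

    return FeatureCatalog(
        per_gene=per_gene,
        intergenic=intergenic,
        chrom_lengths=dict(annotation.chrom_lengths),
        _trees=trees,
    )


def assign_context(interval: GenomicInterval, catalog: FeatureCatalog) -> dict[str, int]:
    """All feature labels overlapping ``interval`` with overlap lengths (bp)."""
    if interval.chrom not in catalog.chrom_lengths:
        raise KeyError(f"unknown chromosome {interval.chrom}")
    out: dict[str, int] = {}
    labels = CONTEXT_PRECEDENCE + ("gene_body",)
    for label in labels:
        tree = catalog.label_tree(interval.chrom, label)
        ov = 0
        for hit in tree.overlap(interval.start, interval.end):
            ov += min(hit.end, interval.end) - max(hit.begin, interval.start)
        if ov > 0:
            out[label] = ov
    if not out:
        out["intergenic"] = interval.width
    return out


def primary_context(interval: GenomicInterval, catalog: FeatureCatalog) -> str:
    """Single label by maximal overlap, ties broken by precedence."""
    overlaps = assign_context(interval, catalog)
    overlaps.pop("gene_body", None)
    rank = {lab: i for i, lab in enumerate(CONTEXT_PRECEDENCE)}
    return min(overlaps.items(), key=lambda kv: (-kv[1], rank.get(kv[0], 99)))[0]
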