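"""Read trimming, clonal deduplication, exact 32-mer alignment and the
unique / distributed-repeat split.

The aligner requires perfect matches: every chromosome is indexed as
2-bit-packed 64-bit integers, one per 32-mer start (a 32-mer fits a
uint64 exactly), and reads are looked up on both strands against the
sorted index.  Reads containing N cannot perfect-match and are counted
as unmapped.  Multi-mapping ("k-mer repeat") reads are equally divided
among all their placements, allowing decimal weights; uniquely aligning
reads are excluded from that distributed branch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)

READ_LEN = 32

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    id: str
    sequence: str


@dataclass
class AlignmentRecord:
    """All perfect-match placements of one read; strand is '+' or '-'."""

    read_id: str
    placements: list[tuple[str, int, str]]

    @property
    def n_placements(self) -> int:
        return len(self.placements)


@dataclass
class CoverageTrack:
    """Per-bp depth: integer unique track, fractional distributed track."""

    unique: dict[str, np.ndarray] = field(default_factory=dict)
    distributed: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# trimming and clonal removal

def trim_reads(reads: list[Read], target_len: int = READ_LEN) -> tuple[list[Read], int]:
    """Truncate every read to its first ``target_len`` bases.

    Reads shorter than ``target_len`` are dropped; the dropped count is
    returned alongside.
    """
    out, dropped = [], 0
    for r in reads:
        if len(r.sequence) < target_len:
            dropped += 1
            continue
        out.append(Read(r.id, r.sequence[:target_len].upper()))
    if dropped:
        log.info("trim_reads: dropped %d reads shorter than %d nt", dropped, target_len)
    return out, dropped


def deduplicate_clonal(reads: list[Read]) -> tuple[list[Read], int]:
    """Keep one read per distinct sequence (first occurrence wins)."""
    seen: set[str] = set()
    out = []
    for r in reads:
        if r.sequence in seen:
            continue
        seen.add(r.sequence)
        out.append(r)
    return out, len(reads) - len(out)


# ---------------------------------------------------------------------------
# exact alignment

def _encode_kmers(seq: str, k: int = READ_LEN) -> tuple[np.ndarray, np.ndarray]:
    """(kmers, valid) for every start position of ``seq``; invalid = has N."""
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, np.uint64), np.empty(0, bool)
    bad = (codes == 255).astype(np.int32)
    bad_in_window = np.convolve(bad, np.ones(k, dtype=np.int32), mode="valid") > 0
    safe = np.where(codes == 255, 0, codes).astype(np.uint64)
    kmers = np.zeros(n, dtype=np.uint64)
    for j in range(k):
        kmers = (kmers << np.uint64(2)) | safe[j:j + n]
    return kmers, ~bad_in_window


class KmerIndex:
    """Sorted 32-mer index over a set of sequences (forward strand)."""

    def __init__(self, sequences: dict[str, str], k: int = READ_LEN):
        self.k = k
        self.chroms = list(sequences)
        kmer_parts, chrom_parts, pos_parts = [], [], []
        for ci, (name, seq) in enumerate(sequences.items()):
            kmers, valid = _encode_kmers(seq, k)
            idx = np.nonzero(valid)[0]
            kmer_parts.append(kmers[idx])
            chrom_parts.append(np.full(idx.size, ci, dtype=np.int32))
            pos_parts.append(idx.astype(np.int64))
        kmers = np.concatenate(kmer_parts) if kmer_parts else np.empty(0, np.uint64)
        order = np.argsort(kmers, kind="stable")
        self._kmers = kmers[order]
        self._chrom = np.concatenate(chrom_parts)[order] if chrom_parts else np.empty(0, np.int32)
        self._pos = np.concatenate(pos_parts)[order] if pos_parts else np.empty(0, np.int64)

    def lookup(self, kmer: int) -> list[tuple[str, int]]:
        lo = np.searchsorted(self._kmers, np.uint64(kmer), side="left")
        hi = np.searchsorted(self._kmers, np.uint64(kmer), side="right")
        return [
            (self.chroms[self._chrom[i]], int(self._pos[i]))
            for i in range(lo, hi)
        ]

    def lookup_many(self, kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorised range lookup: (lo, hi) index bounds per query."""
        lo = np.searchsorted(self._kmers, kmers, side="left")
        hi = np.searchsorted(self._kmers, kmers, side="right")
        return lo, hi

    def placements_between(self, lo: int, hi: int) -> list[tuple[str, int]]:
        return [(self.chroms[self._chrom[i]], int(self._pos[i])) for i in range(lo, hi)]


def _encode_read(seq: str, k: int) -> int | None:
    if len(seq) != k:
        return None
    codes = _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes == 255).any():
        return None
    v = 0
    for c in codes:
        v = (v << 2) | int(c)
    return v


def align_exact(reads: list[Read], genome: dict[str, str] | KmerIndex,
                ) -> tuple[list[AlignmentRecord], int]:
    """Perfect-match alignment of equal-length reads against a genome.

    Returns one record per read with >= 1 placement (both strands
    searched; a '-' placement at position p covers [p, p+k) like its
    reverse complement on '+'), plus the unmapped tally.  Reads
    containing N are unmapped by construction.
    """
    index = genome if isinstance(genome, KmerIndex) else KmerIndex(genome)
    k = index.k
    fwd = np.empty(len(reads), dtype=np.uint64)
    rev = np.empty(len(reads), dtype=np.uint64)
    ok = np.zeros(len(reads), dtype=bool)
    for i, r in enumerate(reads):
        f = _encode_read(r.sequence, k)
        if f is None:
            continue
        b = _encode_read(revcomp(r.sequence), k)
        fwd[i], rev[i], ok[i] = f, b, True

    records: list[AlignmentRecord] = []
    unmapped = 0
    if ok.any():
        flo, fhi = index.lookup_many(fwd)
        rlo, rhi = index.lookup_many(rev)
    for i, r in enumerate(reads):
        if not ok[i]:
            unmapped += 1
            continue
        placements = [(c, p, "+") for c, p in index.placements_between(flo[i], fhi[i])]
        placements += [(c, p, "-") for c, p in index.placements_between(rlo[i], rhi[i])]
        if placements:
            records.append(AlignmentRecord(r.id, placements))
        else:
            unmapped += 1
    return records, unmapped


def filter_organelle(records: list[AlignmentRecord], organelle_names: set[str],
                     ) -> tuple[list[AlignmentRecord], int]:
    """Drop reads whose perfect matches are all organellar.

    Reads that also perfect-match the nuclear genome are kept, with the
    organelle placements stripped.  With no organelle names this is the
    identity.
    """
    if not organelle_names:
        return list(records), 0
    kept, removed = [], 0
    for rec in records:
        nuclear = [p for p in rec.placements if p[0] not in organelle_names]
        if nuclear:
            kept.append(AlignmentRecord(rec.read_id, nuclear))
        else:
            removed += 1
    if removed:
        log.info("filter_organelle: removed %d organelle-only reads", removed)
    return kept, removed


def split_unique_multi(records: list[AlignmentRecord],
                       ) -> tuple[list[AlignmentRecord], list[AlignmentRecord]]:
    """Partition records into uniquely aligning vs multi-mapping."""
    unique = [r for r in records if r.n_placements == 1]
    multi = [r for r in records if r.n_placements > 1]
    return unique, multi


# ---------------------------------------------------------------------------
# distributed repeats and coverage

def distribute_repeats(multi_records: list[AlignmentRecord], grid) -> np.ndarray:
    """Fractional per-window counts from equally divided multi-mappers.

    Each read contributes 1/n_placements at every placement start; total
    mass equals the number of multi reads exactly.  Placements on
    chromosomes outside the grid (e.g. organelles) are skipped.
    """
    counts = np.zeros(grid.n, dtype=np.float64)
    for rec in multi_records:
        w = 1.0 / rec.n_placements
        for chrom, pos, _strand in rec.placements:
            if chrom in grid.offsets:
                counts[grid.locate(chrom, pos)] += w
    return counts


def build_coverage(unique_records, multi_records, chrom_lengths: dict[str, int],
                   read_len: int = READ_LEN) -> CoverageTrack:
    """Per-bp depth tracks for the unique and distributed branches."""
    track = CoverageTrack(
        unique={c: np.zeros(n, dtype=np.float64) for c, n in chrom_lengths.items()},
        distributed={c: np.zeros(n, dtype=np.float64) for c, n in chrom_lengths.items()},
    )

    def paint(arrs, records, weighted):
        for rec in records:
            w = 1.0 / rec.n_placements if weighted else 1.0
            for chrom, pos, _ in rec.placements:
                if chrom in arrs:
                    arr = arrs[chrom]
                    arr[pos:min(pos + read_len, arr.size)] += w

    paint(track.unique, unique_records, weighted=False)
    paint(track.distributed, multi_records, weighted=True)
    return track


def coverage_summary(track: CoverageTrack) -> dict[str, dict[str, float]]:
    """Breadth (% bp covered > 0) and mean depth over covered bp, per branch."""
    out = {}
    for name in ("unique", "distributed"):
        arrs = getattr(track, name)
        total = sum(a.size for a in arrs.values())
        covered = sum(int((a > 0).sum()) for a in arrs.values())
        mass = sum(float(a.sum()) for a in arrs.values())
        out[name] = {
            "breadth_pct": 100.0 * covered / total if total else 0.0,
            "mean_depth_covered": mass / covered if covered else 0.0,
        }
    return out


# ---------------------------------------------------------------------------
# I/O

def read_fastq(path) -> list[Read]:
    from Bio import SeqIO
    return [Read(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def records_from_sam(path) -> tuple[list[AlignmentRecord], int]:
    """Ingest precomputed alignments from SAM (QNAME/RNAME/POS/FLAG only).

    Reads with several hits enter the multi branch downstream; unmapped
    records contribute to the unmapped tally.
    """
    import pysam

    by_read: dict[str, list[tuple[str, int, str]]] = {}
    unmapped_ids: set[str] = set()
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                unmapped_ids.add(aln.query_name)
                continue
            strand = "-" if aln.is_reverse else "+"
            by_read.setdefault(aln.query_name, []).append(
                (aln.reference_name, aln.reference_start, strand))
    records = [AlignmentRecord(q, sorted(set(p))) for q, p in sorted(by_read.items())]
    n_unmapped = len(unmapped_ids - set(by_read))
    return records, n_unmapped


def write_bedgraph(arrs: dict[str, np.ndarray], path) -> None:
    """Run-length-compressed bedGraph of a per-bp track."""
    with open(path, "w") as fh:
        for chrom, arr in arrs.items():
            if arr.size == 0:
                continue
            change = np.nonzero(np.diff(arr))[0] + 1
            bounds = np.concatenate(([0], change, [arr.size]))
            for s, e in zip(bounds[:-1], bounds[1:]):
                v = arr[s]
                if v != 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
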