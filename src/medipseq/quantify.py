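"""Windowed and feature-level RPKM quantification and the metagene profile.

RPKM = count / (length/1000) / (total_mapped/1e6), applied to 1 kb
windows tiled across the genome and to gene-associated features
(promoter, UTRs, exons, introns, gene body, intergenic) scored with
their own widths.  Counts may be fractional in the distributed-repeat
branch.  Replicates within a tissue are pooled by summing counts and
totals before the RPKM is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import FeatureCatalog, GenomeAnnotation, WindowGrid


def rpkm(count, length_bp, total_mapped):
    """Reads per kilobase of target per million mapped reads."""
    length_bp = np.asarray(length_bp, dtype=float)
    total = float(total_mapped)
    if np.any(length_bp <= 0):
        raise ValueError("length_bp must be positive")
    if total <= 0:
        raise ValueError("empty sample: total_mapped must be positive")
    return np.asarray(count, dtype=float) / (length_bp / 1000.0) / (total / 1e6)


def percent_mapped(total_reads: int, mapped_reads: int) -> float:
    """Percent of reads mapped, to one decimal (sequencing summary style)."""
    if total_reads == 0:
        raise ValueError("total_reads is zero")
    if not total_reads >= mapped_reads >= 0:
        raise ValueError("need total_reads >= mapped_reads >= 0")
    return round(100.0 * mapped_reads / total_reads, 1)


def count_into_windows(placements, grid: WindowGrid, weights=None) -> np.ndarray:
    """Per-window counts of placement start positions.

    ``placements`` is an iterable of (chrom, pos); optional per-placement
    weights give fractional (distributed-repeat) counts.  A start on a
    window boundary belongs to the window beginning there (half-open
    convention).
    """
    counts = np.zeros(grid.n, dtype=np.float64)
    if weights is None:
        for chrom, pos in placements:
            counts[grid.locate(chrom, pos)] += 1.0
    else:
        for (chrom, pos), w in zip(placements, weights):
            counts[grid.locate(chrom, pos)] += w
    return counts


@dataclass
class WindowTable:
    """1-kb quantification surface: windows x samples counts + metadata."""

    grid: WindowGrid
    counts: pd.DataFrame = None  # windows x samples
    samples: pd.DataFrame = None  # sample, tissue, replicate, is_input, total_mapped

    def __post_init__(self):
        index = pd.RangeIndex(self.grid.n, name="window")
        if self.counts is None:
            self.counts = pd.DataFrame(index=index)
        if self.samples is None:
            self.samples = pd.DataFrame(
                columns=["tissue", "replicate", "is_input", "total_mapped"])

    def add_sample(self, name: str, counts: np.ndarray, total_mapped: float,
                   tissue: str, replicate: int = 1, is_input: bool = False) -> None:
        if len(counts) != self.grid.n:
            raise ValueError("count vector does not match window universe")
        self.counts[name] = counts
        self.samples.loc[name] = [tissue, replicate, bool(is_input), float(total_mapped)]

    def windows_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [iv.chrom for iv in self.grid.intervals],
                "start": [iv.start for iv in self.grid.intervals],
                "end": [iv.end for iv in self.grid.intervals],
            },
            index=pd.RangeIndex(self.grid.n, name="window"),
        )

    def rpkm(self, sample: str) -> np.ndarray:
        total = self.samples.loc[sample, "total_mapped"]
        return rpkm(self.counts[sample].to_numpy(), self.grid.widths(), total)

    def pooled(self, tissue: str, is_input: bool = False) -> tuple[np.ndarray, float]:
        """Pool replicates of a tissue: summed counts, summed totals."""
        sel = self.samples[(self.samples.tissue == tissue)
                           & (self.samples.is_input == is_input)]
        if sel.empty:
            raise KeyError(f"no samples for tissue {tissue!r} (is_input={is_input})")
        counts = self.counts[sel.index.tolist()].sum(axis=1).to_numpy()
        return counts, float(sel.total_mapped.sum())

    def pooled_rpkm(self, tissue: str, is_input: bool = False) -> np.ndarray:
        counts, total = self.pooled(tissue, is_input)
        return rpkm(counts, self.grid.widths(), total)

    def pooled_inputs(self) -> tuple[np.ndarray, float]:
        """All input lanes pooled: summed counts, summed totals."""
        sel = self.samples[self.samples.is_input]
        if sel.empty:
            raise KeyError("no input samples")
        counts = self.counts[sel.index.tolist()].sum(axis=1).to_numpy()
        return counts, float(sel.total_mapped.sum())

    def input_rpkm_matrix(self) -> np.ndarray:
        """Per-lane RPKM of every input sample, stacked (lanes x windows)."""
        lanes = self.samples[self.samples.is_input].index.tolist()
        if len(lanes) < 2:
            raise ValueError("need >= 2 input samples")
        return np.vstack([self.rpkm(s) for s in lanes])

    def to_tsv(self, path) -> None:
        df = self.windows_frame().join(self.counts)
        df.to_csv(path, sep="\t", float_format="%.6g")


# ---------------------------------------------------------------------------
# feature-level quantification

FEATURE_TYPES = ("promoter", "utr5", "exon", "intron", "utr3", "gene_body")


def feature_counts(placements, catalog: FeatureCatalog, weights=None) -> pd.DataFrame:
    """Counts of placement starts per gene feature.

    Returns a frame indexed by gene id with one column per feature type
    plus the feature widths (``<type>_width``).  A placement whose start
    lies in several features (e.g. exon and gene_body) counts in each.
    """
    per_chrom_trees: dict[str, dict] = {}
    rows: dict[str, dict[str, float]] = {}
    widths: dict[str, dict[str, int]] = {}
    for gid, feats in catalog.per_gene.items():
        rows[gid] = {t: 0.0 for t in FEATURE_TYPES}
        w = {}
        w["promoter"] = (feats["promoter"][1] - feats["promoter"][0]) if feats["promoter"] else 0
        w["utr5"] = (feats["utr5"][1] - feats["utr5"][0]) if feats["utr5"] else 0
        w["utr3"] = (feats["utr3"][1] - feats["utr3"][0]) if feats["utr3"] else 0
        w["exon"] = sum(e - s for s, e in feats["exons"])
        w["intron"] = sum(e - s for s, e in feats["introns"])
        w["gene_body"] = feats["gene_body"][1] - feats["gene_body"][0]
        widths[gid] = w

    from intervaltree import IntervalTree

    for label in FEATURE_TYPES:
        for gid, feats in catalog.per_gene.items():
            chrom = feats["chrom"]
            tree = per_chrom_trees.setdefault(chrom, {}).setdefault(label, IntervalTree())
            if label in ("exon", "intron"):
                ivs = feats["exons"] if label == "exon" else feats["introns"]
                for s, e in ivs:
                    tree.addi(s, e, gid)
            else:
                iv = feats["gene_body"] if label == "gene_body" else feats[label]
                if iv:
                    tree.addi(iv[0], iv[1], gid)

    if weights is None:
        weights = np.ones(len(placements) if hasattr(placements, "__len__") else 0)
        it = ((p, 1.0) for p in placements)
    else:
        it = zip(placements, weights)
    for (chrom, pos), w in it:
        trees = per_chrom_trees.get(chrom)
        if not trees:
            continue
        for label, tree in trees.items():
            for hit in tree.at(pos):
                rows[hit.data][label] += w

    df = pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")
    for t in FEATURE_TYPES:
        df[f"{t}_width"] = [widths[g][t] for g in df.index]
    return df


def feature_rpkm(counts_frames: list[pd.DataFrame], totals: list[float],
                 ) -> pd.DataFrame:
    """Per-feature RPKM with replicates pooled (counts and totals summed).

    Zero-width features yield NaN (skipped downstream).
    """
    if len(counts_frames) != len(totals):
        raise ValueError("one total per counts frame required")
    pooled = counts_frames[0].copy()
    for f in counts_frames[1:]:
        for t in FEATURE_TYPES:
            pooled[t] = pooled[t] + f[t]
    total = float(sum(totals))
    out = pd.DataFrame(index=pooled.index)
    for t in FEATURE_TYPES:
        width = pooled[f"{t}_width"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            v = pooled[t].to_numpy(dtype=float) / (width / 1000.0) / (total / 1e6)
        out[t] = np.where(width > 0, v, np.nan)
        out[f"{t}_width"] = width
    return out


# ---------------------------------------------------------------------------
# metagene profile

@dataclass
class MetageneProfile:
    """Mean RPKM over 100 bp bins of an idealized gene model."""

    bins: pd.DataFrame  # segment, bin, mean_rpkm, n_genes
    segments: dict[str, int] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.bins.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _segment_windows(start: int, end: int, bin_bp: int) -> list[tuple[int, int]]:
    return [(s, min(s + bin_bp, end)) for s in range(start, end, bin_bp)]


def _interp_to_bins(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Linearly rescale a variable-length profile to ``n_bins`` values."""
    if values.size == 0:
        return np.full(n_bins, np.nan)
    if values.size == 1:
        return np.full(n_bins, values[0])
    x_old = np.linspace(0.0, 1.0, values.size)
    x_new = np.linspace(0.0, 1.0, n_bins)
    return np.interp(x_new, x_old, values)


def metagene_profile(placements, total_mapped: float, annotation: GenomeAnnotation,
                     flank: int = 2000, bin_bp: int = 100,
                     weights=None) -> MetageneProfile:
    """Average RPKM across genes over an idealized gene model.

    Only genes with both UTRs annotated contribute.  Segments: ``flank``
    bp upstream of the 5' UTR, the 5' UTR, the transcribed interior
    (between the UTRs), the 3' UTR, and ``flank`` bp downstream, each
    tiled with ``bin_bp`` windows.  Variable-width segments are rescaled
    by linear interpolation to a fixed bin count equal to
    round(mean segment length / bin_bp).  Flank bins overlapping another
    gene model are excluded from that gene's contribution; genes are
    oriented 5'->3'.
    """
    genes = [g for g in annotation.genes if g.utr5 and g.utr3]
    if not genes:
        raise ValueError("no genes with annotated UTRs")

    # per-chromosome sorted placement starts for fast window counting
    starts: dict[str, np.ndarray] = {}
    wts: dict[str, np.ndarray] = {}
    pl = list(placements)
    wt = np.ones(len(pl)) if weights is None else np.asarray(weights, dtype=float)
    by_chrom: dict[str, list[int]] = {}
    by_chrom_w: dict[str, list[float]] = {}
    for (chrom, pos), w in zip(pl, wt):
        by_chrom.setdefault(chrom, []).append(pos)
        by_chrom_w.setdefault(chrom, []).append(w)
    for chrom in by_chrom:
        arr = np.asarray(by_chrom[chrom])
        order = np.argsort(arr, kind="stable")
        starts[chrom] = arr[order]
        wts[chrom] = np.asarray(by_chrom_w[chrom])[order]
    cumw = {c: np.concatenate(([0.0], np.cumsum(wts[c]))) for c in starts}

    def window_rpkm(chrom, s, e):
        if e <= s:
            return np.nan
        if chrom not in starts:
            cnt = 0.0
        else:
            lo = np.searchsorted(starts[chrom], s, side="left")
            hi = np.searchsorted(starts[chrom], e, side="left")
            cnt = cumw[chrom][hi] - cumw[chrom][lo]
        return cnt / ((e - s) / 1000.0) / (total_mapped / 1e6)

    # other-gene bodies, for flank exclusion
    from intervaltree import IntervalTree
    bodies: dict[str, IntervalTree] = {}
    for g in annotation.genes:
        bodies.setdefault(g.chrom, IntervalTree()).addi(g.tx_start, g.tx_end, g.id)

    def overlaps_other(chrom, s, e, gid):
        return any(h.data != gid for h in bodies.get(chrom, IntervalTree()).overlap(s, e))

    # fixed bin counts from genome-average feature lengths
    mean_u5 = np.mean([g.utr5[1] - g.utr5[0] for g in genes])
    mean_u3 = np.mean([g.utr3[1] - g.utr3[0] for g in genes])

    def interior(g):
        if g.strand == "+":
            return g.utr5[1], g.utr3[0]
        return g.utr3[1], g.utr5[0]

    mean_body = np.mean([max(e - s, 0) for s, e in (interior(g) for g in genes)])
    n_bins = {
        "upstream": flank // bin_bp,
        "utr5": max(int(round(mean_u5 / bin_bp)), 1),
        "body": max(int(round(mean_body / bin_bp)), 1),
        "utr3": max(int(round(mean_u3 / bin_bp)), 1),
        "downstream": flank // bin_bp,
    }
    seg_order = ["upstream", "utr5", "body", "utr3", "downstream"]
    sums = {s: np.zeros(n_bins[s]) for s in seg_order}
    ns = {s: np.zeros(n_bins[s]) for s in seg_order}

    for g in genes:
        clen = annotation.chrom_lengths[g.chrom]
        bs, be = interior(g)
        if be <= bs:
            continue
        if g.strand == "+":
            segs = {
                "upstream": (max(0, g.utr5[0] - flank), g.utr5[0]),
                "utr5": g.utr5,
                "body": (bs, be),
                "utr3": g.utr3,
                "downstream": (g.utr3[1], min(clen, g.utr3[1] + flank)),
            }
        else:
            segs = {
                "upstream": (g.utr5[1], min(clen, g.utr5[1] + flank)),
                "utr5": g.utr5,
                "body": (bs, be),
                "utr3": g.utr3,
                "downstream": (max(0, g.utr3[0] - flank), g.utr3[0]),
            }
        for seg in seg_order:
            s, e = segs[seg]
            if e <= s:
                continue
            wins = _segment_windows(s, e, bin_bp)
            vals = []
            for ws, we in wins:
                if seg in ("upstream", "downstream") and overlaps_other(
                        g.chrom, ws, we, g.id):
                    vals.append(np.nan)
                else:
                    vals.append(window_rpkm(g.chrom, ws, we))
            vals = np.asarray(vals, dtype=float)
            if g.strand == "-":
                vals = vals[::-1]
            if seg in ("upstream", "downstream"):
                # flanks are fixed-width: align bins directly, skip excluded
                nb = n_bins[seg]
                padded = np.full(nb, np.nan)
                if seg == "upstream":
                    padded[nb - len(vals):] = vals[:nb]
                else:
                    padded[:len(vals)] = vals[:nb]
                good = ~np.isnan(padded)
                sums[seg][good] += padded[good]
                ns[seg][good] += 1
            else:
                if np.isnan(vals).all():
                    continue
                scaled = _interp_to_bins(vals[~np.isnan(vals)], n_bins[seg])
                sums[seg] += scaled
                ns[seg] += 1

    rows = []
    pos = 0
    for seg in seg_order:
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.where(ns[seg] > 0, sums[seg] / ns[seg], np.nan)
        for b in range(n_bins[seg]):
            rows.append({"segment": seg, "bin": pos, "mean_rpkm": means[b],
                         "n_genes": int(ns[seg][b])})
            pos += 1
    return MetageneProfile(bins=pd.DataFrame(rows), segments=n_bins)
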