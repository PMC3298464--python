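"""Cross-tissue classification of methylation calls and summary statistics.

Windows are classified as methylated in all tissues, unmethylated in all
tissues, or tissue-differential; the tissue-specific proportion is the
differential fraction of everything methylated anywhere.  Pairwise
similarity between tissue call sets reports both directional overlap
fractions and the Jaccard index.  Gene-level calls (promoter / gene
body) use the RPKM empirical-FDR method at feature granularity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import CallSet, NoCutoffError, call_rpkm, empirical_fdr_cutoff

GENE_CATEGORIES = ("unmethylated", "promoter_only", "body_only", "both")


@dataclass
class UbiquityClassification:
    n_methylated_all: int
    n_unmethylated_all: int
    n_tissue_differential: int
    methylated_all: np.ndarray
    unmethylated_all: np.ndarray
    tissue_differential: np.ndarray

    @property
    def tissue_specific_proportion(self) -> float:
        return tissue_specific_proportion(self.n_tissue_differential,
                                          self.n_methylated_all)


def tissue_specific_proportion(n_tissue_differential: int,
                               n_methylated_all: int) -> float:
    """Differential / (differential + ubiquitously methylated), 2 decimals."""
    denom = n_tissue_differential + n_methylated_all
    if denom == 0:
        return float("nan")
    return round(n_tissue_differential / denom, 2)


def classify_ubiquity(callsets: list[CallSet]) -> UbiquityClassification:
    """Partition the window universe by cross-tissue methylation status."""
    if not callsets:
        raise ValueError("no call sets")
    n = callsets[0].mask.size
    if any(cs.mask.size != n for cs in callsets):
        raise ValueError("call sets are on different window universes")
    meth_all = np.logical_and.reduce([cs.mask for cs in callsets])
    unmeth_all = np.logical_and.reduce([~cs.mask for cs in callsets])
    differential = ~(meth_all | unmeth_all)
    return UbiquityClassification(
        n_methylated_all=int(meth_all.sum()),
        n_unmethylated_all=int(unmeth_all.sum()),
        n_tissue_differential=int(differential.sum()),
        methylated_all=meth_all,
        unmethylated_all=unmeth_all,
        tissue_differential=differential,
    )


def pairwise_similarity(a: CallSet, b: CallSet) -> dict:
    """Directional overlap fractions and Jaccard of two call sets."""
    if a.mask.size != b.mask.size:
        raise ValueError("call sets are on different universes")
    inter = int((a.mask & b.mask).sum())
    union = int((a.mask | b.mask).sum())
    na, nb = a.n_called, b.n_called
    return {
        "n_a": na,
        "n_b": nb,
        "n_intersection": inter,
        "frac_of_a": inter / na if na else float("nan"),
        "frac_of_b": inter / nb if nb else float("nan"),
        "jaccard": inter / union if union else float("nan"),
    }


def similarity_matrix(callsets: dict[str, CallSet], statistic: str = "frac_of_a",
                      ) -> pd.DataFrame:
    """Tissue x tissue similarity with |calls| on the diagonal."""
    tissues = list(callsets)
    m = pd.DataFrame(index=tissues, columns=tissues, dtype=float)
    for ta in tissues:
        for tb in tissues:
            if ta == tb:
                m.loc[ta, tb] = callsets[ta].n_called
            else:
                m.loc[ta, tb] = pairwise_similarity(callsets[ta], callsets[tb])[statistic]
    return m


def genome_fraction(mask: np.ndarray, widths: np.ndarray,
                    genome_length: float | None = None) -> float:
    """Fraction of genome bp inside flagged windows (true widths used)."""
    widths = np.asarray(widths, dtype=float)
    total = float(widths.sum()) if genome_length is None else float(genome_length)
    return float(widths[mask].sum() / total)


# ---------------------------------------------------------------------------
# gene-level feature calls

@dataclass
class GeneMethylationCalls:
    """Per-gene promoter/body calls across tissues.

    ``promoter`` and ``body`` are genes x tissues boolean frames.
    """

    promoter: pd.DataFrame
    body: pd.DataFrame
    cutoffs: dict

    @property
    def tissues(self) -> list[str]:
        return list(self.promoter.columns)

    def categories(self, tissue: str) -> pd.Series:
        """Category per gene in one tissue."""
        p = self.promoter[tissue]
        b = self.body[tissue]
        out = pd.Series("unmethylated", index=p.index)
        out[p & ~b] = "promoter_only"
        out[~p & b] = "body_only"
        out[p & b] = "both"
        return out

    def methylated_anywhere(self, feature: str) -> pd.Index:
        frame = self.promoter if feature == "promoter" else self.body
        return frame.index[frame.any(axis=1)]

    def single_tissue_only(self, feature: str) -> dict[str, pd.Index]:
        """Genes methylated at ``feature`` in exactly one tissue, per tissue."""
        frame = self.promoter if feature == "promoter" else self.body
        once = frame.sum(axis=1) == 1
        return {
            t: frame.index[once & frame[t]]
            for t in frame.columns
        }

    def category_counts(self) -> pd.DataFrame:
        rows = {}
        for t in self.tissues:
            rows[t] = self.categories(t).value_counts().reindex(
                GENE_CATEGORIES, fill_value=0)
        return pd.DataFrame(rows).T.rename_axis("tissue")


def call_gene_features(feature_tables: dict[str, pd.DataFrame],
                       input_tables: list[pd.DataFrame],
                       fdr_ratio: int = 100,
                       features: tuple[str, str] = ("promoter", "gene_body"),
                       ) -> GeneMethylationCalls:
    """RPKM empirical-FDR calls at promoter / gene-body granularity.

    ``feature_tables`` maps tissue -> per-gene feature RPKM frame (as
    produced by :func:`medipseq.quantify.feature_rpkm`); ``input_tables``
    are the same frames for each input lane.  The cutoff is derived per
    feature type over the gene universe.  Genes whose feature is absent
    (NaN RPKM) are never called.
    """
    tissues = list(feature_tables)
    genes = feature_tables[tissues[0]].index
    results: dict[str, pd.DataFrame] = {}
    cutoffs: dict = {}
    for feat in features:
        inputs = np.vstack([
            np.nan_to_num(tbl[feat].to_numpy(dtype=float)) for tbl in input_tables])
        calls = pd.DataFrame(False, index=genes, columns=tissues)
        for tissue in tissues:
            valid = ~feature_tables[tissue][feat].isna().to_numpy()
            sample = np.nan_to_num(feature_tables[tissue][feat].to_numpy(dtype=float))
            try:
                res = empirical_fdr_cutoff(sample, inputs, ratio=fdr_ratio)
                cs = call_rpkm(sample, inputs, res.cutoff_rpkm, tissue=tissue)
                calls[tissue] = cs.mask & valid
                cutoffs[(feat, tissue)] = res.cutoff_rpkm
            except NoCutoffError:
                cutoffs[(feat, tissue)] = None
        results[feat] = calls
    return GeneMethylationCalls(
        promoter=results[features[0]],
        body=results[features[1]],
        cutoffs=cutoffs,
    )


def gene_percentages(counts: dict[str, int] | int, n_genes: int):
    """100 x count / n_genes to one decimal."""
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    if isinstance(counts, dict):
        return {k: round(100.0 * v / n_genes, 1) for k, v in counts.items()}
    return round(100.0 * counts / n_genes, 1)


# ---------------------------------------------------------------------------
# repeat-class enrichment

def repeat_class_enrichment(called_mask: np.ndarray, grid, repeats,
                            ) -> pd.DataFrame:
    """Per repeat class: genome bp fraction vs methylated-bp fraction.

    Fractions are of bp; the methylated territory is the union of called
    windows.  ratio = methylated fraction / genome fraction, with its
    log2; classes absent from the genome are skipped.
    """
    widths = grid.widths()
    genome_bp = float(widths.sum())
    meth_bp = float(widths[called_mask].sum())
    if meth_bp == 0:
        raise ValueError("empty call set")

    per_class_genome: dict[str, float] = {}
    per_class_meth: dict[str, float] = {}
    for rep in repeats:
        if rep.chrom not in grid.offsets:
            continue
        label = rep.class_label
        per_class_genome[label] = per_class_genome.get(label, 0.0) + (rep.end - rep.start)
        # bp of this element inside called windows
        w0 = grid.locate(rep.chrom, rep.start)
        w1 = grid.locate(rep.chrom, min(rep.end - 1, grid.chrom_lengths[rep.chrom] - 1))
        ov = 0.0
        for w in range(w0, w1 + 1):
            if called_mask[w]:
                iv = grid.intervals[w]
                ov += min(iv.end, rep.end) - max(iv.start, rep.start)
        per_class_meth[label] = per_class_meth.get(label, 0.0) + ov

    rows = []
    for label, gbp in sorted(per_class_genome.items()):
        if gbp <= 0:
            continue
        gfrac = gbp / genome_bp
        mfrac = per_class_meth.get(label, 0.0) / meth_bp
        ratio = mfrac / gfrac
        rows.append({
            "class_label": label,
            "genome_fraction": gfrac,
            "methylated_fraction": mfrac,
            "ratio": ratio,
            "log2_ratio": np.log2(ratio) if ratio > 0 else -np.inf,
            "enriched": ratio > 1,
        })
    return pd.DataFrame(rows).set_index("class_label")
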