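"""Synthetic MeDIP-seq study generator with known ground truth.

Generates everything the pipeline consumes — a small multi-chromosome
genome with gene models (exons/UTRs/strand), interspersed multi-copy
repeat families (so 32-mers multi-map by construction), a
centromere-like repeat-dense region, an organelle (chloroplast)
contaminant genome, per-tissue window/gene methylation truth, MeDIP and
input counts with negative-binomial overdispersion, 32-mer reads with
clonal duplicates and organelle contamination, and a gene expression
matrix with tissue-biased genes and methylation-dependent repression.

Everything is deterministic under a fixed master seed; each sample draws
from its own RNG stream derived from the seed and the sample name, so
output is stable under sample re-ordering.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import (GenomeAnnotation, GeneModel, RepeatElement, WindowGrid,
                     promoter_interval)
from .reads import READ_LEN, revcomp

TISSUES = ("bud", "male_catkin", "female_catkin", "leaf", "root", "phloem", "xylem")


@dataclass
class RepeatFamily:
    label: str
    copies: int
    length: int


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic experiment.

    Defaults describe a desk-scale analogue of a seven-tissue MeDIP-seq
    survey: 1 Mb genome in 5 chromosomes, 200 genes, 2 biological
    replicates per tissue plus 4 non-immunoprecipitated input lanes,
    8-fold MeDIP enrichment over a mean input of 20 reads per 1 kb
    window with negative-binomial dispersion r = 5, ~2% of windows
    methylated in every tissue and ~5% per tissue specifically
    methylated, and expression repression that is stronger for gene-body
    methylation (x0.25) than for promoter methylation (x0.5).
    """

    seed: int = 0
    n_chromosomes: int = 5
    chrom_length: int = 200_000
    n_genes: int = 200
    gene_length_range: tuple[int, int] = (1_500, 2_500)
    exons_per_gene: tuple[int, int] = (1, 5)
    utr_length_range: tuple[int, int] = (100, 400)
    repeat_families: tuple[RepeatFamily, ...] = (
        RepeatFamily("LTR-gypsy", 30, 400),
        RepeatFamily("LTR-copia", 20, 350),
        RepeatFamily("LINE-L1", 20, 300),
        RepeatFamily("hAT", 15, 250),
    )
    centromere_halfwidth: int = 10_000
    centromere_satellite_copies: int = 40
    centromere_satellite_length: int = 300
    organelle_length: int = 20_000
    tissues: tuple[str, ...] = TISSUES
    n_replicates: int = 2
    n_input_lanes: int = 4
    frac_ubiquitous: float = 0.02
    frac_tissue_specific: float = 0.05
    gene_promoter_ubiquitous: float = 0.06
    gene_promoter_specific: float = 0.11
    gene_body_ubiquitous: float = 0.05
    gene_body_specific: float = 0.105
    enrichment_fold: float = 8.0
    input_mean: float = 20.0
    nb_dispersion: float | None = 5.0     # None -> Poisson counts
    reads_per_sample: int = 50_000
    clonal_rate: float = 0.2
    organelle_rate: float = 0.05
    window_size: int = 1000
    expr_log_mean: float = 4.0
    expr_log_sd: float = 1.0
    expr_noise_sd: float = 0.2
    n_biased_per_tissue: int = 10
    bias_factor: float = 20.0
    promoter_effect: float = 0.5
    body_effect: float = 0.25

    def validate(self) -> None:
        if self.frac_ubiquitous + len(self.tissues) * self.frac_tissue_specific > 1:
            raise ValueError("methylated fractions exceed 1")
        if self.enrichment_fold < 1:
            raise ValueError("enrichment_fold must be >= 1 (1 = null study)")
        if self.nb_dispersion is not None and self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")

    def sample_names(self) -> list[tuple[str, str, int, bool]]:
        """(sample, tissue, replicate, is_input) in a stable order."""
        out = []
        for t in self.tissues:
            for r in range(1, self.n_replicates + 1):
                out.append((f"{t}_rep{r}", t, r, False))
        for r in range(1, self.n_input_lanes + 1):
            out.append((f"input_lane{r}", "input", r, True))
        return out

    def rng_for(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            [self.seed % (2 ** 31), zlib.crc32(stream.encode())])


@dataclass
class SyntheticTruth:
    """Ground-truth methylation per window/gene per tissue, plus bias labels."""

    window: pd.DataFrame          # windows x tissues, boolean
    gene_promoter: pd.DataFrame   # genes x tissues, boolean
    gene_body: pd.DataFrame       # genes x tissues, boolean
    biased_genes: dict[str, list[str]] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.window.astype(int).to_csv(path, sep="\t")


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    annotation: GenomeAnnotation
    grid: WindowGrid
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# genome

def _random_seq(rng, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def simulate_genome(config: SimulationConfig) -> tuple[GenomeAnnotation, WindowGrid]:
    """Random genome + gene models + repeats + organelle contaminant."""
    config.validate()
    rng = config.rng_for("genome")
    seqs: dict[str, str] = {}
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    arrays: dict[str, np.ndarray] = {}
    for c in chroms:
        arrays[c] = np.array(list(_random_seq(rng, config.chrom_length)))

    genes: list[GeneModel] = []
    repeats: list[RepeatElement] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def place(chrom: str, length: int, lo: int, hi: int, tries: int = 200):
        for _ in range(tries):
            s = int(rng.integers(lo, max(lo + 1, hi - length)))
            e = s + length
            if all(e <= os or s >= oe for os, oe in occupied[chrom]):
                occupied[chrom].append((s, e))
                return s, e
        return None

    # centromere: repeat-dense satellite block at each chromosome midpoint
    sat_unit = _random_seq(rng, config.centromere_satellite_length)
    mid = config.chrom_length // 2
    cen_lo = mid - config.centromere_halfwidth
    cen_hi = mid + config.centromere_halfwidth
    for c in chroms:
        per_chrom = max(config.centromere_satellite_copies // config.n_chromosomes, 1)
        for _ in range(per_chrom):
            spot = place(c, len(sat_unit), cen_lo, cen_hi)
            if spot is None:
                continue
            s, e = spot
            arrays[c][s:e] = list(sat_unit)
            repeats.append(RepeatElement(c, s, e, "centromeric-satellite"))

    # genes in regular slots on the chromosome arms (outside the
    # centromere), centered so neighbours stay clear of each other
    genes_per_chrom = -(-config.n_genes // config.n_chromosomes)
    arms = [(0, cen_lo), (cen_hi, config.chrom_length)]
    arm_bp = sum(e - s for s, e in arms)
    if genes_per_chrom * (config.gene_length_range[1] + 2000) > arm_bp:
        raise ValueError("requested genes exceed genome capacity")
    gi = 0
    for c in chroms:
        slots = []
        for arm_s, arm_e in arms:
            n_slots = round(genes_per_chrom * (arm_e - arm_s) / arm_bp)
            width = (arm_e - arm_s) // max(n_slots, 1)
            slots += [(arm_s + i * width, arm_s + (i + 1) * width)
                      for i in range(n_slots)]
        for slot_s, slot_e in slots:
            if gi >= config.n_genes:
                break
            glen = int(rng.integers(*config.gene_length_range))
            tx_start = slot_s + (slot_e - slot_s - glen) // 2
            tx_end = tx_start + glen
            occupied[c].append((tx_start, tx_end))
            gi += 1
            strand = "+" if rng.random() < 0.5 else "-"
            u5 = int(rng.integers(*config.utr_length_range))
            u3 = int(rng.integers(*config.utr_length_range))
            if strand == "+":
                utr5 = (tx_start, tx_start + u5)
                utr3 = (tx_end - u3, tx_end)
            else:
                utr5 = (tx_end - u5, tx_end)
                utr3 = (tx_start, tx_start + u3)
            n_ex = int(rng.integers(config.exons_per_gene[0],
                                    config.exons_per_gene[1] + 1))
            cuts = np.sort(rng.choice(
                np.arange(tx_start + 1, tx_end), size=2 * n_ex - 2,
                replace=False)) if n_ex > 1 else np.array([], dtype=int)
            bounds = [tx_start, *cuts.tolist(), tx_end]
            exons = [(bounds[i], bounds[i + 1])
                     for i in range(0, len(bounds) - 1, 2)]
            genes.append(GeneModel(
                id=f"gene{gi:04d}", chrom=c, strand=strand,
                tx_start=tx_start, tx_end=tx_end, exons=exons,
                utr5=utr5, utr3=utr3,
            ))

    # interspersed repeat families fill intergenic gaps: exact copies so
    # their 32-mers multi-map by construction
    for fam in config.repeat_families:
        unit = _random_seq(rng, fam.length)
        for _ in range(fam.copies):
            c = chroms[int(rng.integers(0, len(chroms)))]
            spot = place(c, fam.length, 0, config.chrom_length)
            if spot is None:
                continue
            s, e = spot
            arrays[c][s:e] = list(unit)
            repeats.append(RepeatElement(c, s, e, fam.label))

    seqs = {c: "".join(arrays[c]) for c in chroms}
    seqs["chloroplast"] = _random_seq(rng, config.organelle_length)
    ann = GenomeAnnotation(
        chrom_lengths={c: len(s) for c, s in seqs.items()},
        genes=genes,
        repeats=repeats,
        organelle_names={"chloroplast"},
        sequences=seqs,
    )
    ann.validate()
    grid = WindowGrid(ann.nuclear_chroms(), size=config.window_size)
    return ann, grid


# ---------------------------------------------------------------------------
# truth

def simulate_window_truth(config: SimulationConfig, n_windows: int) -> pd.DataFrame:
    """Window x tissue truth from the configured fractions alone."""
    rng = config.rng_for("window-truth")
    tissues = list(config.tissues)
    truth = pd.DataFrame(False, index=pd.RangeIndex(n_windows, name="window"),
                         columns=tissues)
    u = rng.random(n_windows)
    ubiq = u < config.frac_ubiquitous
    truth.loc[ubiq, :] = True
    lo = config.frac_ubiquitous
    for t in tissues:
        hi = lo + config.frac_tissue_specific
        truth.loc[(u >= lo) & (u < hi), t] = True
        lo = hi
    return truth


def _gene_feature_truth(config: SimulationConfig, gene_ids: list[str],
                        stream: str, frac_ubiq: float, frac_spec: float,
                        ) -> pd.DataFrame:
    rng = config.rng_for(stream)
    tissues = list(config.tissues)
    truth = pd.DataFrame(False, index=pd.Index(gene_ids, name="gene"),
                         columns=tissues)
    u = rng.random(len(gene_ids))
    truth.loc[u < frac_ubiq, :] = True
    spec = (u >= frac_ubiq) & (u < frac_ubiq + frac_spec)
    which = rng.integers(0, len(tissues), len(gene_ids))
    for ti, t in enumerate(tissues):
        truth.loc[spec & (which == ti), t] = True
    return truth


def simulate_truth(config: SimulationConfig, annotation: GenomeAnnotation,
                   grid: WindowGrid) -> SyntheticTruth:
    """Window + gene truth; methylated gene features mark their windows."""
    window = simulate_window_truth(config, grid.n)
    gene_ids = [g.id for g in annotation.genes]
    prom = _gene_feature_truth(config, gene_ids, "promoter-truth",
                               config.gene_promoter_ubiquitous,
                               config.gene_promoter_specific)
    body = _gene_feature_truth(config, gene_ids, "body-truth",
                               config.gene_body_ubiquitous,
                               config.gene_body_specific)

    by_id = {g.id: g for g in annotation.genes}
    for gid in gene_ids:
        g = by_id[gid]
        clen = annotation.chrom_lengths[g.chrom]
        p_iv = promoter_interval(g, clen)
        for t in config.tissues:
            spans = []
            if prom.loc[gid, t] and p_iv:
                spans.append(p_iv)
            if body.loc[gid, t]:
                spans.append(g.body)
            for s, e in spans:
                w0 = grid.locate(g.chrom, s)
                w1 = grid.locate(g.chrom, e - 1)
                window.loc[w0:w1, t] = True

    rng = config.rng_for("bias-genes")
    biased: dict[str, list[str]] = {}
    pool = list(gene_ids)
    rng.shuffle(pool)
    k = config.n_biased_per_tissue
    for i, t in enumerate(config.tissues):
        biased[t] = sorted(pool[i * k:(i + 1) * k])
    return SyntheticTruth(window=window, gene_promoter=prom, gene_body=body,
                          biased_genes=biased)


# ---------------------------------------------------------------------------
# counts

def _draw_counts(rng, mean: np.ndarray, dispersion: float | None) -> np.ndarray:
    if dispersion is None:
        return rng.poisson(mean)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


@dataclass
class CountSim:
    counts: pd.DataFrame    # windows x samples
    samples: pd.DataFrame   # tissue, replicate, is_input, total_mapped


def simulate_counts(config: SimulationConfig, window_truth: pd.DataFrame,
                    ) -> CountSim:
    """Per-sample window counts from the truth.

    Input lanes draw NB(input_mean, r) everywhere; MeDIP samples draw
    NB(input_mean x fold, r) in windows methylated in their tissue and
    NB(input_mean, r) elsewhere.  r = None gives Poisson counts.
    Library sizes are the realized column sums.
    """
    n = len(window_truth)
    counts = {}
    meta = []
    for sample, tissue, rep, is_input in config.sample_names():
        rng = config.rng_for(f"counts:{sample}")
        if is_input:
            mean = np.full(n, config.input_mean)
        else:
            meth = window_truth[tissue].to_numpy()
            mean = np.where(meth, config.input_mean * config.enrichment_fold,
                            config.input_mean)
        c = _draw_counts(rng, mean, config.nb_dispersion)
        counts[sample] = c
        meta.append({"sample": sample, "tissue": tissue, "replicate": rep,
                     "is_input": is_input, "total_mapped": int(c.sum())})
    return CountSim(
        counts=pd.DataFrame(counts, index=window_truth.index),
        samples=pd.DataFrame(meta).set_index("sample"),
    )


# ---------------------------------------------------------------------------
# reads

def simulate_reads(config: SimulationConfig, annotation: GenomeAnnotation,
                   grid: WindowGrid, window_truth: pd.DataFrame,
                   ) -> dict[str, list[tuple[str, str]]]:
    """32-mer reads per sample as (id, sequence) lists.

    Genuine reads start at positions drawn window-by-window with weights
    matching the count model's intensities; clonal duplicates are
    resampled from already-drawn reads at ``clonal_rate``; organelle
    contaminants are drawn from the chloroplast at ``organelle_rate``.
    """
    seqs = annotation.sequences
    if seqs is None:
        raise ValueError("annotation must carry sequences")
    organelle = next(iter(annotation.organelle_names), None)
    widths = grid.widths().astype(float)
    usable = np.maximum(widths - READ_LEN, 1.0)
    out: dict[str, list[tuple[str, str]]] = {}
    for sample, tissue, _rep, is_input in config.sample_names():
        rng = config.rng_for(f"reads:{sample}")
        if is_input:
            weight = np.ones(grid.n)
        else:
            meth = window_truth[tissue].to_numpy()
            weight = np.where(meth, config.enrichment_fold, 1.0)
        if config.nb_dispersion is not None:
            # gamma-perturb per-window intensities so counts are
            # overdispersed across biological replicates (gamma-Poisson)
            r = config.nb_dispersion
            weight = weight * rng.gamma(r, 1.0 / r, size=grid.n)
        weight = weight * usable
        weight = weight / weight.sum()

        n_total = config.reads_per_sample
        if n_total == 0:
            out[sample] = []
            continue
        n_templates = max(int(round(n_total * (1.0 - config.clonal_rate))), 1)
        n_org = int(round(n_templates * config.organelle_rate)) if organelle else 0
        n_genuine = n_templates - n_org

        win_idx = rng.choice(grid.n, size=n_genuine, p=weight)
        templates: list[str] = []
        for w in win_idx:
            iv = grid.intervals[w]
            span = iv.width - READ_LEN
            pos = iv.start + (int(rng.integers(0, span + 1)) if span > 0 else 0)
            frag = seqs[iv.chrom][pos:pos + READ_LEN]
            if len(frag) < READ_LEN:  # window at chromosome tail
                pos = max(0, annotation.chrom_lengths[iv.chrom] - READ_LEN)
                frag = seqs[iv.chrom][pos:pos + READ_LEN]
            if rng.random() < 0.5:
                frag = revcomp(frag)
            templates.append(frag)
        if organelle:
            oseq = seqs[organelle]
            for _ in range(n_org):
                pos = int(rng.integers(0, len(oseq) - READ_LEN + 1))
                frag = oseq[pos:pos + READ_LEN]
                if rng.random() < 0.5:
                    frag = revcomp(frag)
                templates.append(frag)
        reads = list(templates)
        n_dup = n_total - len(templates)
        if n_dup > 0 and templates:
            dup_idx = rng.integers(0, len(templates), size=n_dup)
            reads.extend(templates[i] for i in dup_idx)
        out[sample] = [(f"{sample}:{i + 1}", s) for i, s in enumerate(reads)]
    return out


def write_fastq(reads: list[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# expression

def simulate_expression(config: SimulationConfig, truth: SyntheticTruth,
                        ) -> pd.DataFrame:
    """Gene x tissue expression with planted bias and methylation repression.

    Baseline is log-normal per gene with per-tissue log-normal noise;
    biased genes have their subset tissue multiplied by ``bias_factor``
    (enough to clear the 0.9 bias threshold); promoter-methylated genes
    in a tissue are scaled by ``promoter_effect`` and body-methylated by
    ``body_effect`` (both multiply when both features are methylated).
    """
    rng = config.rng_for("expression")
    genes = list(truth.gene_promoter.index)
    tissues = list(config.tissues)
    base = rng.lognormal(config.expr_log_mean, config.expr_log_sd, len(genes))
    noise = rng.lognormal(0.0, config.expr_noise_sd, (len(genes), len(tissues)))
    expr = pd.DataFrame(base[:, None] * noise, index=pd.Index(genes, name="gene"),
                        columns=tissues)
    for t, gene_list in truth.biased_genes.items():
        expr.loc[gene_list, t] *= config.bias_factor
    for t in tissues:
        p = truth.gene_promoter[t].to_numpy()
        b = truth.gene_body[t].to_numpy()
        factor = np.where(p, config.promoter_effect, 1.0) * \
            np.where(b, config.body_effect, 1.0)
        expr[t] = expr[t].to_numpy() * factor
    return expr


# ---------------------------------------------------------------------------
# whole-study convenience + file export

def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    annotation, grid = simulate_genome(config)
    truth = simulate_truth(config, annotation, grid)
    return SimulatedStudy(config=config, annotation=annotation, grid=grid,
                          truth=truth)


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write FASTA/GFF3/BED/FASTQ/TSV for a simulated study; path map out."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    ann = study.annotation

    fa = os.path.join(outdir, "genome.fa")
    with open(fa, "w") as fh:
        for name, seq in ann.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
    paths["genome_fasta"] = fa

    gff = os.path.join(outdir, "genes.gff3")
    with open(gff, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in ann.genes:
            attrs = f"ID={g.id}"
            fh.write(f"{g.chrom}\tsim\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            mid = f"{g.id}.1"
            fh.write(f"{g.chrom}\tsim\tmRNA\t{g.tx_start + 1}\t{g.tx_end}\t.\t"
                     f"{g.strand}\t.\tID={mid};Parent={g.id}\n")
            for i, (s, e) in enumerate(g.exons):
                fh.write(f"{g.chrom}\tsim\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                         f"ID={mid}.exon{i + 1};Parent={mid}\n")
            if g.utr5:
                fh.write(f"{g.chrom}\tsim\tfive_prime_UTR\t{g.utr5[0] + 1}\t"
                         f"{g.utr5[1]}\t.\t{g.strand}\t.\tID={mid}.utr5;Parent={mid}\n")
            if g.utr3:
                fh.write(f"{g.chrom}\tsim\tthree_prime_UTR\t{g.utr3[0] + 1}\t"
                         f"{g.utr3[1]}\t.\t{g.strand}\t.\tID={mid}.utr3;Parent={mid}\n")
    paths["gff3"] = gff

    bed = os.path.join(outdir, "repeats.bed")
    with open(bed, "w") as fh:
        for r in ann.repeats:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.class_label}\n")
    paths["repeat_bed"] = bed

    truth_tsv = os.path.join(outdir, "window_truth.tsv")
    study.truth.to_tsv(truth_tsv)
    paths["window_truth"] = truth_tsv

    reads = simulate_reads(study.config, ann, study.grid, study.truth.window)
    for sample, rlist in reads.items():
        p = os.path.join(outdir, f"{sample}.fastq")
        write_fastq(rlist, p)
        paths[f"fastq:{sample}"] = p

    expr = simulate_expression(study.config, study.truth)
    expr_tsv = os.path.join(outdir, "expression.tsv")
    expr.to_csv(expr_tsv, sep="\t", float_format="%.6g")
    paths["expression"] = expr_tsv
    return paths
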