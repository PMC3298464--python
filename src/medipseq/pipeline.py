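"""End-to-end pipeline: reads -> windows -> calls -> comparisons -> association.

A :class:`RunConfig` names the inputs (genome FASTA, GFF3, optional
repeat BED, FASTQ or SAM per sample, expression TSV) and the analysis
parameters (window size 1000, read length 32, promoter 2000 bp, FDR
ratio 100, CPPD alpha 1e-4, NB alphas 1e-4/1e-3).  ``run_pipeline``
executes the stages in order and writes TSV/BED/bedGraph/JSON outputs
into a run directory; the JSON report records thresholds, realized
cutoffs and dispersion fits.  All outputs are deterministic.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calling, expression as expr_mod, quantify, reads as reads_mod, tissues
from .genome import GenomeAnnotation, WindowGrid, derive_features, load_annotation

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Run configuration failed validation."""


@dataclass
class SampleSpec:
    name: str
    tissue: str
    replicate: int = 1
    is_input: bool = False
    fastq: str | None = None
    sam: str | None = None


@dataclass
class RunConfig:
    genome_fasta: str
    gff3: str
    samples: list[SampleSpec]
    repeat_bed: str | None = None
    expression_tsv: str | None = None
    window_size: int = 1000
    read_length: int = 32
    promoter_length: int = 2000
    fdr_ratio: int = 100
    cppd_alpha: float = 1e-4
    nb_alphas: tuple[float, ...] = (1e-4, 1e-3)
    grid_step: float = 0.01
    cutoff_scope: str = "pooled"  # or "per-tissue"
    seed: int = 0

    def validate(self) -> None:
        problems = []
        tissues_seen = {s.tissue for s in self.samples if not s.is_input}
        if not tissues_seen:
            problems.append("no MeDIP samples")
        n_inputs = sum(1 for s in self.samples if s.is_input)
        if n_inputs < 2:
            problems.append("need >= 2 input samples for the empirical FDR")
        for s in self.samples:
            if s.fastq is None and s.sam is None:
                problems.append(f"sample {s.name}: neither fastq nor sam given")
        if problems:
            raise ConfigError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = [SampleSpec(**s) for s in raw.pop("samples")]
        nb = raw.pop("nb_alphas", None)
        cfg = cls(samples=samples, **raw)
        if nb is not None:
            cfg.nb_alphas = tuple(float(a) for a in nb)
        return cfg


def synthetic_run_config(sim_config, study_dir) -> RunConfig:
    """Write a synthetic study to ``study_dir`` and build its RunConfig."""
    from .simulate import simulate_study, write_study

    study = simulate_study(sim_config)
    paths = write_study(study, study_dir)
    samples = [
        SampleSpec(name=name, tissue=tissue, replicate=rep, is_input=is_input,
                   fastq=paths[f"fastq:{name}"])
        for name, tissue, rep, is_input in sim_config.sample_names()
    ]
    return RunConfig(
        genome_fasta=paths["genome_fasta"],
        gff3=paths["gff3"],
        repeat_bed=paths["repeat_bed"],
        expression_tsv=paths["expression"],
        samples=samples,
        seed=sim_config.seed,
    )


# ---------------------------------------------------------------------------
# per-sample read processing

@dataclass
class ProcessedSample:
    name: str
    n_total: int
    n_after_trim: int
    n_clonal_removed: int
    n_unmapped: int
    n_organelle_removed: int
    unique_records: list = field(repr=False, default_factory=list)
    multi_records: list = field(repr=False, default_factory=list)

    @property
    def n_mapped(self) -> int:
        return len(self.unique_records) + len(self.multi_records)


def process_sample(spec: SampleSpec, annotation: GenomeAnnotation,
                   index: reads_mod.KmerIndex | None,
                   read_length: int = 32) -> ProcessedSample:
    """Trim, deduplicate, align (or ingest SAM), filter organelles, split."""
    if spec.sam is not None:
        records, n_unmapped = reads_mod.records_from_sam(spec.sam)
        n_total = len(records) + n_unmapped
        n_trim = n_total
        n_clonal = 0
    else:
        raw = reads_mod.read_fastq(spec.fastq)
        n_total = len(raw)
        trimmed, _ = reads_mod.trim_reads(raw, read_length)
        n_trim = len(trimmed)
        deduped, n_clonal = reads_mod.deduplicate_clonal(trimmed)
        records, n_unmapped = reads_mod.align_exact(deduped, index)
    records, n_org = reads_mod.filter_organelle(records, annotation.organelle_names)
    unique, multi = reads_mod.split_unique_multi(records)
    return ProcessedSample(
        name=spec.name, n_total=n_total, n_after_trim=n_trim,
        n_clonal_removed=n_clonal, n_unmapped=n_unmapped,
        n_organelle_removed=n_org, unique_records=unique, multi_records=multi,
    )


def window_table_from_samples(processed: list[ProcessedSample],
                              specs: list[SampleSpec],
                              grid: WindowGrid) -> quantify.WindowTable:
    """Counts = unique starts + fractional multi mass; M = unique + multi reads."""
    table = quantify.WindowTable(grid)
    by_name = {s.name: s for s in specs}
    for ps in processed:
        uniq = quantify.count_into_windows(
            ((c, p) for rec in ps.unique_records for c, p, _ in rec.placements), grid)
        frac = reads_mod.distribute_repeats(ps.multi_records, grid)
        spec = by_name[ps.name]
        table.add_sample(ps.name, uniq + frac, total_mapped=ps.n_mapped,
                         tissue=spec.tissue, replicate=spec.replicate,
                         is_input=spec.is_input)
    return table


# ---------------------------------------------------------------------------
# calling stage

def call_all_methods(table: quantify.WindowTable, cfg: RunConfig,
                     ) -> tuple[dict[str, dict[str, calling.CallSet]], dict]:
    """RPKM / CPPD / NB call sets per tissue, plus a report of thresholds."""
    report: dict = {"methods": {}}
    input_rpkms = table.input_rpkm_matrix()
    input_counts, input_total = table.pooled_inputs()
    widths = table.grid.widths()

    tissue_names = sorted(
        set(table.samples[~table.samples.is_input].tissue))
    callsets: dict[str, dict[str, calling.CallSet]] = {t: {} for t in tissue_names}

    # RPKM cutoff at 1% FDR: by default one cutoff from all MeDIP samples
    # pooled; optionally derived per tissue from its own pooled RPKM
    cutoff_by_tissue: dict[str, float] = {}
    if cfg.cutoff_scope == "pooled":
        pooled_counts = table.counts[
            table.samples[~table.samples.is_input].index].sum(axis=1).to_numpy()
        pooled_total = float(
            table.samples[~table.samples.is_input].total_mapped.sum())
        pooled_rpkm = quantify.rpkm(pooled_counts, widths, pooled_total)
        fdr = calling.empirical_fdr_cutoff(pooled_rpkm, input_rpkms,
                                           ratio=cfg.fdr_ratio,
                                           grid_step=cfg.grid_step)
        cutoff_by_tissue = {t: fdr.cutoff_rpkm for t in tissue_names}
        report["methods"]["RPKM"] = {
            "cutoff_rpkm": fdr.cutoff_rpkm, "ratio": cfg.fdr_ratio,
            "grid_step": cfg.grid_step, "scope": "pooled",
            "n_sample_exceed": fdr.n_sample_exceed,
            "n_null_exceed": fdr.n_null_exceed,
        }
    elif cfg.cutoff_scope == "per-tissue":
        for tissue in tissue_names:
            fdr = calling.empirical_fdr_cutoff(
                table.pooled_rpkm(tissue), input_rpkms,
                ratio=cfg.fdr_ratio, grid_step=cfg.grid_step)
            cutoff_by_tissue[tissue] = fdr.cutoff_rpkm
        report["methods"]["RPKM"] = {
            "cutoff_by_tissue": cutoff_by_tissue, "ratio": cfg.fdr_ratio,
            "grid_step": cfg.grid_step, "scope": "per-tissue",
        }
    else:
        raise ConfigError(f"unknown cutoff_scope {cfg.cutoff_scope!r}")

    nb_fits: dict[str, float] = {}
    for tissue in tissue_names:
        t_rpkm = table.pooled_rpkm(tissue)
        callsets[tissue]["RPKM"] = calling.call_rpkm(
            t_rpkm, input_rpkms, cutoff_by_tissue[tissue], tissue=tissue)

        t_counts, t_total = table.pooled(tissue)
        lam = calling.normalize_input(input_counts, input_total, t_total)
        callsets[tissue]["CPPD"] = calling.call_cppd(
            t_counts, lam, alpha=cfg.cppd_alpha, tissue=tissue)

        reps = table.samples[(table.samples.tissue == tissue)
                             & (~table.samples.is_input)].index.tolist()
        if len(reps) >= 2:
            fit = calling.fit_nb(table.counts[reps].to_numpy())
            nb_fits[tissue] = fit.r
            # pooled counts are a sum of len(reps) replicates, whose NB
            # dispersion is len(reps) x the per-replicate dispersion
            pooled_r = fit.r * len(reps)
            callsets[tissue]["NB"] = calling.call_nb(
                t_counts, lam, pooled_r, alpha=cfg.nb_alphas[0], tissue=tissue)
    report["methods"]["CPPD"] = {"alpha": cfg.cppd_alpha}
    report["methods"]["NB"] = {"alphas": list(cfg.nb_alphas),
                               "dispersion_by_tissue": nb_fits}
    return callsets, report


# ---------------------------------------------------------------------------
# full run

def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Execute every stage and write the run directory; returns the report."""
    cfg.validate()
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"seed": cfg.seed, "parameters": {
        "window_size": cfg.window_size, "read_length": cfg.read_length,
        "promoter_length": cfg.promoter_length, "fdr_ratio": cfg.fdr_ratio,
        "cppd_alpha": cfg.cppd_alpha, "nb_alphas": list(cfg.nb_alphas),
        "grid_step": cfg.grid_step,
    }}

    annotation = load_annotation(cfg.genome_fasta, cfg.gff3, cfg.repeat_bed)
    grid = WindowGrid(annotation.nuclear_chroms(), size=cfg.window_size)
    need_align = any(s.fastq is not None for s in cfg.samples)
    index = reads_mod.KmerIndex(annotation.sequences) if need_align else None

    processed = [process_sample(s, annotation, index, cfg.read_length)
                 for s in cfg.samples]
    summary = pd.DataFrame([
        {"sample": p.name, "total_reads": p.n_total,
         "clonal_removed": p.n_clonal_removed,
         "organelle_removed": p.n_organelle_removed,
         "mapped_reads": p.n_mapped,
         "percent_mapped": quantify.percent_mapped(p.n_total, p.n_mapped)
         if p.n_total else 0.0}
        for p in processed])
    summary.to_csv(os.path.join(outdir, "alignment_summary.tsv"), sep="\t",
                   index=False)

    table = window_table_from_samples(processed, cfg.samples, grid)
    table.to_tsv(os.path.join(outdir, "window_counts.tsv"))

    callsets, call_report = call_all_methods(table, cfg)
    report.update(call_report)

    win = table.windows_frame()
    rows = []
    for tissue, by_method in callsets.items():
        for method, cs in by_method.items():
            rows.append({"tissue": tissue, "method": method,
                         "n_called": cs.n_called, "threshold": cs.threshold})
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "callsets.tsv"), sep="\t",
                              index=False)
    with open(os.path.join(outdir, "called_windows.bed"), "w") as fh:
        for tissue, by_method in sorted(callsets.items()):
            for method, cs in sorted(by_method.items()):
                for w in np.nonzero(cs.mask)[0]:
                    fh.write(f"{win.chrom[w]}\t{win.start[w]}\t{win.end[w]}\t"
                             f"{tissue}:{method}\n")

    # cross-tissue comparison per method
    comparison: dict = {}
    for method in ("RPKM", "CPPD", "NB"):
        sets = {t: callsets[t][method] for t in sorted(callsets)
                if method in callsets[t]}
        if len(sets) < 2:
            continue
        ub = tissues.classify_ubiquity(list(sets.values()))
        comparison[method] = {
            "methylated_all": ub.n_methylated_all,
            "unmethylated_all": ub.n_unmethylated_all,
            "tissue_differential": ub.n_tissue_differential,
            "tissue_specific_proportion": ub.tissue_specific_proportion,
            "genome_fraction_differential": tissues.genome_fraction(
                ub.tissue_differential, grid.widths()),
        }
        tissues.similarity_matrix(sets).to_csv(
            os.path.join(outdir, f"similarity_{method}.tsv"), sep="\t",
            float_format="%.6g")
    report["comparison"] = comparison

    # agreement among methods per tissue
    agreement = {}
    for tissue in sorted(callsets):
        if len(callsets[tissue]) == 3:
            agreement[tissue] = calling.method_agreement(
                [callsets[tissue][m] for m in ("RPKM", "CPPD", "NB")])
    report["agreement"] = agreement

    # expression association
    if cfg.expression_tsv:
        catalog = derive_features(annotation, promoter_len=cfg.promoter_length)
        expr = pd.read_csv(cfg.expression_tsv, sep="\t", index_col=0)
        feature_tables = {}
        input_tables = []
        by_name = {p.name: p for p in processed}
        specs_by_tissue: dict[str, list[SampleSpec]] = {}
        for s in cfg.samples:
            specs_by_tissue.setdefault(
                "input" if s.is_input else s.tissue, []).append(s)
        for tissue, specs in sorted(specs_by_tissue.items()):
            frames, totals = [], []
            for s in specs:
                p = by_name[s.name]
                placements = [(c, pos) for rec in p.unique_records
                              for c, pos, _ in rec.placements]
                weights = [1.0] * len(placements)
                for rec in p.multi_records:
                    for c, pos, _ in rec.placements:
                        placements.append((c, pos))
                        weights.append(1.0 / rec.n_placements)
                frames.append(quantify.feature_counts(placements, catalog,
                                                      weights=weights))
                totals.append(p.n_mapped)
            if tissue == "input":
                input_tables = [
                    quantify.feature_rpkm([f], [t])
                    for f, t in zip(frames, totals)]
            else:
                feature_tables[tissue] = quantify.feature_rpkm(frames, totals)
        gene_calls = tissues.call_gene_features(
            feature_tables, input_tables, fdr_ratio=cfg.fdr_ratio)
        gene_calls.category_counts().to_csv(
            os.path.join(outdir, "gene_categories.tsv"), sep="\t")
        summary_df, tests_df = expr_mod.category_expression_summary(
            gene_calls, expr)
        summary_df.to_csv(os.path.join(outdir, "expression_by_category.tsv"),
                          sep="\t", index=False, float_format="%.6g")
        tests_df.to_csv(os.path.join(outdir, "expression_tests.tsv"),
                        sep="\t", index=False, float_format="%.6g")
        expr_mod.bias_table(expr).to_csv(
            os.path.join(outdir, "bias_table.tsv"), sep="\t", index=False,
            float_format="%.6g")
        with open(os.path.join(outdir, "expression_clustering.nwk"), "w") as fh:
            fh.write(expr_mod.cluster_tissues(expr) + "\n")
        report["gene_calls"] = {
            "n_promoter_methylated": int(len(gene_calls.methylated_anywhere("promoter"))),
            "n_body_methylated": int(len(gene_calls.methylated_anywhere("body"))),
            "n_genes": int(len(gene_calls.promoter.index)),
        }
        if not tests_df.empty:
            body_vs_unmeth = tests_df[
                (tests_df.group_a == "unmethylated")
                & (tests_df.group_b == "body_only")]
            if len(body_vs_unmeth) >= 1:
                directions = np.sign(body_vs_unmeth.median_a.to_numpy()
                                     - body_vs_unmeth.median_b.to_numpy())
                if (directions != 0).any():
                    report["body_repression_sign_test_p"] = expr_mod.sign_test(
                        directions)

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
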