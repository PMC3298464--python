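# Methods

## Scope and data model

The package analyses enrichment-based methylation sequencing
(MeDIP-seq): reads are evidence of methylated fragments, not
base-resolution calls. All internal coordinates are 0-based half-open;
GFF3 (1-based inclusive) is converted on ingest, BED passes through.
When a gene has several annotated splice variants only the first is
used, everywhere. The final window of each chromosome may be shorter
than the window size; its true width is used as the RPKM length term
and in genome-fraction arithmetic.

## Read processing

Reads are truncated to their first 32 bases (shorter reads dropped and
counted), then deduplicated by full-sequence identity — identical
sequences are presumed PCR clones and all but the first occurrence
removed. Alignment is by perfect match only: each chromosome is
packed into 64-bit integers (2 bits/base; a 32-mer fills a uint64
exactly), the array is sorted, and each read and its reverse complement
are located by binary search. A read containing N cannot perfect-match
and is unmapped by construction. The index includes organelle
sequences; reads whose placements are all organellar are removed, and
surviving reads keep only nuclear placements.

Reads with one placement form the unique branch; reads with k > 1
placements are distributed with weight 1/k at every placement.
Division is deterministic and exact (no RNG), so the distributed mass
equals the multi-read count to 1e-9 — a property the tests assert.
Reads are assigned to 1 kb windows by placement start position; a start
on a boundary belongs to the window beginning there.

Mismatch-tolerant alignment is deliberately not implemented: the exact
matcher is fast and verifiable against a brute-force genome scan (a
test oracle on ≤10 kb genomes). Externally produced mismatch-tolerant
alignments can be ingested from SAM (QNAME/RNAME/POS/FLAG only); reads
with several SAM hits enter the distributed branch.

## Quantification

RPKM = C/(L/10³)/(M/10⁶). The depth denominator M is the sample's
mapped, non-clonal, organelle-filtered read count (unique + distributed
mass). Replicates within a tissue are pooled by summing counts and
summing totals before taking RPKM; a test asserts this equals RPKM of
the summed columns. Gene features (promoter = 2 kb upstream of the
TSS, strand-aware and truncated at chromosome edges; 5'/3' UTRs; exons;
introns = body − exons; gene body = transcribed region; intergenic 1 kb
windows over the complement of bodies and promoters) are each scored
with their own width.

The metagene profile averages RPKM over 100 bp windows across an
idealized gene: 2 kb upstream, 5' UTR, transcribed interior, 3' UTR,
2 kb downstream, for genes with both UTRs annotated. Flank windows
overlapping another gene model are excluded from that gene's
contribution. Variable-width segments are rescaled to a fixed bin
count equal to round(mean segment length / 100 bp) by linear
interpolation, so the displayed UTR and body widths are genome
averages. Uniform coverage therefore produces an exactly flat profile
(asserted to 1e-9).

## Methylation calling

**Empirical-FDR RPKM cutoff.** Null: |RPKM difference| per window for
every ordered pair of input lanes, with exceedance counts averaged
across pairs (ordered-pair absolute differences are one reading of an
ambiguous published procedure; signed ordered differences give
identical counts). Sample statistic: sample RPKM − mean input RPKM.
The grid (step 0.01, recorded in the output) is scanned upward for the
smallest cutoff where sample exceedances ≥ 100 × null exceedances; a
null count of zero qualifies whenever the sample count is positive.
If no grid point qualifies a `NoCutoffError` carries diagnostics —
this is the expected outcome when sample and inputs are exchangeable.
By default one cutoff is derived from all MeDIP samples pooled and
applied to every tissue (`cutoff_scope="pooled"`); per-tissue
derivation is available. Boundary rule: difference ≥ cutoff is called.

**Input normalization.** λ_w = input count × (sample total / input
total), then floored at the genome mean of the normalized counts. The
floor only ever raises λ, so calls with the floor are a subset of calls
without it (a property test). Fractional distributed counts are
floored to integers for the Poisson/NB tails; the RPKM method uses
fractions as-is.

**CPPD.** p = P(X ≥ k | Poisson(λ)) = 1 − F(k−1); called when
p < 1e-4, strictly. The implementation is checked against direct pmf
summation to 1e-10 for λ ≤ 50, k ≤ 200.

**Negative binomial.** Same comparison with Var = μ + μ²/r. The
dispersion is fit per tissue by method of moments on replicate window
counts: per-window mean μ_w and ddof-1 variance v_w, pooled as
r̂ = mean(μ_w)² / (mean(v_w) − mean(μ_w)); when pooled variance does not
exceed the mean, r̂ = ∞ and the test degenerates to Poisson (the NB
tail is asserted to converge to CPPD at r = 1e8, sup diff < 1e-6).
Pooling may optionally stratify windows by mean count; the default is
a single stratum, which recovers r̂ ∈ [4, 6] on 2,000 homogeneous
NB(20, 5) windows. Because a sum of n i.i.d. NB(μ, r) draws is
NB(nμ, nr), calls on pooled replicate counts use dispersion n·r̂.
Maximum-likelihood refinement was considered and omitted: at the
pooled-window sizes involved the moment estimator is already within
the acceptance band, and it keeps the fit closed-form.

## Cross-tissue and expression statistics

Ubiquity partitions the universe into methylated-in-all (∩ called),
unmethylated-in-all (∩ not-called) and tissue-differential (rest);
tissue-specific proportion = differential / (differential +
methylated-in-all). Pairwise similarity reports |A∩B|/|A|, |A∩B|/|B|
and Jaccard, all labelled, because the published two-triangle layout
does not disambiguate its statistic. Gene-level promoter/body calls
reuse the empirical-FDR RPKM method at feature granularity over the
gene universe. Repeat-class enrichment compares each class's share of
methylated bp (union of called windows) with its share of genome bp.

The bias score uses linear-scale expression (the input scale is the
caller's responsibility; log-input would change the score, and linear
is the assumed convention here). Deciles are rank-based with stable
tie-breaking, so all-equal inputs still split 10 ways evenly.
Mann-Whitney uses exact enumeration when both groups are ≤ 20 with no
ties, otherwise the tie-corrected normal approximation; the exact
branch is asserted against full enumeration at n ≤ 8. The sign test
is the exact two-sided binomial with ties dropped. Tissue clustering
is complete linkage on 1 − Pearson r, serialized as newick; a
zero-variance column is an error naming the column.

## Bisulfite module

Forward-strand C at i: CG if s[i+1]=G, else CHG if s[i+2]=G, else CHH;
the reverse strand symmetrically on the reverse complement. Cs whose
context window runs past the sequence end (or contains N) are counted
as cytosines but excluded from context tallies. In aligned clones a
reference C read as C is methylated, as T unmethylated (G/A on the
reverse strand); anything else is excluded. Percentages are computed
per clone and then averaged over the clone set — pooling all cytosines
first would weight clones by coverage instead. Multiple alignment is
out of scope; a sliding end-gap-free placement utility (conversion-
aware match scoring) is provided for unaligned single clones.
Validation regresses per-target % methylation on window RPKM and on
maximum per-bp coverage (unique track) by ordinary least squares.

## Synthetic study generator

The generator emulates the design of a seven-tissue survey at desk
scale, and its defaults are the package's study conditions: 5
chromosomes × 200 kb; 200 genes in regular slots on the chromosome
arms (1.5–2.5 kb, 1–5 exons, UTRs 100–400 bp, random strand);
interspersed exact-copy repeat families (LTR-gypsy, LTR-copia,
LINE-L1, hAT) so their 32-mers multi-map by construction; a
centromere-like satellite-dense 20 kb block at each chromosome
midpoint; a 20 kb organelle contaminant genome; 7 tissues × 2
replicates plus 4 input lanes; 50k reads/sample; clonal duplicate rate
0.2 and organelle contamination 0.05. Methylation truth: 2% of
windows methylated in every tissue and 5% per tissue specifically
(≈34% differential overall), plus gene-level promoter/body truth sized
so ≈17% of genes are promoter- and ≈15.6% body-methylated in at least
one tissue. Counts: input ~ NB(20, r = 5) per window, MeDIP ~
NB(20 × 8, r = 5) in methylated windows (r = None gives Poisson);
read-level simulation draws 32-mer starts window-weighted with
per-replicate gamma-perturbed intensities so replicate counts are
NB-like. Expression: log-normal baseline (log-mean 4, log-sd 1),
per-tissue log-normal noise (sd 0.2), 10 biased genes per tissue
(×20, comfortably above the 0.9 bias threshold), promoter methylation
×0.5 and body methylation ×0.25 — body repression deliberately the
stronger effect.

Each sample has its own RNG stream derived from the master seed and
the sample name, so output is byte-identical under a fixed seed and
stable under sample re-ordering.

What the generator does **not** emulate: sequencing errors and base
qualities, GC/CpG-density bias, mappability structure beyond planted
repeats, fragment-length effects, partial methylation levels (truth is
binary per window), and microarray measurement noise structure.
Passing calibration here therefore demonstrates the statistics behave
as specified under their own model assumptions, not that real tissue
data meets those assumptions.

### Calibration readings

Null calibration draws each caller's null from its own input model:
Poisson counts for the CPPD test, NB counts (dispersion re-fit from
replicates) for the NB test, exchangeable NB counts for the RPKM scan.
Measured at 20,000 windows × 7 tissues, false-call rates are well
under 2× nominal for CPPD and NB, and the RPKM scan either finds no
admissible cutoff (the designed outcome for exchangeable data) or
calls ≈ 0 windows.

On fold-8/dispersion-5 truth (20,000 windows), CPPD attains recall
≈ 0.997 with observed FDR ≈ 0.02 — the input floor at the genome mean
absorbs most of the overdispersion the Poisson tail does not model.
The RPKM caller's recall is ≈ 0.70–0.80 with observed FDR 0: the
input-lane difference null inherits the NB(20, 5) per-lane variance
(CV 0.5), and the 100:1 rule pushes the cutoff into the same range as
the enriched-window differences. This is a real property of the
empirical-FDR procedure at these noise levels, and the package reports
the measured values rather than masking them; with deeper or
less-dispersed input lanes the cutoff drops and recall rises.

## Problem sizes used by the test suite and acceptance script

Caller calibration runs on 20,000-window count-level studies;
dispersion recovery on 2,000 windows × 2 replicates; end-to-end
read-level runs use the default genome with 10,000 reads/sample
(enough for a well-posed cutoff scan at 1,000 windows); the
determinism check runs the full pipeline twice at that size. These
sizes were chosen to keep the whole suite in the low minutes while
leaving every statistic in a regime where its expected behaviour is
unambiguous.

## Known limitations

- Exact-match alignment understates mappability relative to
  2-mismatch alignment; percent-mapped on real data will differ.
- One fitted dispersion per tissue ignores mean-dependence of
  overdispersion; the stratified option mitigates but a full
  mean-dispersion trend (as RNA-seq packages fit) is out of scope.
- The empirical-FDR scan's resolution is its grid step, and its cutoff
  is sensitive to input-lane noise (see calibration readings).
- Gene-level calls inherit the window method's properties; no
  peak-shape or CpG-density modelling is attempted.
- Expression values are taken as already normalized on a linear scale.
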