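# Methods

## The question and the model

Droplet scRNA-seq reads carry a cell barcode (droplet of origin) and a UMI
(molecule of origin). Given a high-confidence somatic variant list from
bulk WES, each read overlapping a variant site supports either the
reference or the alternate allele, so variants can be genotyped per cell —
but transcript capture is sparse, most cells show no coverage at most
sites, and PCR duplicates inflate read counts. The package therefore works
at two levels: per-cell molecule counts (for display and labeling) and
pooled group-level proportions (for inference).

### UMI consensus

Reads sharing a (cell barcode, site, UMI) triple are treated as PCR/optical
duplicates of one cDNA molecule. The molecule's allele is the **strict
majority** of its reads' observed alleles; an exact tie, or a majority of
"other" (neither ref nor alt), discards the molecule. Discards are counted,
so for every (cell, site):

    ref_molecules + alt_molecules + discarded_umis = distinct UMIs observed.

Strict majority with tie-discard is the conservative choice: it never
manufactures evidence from conflicting duplicates. Barcode equivalence is
exact string match — barcode error correction belongs to the upstream
demultiplexer. A raw-read mode (`collapse=False`) is provided because the
upstream convention (reads vs molecules) is a legitimate degree of freedom;
molecules are the default everywhere. Coordinates are 1-based (VCF
convention); an optional SAM/BAM adapter builds the observation table by
pileup at the variant positions using CB/UB-style tags (SNVs only).

### The difference-of-proportions test

For a contrast of groups T and N, counts are pooled over cells and sites:
X = alt molecules, N = alt + ref molecules. With P_T = X_T/N_T,
P_N = X_N/N_N, P_avg = (X_T+X_N)/(N_T+N_N), Q_avg = 1 − P_avg:

    Z = (|P_T − P_N| − (1/N_T + 1/N_N)/2) / (P_avg · Q_avg · √(1/N_T + 1/N_N))

p is the one-sided upper-tail standard-normal probability of Z. The test is
**only performed when P_T > P_N is actually observed**; contrasts with
P_T ≤ P_N are skipped with a reason, which keeps them out of the FDR
denominator. Degenerate pooled proportions (P_avg ∈ {0,1}) and zero-coverage
groups are likewise skipped, never raised. The classical normality
heuristic — N·P_avg·Q_avg ≥ 5 in both groups — is evaluated and attached as
a flag (`normal_approx_ok`), not used to drop tests: flagged results remain
visible to the analyst. Benjamini–Hochberg q-values are computed across the
performed tests of one invocation.

**Variance forms.** The formula above, the package default
(`variance_form="printed"`), places the pooled factor P_avg·Q_avg *outside*
the square root. The classical pooled two-proportion statistic uses
√(P_avg·Q_avg·(1/N_T+1/N_N)) instead (`variance_form="pooled"`). Since
P_avg·Q_avg ≤ 1/4, the default denominator is smaller than the classical
one by a factor √(P_avg·Q_avg) ≤ 1/2, so its Z scores are inflated at least
two-fold and grow as P_avg approaches 0 or 1. The consequence is measurable:
under a simulated null (equal mapping rates), the default form rejects
17–29% of contrasts at α = 0.05, while the pooled form — helped by the
continuity correction and the one-sided skip rule — is conservative
(rejection 2–4%, about half the contrasts skipped). Calibration claims in
this package (and its null-calibration checks) therefore refer to the
pooled form; the default form is kept for comparability of Z magnitudes
with analyses that use the same expression, and both are one switch apart.
With planted effects as large as those simulated here, both forms give the
same qualitative answer.

### Variant filtering

The somatic consensus filter applies, with every threshold configurable and
every comparison implemented exactly as written:

| rule | keep when |
|---|---|
| caller support | ≥ 2 callers, within the class set (SNV: strelka/varscan/mutect; indel: strelka/varscan/pindel) |
| tumor depth | ref+alt ≥ 14 |
| normal depth | ref+alt ≥ 8 |
| tumor VAF | alt/(ref+alt) ≥ 0.05 (boundary passes) |
| normal VAF | alt/(ref+alt) ≤ 0.02 (boundary passes) |
| indel length | abs(len(ref) − len(alt)) < 100 (100 fails) |
| region | exonic |
| databases | not (in dbSNP and not in COSMIC) |

"Depth" means ref+alt (bam-readcount-style biallelic convention) rather
than total pileup depth; the germline filter requires alt depth ≥ 5 and alt
fraction ≥ 0.20 in *both* tumor and normal (boundaries pass), a coding
location, and population frequency < 0.0005 (0.0005 fails). Zero depth in
either sample makes the VAF undefined; the record fails with reason
`no-depth` rather than crashing. The fail table lists *every* violated rule
per record, so pass ∪ fail partitions the input and the decision can be
re-derived from the report. dbSNP/COSMIC/exonic status are consumed as
boolean annotations — database matching is upstream. Multi-allelic VCF rows
are rejected; split them first. Hotspot genotyping reports, per non-reference
base b with coverage, VAF = count(b)/(count(b)+count(ref)) — the per-allele,
not total-depth, denominator — and a locus with no ref or alt coverage is
reported as missing rather than 0.

### Hierarchical labels

Cells carrying several alterations get one display label: any mutation
outranks any copy-number event; within a kind the gene order
KRAS > CDKN2A > SMAD4 > TP53 applies, and genes outside the order rank
after it alphabetically. Deep copy-number events are values ≥ 2.0 (gain) or
≤ 0.25 (loss) on a copy-number-like scale where 1.0 is neutral — "more than
one copy" on a continuous expression-derived scale is inherently fuzzy, so
both cut-offs are configuration, and log-ratio inputs are first converted
as 2^x under a declared-scale switch rather than guessed.

### Expression programs

QC removes a barcode violating any of: total counts < 300, genes < 200,
UMIs < 1,000, genes > 10,000, UMIs > 10,000, mitochondrial fraction
strictly > 10% (exactly 10% is kept). In droplet data total counts and
UMIs are the same number; both thresholds are applied independently as
stated, making 1,000 the effective floor. Normalization is per-cell
depth-scaling to the median depth followed by log1p — a deterministic
stand-in for heavier variance-stabilizing transforms, adequate because all
downstream checks compare groups within one normalized matrix.

Cluster markers: two-sided Wilcoxon rank-sum (tie-corrected normal
approximation, via `scipy.stats.mannwhitneyu`) on the normalized layer,
restricted to genes with max(pct_in, pct_out) ≥ min.pct (global profile
0.25; subcluster profile 0.10 plus pct_in − pct_out ≥ 0.10) and positive
log fold change, where log_fc is the natural-log ratio of
(mean expm1(normalized) + 1). Adjustment is Bonferroni over all genes in
the matrix (BH available), and the returned table keeps adjusted p < 0.05
sorted by descending fold change.

Over-representation: upper-tail hypergeometric — drawing n DEGs from a
universe of M detected genes (detected in > 0.1% of cells) of which K
belong to the set, p = P(overlap ≥ k) — BH-adjusted across sets. Pathway
scores: clusters holding < 0.1% of cells are excluded; a pathway's member
genes are the union, over clusters, of the overlap genes from its
significant (adjusted p < 0.05) enrichments (interpreting "genes shown as
enriched" as the contributing overlap genes; whole-set membership is one
switch away); score(pathway, cluster) is the mean normalized expression of
member genes over the cluster's cells, and each pathway row is centered and
scaled across clusters with the sample (n−1) standard deviation. Constant
rows become zeros and are flagged. Pathways are ranked by the number of
clusters in which they were significant.

A cluster is **spatially distinct** iff ≥ 95% of its cells come from one
sample and that sample lies ≥ 6 mm from *every* other sample contributing
cells (both boundaries inclusive; the all-others reading is the stricter of
the two possible readings of "6 mm from another sample" and is the one
implemented). Bulk counts are transformed as
FPKM-UQ = count·10⁹/(length·UQ), UQ being the per-sample 75th percentile of
counts over expressed protein-coding genes, then log2(x+1); a sample with
zero UQ is reported unusable.

### Arm-level CNV

Genes map to arms by the leading p/q of their cytoband (or by coordinates
against centromere positions); contradictory assignments raise, unmapped
genes are listed and excluded. The arm value is the unweighted mean of the
arm's mapped genes — no length weighting — making it exactly linear: adding
δ to every gene on an arm moves the arm value by exactly δ.

## The synthetic cohort

The generator emulates the *statistical* structure the pipeline consumes,
not transcriptome biology. Defaults (all configurable, all outputs a
deterministic function of the seed via per-component `default_rng([seed,
stream])` streams):

- **Cells**: 800 tumor, 600 PanIN, 400 ADM, 600 normal-duct, 600 acinar
  (~3,000). Tumor cells split into 4 balanced subclusters; subcluster c0 is
  planted spatially distinct (96% from a sample 10 mm away at (10, 0) mm),
  c1 draws 96% from a sample only 2 mm away (fails the distance rule), the
  rest mix samples.
- **Mutation mapping**: per cell and site, one alt molecule with probability
  0.30 (tumor) / 0.15 (PanIN) / 0.01 (others) — tumor and normal rates as
  studied in the recovery analyses, PanIN intermediate so the
  tumor > PanIN > normal significance ordering is a planted truth — and
  Poisson(0.5) reference molecules so totals are never structurally zero.
  Molecules emit 1 + Geometric(0.3) duplicate reads sharing a UMI; each
  read flips its observed allele with probability 0.01 (to one of the other
  two states), creating the within-UMI conflicts the consensus rule must
  resolve.
- **Call sets**: 1,000 (configurable) random records spanning every filter
  branch, plus a deterministic block of exact boundary records (VAF
  0.05/0.025, 1/50 and 1/30 normal VAFs, depths 14/13 and 8/7, indel
  lengths 99/100, single-caller, dbSNP-not-COSMIC, zero depth). Intended
  pass/fail is recorded by an independent plain if-chain at generation
  time.
- **Expression**: negative-binomial counts (size 2), gene means lognormal
  scaled to ~2,500 counts/cell, per-cell lognormal depth (σ = 0.25); each
  tumor subcluster's 50 planted program genes are upshifted by log2FC = 2;
  ten "MT-" genes carry a few percent of counts. Six extra barcodes violate
  specific QC rules (low counts, few genes, ~15,000 UMIs, high mito) and
  are recorded in ground truth.
- **CNV**: gene values 1.0 + N(0, 0.05); arm events +0.5 on 8q and −0.5 on
  18q in tumor cells (classic PDAC-like arm lesions); deep focal events
  (AKT2 ≈ 2.5, CDKN2A ≈ 0.05) in 15% of tumor cells feed the labeler.
  Driver genes sit on their real arms (KRAS 12p, CDKN2A 9p, SMAD4 18q,
  TP53 17p, AKT2 19q).
- **Gene sets**: one GMT set per planted program plus random filler sets,
  50 total.

What the generator does **not** emulate: ambient RNA, doublets, barcode
collisions or sequencing-error structure beyond the uniform allele flip,
gene–gene correlation, batch effects, realistic chromosomal gene ordering,
or expression–CNV coupling. Passing tests therefore demonstrate that the
algorithms recover what they are defined to recover under controlled,
known-truth conditions — not that any biological claim about real tissue is
reproduced. Real-cohort significance values depend on per-cell counts that
are not public and are reproduced only qualitatively (the ordering of
contrasts) on planted rates.

## Numerical and scale choices

- Problem sizes used by the validation suite and `scripts/acceptance.py`:
  the ~3,000-cell default cohort for end-to-end runs; 1,000 random count
  configurations against a 50-digit mpmath reference for formula fidelity
  (relative error observed ~1e-12, bound 1e-10); 10,000 null contrasts with
  group totals 50–2,000 at rate 0.05 for calibration; 100 replicates of a
  500 + 500-cell two-group cohort for planted-enrichment recovery
  (q < 0.01 required in ≥ 95); 10,000 records per filter engine against the
  brute-force oracle; exhaustive hypergeometric enumeration for all
  universes ≤ 20; 50 replicates of a 400-tumor-cell, 4-subcluster cohort
  for pathway-score recovery.
- Ties in the hierarchical labeler are impossible by construction (total
  order over kind, then gene rank, then kind name).
- Empty inputs return empty tables; zero-coverage and degenerate cases
  return reasons, not exceptions.
- BH is applied across whatever family one invocation computes: performed
  contrasts for the enrichment model, gene sets for one ORA call.
- q-values and p-values are reported as computed; p underflows to 0.0 in
  double precision for the default cohort's contrasts, which is the honest
  double-precision answer (Z > 100).

## Known limitations

- The default variance form is anticonservative under the null (see above);
  use `variance_form="pooled"` when calibrated error rates matter.
- Pooling X/N over cells treats molecules as independent Bernoulli draws;
  cells contributing many molecules violate that mildly. At the planted
  effect sizes this does not change any qualitative conclusion.
- The SAM adapter genotypes SNVs only and does no indel realignment,
  phasing, or barcode correction.
- The normalization layer is a library-size transform, not a
  variance-stabilizing regression; marker p-values on real data would
  differ from a pipeline built on such a transform.
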