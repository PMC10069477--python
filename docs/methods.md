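# Methods

This note documents the models, conventions and design choices behind
`pgxpanel`, in the order the pipeline runs.

## Data model and conventions

Coordinates are 1-based inclusive (VCF convention); alleles are stored on
the + genomic strand. `cds_pos` is 1-based on the transcript strand; codon
index = ⌈cds_pos/3⌉ and position-in-codon = ((cds_pos−1) mod 3)+1, matching
HGVS cDNA numbering. Codon-level operations reverse-complement alleles for
minus-strand transcripts. Missing annotation cells ("." or empty) are
represented as *absent* map entries, never sentinel numerics, so downstream
stages can distinguish "no prediction" from "score 0". The annotation-table
column dialect is configuration, with ANNOVAR/dbNSFP-style defaults, because
annotation pipelines disagree on column naming. Inputs must be biallelic per
row; no liftover or indel re-normalization is attempted.

Genotypes ingest from VCF 4.x through pysam: `0/1` → dosage 1 unphased,
`1|0` → dosage 1 with the alt on haplotype 1, `0|1` → haplotype 2, `./.` →
missing; non-diploid GT fields are rejected.

## Composite pathogenicity score

Per-algorithm thresholds (LRT, MutationAssessor, PROVEAN, VEST3, CADD) ship
as a YAML config with dbNSFP-convention defaults (LRT ≤ 0.0025,
MutationAssessor ≥ 1.935, PROVEAN ≤ −2.5, VEST3 ≥ 0.45, CADD phred ≥ 15);
they are deliberately configuration, not constants, because optimized
cutoffs are study-calibrated, and every scoring run logs the thresholds in
effect. The boundary counts as deleterious (inclusive), mirroring the
inclusive composite cutoff C ≥ 0.6. Missing scores: the composite averages
over available predictors with a minimum of 3; below that the variant is
*unscorable* (a value, not an error) and is excluded from arm A with a
logged warning. Averaging over available calls keeps the composite on the
[0,1] scale regardless of availability. The score applies to single-SNV
missense variants only; merged MNVs are outside its domain by construction.

## Filtering

Rarity consults the **maximum** frequency across the configured reference
panels (global + Latino by default) with a strict `< 0.01` cutoff — the
conservative reading of "MAF below 1%". A variant with no frequency entry in
any consulted panel and no dbSNP identifier is *novel*; novel implies rare.
The splice rule defaults to `both`: every available ADA/RF score must reach
0.6, and when only one score is present that one decides (the `either` mode
is available since the published combination logic is ambiguous).
`splice_site` consequences are decided by the ADA/RF rule and counted as the
splice subcategory; only nonsense and frameshift take the LoF subcategory,
so the two tallies stay separate. PharmGKB sub-tier strings (1A, 1B, 2A, 2B)
map to their leading numeric tier; tiers 1–3 qualify, tier 4 and
unrecognized strings never do (logged). B-over-A precedence keeps the arms
disjoint so arm counts add to the retained total. Each decision's reasons
chain (rule, observed value, outcome) is sufficient to recompute the arm,
and `replay_arm` does exactly that; tests assert replay equals the original
on whole simulated cohorts.

## MNV re-annotation

Detection scope is intra-codon only: only same-codon pairs change the
protein consequence jointly, which is what re-annotation corrects.
Cross-codon adjacent pairs are not merged. Cis configuration requires
phased genotypes placing both alt alleles on one haplotype (hom-alt calls
count as both); shared carriers without phase yield `phase_evidence =
unknown` and are emitted for manual review — no statistical phasing is
attempted, mirroring the practice of resolving such cases experimentally.
Pairs only ever observed in trans are reported separately. Translation uses
the standard genetic code (table 1; these are nuclear pharmacogenes) via
Biopython; the test suite carries an independent frozen codon table and
checks all 64 codons × all single and adjacent double substitutions. The
merged HGVS is `c.<min>_<max>delins<joint alt bases>` in cDNA orientation.
Category logic on (component consequences → merged consequence): component
stop resolving to non-stop = rescued nonsense; merged stop with no
component stop = gained nonsense; merged amino acid equal to reference =
synonymous rescue; two missense components merging to a third amino acid =
changed missense.

## Population genetics

HWE uses the plain 1-df χ² goodness-of-fit test without continuity
correction, with expected counts from the sample allele frequencies. An
exact test (conditional distribution of heterozygote counts, log-factorial
form) ships alongside as the low-count oracle and optional mode; the test
suite carries a second, fully independent exact-rational implementation.
Monomorphic variants make the test undefined and are flagged, not counted
as HWE failures. Chi-square and exact decisions can disagree near the α =
0.05 boundary at low counts; the comparison tests accept disagreements only
when the exact p lies in a pre-declared band [α/10, 10α] and log them.

The 2×2 cohort-vs-reference comparison applies the Yates continuity
correction clipped at the expected value, Σ(max(0, |obs−exp|−0.5))²/exp —
the standard convention (identical to scipy's), under which a table with
observed = expected scores exactly 0. Bonferroni uses m = the number of
comparisons actually executed in the run, reported in the output, since the
appropriate family size depends on the analysis. Reference populations are
supplied as allele-count columns (AC/AN) in the annotation table; no
network access. Expected cells below 1 trigger a warning recommending an
exact test. Fold change with a zero reference frequency is reported as
undefined rather than infinite. Significance is α = 0.05 throughout.

The sample-size operation implements the finite-population-corrected
formula for estimating a proportion, n = ⌈(z²p(1−p)/e²)/(1 +
z²p(1−p)/(e²N))⌉; at the default planning parameters (z = 1.96, p = 0.16,
e = 0.03, N = 574) it returns 287.

## Reporting

Percentages are round-half-away-from-zero to one decimal (Decimal
arithmetic, not float), the convention that reproduces standard published
tally arithmetic such as 123/148 → 83.1. Denominators: arm and category
shares over the retained total; per-gene shares over the rare-missense
count; strategy-B breakdown over |B|; HWE share over the number of testable
variants. Zero denominators render blank. Summaries are order-invariant and
rendering is deterministic. An optional exclusions mapping (variant key →
reason) drops manually invalidated variants — e.g. a sequencing false
positive caught by orthogonal validation — before tallying, with a log
line, preserving the audit trail. A merged MNV counts once, under its
merged consequence.

## Synthetic cohort generator

The generator emulates a cohort of diploid individuals genotyped at panel
variants. Per variant with MAF q and deviation coefficient F, genotypes are
drawn i.i.d. from (p²+Fpq, 2pq(1−F), q²+Fpq), clipped and renormalized;
F = 0 gives exact HWE sampling. Defaults are the study conditions the
pipeline was built around: 625 individuals; 123 rare/novel deleterious
missense, 8 LoF, 4 deleterious splice, 13 actionable and 50 common-neutral
variants; rare MAFs log-uniform on [10⁻⁴, 9×10⁻³] (log-uniform because rare
allele frequencies span orders of magnitude), common/actionable MAFs
uniform on [0.02, 0.5]; 13% of rare missense variants novel (no reference
frequencies, no dbSNP id); one RYR1 codon-3376 cis MNV pair with one
carrier. Reference-panel frequency columns are drawn within ±40% of the
cohort MAF (capped below 1% for rare variants) with AC/AN pairs at
gnomAD-scale denominators (250 000 global / 35 000 Latino).

Predictor scores are drawn a non-degenerate margin beyond (deleterious
regime) or short of (neutral regime) each configured threshold — 10–30% of
the threshold scale — so truth labels are recoverable by construction and
threshold-agnostic. The truth table records each variant's category, MAF,
regime and intended filter arm.

A minimal transcript model (gene → chromosome, strand, CDS length,
designated codons; RYR1 codon 3376 designated GAA) ships as a packaged
fixture; undesignated codons get a deterministic non-stop pseudo-codon
hashed from (gene, index). Strands follow the genes' real orientations so
minus-strand allele handling is exercised. One root seed drives a single
NumPy Generator; identical configs produce byte-identical outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequencing and variant-calling error, linkage
disequilibrium beyond injected cis pairs, realistic site-frequency spectra
or per-gene mutation-rate variation, predictor-score correlation structure
(real predictors are highly correlated; simulated regimes are drawn
independently per algorithm), population substructure and admixture, and
star-allele/CNV complexity (e.g. CYP2D6). Recovery results are therefore
statements about the pipeline's logic, not about predictor accuracy on real
variants.

## Problem sizes

The test suite and acceptance script use: exhaustive 2⁵ enumeration for the
composite score; all 64×(12+2×16) codon substitutions for re-translation;
10⁴ simulated variants at n = 625 for HWE type-I calibration; 1 000 random
low-count tables for chi-square/exact concordance; 1 000 random 2×2 tables
for the Yates formula; and a 200-variant, 625-individual cohort for filter
recovery. These sizes give stable statistics (type-I error within ±0.01 of
0.05 across seeds) while keeping the whole suite under ~10 seconds.

## Known limitations

Upstream read alignment, variant calling and QC are out of scope; inputs
are assumed pre-normalized and biallelic per row. No ancestry inference, no
linkage statistics, no star-allele calling, no live PharmGKB/ClinVar
queries, no ACMG classification. The composite score does not re-compute
raw predictor scores and cannot score merged MNVs. The exact HWE test is
two-sided in the "sum of less-probable tables" sense; other exactness
conventions (mid-p) are not offered.
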