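# pgxpanel

Pharmacogenomic variant profiling for a 14-gene anesthesia panel.

Adverse reactions to anesthetic and analgesic drugs — malignant hyperthermia
under volatile anesthetics, opioid toxicity, altered midazolam or propofol
metabolism — are strongly shaped by germline variation in a small set of
pharmacogenes (*RYR1*, *CACNA1S*, *COMT*, *OPRM1*, *CYP2B6*, *CYP3A5*,
*ABCB1*, …). `pgxpanel` implements, as a tested and reusable pipeline, the
variant-profiling analysis used to characterize such a panel from cohort
sequencing data: two-arm variant filtering, ensemble composite pathogenicity
scoring, haplotype-aware re-annotation of intra-codon multi-nucleotide
variants (MNVs), and population-genetics statistics. A built-in synthetic
cohort generator produces annotated variant sets and diploid genotypes with
known truth labels, so every stage is testable without access to protected
cohort data.

It is aimed at researchers analyzing gene-panel or exome variant calls for
pharmacogenomic profiling who want the filtering and statistical logic as an
auditable library rather than a spreadsheet.

## Methods at the core

**Two-arm filtering.** Arm A admits novel or rare variants — MAF < 1%
(strict) in every consulted reference panel (gnomAD-style global + Latino
columns by default) — with evidence of functional impact: missense SNVs
classified functionally relevant by the composite score below,
loss-of-function consequences (nonsense, frameshift), and splice-site
variants with ADA/RF ensemble scores ≥ 0.6. Arm B admits clinically
validated variants (PharmGKB evidence levels 1–3, including sub-tiers
1A/1B/2A/2B, and/or ClinVar drug-response status) regardless of frequency or
consequence class. The arms are disjoint: a dual qualifier is assigned to B.
Every decision carries an ordered rule-evaluation chain that replays to the
same arm.

**Composite pathogenicity score (OPF).** For a missense SNV with predictor
scores *s₁…s₅* (LRT, MutationAssessor, PROVEAN, VEST3, CADD), each score is
binarized against a per-algorithm threshold (deleterious side inclusive,
direction configurable), and the composite is the mean of the available
binary calls *bᵢ*:

    C = (1/k) Σ bᵢ ,  k = number of available predictors (k ≥ 3)

A variant is *functionally relevant* when C ≥ 0.6 — with all five predictors
present, exactly when at least 3 call it deleterious.

**MNV re-annotation.** Two SNVs in the same codon carried in cis change the
protein jointly, not independently. The pipeline finds same-codon SNV pairs
with a shared carrier, uses phased genotypes to establish cis configuration,
re-translates the doubly substituted codon (standard genetic code), emits
the merged delins HGVS (e.g. `c.10126_10127delinsTT`) and classifies the
correction (rescued nonsense, gained nonsense, changed missense, synonymous
rescue). The canonical case: *RYR1* codon 3376 GAA with c.10126G>T
(p.Glu3376Ter alone) and c.10127A>T (p.Glu3376Val alone) in cis is really
TTA — p.Glu3376Leu, a rescued nonsense.

**Population genetics.** Per-variant allele/genotype frequencies; HWE by the
1-df χ² goodness-of-fit test (expected n·p², 2npq, n·q²), with an exact test
as low-count oracle; cohort-vs-reference allele-frequency comparison by the
2×2 Pearson χ² with Yates continuity correction and Bonferroni adjustment
(p_adj = min(1, m·p)); fold-change reporting; and the finite-population
sample-size formula n = [z²p(1−p)/e²] / [1 + z²p(1−p)/(e²N)].

## Worked example

```
$ pgxpanel simulate --n-individuals 625 --seed 3 --outdir demo
$ pgxpanel mnv demo/annotation.tsv demo/genotypes.vcf --out demo/mnv.tsv
1 cis MNV candidates, 0 in trans -> demo/mnv.tsv
$ column -t demo/mnv.tsv | cut -c1-110
```

The MNV report contains one merged call:

```
components                      gene  codon  hgvs_c_merged          ref_codon  alt_codon  aa_ref  aa_alt  category          phase_evidence
19:8010125:G>T|19:8010126:A>T   RYR1  3376   c.10126_10127delinsTT  GAA        TTA        E       L       rescued_nonsense  phased_gt
```

i.e. the two component SNVs annotated separately as a stop and a valine
substitution are, on the haplotype, a single Glu→Leu missense. Running the
filter stage on the same cohort:

```
$ pgxpanel filter demo/annotation.tsv --out demo/decisions.tsv
149 of 200 variants retained -> demo/decisions.tsv
```

123 variants land in arm A as rare pathogenic missense, 9 as LoF (including
the MNV's nonsense component, merged downstream), 4 as deleterious splice,
13 in arm B as actionable; the 51 common/neutral background variants are
dropped. `pgxpanel report` then prints the tally table with one-decimal
percentage shares, and `pgxpanel popgen` the per-variant HWE and
reference-comparison columns.

As a library:

```python
from pgxpanel import retranslate_codon, sample_size, SampleSizeParams

retranslate_codon("GAA", [(1, "T"), (2, "T")])   # ('TTA', 'E', 'L')
sample_size(SampleSizeParams(z=1.96, p=0.16, e=0.03, N=574))  # 287
```

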