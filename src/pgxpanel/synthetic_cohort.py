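"""Synthetic annotated-variant and genotype-cohort generator.

Generates the inputs the downstream analysis expects — an annotation table,
a diploid genotype matrix (optionally phased) and a truth table — with the
statistical structure the pipeline assumes: per-variant genotypes drawn from
Hardy–Weinberg proportions with an optional inbreeding-like deviation
coefficient F (p² + Fpq, 2pq(1−F), q² + Fpq), predictor scores drawn from a
deleterious or neutral regime relative to the configured OPF thresholds, and
adjacent-SNV MNV pairs injected with known phase.

Defaults mirror the study conditions the pipeline was built for: a cohort of
625 diploid individuals genotyped at a 14-gene anesthesia panel, with 123
rare/novel deleterious missense variants, 8 loss-of-function, 4 deleterious
splice-site, 13 clinically actionable and 50 common neutral background
variants, genotypes in HWE (F = 0), and one RYR1 codon-3376 cis MNV carrier.

The transcript model is a minimal packaged fixture (gene → chromosome,
strand, CDS length, designated reference codons); real transcript databases
are never consulted. One root seed drives a single pseudo-random stream.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .data_model import (
    MISSING,
    PHASE_HAP1,
    PHASE_HAP2,
    PHASE_UNPHASED,
    AnnotationDialect,
    GenePanel,
    GenotypeMatrix,
    VariantRecord,
    default_panel,
    revcomp,
    write_annotation_table,
)
from .mnv_reannotation import consequence_of, retranslate_codon
from .opf_scoring import HIGHER, PredictorThresholds, default_thresholds

logger = logging.getLogger("pgxpanel")


class SimulationConfigError(ValueError):
    pass


class InjectionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Minimal transcript model (packaged fixture)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """Desk-scale transcript: strand, CDS anchor and designated codons.

    ``cds_start`` is the genomic position of CDS base 1 on the + strand for
    plus-strand transcripts; for minus-strand transcripts the CDS runs
    leftward from ``cds_start``. Codons not designated explicitly get a
    deterministic pseudo-codon (never a stop) derived from (gene, index).
    """

    gene: str
    transcript_id: str
    chrom: str
    strand: str
    cds_start: int
    n_codons: int
    designated_codons: Mapping[int, str] = field(default_factory=dict)

    def genomic_pos(self, cds_pos: int) -> int:
        if not 1 <= cds_pos <= 3 * self.n_codons:
            raise ValueError(f"cds_pos {cds_pos} outside CDS of {self.gene}")
        if self.strand == "+":
            return self.cds_start + cds_pos - 1
        return self.cds_start - (cds_pos - 1)

    def cds_pos_from_genomic(self, pos: int) -> int:
        if self.strand == "+":
            cds = pos - self.cds_start + 1
        else:
            cds = self.cds_start - pos + 1
        if not 1 <= cds <= 3 * self.n_codons:
            raise ValueError(f"genomic position {pos} outside CDS of {self.gene}")
        return cds

    def codon(self, index: int) -> str:
        if index in self.designated_codons:
            return self.designated_codons[index]
        h = zlib.crc32(f"{self.gene}:{index}".encode())
        return _NONSTOP_CODONS[h % len(_NONSTOP_CODONS)]


_BASES = "ACGT"
_NONSTOP_CODONS = tuple(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
)


def default_transcripts() -> dict[str, TranscriptModel]:
    """Transcript fixtures for the 14-gene panel.

    Chromosomes and strands follow the genes' actual orientations; CDS
    anchors are synthetic, spaced so panel genes never collide. RYR1 codon
    3376 is designated GAA (Glu) so that cDNA positions 10126/10127 reproduce
    the canonical intra-codon MNV site.
    """
    spec = [
        # gene, transcript, chrom, strand, n_codons
        ("ADRB2", "NM_000024", "5", "+", 413),
        ("CACNA1S", "NM_000069", "1", "-", 1873),
        ("COMT", "NM_000754", "22", "+", 271),
        ("KCNJ6", "NM_002240", "21", "-", 423),
        ("OPRM1", "NM_000914", "6", "+", 400),
        ("POR", "NM_000941", "7", "+", 680),
        ("RHBDF2", "NM_024599", "17", "-", 856),
        ("RYR1", "NM_000540", "19", "+", 5038),
        ("CYP1A2", "NM_000761", "15", "+", 515),
        ("CYP2B6", "NM_000767", "19", "+", 491),
        ("CYP2D6", "NM_000106", "22", "-", 497),
        ("CYP3A4", "NM_017460", "7", "-", 503),
        ("CYP3A5", "NM_000777", "7", "-", 502),
        ("ABCB1", "NM_000927", "7", "-", 1280),
    ]
    models = {}
    offset = 1_000_000
    for i, (gene, tx, chrom, strand, n_codons) in enumerate(spec):
        # leave room for the full CDS on either strand
        anchor = offset * (i + 1) + (3 * n_codons if strand == "-" else 0)
        designated = {3376: "GAA"} if gene == "RYR1" else {}
        models[gene] = TranscriptModel(
            gene=gene, transcript_id=tx, chrom=chrom, strand=strand,
            cds_start=anchor, n_codons=n_codons, designated_codons=designated,
        )
    return models


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MnvInjection:
    gene: str
    codon_index: int
    sub1: tuple[int, str]  # (position-in-codon, alt base) on the cDNA strand
    sub2: tuple[int, str]
    carrier_count: int
    cis: bool = True  # False injects carriers in trans (test mode)


@dataclass(frozen=True)
class SimulationConfig:
    n_individuals: int = 625
    panel: GenePanel = field(default_factory=default_panel)
    n_variants_per_category: Mapping[str, int] = field(
        default_factory=lambda: {
            "rare_missense": 123,
            "lof": 8,
            "splice": 4,
            "actionable": 13,
            "common_neutral": 50,
        }
    )
    rare_maf_bounds: tuple[float, float] = (1e-4, 9e-3)  # log-uniform
    common_maf_bounds: tuple[float, float] = (0.02, 0.5)  # uniform
    hwe_deviation: float = 0.0  # inbreeding-like F in [-1, 1]; 0 = HWE
    deleterious_fraction: float = 1.0
    novel_fraction: float = 0.13  # fraction of rare missense with no prior report
    score_margin: float = 0.1  # relative distance of drawn scores from thresholds
    mnv_injections: tuple[MnvInjection, ...] = (
        MnvInjection("RYR1", 3376, (1, "T"), (2, "T"), carrier_count=1),
    )
    thresholds: PredictorThresholds = field(default_factory=default_thresholds)
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1:
            raise SimulationConfigError("n_individuals must be positive")
        if any(c < 0 for c in self.n_variants_per_category.values()):
            raise SimulationConfigError("variant counts must be >= 0")
        for p in (self.deleterious_fraction, self.novel_fraction):
            if not 0.0 <= p <= 1.0:
                raise SimulationConfigError(f"probability {p} outside [0,1]")
        if not -1.0 <= self.hwe_deviation <= 1.0:
            raise SimulationConfigError("hwe_deviation outside [-1,1]")
        for inj in self.mnv_injections:
            if inj.carrier_count > self.n_individuals:
                raise SimulationConfigError(
                    f"MNV carrier_count {inj.carrier_count} exceeds cohort size "
                    f"{self.n_individuals}"
                )


# ---------------------------------------------------------------------------
# Simulation internals
# ---------------------------------------------------------------------------


def genotype_probabilities(q: float, f: float) -> np.ndarray:
    """Genotype distribution (hom-ref, het, hom-alt) with deviation F."""
    p = 1.0 - q
    probs = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
    probs = np.clip(probs, 0.0, None)
    return probs / probs.sum()


def _draw_score(rng, thr, deleterious: bool, margin: float) -> float:
    """Draw a predictor score a non-degenerate margin away from its threshold."""
    scale = max(abs(thr.threshold), 1.0)
    lo, hi = margin * scale, 3 * margin * scale
    offset = rng.uniform(lo, hi)
    toward_deleterious = 1.0 if thr.direction == HIGHER else -1.0
    sign = toward_deleterious if deleterious else -toward_deleterious
    return thr.threshold + sign * offset


class _CodonAllocator:
    """Hands out unique codon indices per gene so positions never collide."""

    def __init__(self, transcripts, rng):
        self._free = {
            g: list(rng.permutation(np.arange(1, t.n_codons + 1)))
            for g, t in transcripts.items()
        }

    def take(self, gene: str) -> int:
        if not self._free[gene]:
            raise SimulationConfigError(f"codon pool exhausted for {gene}")
        return int(self._free[gene].pop())

    def reserve(self, gene: str, index: int) -> None:
        try:
            self._free[gene].remove(index)
        except ValueError:
            pass


def _missense_substitution(codon: str, rng) -> tuple[int, str, str]:
    """Pick (pos_in_codon, ref_base, alt_base) giving a missense change."""
    for pos in rng.permutation([1, 2, 3]):
        ref_base = codon[pos - 1]
        for alt in rng.permutation([b for b in _BASES if b != ref_base]):
            _, aa_ref, aa_alt = retranslate_codon(codon, [(int(pos), str(alt))])
            if consequence_of(aa_ref, aa_alt) == "missense":
                return int(pos), ref_base, str(alt)
    raise SimulationConfigError(f"no missense substitution exists for codon {codon}")


def _synonymous_substitution(codon: str, rng) -> Optional[tuple[int, str, str]]:
    for pos in (3, 2, 1):
        ref_base = codon[pos - 1]
        for alt in rng.permutation([b for b in _BASES if b != ref_base]):
            _, aa_ref, aa_alt = retranslate_codon(codon, [(pos, str(alt))])
            if aa_ref == aa_alt:
                return pos, ref_base, str(alt)
    return None


def _genomic_alleles(t: TranscriptModel, ref_t: str, alt_t: str) -> tuple[str, str]:
    """Transcript-strand single bases → +-strand VCF alleles."""
    if t.strand == "+":
        return ref_t, alt_t
    return revcomp(ref_t), revcomp(alt_t)


@dataclass
class SimulatedCohort:
    records: list[VariantRecord]
    genotypes: GenotypeMatrix
    truth: pd.DataFrame


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate an annotated variant set, genotype cohort and truth table.

    The truth table records, per variant, the intended category, configured
    MAF, score regime, and the filter arm/subcategory the generator built the
    variant to satisfy — the reference for recovery tests.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    transcripts = default_transcripts()
    alloc = _CodonAllocator(transcripts, rng)
    for inj in config.mnv_injections:
        alloc.reserve(inj.gene, inj.codon_index)

    genes = sorted(config.panel.genes)
    sample_ids = [f"S{i:04d}" for i in range(config.n_individuals)]

    records: list[VariantRecord] = []
    truth_rows: list[dict] = []
    mafs: list[float] = []
    rs_counter = 10_000_000

    def rare_maf() -> float:
        lo, hi = np.log(config.rare_maf_bounds[0]), np.log(config.rare_maf_bounds[1])
        return float(np.exp(rng.uniform(lo, hi)))

    def common_maf() -> float:
        return float(rng.uniform(*config.common_maf_bounds))

    def ref_panel_annotations(maf: float, novel: bool):
        """gnomAD-style frequency and allele-count columns consistent with MAF."""
        nonlocal rs_counter
        if novel:
            return {}, {}, None
        freqs, counts = {}, {}
        for panel, an in (("gnomad_global", 250_000), ("gnomad_latino", 35_000)):
            f = maf * float(rng.uniform(0.6, 1.4))
            f = min(f, 0.95)
            if maf < 0.01:
                f = min(f, 0.0095)  # a rare variant stays rare in every panel
            ac = max(1, round(f * an))
            freqs[panel] = ac / an
            counts[panel] = (ac, an)
        rs_counter += 1
        return freqs, counts, f"rs{rs_counter}"

    def predictor_scores(deleterious: bool):
        return {
            algo: _draw_score(rng, thr, deleterious, config.score_margin)
            for algo, thr in config.thresholds.algorithms.items()
        }

    counts = config.n_variants_per_category

    # --- rare / novel missense -------------------------------------------
    for _ in range(counts.get("rare_missense", 0)):
        gene = genes[rng.integers(len(genes))]
        t = transcripts[gene]
        codon_idx = alloc.take(gene)
        codon = t.codon(codon_idx)
        pos_in_codon, ref_t, alt_t = _missense_substitution(codon, rng)
        cds_pos = 3 * (codon_idx - 1) + pos_in_codon
        maf = rare_maf()
        novel = bool(rng.random() < config.novel_fraction)
        freqs, ref_counts, rsid = ref_panel_annotations(maf, novel)
        deleterious = bool(rng.random() < config.deleterious_fraction)
        ref_g, alt_g = _genomic_alleles(t, ref_t, alt_t)
        records.append(VariantRecord(
            chrom=t.chrom, pos=t.genomic_pos(cds_pos), ref=ref_g, alt=alt_g,
            gene=gene, transcript=t.transcript_id, consequence="missense",
            strand=t.strand, cds_pos=cds_pos, hgvs_c=f"c.{cds_pos}{ref_t}>{alt_t}",
            ref_codon=codon, predictor_scores=predictor_scores(deleterious),
            ref_freqs=freqs, ref_counts=ref_counts, dbsnp_id=rsid,
        ))
        mafs.append(maf)
        truth_rows.append(dict(
            variant_key=records[-1].key, category="rare_missense", maf=maf,
            regime="deleterious" if deleterious else "neutral", novel=novel,
            expected_arm="A" if deleterious else "none",
            expected_subcategory="rare_missense_pathogenic" if deleterious else ".",
        ))

    # --- loss of function (nonsense / frameshift) ------------------------
    for i in range(counts.get("lof", 0)):
        gene = genes[rng.integers(len(genes))]
        t = transcripts[gene]
        codon_idx = alloc.take(gene)
        maf = rare_maf()
        freqs, ref_counts, rsid = ref_panel_annotations(maf, novel=False)
        if i % 2 == 0:
            # nonsense via a designated stop-generating substitution
            codon, pos_in_codon, ref_t, alt_t = "GAA", 1, "G", "T"  # GAA -> TAA
            cds_pos = 3 * (codon_idx - 1) + pos_in_codon
            ref_g, alt_g = _genomic_alleles(t, ref_t, alt_t)
            records.append(VariantRecord(
                chrom=t.chrom, pos=t.genomic_pos(cds_pos), ref=ref_g, alt=alt_g,
                gene=gene, transcript=t.transcript_id, consequence="nonsense",
                strand=t.strand, cds_pos=cds_pos,
                hgvs_c=f"c.{cds_pos}{ref_t}>{alt_t}", ref_codon=codon,
                ref_freqs=freqs, ref_counts=ref_counts, dbsnp_id=rsid,
            ))
        else:
            cds_pos = 3 * (codon_idx - 1) + 1
            pos = t.genomic_pos(cds_pos)
            records.append(VariantRecord(
                chrom=t.chrom, pos=pos, ref="AG", alt="A",
                gene=gene, transcript=t.transcript_id, consequence="frameshift",
                strand=t.strand, hgvs_c=f"c.{cds_pos + 1}del",
                ref_freqs=freqs, ref_counts=ref_counts, dbsnp_id=rsid,
            ))
        mafs.append(maf)
        truth_rows.append(dict(
            variant_key=records[-1].key, category="lof", maf=maf,
            regime="deleterious", novel=False,
            expected_arm="A", expected_subcategory="lof",
        ))

    # --- deleterious splice-site variants --------------------------------
    for _ in range(counts.get("splice", 0)):
        gene = genes[rng.integers(len(genes))]
        t = transcripts[gene]
        codon_idx = alloc.take(gene)
        pos = t.genomic_pos(3 * (codon_idx - 1) + 1)
        maf = rare_maf()
        freqs, ref_counts, rsid = ref_panel_annotations(maf, novel=False)
        records.append(VariantRecord(
            chrom=t.chrom, pos=pos, ref="G", alt="C",
            gene=gene, transcript=t.transcript_id, consequence="splice_site",
            strand=t.strand, ada_score=float(rng.uniform(0.75, 0.99)),
            rf_score=float(rng.uniform(0.75, 0.99)),
            ref_freqs=freqs, ref_counts=ref_counts, dbsnp_id=rsid,
        ))
        mafs.append(maf)
        truth_rows.append(dict(
            variant_key=records[-1].key, category="splice", maf=maf,
            regime="deleterious", novel=False,
            expected_arm="A", expected_subcategory="splice_deleterious",
        ))

    # --- clinically actionable (PharmGKB / ClinVar) -----------------------
    b_consequences = ("missense", "synonymous", "utr3", "promoter")
    b_levels = ("1A", "1B", "2A", "2B", "3")
    b_genes = ("COMT", "KCNJ6", "OPRM1", "POR", "CYP3A5")
    for i in range(counts.get("actionable", 0)):
        gene = b_genes[i % len(b_genes)]
        t = transcripts[gene]
        codon_idx = alloc.take(gene)
        codon = t.codon(codon_idx)
        consequence = b_consequences[i % len(b_consequences)]
        maf = common_maf()
        freqs, ref_counts, rsid = ref_panel_annotations(maf, novel=False)
        clinvar = "drug response" if i % 3 == 0 else None
        kwargs = dict(
            gene=gene, transcript=t.transcript_id, consequence=consequence,
            strand=t.strand, ref_freqs=freqs, ref_counts=ref_counts,
            dbsnp_id=rsid, pharmgkb_level=b_levels[i % len(b_levels)],
            clinvar_status=clinvar,
        )
        if consequence == "missense":
            pos_in_codon, ref_t, alt_t = _missense_substitution(codon, rng)
            cds_pos = 3 * (codon_idx - 1) + pos_in_codon
            ref_g, alt_g = _genomic_alleles(t, ref_t, alt_t)
            records.append(VariantRecord(
                chrom=t.chrom, pos=t.genomic_pos(cds_pos), ref=ref_g, alt=alt_g,
                cds_pos=cds_pos, ref_codon=codon,
                predictor_scores=predictor_scores(False), **kwargs,
            ))
        elif consequence == "synonymous":
            sub = _synonymous_substitution(codon, rng)
            if sub is None:  # e.g. ATG/TGG have no synonymous change
                codon = "CTG"
                sub = (3, "G", "A")
            pos_in_codon, ref_t, alt_t = sub
            cds_pos = 3 * (codon_idx - 1) + pos_in_codon
            ref_g, alt_g = _genomic_alleles(t, ref_t, alt_t)
            records.append(VariantRecord(
                chrom=t.chrom, pos=t.genomic_pos(cds_pos), ref=ref_g, alt=alt_g,
                cds_pos=cds_pos, ref_codon=codon, **kwargs,
            ))
        else:  # utr3 / promoter: position outside codon bookkeeping
            pos = t.genomic_pos(3 * (codon_idx - 1) + 1)
            records.append(VariantRecord(
                chrom=t.chrom, pos=pos, ref="A", alt="G", **kwargs,
            ))
        mafs.append(maf)
        truth_rows.append(dict(
            variant_key=records[-1].key, category="actionable", maf=maf,
            regime="neutral", novel=False,
            expected_arm="B", expected_subcategory="actionable",
        ))

    # --- common neutral background ---------------------------------------
    for _ in range(counts.get("common_neutral", 0)):
        gene = genes[rng.integers(len(genes))]
        t = transcripts[gene]
        codon_idx = alloc.take(gene)
        codon = t.codon(codon_idx)
        pos_in_codon, ref_t, alt_t = _missense_substitution(codon, rng)
        cds_pos = 3 * (codon_idx - 1) + pos_in_codon
        maf = common_maf()
        freqs, ref_counts, rsid = ref_panel_annotations(maf, novel=False)
        ref_g, alt_g = _genomic_alleles(t, ref_t, alt_t)
        records.append(VariantRecord(
            chrom=t.chrom, pos=t.genomic_pos(cds_pos), ref=ref_g, alt=alt_g,
            gene=gene, transcript=t.transcript_id, consequence="missense",
            strand=t.strand, cds_pos=cds_pos, ref_codon=codon,
            predictor_scores=predictor_scores(False),
            ref_freqs=freqs, ref_counts=ref_counts, dbsnp_id=rsid,
        ))
        mafs.append(maf)
        truth_rows.append(dict(
            variant_key=records[-1].key, category="common_neutral", maf=maf,
            regime="neutral", novel=False,
            expected_arm="none", expected_subcategory=".",
        ))

    # --- genotypes ---------------------------------------------------------
    n = config.n_individuals
    dosage = np.empty((len(records), n), dtype=np.int8)
    phase = np.full((len(records), n), MISSING, dtype=np.int8)
    for i, maf in enumerate(mafs):
        probs = genotype_probabilities(maf, config.hwe_deviation)
        row = rng.choice(3, size=n, p=probs).astype(np.int8)
        dosage[i] = row
        phase[i, row == 1] = PHASE_UNPHASED

    gt = GenotypeMatrix(
        variant_keys=[r.key for r in records], sample_ids=sample_ids,
        dosage=dosage, phase=phase,
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["variant_key", "category", "maf", "regime", "novel",
                 "expected_arm", "expected_subcategory"],
    )

    cohort = SimulatedCohort(records=records, genotypes=gt, truth=truth)
    for inj in config.mnv_injections:
        cohort = inject_mnv_pair(cohort, inj, rng=rng, transcripts=transcripts)
    return cohort


# ---------------------------------------------------------------------------
# MNV injection
# ---------------------------------------------------------------------------


def inject_mnv_pair(
    cohort: SimulatedCohort,
    spec: MnvInjection,
    rng: np.random.Generator | None = None,
    transcripts: Mapping[str, TranscriptModel] | None = None,
) -> SimulatedCohort:
    """Add a same-codon SNV pair with carriers phased in cis (or trans).

    Two adjacent SNV records are appended; each carrier gets dosage 1 at both
    positions with the alt alleles placed on the same haplotype (``cis=True``)
    or opposite haplotypes (trans test mode). With ``carrier_count = 0`` the
    records are added without genotype changes.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    transcripts = transcripts or default_transcripts()
    if spec.gene not in transcripts:
        raise InjectionError(f"no transcript model for gene {spec.gene}")
    t = transcripts[spec.gene]
    if not 1 <= spec.codon_index <= t.n_codons:
        raise InjectionError(f"codon {spec.codon_index} outside {spec.gene} CDS")
    codon = t.codon(spec.codon_index)

    new_records = []
    for pos_in_codon, alt_t in sorted((spec.sub1, spec.sub2)):
        cds_pos = 3 * (spec.codon_index - 1) + pos_in_codon
        gpos = t.genomic_pos(cds_pos)
        if any(r.chrom == t.chrom and r.pos == gpos for r in cohort.records):
            raise InjectionError(
                f"existing variant at {t.chrom}:{gpos} overlaps MNV injection")
        ref_t = codon[pos_in_codon - 1]
        _, aa_ref, aa_alt = retranslate_codon(codon, [(pos_in_codon, alt_t)])
        ref_g, alt_g = _genomic_alleles(t, ref_t, alt_t)
        new_records.append(VariantRecord(
            chrom=t.chrom, pos=gpos, ref=ref_g, alt=alt_g,
            gene=spec.gene, transcript=t.transcript_id,
            consequence=consequence_of(aa_ref, aa_alt),
            strand=t.strand, cds_pos=cds_pos,
            hgvs_c=f"c.{cds_pos}{ref_t}>{alt_t}", ref_codon=codon,
        ))

    gt = cohort.genotypes
    if spec.carrier_count > gt.n_samples:
        raise SimulationConfigError(
            f"carrier_count {spec.carrier_count} exceeds cohort size {gt.n_samples}")
    carriers = rng.choice(gt.n_samples, size=spec.carrier_count, replace=False)

    dosage = np.vstack([gt.dosage, np.zeros((2, gt.n_samples), dtype=np.int8)])
    phase = np.vstack([gt.phase, np.full((2, gt.n_samples), MISSING, dtype=np.int8)])
    for c in carriers:
        dosage[-2:, c] = 1
        if spec.cis:
            phase[-2:, c] = PHASE_HAP1
        else:
            phase[-2, c] = PHASE_HAP1
            phase[-1, c] = PHASE_HAP2

    records = cohort.records + new_records
    truth_rows = [
        dict(variant_key=r.key, category="mnv_component", maf=np.nan,
             regime="deleterious", novel=True, expected_arm=".",
             expected_subcategory=".")
        for r in new_records
    ]
    truth = pd.concat([cohort.truth, pd.DataFrame(truth_rows)], ignore_index=True)
    return SimulatedCohort(
        records=records,
        genotypes=GenotypeMatrix(
            variant_keys=[r.key for r in records], sample_ids=gt.sample_ids,
            dosage=dosage, phase=phase,
        ),
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Writers (same dialect data_model reads)
# ---------------------------------------------------------------------------


def write_cohort(
    cohort: SimulatedCohort,
    outdir: str | Path,
    dialect: AnnotationDialect | None = None,
) -> dict[str, Path]:
    """Write annotation TSV, VCF and truth TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "annotation": outdir / "annotation.tsv",
        "vcf": outdir / "genotypes.vcf",
        "truth": outdir / "truth.tsv",
    }
    write_annotation_table(cohort.records, paths["annotation"], dialect)
    write_genotypes_vcf(cohort.records, cohort.genotypes, paths["vcf"])
    cohort.truth.to_csv(paths["truth"], sep="\t", index=False, na_rep=".")
    return paths


def write_genotypes_vcf(
    records: Sequence[VariantRecord], gt: GenotypeMatrix, path: str | Path
) -> None:
    header = pysam.VariantHeader()
    for chrom in sorted({r.chrom for r in records}, key=lambda c: (len(c), c)):
        header.contigs.add(chrom, length=300_000_000)
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in gt.sample_ids:
        header.add_sample(s)

    order = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos))
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in order:
            r = records[i]
            rec = vcf.new_record(
                contig=r.chrom, start=r.pos - 1, alleles=(r.ref, r.alt), id=r.dbsnp_id
            )
            drow = gt.row(r.key)
            prow = gt.phase_row(r.key)
            for j, s in enumerate(gt.sample_ids):
                call = rec.samples[s]
                d = int(drow[j])
                if d == MISSING:
                    call["GT"] = (None, None)
                elif d == 0:
                    call["GT"] = (0, 0)
                elif d == 2:
                    call["GT"] = (1, 1)
                elif prow[j] == PHASE_HAP1:
                    call["GT"] = (1, 0)
                    call.phased = True
                elif prow[j] == PHASE_HAP2:
                    call["GT"] = (0, 1)
                    call.phased = True
                else:
                    call["GT"] = (0, 1)
            vcf.write(rec)
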