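"""Core domain types and I/O for the anesthesia pharmacogene panel analysis.

The pipeline operates on three objects: :class:`VariantRecord` (one annotated
variant with predictor scores, reference-population frequencies and clinical
annotations), :class:`GenotypeMatrix` (diploid dosages for a cohort, with
optional phase), and :class:`GenePanel` (the gene → functional-class map).
Annotations travel as tab-separated tables with a configurable column dialect
(ANNOVAR-style defaults); genotypes travel as VCF 4.x read through pysam.

Missing annotation cells are represented as *absent* dictionary entries, never
as sentinel numerics: downstream scoring must be able to distinguish "no
prediction" from "score 0".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger("pgxpanel")

# ---------------------------------------------------------------------------
# Constants and errors
# ---------------------------------------------------------------------------

CONSEQUENCES = frozenset(
    {"missense", "nonsense", "frameshift", "splice_site", "synonymous",
     "utr3", "promoter", "other"}
)
#: consequence classes whose records must carry cds_pos and ref_codon
CODING_SNV_CONSEQUENCES = frozenset({"missense", "nonsense", "synonymous"})

GENE_CLASSES = ("pharmacodynamic", "phase1_metabolism", "transporter")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MISSING = -1  # dosage / phase sentinel in GenotypeMatrix arrays
PHASE_UNPHASED = 0
PHASE_HAP1 = 1
PHASE_HAP2 = 2


class PanelConfigError(ValueError):
    """Raised for malformed panel or column-mapping configuration."""


class AnnotationRowError(ValueError):
    """Raised for a malformed annotation row; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        super().__init__(f"annotation row {line}: {message}")
        self.line = line


class PloidyError(ValueError):
    """Raised when a VCF genotype is not diploid."""


def revcomp(seq: str) -> str:
    """Reverse-complement an upper-case DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRecord:
    """One annotated variant.

    Coordinates are 1-based inclusive (VCF convention) with alleles on the +
    genomic strand; ``cds_pos`` is 1-based on the transcript strand and
    ``ref_codon`` is the transcript-strand codon containing it, so codon-level
    checks reverse-complement ``ref`` for minus-strand transcripts.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    transcript: str
    consequence: str
    strand: str = "+"
    cds_pos: Optional[int] = None
    hgvs_c: Optional[str] = None
    hgvs_p: Optional[str] = None
    ref_codon: Optional[str] = None
    predictor_scores: Mapping[str, float] = field(default_factory=dict)
    ada_score: Optional[float] = None
    rf_score: Optional[float] = None
    ref_freqs: Mapping[str, float] = field(default_factory=dict)
    ref_counts: Mapping[str, tuple[int, int]] = field(default_factory=dict)
    dbsnp_id: Optional[str] = None
    pharmgkb_level: Optional[str] = None
    clinvar_status: Optional[str] = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for panel, f in self.ref_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"frequency {f} for panel {panel!r} outside [0,1]")
        for s in (self.ada_score, self.rf_score):
            if s is not None and not 0.0 <= s <= 1.0:
                raise ValueError(f"splice score {s} outside [0,1]")
        if self.consequence in CODING_SNV_CONSEQUENCES:
            # consistency of ref_codon with the ref allele is a report-level
            # concern (validate_dataset); presence is a hard requirement
            if self.cds_pos is None or self.ref_codon is None:
                raise ValueError(
                    f"{self.consequence} variant at {self.chrom}:{self.pos} "
                    "requires cds_pos and ref_codon"
                )

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    @property
    def codon_index(self) -> Optional[int]:
        """1-based codon number: ceil(cds_pos / 3)."""
        if self.cds_pos is None:
            return None
        return math.ceil(self.cds_pos / 3)

    @property
    def pos_in_codon(self) -> Optional[int]:
        """1-based position within the codon: ((cds_pos - 1) mod 3) + 1."""
        if self.cds_pos is None:
            return None
        return (self.cds_pos - 1) % 3 + 1

    @property
    def ref_on_transcript(self) -> str:
        """ref allele expressed on the transcript strand."""
        return self.ref if self.strand == "+" else revcomp(self.ref)

    @property
    def alt_on_transcript(self) -> str:
        return self.alt if self.strand == "+" else revcomp(self.alt)

    def codon_consistent(self) -> bool:
        if self.cds_pos is None or self.ref_codon is None:
            return False
        if len(self.ref_codon) != 3 or len(self.ref) != 1:
            return False
        return self.ref_codon[self.pos_in_codon - 1] == self.ref_on_transcript


@dataclass
class GenotypeMatrix:
    """Diploid dosages (variants x samples) with optional phase.

    ``dosage`` holds 0/1/2 with -1 for missing. ``phase`` holds, for dosage-1
    calls from phased genotypes, which haplotype carries the alt allele
    (1 = hap1, 2 = hap2), 0 for unphased hets and -1 where not applicable.
    """

    variant_keys: list[str]
    sample_ids: list[str]
    dosage: np.ndarray
    phase: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.phase = np.asarray(self.phase, dtype=np.int8)
        shape = (len(self.variant_keys), len(self.sample_ids))
        if self.dosage.shape != shape or self.phase.shape != shape:
            raise ValueError(
                f"genotype arrays {self.dosage.shape}/{self.phase.shape} "
                f"inconsistent with {shape} keys x samples"
            )
        hap_set = np.isin(self.phase, (PHASE_HAP1, PHASE_HAP2))
        if np.any(hap_set & (self.dosage != 1)):
            raise ValueError("haplotype phase set on a non-heterozygous call")
        self._index = {k: i for i, k in enumerate(self.variant_keys)}

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, key: str) -> np.ndarray:
        return self.dosage[self._index[key]]

    def phase_row(self, key: str) -> np.ndarray:
        return self.phase[self._index[key]]

    def __contains__(self, key: str) -> bool:
        return key in self._index


@dataclass(frozen=True)
class GenePanel:
    """Gene → functional-class map plus gene → drug links."""

    genes: Mapping[str, str]
    drug_links: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        for gene, cls in self.genes.items():
            if cls not in GENE_CLASSES:
                raise PanelConfigError(f"gene {gene}: unknown class {cls!r}")

    def gene_class(self, gene: str) -> Optional[str]:
        return self.genes.get(gene)

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


def default_panel() -> GenePanel:
    """The 14-gene anesthesia panel with its functional-class partition.

    Eight pharmacodynamic genes (drug targets, receptors, channels), five
    phase-1 metabolism genes (CYP enzymes) and the ABCB1 efflux transporter.
    """
    genes = {
        "ADRB2": "pharmacodynamic",
        "CACNA1S": "pharmacodynamic",
        "COMT": "pharmacodynamic",
        "KCNJ6": "pharmacodynamic",
        "OPRM1": "pharmacodynamic",
        "POR": "pharmacodynamic",
        "RHBDF2": "pharmacodynamic",
        "RYR1": "pharmacodynamic",
        "CYP1A2": "phase1_metabolism",
        "CYP2B6": "phase1_metabolism",
        "CYP2D6": "phase1_metabolism",
        "CYP3A4": "phase1_metabolism",
        "CYP3A5": "phase1_metabolism",
        "ABCB1": "transporter",
    }
    drug_links = {
        "ABCB1": ("fentanyl", "ondansetron", "propofol", "sevoflurane", "rocuronium"),
        "CACNA1S": ("fentanyl", "sevoflurane", "isoflurane", "desflurane"),
        "RYR1": ("sevoflurane", "isoflurane", "desflurane", "succinylcholine"),
        "CYP3A4": ("fentanyl", "midazolam"),
        "CYP3A5": ("midazolam",),
        "COMT": ("fentanyl", "oxycodone"),
        "KCNJ6": ("fentanyl",),
        "OPRM1": ("fentanyl",),
        "RHBDF2": ("fentanyl",),
        "CYP2D6": ("ondansetron", "dihydrocodeine", "oxycodone"),
        "POR": ("midazolam",),
        "ADRB2": ("propofol",),
        "CYP2B6": ("propofol", "ketamine"),
        "CYP1A2": ("bupivacaine",),
    }
    return GenePanel(genes=genes, drug_links={g: tuple(d) for g, d in drug_links.items()})


# ---------------------------------------------------------------------------
# Annotation table dialect and I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnnotationDialect:
    """Column mapping binding VariantRecord fields to TSV column names.

    Defaults follow ANNOVAR/dbNSFP naming for the five missense predictors and
    gnomAD-style exome frequency columns (global + Latino). ``"."`` and empty
    cells are missing.
    """

    chrom: str = "Chr"
    pos: str = "Start"
    ref: str = "Ref"
    alt: str = "Alt"
    gene: str = "Gene"
    transcript: str = "Transcript"
    consequence: str = "Consequence"
    strand: str = "Strand"
    cds_pos: str = "CDS_pos"
    hgvs_c: str = "HGVS_c"
    hgvs_p: str = "HGVS_p"
    ref_codon: str = "Ref_codon"
    ada_score: str = "dbscSNV_ADA_SCORE"
    rf_score: str = "dbscSNV_RF_SCORE"
    dbsnp_id: str = "avsnp"
    pharmgkb_level: str = "PharmGKB_level"
    clinvar_status: str = "ClinVar_status"
    score_columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "LRT": "LRT_score",
            "MutationAssessor": "MutationAssessor_score",
            "PROVEAN": "PROVEAN_score",
            "VEST3": "VEST3_score",
            "CADD": "CADD_phred",
        }
    )
    freq_columns: Mapping[str, str] = field(
        default_factory=lambda: {
            "gnomad_global": "gnomAD_exome_ALL",
            "gnomad_latino": "gnomAD_exome_AMR",
        }
    )
    # allele-count column pairs per reference panel, for population comparison
    count_columns: Mapping[str, tuple[str, str]] = field(
        default_factory=lambda: {
            "gnomad_global": ("gnomAD_exome_ALL_AC", "gnomAD_exome_ALL_AN"),
            "gnomad_latino": ("gnomAD_exome_AMR_AC", "gnomAD_exome_AMR_AN"),
        }
    )

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (self.chrom, self.pos, self.ref, self.alt, self.gene,
                self.transcript, self.consequence)


def _cell(row: pd.Series, col: str):
    """Return the cell value or None when the column is absent or NA."""
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str) and v.strip() in ("", "."):
        return None
    return v


def read_annotation_table(
    path: str | Path, dialect: AnnotationDialect | None = None
) -> list[VariantRecord]:
    """Read an annotation TSV into VariantRecords.

    Missing score/frequency cells become absent map entries, never 0.0.
    Raises :class:`PanelConfigError` for a missing mandatory column and
    :class:`AnnotationRowError` (with the 1-based data line number) for a
    malformed allele or position.
    """
    dialect = dialect or AnnotationDialect()
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["", "."],
                     keep_default_na=False)
    for col in dialect.mandatory:
        if col not in df.columns:
            raise PanelConfigError(f"annotation table missing mandatory column {col!r}")

    records: list[VariantRecord] = []
    for i, (_, row) in enumerate(df.iterrows()):
        line = i + 1  # 1-based data row (header excluded)
        try:
            pos = int(row[dialect.pos])
        except (TypeError, ValueError):
            raise AnnotationRowError(line, f"malformed position {row[dialect.pos]!r}")
        ref = _cell(row, dialect.ref)
        alt = _cell(row, dialect.alt)
        if ref is None or alt is None or not _valid_allele(ref) or not _valid_allele(alt):
            raise AnnotationRowError(line, f"malformed alleles {ref!r}/{alt!r}")

        scores = {}
        for algo, col in dialect.score_columns.items():
            v = _cell(row, col)
            if v is not None:
                scores[algo] = float(v)
        freqs = {}
        for panel, col in dialect.freq_columns.items():
            v = _cell(row, col)
            if v is not None:
                freqs[panel] = float(v)
        counts = {}
        for panel, (ac_col, an_col) in dialect.count_columns.items():
            ac, an = _cell(row, ac_col), _cell(row, an_col)
            if ac is not None and an is not None:
                counts[panel] = (int(float(ac)), int(float(an)))

        cds = _cell(row, dialect.cds_pos)
        ada = _cell(row, dialect.ada_score)
        rf = _cell(row, dialect.rf_score)
        try:
            records.append(
                VariantRecord(
                    chrom=str(row[dialect.chrom]),
                    pos=pos,
                    ref=ref.upper(),
                    alt=alt.upper(),
                    gene=str(row[dialect.gene]),
                    transcript=str(row[dialect.transcript]),
                    consequence=str(row[dialect.consequence]),
                    strand=_cell(row, dialect.strand) or "+",
                    cds_pos=int(float(cds)) if cds is not None else None,
                    hgvs_c=_cell(row, dialect.hgvs_c),
                    hgvs_p=_cell(row, dialect.hgvs_p),
                    ref_codon=_cell(row, dialect.ref_codon),
                    predictor_scores=scores,
                    ada_score=float(ada) if ada is not None else None,
                    rf_score=float(rf) if rf is not None else None,
                    ref_freqs=freqs,
                    ref_counts=counts,
                    dbsnp_id=_cell(row, dialect.dbsnp_id),
                    pharmgkb_level=_cell(row, dialect.pharmgkb_level),
                    clinvar_status=_cell(row, dialect.clinvar_status),
                )
            )
        except ValueError as exc:
            raise AnnotationRowError(line, str(exc)) from exc
    return records


def _valid_allele(a: str) -> bool:
    return len(a) >= 1 and all(b in "ACGTacgt" for b in a)


def write_annotation_table(
    records: Sequence[VariantRecord],
    path: str | Path,
    dialect: AnnotationDialect | None = None,
) -> None:
    """Write VariantRecords to TSV in the given dialect (absent cells as '.')."""
    dialect = dialect or AnnotationDialect()
    rows = []
    for r in records:
        row = {
            dialect.chrom: r.chrom,
            dialect.pos: r.pos,
            dialect.ref: r.ref,
            dialect.alt: r.alt,
            dialect.gene: r.gene,
            dialect.transcript: r.transcript,
            dialect.consequence: r.consequence,
            dialect.strand: r.strand,
            dialect.cds_pos: r.cds_pos,
            dialect.hgvs_c: r.hgvs_c,
            dialect.hgvs_p: r.hgvs_p,
            dialect.ref_codon: r.ref_codon,
            dialect.ada_score: r.ada_score,
            dialect.rf_score: r.rf_score,
            dialect.dbsnp_id: r.dbsnp_id,
            dialect.pharmgkb_level: r.pharmgkb_level,
            dialect.clinvar_status: r.clinvar_status,
        }
        for algo, col in dialect.score_columns.items():
            row[col] = r.predictor_scores.get(algo)
        for panel, col in dialect.freq_columns.items():
            row[col] = r.ref_freqs.get(panel)
        for panel, (ac_col, an_col) in dialect.count_columns.items():
            ac_an = r.ref_counts.get(panel)
            row[ac_col] = ac_an[0] if ac_an else None
            row[an_col] = ac_an[1] if ac_an else None
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, na_rep=".")


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read diploid genotypes from a (possibly phased) VCF 4.x file.

    ``0/1`` → dosage 1 unphased; ``1|0`` → dosage 1, alt on hap1; ``0|1`` →
    dosage 1, alt on hap2; ``./.`` → missing. Records must be biallelic.
    Raises :class:`PloidyError` on non-diploid GT fields.
    """
    keys: list[str] = []
    dosage_rows: list[list[int]] = []
    phase_rows: list[list[int]] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"record {rec.chrom}:{rec.pos} is not biallelic"
                )
            keys.append(f"{rec.chrom}:{rec.pos}:{rec.ref}>{rec.alts[0]}")
            drow, prow = [], []
            for s in samples:
                call = rec.samples[s]
                gt = call["GT"]
                if gt is None or all(a is None for a in gt):
                    drow.append(MISSING)
                    prow.append(MISSING)
                    continue
                if len(gt) != 2:
                    raise PloidyError(
                        f"{rec.chrom}:{rec.pos} sample {s}: ploidy {len(gt)}"
                    )
                d = sum(1 for a in gt if a == 1)
                drow.append(d)
                if d == 1 and call.phased:
                    prow.append(PHASE_HAP1 if gt[0] == 1 else PHASE_HAP2)
                elif d == 1:
                    prow.append(PHASE_UNPHASED)
                else:
                    prow.append(MISSING)
            dosage_rows.append(drow)
            phase_rows.append(prow)
    return GenotypeMatrix(
        variant_keys=keys,
        sample_ids=samples,
        dosage=np.array(dosage_rows, dtype=np.int8).reshape(len(keys), len(samples)),
        phase=np.array(phase_rows, dtype=np.int8).reshape(len(keys), len(samples)),
    )


# ---------------------------------------------------------------------------
# Dataset validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Finding:
    kind: str
    subject: str
    detail: str


@dataclass
class ValidationReport:
    findings: list[Finding]

    @property
    def passed(self) -> bool:
        return not self.findings


def validate_dataset(
    records: Sequence[VariantRecord],
    gt: GenotypeMatrix,
    panel: GenePanel,
) -> ValidationReport:
    """Cross-check records, genotypes and panel; report-only, never raises.

    Flags genes outside the panel, codon/allele inconsistencies, and variants
    present in the annotation but absent from the genotype matrix (and vice
    versa). Dimension inconsistencies inside GenotypeMatrix are caught at
    construction; here we flag key mismatches.
    """
    findings: list[Finding] = []
    record_keys = set()
    for r in records:
        record_keys.add(r.key)
        if r.gene not in panel:
            findings.append(Finding("gene_not_in_panel", r.key, r.gene))
        if r.consequence in CODING_SNV_CONSEQUENCES and not r.codon_consistent():
            findings.append(
                Finding("codon_inconsistency", r.key,
                        f"ref_codon {r.ref_codon} vs ref {r.ref} at codon "
                        f"position {r.pos_in_codon}")
            )
        if r.key not in gt:
            findings.append(Finding("missing_genotypes", r.key, "not in VCF"))
    for k in gt.variant_keys:
        if k not in record_keys:
            findings.append(Finding("unannotated_variant", k, "not in annotation table"))
    return ValidationReport(findings=findings)
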