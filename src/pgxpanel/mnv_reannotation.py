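"""Haplotype-aware re-annotation of intra-codon multi-nucleotide variants.

Variant callers that emit SNVs independently mis-annotate two substitutions
falling in the same codon on the same haplotype: each SNV gets a protein
consequence computed against the reference codon, while the true consequence
comes from the jointly substituted codon. The canonical example is a codon
GAA (Glu) hit at positions 1 and 2 by G>T and A>T in cis: annotated alone the
SNVs read as a nonsense (TAA) and a missense (GTA, Val), but the haplotype
carries TTA — leucine, a *rescued nonsense*.

This module finds same-codon SNV pairs sharing a carrier, uses phased
genotypes to establish cis configuration (unphased shared carriers are
flagged for experimental phasing, not guessed), re-translates the doubly
substituted codon with the standard genetic code, emits the merged delins
HGVS string, and classifies the annotation correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqUtils import seq3

from .data_model import (
    MISSING,
    PHASE_HAP1,
    PHASE_HAP2,
    GenotypeMatrix,
    VariantRecord,
)

logger = logging.getLogger("pgxpanel")

# translation table 1 (standard code); stop codons mapped to "*"
_CODON_TO_AA = dict(standard_dna_table.forward_table)
_CODON_TO_AA.update({c: "*" for c in standard_dna_table.stop_codons})

PHASED_GT = "phased_gt"
ASSUMED = "assumed"
UNKNOWN = "unknown"

CATEGORIES = (
    "rescued_nonsense", "gained_nonsense", "changed_missense",
    "same_missense", "synonymous_rescue", "other",
)


@dataclass
class MnvCall:
    """A same-codon SNV pair, optionally merged into a delins re-annotation."""

    component_keys: tuple[str, str]
    gene: str
    transcript: str
    codon_index: int
    ref_codon: str
    substitutions: tuple[tuple[int, str], ...]  # (position-in-codon, alt base), cDNA strand
    cds_positions: tuple[int, int]
    carrier_samples: tuple[str, ...]
    phase_evidence: str
    hgvs_c_merged: Optional[str] = None
    alt_codon: Optional[str] = None
    aa_ref: Optional[str] = None
    aa_alt: Optional[str] = None
    per_snv_consequences: Optional[tuple[str, str]] = None
    merged_consequence: Optional[str] = None
    category: Optional[str] = None


@dataclass
class MnvScan:
    """Result of candidate detection: cis/unknown candidates plus trans pairs."""

    candidates: list[MnvCall]
    in_trans: list[MnvCall]


def translate_codon(codon: str) -> str:
    """Standard-genetic-code translation of a single codon; '*' for stop."""
    return _CODON_TO_AA[codon.upper()]


def retranslate_codon(
    ref_codon: str, substitutions: Sequence[tuple[int, str]]
) -> tuple[str, str, str]:
    """Apply substitutions (1-based position-in-codon, alt base) to a codon.

    Returns ``(alt_codon, aa_ref, aa_alt)`` with amino acids as 1-letter
    codes ('*' for stop). Substituting a base with itself is a logged no-op.
    """
    ref_codon = ref_codon.upper()
    if len(ref_codon) != 3 or any(b not in "ACGT" for b in ref_codon):
        raise ValueError(f"invalid codon {ref_codon!r}")
    positions = [p for p, _ in substitutions]
    if len(set(positions)) != len(positions):
        raise ValueError(f"duplicate codon positions in {substitutions}")
    bases = list(ref_codon)
    for pos, alt in substitutions:
        if pos not in (1, 2, 3):
            raise ValueError(f"codon position {pos} outside 1..3")
        alt = alt.upper()
        if alt not in "ACGT":
            raise ValueError(f"invalid base {alt!r}")
        if bases[pos - 1] == alt:
            logger.warning("substitution %s at codon position %d is a no-op", alt, pos)
        bases[pos - 1] = alt
    alt_codon = "".join(bases)
    return alt_codon, translate_codon(ref_codon), translate_codon(alt_codon)


def consequence_of(aa_ref: str, aa_alt: str) -> str:
    if aa_alt == "*":
        return "nonsense" if aa_ref != "*" else "other"
    if aa_ref == "*":
        return "other"  # stop-loss, outside the modelled categories
    return "synonymous" if aa_ref == aa_alt else "missense"


def find_candidate_mnvs(
    records: Sequence[VariantRecord], gt: GenotypeMatrix
) -> MnvScan:
    """Find same-codon SNV pairs with at least one shared carrier.

    Pairs whose shared carriers are phased with both alt alleles on one
    haplotype get ``phase_evidence = phased_gt``; unphased shared carriers
    yield ``unknown`` (emitted for manual review, mirroring the need for
    experimental phasing); pairs whose only shared carriers place the alts on
    opposite haplotypes land in the trans list, not the candidate list.
    Detection is intra-codon only: cross-codon adjacency does not alter the
    protein re-annotation and is out of scope.
    """
    coding = [
        r for r in records
        if r.cds_pos is not None and r.ref_codon is not None
        and len(r.ref) == 1 and len(r.alt) == 1
    ]
    by_codon: dict[tuple[str, int], list[VariantRecord]] = {}
    for r in coding:
        by_codon.setdefault((r.transcript, r.codon_index), []).append(r)

    candidates: list[MnvCall] = []
    in_trans: list[MnvCall] = []
    for (transcript, codon_index), group in sorted(by_codon.items()):
        for a, b in combinations(sorted(group, key=lambda r: r.cds_pos), 2):
            if a.pos_in_codon == b.pos_in_codon:
                continue  # two alt alleles at one site cannot co-occur in cis
            if a.key not in gt or b.key not in gt:
                continue
            da, db = gt.row(a.key), gt.row(b.key)
            shared = np.flatnonzero((da > 0) & (da != MISSING) & (db > 0) & (db != MISSING))
            if shared.size == 0:
                continue
            pa, pb = gt.phase_row(a.key), gt.phase_row(b.key)
            cis, trans, unphased = [], [], []
            for i in shared:
                sample = gt.sample_ids[i]
                # a hom-alt call carries the alt on both haplotypes
                ha = {PHASE_HAP1, PHASE_HAP2} if da[i] == 2 else (
                    {pa[i]} if pa[i] in (PHASE_HAP1, PHASE_HAP2) else None)
                hb = {PHASE_HAP1, PHASE_HAP2} if db[i] == 2 else (
                    {pb[i]} if pb[i] in (PHASE_HAP1, PHASE_HAP2) else None)
                if ha is None or hb is None:
                    unphased.append(sample)
                elif ha & hb:
                    cis.append(sample)
                else:
                    trans.append(sample)
            subs = tuple(
                sorted(
                    ((r.pos_in_codon, r.alt_on_transcript) for r in (a, b)),
                    key=lambda s: s[0],
                )
            )
            common = dict(
                component_keys=(a.key, b.key),
                gene=a.gene,
                transcript=transcript,
                codon_index=codon_index,
                ref_codon=a.ref_codon,
                substitutions=subs,
                cds_positions=(min(a.cds_pos, b.cds_pos), max(a.cds_pos, b.cds_pos)),
            )
            if cis:
                candidates.append(MnvCall(
                    **common, carrier_samples=tuple(cis), phase_evidence=PHASED_GT))
            elif unphased:
                candidates.append(MnvCall(
                    **common, carrier_samples=tuple(unphased), phase_evidence=UNKNOWN))
                logger.info(
                    "MNV candidate %s/%s has unphased shared carriers; "
                    "phase must be resolved experimentally", a.key, b.key)
            elif trans:
                in_trans.append(MnvCall(
                    **common, carrier_samples=tuple(trans), phase_evidence=PHASED_GT))
    return MnvScan(candidates=candidates, in_trans=in_trans)


def merge_and_classify(candidate: MnvCall) -> MnvCall:
    """Complete a candidate: delins HGVS, joint re-translation, category.

    Category logic on (per-SNV consequence multiset → merged consequence):
    a component nonsense resolving to a merged missense/synonymous is a
    *rescued nonsense*; a merged stop with no component stop is a *gained
    nonsense*; missense components merging to a third amino acid are a
    *changed missense* (same amino acid as one component: *same missense*);
    non-synonymous components merging back to the reference amino acid are a
    *synonymous rescue*.
    """
    subs = sorted(candidate.substitutions)
    alt_codon, aa_ref, aa_alt = retranslate_codon(candidate.ref_codon, subs)
    singles = []
    for pos, alt in subs:
        _, _, aa = retranslate_codon(candidate.ref_codon, [(pos, alt)])
        singles.append(consequence_of(aa_ref, aa))
    merged_cons = consequence_of(aa_ref, aa_alt)

    single_set = set(singles)
    if merged_cons == "nonsense":
        # a stop gained jointly that neither SNV predicts alone
        category = "gained_nonsense" if "nonsense" not in single_set else "other"
    elif "nonsense" in single_set:
        category = "rescued_nonsense"
    elif merged_cons == "synonymous":
        category = "synonymous_rescue" if single_set != {"synonymous"} else "other"
    elif merged_cons == "missense":
        single_aas = {
            retranslate_codon(candidate.ref_codon, [(p, b)])[2] for p, b in subs
        }
        category = "same_missense" if aa_alt in single_aas else "changed_missense"
    else:
        category = "other"

    lo, hi = candidate.cds_positions
    joint_alt = "".join(b for _, b in subs)
    return replace(
        candidate,
        hgvs_c_merged=f"c.{lo}_{hi}delins{joint_alt}",
        alt_codon=alt_codon,
        aa_ref=aa_ref,
        aa_alt=aa_alt,
        per_snv_consequences=tuple(singles),
        merged_consequence=merged_cons,
        category=category,
    )


def merged_hgvs_p(call: MnvCall) -> str:
    """Protein HGVS for a completed merge, e.g. ``p.Glu3376Leu``."""
    if call.aa_ref is None or call.aa_alt is None:
        raise ValueError("call not merged yet")
    ref3 = seq3(call.aa_ref) if call.aa_ref != "*" else "Ter"
    alt3 = seq3(call.aa_alt) if call.aa_alt != "*" else "Ter"
    if call.aa_ref == call.aa_alt:
        return f"p.{ref3}{call.codon_index}="
    return f"p.{ref3}{call.codon_index}{alt3}"


def scan_and_merge(records: Sequence[VariantRecord], gt: GenotypeMatrix) -> MnvScan:
    """Convenience: detect candidates and complete every merge."""
    scan = find_candidate_mnvs(records, gt)
    scan.candidates = [merge_and_classify(c) for c in scan.candidates]
    return scan
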