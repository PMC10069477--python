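"""Two-arm variant filtering with provenance tracking.

Strategy A admits novel or rare (MAF < 1% across the consulted reference
panels) variants with evidence of functional impact: missense SNVs classified
functionally relevant by the OPF composite, loss-of-function consequences
(nonsense, frameshift), and splice-site variants passing the ADA/RF ensemble
cutoff (default ≥ 0.6). Strategy B admits clinically validated variants —
PharmGKB evidence tiers 1–3 (sub-tiers 1A/1B/2A/2B included) and/or ClinVar
drug-response annotations — regardless of frequency or consequence class.

A variant qualifying for both arms is assigned to B (the arms are disjoint in
the merged output). Every decision carries an ordered chain of rule
evaluations sufficient to recompute the arm assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .data_model import VariantRecord
from .opf_scoring import FUNCTIONALLY_RELEVANT, UNSCORABLE, CompositeResult

logger = logging.getLogger("pgxpanel")

ARM_A = "A"
ARM_B = "B"
ARM_NONE = "none"

SUBCATEGORIES = ("rare_missense_pathogenic", "lof", "splice_deleterious", "actionable")


class ScoringGapError(ValueError):
    """A missense record reached strategy A without a composite result."""


@dataclass(frozen=True)
class FilterConfig:
    maf_cutoff: float = 0.01
    rare_panels: tuple[str, ...] = ("gnomad_global", "gnomad_latino")
    splice_cutoff: float = 0.6
    splice_rule: str = "both"  # {"both", "either"}
    pharmgkb_accepted_tiers: frozenset[int] = frozenset({1, 2, 3})
    clinvar_actionable: tuple[str, ...] = ("drug response", "drug_response", "actionable")
    lof_consequences: frozenset[str] = frozenset({"nonsense", "frameshift", "splice_site"})
    precedence: str = "B_over_A"

    def __post_init__(self):
        if not 0.0 < self.maf_cutoff < 1.0:
            raise ValueError(f"maf_cutoff {self.maf_cutoff} outside (0,1)")
        if not 0.0 <= self.splice_cutoff <= 1.0:
            raise ValueError(f"splice_cutoff {self.splice_cutoff} outside [0,1]")
        if self.splice_rule not in ("both", "either"):
            raise ValueError(f"unknown splice_rule {self.splice_rule!r}")


@dataclass(frozen=True)
class Reason:
    """One rule evaluation in a decision's audit chain."""

    rule: str
    observed: object
    outcome: bool


@dataclass(frozen=True)
class FilterDecision:
    variant_key: str
    arm: str
    subcategory: Optional[str]
    reasons: tuple[Reason, ...]
    novel: bool


# ---------------------------------------------------------------------------
# Elementary rules
# ---------------------------------------------------------------------------


def is_rare(record: VariantRecord, config: FilterConfig) -> tuple[bool, bool]:
    """(rare, novel) under the strict MAF < cutoff rule.

    Rare iff *every available* consulted panel frequency is strictly below the
    cutoff (a variant absent from all panels is rare); novel iff no consulted
    panel carries a frequency entry and there is no dbSNP identifier. Novel
    implies rare.
    """
    freqs = [record.ref_freqs[p] for p in config.rare_panels if p in record.ref_freqs]
    rare = all(f < config.maf_cutoff for f in freqs)
    novel = not freqs and record.dbsnp_id is None
    return rare, novel


def splice_deleterious(record: VariantRecord, config: FilterConfig) -> bool:
    """ADA/RF ensemble call for a splice-site variant.

    Under rule ``both``, every available score must reach the cutoff (and at
    least one must be available); when only one of ADA/RF is present, that one
    decides. Under ``either``, any available score at the cutoff suffices.
    """
    if record.consequence != "splice_site":
        raise ValueError(f"{record.key} is not a splice_site variant")
    scores = [s for s in (record.ada_score, record.rf_score) if s is not None]
    if not scores:
        return False
    hits = [s >= config.splice_cutoff for s in scores]
    return all(hits) if config.splice_rule == "both" else any(hits)


def _pharmgkb_tier(level: str) -> Optional[int]:
    """Numeric tier from a PharmGKB evidence-level string ('1A' → 1)."""
    s = level.strip()
    if s and s[0].isdigit():
        return int(s[0])
    return None


def clinically_validated(record: VariantRecord, config: FilterConfig) -> tuple[bool, list[Reason]]:
    reasons: list[Reason] = []
    pg_ok = False
    if record.pharmgkb_level is not None:
        tier = _pharmgkb_tier(record.pharmgkb_level)
        if tier is None:
            logger.warning(
                "unrecognized PharmGKB level %r on %s: treated as non-qualifying",
                record.pharmgkb_level, record.key,
            )
        pg_ok = tier is not None and tier in config.pharmgkb_accepted_tiers
        reasons.append(Reason("pharmgkb_tier", record.pharmgkb_level, pg_ok))
    cv_ok = False
    if record.clinvar_status is not None:
        status = record.clinvar_status.strip().lower()
        cv_ok = any(tag in status for tag in config.clinvar_actionable)
        reasons.append(Reason("clinvar_status", record.clinvar_status, cv_ok))
    return pg_ok or cv_ok, reasons


# ---------------------------------------------------------------------------
# Strategy A and B
# ---------------------------------------------------------------------------


def filter_strategy_A(
    records: Sequence[VariantRecord],
    composites: Mapping[str, CompositeResult],
    config: FilterConfig | None = None,
) -> list[FilterDecision]:
    """Arm-A decisions (novel/rare deleterious) for every record.

    Requires a composite result for every missense record (raises
    :class:`ScoringGapError` otherwise); unscorable missense variants are
    excluded from arm A with a logged warning.
    """
    config = config or FilterConfig()
    decisions = []
    for r in records:
        rare, novel = is_rare(r, config)
        max_freq = max(
            (r.ref_freqs[p] for p in config.rare_panels if p in r.ref_freqs),
            default=None,
        )
        reasons = [Reason("rarity", max_freq, rare), Reason("novel", r.dbsnp_id, novel)]
        arm, sub = ARM_NONE, None
        if rare:
            if r.consequence == "missense":
                comp = composites.get(r.key)
                if comp is None:
                    raise ScoringGapError(f"no composite supplied for missense {r.key}")
                if comp.classification == UNSCORABLE:
                    logger.warning("missense %s unscorable; excluded from arm A", r.key)
                    reasons.append(Reason("opf_classification", None, False))
                else:
                    hit = comp.classification == FUNCTIONALLY_RELEVANT
                    reasons.append(Reason("opf_classification", comp.composite, hit))
                    if hit:
                        arm, sub = ARM_A, "rare_missense_pathogenic"
            elif r.consequence == "splice_site":
                hit = splice_deleterious(r, config)
                reasons.append(
                    Reason("splice_scores", (r.ada_score, r.rf_score), hit))
                if hit:
                    arm, sub = ARM_A, "splice_deleterious"
            elif r.consequence in config.lof_consequences:
                reasons.append(Reason("lof_consequence", r.consequence, True))
                arm, sub = ARM_A, "lof"
        decisions.append(FilterDecision(r.key, arm, sub, tuple(reasons), novel))
    return decisions


def filter_strategy_B(
    records: Sequence[VariantRecord], config: FilterConfig | None = None
) -> list[FilterDecision]:
    """Arm-B decisions (clinically validated) for every record.

    Admits any record with a PharmGKB level in the accepted tiers or a
    ClinVar drug-response/actionable status, regardless of MAF or consequence
    class (synonymous, UTR and promoter variants qualify).
    """
    config = config or FilterConfig()
    decisions = []
    for r in records:
        ok, reasons = clinically_validated(r, config)
        _, novel = is_rare(r, config)
        decisions.append(
            FilterDecision(
                r.key,
                ARM_B if ok else ARM_NONE,
                "actionable" if ok else None,
                tuple(reasons) if reasons else (Reason("clinical_annotation", None, False),),
                novel,
            )
        )
    return decisions


def apply_filters(
    records: Sequence[VariantRecord],
    composites: Mapping[str, CompositeResult],
    config: FilterConfig | None = None,
) -> list[FilterDecision]:
    """Merged two-arm decisions with B-over-A precedence.

    The arms are disjoint: a variant qualifying for both strategies is
    assigned to B, so |A| + |B| equals the number of retained variants.
    """
    config = config or FilterConfig()
    a = filter_strategy_A(records, composites, config)
    b = filter_strategy_B(records, config)
    merged = []
    for da, db in zip(a, b):
        if db.arm == ARM_B:
            merged.append(
                FilterDecision(db.variant_key, ARM_B, db.subcategory,
                               db.reasons + da.reasons, da.novel)
            )
        else:
            merged.append(
                FilterDecision(da.variant_key, da.arm, da.subcategory,
                               da.reasons + db.reasons, da.novel)
            )
    return merged


def replay_arm(decision: FilterDecision) -> str:
    """Recompute the arm assignment from the decision's reasons chain alone."""
    outcomes = {}
    for reason in decision.reasons:
        outcomes.setdefault(reason.rule, reason.outcome)
        outcomes[reason.rule] = outcomes[reason.rule] or reason.outcome
    if outcomes.get("pharmgkb_tier") or outcomes.get("clinvar_status"):
        return ARM_B
    if outcomes.get("rarity") and (
        outcomes.get("opf_classification")
        or outcomes.get("splice_scores")
        or outcomes.get("lof_consequence")
    ):
        return ARM_A
    return ARM_NONE


def decisions_to_rows(decisions: Sequence[FilterDecision]) -> list[dict]:
    """Serialize decisions for TSV output (reasons as 'rule=observed→outcome;...')."""
    rows = []
    for d in decisions:
        rows.append({
            "variant_key": d.variant_key,
            "arm": d.arm,
            "subcategory": d.subcategory or ".",
            "novel": int(d.novel),
            "reasons": ";".join(
                f"{r.rule}={r.observed}->{int(r.outcome)}" for r in d.reasons
            ),
        })
    return rows
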