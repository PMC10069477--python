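"""Cohort summary: tallies and percentages by arm, category, gene class, gene.

Percentages are computed as round-half-away-from-zero to one decimal, the
convention that reproduces standard published tallies (e.g. 123/148 → 83.1).
Denominators follow the summary definitions: arm and consequence-category
shares over the retained total, per-gene shares over the rare/novel missense
set, strategy-B breakdown shares over |B|, and the HWE share over the number
of testable variants. Undefined percentages (zero denominator) render blank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

from .data_model import GenePanel, VariantRecord
from .popgen import HweResult
from .variant_filters import ARM_A, ARM_B, ARM_NONE, FilterDecision

logger = logging.getLogger("pgxpanel")

_B_CONSEQUENCE_BUCKETS = {
    "missense": "missense",
    "nonsense": "lof",
    "frameshift": "lof",
    "splice_site": "lof",
    "utr3": "utr3",
    "promoter": "promoter",
    "synonymous": "synonymous",
}


class ConsistencyError(ValueError):
    """A decision references a variant absent from the record set."""


def pct(count: int, denominator: int) -> Optional[float]:
    """Percentage share, rounded half away from zero to one decimal.

    Returns None (rendered blank) when the denominator is zero.
    """
    if denominator == 0:
        return None
    val = Decimal(100 * count) / Decimal(denominator)
    return float(val.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    n_total: int
    by_arm: dict[str, int]
    by_category: dict[str, int]
    by_gene_class: dict[str, int]
    by_gene: dict[str, int]  # per-gene counts within rare/novel missense
    n_novel: int
    b_breakdown: dict[str, int]
    hwe_summary: tuple[int, int, tuple[str, ...]]  # (n_tested, n_in_hwe, deviating keys)
    percentages: dict[str, Optional[float]]


def summarize(
    decisions: Sequence[FilterDecision],
    records: Sequence[VariantRecord],
    panel: GenePanel,
    hwe: Sequence[tuple[str, HweResult]] = (),
    exclusions: Mapping[str, str] | None = None,
) -> CohortSummary:
    """Tally retained variants into the cohort summary.

    ``exclusions`` maps variant keys to a reason (e.g. a Sanger-identified
    false positive); excluded variants are dropped before tallying, logged.
    The result is invariant to the ordering of the decisions list.
    """
    by_key = {r.key: r for r in records}
    exclusions = exclusions or {}
    kept: list[FilterDecision] = []
    for d in sorted(decisions, key=lambda d: d.variant_key):
        if d.variant_key not in by_key:
            raise ConsistencyError(f"decision for unknown variant {d.variant_key}")
        if d.variant_key in exclusions:
            logger.info("excluding %s from summary: %s",
                        d.variant_key, exclusions[d.variant_key])
            continue
        if d.arm != ARM_NONE:
            kept.append(d)

    n_total = len(kept)
    by_arm = {ARM_A: 0, ARM_B: 0}
    by_category = {"rare_missense_pathogenic": 0, "lof": 0,
                   "splice_deleterious": 0, "actionable": 0}
    by_gene_class = {"pharmacodynamic": 0, "phase1_metabolism": 0, "transporter": 0}
    by_gene: dict[str, int] = {}
    b_breakdown = {"missense": 0, "lof": 0, "utr3": 0, "promoter": 0, "synonymous": 0}
    n_novel = 0

    for d in kept:
        r = by_key[d.variant_key]
        by_arm[d.arm] += 1
        if d.subcategory in by_category:
            by_category[d.subcategory] += 1
        cls = panel.gene_class(r.gene)
        if cls is not None:
            by_gene_class[cls] += 1
        if d.novel:
            n_novel += 1
        if d.subcategory == "rare_missense_pathogenic":
            by_gene[r.gene] = by_gene.get(r.gene, 0) + 1
        if d.arm == ARM_B:
            bucket = _B_CONSEQUENCE_BUCKETS.get(r.consequence)
            if bucket is not None:
                b_breakdown[bucket] += 1

    deviating = tuple(sorted(k for k, h in hwe if h.defined and h.in_hwe is False))
    n_tested = sum(1 for _, h in hwe if h.defined)
    n_in_hwe = sum(1 for _, h in hwe if h.defined and h.in_hwe)
    n_b = by_arm[ARM_B]
    n_missense = by_category["rare_missense_pathogenic"]

    percentages: dict[str, Optional[float]] = {
        "arm_A": pct(by_arm[ARM_A], n_total),
        "arm_B": pct(by_arm[ARM_B], n_total),
        "rare_missense_pathogenic": pct(n_missense, n_total),
        "lof": pct(by_category["lof"], n_total),
        "splice_deleterious": pct(by_category["splice_deleterious"], n_total),
        "actionable": pct(by_category["actionable"], n_total),
        "pharmacodynamic": pct(by_gene_class["pharmacodynamic"], n_total),
        "phase1_metabolism": pct(by_gene_class["phase1_metabolism"], n_total),
        "transporter": pct(by_gene_class["transporter"], n_total),
        "novel": pct(n_novel, n_total),
        "hwe_in_equilibrium": pct(n_in_hwe, n_tested),
    }
    for gene in sorted(by_gene):
        percentages[f"gene:{gene}"] = pct(by_gene[gene], n_missense)
    for bucket in b_breakdown:
        percentages[f"B:{bucket}"] = pct(b_breakdown[bucket], n_b)

    return CohortSummary(
        n_total=n_total, by_arm=by_arm, by_category=by_category,
        by_gene_class=by_gene_class, by_gene=dict(sorted(by_gene.items())),
        n_novel=n_novel, b_breakdown=b_breakdown,
        hwe_summary=(n_tested, n_in_hwe, deviating),
        percentages=percentages,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _fmt_pct(v: Optional[float]) -> str:
    return "" if v is None else f"{v:.1f}"


def render_tables(summary: CohortSummary, format: str = "tsv") -> str:
    """Render the summary as deterministic TSV or markdown text."""
    if format not in ("tsv", "markdown"):
        raise ValueError(f"unknown format {format!r}")

    rows: list[tuple[str, str, str, str]] = [("section", "item", "count", "percent")]
    rows.append(("total", "retained_variants", str(summary.n_total), ""))
    for arm in (ARM_A, ARM_B):
        rows.append(("arm", arm, str(summary.by_arm[arm]),
                     _fmt_pct(summary.percentages[f"arm_{arm}"])))
    for cat in ("rare_missense_pathogenic", "lof", "splice_deleterious", "actionable"):
        rows.append(("category", cat, str(summary.by_category[cat]),
                     _fmt_pct(summary.percentages[cat])))
    for cls in ("pharmacodynamic", "phase1_metabolism", "transporter"):
        rows.append(("gene_class", cls, str(summary.by_gene_class[cls]),
                     _fmt_pct(summary.percentages[cls])))
    for gene, count in summary.by_gene.items():
        rows.append(("gene_missense", gene, str(count),
                     _fmt_pct(summary.percentages[f"gene:{gene}"])))
    rows.append(("novel", "novel_variants", str(summary.n_novel),
                 _fmt_pct(summary.percentages["novel"])))
    for bucket in ("missense", "lof", "utr3", "promoter", "synonymous"):
        rows.append(("strategy_B", bucket, str(summary.b_breakdown[bucket]),
                     _fmt_pct(summary.percentages[f"B:{bucket}"])))
    n_tested, n_in_hwe, deviating = summary.hwe_summary
    rows.append(("hwe", "tested", str(n_tested), ""))
    rows.append(("hwe", "in_equilibrium", str(n_in_hwe),
                 _fmt_pct(summary.percentages["hwe_in_equilibrium"])))
    rows.append(("hwe", "deviating", str(len(deviating)), ""))

    if format == "tsv":
        return "\n".join("\t".join(r) for r in rows) + "\n"
    header, *body = rows
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join(" --- " for _ in header) + "|"]
    lines += ["| " + " | ".join(r) + " |" for r in body]
    return "\n".join(lines) + "\n"
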