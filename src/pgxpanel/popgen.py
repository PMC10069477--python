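"""Population-genetics statistics for the cohort.

Covers per-variant allele/genotype frequencies, Hardy–Weinberg equilibrium
(HWE) testing by the 1-df chi-square goodness-of-fit test (with an exact test
available as a low-count oracle and optional mode), cohort-versus-reference
allele-frequency comparison via the 2x2 Pearson chi-square with Yates
continuity correction and Bonferroni adjustment, fold-change reporting, and
the finite-population-corrected sample-size formula used to plan the cohort.

Significance defaults to alpha = 0.05 throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import gammaln

logger = logging.getLogger("pgxpanel")


class NoDataError(ValueError):
    """All genotypes missing, or an empty allele pool."""


# ---------------------------------------------------------------------------
# Allele and genotype frequencies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyResult:
    counts: tuple[int, int, int]  # hom-ref, het, hom-alt
    n_called: int
    alt_af: float
    genotype_fractions: tuple[float, float, float]


def allele_and_genotype_frequencies(dosages: Sequence[int] | np.ndarray) -> FrequencyResult:
    """Alt allele frequency and genotype fractions from a dosage vector.

    Missing calls (negative dosage) are excluded from all denominators.
    """
    d = np.asarray(dosages)
    d = d[d >= 0]
    n = d.size
    if n == 0:
        raise NoDataError("all genotypes missing")
    counts = (int(np.sum(d == 0)), int(np.sum(d == 1)), int(np.sum(d == 2)))
    alt_af = (counts[1] + 2 * counts[2]) / (2 * n)
    fracs = tuple(c / n for c in counts)
    return FrequencyResult(counts, n, alt_af, fracs)


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HweResult:
    observed: tuple[int, int, int]
    expected: Optional[tuple[float, float, float]]
    chi2: Optional[float]
    df: int
    p_value: Optional[float]
    in_hwe: Optional[bool]
    defined: bool  # False for monomorphic variants (test undefined, not a failure)


def hwe_test(observed: tuple[int, int, int], alpha: float = 0.05) -> HweResult:
    """1-df chi-square goodness-of-fit test for HWE.

    Expected counts come from the sample allele frequencies (n·p², 2npq,
    n·q²), so the statistic is Σ(obs − exp)²/exp on the three genotype
    classes with one degree of freedom. Monomorphic variants make the test
    undefined and are flagged rather than treated as HWE failures.
    """
    n00, n01, n11 = (int(c) for c in observed)
    if min(n00, n01, n11) < 0:
        raise ValueError(f"negative genotype count in {observed}")
    n = n00 + n01 + n11
    if n < 1:
        raise NoDataError("no called genotypes")
    q = (n01 + 2 * n11) / (2 * n)
    p = 1.0 - q
    if q == 0.0 or q == 1.0:
        logger.info("monomorphic variant (q=%g): HWE test undefined", q)
        return HweResult((n00, n01, n11), None, None, 1, None, None, False)
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    chi2 = sum((o - e) ** 2 / e for o, e in zip((n00, n01, n11), expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HweResult(
        (n00, n01, n11), expected, float(chi2), 1, p_value, p_value > alpha, True
    )


def hwe_exact_test(observed: tuple[int, int, int]) -> float:
    """Exact HWE test p-value (sum of probabilities ≤ that of the observed
    heterozygote count, conditional on allele counts).

    Serves as the low-count oracle alongside the chi-square mode; uses the
    log-factorial form of the conditional distribution of heterozygote counts.
    """
    n00, n01, n11 = (int(c) for c in observed)
    n = n00 + n01 + n11
    na = n01 + 2 * n11  # alt allele count
    if n < 1:
        raise NoDataError("no called genotypes")
    if na == 0 or na == 2 * n:
        return 1.0

    rare = min(na, 2 * n - na)
    hets = np.arange(rare % 2, rare + 1, 2)

    def log_prob(nab: np.ndarray) -> np.ndarray:
        naa = (rare - nab) // 2
        nbb = n - nab - naa
        return (
            gammaln(n + 1) - gammaln(naa + 1) - gammaln(nab + 1) - gammaln(nbb + 1)
            + nab * math.log(2)
            + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
        )

    logs = log_prob(hets)
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs_prob = probs[hets == n01][0]
    # tolerance guards against float ties in the conditional distribution
    return float(min(1.0, probs[probs <= obs_prob * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# Cross-population comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopComparison:
    variant_key: Optional[str]
    cohort_ac: int
    cohort_an: int
    ref_ac: int
    ref_an: int
    cohort_af: float
    ref_af: float
    chi2_yates: float
    p_raw: float
    p_bonferroni: float
    m: int
    significant: bool
    fold_change: Optional[float]
    low_count_warning: bool


def yates_chi2(table: np.ndarray) -> float:
    """2x2 Pearson chi-square with Yates continuity correction.

    Implements Σ(max(0, |obs − exp| − 0.5))²/exp with expected counts from
    the margins; the correction never overshoots past the expected value
    (standard convention), so a table with obs = exp gives exactly 0.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    total = obs.sum()
    if total <= 0:
        raise NoDataError("empty contingency table")
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    if np.any(exp == 0):
        raise NoDataError("zero marginal in contingency table")
    delta = np.maximum(np.abs(obs - exp) - 0.5, 0.0)
    return float(((delta ** 2) / exp).sum())


def compare_populations(
    cohort_ac: int,
    cohort_an: int,
    ref_ac: int,
    ref_an: int,
    m: int = 1,
    alpha: float = 0.05,
    variant_key: Optional[str] = None,
) -> PopComparison:
    """Compare cohort vs reference alt-allele frequencies.

    Builds the 2x2 allele-count table (alt/ref alleles x cohort/reference),
    applies the Yates-corrected chi-square with 1 df and a Bonferroni
    adjustment over ``m`` comparisons. Expected cells below 1 trigger a
    low-count warning recommending an exact test. ``fold_change`` is
    cohort_af / ref_af, undefined (None) when ref_af is 0.
    """
    for label, ac, an in (("cohort", cohort_ac, cohort_an), ("reference", ref_ac, ref_an)):
        if not 0 <= ac <= an:
            raise ValueError(f"{label} allele counts invalid: ac={ac}, an={an}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if cohort_an == 0 or ref_an == 0:
        raise NoDataError("zero allele number (an = 0)")
    table = np.array(
        [[cohort_ac, cohort_an - cohort_ac], [ref_ac, ref_an - ref_ac]], dtype=float
    )
    exp = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    low = bool(np.any(exp < 1))
    if low:
        logger.warning(
            "expected cell below 1 for %s; Yates chi-square unreliable, "
            "consider an exact test", variant_key or "comparison",
        )
    chi2 = yates_chi2(table)
    p_raw = float(stats.chi2.sf(chi2, df=1))
    p_bonf = min(1.0, m * p_raw)
    cohort_af = cohort_ac / cohort_an
    ref_af = ref_ac / ref_an
    fold = (cohort_af / ref_af) if ref_af > 0 else None
    return PopComparison(
        variant_key, cohort_ac, cohort_an, ref_ac, ref_an, cohort_af, ref_af,
        chi2, p_raw, p_bonf, m, p_bonf < alpha, fold, low,
    )


# ---------------------------------------------------------------------------
# Cohort sample-size formula
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleSizeParams:
    z: float = 1.96
    p: float = 0.16
    e: float = 0.03
    N: Optional[int] = None  # None = infinite population (no correction)


def sample_size(params: SampleSizeParams) -> int:
    """Sample size for estimating a proportion, finite-population corrected.

    n = ceil( [z²p(1−p)/e²] / [1 + z²p(1−p)/(e²N)] ); with N = None the
    uncorrected z²p(1−p)/e² is used.
    """
    if not 0.0 < params.p < 1.0:
        raise ValueError(f"p must be in (0,1), got {params.p}")
    if params.e <= 0.0 or params.e >= 1.0:
        raise ValueError(f"e must be in (0,1), got {params.e}")
    n0 = params.z ** 2 * params.p * (1.0 - params.p) / params.e ** 2
    if params.N is None:
        return math.ceil(n0)
    if params.N < 1:
        raise ValueError(f"N must be >= 1, got {params.N}")
    return math.ceil(n0 / (1.0 + n0 / params.N))
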