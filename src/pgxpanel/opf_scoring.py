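"""Optimized prediction framework (OPF) composite pathogenicity score.

Missense variants get a per-algorithm binary call (1 = deleterious, 0 =
functionally neutral) by thresholding each available predictor score (LRT,
MutationAssessor, PROVEAN, VEST3, CADD); the composite is the mean of the
available binary calls, and a variant is classified *functionally relevant*
when the composite reaches the classification cutoff (default 0.6, i.e. at
least 3 of 5 predictors deleterious).

The framework applies to single-nucleotide missense variants only; merged
multi-nucleotide variants are outside its domain and are never scored here.
Threshold values ship as a packaged YAML config and every scoring run logs
the thresholds in effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .data_model import VariantRecord

logger = logging.getLogger("pgxpanel")

HIGHER = "higher_is_deleterious"
LOWER = "lower_is_deleterious"

FUNCTIONALLY_RELEVANT = "functionally_relevant"
NEUTRAL = "neutral"
UNSCORABLE = "unscorable"


class ThresholdConfigError(ValueError):
    """Unknown algorithm or malformed thresholds configuration."""


@dataclass(frozen=True)
class AlgorithmThreshold:
    threshold: float
    direction: str

    def __post_init__(self):
        if self.direction not in (HIGHER, LOWER):
            raise ThresholdConfigError(f"unknown direction {self.direction!r}")


@dataclass(frozen=True)
class PredictorThresholds:
    """Per-algorithm thresholds plus composite classification parameters."""

    algorithms: Mapping[str, AlgorithmThreshold]
    min_available: int = 3
    classification_cutoff: float = 0.6

    def __post_init__(self):
        if not 1 <= self.min_available <= len(self.algorithms):
            raise ThresholdConfigError(
                f"min_available {self.min_available} outside "
                f"1..{len(self.algorithms)}"
            )
        if not 0.0 < self.classification_cutoff <= 1.0:
            raise ThresholdConfigError(
                f"classification_cutoff {self.classification_cutoff} outside (0, 1]"
            )


@dataclass(frozen=True)
class CompositeResult:
    variant_key: str
    binary_calls: Mapping[str, int]
    n_available: int
    composite: Optional[float]
    classification: str


def default_thresholds() -> PredictorThresholds:
    """Load the packaged default thresholds config."""
    text = resources.files("pgxpanel.data").joinpath("opf_thresholds.yaml").read_text()
    return _parse_thresholds(yaml.safe_load(text))


def load_thresholds(path: str | Path) -> PredictorThresholds:
    with open(path) as fh:
        return _parse_thresholds(yaml.safe_load(fh))


def _parse_thresholds(cfg: dict) -> PredictorThresholds:
    try:
        algos = {
            name: AlgorithmThreshold(float(spec["threshold"]), str(spec["direction"]))
            for name, spec in cfg["algorithms"].items()
        }
    except (KeyError, TypeError) as exc:
        raise ThresholdConfigError(f"malformed thresholds config: {exc}") from exc
    return PredictorThresholds(
        algorithms=algos,
        min_available=int(cfg.get("min_available", 3)),
        classification_cutoff=float(cfg.get("classification_cutoff", 0.6)),
    )


def binarize(score: float, algorithm: str, thresholds: PredictorThresholds) -> int:
    """Binarize one predictor score; the threshold itself counts as deleterious."""
    spec = thresholds.algorithms.get(algorithm)
    if spec is None:
        raise ThresholdConfigError(f"no threshold configured for {algorithm!r}")
    if spec.direction == HIGHER:
        return int(score >= spec.threshold)
    return int(score <= spec.threshold)


def composite_score(
    record: VariantRecord, thresholds: PredictorThresholds | None = None
) -> CompositeResult:
    """Compute the OPF composite for a missense variant.

    The composite averages the binary calls over *available* predictor scores;
    with fewer than ``min_available`` scores the variant is unscorable (a
    value, not an error) and is logged.
    """
    thresholds = thresholds or default_thresholds()
    if record.consequence != "missense":
        raise ValueError(
            f"OPF composite applies to missense SNVs only, got "
            f"{record.consequence} for {record.key}"
        )
    calls = {
        algo: binarize(score, algo, thresholds)
        for algo, score in record.predictor_scores.items()
        if algo in thresholds.algorithms
    }
    n = len(calls)
    if n < thresholds.min_available:
        logger.warning(
            "variant %s unscorable: %d predictor scores available, need %d",
            record.key, n, thresholds.min_available,
        )
        return CompositeResult(record.key, calls, n, None, UNSCORABLE)
    comp = sum(calls.values()) / n
    cls = FUNCTIONALLY_RELEVANT if comp >= thresholds.classification_cutoff else NEUTRAL
    return CompositeResult(record.key, calls, n, comp, cls)


def score_missense(
    records, thresholds: PredictorThresholds | None = None
) -> dict[str, CompositeResult]:
    """Score every missense record; returns variant key → CompositeResult."""
    thresholds = thresholds or default_thresholds()
    logger.info(
        "OPF thresholds in effect: %s; min_available=%d cutoff=%.2f",
        {a: (t.threshold, t.direction) for a, t in thresholds.algorithms.items()},
        thresholds.min_available, thresholds.classification_cutoff,
    )
    return {
        r.key: composite_score(r, thresholds)
        for r in records
        if r.consequence == "missense"
    }
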