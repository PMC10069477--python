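import numpy as np
import pytest

from pgxpanel import (
    GenotypeMatrix,
    SimulationConfig,
    VariantRecord,
    default_panel,
    default_thresholds,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def thresholds():
    return default_thresholds()


@pytest.fixture(scope="session")
def cohort():
    """One seeded paper-scale cohort shared across tests (625 individuals)."""
    return simulate_cohort(SimulationConfig(seed=7))


def make_missense(scores=None, freqs=None, dbsnp=None, **kw) -> VariantRecord:
    """A minimal valid missense record for rule-level tests."""
    defaults = dict(
        chrom="19", pos=1000, ref="G", alt="A", gene="RYR1",
        transcript="NM_000540", consequence="missense", strand="+",
        cds_pos=4, ref_codon="GCT",  # codon pos 1, ref G
        predictor_scores=scores or {},
        ref_freqs=freqs or {},
        dbsnp_id=dbsnp,
    )
    defaults.update(kw)
    return VariantRecord(**defaults)


def single_variant_matrix(key, dosages, phases=None, sample_prefix="S"):
    n = len(dosages)
    dosage = np.array([dosages], dtype=np.int8)
    if phases is None:
        phases = [0 if d == 1 else -1 for d in dosages]
    return GenotypeMatrix(
        variant_keys=[key],
        sample_ids=[f"{sample_prefix}{i}" for i in range(n)],
        dosage=dosage,
        phase=np.array([phases], dtype=np.int8),
    )
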