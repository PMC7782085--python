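import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ampliconcord import PanelManifest, SimulationConfig, simulate_cohort
from ampliconcord.core_io import Amplicon

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_manifest() -> PanelManifest:
    """Three amplicons over two genes on one chromosome."""
    return PanelManifest([
        Amplicon("a1", "chr1", 100, 240, 20, 20, "GENEA"),
        Amplicon("a2", "chr1", 300, 440, 20, 20, "GENEA"),
        Amplicon("a3", "chr1", 500, 640, 20, 20, "GENEB"),
    ])


@pytest.fixture(scope="session")
def default_cohort():
    """One default-condition synthetic cohort, shared across tests."""
    return simulate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def cohort_battery():
    """100 seeded default cohorts run end-to-end; used by the planted-event
    recovery and deletion-vs-variant concordance checks."""
    from ampliconcord import run_pipeline
    from ampliconcord.pipeline import recovery_stats

    agg = {k: {"tp": 0, "fn": 0, "fp": 0}
           for k in ("pathogenic_variant", "amplification",
                     "homozygous_deletion")}
    n_ordered = 0
    n_cohorts = 0
    for seed in range(100):
        cohort = simulate_cohort(SimulationConfig(seed=seed))
        result = run_pipeline(cohort)
        stats = recovery_stats(cohort, result)
        for k in agg:
            for m in agg[k]:
                agg[k][m] += stats[k][m]
        pct = result.report.per_class_pct
        v, d = pct["pathogenic_variant"], pct["homozygous_deletion"]
        if v is not None and d is not None:
            n_cohorts += 1
            if d < v:
                n_ordered += 1
    return {"recovery": agg, "n_deletion_below_variant": n_ordered,
            "n_cohorts_compared": n_cohorts}


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
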