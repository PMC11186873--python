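import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from episig import (
    PipelineConfig,
    SimulationConfig,
    simulate_cohort,
    simulate_overlapping_syndromes,
)
from episig.containers import BetaMatrix
from episig.pipeline import run_discovery

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


#: study-scale discovery conditions: 13 discovery + 13 validation cases
#: against a 200-sample control pool, 300 planted probes at delta-beta 0.15
DISCOVERY_CONFIG = SimulationConfig(
    n_probes=20000,
    signature_size=300,
    effect_delta_beta=0.15,
    n_cases=13,
    n_validation_cases=13,
    n_control_pool=200,
    seed=42,
)


@pytest.fixture(scope="session")
def discovery_sim():
    beta, samples, truth = simulate_cohort(DISCOVERY_CONFIG)
    return beta, samples, truth


@pytest.fixture(scope="session")
def discovery_result(discovery_sim):
    beta, _, truth = discovery_sim
    config = PipelineConfig(holdout_cohorts=("syndrome_a_validation",))
    return run_discovery(
        beta, truth.reference_profiles, ("syndrome_a",), config
    )


@pytest.fixture(scope="session")
def overlap_sim():
    """Three case cohorts: b shares half of a's signature, c is unrelated."""
    config = SimulationConfig(
        n_probes=20000,
        signature_size=300,
        effect_delta_beta=0.15,
        n_cases=13,
        n_control_pool=200,
        overlap_fraction_secondary=0.5,
        overlap_fraction_tertiary=0.0,
        seed=7,
    )
    beta, samples, truth = simulate_overlapping_syndromes(
        config, n_secondary=14, n_tertiary=4
    )
    return beta, samples, truth


def make_manifest(probe_ids, **overrides) -> pd.DataFrame:
    n = len(probe_ids)
    base = {
        "chrom": ["chr1"] * n,
        "start": np.arange(n) * 1000 + 100,
        "cgi_class": ["island"] * n,
        "gene_class": ["promoter"] * n,
        "snp_flag": [False] * n,
        "crossreactive_flag": [False] * n,
        "excluded_by_vendor_flag": [False] * n,
    }
    base.update(overrides)
    manifest = pd.DataFrame(base, index=pd.Index(probe_ids, name="probe_id"))
    manifest["end"] = manifest["start"] + 2
    return manifest


def make_beta(values: np.ndarray, probe_ids=None, sample_ids=None) -> BetaMatrix:
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"cg{i:05d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    return BetaMatrix(df, make_manifest(probe_ids))


def make_sheet(rows) -> pd.DataFrame:
    """rows: iterable of (sample_id, sex, age, group, cohort)."""
    df = pd.DataFrame(
        rows, columns=["sample_id", "sex", "age_years", "group", "cohort"]
    )
    return df.set_index("sample_id")
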