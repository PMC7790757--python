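import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from crypticsplice import SimConfig, simulate_cohort
from crypticsplice.junction_core import (
    build_si_matrix,
    classify_junctions,
    collect_junctions,
    junctions_from_frame,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: compact cohort reused by several module tests (session-scoped: read-only)
SMALL_CONFIG = SimConfig(
    seed=7,
    n_genes=30,
    n_controls=40,
    n_groupA=4,
    n_groupB=3,
    n_sensitive_junctions=12,
)


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_samples(small_cohort):
    return {s: junctions_from_frame(t) for s, t in small_cohort.sj_tables.items()}


@pytest.fixture(scope="session")
def small_classification(small_cohort, small_samples):
    return classify_junctions(collect_junctions(small_samples), small_cohort.model.exons)


@pytest.fixture(scope="session")
def small_matrix(small_cohort, small_samples, small_classification):
    res = small_classification
    return build_si_matrix(
        small_samples, res.pairs, res.canonical, groups=small_cohort.truth.sample_groups
    )


@pytest.fixture(scope="session")
def cryptic_id_map(small_cohort):
    """Truth canonical junction id -> its cryptic (aberrant) junction id."""
    jc = small_cohort.model.junctions.set_index("junction_id")

    def cid(jid: str) -> str:
        r = jc.loc[jid]
        return f"{r.chrom}:{r.cryptic_start}-{r.cryptic_end}"

    return cid


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
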