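import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cscm_sieve.core import CohortGenotypes, GenomeBuild, VariantRecord
from cscm_sieve.synth import SimConfig, default_gene_models, simulate_cohort

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gene_models():
    return default_gene_models()


@pytest.fixture(scope="session")
def default_build():
    return SimConfig().build


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated cohort reused across read-only tests."""
    return simulate_cohort(SimConfig(seed=3, n_background_variants=3000))


def make_cohort(genotypes, positions=None, chrom="chr1", samples=None, roles=None):
    """Tiny hand-built cohort: genotypes is (n_variants, n_samples) of codes."""
    gt = np.asarray(genotypes, dtype=np.int8)
    n_var, n_samp = gt.shape
    positions = positions or [1000 * (i + 1) for i in range(n_var)]
    samples = samples or [f"s{j}" for j in range(n_samp)]
    build = GenomeBuild(("chr1", "chr2"), (10_000_000, 10_000_000))
    variants = [VariantRecord(chrom, p, "A", "G") for p in positions]
    return CohortGenotypes(build, variants, samples, gt, roles)
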