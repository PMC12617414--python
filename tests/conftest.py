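import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sirpa_allo import default_panel
from sirpa_allo.haplotyping import Haplotype, HaplotypePanel, SiteType, VariantSite

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def panel():
    return default_panel()


def make_random_panel(rng: np.random.Generator, n_sites: int, n_haps: int) -> HaplotypePanel:
    """A random biallelic panel with distinct haplotype vectors, for oracles."""
    sites = tuple(
        VariantSite(f"rsX{i}", "20", 1000 + 10 * i, "A", "G", SiteType.SNP)
        for i in range(n_sites)
    )
    n_haps = min(n_haps, 2**min(n_sites, 30))  # cannot exceed the distinct vectors
    vectors: set[tuple[str, ...]] = set()
    while len(vectors) < n_haps:
        vectors.add(tuple(rng.choice(["A", "G"], size=n_sites)))
    haps = tuple(Haplotype(f"H{k}", v) for k, v in enumerate(sorted(vectors)))
    return HaplotypePanel(sites, haps)
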