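import numpy as np
import pytest
from hypothesis import settings

import grsim

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def gr_mini():
    """The GR-mini fixture: 100-site, 400-haplotype founder-block panel over
    300 kb with a hotspot-punctuated map."""
    spec = grsim.gr_mini_spec(seed=3)
    return grsim.make_panel(spec), grsim.make_map(spec)


@pytest.fixture()
def small_panel():
    """A small random panel for exact-arithmetic checks."""
    rng = np.random.default_rng(11)
    n_sites, n_hap = 12, 40
    alleles = (rng.random((n_sites, n_hap)) < rng.uniform(0.1, 0.9, (n_sites, 1)))
    sites = [
        grsim.SiteRecord(f"s{i}", 1000 * (i + 1), "A", "C")
        for i in range(n_sites)
    ]
    return grsim.HaplotypePanel(sites=sites, alleles=alleles.astype(np.uint8))


def panel_from_columns(cols):
    """Build a tiny panel from a list of per-site allele tuples."""
    alleles = np.asarray(cols, dtype=np.uint8)
    sites = [
        grsim.SiteRecord(f"s{i}", 100 * (i + 1), "A", "G")
        for i in range(alleles.shape[0])
    ]
    return grsim.HaplotypePanel(sites=sites, alleles=alleles)
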