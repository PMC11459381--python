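import numpy as np
import pandas as pd
import pytest

from spikequant.io_ingest import CountTable, SampleRecord, StandardSpec
from spikequant.synthetic import (SimulationConfig, StandardConfig,
                                  TaxonProfile, simulate_study)

UTC0 = pd.Timestamp("2021-11-20T00:00:00Z")


def make_sample(sample_id="S001R1", site_id="S001", replicate=1,
                volume_L=2.0, lat=30.0, lon=-152.0, hours=0.0):
    return SampleRecord(sample_id=sample_id, site_id=site_id,
                        replicate=replicate, volume_L=volume_L,
                        lat=lat, lon=lon,
                        timestamp=UTC0 + pd.Timedelta(hours=hours))


def make_standard(name="stdA", copies_added=1e6, asv_ids=("sA",)):
    """Standard with an explicit copy load (mass fields are placeholders)."""
    return StandardSpec(name=name, mass_ng=1.0, genome_size_bp=1e6,
                        copies_per_genome=1, asv_ids=frozenset(asv_ids),
                        copies_added=copies_added)


@pytest.fixture
def site_counts():
    """One site, 3 replicates, 3 single-ASV standards, 2 community ASVs."""
    asvs = ["A", "B", "sA", "sB", "sC"]
    samples = ["S001R1", "S001R2", "S001R3"]
    counts = np.array([
        [100, 110, 90],   # A
        [10, 12, 8],      # B
        [50, 55, 45],     # sA
        [40, 42, 38],     # sB
        [60, 58, 62],     # sC
    ])
    table = CountTable(asv_ids=asvs, sample_ids=samples, counts=counts)
    meta = [make_sample(f"S001R{r}", "S001", r, volume_L=2.0,
                        hours=0.05 * (r - 1)) for r in (1, 2, 3)]
    standards = [make_standard("stdA", 1e6, ("sA",)),
                 make_standard("stdB", 2e6, ("sB",)),
                 make_standard("stdC", 5e5, ("sC",))]
    return table, meta, standards


@pytest.fixture(scope="session")
def small_sim_config():
    """Cut-down transect for fast end-to-end tests."""
    return SimulationConfig(n_sites=10, reads_per_sample=20_000)


@pytest.fixture(scope="session")
def small_study(small_sim_config):
    return simulate_study(small_sim_config, seed=7)
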