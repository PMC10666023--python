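import numpy as np
import pytest

from dsbend import (AnalysisConfig, GenomeSpec, HotspotSet, bin_coverage,
                    example_genome, genotype_preset, rpm_normalize,
                    simulate_end_reads, simulate_hotspots)


@pytest.fixture(scope="session")
def genome():
    return example_genome()


@pytest.fixture(scope="session")
def tiny_genome():
    return GenomeSpec(chroms={"chr1": 100_000, "chr2": 60_000},
                      par=("chr2", 50_000, 58_000))


@pytest.fixture(scope="session")
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def catalog(genome):
    """Dense mixed catalog used for profile-scale simulations."""
    prdm9 = simulate_hotspots(genome, 2000, hclass="prdm9", seed=1)
    default = simulate_hotspots(genome, 1000, hclass="default", seed=2)
    return prdm9, default, HotspotSet.concat([prdm9, default])


@pytest.fixture(scope="session")
def wildtype_profile_inputs(genome, catalog, cfg):
    """Wildtype reads binned at 1 bp and RPM-normalized, with its catalog.

    Session-scoped: the 1-bp track is the most expensive fixture and
    several resection/profile tests share it read-only.
    """
    prdm9, _, cat = catalog
    params = genotype_preset("wildtype").replace(total_reads=250_000, seed=7)
    ends = simulate_end_reads(genome, cat, params)
    track = rpm_normalize(bin_coverage(ends, genome, cfg.profile_bin_bp))
    return track, prdm9, params
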