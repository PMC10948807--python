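import numpy as np
import pandas as pd
import pytest

from coraligv.config import DepthModel, FilterConfig, SimulationConfig
from coraligv.genotypes import GenotypeMatrix, apply_filters
from coraligv.simulate import simulate_dataset


def make_gm(gt, sample_ids=None, quals=None, dp=None, sp=None,
            ref="A", alt="T") -> GenotypeMatrix:
    """Build a GenotypeMatrix from a (n_sites, n_samples) dosage array.

    Dosages: 0 hom-REF, 1 het, 2 hom-ALT, -1 missing.
    """
    gt = np.asarray(gt, dtype=np.int8)
    n_sites, n_samples = gt.shape
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    sites = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, n_sites + 1) * 10,
        "ref": ref, "alt": alt,
        "qual": np.full(n_sites, 100.0) if quals is None else np.asarray(quals, float),
        "biallelic": True,
    })
    dp = np.full(gt.shape, 50, dtype=np.int32) if dp is None else np.asarray(dp, np.int32)
    sp = np.zeros(gt.shape, dtype=np.float32) if sp is None else np.asarray(sp, np.float32)
    return GenotypeMatrix(sample_ids=list(sample_ids), sites=sites, gt=gt, dp=dp, sp=sp)


def recovery_config(seed: int) -> SimulationConfig:
    """Study-condition generator scaled to desk size for repeated runs.

    Separation parameters (divergences, error rate and spread, mutation load
    per site) follow the defaults; site count and colony number are scaled
    down while keeping the per-pair dissimilarity noise close to the
    full-size survey, and the somatic mutation count keeps the default
    0.5-percentage-point mosaic offset at the reduced site count.
    """
    return SimulationConfig(n_colonies=25, n_sites_total=40_000, n_lineages=8,
                            mosaic_mutation_count=400, missing_rate=0.15,
                            depth_model=DepthModel(mean=46, shape=5.0),
                            n_replicated_nubbins=0, seed=seed)


@pytest.fixture(scope="session")
def sim_config() -> SimulationConfig:
    return SimulationConfig(n_colonies=20, n_sites_total=8000, n_lineages=6,
                            mosaic_mutation_count=80, missing_rate=0.2,
                            p_mosaic_colony=0.15, p_chimera_colony=0.15,
                            seed=20240901)


@pytest.fixture(scope="session")
def dataset(sim_config):
    return simulate_dataset(sim_config)


@pytest.fixture(scope="session")
def filtered(dataset):
    return apply_filters(dataset.genotypes, FilterConfig())


@pytest.fixture(scope="session")
def dmatrix(filtered):
    from coraligv.dissimilarity import pairwise_dissimilarity

    return pairwise_dissimilarity(filtered)
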