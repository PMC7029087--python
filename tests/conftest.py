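import numpy as np
import pytest

from hybridscan.admixture_inference import McmcSettings
from hybridscan.core_data import MicrosatDataset, SampleMeta
from hybridscan.hybrid_simulation import AlleleFrequencyModel

N_LOCI = 11


@pytest.fixture
def diagnostic_model() -> AlleleFrequencyModel:
    """Two pools fixed for alternative alleles at every locus."""
    loci = [f"L{i + 1}" for i in range(N_LOCI)]
    alleles = [["100", "102"] for _ in loci]
    one = np.array([1.0, 0.0])
    return AlleleFrequencyModel(
        loci=loci,
        alleles=alleles,
        freqs={
            "fabalis": [one.copy() for _ in loci],
            "obtusata": [one[::-1].copy() for _ in loci],
        },
    )


def make_reference_dataset(n_per_species: int = 12, n_loci: int = N_LOCI) -> MicrosatDataset:
    """Allopatric reference individuals homozygous for species-diagnostic
    alleles."""
    loci = [f"L{i + 1}" for i in range(n_loci)]
    samples, geno = [], []
    for i in range(n_per_species):
        samples.append(SampleMeta(f"fab{i}", "ALF1", "allopatric", "fabalis"))
        geno.append([("100", "100")] * n_loci)
    for i in range(n_per_species):
        samples.append(SampleMeta(f"obt{i}", "ALO1", "allopatric", "obtusata"))
        geno.append([("102", "102")] * n_loci)
    return MicrosatDataset(samples=samples, loci=loci, genotypes=geno)


@pytest.fixture
def reference_dataset() -> MicrosatDataset:
    return make_reference_dataset()


@pytest.fixture
def tiny_mcmc() -> McmcSettings:
    """Short chains for unit tests on strongly informative data."""
    return McmcSettings(burnin=500, sweeps=5_000, replicates=2, seed=11)
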