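import numpy as np
import pytest

from panmag.calling import CallingParams, call_dataset
from panmag.pangenome import build_pangenome
from panmag.species import build_species_model, sample_genomes

SMALL_CONFIG = dict(
    species_id="sp",
    n_core_families=30,
    n_accessory_families=20,
    unique_genes_per_genome=3,
    gene_length_range=(300, 600),
    intergenic_length_range=(200, 400),
    within_family_divergence=0.01,
    rng_seed=7,
)


@pytest.fixture(scope="session")
def small_model():
    return build_species_model(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_genomes(small_model):
    return sample_genomes(small_model, 8, seed=1)


@pytest.fixture(scope="session")
def genome_index(small_model, small_genomes):
    index = {g.genome_id: g for g in small_genomes}
    donors = sample_genomes(small_model, 4, seed=99, id_prefix="donor")
    for d in donors:
        index[d.genome_id] = d
    partners = sample_genomes(small_model, 3, seed=55, genus_partner=True)
    for p in partners:
        index[p.genome_id] = p
    return index


@pytest.fixture(scope="session")
def donor_genomes(genome_index):
    return [g for gid, g in genome_index.items() if gid.startswith("donor")]


@pytest.fixture(scope="session")
def partner_genomes(genome_index):
    return [g for gid, g in genome_index.items() if "_gp_" in gid]


@pytest.fixture(scope="session")
def small_calls(small_genomes, genome_index):
    return call_dataset(small_genomes, CallingParams("normal"), genome_index)


@pytest.fixture(scope="session")
def small_pan(small_calls, small_genomes):
    return build_pangenome(small_calls, [g.genome_id for g in small_genomes],
                           si=90.0, cg_threshold=100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
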