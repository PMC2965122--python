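import numpy as np
import pytest

from barcodegap.seqdata import LocusAlignment, SpeciesMap, SpeciesRecord
from barcodegap import synthetic


def make_alignment(seqs: dict[str, str], locus: str = "toy") -> LocusAlignment:
    return LocusAlignment(locus, tuple(seqs), tuple(seqs.values()))


def make_species_map(assignment: dict[str, str], **extra) -> SpeciesMap:
    return SpeciesMap(
        {acc: SpeciesRecord(species=sp, **extra.get(acc, {})) for acc, sp in assignment.items()}
    )


def random_alignment(
    rng: np.random.Generator, n: int, length: int, alphabet: str = "ACGT", locus: str = "rand"
) -> LocusAlignment:
    chars = np.array(list(alphabet))
    seqs = {
        f"t{i:02d}": "".join(rng.choice(chars, size=length)) for i in range(n)
    }
    return make_alignment(seqs, locus)


@pytest.fixture(scope="session")
def two_species_aln():
    """Two species x two accessions: zero within-species divergence, clear
    between-species differences."""
    seqs = {
        "A1": "ACGTACGTACGTACGTACGT",
        "A2": "ACGTACGTACGTACGTACGT",
        "B1": "ACGTACGTACGTGCGTACTT",
        "B2": "ACGTACGTACGTGCGTACTT",
    }
    return make_alignment(seqs)


@pytest.fixture(scope="session")
def two_species_map():
    return make_species_map({"A1": "A", "A2": "A", "B1": "B", "B2": "B"})


@pytest.fixture(scope="session")
def sim_default():
    """The default study design: 16 species, 5 accessions each, 4 regions,
    4 loci, no gene flow."""
    cfg = synthetic.SimConfig(seed=101)
    return synthetic.simulate_species_dataset(cfg) + (cfg,)


@pytest.fixture(scope="session")
def sim_aflp():
    cfg = synthetic.SimConfig(seed=202, n_species=13, accessions_per_species=4)
    return synthetic.simulate_band_matrix(cfg) + (cfg,)
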