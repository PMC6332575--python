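import pandas as pd
import pytest

from ocskit import Pedigree, prepare_pedigree
from ocskit.simulate import (SimConfig, simulate_ebv, simulate_haplotypes,
                             simulate_pedigree)


def make_pedigree(rows):
    """Build a prepared pedigree from (indiv, sire, dam, sex, born, breed)
    tuples; None marks a missing parent."""
    df = pd.DataFrame(rows, columns=["Indiv", "Sire", "Dam", "Sex", "Born",
                                     "Breed"])
    df["Born"] = df["Born"].astype("Int64")
    return prepare_pedigree(Pedigree(df))


@pytest.fixture
def trio():
    """Two unrelated founders and one offspring."""
    return make_pedigree([
        ("A", None, None, "male", 2000, "Angler"),
        ("B", None, None, "female", 2000, "Angler"),
        ("C", "A", "B", "male", 2001, "Angler"),
    ])


@pytest.fixture
def full_sibs():
    """Full sibs plus their inbred offspring."""
    return make_pedigree([
        ("A", None, None, "male", 2000, "Angler"),
        ("B", None, None, "female", 2000, "Angler"),
        ("S1", "A", "B", "male", 2001, "Angler"),
        ("S2", "A", "B", "female", 2001, "Angler"),
        ("O", "S1", "S2", "male", 2002, "Angler"),
    ])


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(years=5, n_offspring_per_year=20,
                     n_markers_per_chrom=150, spacing_mb=0.4, seed=777)


@pytest.fixture(scope="session")
def sim_ped(sim_cfg):
    return simulate_pedigree(sim_cfg)


@pytest.fixture(scope="session")
def sim_haps(sim_ped, sim_cfg):
    return simulate_haplotypes(sim_ped, sim_cfg)


@pytest.fixture(scope="session")
def sim_ebv(sim_ped, sim_cfg):
    return simulate_ebv(sim_ped, sim_cfg)
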