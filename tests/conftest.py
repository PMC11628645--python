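import numpy as np
import pandas as pd
import pytest

from invscan.datamodel import GenotypeTable, SnpRecord
from invscan.simulate import InversionSpec, PopulationSpec, SimConfig, simulate


def make_table(genotypes, cms, lg=1, contigs=None):
    """Hand-built GenotypeTable from a genotype matrix and cM positions."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, m = genotypes.shape
    if contigs is None:
        contigs = [f"ctg{j}" for j in range(m)]
    snps = [
        SnpRecord(f"s{j}", contigs[j], lg, float(cms[j]), ("A", "T")) for j in range(m)
    ]
    return GenotypeTable(
        samples=[f"ind{i}" for i in range(n)], snps=snps, genotypes=genotypes
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def simple_inversion_sim():
    """One simple inversion (d=0.8, freq 0.5) on a 20-cM LG, 2 locations."""
    pops = (
        PopulationSpec("loc1", "crab", "northern_saxatilis", 30),
        PopulationSpec("loc1", "wave", "northern_saxatilis", 30),
        PopulationSpec("loc2", "crab", "northern_saxatilis", 30),
        PopulationSpec("loc2", "wave", "northern_saxatilis", 30),
    )
    cfg = SimConfig(
        lg_length_cm=20.0,
        populations=pops,
        inversions=(
            InversionSpec(1, 5.0, 15.0, 2, ((0.5, 0.5),) * 4, 0.8),
        ),
        seed=11,
    )
    return cfg, simulate(cfg)


@pytest.fixture(scope="session")
def complex_inversion_sim():
    """Three-arrangement complex region, all six karyotype classes expected."""
    pops = (
        PopulationSpec("loc1", "crab", "northern_saxatilis", 60),
        PopulationSpec("loc1", "wave", "northern_saxatilis", 60),
    )
    cfg = SimConfig(
        lg_length_cm=20.0,
        populations=pops,
        inversions=(
            InversionSpec(1, 5.0, 15.0, 3, ((1 / 3, 1 / 3, 1 / 3),) * 2, 0.8),
        ),
        seed=5,
    )
    return cfg, simulate(cfg)


@pytest.fixture
def meta_two_locations():
    rows = []
    for loc in ("loc1", "loc2"):
        for eco in ("crab", "wave"):
            for i in range(5):
                rows.append(
                    {
                        "individual": f"{loc}_{eco}_{i}",
                        "location": loc,
                        "ecotype": eco,
                        "group": "northern_saxatilis",
                    }
                )
    return pd.DataFrame(rows)
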