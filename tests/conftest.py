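import numpy as np
import pytest

from pedlod.pedio import GenotypeMatrix, Individual, Pedigree, VariantRecord
from pedlod.synthetic_data import QTL, SimConfig, simulate_dataset


def make_nuclear(fam: str = "F1", n_children: int = 3) -> Pedigree:
    members = [
        Individual("P1", None, None, "male", fam),
        Individual("P2", None, None, "female", fam),
    ] + [
        Individual(f"C{i}", "P1", "P2", "male" if i % 2 else "female", fam)
        for i in range(1, n_children + 1)
    ]
    return Pedigree(fam, members)


def make_three_gen_12(fam: str = "F1") -> Pedigree:
    """12-member 3-generation family: grandparent couple, 3 children (two
    married in), 5 grandchildren."""
    m = [
        Individual("GP1", None, None, "male", fam),
        Individual("GP2", None, None, "female", fam),
        Individual("K1", "GP1", "GP2", "male", fam),
        Individual("K2", "GP1", "GP2", "female", fam),
        Individual("K3", "GP1", "GP2", "male", fam),
        Individual("S1", None, None, "female", fam),
        Individual("S2", None, None, "male", fam),
        Individual("G1", "K1", "S1", "male", fam),
        Individual("G2", "K1", "S1", "female", fam),
        Individual("G3", "K1", "S1", "male", fam),
        Individual("G4", "S2", "K2", "female", fam),
        Individual("G5", "S2", "K2", "male", fam),
    ]
    return Pedigree(fam, m)


@pytest.fixture
def nuclear5() -> Pedigree:
    return make_nuclear()


@pytest.fixture
def three_gen_12() -> Pedigree:
    return make_three_gen_12()


def geno_for(ped: Pedigree, dosages, cms) -> GenotypeMatrix:
    """Genotype matrix for one pedigree from a (n x v) dosage list."""
    d = np.asarray(dosages, dtype=float)
    variants = [
        VariantRecord("1", 1000 * (j + 1), "A", "G", f"m{j}", cM=float(cms[j]))
        for j in range(d.shape[1])
    ]
    return GenotypeMatrix(variants, ped.ids, d)


@pytest.fixture(scope="session")
def qtl_dataset():
    """Small simulated study with a planted QTL at 50 cM (15% of variance)."""
    cfg = SimConfig(
        n_families=25, n_variants=80, seed=7,
        qtl=(QTL(cM=50.0, var_frac=0.15),),
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """Small simulated study with polygenic signal only."""
    cfg = SimConfig(n_families=25, n_variants=60, seed=13)
    return simulate_dataset(cfg)
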