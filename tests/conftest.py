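import numpy as np
import pandas as pd
import pytest

from pstfst.containers import GenotypeMatrix, PopulationMap


def make_geno(dosage, sample_ids=None, locus_ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from a plain dosage array (-1 = missing)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    sample_ids = sample_ids or [f"i{j + 1}" for j in range(n)]
    locus_ids = locus_ids or [f"snp{l + 1}" for l in range(m)]
    meta = pd.DataFrame({
        "chrom": [f"loc{l + 1}" for l in range(m)],
        "pos": 1, "id": locus_ids, "ref": "A", "alt": "G",
        "multiallelic": False, "is_indel": False,
    })
    return GenotypeMatrix(dosage=dosage, locus_meta=meta, sample_ids=sample_ids)


def make_map(assignments) -> PopulationMap:
    """assignments: list of (individual, population, region, range)."""
    t = pd.DataFrame(assignments,
                     columns=["individual", "population", "region", "range"])
    return PopulationMap(t.set_index("individual"))


def two_region_map(n_per=None, ids=None):
    """Individuals split evenly into two regions (one population each)."""
    if ids is None:
        ids = [f"i{j + 1}" for j in range(2 * n_per)]
    half = len(ids) // 2
    rows = [(s, "popA", "regA", "native") for s in ids[:half]]
    rows += [(s, "popB", "regB", "non-native") for s in ids[half:]]
    return make_map(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def toy_geno():
    """4 individuals x 3 loci, no missing data, hand-checkable."""
    return make_geno([
        [0, 1, 2],
        [1, 1, 0],
        [2, 1, 0],
        [0, 1, 1],
    ])


@pytest.fixture
def toy_map():
    return two_region_map(2)
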