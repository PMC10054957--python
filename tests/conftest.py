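"""Shared fixtures: small explicit peptide sets and synthetic generators."""

import numpy as np
import pytest

from pepnb import (
    SyntheticPatient,
    anchor_generator,
    paired_coupling,
    sample_allele,
    sample_patient,
    sample_proteome,
)
from pepnb.features import PAIR_KEYS, build_feature_set

#: Six well-separated anchor palettes, one per synthetic allele.
ANCHOR_PALETTES = (
    {2: "L", 0: "V"},
    {2: "P", 0: "A"},
    {2: "E", 0: "R"},
    {2: "S", 0: "F"},
    {2: "K", 0: "W"},
    {2: "D", 0: "Y"},
)


def make_generator(i: int, **kwargs):
    """Synthetic allele i (0-5) with its own anchors and mild preferences."""
    return anchor_generator(f"SYN{i:02d}", anchors=ANCHOR_PALETTES[i], seed=100 + i, **kwargs)


@pytest.fixture(scope="session")
def tiny_peptides():
    """A small explicit 9-mer set for brute-force oracle comparisons."""
    return [
        "ALDEKWQTV", "SLYNTVATL", "GLCTLVAML", "KLMEYGHIV", "ALAKAAAAV",
        "RLRPGGKKK", "YLQPRTFLL", "TLNAWVKVV", "FLGKIWPSH", "SLFNTVATL",
    ]


@pytest.fixture(scope="session")
def any_feature_set():
    """A syntactically valid 29-feature set (first 20 canonical pairs)."""
    return build_feature_set(PAIR_KEYS[:10], PAIR_KEYS[10:20])


@pytest.fixture(scope="session")
def planted_generator():
    """Allele generator with a strong (2, 0) coupling planted."""
    coupling = paired_coupling((2, 0), [("P", "A"), ("V", "R")], lam=0.6)
    return make_generator(0, couplings=(coupling,))


@pytest.fixture(scope="session")
def planted_pool(planted_generator):
    return sample_allele(planted_generator, 1500, seed=7)


@pytest.fixture(scope="session")
def toy_proteome():
    return sample_proteome(40, mean_length=300, seed=11)


@pytest.fixture(scope="session")
def two_allele_patient():
    """A 50/50 two-allele mixture with held-out truth labels."""
    gens = (make_generator(0), make_generator(1))
    patient = SyntheticPatient("PT01", gens, (0.5, 0.5), 600)
    pool, truth = sample_patient(patient, seed=13)
    return gens, pool, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
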