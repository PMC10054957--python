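"""Seeded generators for allele-specific peptidomes, proteomes and patients.

Real eluted-ligand data have three statistical signatures the test data
must reproduce: (i) anchor dominance -- strong residue preferences at
P2 and the C-terminal position (label 0), milder preferences elsewhere;
(ii) pairwise couplings between positions (the dependencies the
interactive-motif features exist to capture); and (iii) mixtures --
a patient's eluted pool combines peptides from up to six alleles.

An :class:`AlleleGenerator` samples peptides position-wise from
per-label marginal distributions (a PWM over the nine labels), then,
for each planted coupling ``(pair, joint, lambda)``, redraws the pair's
residues jointly with probability ``lambda``. Because the coupling is a
lambda-mixture of the joint and the independent draw, the generator's
true mutual information is analytically computable, which the oracle
tests exploit. ``lambda = 0`` everywhere reduces to fully independent
sampling.

What these generators deliberately do NOT emulate: mass-spectrometry
detectability bias, missed cleavages, chimeric spectra, or shared
peptides between alleles. Results on them demonstrate correctness of
the estimators, not real-world benchmark performance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .features import canonical_pair
from .model import NATURAL_AA_FREQS
from .peptides import AA_INDEX, AMINO_ACIDS, POSITION_LABELS, label_indices

#: Length mix typical of HLA-I eluted ligands: 9-mers dominate.
DEFAULT_LENGTH_PROBS: dict[int, float] = {
    8: 0.15, 9: 0.55, 10: 0.15, 11: 0.08, 12: 0.04, 13: 0.03,
}

_NATURAL = np.array([NATURAL_AA_FREQS[a] for a in AMINO_ACIDS])
_NATURAL = _NATURAL / _NATURAL.sum()


def _check_dist(p: np.ndarray, what: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"{what} is not a probability distribution")
    return p


@dataclass(frozen=True)
class Coupling:
    """A planted dependency between two position labels.

    With probability ``lam`` the residue pair is drawn from ``joint``
    (a 20x20 distribution); otherwise both residues keep their
    independent marginal draws.
    """

    pair: tuple[int, int]
    joint: np.ndarray
    lam: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", canonical_pair(*self.pair))
        j = _check_dist(self.joint, f"coupling joint for {self.pair}")
        if j.shape != (20, 20):
            raise ValueError("coupling joint must be 20x20")
        object.__setattr__(self, "joint", j)
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("coupling weight must lie in [0, 1]")


@dataclass(frozen=True)
class AlleleGenerator:
    """Sampling spec for one synthetic allele's peptidome."""

    name: str
    pwm: Mapping[int, np.ndarray]
    length_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_PROBS)
    )
    couplings: tuple[Coupling, ...] = ()
    filler: np.ndarray = field(default_factory=lambda: _NATURAL.copy())

    def __post_init__(self) -> None:
        pwm = {lab: _check_dist(col, f"PWM column {lab}") for lab, col in self.pwm.items()}
        if set(pwm) != set(POSITION_LABELS):
            raise ValueError("PWM must define exactly the nine position labels")
        object.__setattr__(self, "pwm", pwm)
        lp = dict(self.length_probs)
        if any(not 8 <= L <= 13 for L in lp) or not np.isclose(sum(lp.values()), 1.0):
            raise ValueError("length distribution must be over lengths 8..13 and sum to 1")
        object.__setattr__(self, "length_probs", lp)
        object.__setattr__(self, "filler", _check_dist(self.filler, "filler distribution"))


def sample_allele(
    gen: AlleleGenerator, n: int, seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Draw ``n`` peptides from an allele generator, reproducibly by seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    lens = sorted(gen.length_probs)
    lprobs = np.array([gen.length_probs[L] for L in lens])
    lengths = rng.choice(lens, size=n, p=lprobs)
    peptides: list[str] = [""] * n
    for L in lens:
        which = np.flatnonzero(lengths == L)
        if which.size == 0:
            continue
        m = which.size
        idx = label_indices(L)
        # absolute index -> sampling distribution; on 8-mers index 4 is
        # shared by labels 5 and 7 and samples from the label-5 column
        dists = [gen.filler] * L
        for lab in reversed(POSITION_LABELS):  # label 5 wins the shared 8-mer index
            dists[idx[lab]] = gen.pwm[lab]
        mat = np.empty((m, L), dtype=np.int64)
        for col, d in enumerate(dists):
            mat[:, col] = rng.choice(20, size=m, p=d)
        for c in gen.couplings:
            hit = rng.random(m) < c.lam
            k = int(hit.sum())
            if k:
                cells = rng.choice(400, size=k, p=c.joint.ravel())
                mat[hit, idx[c.pair[0]]] = cells // 20
                mat[hit, idx[c.pair[1]]] = cells % 20
        for row, g in zip(which, mat):
            peptides[row] = "".join(AMINO_ACIDS[a] for a in g)
    return peptides


def anchor_pwm(
    anchors: Mapping[int, str],
    anchor_weight: float = 0.7,
    mild_weight: float = 0.25,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Anchor-dominated PWM: concentrated columns at the anchor labels
    (canonically 2 and 0), mild seeded preferences elsewhere, natural
    frequencies as the base."""
    rng = np.random.default_rng(seed)
    pwm: dict[int, np.ndarray] = {}
    for lab in POSITION_LABELS:
        col = _NATURAL.copy()
        if lab in anchors:
            col = col * (1 - anchor_weight) / col.sum()
            col[AA_INDEX[anchors[lab]]] += anchor_weight
        else:
            fav = rng.integers(20)
            col = col * (1 - mild_weight)
            col[fav] += mild_weight
        pwm[lab] = col / col.sum()
    return pwm


def anchor_generator(
    name: str,
    anchors: Mapping[int, str] | None = None,
    anchor_weight: float = 0.7,
    couplings: tuple[Coupling, ...] = (),
    seed: int = 0,
) -> AlleleGenerator:
    """Realistic preset: strong P2/C-terminal anchors, mild elsewhere."""
    if anchors is None:
        anchors = {2: "L", 0: "V"}
    return AlleleGenerator(
        name=name,
        pwm=anchor_pwm(anchors, anchor_weight=anchor_weight, seed=seed),
        couplings=couplings,
    )


def paired_coupling(
    pair: tuple[int, int], cells: Sequence[tuple[str, str]], lam: float,
    weights: Sequence[float] | None = None,
) -> Coupling:
    """Coupling whose joint concentrates on a few residue pairs."""
    joint = np.zeros((20, 20))
    w = np.full(len(cells), 1 / len(cells)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    for (a, b), wk in zip(cells, w):
        joint[AA_INDEX[a], AA_INDEX[b]] += wk
    return Coupling(pair=canonical_pair(*pair), joint=joint, lam=lam)


def sample_proteome(
    n_proteins: int,
    mean_length: int = 350,
    aa_freqs: np.ndarray | None = None,
    seed: int | None = None,
) -> list[tuple[str, str]]:
    """I.i.d. protein sequences as (header, sequence) records.

    Lengths are Poisson around ``mean_length`` (floored at 30); residues
    are drawn from ``aa_freqs`` (natural composition by default). Serves
    as the decoy source in benchmarks.
    """
    rng = np.random.default_rng(seed)
    freqs = _check_dist(_NATURAL if aa_freqs is None else aa_freqs, "aa_freqs")
    records = []
    for k in range(n_proteins):
        L = max(30, int(rng.poisson(mean_length)))
        seq = "".join(AMINO_ACIDS[a] for a in rng.choice(20, size=L, p=freqs))
        records.append((f"synthetic_protein_{k + 1}", seq))
    return records


@dataclass(frozen=True)
class SyntheticPatient:
    """A patient mixture: up to six allele generators with proportions."""

    patient_id: str
    generators: tuple[AlleleGenerator, ...]
    proportions: tuple[float, ...]
    n_peptides: int

    def __post_init__(self) -> None:
        if not 1 <= len(self.generators) <= 6:
            raise ValueError("a patient has 1 to 6 allotypes")
        if len(self.proportions) != len(self.generators):
            raise ValueError("one proportion per allotype")
        _check_dist(np.asarray(self.proportions), "mixture proportions")
        if self.n_peptides < 1:
            raise ValueError("n_peptides must be >= 1")

    @property
    def allotypes(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.generators)


def sample_patient(
    patient: SyntheticPatient, seed: int | None = None
) -> tuple[list[str], list[str]]:
    """Sample a patient's eluted pool; returns (peptides, true allele labels).

    The truth labels are for test evaluation only -- the deconvolution
    code never sees them.
    """
    rng = np.random.default_rng(seed)
    k = rng.choice(len(patient.generators), size=patient.n_peptides,
                   p=np.asarray(patient.proportions))
    pools = []
    for gi, g in enumerate(patient.generators):
        m = int(np.sum(k == gi))
        pools.append(iter(sample_allele(g, m, rng=rng) if m else []))
    peptides = [next(pools[gi]) for gi in k]
    labels = [patient.generators[gi].name for gi in k]
    return peptides, labels
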