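"""Mutual-information feature selection over peptide position pairs.

A model scores a peptide through 29 features: the nine single-position
labels (``1..5, 7..0`` -- the "motifs") plus 20 position-pair features
(the "interactive motifs", iMotifs) that capture dependencies between
two residues within an allele's peptidome. Ten pair features are
*pan-allelic* -- the pairs with the highest mutual information on the
pooled training peptides of all alleles -- and ten are *allele-specific*,
selected on one allele's peptides while skipping pairs already taken by
the pan-allelic set, so the 29 features are always distinct.

Mutual information between the residues at labels i and j is the
plug-in estimate

    I(f_i; f_j) = H(f_i) + H(f_j) - H(f_i, f_j)

in nats, computed on the 20x20 joint count table. Only the ranking of
pairs matters for selection, so the log base is immaterial to the
selected set; ties are broken lexicographically on the canonical label
order to keep selection deterministic and seed-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .errors import DegenerateDataError
from .peptides import AA_INDEX, POSITION_LABELS, label_indices

#: A feature key: a single position label (int) or a canonical pair (i, j).
FeatureKey = Union[int, tuple[int, int]]

_LABEL_RANK = {lab: r for r, lab in enumerate(POSITION_LABELS)}

#: All 36 candidate pair keys, canonically ordered (i before j in label order).
PAIR_KEYS: tuple[tuple[int, int], ...] = tuple(combinations(POSITION_LABELS, 2))

_PAIR_RANK = {p: r for r, p in enumerate(PAIR_KEYS)}


def canonical_pair(i: int, j: int) -> tuple[int, int]:
    """Order a label pair canonically (N-terminal-most label first)."""
    if i == j:
        raise ValueError(f"self-pair ({i}, {j}) is not a valid feature")
    if i not in _LABEL_RANK or j not in _LABEL_RANK:
        raise ValueError(f"unknown position label in pair ({i}, {j})")
    return (i, j) if _LABEL_RANK[i] < _LABEL_RANK[j] else (j, i)


def feature_to_str(key: FeatureKey) -> str:
    return str(key) if isinstance(key, int) else f"{key[0]}-{key[1]}"


def str_to_feature(s: str) -> FeatureKey:
    if "-" in s:
        i, j = s.split("-")
        return canonical_pair(int(i), int(j))
    return int(s)


def encode_positions(peptides: Sequence[str]) -> np.ndarray:
    """Encode peptides as an (n, 9) matrix of residue indices per label.

    Column order follows ``POSITION_LABELS``. 8-mers contribute their
    shared residue to both the label-5 and label-7 columns, so every
    feature is defined for every peptide length.
    """
    n = len(peptides)
    out = np.empty((n, 9), dtype=np.int64)
    # index maps are a pure function of length; precompute per length
    maps = {}
    for k, pep in enumerate(peptides):
        L = len(pep)
        if L not in maps:
            idx = label_indices(L)
            maps[L] = [idx[lab] for lab in POSITION_LABELS]
        for c, i in enumerate(maps[L]):
            out[k, c] = AA_INDEX[pep[i]]
    return out


def count_entropy(counts) -> float:
    """Plug-in Shannon entropy (nats) of a count table.

    Zero-count cells contribute nothing; an all-zero or empty table is
    rejected.
    """
    arr = np.asarray(counts, dtype=float).ravel()
    if arr.size == 0 or arr.sum() <= 0:
        raise DegenerateDataError("entropy of an empty count table is undefined")
    if np.any(arr < 0):
        raise ValueError("negative counts")
    return float(_scipy_entropy(arr))


def joint_counts(
    peptides: Sequence[str], i: int, j: int, codes: np.ndarray | None = None
) -> np.ndarray:
    """20x20 joint residue count table for labels i and j."""
    pair = canonical_pair(i, j)
    if codes is None:
        codes = encode_positions(peptides)
    ci = codes[:, _LABEL_RANK[pair[0]]]
    cj = codes[:, _LABEL_RANK[pair[1]]]
    flat = np.bincount(ci * 20 + cj, minlength=400)
    table = flat.reshape(20, 20).astype(float)
    return table if (i, j) == pair else table.T


def single_counts(
    peptides: Sequence[str], label: int, codes: np.ndarray | None = None
) -> np.ndarray:
    """Length-20 residue count vector for one position label."""
    if codes is None:
        codes = encode_positions(peptides)
    return np.bincount(codes[:, _LABEL_RANK[label]], minlength=20).astype(float)


def mutual_information(
    peptides: Sequence[str], i: int, j: int, codes: np.ndarray | None = None
) -> float:
    """Plug-in mutual information (nats) between residues at labels i, j.

    ``I = H(f_i) + H(f_j) - H(f_i, f_j)`` on the empirical joint table.
    Symmetric in (i, j); self-pairs are rejected.
    """
    if i == j:
        raise ValueError("mutual information of a position with itself is excluded")
    if len(peptides) == 0 and codes is None:
        raise DegenerateDataError("no peptides")
    joint = joint_counts(peptides, i, j, codes=codes)
    hi = count_entropy(joint.sum(axis=1))
    hj = count_entropy(joint.sum(axis=0))
    hij = count_entropy(joint)
    return hi + hj - hij


def rank_pairs(
    peptides: Sequence[str], codes: np.ndarray | None = None
) -> list[tuple[tuple[int, int], float]]:
    """All 36 pair keys with their MI, best first.

    Ties break lexicographically on the canonical pair order, making the
    ranking deterministic.
    """
    if codes is None:
        codes = encode_positions(peptides)
    scored = [(p, mutual_information(peptides, *p, codes=codes)) for p in PAIR_KEYS]
    scored.sort(key=lambda kv: (-kv[1], _PAIR_RANK[kv[0]]))
    return scored


def _pool(training: Union[Mapping[str, Sequence[str]], Iterable[str]]) -> list[str]:
    if isinstance(training, Mapping):
        pooled: list[str] = []
        for peps in training.values():
            pooled.extend(peps)
        return pooled
    return list(training)


def select_pan_features(
    training: Union[Mapping[str, Sequence[str]], Iterable[str]],
) -> list[tuple[int, int]]:
    """Top-10 MI pairs on the pooled training peptides of all alleles."""
    pooled = _pool(training)
    if not pooled:
        raise DegenerateDataError("empty pooled training set")
    codes = encode_positions(pooled)
    if all(count_entropy(single_counts(pooled, lab, codes)) == 0.0 for lab in POSITION_LABELS):
        raise DegenerateDataError(
            "no residue variation at any position; cannot rank pair features"
        )
    return [p for p, _ in rank_pairs(pooled, codes)[:10]]


def select_allele_features(
    allele_peptides: Sequence[str], pan: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Top-10 MI pairs on one allele's peptides, skipping pan-allelic keys.

    Pairs already in the pan-allelic set are passed over, taking the
    11th, 12th, ... best until ten distinct new keys accumulate.
    """
    allele_peptides = list(allele_peptides)
    if not allele_peptides:
        raise DegenerateDataError("empty allele training set")
    pan_set = {canonical_pair(*p) for p in pan}
    if len(pan_set) != 10:
        raise ValueError(f"expected 10 distinct pan-allelic pairs, got {len(pan_set)}")
    chosen = [p for p, _ in rank_pairs(allele_peptides) if p not in pan_set][:10]
    if len(chosen) < 10:  # unreachable with 36 candidates and 10 excluded
        raise DegenerateDataError("fewer than 10 eligible pair features remain")
    return chosen


@dataclass(frozen=True)
class FeatureSet:
    """The fixed 29-feature set of one allele's model.

    Nine single-position features (shared by construction), ten
    pan-allelic pair features and ten allele-specific pair features,
    all distinct; the total is always 29.
    """

    pan_pairs: tuple[tuple[int, int], ...]
    allele_pairs: tuple[tuple[int, int], ...]
    singles: tuple[int, ...] = field(default=POSITION_LABELS)

    def __post_init__(self) -> None:
        if tuple(self.singles) != POSITION_LABELS:
            raise ValueError("single features are fixed to the nine position labels")
        pan = tuple(canonical_pair(*p) for p in self.pan_pairs)
        ap = tuple(canonical_pair(*p) for p in self.allele_pairs)
        if len(set(pan)) != 10 or len(set(ap)) != 10:
            raise ValueError("pan and allele-specific sets must each hold 10 distinct pairs")
        if set(pan) & set(ap):
            raise ValueError(
                f"pan-allelic and allele-specific pairs overlap: {sorted(set(pan) & set(ap))}"
            )
        object.__setattr__(self, "pan_pairs", pan)
        object.__setattr__(self, "allele_pairs", ap)

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        return self.pan_pairs + self.allele_pairs

    @property
    def features(self) -> tuple[FeatureKey, ...]:
        """All 29 feature keys: singles, then pan pairs, then allele pairs."""
        return tuple(self.singles) + self.pairs

    def __len__(self) -> int:
        return len(self.features)

    def to_dict(self) -> dict:
        return {
            "singles": [feature_to_str(s) for s in self.singles],
            "pan_pairs": [feature_to_str(p) for p in self.pan_pairs],
            "allele_pairs": [feature_to_str(p) for p in self.allele_pairs],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FeatureSet":
        return cls(
            pan_pairs=tuple(str_to_feature(p) for p in d["pan_pairs"]),
            allele_pairs=tuple(str_to_feature(p) for p in d["allele_pairs"]),
        )


def build_feature_set(
    pan: Sequence[tuple[int, int]], allele_pairs: Sequence[tuple[int, int]]
) -> FeatureSet:
    """Assemble the 29-feature set from the two pair selections."""
    return FeatureSet(pan_pairs=tuple(pan), allele_pairs=tuple(allele_pairs))


def select_feature_set(
    training: Mapping[str, Sequence[str]], allele: str
) -> FeatureSet:
    """Convenience: pan selection on the pool, allele selection for one allele."""
    pan = select_pan_features(training)
    return build_feature_set(pan, select_allele_features(training[allele], pan))
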