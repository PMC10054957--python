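"""Positive-example-only naive Bayes scoring of candidate peptides.

The classifier is trained on presented (positive) peptides only.
Per-feature conditionals P(f|+) are tallied from the training binders
and smoothed; the negative class is never sampled -- P(f|-) is taken
from the natural background frequencies of amino acids (pair features
use the product of the two marginals, i.e. residues of a random
non-binder are independent). A peptide's score of record is the log
odds ratio

    sum_{f in F} [ ln P(f_value | +) - ln P(f_value | -) ]

over the 29 features F, and the posterior probability follows from the
prior odds r = p(-)/p(+):

    p(+|peptide) = 1 / (1 + r * exp(-log_odds)).

The prior odds rescale the probability but can never change the ordering
of peptides; the default r = 10^5 - 1 (i.e. p(+) = 10^-5) keeps scores
away from saturation at 1. All accumulation is done in log space.

Two smoothing strategies are provided. Laplace (additive) smoothing with
pseudo-count alpha per cell is the default. BLOSUM62 smoothing instead
distributes the same total pseudo-mass according to substitution
probabilities derived from the BLOSUM62 matrix, so sparse tables borrow
strength from biochemically similar residues; it exists for ablation --
in practice plain additive smoothing scores better, suggesting the
positional dependencies reflect antigen presentation rather than
sequence evolution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DegenerateDataError
from .features import (
    FeatureKey,
    FeatureSet,
    _LABEL_RANK,
    encode_positions,
    feature_to_str,
    str_to_feature,
)
from .peptides import AA_INDEX, AMINO_ACIDS, validate_peptide

#: Default prior odds p(-)/p(+): one binder per 10^5 random peptides.
DEFAULT_PRIOR_ODDS: float = 1e5 - 1

#: Swiss-Prot release-wide amino-acid composition (natural frequencies).
NATURAL_AA_FREQS: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}


@dataclass(frozen=True)
class BackgroundModel:
    """Background (negative-class) amino-acid frequencies.

    Stores the 20 marginal frequencies; pair backgrounds are the outer
    product of marginals, so a "negative" peptide is a random draw with
    independent positions.
    """

    freqs: np.ndarray
    source: str = "custom"

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (20,):
            raise ValueError("background needs exactly 20 frequencies")
        if np.any(f <= 0):
            raise ValueError("background frequencies must be strictly positive")
        # normalize only when needed so save/load round trips bit-exactly
        if abs(f.sum() - 1.0) > 1e-12:
            f = f / f.sum()
        object.__setattr__(self, "freqs", f)

    @classmethod
    def natural(cls) -> "BackgroundModel":
        """Swiss-Prot composition -- the default when no proteome is given."""
        return cls(np.array([NATURAL_AA_FREQS[a] for a in AMINO_ACIDS]), source="natural")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls(np.full(20, 1 / 20), source="uniform")

    @classmethod
    def from_proteome(cls, sequences: Iterable[str]) -> "BackgroundModel":
        """Tally marginals from protein sequences (non-canonical letters skipped)."""
        counts = np.zeros(20)
        for seq in sequences:
            for ch in seq.upper():
                i = AA_INDEX.get(ch)
                if i is not None:
                    counts[i] += 1
        if counts.sum() == 0:
            raise DegenerateDataError("proteome contains no canonical residues")
        # one pseudo-count guards against an absent residue in tiny proteomes
        return cls(counts + 1.0, source="proteome")

    def log_single(self) -> np.ndarray:
        return np.log(self.freqs)

    def pair_freqs(self) -> np.ndarray:
        return np.outer(self.freqs, self.freqs)


@lru_cache(maxsize=1)
def _blosum62_kernel() -> np.ndarray:
    """Row-stochastic substitution kernel K[b, a] ~ P(a | b) from BLOSUM62.

    BLOSUM62 entries are rounded half-bit log odds s(a,b) of the joint
    substitution frequency over the product of backgrounds, so
    q(a|b) is proportional to p(a) * 2^(s(a,b)/2).
    """
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    bg = np.array([NATURAL_AA_FREQS[a] for a in AMINO_ACIDS])
    K = np.empty((20, 20))
    for bi, b in enumerate(AMINO_ACIDS):
        for ai, a in enumerate(AMINO_ACIDS):
            K[bi, ai] = bg[ai] * 2.0 ** (mat[b, a] / 2.0)
    return K / K.sum(axis=1, keepdims=True)


def _smooth(counts: np.ndarray, smoothing: str, alpha: float) -> np.ndarray:
    """Smoothed probability table from a count table (20 or 20x20).

    Laplace adds ``alpha`` to every cell. BLOSUM62 distributes the same
    total pseudo-mass (alpha * #cells) according to the substitution
    kernel applied to the empirical distribution -- for pairs the kernel
    acts independently on the two positions.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    cells = counts.size
    if smoothing == "laplace":
        table = counts + alpha
    elif smoothing == "blosum62":
        if n == 0:
            raise DegenerateDataError("cannot BLOSUM-smooth an empty table")
        K = _blosum62_kernel()
        p_hat = counts / n
        if counts.ndim == 1:
            pseudo = p_hat @ K
        else:
            pseudo = K.T @ p_hat @ K
        table = counts + alpha * cells * pseudo
        # kernel rows are strictly positive, so the table is too
    else:
        raise ValueError(f"unknown smoothing {smoothing!r}")
    return table / table.sum()


@dataclass(frozen=True)
class ReportRow:
    """One line of the white-box prediction report."""

    feature: FeatureKey
    residues: str
    log_odds: float


@dataclass(frozen=True)
class PredictionReport:
    """Per-feature evidence breakdown for a single peptide.

    The rows' log odds sum to the total log odds, and the probability is
    ``1 / (1 + prior_odds * exp(-total))``, so every prediction can be
    audited feature by feature.
    """

    peptide: str
    rows: tuple[ReportRow, ...]
    total_log_odds: float
    probability: float
    prior_odds: float

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            [(feature_to_str(r.feature), r.residues, r.log_odds) for r in self.rows],
            columns=["feature", "residues", "log_odds"],
        )
        return df


@dataclass
class NBModel:
    """A trained positive-only naive Bayes model for one HLA allele."""

    allele: str
    feature_set: FeatureSet
    conditionals: dict[FeatureKey, np.ndarray]
    background: BackgroundModel
    prior_odds: float = DEFAULT_PRIOR_ODDS
    smoothing: str = "laplace"
    alpha: float = 1.0
    training_n: int = 0
    _log_ratio: dict[FeatureKey, np.ndarray] = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.prior_odds <= 0:
            raise ValueError("prior odds must be positive")
        missing = set(self.feature_set.features) - set(self.conditionals)
        if missing:
            raise ValueError(f"conditionals missing for features {sorted(map(str, missing))}")
        self._log_ratio = None

    # -- scoring ---------------------------------------------------------

    def _ratios(self) -> dict[FeatureKey, np.ndarray]:
        if self._log_ratio is None:
            bg1 = np.log(self.background.freqs)
            bg2 = np.log(self.background.pair_freqs())
            ratios: dict[FeatureKey, np.ndarray] = {}
            for key in self.feature_set.features:
                lp = np.log(self.conditionals[key])
                ratios[key] = lp - (bg1 if isinstance(key, int) else bg2)
            self._log_ratio = ratios
        return self._log_ratio

    def score_many(self, peptides: Sequence[str]) -> np.ndarray:
        """Vectorized log odds for a batch of validated peptides."""
        if len(peptides) == 0:
            return np.zeros(0)
        codes = encode_positions(peptides)
        ratios = self._ratios()
        total = np.zeros(len(peptides))
        for key in self.feature_set.features:
            if isinstance(key, int):
                total += ratios[key][codes[:, _LABEL_RANK[key]]]
            else:
                i, j = key
                total += ratios[key][codes[:, _LABEL_RANK[i]], codes[:, _LABEL_RANK[j]]]
        return total

    def log_odds(self, peptide: str) -> float:
        """Total log odds ratio of one peptide over all 29 features."""
        return float(self.score_many([peptide])[0])

    def predict_proba(self, peptide: str, prior_odds: float | None = None) -> float:
        """Posterior probability of presentation, in (0, 1)."""
        r = self.prior_odds if prior_odds is None else prior_odds
        if r <= 0:
            raise ValueError("prior odds must be positive")
        return float(1.0 / (1.0 + r * math.exp(-self.log_odds(peptide))))

    def rank_peptides(self, peptides: Sequence[str]) -> list[tuple[str, float]]:
        """Peptides sorted by descending log odds; ties keep input order.

        The ordering is identical for every positive prior odds, which
        is why the odds ratio rather than the probability is the score
        of record.
        """
        if len(peptides) == 0:
            raise ValueError("no peptides to rank")
        scores = self.score_many(peptides)
        order = np.argsort(-scores, kind="stable")
        return [(peptides[k], float(scores[k])) for k in order]

    def prediction_report(self, peptide: str) -> PredictionReport:
        """Per-feature log odds breakdown (the white-box explanation)."""
        peptide = validate_peptide(peptide)
        codes = encode_positions([peptide])[0]
        ratios = self._ratios()
        rows = []
        total = 0.0
        for key in self.feature_set.features:
            if isinstance(key, int):
                ai = codes[_LABEL_RANK[key]]
                res = AMINO_ACIDS[ai]
                lo = float(ratios[key][ai])
            else:
                i, j = key
                ai, aj = codes[_LABEL_RANK[i]], codes[_LABEL_RANK[j]]
                res = AMINO_ACIDS[ai] + AMINO_ACIDS[aj]
                lo = float(ratios[key][ai, aj])
            rows.append(ReportRow(feature=key, residues=res, log_odds=lo))
            total += lo
        proba = 1.0 / (1.0 + self.prior_odds * math.exp(-total))
        return PredictionReport(
            peptide=peptide,
            rows=tuple(rows),
            total_log_odds=total,
            probability=proba,
            prior_odds=self.prior_odds,
        )

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema": "pepnb-model/1",
            "allele": self.allele,
            "feature_set": self.feature_set.to_dict(),
            "conditionals": {
                feature_to_str(k): np.asarray(v).ravel().tolist()
                for k, v in self.conditionals.items()
            },
            "background": {
                "freqs": self.background.freqs.tolist(),
                "source": self.background.source,
            },
            "prior_odds": self.prior_odds,
            "smoothing": self.smoothing,
            "alpha": self.alpha,
            "training_n": self.training_n,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NBModel":
        from .errors import ModelSchemaError

        try:
            if d["schema"] != "pepnb-model/1":
                raise ModelSchemaError(f"unknown model schema {d.get('schema')!r}")
            fs = FeatureSet.from_dict(d["feature_set"])
            conditionals = {}
            for ks, vals in d["conditionals"].items():
                key = str_to_feature(ks)
                arr = np.asarray(vals, dtype=float)
                conditionals[key] = arr if isinstance(key, int) else arr.reshape(20, 20)
            return cls(
                allele=d["allele"],
                feature_set=fs,
                conditionals=conditionals,
                background=BackgroundModel(
                    np.asarray(d["background"]["freqs"]), source=d["background"]["source"]
                ),
                prior_odds=float(d["prior_odds"]),
                smoothing=d["smoothing"],
                alpha=float(d["alpha"]),
                training_n=int(d["training_n"]),
            )
        except (KeyError, TypeError, IndexError) as exc:
            raise ModelSchemaError(f"malformed model file: {exc}") from exc


def fit(
    allele_peptides: Sequence[str],
    feature_set: FeatureSet,
    background: BackgroundModel | None = None,
    smoothing: str = "laplace",
    alpha: float = 1.0,
    allele: str = "unknown",
    prior_odds: float = DEFAULT_PRIOR_ODDS,
) -> NBModel:
    """Fit the conditional tables P(f|+) from positive peptides only.

    Every feature's table is tallied over the training binders (8-mers
    contribute their shared residue to both labels 5 and 7), smoothed to
    strict positivity, and normalized.
    """
    peptides = list(allele_peptides)
    if not peptides:
        raise DegenerateDataError("cannot fit a model on an empty training set")
    if background is None:
        background = BackgroundModel.natural()
    codes = encode_positions(peptides)
    conditionals: dict[FeatureKey, np.ndarray] = {}
    for key in feature_set.features:
        if isinstance(key, int):
            counts = np.bincount(codes[:, _LABEL_RANK[key]], minlength=20).astype(float)
        else:
            i, j = key
            flat = codes[:, _LABEL_RANK[i]] * 20 + codes[:, _LABEL_RANK[j]]
            counts = np.bincount(flat, minlength=400).astype(float).reshape(20, 20)
        conditionals[key] = _smooth(counts, smoothing, alpha)
    return NBModel(
        allele=allele,
        feature_set=feature_set,
        conditionals=conditionals,
        background=background,
        prior_odds=prior_odds,
        smoothing=smoothing,
        alpha=alpha,
        training_n=len(peptides),
    )
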