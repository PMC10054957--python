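"""Proteome decoy generation and the evaluation metrics.

Finding presented peptides among candidates is a needle-in-a-haystack
problem, so models are benchmarked at a 1:99 positive:decoy ratio:
for each positive peptide, 99 decoys are drawn as contiguous substrings
of a proteome, any decoy that coincides with a positive is replaced so
the exact ratio is maintained, and decoy lengths follow the positives'
empirical length distribution (removing length as a confounder).

Two metrics are reported. *Precision at 40% recall* -- the precision at
the highest score threshold recovering at least 40% of the true binders
-- is the more informative number on such imbalanced data, since AUROC
is dominated by the vast bulk of easy negatives. *AUROC* is included
for comparability. The reverse calibration (the threshold reaching a
target precision, and the recall there) supports picking an operating
point for a candidate short-list.

Threshold semantics throughout: a peptide is called positive when its
score is >= the threshold; tied scores are treated identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

from .errors import DegenerateDataError, ExhaustionError
from .peptides import AMINO_ACIDS

_ALPHABET = frozenset(AMINO_ACIDS)


def _check_labels(labels: np.ndarray) -> None:
    if labels.size == 0 or labels.min() == labels.max():
        raise DegenerateDataError("metrics need at least one positive and one negative")


def generate_decoys(
    positives: Sequence[str],
    proteome: Sequence[str] | Sequence[tuple[str, str]],
    ratio: int = 99,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    unique: bool = False,
) -> list[str]:
    """Sample ``ratio`` proteome-substring decoys per positive peptide.

    Start sites are uniform over all eligible windows of the drawn
    length; windows equal to a positive (or containing non-canonical
    letters) are rejected and redrawn, keeping the exact count. With
    ``unique=True`` decoys are also distinct from each other.

    Raises :class:`ExhaustionError` when the proteome cannot supply
    enough eligible windows of some required length.
    """
    positives = list(positives)
    if not positives:
        raise ValueError("no positive peptides")
    seqs = [r[1] if isinstance(r, tuple) else str(r) for r in proteome]
    seqs = [s.upper() for s in seqs if s]
    if not seqs:
        raise ExhaustionError("empty proteome")
    if rng is None:
        rng = np.random.default_rng(seed)

    pos_set = frozenset(positives)
    lengths = np.array([len(p) for p in positives])
    draws = rng.choice(lengths, size=ratio * len(positives), replace=True)

    # per-length cumulative window counts over proteins
    window_index: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for L in np.unique(draws):
        counts = np.array([max(0, len(s) - L + 1) for s in seqs])
        if counts.sum() == 0:
            raise ExhaustionError(f"proteome has no windows of length {L}")
        window_index[int(L)] = (np.flatnonzero(counts), np.cumsum(counts[counts > 0]))

    chosen: set[str] = set()
    decoys: list[str] = []
    eligible_cache: dict[int, list[str]] = {}
    for L in draws:
        L = int(L)
        prot_ids, cum = window_index[L]
        decoy = None
        for _ in range(200):
            w = int(rng.integers(cum[-1]))
            k = int(np.searchsorted(cum, w, side="right"))
            start = w - (cum[k - 1] if k else 0)
            cand = seqs[prot_ids[k]][start:start + L]
            if cand in pos_set or (unique and cand in chosen) or not _ALPHABET.issuperset(cand):
                continue
            decoy = cand
            break
        if decoy is None:
            # rejection failed: enumerate eligible windows of this length
            if L not in eligible_cache:
                eligible_cache[L] = [
                    s[i:i + L]
                    for s in seqs
                    for i in range(len(s) - L + 1)
                    if s[i:i + L] not in pos_set and _ALPHABET.issuperset(s[i:i + L])
                ]
            pool = eligible_cache[L]
            if unique:
                pool = [w for w in pool if w not in chosen]
            if not pool:
                raise ExhaustionError(
                    f"proteome exhausted: no eligible decoy window of length {L}"
                )
            decoy = pool[int(rng.integers(len(pool)))]
        decoys.append(decoy)
        if unique:
            chosen.add(decoy)
    return decoys


def auroc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (equals the normalized Mann-Whitney U,
    ties counted half)."""
    labels = np.asarray(labels)
    _check_labels(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def precision_at_recall(
    scores: Sequence[float], labels: Sequence[int], recall_target: float = 0.40
) -> float:
    """Precision at the highest threshold achieving recall >= target.

    Exact recall equal to the target may be unattainable on small sets;
    the step-function convention (smallest recall at or above target)
    is used.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    _check_labels(labels)
    precision, recall, _ = precision_recall_curve(labels, scores)
    # points are ordered by increasing threshold; recall is non-increasing.
    # The last real-threshold point with recall >= target is the answer.
    ok = np.flatnonzero(recall[:-1] >= recall_target)  # drop the (1, 0) sentinel
    if ok.size == 0:
        raise DegenerateDataError(f"recall {recall_target} unattainable")
    return float(precision[ok[-1]])


def calibrate_recall_at_precision(
    scores: Sequence[float], labels: Sequence[int], precision_target: float = 0.40
) -> tuple[float, float]:
    """Threshold achieving precision >= target with maximal recall.

    Returns ``(threshold, recall)``. If no threshold reaches the target
    precision, returns ``(inf, 0.0)`` with a warning.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    _check_labels(labels)
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    ok = np.flatnonzero(precision[:-1] >= precision_target)
    if ok.size == 0:
        warnings.warn(
            f"no threshold reaches precision {precision_target}; returning recall 0",
            stacklevel=2,
        )
        return float("inf"), 0.0
    best = ok[0]  # recall is non-increasing in threshold index
    return float(thresholds[best]), float(recall[best])


@dataclass(frozen=True)
class BenchmarkResult:
    """Metrics and curves from one labeled score set."""

    precision_at_recall40: float
    auroc: float
    threshold_for_precision40: float
    recall_at_precision40: float
    roc_points: tuple  # (fpr, tpr) arrays
    pr_points: tuple   # (precision, recall) arrays
    n_positives: int
    n_decoys: int

    def to_dict(self) -> dict:
        return {
            "precision_at_recall40": self.precision_at_recall40,
            "auroc": self.auroc,
            "threshold_for_precision40": self.threshold_for_precision40,
            "recall_at_precision40": self.recall_at_precision40,
            "n_positives": self.n_positives,
            "n_decoys": self.n_decoys,
        }


def evaluate(scores: Sequence[float], labels: Sequence[int]) -> BenchmarkResult:
    """All benchmark metrics for one labeled score set."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    _check_labels(labels)
    fpr, tpr, _ = roc_curve(labels, scores)
    precision, recall, _ = precision_recall_curve(labels, scores)
    thr40, rec40 = calibrate_recall_at_precision(scores, labels, 0.40)
    return BenchmarkResult(
        precision_at_recall40=precision_at_recall(scores, labels, 0.40),
        auroc=auroc(scores, labels),
        threshold_for_precision40=thr40,
        recall_at_precision40=rec40,
        roc_points=(fpr, tpr),
        pr_points=(precision, recall),
        n_positives=int(labels.sum()),
        n_decoys=int((labels == 0).sum()),
    )


def run_benchmark(
    model,
    positives: Sequence[str],
    proteome: Sequence[str] | Sequence[tuple[str, str]],
    ratio: int = 99,
    seed: int | None = None,
) -> BenchmarkResult:
    """Score positives against freshly sampled 1:ratio proteome decoys."""
    decoys = generate_decoys(positives, proteome, ratio=ratio, seed=seed)
    peptides = list(positives) + decoys
    labels = np.r_[np.ones(len(positives), dtype=int), np.zeros(len(decoys), dtype=int)]
    scores = model.score_many(peptides)
    return evaluate(scores, labels)
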