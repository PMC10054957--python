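"""White-box interpretation tables: iMotif surplus/deficit and logo heights.

Every number here is an exact function of residue counts, so each cell
can be re-derived by independent tallying. The iMotif table contrasts
the observed joint frequency of a residue pair at two positions with
the frequency expected if the positions were independent (the outer
product of the two marginals); pairs occurring more often than expected
are "surplus" iMotifs, less often "deficit". Logo heights follow the
information-content convention: a position's total height is
``log(20) - entropy(position)`` (zero for a uniform position, log 20
for an invariant one) and each residue's share is proportional to its
frequency. Natural log by default, base 2 available for bit-scaled
logos. Output is tabular; rendering is left to external plotting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDataError
from .features import canonical_pair, encode_positions, joint_counts, single_counts
from .peptides import AMINO_ACIDS, POSITION_LABELS


@dataclass(frozen=True)
class IMotifTable:
    """Observed vs independence-expected residue-pair frequencies."""

    pair: tuple[int, int]
    observed: np.ndarray   # 20x20, sums to 1
    expected: np.ndarray   # outer product of the marginals
    marginal_i: np.ndarray
    marginal_j: np.ndarray
    n: int

    @property
    def difference(self) -> np.ndarray:
        return self.observed - self.expected

    def _ranked(self, descending: bool) -> pd.DataFrame:
        diff = self.difference
        rows = [
            (AMINO_ACIDS[a] + AMINO_ACIDS[b], self.observed[a, b],
             self.expected[a, b], diff[a, b])
            for a in range(20) for b in range(20)
        ]
        df = pd.DataFrame(rows, columns=["pair_value", "observed", "expected", "difference"])
        df = df.sort_values(
            "difference", ascending=not descending, kind="stable"
        ).reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        return df

    def surplus(self, k: int = 10) -> pd.DataFrame:
        """Residue pairs most enriched over the independence expectation."""
        return self._ranked(descending=True).head(k)

    def deficit(self, k: int = 10) -> pd.DataFrame:
        """Residue pairs most depleted below the independence expectation."""
        return self._ranked(descending=False).head(k)

    def to_dataframe(self) -> pd.DataFrame:
        return self._ranked(descending=True)


def imotif_table(peptides: Sequence[str], pair: tuple[int, int]) -> IMotifTable:
    """Build the surplus/deficit table for one position pair."""
    peptides = list(peptides)
    if not peptides:
        raise DegenerateDataError("no peptides")
    pair = canonical_pair(*pair)
    joint = joint_counts(peptides, *pair)
    n = joint.sum()
    observed = joint / n
    mi_ = observed.sum(axis=1)
    mj_ = observed.sum(axis=0)
    return IMotifTable(
        pair=pair, observed=observed, expected=np.outer(mi_, mj_),
        marginal_i=mi_, marginal_j=mj_, n=int(n),
    )


@dataclass(frozen=True)
class LogoData:
    """Per-position information content and residue heights."""

    base: str  # "e" (nats) or "2" (bits)
    total_heights: dict[int, float]
    residue_heights: dict[int, dict[str, float]]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for lab in POSITION_LABELS:
            row = {"position": lab, "total_height": self.total_heights[lab]}
            row.update(self.residue_heights[lab])
            rows.append(row)
        return pd.DataFrame(rows)


def logo_heights(peptides: Sequence[str], base: str = "e") -> LogoData:
    """Information-content logo heights for all nine position labels.

    Total height of a position is ``log(20) - entropy(position)``;
    each residue's height is its frequency times the total.
    """
    peptides = list(peptides)
    if not peptides:
        raise DegenerateDataError("no peptides")
    if base not in ("e", "2"):
        raise ValueError("base must be 'e' (nats) or '2' (bits)")
    scale = 1.0 if base == "e" else 1.0 / math.log(2)
    codes = encode_positions(peptides)
    totals: dict[int, float] = {}
    heights: dict[int, dict[str, float]] = {}
    for lab in POSITION_LABELS:
        counts = single_counts(peptides, lab, codes)
        freqs = counts / counts.sum()
        nz = freqs[freqs > 0]
        h = float(-(nz * np.log(nz)).sum())
        total = (math.log(20) - h) * scale
        totals[lab] = total
        heights[lab] = {AMINO_ACIDS[a]: float(freqs[a] * total) for a in range(20)}
    return LogoData(base=base, total_heights=totals, residue_heights=heights)


def allele_pair_frequency(
    allele_sets: Mapping[str, Sequence[str]],
    pair: tuple[int, int],
    pair_value: str,
) -> pd.DataFrame:
    """Per-allele frequency of one residue pair at one position pair.

    For each allele, the fraction of its peptides whose residues at the
    pair's positions equal ``pair_value`` (two letters, e.g. ``"PA"``),
    sorted descending -- the table behind "which alleles carry this
    iMotif".
    """
    pair = canonical_pair(*pair)
    if len(pair_value) != 2 or any(c not in AMINO_ACIDS for c in pair_value.upper()):
        raise ValueError(f"pair value must be two canonical letters, got {pair_value!r}")
    a = AMINO_ACIDS.index(pair_value[0].upper())
    b = AMINO_ACIDS.index(pair_value[1].upper())
    rows = []
    for allele, peps in allele_sets.items():
        peps = list(peps)
        if not peps:
            rows.append((allele, 0, 0.0))
            continue
        joint = joint_counts(peps, *pair)
        rows.append((allele, len(peps), float(joint[a, b] / joint.sum())))
    df = pd.DataFrame(rows, columns=["allele", "n_peptides", "frequency"])
    return df.sort_values("frequency", ascending=False, kind="stable").reset_index(drop=True)
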