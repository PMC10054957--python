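"""Peptide validation and the length-invariant position-labeling scheme.

HLA class I molecules present peptides of 8-13 residues. Binding
specificity is concentrated near the two termini, so positions are
named after their distance from an end rather than by absolute index:
the first five residues are labeled ``1 2 3 4 5`` (N-terminal side) and
the last four ``7 8 9 0`` (C-terminal side, ``0`` being the C-terminal
residue, often written as Omega). Label ``6`` never occurs. The scheme
is a pure function of peptide length:

* labels 1-5 always map to sequence indices 1-5 (1-based);
* labels 7, 8, 9, 0 always map to the last four indices;
* for an 8-mer, labels 5 and 7 land on the same residue;
* the middle residues of 11-13-mers carry no label.

Every downstream module (feature selection, the Bayes scorer, the
interpretation tables) addresses residues exclusively through these
nine labels, which is what makes a single model applicable to peptides
of every length in the 8-13 range.
"""

from __future__ import annotations

from .errors import PeptideAlphabetError, PeptideLengthError

#: The 20 canonical amino acids, alphabetical one-letter codes.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Letter -> dense index 0..19, used by every count table in the package.
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}

MIN_LENGTH: int = 8
MAX_LENGTH: int = 13

#: The nine position labels in canonical (N- to C-terminal) order.
POSITION_LABELS: tuple[int, ...] = (1, 2, 3, 4, 5, 7, 8, 9, 0)

_ALPHABET = frozenset(AMINO_ACIDS)


def validate_peptide(raw: str) -> str:
    """Validate and normalize one peptide sequence.

    Uppercases the input, then checks the alphabet (the 20 canonical
    letters only -- ambiguity codes B, J, O, U, X, Z and modification
    annotations are rejected, never silently stripped) and the length
    bound 8..13.

    Returns the normalized sequence string.

    Raises
    ------
    PeptideAlphabetError
        If any character is not a canonical amino-acid letter.
    PeptideLengthError
        If the length is outside [8, 13].
    """
    if not isinstance(raw, str) or not raw:
        raise PeptideAlphabetError("peptide must be a non-empty string")
    seq = raw.strip().upper()
    bad = set(seq) - _ALPHABET
    if bad:
        raise PeptideAlphabetError(
            f"non-canonical character(s) {sorted(bad)} in peptide {raw!r}"
        )
    if not MIN_LENGTH <= len(seq) <= MAX_LENGTH:
        raise PeptideLengthError(
            f"peptide {seq!r} has length {len(seq)}, outside [{MIN_LENGTH}, {MAX_LENGTH}]"
        )
    return seq


def label_indices(length: int) -> dict[int, int]:
    """Map each of the nine position labels to a 0-based sequence index.

    Labels 1-5 map to indices 0-4; labels 7, 8, 9, 0 map to the last
    four indices ``length-4 .. length-1``. For ``length == 8`` labels 5
    and 7 both map to index 4 (the shared residue).
    """
    if not MIN_LENGTH <= length <= MAX_LENGTH:
        raise PeptideLengthError(f"length {length} outside [{MIN_LENGTH}, {MAX_LENGTH}]")
    idx = {lab: lab - 1 for lab in (1, 2, 3, 4, 5)}
    for offset, lab in enumerate((7, 8, 9, 0)):
        idx[lab] = length - 4 + offset
    return idx


def position_labels(peptide: str) -> dict[int, str]:
    """Return the label -> residue map for a validated peptide.

    The map always has exactly nine entries; for an 8-mer, labels 5 and
    7 return the same residue. Residues that are neither in the first
    five nor the last four positions (possible for 11-13-mers) do not
    appear.
    """
    idx = label_indices(len(peptide))
    return {lab: peptide[i] for lab, i in idx.items()}


def residue_at(peptide: str, label: int) -> str:
    """Residue carried by one position label of a validated peptide."""
    return peptide[label_indices(len(peptide))[label]]
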