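"""File formats: peptide lists, FASTA proteomes, model JSON, TSV reports.

Peptide lists are plain text (one peptide per line, ``#`` comments) or
TSV with a ``peptide`` column and optional ``allele`` / ``label``
columns. FASTA goes through Biopython. Models round-trip through a
versioned JSON schema so a loaded model scores identically to the one
saved.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .errors import InputFormatError, ModelSchemaError, PeptideError
from .model import NBModel
from .peptides import validate_peptide


def read_peptide_table(path: str | Path, strict: bool = True) -> pd.DataFrame:
    """Read a peptide list or TSV into a DataFrame with a ``peptide`` column.

    Malformed peptides are reported with their line numbers; in strict
    mode (the default) any malformed line aborts the read.
    """
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    text = path.read_text()
    lines = text.splitlines()
    body = [ln for ln in lines if ln.strip() and not ln.lstrip().startswith("#")]
    if not body:
        raise InputFormatError(f"{path}: no peptides found")

    if "\t" in body[0]:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        if "peptide" not in df.columns:
            raise InputFormatError(f"{path}: TSV must have a 'peptide' column")
        raw = list(df["peptide"])
        rows = list(range(2, len(raw) + 2))  # 1-based, after header
    else:
        raw, rows = [], []
        for i, ln in enumerate(lines, start=1):
            s = ln.strip()
            if s and not s.startswith("#"):
                raw.append(s)
                rows.append(i)
        df = pd.DataFrame({"peptide": raw})

    validated, errors = [], []
    for lineno, pep in zip(rows, raw):
        try:
            validated.append(validate_peptide(pep))
        except PeptideError as exc:
            errors.append(f"line {lineno}: {exc}")
            validated.append(None)
    if errors:
        report = "; ".join(errors[:10]) + ("; ..." if len(errors) > 10 else "")
        if strict:
            raise InputFormatError(f"{path}: {len(errors)} malformed line(s): {report}")
        df = df[[v is not None for v in validated]].copy()
        df["peptide"] = [v for v in validated if v is not None]
    else:
        df = df.copy()
        df["peptide"] = validated
    return df.reset_index(drop=True)


def read_peptides(path: str | Path, strict: bool = True) -> list[str]:
    """Read a flat peptide list (ignores any extra TSV columns)."""
    return list(read_peptide_table(path, strict=strict)["peptide"])


def group_by_allele(df: pd.DataFrame) -> dict[str, list[str]]:
    """Split a peptide table with an ``allele`` column into per-allele lists."""
    if "allele" not in df.columns:
        raise InputFormatError("peptide table has no 'allele' column")
    return {a: list(g["peptide"]) for a, g in df.groupby("allele", sort=False)}


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (header, sequence), multi-line sequences joined."""
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    text = path.read_text()
    if not text.strip():
        raise InputFormatError(f"{path}: empty FASTA file")
    if not text.lstrip().startswith(">"):
        raise InputFormatError(f"{path}: not FASTA (no '>' header)")
    records = [(r.description, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputFormatError(f"{path}: no FASTA records")
    empties = [h for h, s in records if not s]
    if empties:
        raise InputFormatError(f"{path}: empty sequence for record(s) {empties[:3]}")
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def save_model(model: NBModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path: str | Path) -> NBModel:
    path = Path(path)
    if not path.exists():
        raise InputFormatError(f"no such file: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ModelSchemaError(f"{path}: not valid model JSON ({exc})") from exc
    if not isinstance(payload, dict):
        raise ModelSchemaError(f"{path}: model file must hold a JSON object")
    return NBModel.from_dict(payload)


def config_digest(config: Mapping) -> str:
    """Short stable digest of a run configuration, for report headers."""
    blob = json.dumps({k: str(v) for k, v in sorted(config.items())}, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: str | Path, config: Mapping | None = None) -> None:
    """Write a TSV report with a commented provenance header."""
    from . import __version__

    with open(path, "w") as fh:
        fh.write(f"# pepnb {__version__}")
        if config:
            fh.write(f" config={config_digest(config)}")
            for k, v in sorted(config.items()):
                fh.write(f" {k}={v}")
        fh.write("\n")
        df.to_csv(fh, sep="\t", index=False)
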