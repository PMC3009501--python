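"""Readers and writers for every external representation the pipeline touches.

Formats: multi-record FASTA, the PSI-BLAST ASCII PSSM dialect (only the
first 20-column log-odds block is read; the percentage block and trailing
information-content columns are ignored), three-column RSA tables
(tab-separated ``index  aa  rsa`` with ``#`` comments), pair lists
(``id_a  id_b  label``), and versioned single-file model archives.

All residue positions in user-facing files are 1-based and inclusive.
Malformed rows are rejected, never silently repaired.
"""

from __future__ import annotations

import dataclasses
import enum
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from Bio import SeqIO

from .profile_encoding import N_AA, PSSM_COLUMNS, PssmProfile

#: The 20 canonical amino-acid letters.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Non-canonical codes collapsed to 'X' on input.
_NON_CANONICAL = {"B", "Z", "X", "U", "O", "J"}

MODEL_FORMAT_VERSION = 1


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ModelIOError(RuntimeError):
    """A model archive could not be (de)serialized."""


class PairLabel(enum.Enum):
    INTERACTING = 1
    NON_INTERACTING = 0
    UNKNOWN = -1


@dataclasses.dataclass
class SequenceRecord:
    """One protein sequence over the canonical alphabet (plus 'X')."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FormatError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - AMINO_ACIDS - {"X"}
        if bad:
            raise FormatError(
                f"sequence {self.id!r} contains illegal residue(s) "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclasses.dataclass
class PairRecord:
    id_a: str
    id_b: str
    label: PairLabel


@dataclasses.dataclass
class RsaTable:
    """Per-residue relative solvent accessibility in [0, 1].

    Stands in for DSSP-derived actual ASA: ``rows`` holds
    (1-based index, amino-acid letter, RSA) triples with strictly
    increasing indices.
    """

    protein_id: str
    rows: list  # of (int, str, float)

    def __post_init__(self) -> None:
        prev = 0
        for idx, aa, rsa in self.rows:
            if idx <= prev:
                raise FormatError(
                    f"{self.protein_id}: residue indices must be strictly "
                    f"increasing (saw {idx} after {prev})"
                )
            if not 0.0 <= rsa <= 1.0:
                raise FormatError(
                    f"{self.protein_id}: RSA {rsa} at index {idx} outside [0, 1]"
                )
            prev = idx

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def values(self) -> np.ndarray:
        return np.array([r[2] for r in self.rows], dtype=float)

    @property
    def letters(self) -> str:
        return "".join(r[1] for r in self.rows)


def _clean_residues(raw: str, record_id: str) -> str:
    out = []
    for ch in raw.upper():
        if ch in AMINO_ACIDS:
            out.append(ch)
        elif ch in _NON_CANONICAL:
            out.append("X")
        elif ch in ("*", "-"):
            continue
        else:
            raise FormatError(
                f"sequence {record_id!r}: illegal residue character {ch!r}"
            )
    return "".join(out)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a multi-record FASTA file, preserving record order.

    Residues are upper-cased; non-canonical codes (B, Z, X, U, O, J) map
    to 'X'. Duplicate IDs and any other character are errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(
            SequenceRecord(id=rec.id, residues=_clean_residues(str(rec.seq), rec.id))
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), 60):
                fh.write(rec.residues[i : i + 60] + "\n")


def read_pssm(path, protein_id: str | None = None) -> PssmProfile:
    """Parse a PSI-BLAST ASCII PSSM file (first log-odds block only).

    Rows look like ``   12 K   -1  0  ...`` — a 1-based position, the
    query residue, then at least 20 integer log-odds scores. Extra
    columns (the percentage block, information content) are ignored.
    """
    path = Path(path)
    letters: list[str] = []
    scores: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if len(parts) < 2:
                continue
            if not parts[0].isdigit():
                continue  # header / footer lines
            if len(parts) < 2 + N_AA:
                raise FormatError(
                    f"{path}:{lineno}: expected {N_AA} scores after the "
                    f"residue letter, found {len(parts) - 2}"
                )
            pos, aa = parts[0], parts[1]
            if len(aa) != 1 or not aa.isalpha():
                raise FormatError(
                    f"{path}:{lineno}: expected a residue letter, got {aa!r}"
                )
            row = []
            for cell in parts[2 : 2 + N_AA]:
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric score cell {cell!r}"
                    ) from None
            if int(pos) != len(scores) + 1:
                raise FormatError(
                    f"{path}:{lineno}: positions must run 1..L without gaps "
                    f"(saw {pos}, expected {len(scores) + 1})"
                )
            letters.append(aa.upper())
            scores.append(row)
    if not scores:
        raise FormatError(f"{path}: no PSSM rows found")
    return PssmProfile(
        protein_id=protein_id or path.stem,
        raw=np.array(scores, dtype=float),
        letters="".join(letters),
    )


def write_pssm(profile: PssmProfile, path) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect :func:`read_pssm` reads."""
    header = " ".join(f"{aa:>3}" for aa in PSSM_COLUMNS)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        fh.write(f"      {header}\n")
        for i, (aa, row) in enumerate(zip(profile.letters, profile.raw), start=1):
            cells = " ".join(f"{int(round(v)):>3d}" for v in row)
            fh.write(f"{i:>5d} {aa} {cells}\n")


def read_rsa_table(path, protein_id: str | None = None) -> RsaTable:
    """Read a 3-column RSA table (index, amino acid, RSA in [0, 1])."""
    path = Path(path)
    rows: list = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(parts)}"
                )
            try:
                idx = int(parts[0])
                rsa = float(parts[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric index or RSA value"
                ) from None
            rows.append((idx, parts[1].upper(), rsa))
    return RsaTable(protein_id=protein_id or path.stem, rows=rows)


def write_rsa_table(table: RsaTable, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# RSA table for {table.protein_id}\n")
        for idx, aa, rsa in table.rows:
            fh.write(f"{idx}\t{aa}\t{rsa:.4f}\n")


_LABEL_MAP = {
    "1": PairLabel.INTERACTING,
    "0": PairLabel.NON_INTERACTING,
    "?": PairLabel.UNKNOWN,
}


def read_pairs(path) -> list[PairRecord]:
    """Read a pair list (TSV: id_a, id_b, label in {0, 1, ?})."""
    path = Path(path)
    pairs: list[PairRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(
                    f"{path}:{lineno}: expected 3 tab-separated columns"
                )
            if parts[2] not in _LABEL_MAP:
                raise FormatError(
                    f"{path}:{lineno}: label must be 0, 1 or ?, got {parts[2]!r}"
                )
            pairs.append(PairRecord(parts[0], parts[1], _LABEL_MAP[parts[2]]))
    return pairs


def write_pairs(pairs: Sequence[PairRecord], path) -> None:
    inv = {v: k for k, v in _LABEL_MAP.items()}
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.id_b}\t{inv[p.label]}\n")


def save_model(path, model, kind: str) -> None:
    """Serialize a trained model to a versioned single-file archive."""
    joblib.dump(
        {"format_version": MODEL_FORMAT_VERSION, "kind": kind, "payload": model},
        path,
    )


def load_model(path, expect_kind: str | None = None):
    """Load a model archive, checking version and (optionally) kind."""
    try:
        blob = joblib.load(path)
    except Exception as exc:  # joblib raises a zoo of unpickling errors
        raise ModelIOError(f"could not deserialize model file {path}: {exc}")
    if not isinstance(blob, dict) or "format_version" not in blob:
        raise ModelIOError(f"{path} is not a surfppi model archive")
    if blob["format_version"] != MODEL_FORMAT_VERSION:
        raise ModelIOError(
            f"{path}: model format version {blob['format_version']} "
            f"not supported (expected {MODEL_FORMAT_VERSION})"
        )
    if expect_kind is not None and blob.get("kind") != expect_kind:
        raise ModelIOError(
            f"{path}: expected a {expect_kind!r} model, found {blob.get('kind')!r}"
        )
    return blob["payload"]
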