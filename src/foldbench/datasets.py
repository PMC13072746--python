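"""Protein kinetics datasets: records, collections and delimited-table / FASTA I/O.

A dataset row is one protein with a PDB code, an amino-acid sequence and/or a
chain length ``L``, and an experimentally determined folding rate on the
natural-log scale, ``ln(k_f)`` with ``k_f = 1/t`` (``t`` the folding time in
seconds).  Compilations in this field (S77, S80, S111, S30 and the like) are
small — tens to ~150 proteins — and may legitimately contain the same PDB code
twice with different measured rates, so a :class:`ProteinDataset` is an
*ordered list*, never a mapping, and parsing never deduplicates.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / nonstandard codes accepted only in permissive mode.
NONSTANDARD_RESIDUES = frozenset("BZXUO")

KINETIC_CLASSES = {"two-state", "multi-state", "unknown"}
STRUCTURAL_CLASSES = {"all-alpha", "all-beta", "mixed", "unknown"}

_DATASET_COLUMNS = [
    "pdb_id",
    "sequence",
    "length",
    "ln_kf",
    "kinetic_class",
    "structural_class",
]


class DatasetFormatError(ValueError):
    """A table is structurally unusable (missing columns, duplicate keys...)."""


class RecordValidationError(ValueError):
    """A single row failed validation; carries the row index and field name."""

    def __init__(self, message: str, row: Optional[int] = None, field: Optional[str] = None):
        self.row = row
        self.field = field
        prefix = ""
        if row is not None:
            prefix += f"row {row}: "
        if field is not None:
            prefix += f"field '{field}': "
        super().__init__(prefix + message)


def normalize_pdb_id(pdb_id: str) -> str:
    """Upper-case a PDB code (codes are case-insensitive in practice)."""
    return str(pdb_id).strip().upper()


def validate_sequence(sequence: str, *, permissive: bool = False) -> str:
    """Upper-case and validate an amino-acid sequence.

    Rejects anything outside the 20 standard residues unless *permissive*,
    in which case the ambiguity codes B, Z, X, U, O are tolerated as
    length-contributing unknowns.
    """
    seq = str(sequence).strip().upper()
    allowed = STANDARD_RESIDUES | NONSTANDARD_RESIDUES if permissive else STANDARD_RESIDUES
    for ch in seq:
        if ch not in allowed:
            raise RecordValidationError(
                f"invalid residue {ch!r} in sequence", field="sequence"
            )
    return seq


@dataclass
class ProteinRecord:
    """One protein: identifier, sequence and/or length, and ln(k_f).

    ``length`` is the residue count ``L``.  When a sequence is present it is
    authoritative for the length; a conflicting explicit length is replaced
    (the reader logs this, mirroring the internal inconsistencies the
    published compilations themselves exhibit).
    """

    pdb_id: str
    ln_kf: float
    sequence: Optional[str] = None
    length: Optional[int] = None
    kinetic_class: Optional[str] = None
    structural_class: Optional[str] = None
    source: Optional[str] = None
    permissive: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.pdb_id = normalize_pdb_id(self.pdb_id)
        if not self.pdb_id:
            raise RecordValidationError("empty pdb_id", field="pdb_id")
        self.ln_kf = float(self.ln_kf)
        if not math.isfinite(self.ln_kf):
            raise RecordValidationError("ln_kf must be finite", field="ln_kf")
        if self.sequence is not None:
            self.sequence = validate_sequence(self.sequence, permissive=self.permissive)
            seq_len = len(self.sequence)
            if self.length is not None and int(self.length) != seq_len:
                logger.warning(
                    "pdb_id %s: declared length %s conflicts with sequence length %d; "
                    "using sequence",
                    self.pdb_id,
                    self.length,
                    seq_len,
                )
            self.length = seq_len
        if self.length is None:
            raise RecordValidationError(
                "record needs a sequence or a length", field="length"
            )
        self.length = int(self.length)
        if self.length < 1:
            raise RecordValidationError("length must be >= 1", field="length")
        if self.kinetic_class is not None and self.kinetic_class not in KINETIC_CLASSES:
            raise RecordValidationError(
                f"unknown kinetic_class {self.kinetic_class!r}", field="kinetic_class"
            )
        if (
            self.structural_class is not None
            and self.structural_class not in STRUCTURAL_CLASSES
        ):
            raise RecordValidationError(
                f"unknown structural_class {self.structural_class!r}",
                field="structural_class",
            )


@dataclass
class ProteinDataset:
    """Named, ordered collection of :class:`ProteinRecord` (duplicates allowed)."""

    name: str
    records: list[ProteinRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 1:
            raise DatasetFormatError(f"dataset {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def pdb_ids(self) -> list[str]:
        return [r.pdb_id for r in self.records]

    def lengths(self) -> np.ndarray:
        return np.array([r.length for r in self.records], dtype=float)

    def ln_kf(self) -> np.ndarray:
        return np.array([r.ln_kf for r in self.records], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pdb_id": [r.pdb_id for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "length": [r.length for r in self.records],
                "ln_kf": [r.ln_kf for r in self.records],
                "kinetic_class": [r.kinetic_class for r in self.records],
                "structural_class": [r.structural_class for r in self.records],
            }
        )

    def rename(self, name: str) -> "ProteinDataset":
        return ProteinDataset(name=name, records=list(self.records))


@dataclass
class PredictionTable:
    """Third-party predictor output: pdb_id -> predicted ln(k_f), natural log.

    Carrier for server predictions ingested from delimited tables; the
    predictors' internals are outside this package, only their numbers enter.
    """

    predictor_name: str
    entries: dict[str, float]

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        for pdb_id, value in self.entries.items():
            key = normalize_pdb_id(pdb_id)
            if key in clean:
                raise DatasetFormatError(
                    f"duplicate pdb_id {key!r} in predictions {self.predictor_name!r}"
                )
            v = float(value)
            if not math.isfinite(v):
                raise RecordValidationError(
                    f"non-finite prediction for {key!r}", field="ln_kf_pred"
                )
            clean[key] = v
        self.entries = clean

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pdb_id: str) -> bool:
        return normalize_pdb_id(pdb_id) in self.entries

    def __getitem__(self, pdb_id: str) -> float:
        return self.entries[normalize_pdb_id(pdb_id)]


def _delimiter(fmt: str) -> str:
    if fmt == "tsv":
        return "\t"
    if fmt == "csv":
        return ","
    raise DatasetFormatError(f"unknown format {fmt!r} (expected 'tsv' or 'csv')")


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "tsv"


def _opt(value) -> Optional[str]:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() in {"nan", "na", "none"}:
        return None
    return s


def read_dataset(
    path,
    name: Optional[str] = None,
    format: Optional[str] = None,
    *,
    permissive: bool = False,
) -> ProteinDataset:
    """Read a protein kinetics table (TSV by default, CSV via *format*).

    Required columns: ``pdb_id``, ``ln_kf`` and at least one of ``sequence`` /
    ``length``.  Row order and duplicate pdb_ids are preserved.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    df = pd.read_csv(path, sep=_delimiter(fmt), dtype=str, keep_default_na=False)
    missing = {"pdb_id", "ln_kf"} - set(df.columns)
    if missing:
        raise DatasetFormatError(
            f"{path}: missing required column(s) {sorted(missing)}"
        )
    if "sequence" not in df.columns and "length" not in df.columns:
        raise DatasetFormatError(f"{path}: need a 'sequence' or 'length' column")

    label = name if name is not None else path.stem
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        rowd = dict(zip(df.columns, row))
        try:
            ln_kf_raw = _opt(rowd.get("ln_kf"))
            if ln_kf_raw is None:
                raise RecordValidationError("missing ln_kf", field="ln_kf")
            length_raw = _opt(rowd.get("length"))
            records.append(
                ProteinRecord(
                    pdb_id=rowd["pdb_id"],
                    ln_kf=float(ln_kf_raw),
                    sequence=_opt(rowd.get("sequence")),
                    length=int(length_raw) if length_raw is not None else None,
                    kinetic_class=_opt(rowd.get("kinetic_class")),
                    structural_class=_opt(rowd.get("structural_class")),
                    source=label,
                    permissive=permissive,
                )
            )
        except RecordValidationError as exc:
            raise RecordValidationError(str(exc), row=i) from exc
        except ValueError as exc:
            raise RecordValidationError(str(exc), row=i) from exc
    return ProteinDataset(name=label, records=records)


def write_dataset(dataset: ProteinDataset, path, format: Optional[str] = None) -> Path:
    """Write a dataset table such that :func:`read_dataset` round-trips it."""
    path = Path(path)
    fmt = _infer_format(path, format)
    sep = _delimiter(fmt)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(_DATASET_COLUMNS)
        for r in dataset:
            writer.writerow(
                [
                    r.pdb_id,
                    r.sequence or "",
                    r.length,
                    repr(r.ln_kf),
                    r.kinetic_class or "",
                    r.structural_class or "",
                ]
            )
    return path


def read_fasta_with_rates(
    fasta_path,
    rates_path,
    name: Optional[str] = None,
    *,
    permissive: bool = False,
) -> ProteinDataset:
    """Join a FASTA file of sequences with a pdb_id -> ln_kf rates table.

    FASTA entries without a rate are dropped with a warning; a rate whose
    pdb_id has no sequence is an error (rates are the scarce commodity).
    """
    fasta_path = Path(fasta_path)
    rates_path = Path(rates_path)
    sequences: dict[str, str] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        key = normalize_pdb_id(rec.id.split()[0])
        sequences[key] = str(rec.seq)
        order.append(key)

    fmt = _infer_format(rates_path, None)
    df = pd.read_csv(rates_path, sep=_delimiter(fmt), dtype=str, keep_default_na=False)
    if "pdb_id" not in df.columns or "ln_kf" not in df.columns:
        raise DatasetFormatError(f"{rates_path}: need columns pdb_id, ln_kf")
    rates = {
        normalize_pdb_id(row.pdb_id): float(row.ln_kf)
        for row in df.itertuples(index=False)
    }

    missing = sorted(set(rates) - set(sequences))
    if missing:
        raise DatasetFormatError(
            f"rate entries with no FASTA sequence: {', '.join(missing)}"
        )
    unmatched = [k for k in order if k not in rates]
    if unmatched:
        logger.warning(
            "dropping %d FASTA entr%s without a rate: %s",
            len(unmatched),
            "y" if len(unmatched) == 1 else "ies",
            ", ".join(unmatched),
        )

    label = name if name is not None else fasta_path.stem
    records = [
        ProteinRecord(
            pdb_id=k,
            ln_kf=rates[k],
            sequence=sequences[k],
            source=label,
            permissive=permissive,
        )
        for k in order
        if k in rates
    ]
    if not records:
        raise DatasetFormatError("no FASTA entry matched a rate")
    return ProteinDataset(name=label, records=records)


LN10 = math.log(10.0)


def read_predictions(path, predictor_name: str, scale: str = "natural-log") -> PredictionTable:
    """Read a two-column pdb_id / predicted-ln(k_f) table.

    ``scale='log10'`` converts to natural log by multiplying by ln(10); the
    returned table is always on the natural-log scale.
    """
    if scale not in {"natural-log", "log10"}:
        raise DatasetFormatError(f"unknown scale {scale!r}")
    path = Path(path)
    fmt = _infer_format(path, None)
    df = pd.read_csv(path, sep=_delimiter(fmt), dtype=str, keep_default_na=False)
    if "pdb_id" not in df.columns:
        raise DatasetFormatError(f"{path}: need a pdb_id column")
    value_col = next(
        (c for c in ("ln_kf_pred", "ln_kf", "prediction") if c in df.columns), None
    )
    if value_col is None:
        raise DatasetFormatError(
            f"{path}: need a prediction column (ln_kf_pred, ln_kf or prediction)"
        )
    entries: dict[str, float] = {}
    for row in df.itertuples(index=False):
        rowd = dict(zip(df.columns, row))
        key = normalize_pdb_id(rowd["pdb_id"])
        if key in entries:
            raise DatasetFormatError(f"{path}: duplicate pdb_id {key!r}")
        value = float(rowd[value_col])
        if scale == "log10":
            value *= LN10
        entries[key] = value
    return PredictionTable(predictor_name=predictor_name, entries=entries)
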