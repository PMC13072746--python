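"""Experimental-data disagreement between compilations sharing PDB codes.

Different kinetics compilations report, for the same PDB code, sequences of
different length (different constructs, tags, chain choices) and different
ln(k_f) (different temperature, pH, denaturant...).  This module quantifies
that scatter pairwise: one comparison pair per distinct shared code (first
occurrence on each side, so duplicated entries never double-count), exact
string equality for sequences, and a rate threshold — two values of ln(k_f)
count as non-identical when they differ by at least ``rate_tol`` (default
0.01, the resolution at which the compilations print rates).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .datasets import ProteinDataset, ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_RATE_TOL = 0.01


@dataclass
class DiscrepancyReport:
    """Pairwise dataset-comparison summary over shared PDB codes.

    Sequence counts cover only pairs where both sides carry a sequence
    (``seq_uncompared`` holds the rest); length statistics are over the
    sequence-nonidentical pairs.  Rate statistics are over pairs whose
    |Δ ln k_f| >= the threshold used.
    """

    pair: tuple[str, str]
    n_overlap: int
    seq_identical: int
    seq_nonidentical: int
    seq_uncompared: int
    length_diff_range: Optional[tuple[int, int]]
    length_diff_mean: Optional[float]
    rate_identical: int
    rate_nonidentical: int
    rate_diff_range: Optional[tuple[float, float]]
    rate_diff_mean: Optional[float]
    rate_tol: float = DEFAULT_RATE_TOL

    def __post_init__(self) -> None:
        if self.seq_identical + self.seq_nonidentical + self.seq_uncompared != self.n_overlap:
            raise ValueError("sequence counts do not partition the overlap")
        if self.rate_identical + self.rate_nonidentical != self.n_overlap:
            raise ValueError("rate counts do not partition the overlap")

    def to_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "n_overlap": self.n_overlap,
            "seq_identical": self.seq_identical,
            "seq_nonidentical": self.seq_nonidentical,
            "seq_uncompared": self.seq_uncompared,
            "length_diff_range": list(self.length_diff_range)
            if self.length_diff_range
            else None,
            "length_diff_mean": self.length_diff_mean,
            "rate_identical": self.rate_identical,
            "rate_nonidentical": self.rate_nonidentical,
            "rate_diff_range": list(self.rate_diff_range)
            if self.rate_diff_range
            else None,
            "rate_diff_mean": self.rate_diff_mean,
            "rate_tol": self.rate_tol,
        }


def _first_by_id(ds: ProteinDataset) -> dict[str, ProteinRecord]:
    out: dict[str, ProteinRecord] = {}
    dups = []
    for r in ds:
        if r.pdb_id in out:
            dups.append(r.pdb_id)
        else:
            out[r.pdb_id] = r
    if dups:
        logger.info(
            "%s: using first occurrence for duplicated code(s) %s",
            ds.name,
            ", ".join(sorted(set(dups))),
        )
    return out


def _shared(a: ProteinDataset, b: ProteinDataset):
    a_map = _first_by_id(a)
    b_map = _first_by_id(b)
    shared = [pid for pid in a_map if pid in b_map]  # order of A
    if not shared:
        raise ValueError(f"datasets {a.name!r} and {b.name!r} share no pdb_id")
    return a_map, b_map, shared


def _length_of(r: ProteinRecord) -> int:
    # sequence is authoritative when present (the record enforces this)
    return r.length


def compare_datasets(
    a: ProteinDataset, b: ProteinDataset, rate_tol: float = DEFAULT_RATE_TOL
) -> DiscrepancyReport:
    """Summarise sequence/length and ln(k_f) disagreement over shared codes."""
    a_map, b_map, shared = _shared(a, b)

    seq_identical = seq_nonidentical = seq_uncompared = 0
    len_diffs: list[int] = []
    rate_nonidentical = 0
    rate_diffs: list[float] = []

    for pid in shared:
        ra, rb = a_map[pid], b_map[pid]
        if ra.sequence is None or rb.sequence is None:
            seq_uncompared += 1
        elif ra.sequence == rb.sequence:
            seq_identical += 1
        else:
            seq_nonidentical += 1
            len_diffs.append(abs(_length_of(ra) - _length_of(rb)))
        d = abs(ra.ln_kf - rb.ln_kf)
        # tolerance guard so table-precision differences like 5.010-5.000
        # compare as >= 0.01 despite binary floating point
        if d >= rate_tol - 1e-9:
            rate_nonidentical += 1
            rate_diffs.append(d)

    n = len(shared)
    return DiscrepancyReport(
        pair=(a.name, b.name),
        n_overlap=n,
        seq_identical=seq_identical,
        seq_nonidentical=seq_nonidentical,
        seq_uncompared=seq_uncompared,
        length_diff_range=(min(len_diffs), max(len_diffs)) if len_diffs else None,
        length_diff_mean=sum(len_diffs) / len(len_diffs) if len_diffs else None,
        rate_identical=n - rate_nonidentical,
        rate_nonidentical=rate_nonidentical,
        rate_diff_range=(min(rate_diffs), max(rate_diffs)) if rate_diffs else None,
        rate_diff_mean=sum(rate_diffs) / len(rate_diffs) if rate_diffs else None,
        rate_tol=rate_tol,
    )


def list_discrepant_pairs(
    a: ProteinDataset, b: ProteinDataset, rate_tol: float = DEFAULT_RATE_TOL
) -> pd.DataFrame:
    """One row per shared code with any length or rate discrepancy.

    Columns: pdb_id, L_A, L_B, ln_kf_A, ln_kf_B, abs_dL, abs_dlnkf;
    sorted by |Δ ln k_f| descending.
    """
    a_map, b_map, shared = _shared(a, b)
    rows = []
    for pid in shared:
        ra, rb = a_map[pid], b_map[pid]
        d_len = abs(_length_of(ra) - _length_of(rb))
        d_rate = abs(ra.ln_kf - rb.ln_kf)
        seq_differs = (
            ra.sequence is not None
            and rb.sequence is not None
            and ra.sequence != rb.sequence
        )
        if seq_differs or d_len > 0 or d_rate >= rate_tol - 1e-9:
            rows.append(
                {
                    "pdb_id": pid,
                    "L_A": _length_of(ra),
                    "L_B": _length_of(rb),
                    "ln_kf_A": ra.ln_kf,
                    "ln_kf_B": rb.ln_kf,
                    "abs_dL": d_len,
                    "abs_dlnkf": d_rate if d_rate >= rate_tol - 1e-9 else 0.0,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["pdb_id", "L_A", "L_B", "ln_kf_A", "ln_kf_B", "abs_dL", "abs_dlnkf"],
    )
    return df.sort_values("abs_dlnkf", ascending=False, kind="stable").reset_index(
        drop=True
    )
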