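import numpy as np
import pytest

from foldbench.datasets import ProteinDataset, ProteinRecord


def make_record(pdb_id, ln_kf, length=None, sequence=None, **kw):
    return ProteinRecord(pdb_id=pdb_id, ln_kf=ln_kf, length=length, sequence=sequence, **kw)


def make_dataset(name, rows):
    """rows: iterable of (pdb_id, length, ln_kf) or (pdb_id, length, ln_kf, sequence)."""
    records = []
    for row in rows:
        pdb_id, length, ln_kf = row[:3]
        seq = row[3] if len(row) > 3 else None
        records.append(make_record(pdb_id, ln_kf, length=length, sequence=seq))
    return ProteinDataset(name=name, records=records)


@pytest.fixture
def toy_dataset():
    """Five proteins on a slightly noisy length trend."""
    return make_dataset(
        "toy",
        [
            ("P001", 50, 7.0),
            ("P002", 80, 4.1),
            ("P003", 120, 2.2),
            ("P004", 200, -0.5),
            ("P005", 300, -2.9),
        ],
    )


def random_kinetics_dataset(rng, n=None, allow_duplicates=False, name="rand"):
    """Random dataset for property tests (not the calibrated generator)."""
    n = n if n is not None else int(rng.integers(5, 30))
    lengths = rng.integers(30, 400, size=n)
    ln_kf = rng.normal(2.0, 3.0, size=n)
    ids = [f"{i:04d}" for i in range(n)]
    if allow_duplicates and n > 2:
        ids[1] = ids[0]  # deliberate duplicated PDB code
    return make_dataset(name, list(zip(ids, lengths.tolist(), ln_kf.tolist())))
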