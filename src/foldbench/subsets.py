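"""Overlap / difference subsets of protein datasets, matched by PDB code.

External validation needs overlap subsets (shared proteins, usable as a
training set with one compilation's experimental data) and difference
subsets (proteins only one compilation contains, usable as an external test
set).  Because the two compilations can report different sequences and rates
for the same PDB code, the overlap is *not* symmetric as a dataset: the
first-named set supplies the experimental data.  ``overlap(A, B)`` keeps
every record of A — including duplicated codes in A — whose code occurs in
B, which is exactly what makes |S77∩S80| = 52 but |S80∩S77| = 50 when S77
carries two duplicated proteins.
"""

from __future__ import annotations

import logging

from .datasets import ProteinDataset

logger = logging.getLogger(__name__)


def overlap(a: ProteinDataset, b: ProteinDataset) -> ProteinDataset:
    """Records of *a* whose pdb_id occurs in *b*; data and order from *a*.

    Membership in *b* is tested against its distinct codes, so duplicates
    in *b* never multiply records of *a*.  The swapped overlap is
    ``overlap(b, a)``.
    """
    b_ids = set(b.pdb_ids)
    records = [r for r in a if r.pdb_id in b_ids]
    name = f"{a.name}∩{b.name}"
    if not records:
        logger.warning("overlap %s is empty", name)
        out = ProteinDataset.__new__(ProteinDataset)
        out.name = name
        out.records = []
        return out
    return ProteinDataset(name=name, records=records)


def difference(a: ProteinDataset, b: ProteinDataset) -> ProteinDataset:
    """Records of *a* whose pdb_id does not occur in *b*; data and order from *a*."""
    b_ids = set(b.pdb_ids)
    records = [r for r in a if r.pdb_id not in b_ids]
    name = f"{a.name}\\{b.name}"
    if not records:
        logger.warning("difference %s is empty", name)
        out = ProteinDataset.__new__(ProteinDataset)
        out.name = name
        out.records = []
        return out
    return ProteinDataset(name=name, records=records)


def partition_check(a: ProteinDataset, b: ProteinDataset) -> bool:
    """True iff overlap and difference partition *a*: |a∩b| + |a\\b| == |a|."""
    return len(overlap(a, b)) + len(difference(a, b)) == len(a)
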