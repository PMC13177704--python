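"""ORF detection on oriented elements and per-cluster ORF-probability
profiles on MSA coordinates.

An ORF is an interval of at least ``orf_min_len`` bases running from an
ATG to the next in-frame stop codon (TAA, TAG or TGA), inclusive of both,
scanned over the three forward frames of the orientation-normalized
element.  ATGs inside an already-open ORF of the same frame do not spawn
nested ORFs; ORFs without a stop before the sequence end are not reported.
Codons containing ambiguous bases are treated as sense codons (neither
start nor stop).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import MsaResult
from .core import InputError

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class OrfInterval:
    element_id: str
    start: int  # element-local, 0-based
    end: int  # exclusive; (end - start) % 3 == 0
    frame: int  # 0, 1, 2

    @property
    def length(self) -> int:
        return self.end - self.start


def find_orfs(sequence: str, orf_min_len: int = 300, element_id: str = ""):
    """All closed ORFs of >= orf_min_len bases over the three forward
    frames (longest-per-stop convention)."""
    seq = sequence.upper()
    n = len(seq)
    orfs = []
    for frame in range(3):
        open_start = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if any(b not in "ACGT" for b in codon):
                continue  # ambiguous codon: sense, neither start nor stop
            if open_start is None:
                if codon == "ATG":
                    open_start = pos
            elif codon in STOP_CODONS:
                end = pos + 3
                if end - open_start >= orf_min_len:
                    orfs.append(OrfInterval(element_id, open_start, end, frame))
                open_start = None
    orfs.sort(key=lambda o: (o.start, o.frame))
    return orfs


def orf_mask(sequence: str, orf_min_len: int = 300) -> np.ndarray:
    """Boolean per-position mask: covered by an ORF in any frame."""
    mask = np.zeros(len(sequence), dtype=bool)
    for orf in find_orfs(sequence, orf_min_len):
        mask[orf.start : orf.end] = True
    return mask


@dataclass
class OrfProbabilityProfile:
    cluster_id: str
    values: np.ndarray  # per-MSA-column fraction of members with an ORF
    n_members: int


def orf_probability_profile(
    member_ids,
    msa: MsaResult,
    orf_min_len: int = 300,
    cluster_id: str = "",
) -> OrfProbabilityProfile:
    """Fraction of cluster members whose ORF mask (union over frames),
    lifted through their MSA row, covers each alignment column.  Gap
    columns of a member contribute 'absent'."""
    member_ids = list(member_ids)
    for mid in member_ids:
        if mid not in msa.ids:
            raise InputError(f"member {mid!r} missing from the MSA")
    width = msa.n_columns
    counts = np.zeros(width, dtype=np.int64)
    for mid in member_ids:
        row = msa.row(mid)
        seq = row.replace("-", "")
        mask = orf_mask(seq, orf_min_len)
        cols = np.frombuffer(row.encode(), dtype=np.uint8) != ord("-")
        col_idx = np.flatnonzero(cols)
        counts[col_idx[mask]] += 1
    values = counts / len(member_ids)
    return OrfProbabilityProfile(cluster_id, values, len(member_ids))
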