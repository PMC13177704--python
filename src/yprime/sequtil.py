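"""Small sequence helpers shared across modules (FASTA I/O via Biopython)."""
from __future__ import annotations

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import InputError

_COMPLEMENT = str.maketrans("ACGTNRYKMWSacgtnrykmws", "TGCANYRMKWStgcanyrmkws")

BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence as uint8 codes (A=0 C=1 G=2 T=3, anything else 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        out[arr == ord(base)] = code
    return out


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n))


def mutate_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply i.i.d. substitutions at the given per-base rate."""
    if rate <= 0:
        return seq
    arr = list(seq)
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in BASES if b != arr[i].upper()]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


def mutate_fixed(seq: str, n_subs: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n_subs`` substitutions at distinct positions."""
    if n_subs <= 0:
        return seq
    arr = list(seq)
    pos = rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False)
    for i in pos:
        choices = [b for b in BASES if b != arr[i].upper()]
        arr[i] = choices[rng.integers(len(choices))]
    return "".join(arr)


def read_fasta(path) -> dict:
    """FASTA file -> ordered {id: uppercase sequence}. Raises InputError."""
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read FASTA file {path}: {exc}") from exc
    if not records:
        raise InputError(f"FASTA file {path} contains no sequences")
    out = {}
    for rec in records:
        if rec.id in out:
            raise InputError(f"duplicate sequence id {rec.id!r} in {path}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(entries: dict, path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in entries.items()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
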