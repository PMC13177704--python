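"""Repeat-motif fixtures and IUPAC helpers.

The degenerate 36-mer consensus and the two CA-rich patterns below are
SYNTHETIC stand-ins with the documented structural properties (length,
ambiguity content, base composition), not the published motifs, which are
only available as supplementary data.  Any fixed degenerate motif set
exercises the sliding edit-distance scanner identically; users can supply
their own motif databases to every scanner entry point.
"""
from __future__ import annotations

from itertools import product

import numpy as np

IUPAC = {
    "A": "A",
    "C": "C",
    "G": "G",
    "T": "T",
    "R": "AG",
    "Y": "CT",
    "W": "AT",
    "S": "CG",
    "K": "GT",
    "M": "AC",
    "B": "CGT",
    "D": "AGT",
    "H": "ACT",
    "V": "ACG",
    "N": "ACGT",
}

#: Synthetic degenerate 36-mer consensus (four two-fold ambiguity codes,
#: 16 concrete expansions, composition not CA-biased).
MER36_CONSENSUS = "ACTGTCRGGGTTAGYACTGGTTCAAGWGSACTTCAG"
assert len(MER36_CONSENSUS) == 36

#: Synthetic CA-rich Pattern 1 (37 bp; A 16, C 16, T 3, G 2 -> near-equal
#: A/C with minor T/G, mirroring the observed 45/42/7.5/5.5 composition).
CA_PATTERN_1 = "AACCACA" + "CCATACC" + "AACCAGC" + "ACTACCA" + "CAACCTA" + "AG"
assert len(CA_PATTERN_1) == 37

#: Synthetic CA-rich Pattern 2 (33 bp; distinct first half, second half
#: shared with Pattern 1).
CA_PATTERN_2 = "CACCAAACCATCACAAC" + CA_PATTERN_1[-16:]
assert len(CA_PATTERN_2) == 33


def expand_degenerate(consensus: str):
    """All concrete sequences matching a degenerate IUPAC string (sorted)."""
    pools = [IUPAC[b] for b in consensus.upper()]
    return ["".join(p) for p in product(*pools)]


def resolve_degenerate(consensus: str, rng: np.random.Generator) -> str:
    """One concrete sequence, ambiguities resolved uniformly at random."""
    return "".join(
        IUPAC[b][rng.integers(len(IUPAC[b]))] for b in consensus.upper()
    )


def default_mer36_db():
    return expand_degenerate(MER36_CONSENSUS)


def default_ca_pattern_db():
    return {"P1": [CA_PATTERN_1], "P2": [CA_PATTERN_2]}
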