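"""Internal repeat profiling of Y' elements: 36-mer stretches, CA-rich
regions, pattern segmentation, masking, and position frequency matrices.

The 36-mer scanner slides a 36 bp window along the oriented element and
scores each position as the proportion of matching bases against the best
motif of a database, derived from the Levenshtein distance:
``score = (36 - d) / 36``.  Stretches are delimited by score peaks
(``scipy.signal.find_peaks``; height 0.85, spacing 30, leftmost plateau
index) and run from the first peak to the end of the last peak window.
Units whose optimal alignment to the best motif requires indels ("match of
length different than 36") are dropped from the unit list but still delimit
the stretch.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import find_peaks

from ._dp import hamming_best_many, lev_best_many
from .core import InputError
from .sequtil import encode

MER36 = 36


@dataclass
class RepeatStretch:
    element_id: str
    stretch_class: str  # mer36 | ca_rich
    start: int  # element-local, oriented coordinates
    end: int
    unit_count: int
    units: list = field(default_factory=list)
    composition: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MaskedElement:
    element_id: str
    masked_sequence: str
    removed: list = field(default_factory=list)  # (start, end, class, sequence)

    def reconstruct(self) -> str:
        """Re-insert the removed stretches (round-trip identity)."""
        seq = self.masked_sequence
        for start, _end, _cls, sub in sorted(self.removed):
            seq = seq[:start] + sub + seq[start:]
        return seq


@dataclass
class MotifScoreTrack:
    element_id: str
    scores: np.ndarray  # defined for positions 0 .. len(seq) - motif_len
    motif_len: int = MER36


def _composition(seq: str) -> dict:
    n = max(1, len(seq))
    return {b: seq.count(b) / n for b in "ACGT"}


def _encode_windows(seq: str, width: int) -> np.ndarray:
    codes = encode(seq)
    if codes.size < width:
        return np.zeros((0, width), dtype=np.uint8)
    return np.ascontiguousarray(sliding_window_view(codes, width))


def score_motif_track(sequence: str, motif_db, motif_len: int | None = None) -> np.ndarray:
    """Sliding best-motif score track: (L - d_Levenshtein) / L per window."""
    if not motif_db:
        raise InputError("motif database must be non-empty")
    lengths = {len(m) for m in motif_db}
    if len(lengths) != 1:
        raise InputError("all motifs in one database must share a length")
    width = lengths.pop()
    if motif_len is not None and width != motif_len:
        raise InputError(f"expected motif length {motif_len}, got {width}")
    windows = _encode_windows(sequence.upper(), width)
    if windows.shape[0] == 0:
        return np.zeros(0)
    motifs = np.ascontiguousarray(
        np.stack([encode(m.upper()) for m in sorted(set(motif_db))])
    )
    dist = lev_best_many(windows, motifs)
    return (width - dist) / width


def score_36mer_track(sequence: str, motif_db, element_id: str = "") -> MotifScoreTrack:
    """36-meric alignment score across an element (empty track if shorter
    than 36)."""
    for m in motif_db:
        if len(m) != MER36:
            raise InputError("36-mer database entries must have length 36")
    return MotifScoreTrack(element_id, score_motif_track(sequence, motif_db), MER36)


def _peaks(scores: np.ndarray, spacing: int, threshold: float) -> np.ndarray:
    """Local maxima >= threshold, greedy spacing from the highest score
    down, leftmost index of score plateaus."""
    if scores.size == 0:
        return np.zeros(0, dtype=int)
    padded = np.concatenate([[-1.0], scores, [-1.0]])
    idx, props = find_peaks(
        padded, height=threshold, distance=spacing, plateau_size=(1, None)
    )
    if idx.size == 0:
        return idx
    return np.asarray(props["left_edges"], dtype=int) - 1


def _unit_is_clean(window_codes: np.ndarray, motifs: np.ndarray) -> bool:
    """True iff the best-motif optimal alignment needs no indels, i.e. the
    minimum Hamming distance equals the minimum Levenshtein distance."""
    lev = int(lev_best_many(window_codes[None, :], motifs)[0])
    ham = int(hamming_best_many(window_codes[None, :], motifs)[0])
    return ham == lev


def call_36mer_stretch(
    track: MotifScoreTrack,
    sequence: str,
    motif_db,
    peak_spacing: int = 30,
    peak_threshold: float = 0.85,
):
    """Delimit the 36-mer stretch of one element from its score track.

    Stretch interval = [first peak, last peak + 36); unit_count is the
    number of 36 bp periods spanned (round(span / 36)); ``units`` holds the
    peak windows whose best alignment is indel-free.  Returns None when no
    peak clears the threshold.
    """
    peaks = _peaks(track.scores, peak_spacing, peak_threshold)
    if peaks.size == 0:
        return None
    seq = sequence.upper()
    start = int(peaks[0])
    end = int(peaks[-1]) + MER36
    motifs = np.ascontiguousarray(np.stack([encode(m) for m in sorted(set(motif_db))]))
    units = []
    for p in peaks:
        window = seq[p : p + MER36]
        if _unit_is_clean(encode(window), motifs):
            units.append(window)
    span = end - start
    return RepeatStretch(
        element_id=track.element_id,
        stretch_class="mer36",
        start=start,
        end=end,
        unit_count=int(round(span / MER36)),
        units=units,
        composition=_composition(seq[start:end]),
    )


def detect_36mer_stretch(
    sequence: str,
    motif_db,
    element_id: str = "",
    peak_spacing: int = 30,
    peak_threshold: float = 0.85,
):
    track = score_36mer_track(sequence, motif_db, element_id)
    return call_36mer_stretch(track, sequence, motif_db, peak_spacing, peak_threshold)


def refine_motif_db(element_sequences, seed_db, peak_spacing=30, peak_threshold=0.85):
    """One bootstrap round: detect units with the seed database, pool all
    retained (indel-free) units, deduplicate, return the new database.
    Falls back to the seed database with a warning when nothing is found."""
    if not seed_db:
        raise InputError("seed motif database must be non-empty")
    pooled = set()
    for seq in element_sequences:
        stretch = detect_36mer_stretch(
            seq, seed_db, peak_spacing=peak_spacing, peak_threshold=peak_threshold
        )
        if stretch is not None:
            pooled.update(stretch.units)
    if not pooled:
        warnings.warn("no 36-mer units found; keeping the seed database")
        return list(seed_db)
    return sorted(pooled)


# ---------------------------------------------------------------------------
# CA-rich regions


def detect_ca_region(
    sequence: str,
    window: int = 100,
    min_len: int = 100,
    element_id: str = "",
    ac_min: float = 0.8,
    minor_min: float = 0.25,
    telomeric_c_frac: float = 0.55,
):
    """Maximal run of windows that are jointly A+C rich (>= ac_min) with
    both bases well represented (min fraction >= minor_min).  Candidate
    regions that look telomeric -- overall C/(C+A) >= telomeric_c_frac or
    high structural C{1,3}A motif-run coverage -- are rejected: telomeric
    tracts are strongly C-biased (62.5% C / 37.5% A on the CA strand)
    whereas CA-rich repeats have near-equal A and C.  Returns the longest
    surviving region of at least ``min_len`` bp, or None."""
    from .telomeres import is_telomeric_tract

    seq = sequence.upper()
    n = len(seq)
    if n < window:
        return None
    codes = encode(seq)
    is_a = (codes == 0).astype(np.float64)
    is_c = (codes == 1).astype(np.float64)
    ca = np.cumsum(np.concatenate([[0.0], is_a]))
    cc = np.cumsum(np.concatenate([[0.0], is_c]))
    fa = (ca[window:] - ca[:-window]) / window
    fc = (cc[window:] - cc[:-window]) / window
    good = (fa + fc >= ac_min) & (np.minimum(fa, fc) >= minor_min)
    if not good.any():
        return None
    idx = np.flatnonzero(good)
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i > prev + window:  # merge runs separated by less than a window
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))
    for r0, r1 in sorted(runs, key=lambda r: r[0] - r[1]):
        lo, hi = int(r0), int(r1) + window
        if hi - lo < min_len:
            continue
        region = seq[lo:hi]
        n_a, n_c = region.count("A"), region.count("C")
        if n_a + n_c == 0 or n_c / (n_a + n_c) >= telomeric_c_frac:
            continue
        if is_telomeric_tract(region, min_coverage=0.8):
            continue
        return RepeatStretch(
            element_id=element_id,
            stretch_class="ca_rich",
            start=lo,
            end=hi,
            unit_count=0,
            units=[],
            composition=_composition(region),
        )
    return None


@dataclass
class PatternAssignment:
    labels: np.ndarray  # int8 per base: 0 unassigned, 1.. = pattern index
    pattern_names: list
    fractions: dict  # pattern name -> fraction of bases assigned

    def fraction_unassigned(self) -> float:
        return float((self.labels == 0).mean()) if self.labels.size else 1.0


def segment_ca_patterns(sequence: str, pattern_db: dict) -> PatternAssignment:
    """Label each base of a CA-rich region by the repeated pattern whose
    peak window covers it (same sliding edit-distance peak procedure as the
    36-mers, with pattern-specific window lengths).  Conflicts resolve to
    the higher-scoring peak; ties to the earlier pattern name."""
    if not pattern_db:
        raise InputError("pattern database must be non-empty")
    seq = sequence.upper()
    n = len(seq)
    labels = np.zeros(n, dtype=np.int8)
    best_score = np.full(n, -1.0)
    names = sorted(pattern_db)
    for pi, name in enumerate(names, start=1):
        variants = pattern_db[name]
        if not variants:
            continue
        width = len(variants[0])
        track = score_motif_track(seq, variants)
        spacing = max(2, width - 6)
        for p in _peaks(track, spacing, 0.85):
            sc = track[p]
            sl = slice(int(p), int(p) + width)
            upd = best_score[sl] < sc
            labels[sl] = np.where(upd, pi, labels[sl])
            best_score[sl] = np.where(upd, sc, best_score[sl])
    fractions = {
        name: float((labels == pi).mean()) if n else 0.0
        for pi, name in enumerate(names, start=1)
    }
    return PatternAssignment(labels, names, fractions)


# ---------------------------------------------------------------------------
# masking and PFMs


def mask_stretches(sequence: str, stretches, element_id: str = "") -> MaskedElement:
    """Remove stretch intervals from an element, recording enough to lift
    coordinates (and the round trip) back."""
    ivs = sorted((s.start, s.end, s.stretch_class) for s in stretches)
    for (s0, e0, _), (s1, e1, _) in zip(ivs, ivs[1:]):
        if s1 < e0:
            raise InputError("stretch intervals overlap")
    for s0, e0, _ in ivs:
        if s0 < 0 or e0 > len(sequence):
            raise InputError("stretch interval outside the element")
    removed = [(s0, e0, cls, sequence[s0:e0]) for s0, e0, cls in ivs]
    masked = []
    cursor = 0
    for s0, e0, _cls, _sub in removed:
        masked.append(sequence[cursor:s0])
        cursor = e0
    masked.append(sequence[cursor:])
    return MaskedElement(element_id, "".join(masked), removed)


def build_pfm(units) -> pd.DataFrame:
    """Position frequency matrix of equal-length units (rows A,C,G,T;
    columns sum to 1)."""
    units = list(units)
    if not units:
        raise InputError("cannot build a PFM from zero units")
    width = len(units[0])
    if any(len(u) != width for u in units):
        raise InputError("all units must have the same length for a PFM")
    counts = np.zeros((4, width))
    for u in units:
        codes = encode(u)
        for b in range(4):
            counts[b] += codes == b
    totals = counts.sum(axis=0)
    totals[totals == 0] = 1.0
    freq = counts / totals
    return pd.DataFrame(freq, index=list("ACGT"), columns=range(width))
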