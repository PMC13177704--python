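"""Terminal telomere and interstitial telomeric sequence (ITS) detection.

Budding-yeast telomeric DNA is a degenerate C(1-3)A / TG(1-3) repeat.  The
scanner marks every position covered by a sufficiently long maximal run of
the repeat pattern on either strand, averages coverage in sliding windows,
and calls maximal above-threshold runs.  Runs near a contig edge are
terminal telomeres; internal runs of at least ``min_its_len`` are ITSs.

This is a self-contained functional stand-in for an external telomere
finder; externally produced GFF3 telomere calls can be substituted for the
internal ones anywhere downstream (see :func:`calls_from_gff3`).
"""
from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .core import GenomicInterval, PipelineConfig, FORWARD
from . import gff3 as _gff3
from .core import AnnotationRecord

# CA strand: C{1,3}A repeats; TG strand is its reverse complement.
_CA_RE = re.compile(r"(?:C{1,3}A)+")
_TG_RE = re.compile(r"(?:TG{1,3})+")

TERMINAL = "terminal"
INTERSTITIAL = "interstitial"


@dataclass
class TelomereCall:
    interval: GenomicInterval
    kind: str  # terminal | interstitial
    score: float  # mean per-window telomere score inside the call
    strand_class: str  # CA_strand | TG_strand

    @property
    def length(self) -> int:
        return self.interval.length


def motif_coverage(sequence: str, min_run: int = 8):
    """Boolean per-position coverage by maximal telomere-motif runs of at
    least ``min_run`` bp, per strand (CA, TG)."""
    seq = sequence.upper()
    n = len(seq)
    cov_ca = np.zeros(n, dtype=bool)
    cov_tg = np.zeros(n, dtype=bool)
    for pattern, cov in ((_CA_RE, cov_ca), (_TG_RE, cov_tg)):
        for m in pattern.finditer(seq):
            if m.end() - m.start() >= min_run:
                cov[m.start() : m.end()] = True
    return cov_ca, cov_tg


def score_telomere_windows(
    sequence: str, window: int = 20, min_run: int = 8
) -> np.ndarray:
    """Per-start-position telomere score in [0, 1].

    score(p) = fraction of the window [p, p+window) covered by maximal
    telomere-motif matches; both strands are scored and the maximum taken.
    Sequences shorter than the window yield an empty track.
    """
    n = len(sequence)
    if n < window:
        return np.zeros(0)
    cov_ca, cov_tg = motif_coverage(sequence, min_run)
    cov = np.maximum(cov_ca, cov_tg).astype(np.float64)
    csum = np.concatenate([[0.0], np.cumsum(cov)])
    return (csum[window:] - csum[:-window]) / window


def call_telomeres(
    sequence: str,
    contig: str,
    *,
    window: int = 20,
    threshold: float = 0.8,
    merge_gap: int = 10,
    min_its_len: int = 20,
    terminal_margin: int = 50,
    min_run: int = 8,
):
    """Call terminal and interstitial telomeric tracts on one contig.

    Maximal runs of window scores >= threshold are merged across gaps
    <= merge_gap, then refined to the union of the underlying motif runs.
    Calls within ``terminal_margin`` of a contig edge are terminal;
    interstitial calls shorter than ``min_its_len`` are discarded.
    """
    seq = sequence.upper()
    n = len(seq)
    track = score_telomere_windows(seq, window, min_run)
    if track.size == 0:
        return []
    above = track >= threshold
    if not above.any():
        return []
    cov_ca, cov_tg = motif_coverage(seq, min_run)
    cov_any = np.maximum(cov_ca, cov_tg)

    # maximal runs of above-threshold window starts (window-width tolerant)
    idx = np.flatnonzero(above)
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > window:
            runs.append((start, prev))
            start = i
        prev = i
    runs.append((start, prev))

    # refine each run to exact motif-run boundaries
    refined = []
    for p0, p1 in runs:
        lo, hi = p0, min(n, p1 + window)
        covered = np.flatnonzero(cov_any[lo:hi])
        if covered.size:
            lo, hi = lo + covered[0], lo + covered[-1] + 1
        refined.append([int(lo), int(hi), float(track[p0 : p1 + 1].mean())])

    # merge refined tracts separated by at most merge_gap bases
    refined.sort()
    merged = [refined[0]]
    for lo, hi, sc in refined[1:]:
        if lo - merged[-1][1] <= merge_gap:
            weight_prev = merged[-1][1] - merged[-1][0]
            weight_new = hi - lo
            merged[-1][2] = (
                merged[-1][2] * weight_prev + sc * weight_new
            ) / max(1, weight_prev + weight_new)
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi, sc])

    calls = []
    for lo, hi, score in merged:
        kind = (
            TERMINAL
            if lo <= terminal_margin or hi >= n - terminal_margin
            else INTERSTITIAL
        )
        if kind == INTERSTITIAL and hi - lo < min_its_len:
            continue
        ca = int(cov_ca[lo:hi].sum())
        tg = int(cov_tg[lo:hi].sum())
        strand_class = "CA_strand" if ca >= tg else "TG_strand"
        calls.append(
            TelomereCall(GenomicInterval(contig, lo, hi, FORWARD), kind, score, strand_class)
        )
    return calls


def scan_contig(sequence: str, contig: str, config: PipelineConfig):
    return call_telomeres(
        sequence,
        contig,
        window=config.telomere_window,
        threshold=config.telomere_threshold,
        merge_gap=config.telomere_merge_gap,
        min_its_len=config.min_its_len,
        terminal_margin=config.terminal_margin,
        min_run=config.telomere_min_run,
    )


def mask_telomeres(sequence: str, calls) -> str:
    """Replace every telomere call (terminal and interstitial) with N."""
    arr = list(sequence)
    for call in calls:
        for i in range(call.interval.start, call.interval.end):
            arr[i] = "N"
    return "".join(arr)


def is_telomeric_tract(sequence: str, min_coverage: float = 0.8, min_run: int = 8) -> bool:
    """Classify a tract as telomeric (vs e.g. CA-rich repeat) by structural
    motif-run coverage rather than base composition."""
    if not sequence:
        return False
    cov_ca, cov_tg = motif_coverage(sequence, min_run)
    return float(np.maximum(cov_ca, cov_tg).mean()) >= min_coverage


def calls_to_records(calls):
    records = []
    for call in calls:
        records.append(
            AnnotationRecord(
                call.interval,
                "telomere_terminal" if call.kind == TERMINAL else "telomere_interstitial",
                {
                    "score": f"{call.score:.4f}",
                    "strand_class": call.strand_class,
                },
            )
        )
    return records


def calls_from_gff3(path):
    """Plug-in: read telomere calls produced by an external tool (GFF3 with
    telomere_terminal / telomere_interstitial feature types)."""
    calls = []
    for rec in _gff3.read_gff3(path):
        if rec.feature_class not in ("telomere_terminal", "telomere_interstitial"):
            continue
        kind = TERMINAL if rec.feature_class == "telomere_terminal" else INTERSTITIAL
        score = float(rec.attributes.get("score", "1.0"))
        strand_class = rec.attributes.get("strand_class", "CA_strand")
        calls.append(TelomereCall(rec.interval, kind, score, strand_class))
    return calls
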