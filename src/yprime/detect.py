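"""Y' element discovery: window self-repeats, high-confidence database,
hit trimming, and exhaustive detection across genomes.

The bottom-up procedure: (1) mask telomeric tracts, then self-align 25 kb
sliding windows (5 kb step) over the terminal 100 kb of every contig and
keep off-diagonal repeats of 4.0-9.5 kb at >= 90% identity; (2) promote a
repeat copy to the high-confidence database iff it matches a reference Y'
sequence and both of its ends are directly flanked by telomeric sequence
(terminal telomere or ITS); reference entries are appended; (3) map every
database entry back onto every contig with spliced alignment (internal
gaps up to 1 kb absorb 36-mer stretch length variation), trim spurious
terminal alignment blocks, reconcile overlapping hits from different
entries, and emit oriented, telomere-annotated elements of >= 1 kb.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

from .align import LocalHit, build_kmer_index, local_align, map_spliced
from .core import (
    GenomicInterval,
    InputError,
    PipelineConfig,
    FORWARD,
    REVERSE,
)
from .sequtil import revcomp
from .telomeres import mask_telomeres


@dataclass
class YPrimeElement:
    element_id: str
    strain: str
    interval: GenomicInterval  # orientation: '+' start is centromere-proximal
    sequence: str  # forward-strand slice of the contig
    telomere_flanked: str = "none"  # both | distal_only | proximal_only | none
    edge_truncated: bool = False
    source_hit: LocalHit | None = None
    cluster: str | None = None

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def oriented_sequence(self) -> str:
        """5'->3' from the centromere-proximal end toward the telomere."""
        if self.interval.orientation == REVERSE:
            return revcomp(self.sequence)
        return self.sequence

    @property
    def distal_end(self) -> int:
        """Contig coordinate of the telomere-proximal extremity."""
        return self.interval.end if self.interval.orientation == FORWARD else self.interval.start


@dataclass
class YPrimeDatabase:
    entries: list = field(default_factory=list)  # (id, sequence, provenance)
    version: str = ""

    def __post_init__(self) -> None:
        seqs = [seq for _, seq, _ in self.entries]
        if len(set(seqs)) != len(seqs):
            raise ValueError("database entries must have unique sequences")
        if not self.version:
            h = hashlib.sha256()
            for seq in sorted(seqs):
                h.update(seq.encode())
            self.version = h.hexdigest()[:12]

    def __len__(self) -> int:
        return len(self.entries)

    def sequences(self) -> dict:
        return {eid: seq for eid, seq, _ in self.entries}


# ---------------------------------------------------------------------------
# stage 1: window self-repeats


def _window_starts(span_start: int, span_end: int, window: int, step: int):
    if span_end - span_start <= window:
        return [(span_start, span_end)]
    starts = list(range(span_start, span_end - window + 1, step))
    windows = [(s, s + window) for s in starts]
    if windows[-1][1] < span_end:
        windows.append((span_end - window, span_end))
    return windows


def find_window_repeats(
    sequence: str,
    contig: str,
    config: PipelineConfig,
    telomere_calls=(),
):
    """Self-alignment repeats within sliding windows over both terminal
    spans of a contig (telomeres masked first).  Returns deduplicated hits
    with contig coordinates, restricted to aligned lengths within
    [repeat_len_min, repeat_len_max] at >= repeat_identity_min."""
    masked = mask_telomeres(sequence.upper(), telomere_calls)
    n = len(masked)
    span = config.terminal_span
    if 2 * span >= n:
        spans = [(0, n)]
    else:
        spans = [(0, span), (n - span, n)]
    windows = []
    for s0, s1 in spans:
        windows.extend(_window_starts(s0, s1, config.window_size, config.window_step))
    windows = sorted(set(windows))

    hits = []
    for w0, w1 in windows:
        wseq = masked[w0:w1]
        if len(wseq) < 2 * config.repeat_len_min:
            # window cannot host two repeat copies of the minimum length
            continue
        for h in local_align(
            wseq,
            wseq,
            min_identity=config.repeat_identity_min,
            max_gap=config.max_intra_element_gap,
            splice_min=30,
            self_comparison=True,
            query_id=contig,
            target_id=contig,
        ):
            length = max(h.query_span, h.target_span)
            if not config.repeat_len_min <= length <= config.repeat_len_max:
                continue
            hits.append(
                LocalHit(
                    query_id=contig,
                    target_id=contig,
                    query_start=h.query_start + w0,
                    query_end=h.query_end + w0,
                    target_start=h.target_start + w0,
                    target_end=h.target_end + w0,
                    strand=FORWARD,
                    target_len=n,
                    blocks=[(qs + w0, qe + w0, ts + w0, te + w0) for qs, qe, ts, te in h.blocks],
                    block_matches=list(h.block_matches),
                    percent_identity=h.percent_identity,
                    score=h.score,
                    n_matches=h.n_matches,
                    aligned_columns=h.aligned_columns,
                )
            )
    return _dedupe_lifted(hits)


def _span_close(a, b, tol: float = 0.95) -> bool:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    if ov == 0:
        return False
    return ov / (a[1] - a[0]) >= tol and ov / (b[1] - b[0]) >= tol


def _dedupe_lifted(hits):
    """Collapse hits rediscovered in overlapping windows (both spans nearly
    identical after coordinate lifting)."""
    kept = []
    for h in sorted(hits, key=lambda h: (-h.score, h.query_start, h.target_start)):
        a = ((h.query_start, h.query_end), (h.target_start, h.target_end))
        dup = False
        for other in kept:
            b = ((other.query_start, other.query_end), (other.target_start, other.target_end))
            if (_span_close(a[0], b[0]) and _span_close(a[1], b[1])) or (
                _span_close(a[0], b[1]) and _span_close(a[1], b[0])
            ):
                dup = True
                break
        if not dup:
            kept.append(h)
    return kept


def repeat_copy_intervals(hits, contig: str):
    """Each aligned span of a self-repeat hit is a candidate element copy."""
    spans = []
    for h in hits:
        spans.append((h.query_start, h.query_end))
        spans.append((h.target_start, h.target_end))
    kept = []
    for span in sorted(set(spans)):
        if not any(_span_close(span, other) for other in kept):
            kept.append(span)
    return [GenomicInterval(contig, s, e, FORWARD) for s, e in kept]


# ---------------------------------------------------------------------------
# stage 2: high-confidence database


def _flanked_side(pos: int, calls, side: str, gap_max: int) -> bool:
    """Is a telomere call directly adjacent to the given element end?"""
    for call in calls:
        if side == "left":
            gap = pos - call.interval.end
        else:
            gap = call.interval.start - pos
        if -20 <= gap <= gap_max:
            return True
    return False


def matches_reference(seq: str, reference: dict, config: PipelineConfig) -> bool:
    """Does the candidate match at least part of a known reference Y'
    (>= ref_match_min bp at >= ref_match_identity, either strand)?"""
    for ref_seq in reference.values():
        try:
            hits = map_spliced(
                seq,
                ref_seq,
                max_intra_element_gap=config.max_intra_element_gap,
                min_identity=config.ref_match_identity,
                query_id="candidate",
                target_id="reference",
            )
        except InputError:
            continue
        for h in hits:
            if min(h.query_span, h.target_span) >= config.ref_match_min:
                return True
    return False


def build_high_confidence_db(
    candidates_by_contig: dict,
    genomes: dict,
    reference: dict,
    telomere_calls: dict,
    config: PipelineConfig,
) -> YPrimeDatabase:
    """Promote repeat copies to the database iff they match a reference Y'
    and are directly flanked by telomeric sequence on both sides; append
    the reference entries themselves; collapse duplicates.

    ``candidates_by_contig``: {(strain, contig): [GenomicInterval, ...]};
    ``telomere_calls``: {(strain, contig): [TelomereCall, ...]}.
    """
    if not reference:
        raise InputError("reference Y' FASTA is empty")
    entries = []
    seen = set()
    for key in sorted(candidates_by_contig):
        strain, contig = key
        seq = genomes[strain][contig]
        calls = telomere_calls.get(key, [])
        for iv in sorted(candidates_by_contig[key]):
            if not (
                _flanked_side(iv.start, calls, "left", config.flank_gap_max)
                and _flanked_side(iv.end, calls, "right", config.flank_gap_max)
            ):
                continue
            sub = seq[iv.start : iv.end]
            if not config.repeat_len_min <= len(sub) <= config.repeat_len_max + 2000:
                continue
            if not matches_reference(sub, reference, config):
                continue
            canon = min(sub, revcomp(sub))
            if canon in seen:
                continue
            seen.add(canon)
            entries.append(
                (f"hc{len(entries):04d}.{strain}.{contig}", sub, "window_repeat")
            )
    for name in sorted(reference):
        ref_seq = reference[name].upper()
        canon = min(ref_seq, revcomp(ref_seq))
        if canon in seen:
            continue
        seen.add(canon)
        entries.append((name, ref_seq, "reference_seed"))
    return YPrimeDatabase(entries)


# ---------------------------------------------------------------------------
# stage 3: hit trimming and element detection


def trim_hit_blocks(
    hit: LocalHit, block_trim_len: int = 20, block_trim_gap: int = 100
):
    """Iteratively drop extremal alignment blocks smaller than
    ``block_trim_len`` whose gap to the adjacent block exceeds
    ``block_trim_gap`` (overextension artifacts); returns the trimmed hit
    or None when nothing is left."""
    if not hit.blocks:
        return None
    blocks = list(hit.blocks)
    matches = list(hit.block_matches)

    def gap(i: int, j: int) -> int:
        qgap = blocks[j][0] - blocks[i][1]
        tgap = blocks[j][2] - blocks[i][3]
        return max(qgap, tgap)

    changed = True
    while changed and blocks:
        changed = False
        if len(blocks) >= 2:
            first_len = blocks[0][1] - blocks[0][0]
            if first_len < block_trim_len and gap(0, 1) > block_trim_gap:
                blocks.pop(0)
                matches.pop(0)
                changed = True
        if len(blocks) >= 2:
            last_len = blocks[-1][1] - blocks[-1][0]
            if last_len < block_trim_len and gap(-2, -1) > block_trim_gap:
                blocks.pop()
                matches.pop()
                changed = True
        if len(blocks) == 1:
            only_len = blocks[0][1] - blocks[0][0]
            if only_len < block_trim_len:
                blocks.pop()
                matches.pop()
                changed = True
    if not blocks:
        return None
    total_cols = sum(b[1] - b[0] for b in blocks)
    total_matches = sum(matches)
    n_gaps = len(blocks) - 1
    score = total_matches * 1 + (total_cols - total_matches) * (-2) - 6 * n_gaps
    return LocalHit(
        query_id=hit.query_id,
        target_id=hit.target_id,
        query_start=blocks[0][0],
        query_end=blocks[-1][1],
        target_start=blocks[0][2],
        target_end=blocks[-1][3],
        strand=hit.strand,
        target_len=hit.target_len,
        blocks=blocks,
        block_matches=matches,
        percent_identity=100.0 * total_matches / total_cols if total_cols else 0.0,
        score=float(score),
        n_matches=total_matches,
        aligned_columns=hit.aligned_columns,
    )


def _set_flanking(element: YPrimeElement, calls, gap_max: int) -> None:
    iv = element.interval
    left = _flanked_side(iv.start, calls, "left", gap_max)
    right = _flanked_side(iv.end, calls, "right", gap_max)
    if iv.orientation == FORWARD:
        distal, proximal = right, left
    else:
        distal, proximal = left, right
    if distal and proximal:
        element.telomere_flanked = "both"
    elif distal:
        element.telomere_flanked = "distal_only"
    elif proximal:
        element.telomere_flanked = "proximal_only"
    else:
        element.telomere_flanked = "none"


def detect_elements(
    db: YPrimeDatabase,
    genomes: dict,
    telomere_calls: dict,
    config: PipelineConfig,
    funnel: dict | None = None,
):
    """Exhaustive element detection: spliced-map every database entry onto
    every contig, trim hits, reconcile overlaps (reciprocal > 50% keeps the
    best score), filter short elements, flag edge truncation and telomere
    flanking, and normalize orientation."""
    if not len(db):
        raise InputError("Y' database is empty")
    k = 15
    elements = []
    counts = {
        "raw_hits": 0,
        "trimmed_hits": 0,
        "merged": 0,
        "len_ge_min": 0,
        "len_gt_core": 0,
        "edge_truncated": 0,
        "kept": 0,
    }
    for strain in sorted(genomes):
        for contig in sorted(genomes[strain]):
            seq = genomes[strain][contig].upper()
            indexes = (build_kmer_index(seq, k), build_kmer_index(revcomp(seq), k))
            calls = telomere_calls.get((strain, contig), [])
            candidates = []
            for entry_id, entry_seq, _prov in db.entries:
                hits = map_spliced(
                    entry_seq,
                    seq,
                    max_intra_element_gap=config.max_intra_element_gap,
                    min_identity=config.repeat_identity_min,
                    k=k,
                    query_id=entry_id,
                    target_id=contig,
                    target_indexes=indexes,
                )
                counts["raw_hits"] += len(hits)
                for h in hits:
                    trimmed = trim_hit_blocks(
                        h, config.block_trim_len, config.block_trim_gap
                    )
                    if trimmed is not None:
                        counts["trimmed_hits"] += 1
                        candidates.append((entry_id, trimmed))
            # reconcile overlapping hits from different database entries
            candidates.sort(
                key=lambda c: (-c[1].score, c[1].forward_interval().start, c[0])
            )
            accepted = []
            for entry_id, hit in candidates:
                iv = hit.forward_interval()
                if any(iv.reciprocal_overlap(other[1]) > 0.5 for other in accepted):
                    counts["merged"] += 1
                    continue
                accepted.append((entry_id, iv, hit))
            # clip residual partial overlaps against higher-scoring hits
            final = []
            for entry_id, iv, hit in accepted:
                start, end = iv.start, iv.end
                for _eid, other_iv, _h in final:
                    ov = max(0, min(end, other_iv.end) - max(start, other_iv.start))
                    if ov > 0:
                        if start < other_iv.start:
                            end = min(end, other_iv.start)
                        else:
                            start = max(start, other_iv.end)
                    if end - start <= 0:
                        break
                if end - start <= 0:
                    continue
                final.append(
                    (entry_id, GenomicInterval(iv.contig, start, end, iv.orientation), hit)
                )
            final.sort(key=lambda c: c[1].start)
            n = len(seq)
            for i, (entry_id, iv, hit) in enumerate(final):
                if iv.length < config.element_len_min:
                    continue
                counts["len_ge_min"] += 1
                if iv.length > config.element_len_core:
                    counts["len_gt_core"] += 1
                element = YPrimeElement(
                    element_id=f"{strain}.{contig}.{i:03d}",
                    strain=strain,
                    interval=iv,
                    sequence=seq[iv.start : iv.end],
                    source_hit=hit,
                )
                element.edge_truncated = (
                    iv.start <= config.edge_margin or iv.end >= n - config.edge_margin
                )
                if element.edge_truncated:
                    counts["edge_truncated"] += 1
                _set_flanking(element, calls, config.flank_gap_max)
                elements.append(element)
    elements = [e for e in elements]
    counts["kept"] = sum(
        1 for e in elements if not e.edge_truncated
    )
    if funnel is not None:
        funnel.update(counts)
    return elements
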