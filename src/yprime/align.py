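"""Alignment primitives: seeded gapped local alignment and MSA.

Two contracts are provided:

* :func:`local_align` / :func:`map_spliced` -- exact k-mer anchors, collinear
  chaining grouped by diagonal bands, then gapped extension.  Short candidate
  windows get an exact affine-gap local alignment (Gotoh); long ones use an
  edlib global alignment over the padded chained span followed by extraction
  of the maximum-scoring sub-path, which trims overextension into unrelated
  flanks.  Scoring: match +1, mismatch -2, gap open -4, gap extend -1.
* :func:`build_msa` -- multiple sequence alignment.  The default backend is
  the MAFFT executable (deterministic, single-threaded invocation); a
  deterministic internal progressive aligner (pairwise-identity guide order,
  profile Needleman-Wunsch) is used when MAFFT is unavailable or requested
  explicitly.

Spliced mapping tolerates internal gaps up to ``max_gap`` (accommodating
36-mer stretch length differences between query and target); gap runs longer
than ``splice_min`` are treated as splices and excluded from the identity
denominator.
"""
from __future__ import annotations

import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np

from . import _dp
from .core import GenomicInterval, InputError, FORWARD, REVERSE
from .sequtil import encode, revcomp

MATCH = 1
MISMATCH = -2
GAP_OPEN = -4
GAP_EXTEND = -1
SPLICE_PENALTY = -8
SPLICE_MIN = 30  # gap runs longer than this are splices, not alignment gaps
SW_MAX_SPAN = 1500  # exact local DP below this span; edlib path above
PAD = 120  # padding around the chained span before gapped extension


@dataclass
class LocalHit:
    """A gapped local alignment between a query and a (stranded) target.

    Coordinates are on the aligned strand: for ``strand == '-'`` they refer
    to the reverse complement of the target; :meth:`forward_interval`
    converts to forward-strand contig coordinates.
    """

    query_id: str
    target_id: str
    query_start: int
    query_end: int
    target_start: int
    target_end: int
    strand: str
    target_len: int
    blocks: list = field(default_factory=list)  # (qs, qe, ts, te) gap-free
    block_matches: list = field(default_factory=list)
    percent_identity: float = 0.0
    score: float = 0.0
    n_matches: int = 0
    aligned_columns: int = 0

    @property
    def query_span(self) -> int:
        return self.query_end - self.query_start

    @property
    def target_span(self) -> int:
        return self.target_end - self.target_start

    @property
    def length(self) -> int:
        return max(self.query_span, self.target_span)

    def forward_interval(self) -> GenomicInterval:
        if self.strand == FORWARD:
            return GenomicInterval(
                self.target_id, self.target_start, self.target_end, FORWARD
            )
        return GenomicInterval(
            self.target_id,
            self.target_len - self.target_end,
            self.target_len - self.target_start,
            REVERSE,
        )


# ---------------------------------------------------------------------------
# seeding and chaining


def build_kmer_index(target: str, k: int) -> dict:
    """Position index of the target's k-mers (skipping N-containing ones);
    reusable across queries mapped onto the same target."""
    index: dict = {}
    for i in range(len(target) - k + 1):
        kmer = target[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _kmer_anchors(query: str, target: str, k: int, same: bool, index: dict | None = None):
    if index is None:
        index = build_kmer_index(target, k)
    anchors = []
    for i in range(len(query) - k + 1):
        kmer = query[i : i + k]
        positions = index.get(kmer)
        if not positions:
            continue
        if len(positions) > 200:  # low-complexity k-mer, skip
            continue
        for j in positions:
            if same and abs(i - j) < 200:
                continue
            anchors.append((i, j))
    return anchors


def _lis_chain(group):
    """Maximum collinear subset of anchors: sort by (q, t) and take the
    longest strictly-increasing subsequence in t (patience algorithm).
    Maximizing anchor count keeps the true diagonal path through tandem
    repeats, where greedy first-fit chaining can jump to the wrong unit."""
    import bisect

    group = sorted(group)
    ts = [t for _q, t in group]
    tails: list = []  # t values of best-known subsequence ends
    tails_idx: list = []
    parent = [-1] * len(group)
    for i, t in enumerate(ts):
        pos = bisect.bisect_left(tails, t)
        if pos == len(tails):
            tails.append(t)
            tails_idx.append(i)
        else:
            tails[pos] = t
            tails_idx[pos] = i
        parent[i] = tails_idx[pos - 1] if pos > 0 else -1
    out = []
    i = tails_idx[-1] if tails_idx else -1
    while i != -1:
        out.append(group[i])
        i = parent[i]
    return out[::-1]


def _chain_anchors(anchors, k: int, band: int, max_chain_gap: int):
    """Group anchors by diagonal band, then chain monotonically by position."""
    if not anchors:
        return []
    anchors = sorted(anchors, key=lambda a: (a[1] - a[0], a[0]))
    groups = []
    cur = [anchors[0]]
    for a in anchors[1:]:
        if (a[1] - a[0]) - (cur[-1][1] - cur[-1][0]) > band:
            groups.append(cur)
            cur = [a]
        else:
            cur.append(a)
    groups.append(cur)

    chains = []
    for group in groups:
        selected = _lis_chain(group)
        chain = []
        last_q = last_t = -(10**9)
        for q, t in selected:
            if chain and q - last_q > max_chain_gap and t - last_t > max_chain_gap:
                chains.append(chain)
                chain = []
            chain.append((q, t))
            last_q, last_t = q, t
        if chain:
            chains.append(chain)
    spans = []
    for chain in chains:
        qs = chain[0][0]
        qe = chain[-1][0] + k
        ts = chain[0][1]
        te = chain[-1][1] + k
        spans.append((qs, qe, ts, te, chain))
    return spans


# ---------------------------------------------------------------------------
# gapped extension

_CIG_NUM = "0123456789"


def _parse_cigar(cigar: str):
    ops = []
    num = 0
    for ch in cigar:
        if ch in _CIG_NUM:
            num = num * 10 + ord(ch) - 48
        else:
            ops.append((ch, num))
            num = 0
    return ops


def _ops_from_gotoh(q_arr, t_arr, qs, ts, ops_codes):
    """Convert gotoh op codes to (char, length) runs with '='/'X' split."""
    runs = []
    qi, ti = qs, ts
    for code in ops_codes:
        if code == _dp.OP_DIAG:
            ch = "=" if (q_arr[qi] == t_arr[ti] and q_arr[qi] < 4) else "X"
            qi += 1
            ti += 1
        elif code == _dp.OP_UP:
            ch = "D"  # consumes query, gap in target
            qi += 1
        else:
            ch = "I"  # consumes target, gap in query
            ti += 1
        if runs and runs[-1][0] == ch:
            runs[-1][1] += 1
        else:
            runs.append([ch, 1])
    return [(ch, ln) for ch, ln in runs]


def _swap_edlib_runs(cigar: str):
    runs = _parse_cigar(cigar)
    # edlib: 'D' consumes target, 'I' consumes query -> swap to our
    # convention ('D' consumes query)
    return [("D" if ch == "I" else "I" if ch == "D" else ch, ln) for ch, ln in runs]


def _thin_anchors(anchors, k: int, spacing: int = 50):
    sel = []
    for q, t in anchors:
        if not sel or (q >= sel[-1][0] + spacing and t >= sel[-1][1] + spacing):
            sel.append((q, t))
    return sel


def _piecewise_runs(query: str, target: str, anchors, k: int):
    """Anchor-guided spliced alignment: exact k-mer anchors pin the path;
    inter-anchor segments are aligned globally, the head/tail segments with
    a free target end.  Avoids the unit-cost pathology where a long
    repeat-length difference is absorbed as spread mismatches instead of a
    clean gap.  Returns (runs, query_start=0 base, target_start)."""
    sel = _thin_anchors(anchors, k)
    runs = []
    q0, t0 = sel[0]
    t_start = t0
    # head: query[0:q0] must end exactly at t0; free target start
    if q0 > 0:
        t_lo = max(0, t0 - q0 - PAD)
        rq = query[:q0][::-1]
        rt = target[t_lo:t0][::-1]
        if rt:
            res = edlib.align(rq, rt, mode="SHW", task="path")
            head = _swap_edlib_runs(res["cigar"])[::-1]
            consumed_t = sum(ln for ch, ln in head if ch in ("=", "X", "I", "M"))
            t_start = t0 - consumed_t
            runs.extend(head)
        else:
            runs.append(("D", q0))
    prev_q, prev_t = q0, t0
    for qa, ta in sel[1:] + [(None, None)]:
        runs.append(("=", k))  # the anchor itself (exact match)
        if qa is None:
            break
        qseg = query[prev_q + k : qa]
        tseg = target[prev_t + k : ta]
        if qseg and tseg:
            res = edlib.align(qseg, tseg, mode="NW", task="path")
            runs.extend(_swap_edlib_runs(res["cigar"]))
        elif qseg:
            runs.append(("D", len(qseg)))
        elif tseg:
            runs.append(("I", len(tseg)))
        prev_q, prev_t = qa, ta
    # tail: query[prev_q+k:] from prev_t+k onward; free target end
    qtail = query[prev_q + k :]
    if qtail:
        t_hi = min(len(target), prev_t + k + len(qtail) + PAD)
        ttail = target[prev_t + k : t_hi]
        if ttail:
            res = edlib.align(qtail, ttail, mode="SHW", task="path")
            runs.extend(_swap_edlib_runs(res["cigar"]))
        else:
            runs.append(("D", len(qtail)))
    # merge adjacent runs of the same op
    merged = []
    for ch, ln in runs:
        if merged and merged[-1][0] == ch:
            merged[-1] = (ch, merged[-1][1] + ln)
        else:
            merged.append((ch, ln))
    return merged, t_start


def _split_masked_matches(runs, query: str, q0: int):
    """edlib counts N==N as a match; reclassify '=' columns over masked
    (N) query bases as mismatches so alignments cannot extend through
    masked telomeric tracts."""
    if "N" not in query:
        return runs
    out = []
    q = q0
    for ch, ln in runs:
        if ch == "=":
            sub = query[q : q + ln]
            if "N" in sub:
                for base in sub:
                    c = "X" if base == "N" else "="
                    if out and out[-1][0] == c:
                        out[-1] = (c, out[-1][1] + 1)
                    else:
                        out.append((c, 1))
            else:
                out.append((ch, ln))
            q += ln
        else:
            out.append((ch, ln))
            if ch in ("D", "X"):
                q += ln
            elif ch == "M":
                q += ln
    return out


def _coalesce_runs(runs, splice_min: int, min_block: int = 12):
    """Merge zones of gaps interleaved with tiny aligned runs into one
    mismatch run plus one net gap (BLAT-like block semantics).  Applied only
    when splices are enabled; keeps long gaps as single blocks boundaries."""
    out = []
    zone = []  # buffered runs belonging to a candidate gap zone

    def flush():
        if not zone:
            return
        dq = sum(ln for ch, ln in zone if ch in ("=", "X", "D"))
        dt = sum(ln for ch, ln in zone if ch in ("=", "X", "I"))
        gap = abs(dq - dt)
        total_gap = sum(ln for ch, ln in zone if ch in ("I", "D"))
        if total_gap >= splice_min and len(zone) > 1:
            m = min(dq, dt)
            if m:
                out.append(("X", m))
            if gap:
                out.append(("D" if dq > dt else "I", gap))
        else:
            out.extend(zone)
        zone.clear()

    for ch, ln in runs:
        if ch in ("I", "D") or (ch in ("=", "X") and ln < min_block):
            zone.append((ch, ln))
        else:
            flush()
            out.append((ch, ln))
    flush()
    return out


def _units_from_runs(runs, q0: int, t0: int, max_gap: int, splice_min: int):
    """Per-run scoring units: (score, matches, qlen, tlen, kind, q, t).

    kind: 0 aligned, 1 small gap, 2 splice gap, 3 hard break.
    Query consumed by 'D', target consumed by 'I' (edlib convention where
    the first sequence is the query).
    """
    if splice_min <= max_gap:
        runs = _coalesce_runs(runs, splice_min)
    units = []
    q, t = q0, t0
    for ch, ln in runs:
        if ch == "=":
            units.append((MATCH * ln, ln, ln, ln, 0, q, t))
            q += ln
            t += ln
        elif ch == "X":
            units.append((MISMATCH * ln, 0, ln, ln, 0, q, t))
            q += ln
            t += ln
        elif ch in ("D", "I"):
            dq = ln if ch == "D" else 0
            dt = ln if ch == "I" else 0
            if ln > max_gap:
                kind = 3
                score = 0
            elif ln > splice_min:
                kind = 2
                score = SPLICE_PENALTY
            else:
                kind = 1
                score = GAP_OPEN + GAP_EXTEND * ln
            units.append((score, 0, dq, dt, kind, q, t))
            q += dq
            t += dt
        else:  # 'M' (shouldn't occur with nice cigars) -- treat as aligned
            units.append((0, 0, ln, ln, 0, q, t))
            q += ln
            t += ln
    return units


def _best_segments(units):
    """Split at hard breaks; within each piece return the max-scoring
    contiguous unit run (Kadane)."""
    segments = []
    piece = []
    for u in units:
        if u[4] == 3:
            if piece:
                segments.append(piece)
            piece = []
        else:
            piece.append(u)
    if piece:
        segments.append(piece)

    out = []
    for piece in segments:
        best, best_lo, best_hi = 0, 0, 0
        run, lo = 0, 0
        for idx, u in enumerate(piece):
            if run <= 0:
                run, lo = u[0], idx
            else:
                run += u[0]
            if run > best:
                best, best_lo, best_hi = run, lo, idx
        if best > 0:
            out.append((piece[best_lo : best_hi + 1], best))
    return out


def _hit_from_units(units, score, query_id, target_id, strand, target_len):
    blocks = []
    block_matches = []
    matches = 0
    aligned = 0
    splice_cols = 0
    cur = None  # [qs, qe, ts, te, matches]
    for u in units:
        sc, mt, dq, dt, kind, q, t = u
        if kind == 0:
            if cur is None:
                cur = [q, q + dq, t, t + dt, mt]
            else:
                cur[1] += dq
                cur[3] += dt
                cur[4] += mt
            matches += mt
            aligned += dq
        else:
            if cur is not None:
                blocks.append((cur[0], cur[1], cur[2], cur[3]))
                block_matches.append(cur[4])
                cur = None
            gap = max(dq, dt)
            aligned += gap
            if kind == 2:
                splice_cols += gap
    if cur is not None:
        blocks.append((cur[0], cur[1], cur[2], cur[3]))
        block_matches.append(cur[4])
    if not blocks:
        return None
    denom = aligned - splice_cols
    identity = 100.0 * matches / denom if denom > 0 else 0.0
    return LocalHit(
        query_id=query_id,
        target_id=target_id,
        query_start=blocks[0][0],
        query_end=blocks[-1][1],
        target_start=blocks[0][2],
        target_end=blocks[-1][3],
        strand=strand,
        target_len=target_len,
        blocks=blocks,
        block_matches=block_matches,
        percent_identity=identity,
        score=float(score),
        n_matches=matches,
        aligned_columns=aligned,
    )


def _align_span(
    query: str,
    target: str,
    span,
    *,
    max_gap: int,
    splice_min: int,
    query_id: str,
    target_id: str,
    strand: str,
    infix: bool = False,
    k: int = 15,
):
    qs, qe, ts, te, chain = span
    if infix:
        runs, t0 = _piecewise_runs(query, target, chain, k=k)
        runs = _split_masked_matches(runs, query, 0)
        units = _units_from_runs(runs, 0, t0, max_gap, splice_min)
    else:
        qs = max(0, qs - PAD)
        qe = min(len(query), qe + PAD)
        ts = max(0, ts - PAD)
        te = min(len(target), te + PAD)
        qsub = query[qs:qe]
        tsub = target[ts:te]
        if qe - qs <= SW_MAX_SPAN and te - ts <= SW_MAX_SPAN:
            q_arr = encode(qsub)
            t_arr = encode(tsub)
            score, a0, _a1, b0, _b1, ops = _dp.gotoh_local(
                q_arr, t_arr, MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND
            )
            if score <= 0 or len(ops) == 0:
                return []
            runs = _ops_from_gotoh(q_arr, t_arr, a0, b0, ops)
            units = _units_from_runs(runs, qs + a0, ts + b0, max_gap, splice_min)
        else:
            res = edlib.align(qsub, tsub, task="path", mode="NW")
            runs = _swap_edlib_runs(res["cigar"])
            runs = _split_masked_matches(runs, query, qs)
            units = _units_from_runs(runs, qs, ts, max_gap, splice_min)
    hits = []
    for seg_units, seg_score in _best_segments(units):
        hit = _hit_from_units(
            seg_units, seg_score, query_id, target_id, strand, len(target)
        )
        if hit is not None:
            hits.append(hit)
    return hits


def _dedupe(hits):
    """Drop exact duplicates and hits contained in a better hit."""
    seen = set()
    unique = []
    for h in sorted(hits, key=lambda h: (-h.score, h.target_start, h.query_start)):
        key = (h.query_start, h.query_end, h.target_start, h.target_end, h.strand)
        if key in seen:
            continue
        seen.add(key)
        contained = False
        for other in unique:
            if (
                other.strand == h.strand
                and other.query_start <= h.query_start
                and h.query_end <= other.query_end
                and other.target_start <= h.target_start
                and h.target_end <= other.target_end
            ):
                contained = True
                break
        if not contained:
            unique.append(h)
    return unique


def local_align(
    query: str,
    target: str,
    *,
    min_identity: float = 90.0,
    max_gap: int = 50,
    k: int = 15,
    query_id: str = "query",
    target_id: str = "target",
    self_comparison: bool = False,
    splice_min: int = 0,
):
    """All maximal seeded local alignments at ``>= min_identity`` whose
    internal gaps are each ``<= max_gap``.

    For a self comparison (``query is target``) the trivial identity
    diagonal is excluded: hits whose query and target spans overlap
    reciprocally by more than 50% are dropped.  When ``splice_min`` is set,
    gap runs longer than it are scored as splices and excluded from the
    identity denominator (used for stretch-length variation between repeat
    copies).
    """
    if not query or not target:
        raise InputError("local_align requires non-empty sequences")
    query = query.upper()
    target = target.upper()
    anchors = _kmer_anchors(query, target, k, same=self_comparison)
    spans = _chain_anchors(anchors, k, band=max(2 * max_gap, 100), max_chain_gap=max(500, 4 * max_gap))
    hits = []
    for span in spans:
        hits.extend(
            _align_span(
                query,
                target,
                span,
                max_gap=max_gap,
                splice_min=splice_min if splice_min > 0 else max_gap + 1,
                query_id=query_id,
                target_id=target_id,
                strand=FORWARD,
            )
        )
    hits = [h for h in hits if h.percent_identity >= min_identity]
    if self_comparison:
        kept = []
        for h in hits:
            a = (h.query_start, h.query_end)
            b = (h.target_start, h.target_end)
            ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
            rec = min(
                ov / max(1, a[1] - a[0]),
                ov / max(1, b[1] - b[0]),
            )
            if rec <= 0.5:
                kept.append(h)
        hits = kept
    return _dedupe(hits)


def map_spliced(
    query: str,
    target: str,
    *,
    max_intra_element_gap: int = 1000,
    min_identity: float = 90.0,
    k: int = 15,
    query_id: str = "query",
    target_id: str = "target",
    both_strands: bool = True,
    min_query_len: int = 500,
    target_indexes: tuple | None = None,
):
    """Map a query onto a contig allowing internal target/query gaps up to
    ``max_intra_element_gap`` (36-mer stretch length variation); hits below
    ``min_identity`` (splice gaps excluded from the denominator) are dropped.
    """
    if not query or not target:
        raise InputError("map_spliced requires non-empty sequences")
    if len(query) < min_query_len:
        raise InputError(
            f"spliced mapping requires query length >= {min_query_len}, got {len(query)}"
        )
    query = query.upper()
    strands = [(FORWARD, target.upper(), 0)]
    if both_strands:
        strands.append((REVERSE, revcomp(target.upper()), 1))
    hits = []
    for strand, tseq, sidx in strands:
        index = target_indexes[sidx] if target_indexes else None
        anchors = _kmer_anchors(query, tseq, k, same=False, index=index)
        spans = _chain_anchors(
            anchors, k, band=max_intra_element_gap, max_chain_gap=max_intra_element_gap
        )
        for span in spans:
            for h in _align_span(
                query,
                tseq,
                span,
                max_gap=max_intra_element_gap,
                splice_min=SPLICE_MIN,
                query_id=query_id,
                target_id=target_id,
                strand=strand,
                infix=True,
                k=k,
            ):
                if h.percent_identity >= min_identity:
                    hits.append(h)
    return _dedupe(hits)


# ---------------------------------------------------------------------------
# multiple sequence alignment


@dataclass
class MsaResult:
    ids: list
    rows: list

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.ids):
            raise ValueError("ids/rows length mismatch")
        if self.rows:
            width = len(self.rows[0])
            if any(len(r) != width for r in self.rows):
                raise ValueError("MSA rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def ungapped(self) -> list:
        return [r.replace("-", "") for r in self.rows]


def _mafft_available() -> bool:
    return shutil.which("mafft") is not None


def _msa_mafft(seqs, auto: bool = False):
    # FFT-NS-2 (two-round progressive) by default: deterministic and fast;
    # '--auto' mode available as the mafft-auto backend
    args = ["--auto"] if auto else ["--retree", "2", "--maxiterate", "0"]
    with tempfile.TemporaryDirectory() as tmp:
        fasta = Path(tmp) / "in.fa"
        with open(fasta, "w") as fh:
            for i, s in enumerate(seqs):
                fh.write(f">s{i}\n{s}\n")
        proc = subprocess.run(
            ["mafft", *args, "--quiet", "--thread", "1", str(fasta)],
            capture_output=True,
            text=True,
            check=True,
        )
    rows = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            rows[name] = []
        elif name is not None:
            rows[name].append(line.strip())
    return ["".join(rows[f"s{i}"]).upper() for i in range(len(seqs))]


def _profile(rows):
    width = len(rows[0])
    prof = np.zeros((width, 4), dtype=np.float32)
    for r in rows:
        codes = encode(r.replace("-", "\0").replace("\0", "N"))
        # encode maps '-'->4 via the N fallback; count only ACGT
        for base in range(4):
            prof[:, base] += codes == base
    prof /= len(rows)
    return prof


def _merge_rows(rows_a, rows_b, ops):
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == _dp.OP_DIAG:
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ia += 1
            ib += 1
        elif op == _dp.OP_UP:
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            for r in out_b:
                r.append("-")
            ia += 1
        else:
            for r in out_a:
                r.append("-")
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ib += 1
    return ["".join(r) for r in out_a] + ["".join(r) for r in out_b]


def _msa_internal(seqs):
    n = len(seqs)
    if n == 1:
        return list(seqs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = edlib.align(seqs[i], seqs[j], task="distance")["editDistance"]
            dist[i, j] = dist[j, i] = d / max(len(seqs[i]), len(seqs[j]))
    clusters = [([i], [seqs[i]]) for i in range(n)]
    cdist = dist.copy()
    active = list(range(n))
    merged = {}
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                i, j = active[ai], active[bi]
                d = cdist[i, j]
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        members = clusters[i][0] + clusters[j][0]
        pa = _profile(clusters[i][1])
        pb = _profile(clusters[j][1])
        ops = _dp.profile_nw(pa, pb, -1.5)
        rows = _merge_rows(clusters[i][1], clusters[j][1], ops)
        clusters[i] = (members, rows)
        active.remove(j)
        # average-linkage update
        for kdx in active:
            if kdx == i:
                continue
            total = 0.0
            for a in members:
                for b in clusters[kdx][0]:
                    total += dist[a, b]
            cdist[i, kdx] = cdist[kdx, i] = total / (
                len(members) * len(clusters[kdx][0])
            )
    members, rows = clusters[active[0]]
    order = np.argsort(members)
    return [rows[int(i)] for i in order]


def build_msa(seqs, ids=None, backend: str = "auto") -> MsaResult:
    """Align two or more sequences; gap removal reproduces inputs exactly."""
    seqs = [s.upper() for s in seqs]
    if len(seqs) < 2:
        raise InputError("build_msa requires at least 2 sequences")
    if any(not s for s in seqs):
        raise InputError("build_msa requires non-empty sequences")
    if ids is None:
        ids = [f"seq{i}" for i in range(len(seqs))]
    if len(ids) != len(seqs):
        raise InputError("ids/sequences length mismatch")
    if backend == "auto":
        backend = "mafft" if _mafft_available() else "internal"
    if backend == "mafft":
        rows = _msa_mafft(seqs)
    elif backend == "mafft-auto":
        rows = _msa_mafft(seqs, auto=True)
    elif backend == "internal":
        rows = _msa_internal(seqs)
    else:
        raise InputError(f"unknown MSA backend {backend!r}")
    result = MsaResult(list(ids), rows)
    for row, seq in zip(result.rows, seqs):
        if row.replace("-", "") != seq:
            raise RuntimeError("MSA row does not reproduce its input sequence")
    return result
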