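"""Minimal lossless GFF3 writer/reader for this package's annotation records.

Internally everything is 0-based half-open; the GFF3 column convention is
1-based inclusive, so ``start + 1`` is written and subtracted on read.
Attribute keys/values are percent-escaped so arbitrary strings round-trip.
"""
from __future__ import annotations

from urllib.parse import quote, unquote

from .core import AnnotationRecord, GenomicInterval

_SAFE = "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789.:^*$@!+_?|-"

SOURCE = "yprime"


def _esc(s: str) -> str:
    return quote(s, safe=_SAFE)


def format_record(rec: AnnotationRecord) -> str:
    iv = rec.interval
    attrs = ";".join(f"{_esc(k)}={_esc(v)}" for k, v in rec.attributes.items()) or "."
    score = rec.attributes.get("score", ".")
    return "\t".join(
        [
            iv.contig,
            SOURCE,
            rec.feature_class,
            str(iv.start + 1),
            str(iv.end),
            score,
            iv.orientation,
            ".",
            attrs,
        ]
    )


def write_gff3(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(format_record(rec) + "\n")


def parse_line(line: str) -> AnnotationRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) != 9:
        raise ValueError(f"malformed GFF3 line: {line!r}")
    contig, _source, ftype, start, end, _score, strand, _frame, attrs = cols
    interval = GenomicInterval(contig, int(start) - 1, int(end), strand)
    attributes = {}
    if attrs != ".":
        for pair in attrs.split(";"):
            if not pair:
                continue
            key, _, value = pair.partition("=")
            attributes[unquote(key)] = unquote(value)
    return AnnotationRecord(interval, ftype, attributes)


def read_gff3(path):
    records = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            records.append(parse_line(line))
    return records
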