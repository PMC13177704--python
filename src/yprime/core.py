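"""Coordinate conventions, annotation records and pipeline configuration.

All coordinates are 0-based, half-open on the forward strand of the contig.
GFF3 emission (see :mod:`yprime.gff3`) converts to 1-based inclusive.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields
from typing import Optional

FORWARD = "+"
REVERSE = "-"

#: Closed feature vocabulary used throughout the package.
FEATURE_CLASSES = frozenset(
    {
        "telomere_terminal",
        "telomere_interstitial",
        "yprime",
        "stretch_36mer",
        "stretch_ca",
        "orf",
        "x_element_placeholder",
    }
)


class InputError(ValueError):
    """Raised when user-facing inputs violate a documented precondition."""


class GenerationError(RuntimeError):
    """Raised when the simulator cannot host the requested features."""


class DegenerateInputError(ValueError):
    """Raised when a computation is undefined on the given data (e.g. all
    pairwise distances zero, so silhouette scores do not exist)."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A contig-anchored span, 0-based half-open, with orientation.

    ``orientation`` is the strand the feature lives on; coordinates are
    always expressed on the forward strand regardless of orientation.
    """

    contig: str
    start: int
    end: int
    orientation: str = FORWARD

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start for interval on {self.contig}")
        if self.end <= self.start:
            raise ValueError(
                f"empty or inverted interval {self.contig}:{self.start}-{self.end}"
            )
        if self.orientation not in (FORWARD, REVERSE):
            raise ValueError(f"orientation must be '+' or '-', got {self.orientation!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def reciprocal_overlap(self, other: "GenomicInterval") -> float:
        """min(overlap/len(self), overlap/len(other)); 0 across contigs."""
        ov = self.overlap(other)
        if ov == 0:
            return 0.0
        return min(ov / self.length, ov / other.length)

    def distance(self, other: "GenomicInterval") -> int:
        """Gap between the two intervals; 0 when they touch or overlap."""
        if self.contig != other.contig:
            raise ValueError("distance undefined across contigs")
        if self.overlap(other) > 0:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


@dataclass
class AnnotationRecord:
    """A typed feature with free-form string attributes.

    Attributes round-trip losslessly through GFF3 (percent-escaping).
    """

    interval: GenomicInterval
    feature_class: str
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature_class {self.feature_class!r}")
        self.attributes = {str(k): str(v) for k, v in self.attributes.items()}


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults.

    Defaults follow the published procedure where it states a value
    (window sizes, repeat length/identity bounds, block trimming, peak
    calling, ORF floor, silhouette range) and are otherwise calibrated
    choices documented in docs/methods.md.
    """

    # window self-repeat discovery
    window_size: int = 25000
    window_step: int = 5000
    terminal_span: int = 100000
    repeat_len_min: int = 4000
    repeat_len_max: int = 9500
    repeat_identity_min: float = 90.0
    # hit post-processing
    block_trim_len: int = 20
    block_trim_gap: int = 100
    max_intra_element_gap: int = 1000
    # element filters
    element_len_min: int = 1000
    element_len_core: int = 3500
    edge_margin: int = 10
    flank_gap_max: int = 50
    ref_match_min: int = 500
    ref_match_identity: float = 80.0
    # 36-mer / CA profiling
    mer_window: int = 36
    peak_spacing: int = 30
    peak_threshold: float = 0.85
    ca_window: int = 100
    ca_min_len: int = 100
    # ORFs
    orf_min_len: int = 300
    # clustering
    k_min: int = 2
    k_max: int = 100
    cluster_min_size: int = 5
    heterogeneity_max: float = 15.0
    # telomere scan
    telomere_window: int = 20
    telomere_threshold: float = 0.8
    telomere_merge_gap: int = 10
    min_its_len: int = 20
    terminal_margin: int = 50
    telomere_min_run: int = 8
    # stats
    association_window: int = 500
    equal_variance_ttest: bool = False
    excluded_strains: tuple = ()
    # misc
    msa_backend: str = "auto"
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, bool) or not isinstance(v, (int, float)):
                continue
            if f.name == "seed":
                continue
            if v <= 0:
                raise ValueError(f"config parameter {f.name} must be positive, got {v}")
        if not self.k_min < self.k_max:
            raise ValueError("k_min must be < k_max")
        if not self.repeat_len_min < self.repeat_len_max:
            raise ValueError("repeat_len_min must be < repeat_len_max")
        return self

    def to_dict(self) -> dict:
        d = asdict(self)
        d["excluded_strains"] = list(self.excluded_strains)
        return d

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        """Read ``key = value`` overrides (one per line, '#' comments)."""
        overrides: dict = {}
        valid = {f.name: f for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise InputError(f"cannot parse config line: {line!r}")
                key, _, raw = line.partition("=")
                key, raw = key.strip(), raw.strip()
                if key not in valid:
                    raise InputError(f"unknown config parameter {key!r}")
                default = getattr(cls(), key)
                if isinstance(default, bool):
                    overrides[key] = raw.lower() in ("1", "true", "yes")
                elif isinstance(default, int):
                    overrides[key] = int(raw)
                elif isinstance(default, float):
                    overrides[key] = float(raw)
                elif isinstance(default, tuple):
                    overrides[key] = tuple(x for x in raw.split(",") if x)
                else:
                    overrides[key] = raw
        return cls(**overrides).validate()


def extremity_name(contig: str, side: str) -> str:
    """Canonical name of a chromosome extremity, e.g. ``chrI.L``."""
    if side not in ("L", "R"):
        raise ValueError("side must be 'L' or 'R'")
    return f"{contig}.{side}"


def nearest_side(interval: GenomicInterval, contig_length: int) -> str:
    """Which extremity an interval belongs to (midpoint rule on short contigs)."""
    mid = (interval.start + interval.end) / 2
    return "L" if mid <= contig_length / 2 else "R"
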