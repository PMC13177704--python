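"""Synthetic chromosome-end generator with machine-readable ground truth.

The simulator plants the structures the pipeline is built to recover:
terminal telomere tracts, tandem arrays of Y' elements of six structural
classes (long / short / mid1 / mid2 / two CA-rich families) separated by
interstitial telomeric sequences (ITSs), degenerate 36-mer or CA-rich
repeat stretches inside the elements, an inert X-element placeholder, and
per-extremity telomere-length tables with configurable class-specific
effects.  Everything is deterministic given the spec seed, and the emitted
ground truth is exact: re-extracting any truth interval from the FASTA
reproduces the planted (mutated) sequence.

Structural conventions mirror the biology: the long element carries two
internal blocks of 465 and 600 bp whose joint deletion yields the short
element and whose single deletions yield mid1/mid2; CA-rich classes replace
the distal half of the long backbone with one of two distinct 1.6-1.8 kb
domains hosting the CA-rich repeats.  Planted elements always point toward
the nearer telomere.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    GenomicInterval,
    GenerationError,
    FORWARD,
    REVERSE,
    extremity_name,
)
from .motifs import (
    CA_PATTERN_1,
    CA_PATTERN_2,
    MER36_CONSENSUS,
    resolve_degenerate,
)
from .sequtil import mutate_fixed, mutate_substitutions, random_dna, revcomp

# long-backbone geometry (see docs/methods.md)
LONG_LEN = 6256
DELETION_1 = (1000, 1465)  # 465 bp; absent from short and mid1
DELETION_2 = (2200, 2800)  # 600 bp; absent from short and mid2
ORF_SPANS_LONG = ((300, 900), (3000, 3900), (4100, 5999))
STRETCH_SLOT_LONG = 4000
CONSERVED_SPAN_LONG = (3000, 3900)
CA_SPLIT = 3128  # distal half replaced in CA-rich classes
CA_DOMAIN_LEN = {"ca_rich_a": 1700, "ca_rich_b": 1800}
CA_SLOT_OFFSET = 850

MER36_CLASSES = ("long", "short", "mid1", "mid2")
CA_CLASSES = ("ca_rich_a", "ca_rich_b")
ALL_CLASSES = MER36_CLASSES + CA_CLASSES

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)

# C{1,3}A repeat-unit length weights giving E[#C per A] = 5/3, i.e. a CA
# strand with ~62.5% C / 37.5% A, the composition of telomeric tracts.
_TEL_UNIT_P = (0.4, 0.5333, 0.0667)


@dataclass(frozen=True)
class ElementTemplate:
    class_name: str
    backbone: str
    stretch_slot: int
    orf_spans: tuple
    conserved_span: tuple | None
    stretch_kind: str  # mer36 | ca_rich

    @property
    def length(self) -> int:
        return len(self.backbone)


def _plant_orf(seq: list, start: int, end: int, rng: np.random.Generator) -> None:
    """Overwrite [start, end) with ATG + sense codons + TAA ((end-start)%3==0)."""
    assert (end - start) % 3 == 0
    codons = ["ATG"]
    for _ in range((end - start) // 3 - 2):
        codons.append(_SENSE_CODONS[rng.integers(len(_SENSE_CODONS))])
    codons.append("TAA")
    seq[start:end] = list("".join(codons))


def _shift_spans(spans, blocks):
    """Lift spans on the long backbone onto a backbone with blocks removed."""
    out = []
    for s, e in spans:
        shift_s = sum(b1 - b0 for b0, b1 in blocks if b1 <= s)
        out.append((s - shift_s, e - shift_s))
    return tuple(out)


def build_templates(seed: int = 0):
    """The six element-class templates, deterministic per seed.

    Invariants: len(long) - len(short) = 465 + 600; mid1/mid2 each lack
    exactly one of the two blocks; CA-rich classes share the proximal half
    of the long backbone and differ in their distal domain.
    """
    rng = np.random.default_rng(seed)
    long_seq = list(random_dna(rng, LONG_LEN))
    for s, e in ORF_SPANS_LONG:
        _plant_orf(long_seq, s, e, rng)
    long_bb = "".join(long_seq)

    def remove(blocks):
        seq = long_bb
        for b0, b1 in sorted(blocks, reverse=True):
            seq = seq[:b0] + seq[b1:]
        return seq

    def shifted_slot(blocks):
        return STRETCH_SLOT_LONG - sum(
            b1 - b0 for b0, b1 in blocks if b1 <= STRETCH_SLOT_LONG
        )

    templates = []
    for class_name, blocks in (
        ("long", ()),
        ("short", (DELETION_1, DELETION_2)),
        ("mid1", (DELETION_1,)),
        ("mid2", (DELETION_2,)),
    ):
        templates.append(
            ElementTemplate(
                class_name=class_name,
                backbone=remove(blocks),
                stretch_slot=shifted_slot(blocks),
                orf_spans=_shift_spans(ORF_SPANS_LONG, blocks),
                conserved_span=_shift_spans((CONSERVED_SPAN_LONG,), blocks)[0],
                stretch_kind="mer36",
            )
        )
    proximal = long_bb[:CA_SPLIT]
    for class_name in CA_CLASSES:
        domain = random_dna(rng, CA_DOMAIN_LEN[class_name])
        templates.append(
            ElementTemplate(
                class_name=class_name,
                backbone=proximal + domain,
                stretch_slot=CA_SPLIT + CA_SLOT_OFFSET,
                orf_spans=((300, 900),),
                conserved_span=None,
                stretch_kind="ca_rich",
            )
        )
    return templates


def templates_by_class(templates) -> dict:
    return {t.class_name: t for t in templates}


@dataclass
class SimulationSpec:
    """Study conditions for the generator (all rates in [0, 1])."""

    n_strains: int = 3
    contigs_per_strain: int = 4
    core_len: int = 15000
    elements_per_end: tuple = (0.64, 0.30, 0.05, 0.01)  # weights for 0,1,2,3
    class_mix: dict = field(
        default_factory=lambda: {
            "long": 0.35,
            "short": 0.30,
            "mid1": 0.10,
            "mid2": 0.08,
            "ca_rich_a": 0.09,
            "ca_rich_b": 0.08,
        }
    )
    substitution_rate: float = 0.005
    stretch_count_n: int = 36  # Binomial(n, p) unit counts in 0..36
    stretch_count_p: float = 0.28  # median ~10 units, the observed median
    per_repeat_divergence: float = 0.08
    ca_stretch_count_range: tuple = (8, 41)
    its_len_min: int = 20
    its_len_max: int = 500
    its_junction_prob: float = 0.62
    its_proximal_prob: float = 0.5
    telomere_len_mean: float = 330.0
    telomere_len_sd: float = 75.0
    telomere_len_min: int = 100
    telomere_effects: dict = field(default_factory=dict)  # class -> cis fraction
    trans_effect_per_copy: dict = field(default_factory=dict)  # class -> per-copy
    strain_template_divergence: float = 0.0
    x_placeholder_len: int = 500
    seed: int = 0

    def validate(self) -> "SimulationSpec":
        for name in (
            "substitution_rate",
            "stretch_count_p",
            "per_repeat_divergence",
            "its_junction_prob",
            "its_proximal_prob",
            "strain_template_divergence",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0 <= self.stretch_count_n <= 36:
            raise ValueError("stretch counts must lie in [0, 36]")
        if self.its_len_min < 20:
            raise ValueError("its_len_min must be >= 20")
        if abs(sum(self.elements_per_end) - 1.0) > 1e-9:
            raise ValueError("elements_per_end weights must sum to 1")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        return self


@dataclass
class PlantedElement:
    strain: str
    interval: GenomicInterval
    class_name: str
    sequence: str  # forward-strand slice of the contig
    stretch_interval: GenomicInterval | None
    unit_count: int
    stretch_kind: str

    @property
    def oriented_sequence(self) -> str:
        if self.interval.orientation == REVERSE:
            return revcomp(self.sequence)
        return self.sequence

    @property
    def oriented_stretch_span(self) -> tuple | None:
        """Stretch interval in oriented element-local coordinates."""
        if self.stretch_interval is None:
            return None
        iv, sv = self.interval, self.stretch_interval
        if iv.orientation == FORWARD:
            return (sv.start - iv.start, sv.end - iv.start)
        return (iv.end - sv.end, iv.end - sv.start)


@dataclass
class PlantedIts:
    strain: str
    interval: GenomicInterval
    context: str  # tandem_junction | centromere_proximal


@dataclass
class PlantedTelomere:
    strain: str
    interval: GenomicInterval
    side: str  # L | R


@dataclass
class PlantedTruth:
    elements: list = field(default_factory=list)
    its: list = field(default_factory=list)
    telomeres: list = field(default_factory=list)
    x_placeholders: list = field(default_factory=list)
    contig_lengths: dict = field(default_factory=dict)  # strain -> {contig: len}

    def elements_at(self, strain: str, contig: str, side: str):
        out = []
        for el in self.elements:
            if el.strain != strain or el.interval.contig != contig:
                continue
            length = self.contig_lengths[strain][el.interval.contig]
            mid = (el.interval.start + el.interval.end) / 2
            el_side = "L" if mid <= length / 2 else "R"
            if el_side == side:
                out.append(el)
        return out

    def distal_class(self, strain: str, contig: str, side: str):
        """Class of the telomere-adjacent (distal-most) element, or None."""
        els = self.elements_at(strain, contig, side)
        if not els:
            return None
        if side == "L":
            return min(els, key=lambda e: e.interval.start).class_name
        return max(els, key=lambda e: e.interval.end).class_name

    def copy_number(self, strain: str, class_names=None) -> int:
        return sum(
            1
            for el in self.elements
            if el.strain == strain
            and (class_names is None or el.class_name in class_names)
        )


# ---------------------------------------------------------------------------
# sequence pieces


def telomere_tract(rng: np.random.Generator, length: int) -> str:
    """A degenerate C{1,3}A tract (CA strand) of exactly ``length`` bp with
    C fraction strictly above 0.5."""
    for _ in range(64):
        parts = []
        total = 0
        while total < length:
            k = 1 + rng.choice(3, p=_TEL_UNIT_P)
            parts.append("C" * k + "A")
            total += k + 1
        tract = "".join(parts)[:length]
        if tract.count("C") / length > 0.52:
            return tract
    raise RuntimeError("could not draw a C-dominated telomeric tract")


def mer36_stretch(rng: np.random.Generator, n_units: int, divergence: float) -> str:
    """Tandem 36-mer units: ambiguities resolved uniformly per unit, then a
    controlled round(divergence*36) substitutions per unit."""
    n_subs = round(divergence * 36)
    units = []
    for _ in range(n_units):
        unit = resolve_degenerate(MER36_CONSENSUS, rng)
        units.append(mutate_fixed(unit, n_subs, rng))
    return "".join(units)


_CA_BASES = "ACGT"
_CA_BASE_P = np.array([0.45, 0.42, 0.055, 0.075])  # A, C, G, T


def ca_stretch(rng: np.random.Generator, n_units: int, divergence: float, p1_frac: float = 0.7) -> str:
    """Tandem CA-rich units mixing Pattern-1-like and Pattern-2-like motifs.

    Substitutions draw replacement bases from the CA-rich composition so
    the A~45%/C~42% bias is stationary under divergence."""
    units = []
    for _ in range(n_units):
        motif = CA_PATTERN_1 if rng.random() < p1_frac else CA_PATTERN_2
        n_subs = round(divergence * len(motif))
        arr = list(motif)
        for i in rng.choice(len(arr), size=n_subs, replace=False):
            cur = arr[i]
            probs = np.array(
                [p for b, p in zip(_CA_BASES, _CA_BASE_P) if b != cur]
            )
            choices = [b for b in _CA_BASES if b != cur]
            arr[i] = choices[rng.choice(len(choices), p=probs / probs.sum())]
        units.append("".join(arr))
    return "".join(units)


def make_element(
    template: ElementTemplate,
    rng: np.random.Generator,
    spec: SimulationSpec,
    backbone: str | None = None,
):
    """One planted element: (sequence, stretch local span or None, unit count)."""
    bb = backbone if backbone is not None else template.backbone
    if template.stretch_kind == "mer36":
        n_units = int(rng.binomial(spec.stretch_count_n, spec.stretch_count_p))
        stretch = mer36_stretch(rng, n_units, spec.per_repeat_divergence)
    else:
        lo, hi = spec.ca_stretch_count_range
        n_units = int(rng.integers(lo, hi))
        stretch = ca_stretch(rng, n_units, spec.per_repeat_divergence)
    slot = template.stretch_slot
    seq = bb[:slot] + stretch + bb[slot:]
    seq = mutate_substitutions(seq, spec.substitution_rate, rng)
    span = (slot, slot + len(stretch)) if stretch else None
    return seq, span, n_units


def _its_sequence(rng: np.random.Generator, spec: SimulationSpec) -> str:
    lo, hi = spec.its_len_min, spec.its_len_max
    length = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    length = max(lo, min(hi, length))
    return telomere_tract(rng, length)


def _draw_telomere_len(rng: np.random.Generator, spec: SimulationSpec) -> int:
    raw = rng.normal(spec.telomere_len_mean, spec.telomere_len_sd)
    return int(max(spec.telomere_len_min, round(raw)))


# ---------------------------------------------------------------------------
# genome assembly


def _build_end_block(rng, spec, tpl_map, variants, strain):
    """One chromosome-end block read centromere -> telomere.

    Returns (sequence, element features, its features) with block-local
    coordinates; elements are in telomere-pointing (forward) orientation.
    """
    weights = np.asarray(spec.elements_per_end)
    n_el = int(rng.choice(len(weights), p=weights))
    class_names = sorted(spec.class_mix)
    class_p = np.asarray([spec.class_mix[c] for c in class_names])

    pieces = []
    elements = []
    its_feats = []
    cursor = 0

    def push(seq):
        nonlocal cursor
        pieces.append(seq)
        cursor += len(seq)

    if n_el > 0 and rng.random() < spec.its_proximal_prob:
        its = _its_sequence(rng, spec)
        its_feats.append(("centromere_proximal", cursor, cursor + len(its)))
        push(revcomp(its))  # TG strand, like the adjacent telomere
    for i in range(n_el):
        cls = class_names[int(rng.choice(len(class_names), p=class_p))]
        tpl = tpl_map[cls]
        bb = variants.get((strain, cls)) if variants else None
        seq, span, n_units = make_element(tpl, rng, spec, backbone=bb)
        start = cursor
        push(seq)
        elements.append((cls, start, start + len(seq), span, n_units, tpl.stretch_kind))
        if i < n_el - 1 and rng.random() < spec.its_junction_prob:
            its = _its_sequence(rng, spec)
            its_feats.append(("tandem_junction", cursor, cursor + len(its)))
            push(revcomp(its))
    tel_len = _draw_telomere_len(rng, spec)
    tel_start = cursor
    push(revcomp(telomere_tract(rng, tel_len)))
    return "".join(pieces), elements, its_feats, (tel_start, cursor)


def simulate_genome(spec: SimulationSpec, templates=None):
    """Generate genomes and exact ground truth.

    Returns ({strain: {contig: sequence}}, PlantedTruth).
    """
    spec.validate()
    if spec.core_len < 2000:
        raise GenerationError(
            "core_len too short to host the requested features (need >= 2000)"
        )
    rng = np.random.default_rng(spec.seed)
    if templates is None:
        templates = build_templates(seed=0)
    tpl_map = templates_by_class(templates)

    variants = {}
    if spec.strain_template_divergence > 0:
        for s in range(spec.n_strains):
            strain = f"strain{s:02d}"
            for cls, tpl in tpl_map.items():
                variants[(strain, cls)] = mutate_substitutions(
                    tpl.backbone, spec.strain_template_divergence, rng
                )

    genomes: dict = {}
    truth = PlantedTruth()
    for s in range(spec.n_strains):
        strain = f"strain{s:02d}"
        genomes[strain] = {}
        truth.contig_lengths[strain] = {}
        for c in range(spec.contigs_per_strain):
            contig = f"chr{c + 1:02d}"
            left_seq, left_els, left_its, left_tel = _build_end_block(
                rng, spec, tpl_map, variants, strain
            )
            right_seq, right_els, right_its, right_tel = _build_end_block(
                rng, spec, tpl_map, variants, strain
            )
            if spec.core_len < spec.x_placeholder_len + 2000:
                raise GenerationError(
                    f"contig {contig}: core too short for the X placeholder"
                )
            half = (spec.core_len - spec.x_placeholder_len) // 2
            core1 = random_dna(rng, half)
            x_seq = random_dna(rng, spec.x_placeholder_len)
            core2 = random_dna(rng, spec.core_len - spec.x_placeholder_len - half)

            left_block = revcomp(left_seq)
            L_left = len(left_seq)
            contig_seq = left_block + core1 + x_seq + core2 + right_seq
            right_off = len(left_block) + spec.core_len
            genomes[strain][contig] = contig_seq
            truth.contig_lengths[strain][contig] = len(contig_seq)

            def mirror(span):  # block-local -> contig coords on the left arm
                s0, e0 = span
                return (L_left - e0, L_left - s0)

            for cls, s0, e0, span, n_units, kind in left_els:
                a, b = mirror((s0, e0))
                stretch_iv = None
                if span is not None:
                    ls, le = span
                    sa, sb = mirror((s0 + ls, s0 + le))
                    stretch_iv = GenomicInterval(contig, sa, sb, REVERSE)
                truth.elements.append(
                    PlantedElement(
                        strain,
                        GenomicInterval(contig, a, b, REVERSE),
                        cls,
                        contig_seq[a:b],
                        stretch_iv,
                        n_units,
                        kind,
                    )
                )
            for ctx, s0, e0 in left_its:
                a, b = mirror((s0, e0))
                truth.its.append(
                    PlantedIts(strain, GenomicInterval(contig, a, b), ctx)
                )
            a, b = mirror(left_tel)
            truth.telomeres.append(
                PlantedTelomere(strain, GenomicInterval(contig, a, b), "L")
            )

            for cls, s0, e0, span, n_units, kind in right_els:
                a, b = right_off + s0, right_off + e0
                stretch_iv = None
                if span is not None:
                    ls, le = span
                    stretch_iv = GenomicInterval(
                        contig, a + ls, a + le, FORWARD
                    )
                truth.elements.append(
                    PlantedElement(
                        strain,
                        GenomicInterval(contig, a, b, FORWARD),
                        cls,
                        contig_seq[a:b],
                        stretch_iv,
                        n_units,
                        kind,
                    )
                )
            for ctx, s0, e0 in right_its:
                truth.its.append(
                    PlantedIts(
                        strain,
                        GenomicInterval(contig, right_off + s0, right_off + e0),
                        ctx,
                    )
                )
            truth.telomeres.append(
                PlantedTelomere(
                    strain,
                    GenomicInterval(
                        contig, right_off + right_tel[0], right_off + right_tel[1]
                    ),
                    "R",
                )
            )
            x_start = len(left_block) + half
            truth.x_placeholders.append(
                (strain, GenomicInterval(contig, x_start, x_start + spec.x_placeholder_len))
            )
    return genomes, truth


def sample_element_set(
    templates,
    class_names,
    n_per_class: int,
    substitution_rate: float,
    seed: int = 0,
    with_stretch: bool = False,
    spec: SimulationSpec | None = None,
):
    """Directly sample mutated element copies from templates (no genome
    scaffolding) -- convenient for clustering/consensus experiments.

    Returns (ids, sequences, class labels).
    """
    rng = np.random.default_rng(seed)
    tpl_map = templates_by_class(templates)
    spec = spec or SimulationSpec()
    ids, seqs, labels = [], [], []
    for cls in class_names:
        tpl = tpl_map[cls]
        for i in range(n_per_class):
            if with_stretch:
                seq, _, _ = make_element(tpl, rng, spec)
            else:
                seq = mutate_substitutions(tpl.backbone, substitution_rate, rng)
            ids.append(f"{cls}.{i:03d}")
            seqs.append(seq)
            labels.append(cls)
    return ids, seqs, labels


# ---------------------------------------------------------------------------
# telomere-length table


def draw_length_table(
    classes: dict,
    spec: SimulationSpec,
    rng: np.random.Generator,
    strain_factors: dict | None = None,
) -> pd.DataFrame:
    """Sample a per-extremity telomere-length table.

    ``classes``: {(strain, extremity): class name or None}; extremities
    carrying class c are scaled by (1 - telomere_effects[c]); optional
    per-strain multiplicative factors model copy-number (trans) effects.
    """
    rows = []
    for (strain, extremity), cls in sorted(classes.items()):
        base = max(
            float(spec.telomere_len_min),
            rng.normal(spec.telomere_len_mean, spec.telomere_len_sd),
        )
        effect = spec.telomere_effects.get(cls, 0.0) if cls else 0.0
        factor = (strain_factors or {}).get(strain, 1.0)
        rows.append(
            {
                "strain": strain,
                "extremity": extremity,
                "length_bp": base * (1.0 - effect) * factor,
            }
        )
    return pd.DataFrame(rows)


def simulate_telomere_table(
    spec: SimulationSpec, truth: PlantedTruth, seed: int | None = None
) -> pd.DataFrame:
    """Per-extremity telomere lengths with planted class effects.

    Extremities whose telomere-adjacent element belongs to class c are
    scaled by (1 - telomere_effects[c]); per-strain multiplicative factors
    implement the copy-number (trans) effects.  Columns: strain, extremity,
    length_bp.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    classes = {}
    factors = {}
    for strain, contigs in truth.contig_lengths.items():
        factor = 1.0
        for cls, per_copy in spec.trans_effect_per_copy.items():
            factor *= 1.0 + per_copy * truth.copy_number(strain, (cls,))
        factors[strain] = factor
        for contig in contigs:
            for side in ("L", "R"):
                classes[(strain, extremity_name(contig, side))] = truth.distal_class(
                    strain, contig, side
                )
    return draw_length_table(classes, spec, rng, factors)


def reference_entries(
    templates, n_units: int = 10, ca_units: int = 24, seed: int = 97
) -> dict:
    """Reference element sequences (template backbones carrying a canonical
    stretch: the median 10 units for 36-mer classes, a mid-range count for
    the longer CA repeats), playing the role of the curated reference
    database appended to the high-confidence set."""
    rng = np.random.default_rng(seed)
    out = {}
    for tpl in templates:
        if tpl.stretch_kind == "mer36":
            stretch = mer36_stretch(rng, n_units, 0.0)
        else:
            stretch = ca_stretch(rng, ca_units, 0.0)
        slot = tpl.stretch_slot
        out[f"ref_{tpl.class_name}"] = tpl.backbone[:slot] + stretch + tpl.backbone[slot:]
    return out
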