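"""Window self-repeats, database construction, hit trimming, detection."""
import numpy as np
import pytest

from yprime.align import LocalHit
from yprime.core import GenomicInterval, InputError, PipelineConfig
from yprime.detect import (
    YPrimeDatabase,
    build_high_confidence_db,
    detect_elements,
    find_window_repeats,
    repeat_copy_intervals,
    trim_hit_blocks,
)
from yprime.simulate import (
    SimulationSpec,
    make_element,
    reference_entries,
    simulate_genome,
    telomere_tract,
)
from yprime.sequtil import mutate_substitutions, random_dna, revcomp
from yprime.telomeres import scan_contig


def _rng(seed):
    return np.random.default_rng(seed)


def _scan_all(genomes, cfg):
    return {
        (s, c): scan_contig(seq, c, cfg)
        for s, contigs in genomes.items()
        for c, seq in contigs.items()
    }


class TestWindowRepeats:
    def _tandem_contig(self, rng, copy_len, divergence=0.0, its_len=100):
        copy = random_dna(rng, copy_len)
        copy2 = mutate_substitutions(copy, divergence, rng)
        return (
            random_dna(rng, 3000)
            + revcomp(telomere_tract(rng, 120))
            + copy
            + revcomp(telomere_tract(rng, its_len))
            + copy2
            + revcomp(telomere_tract(rng, 300))
        ), copy

    def test_planted_tandem_pair_detected(self, config):
        seq, copy = self._tandem_contig(_rng(1), 5200)
        calls = scan_contig(seq, "c", config)
        hits = find_window_repeats(seq, "c", config, calls)
        assert hits
        spans = repeat_copy_intervals(hits, "c")
        # both copies' spans are recovered as candidates
        starts = sorted(iv.start for iv in spans)
        assert abs(starts[0] - 3120) <= 30
        assert len(spans) >= 2

    def test_diverged_tandem_retained_at_92_percent(self, config):
        seq, _ = self._tandem_contig(_rng(2), 4500, divergence=0.08)
        calls = scan_contig(seq, "c", config)
        hits = find_window_repeats(seq, "c", config, calls)
        assert hits
        assert all(h.percent_identity >= 90 for h in hits)

    def test_repeats_below_length_floor_discarded(self, config):
        seq, _ = self._tandem_contig(_rng(3), 3500)
        calls = scan_contig(seq, "c", config)
        hits = find_window_repeats(seq, "c", config, calls)
        assert hits == []

    def test_repeats_above_length_ceiling_discarded(self, config):
        seq, _ = self._tandem_contig(_rng(4), 9800)
        calls = scan_contig(seq, "c", config)
        assert find_window_repeats(seq, "c", config, calls) == []


def _hit(blocks, matches=None):
    return LocalHit(
        query_id="q",
        target_id="t",
        query_start=blocks[0][0],
        query_end=blocks[-1][1],
        target_start=blocks[0][2],
        target_end=blocks[-1][3],
        strand="+",
        target_len=10**6,
        blocks=list(blocks),
        block_matches=matches or [b[1] - b[0] for b in blocks],
    )


class TestTrimHitBlocks:
    def test_small_distant_extremal_block_trimmed(self):
        hit = _hit([(0, 15, 0, 15), (165, 2000, 165, 2000)])
        trimmed = trim_hit_blocks(hit)
        assert len(trimmed.blocks) == 1
        assert trimmed.query_start == 165

    def test_large_extremal_block_kept(self):
        hit = _hit([(0, 25, 0, 25), (175, 2000, 175, 2000)])
        trimmed = trim_hit_blocks(hit)
        assert len(trimmed.blocks) == 2

    def test_small_but_close_extremal_block_kept(self):
        hit = _hit([(0, 15, 0, 15), (65, 2000, 65, 2000)])
        trimmed = trim_hit_blocks(hit)
        assert len(trimmed.blocks) == 2

    def test_trailing_block_trimmed_iteratively(self):
        hit = _hit(
            [(0, 2000, 0, 2000), (2150, 2165, 2150, 2165), (2300, 2310, 2300, 2310)]
        )
        trimmed = trim_hit_blocks(hit)
        assert len(trimmed.blocks) == 1
        assert trimmed.query_end == 2000

    def test_everything_trimmed_returns_none(self):
        hit = _hit([(0, 10, 0, 10)])
        assert trim_hit_blocks(hit) is None


class TestDatabase:
    def _scene(self, seed, its=True):
        """One contig with a telomere-flanked tandem pair of short elements."""
        from yprime.simulate import build_templates

        rng = _rng(seed)
        spec = SimulationSpec(seed=seed)
        tpl_el, _, _ = make_element(build_templates(0)[1], rng, spec)
        copy2 = mutate_substitutions(tpl_el, 0.005, rng)
        mid = revcomp(telomere_tract(rng, 80)) if its else random_dna(rng, 80)
        seq = (
            random_dna(rng, 4000)
            + revcomp(telomere_tract(rng, 100))
            + tpl_el
            + mid
            + copy2
            + revcomp(telomere_tract(rng, 300))
        )
        genomes = {"s": {"c": seq}}
        cfg = PipelineConfig()
        calls = _scan_all(genomes, cfg)
        cands = {
            ("s", "c"): repeat_copy_intervals(
                find_window_repeats(seq, "c", cfg, calls[("s", "c")]), "c"
            )
        }
        return genomes, calls, cands, cfg

    def test_flanked_matching_repeat_enters_db(self, templates):
        genomes, calls, cands, cfg = self._scene(1, its=True)
        db = build_high_confidence_db(
            cands, genomes, reference_entries(templates), calls, cfg
        )
        assert any(prov == "window_repeat" for _, _, prov in db.entries)

    def test_unflanked_repeat_excluded(self, templates):
        genomes, calls, cands, cfg = self._scene(2, its=False)
        db = build_high_confidence_db(
            cands, genomes, reference_entries(templates), calls, cfg
        )
        assert not any(prov == "window_repeat" for _, _, prov in db.entries)

    def test_repeat_without_reference_match_excluded(self, templates):
        genomes, calls, cands, cfg = self._scene(3, its=True)
        rng = _rng(99)
        unrelated = {"refX": random_dna(rng, 6000)}
        db = build_high_confidence_db(cands, genomes, unrelated, calls, cfg)
        assert not any(prov == "window_repeat" for _, _, prov in db.entries)

    def test_empty_reference_rejected(self, templates):
        genomes, calls, cands, cfg = self._scene(4)
        with pytest.raises(InputError):
            build_high_confidence_db(cands, genomes, {}, calls, cfg)

    def test_duplicate_sequences_rejected(self):
        with pytest.raises(ValueError):
            YPrimeDatabase([("a", "ACGT" * 1200, "x"), ("b", "ACGT" * 1200, "y")])


class TestDetectElements:
    def _detect(self, genomes, cfg, templates):
        calls = _scan_all(genomes, cfg)
        cands = {
            key: repeat_copy_intervals(
                find_window_repeats(genomes[key[0]][key[1]], key[1], cfg, cl), key[1]
            )
            for key, cl in calls.items()
        }
        db = build_high_confidence_db(
            cands, genomes, reference_entries(templates), calls, cfg
        )
        return detect_elements(db, genomes, calls, cfg)

    def test_planted_element_boundaries_and_orientation(self, templates, config):
        spec = SimulationSpec(
            n_strains=1,
            contigs_per_strain=2,
            elements_per_end=(0.0, 1.0, 0.0, 0.0),
            seed=21,
        )
        genomes, truth = simulate_genome(spec, templates)
        elements = self._detect(genomes, config, templates)
        assert len(elements) == len(truth.elements)
        for t in truth.elements:
            matches = [
                e
                for e in elements
                if e.interval.reciprocal_overlap(t.interval) >= 0.9
            ]
            assert len(matches) == 1
            e = matches[0]
            assert abs(e.interval.start - t.interval.start) <= 25
            assert abs(e.interval.end - t.interval.end) <= 25
            assert e.interval.orientation == t.interval.orientation
            assert e.telomere_flanked in ("both", "distal_only")

    def test_short_fragment_not_emitted(self, templates, template_map, config):
        rng = _rng(22)
        frag = template_map["long"].backbone[:900]
        seq = (
            random_dna(rng, 6000)
            + frag
            + revcomp(telomere_tract(rng, 250))
        )
        genomes = {"s": {"c": seq}}
        elements = self._detect(genomes, config, templates)
        assert elements == []

    def test_edge_overlapping_element_flagged_truncated(self, templates, template_map, config):
        rng = _rng(23)
        half = template_map["long"].backbone[:3200]
        seq = revcomp(telomere_tract(rng, 200)) + random_dna(rng, 6000) + half
        genomes = {"s": {"c": seq}}
        elements = self._detect(genomes, config, templates)
        assert len(elements) == 1
        assert elements[0].edge_truncated

    @pytest.mark.parametrize("n_copies", [2, 3, 4])
    def test_tandem_arrays_yield_exactly_n_elements(self, templates, config, n_copies):
        weights = [0.0, 0.0, 0.0, 0.0]
        spec_weights = tuple(
            1.0 if i == n_copies else 0.0 for i in range(4)
        )
        if n_copies < 4:
            spec = SimulationSpec(
                n_strains=1,
                contigs_per_strain=1,
                elements_per_end=spec_weights,
                its_junction_prob=0.6,
                seed=30 + n_copies,
            )
            genomes, truth = simulate_genome(spec, templates)
        else:
            # four copies: build the array manually
            rng = _rng(34)
            spec = SimulationSpec(seed=34)
            tpl = templates[0]
            parts = [random_dna(rng, 5000), revcomp(telomere_tract(rng, 90))]
            truth_n = 4
            for i in range(4):
                el, _, _ = make_element(tpl, rng, spec)
                parts.append(el)
                if i < 3:
                    parts.append(revcomp(telomere_tract(rng, 80)))
            parts.append(revcomp(telomere_tract(rng, 300)))
            genomes = {"s": {"c": "".join(parts)}}

            class T:
                elements = [None] * truth_n

            truth = T()
        elements = self._detect(genomes, config, templates)
        assert len(elements) == len(truth.elements)

    def test_funnel_is_monotone(self, templates, config, small_sim):
        _spec, genomes, _truth = small_sim
        calls = _scan_all(genomes, config)
        cands = {
            key: repeat_copy_intervals(
                find_window_repeats(genomes[key[0]][key[1]], key[1], config, cl),
                key[1],
            )
            for key, cl in calls.items()
        }
        db = build_high_confidence_db(
            cands, genomes, reference_entries(templates), calls, config
        )
        funnel = {}
        elements = detect_elements(db, genomes, calls, config, funnel)
        assert funnel["kept"] <= funnel["len_ge_min"] <= funnel["trimmed_hits"]
        assert funnel["trimmed_hits"] <= funnel["raw_hits"]
        # emitted elements are non-overlapping per contig
        per_contig = {}
        for e in elements:
            per_contig.setdefault((e.strain, e.interval.contig), []).append(e.interval)
        for ivs in per_contig.values():
            ivs.sort()
            for a, b in zip(ivs, ivs[1:]):
                assert a.end <= b.start
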