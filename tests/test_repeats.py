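"""36-mer scanning, stretch calling, CA regions, masking and PFMs."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from yprime.core import InputError
from yprime.motifs import (
    CA_PATTERN_1,
    CA_PATTERN_2,
    MER36_CONSENSUS,
    default_ca_pattern_db,
    default_mer36_db,
    expand_degenerate,
)
from yprime.repeats import (
    RepeatStretch,
    build_pfm,
    detect_36mer_stretch,
    detect_ca_region,
    mask_stretches,
    refine_motif_db,
    score_36mer_track,
    segment_ca_patterns,
)
from yprime.simulate import ca_stretch, mer36_stretch, telomere_tract
from yprime.sequtil import mutate_fixed, random_dna


def _rng(seed):
    return np.random.default_rng(seed)


class TestScoring:
    def test_exact_motif_scores_one(self):
        db = default_mer36_db()
        rng = _rng(0)
        seq = random_dna(rng, 100) + db[0] + random_dna(rng, 100)
        track = score_36mer_track(seq, db)
        assert track.scores[100] == 1.0

    def test_two_substitutions_score_34_over_36(self):
        db = default_mer36_db()
        rng = _rng(1)
        # mutate positions outside the ambiguity sites of the consensus
        unit = list(db[0])
        fixed_pos = [i for i, b in enumerate(MER36_CONSENSUS) if b in "ACGT"]
        unit[fixed_pos[0]] = {"A": "C", "C": "A", "G": "T", "T": "G"}[unit[fixed_pos[0]]]
        unit[fixed_pos[5]] = {"A": "C", "C": "A", "G": "T", "T": "G"}[unit[fixed_pos[5]]]
        seq = random_dna(rng, 50) + "".join(unit) + random_dna(rng, 50)
        track = score_36mer_track(seq, db)
        assert track.scores[50] == pytest.approx(34 / 36)

    def test_track_invariant_to_db_order(self):
        db = default_mer36_db()
        rng = _rng(2)
        seq = random_dna(rng, 200) + mer36_stretch(rng, 3, 0.1) + random_dna(rng, 200)
        t1 = score_36mer_track(seq, db).scores
        t2 = score_36mer_track(seq, list(reversed(db))).scores
        assert np.array_equal(t1, t2)

    def test_random_windows_stay_below_threshold(self):
        db = default_mer36_db()[:10]
        rng = _rng(3)
        seq = random_dna(rng, 10035)  # 10,000 windows
        track = score_36mer_track(seq, db).scores
        assert (track >= 0.85).mean() <= 0.001

    def test_short_element_gives_empty_track(self):
        assert score_36mer_track("ACGT" * 5, default_mer36_db()).scores.size == 0

    def test_uneven_motif_lengths_rejected(self):
        with pytest.raises(InputError):
            score_36mer_track("A" * 100, ["ACG" * 12, "ACGT"])


class TestStretchCalling:
    def test_planted_stretch_count_and_interval(self):
        db = default_mer36_db()
        rng = _rng(4)
        stretch = mer36_stretch(rng, 10, 0.10)
        seq = random_dna(rng, 400) + stretch + random_dna(rng, 400)
        found = detect_36mer_stretch(seq, db)
        assert found is not None
        assert found.unit_count == 10
        assert abs(found.start - 400) <= 36
        assert abs(found.end - (400 + len(stretch))) <= 36

    def test_no_units_gives_none(self):
        db = default_mer36_db()
        assert detect_36mer_stretch(random_dna(_rng(5), 2000), db) is None

    def test_close_peaks_suppressed_by_spacing(self):
        db = [MER36_CONSENSUS.replace("R", "A").replace("Y", "C").replace("W", "A").replace("S", "C")]
        unit = db[0]
        # two overlapping near-copies 20 bp apart: only one peak survives
        seq = random_dna(_rng(6), 100) + unit[:20] + unit + random_dna(_rng(7), 100)
        found = detect_36mer_stretch(seq, db)
        assert found is not None
        assert found.unit_count == 1

    def test_indel_unit_dropped_from_units_but_delimits(self):
        db = default_mer36_db()
        rng = _rng(8)
        u1 = mer36_stretch(rng, 1, 0.0)
        u_indel = u1[:17] + u1[18:] + "A"  # one deletion, length preserved
        u3 = mer36_stretch(rng, 1, 0.0)
        seq = random_dna(rng, 300) + u1 + u_indel + u3 + random_dna(rng, 300)
        found = detect_36mer_stretch(seq, db)
        assert found is not None
        assert found.unit_count == 3
        assert len(found.units) <= 2 or all(len(u) == 36 for u in found.units)


class TestRefinement:
    def test_refined_db_contains_planted_units(self):
        rng = _rng(9)
        seed_db = default_mer36_db()
        elements = []
        planted = set()
        for _ in range(10):
            stretch = mer36_stretch(rng, 5, 0.05)
            units = [stretch[i * 36 : (i + 1) * 36] for i in range(5)]
            planted.update(units)
            elements.append(random_dna(rng, 200) + stretch + random_dna(rng, 200))
        refined = refine_motif_db(elements, seed_db)
        missing = planted - set(refined)
        assert len(missing) <= 1  # boundary units may shift by the peak offset

    def test_elements_without_stretches_keep_seed_db(self):
        seed_db = default_mer36_db()
        with pytest.warns(UserWarning):
            refined = refine_motif_db([random_dna(_rng(10), 500)], seed_db)
        assert refined == list(seed_db)

    def test_refinement_never_reduces_unit_count(self):
        rng = _rng(11)
        seed_db = default_mer36_db()
        elements = []
        for _ in range(100):
            n = int(rng.integers(0, 4))
            stretch = mer36_stretch(rng, n, 0.10)
            elements.append(random_dna(rng, 120) + stretch + random_dna(rng, 120))
        refined = refine_motif_db(elements, seed_db)
        for seq in elements:
            first = detect_36mer_stretch(seq, seed_db)
            second = detect_36mer_stretch(seq, refined)
            c1 = first.unit_count if first else 0
            c2 = second.unit_count if second else 0
            assert c2 >= c1


class TestCaRegions:
    def test_planted_region_recovered_within_50bp(self):
        rng = _rng(12)
        region = ca_stretch(rng, 20, 0.08)
        seq = random_dna(rng, 500) + region + random_dna(rng, 500)
        found = detect_ca_region(seq)
        assert found is not None
        assert abs(found.start - 500) <= 50
        assert abs(found.end - (500 + len(region))) <= 50
        comp = found.composition
        assert comp["A"] + comp["C"] >= 0.8

    def test_telomeric_tract_not_called_ca_rich(self):
        rng = _rng(13)
        seq = random_dna(rng, 300) + telomere_tract(rng, 300) + random_dna(rng, 300)
        assert detect_ca_region(seq) is None

    def test_random_sequence_rarely_called(self):
        fp = 0
        for seed in range(1000):
            if detect_ca_region(random_dna(_rng(20000 + seed), 800)) is not None:
                fp += 1
        assert fp <= 10  # >= 99% clean


class TestPatternSegmentation:
    def test_exact_p1_tiling_fully_labeled(self):
        out = segment_ca_patterns(CA_PATTERN_1 * 10, default_ca_pattern_db())
        assert out.fractions["P1"] == 1.0
        assert out.fractions["P2"] == 0.0

    def test_random_ca_composition_mostly_unassigned(self):
        rng = _rng(14)
        hits = []
        for _ in range(20):
            seq = "".join(
                rng.choice(list("ACGT"), p=[0.45, 0.42, 0.055, 0.075], size=800)
            )
            out = segment_ca_patterns(seq, default_ca_pattern_db())
            hits.append(out.fraction_unassigned())
        assert np.mean(hits) >= 0.8

    def test_mixed_tiling_fractions_recovered(self):
        region = CA_PATTERN_1 * 6 + CA_PATTERN_2 * 4
        out = segment_ca_patterns(region, default_ca_pattern_db())
        expected_p1 = 6 * 37 / len(region)
        expected_p2 = 4 * 33 / len(region)
        assert abs(out.fractions["P1"] - expected_p1) <= 0.10
        assert abs(out.fractions["P2"] - expected_p2) <= 0.10

    def test_empty_pattern_db_rejected(self):
        with pytest.raises(InputError):
            segment_ca_patterns("ACAC" * 50, {})


class TestMasking:
    def test_length_accounting_exact(self):
        rng = _rng(15)
        seq = random_dna(rng, 5452)
        stretch = RepeatStretch("e", "mer36", 2000, 2360, 10)
        masked = mask_stretches(seq, [stretch], "e")
        assert len(masked.masked_sequence) == 5452 - 360
        assert len(masked.masked_sequence) + sum(
            e - s for s, e, _, _ in masked.removed
        ) == len(seq)

    def test_no_stretches_is_identity(self):
        seq = random_dna(_rng(16), 500)
        assert mask_stretches(seq, []).masked_sequence == seq

    @given(
        spans=st.lists(
            st.tuples(st.integers(0, 900), st.integers(1, 80)),
            min_size=0,
            max_size=4,
        )
    )
    @settings(max_examples=60, derandomize=True)
    def test_mask_reinsert_round_trip(self, spans):
        seq = random_dna(_rng(17), 1000)
        ivs = sorted((s, min(1000, s + l)) for s, l in spans)
        merged = []
        for s, e in ivs:  # keep only non-overlapping spans
            if not merged or s >= merged[-1][1]:
                merged.append((s, e))
        stretches = [RepeatStretch("e", "mer36", s, e, 0) for s, e in merged]
        masked = mask_stretches(seq, stretches)
        assert masked.reconstruct() == seq

    def test_overlapping_stretches_rejected(self):
        seq = random_dna(_rng(18), 500)
        a = RepeatStretch("e", "mer36", 100, 200, 1)
        b = RepeatStretch("e", "ca_rich", 150, 300, 0)
        with pytest.raises(InputError):
            mask_stretches(seq, [a, b])


class TestPfm:
    def test_identical_units_give_one_hot_columns(self):
        pfm = build_pfm(["ACGT"] * 10)
        assert np.allclose(pfm.sum(axis=0), 1.0)
        assert np.allclose(pfm.max(axis=0), 1.0)

    def test_sampled_distribution_recovered_within_ci(self):
        rng = _rng(19)
        n = 600
        units = [
            ("A" if rng.random() < 0.7 else "C")
            + ("G" if rng.random() < 0.4 else "T")
            for _ in range(n)
        ]
        pfm = build_pfm(units)
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(pfm.loc["A", 0] - 0.7) <= 4 * se
        assert abs(pfm.loc["G", 1] - 0.4) <= 4 * np.sqrt(0.4 * 0.6 / n)

    def test_empty_and_mixed_length_inputs_rejected(self):
        with pytest.raises(InputError):
            build_pfm([])
        with pytest.raises(InputError):
            build_pfm(["ACGT", "ACG"])
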