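"""Distribution tables, ITS classification, diversity, association tests."""
import warnings

import numpy as np
import pandas as pd
import pytest

from yprime.core import GenomicInterval, InputError, PipelineConfig
from yprime.detect import YPrimeElement
from yprime.simulate import (
    SimulationSpec,
    simulate_genome,
    simulate_telomere_table,
)
from yprime.sequtil import mutate_substitutions, random_dna
from yprime.stats import (
    classify_its,
    contingency_test,
    diversity_within_between,
    extremity_classes,
    normalize_telomere_table,
    tabulate_distribution,
    telomere_association,
)
from yprime.telomeres import TelomereCall, scan_contig


def _element(eid, strain, contig, start, end, orientation="+"):
    return YPrimeElement(
        element_id=eid,
        strain=strain,
        interval=GenomicInterval(contig, start, end, orientation),
        sequence="A" * (end - start),
    )


def _its_call(contig, start, end):
    return TelomereCall(GenomicInterval(contig, start, end), "interstitial", 1.0, "CA_strand")


class TestTabulate:
    def _setup(self):
        contig_lengths = {"s0": {"c1": 40000, "c2": 40000}, "s1": {"c1": 40000}}
        elements = [
            _element("s0.c1.000", "s0", "c1", 1000, 7000, "-"),
            _element("s0.c1.001", "s0", "c1", 7100, 13000, "-"),
            _element("s0.c2.000", "s0", "c2", 33000, 39000),
        ]
        return elements, contig_lengths

    def test_counts_conserve_total(self):
        elements, lengths = self._setup()
        tables = tabulate_distribution(elements, {}, lengths)
        assert tables["per_strain"]["n_elements"].sum() == len(elements)
        assert tables["per_extremity"]["n_elements"].sum() == len(elements)

    def test_zero_rows_retained(self):
        elements, lengths = self._setup()
        tables = tabulate_distribution(elements, {}, lengths)
        s1 = tables["per_strain"].set_index("strain").loc["s1", "n_elements"]
        assert s1 == 0
        assert len(tables["per_extremity"]) == 6

    def test_tandem_histogram_bins(self):
        elements, lengths = self._setup()
        tables = tabulate_distribution(elements, {}, lengths)
        hist = tables["tandem_histogram"].set_index("array_size")["n_extremities"]
        assert hist["2"] == 1  # the c1.L tandem pair
        assert hist["1"] == 1
        assert hist["0"] == 4


class TestClassifyIts:
    def test_tandem_junction(self):
        elements = [
            _element("e0", "s", "c", 1000, 6000),
            _element("e1", "s", "c", 6100, 11000),
        ]
        calls = {("s", "c"): [_its_call("c", 6010, 6090)]}
        (rec,) = classify_its(calls, elements)
        assert rec.context == "tandem_junction"
        assert set(rec.flanking_elements) == {"e0", "e1"}

    def test_centromere_proximal_with_distance(self):
        elements = [_element("e0", "s", "c", 1000, 6000, "+")]
        calls = {("s", "c"): [_its_call("c", 820, 920)]}
        (rec,) = classify_its(calls, elements)
        assert rec.context == "centromere_proximal"
        assert rec.distance_to_element == 80

    def test_far_its_unassigned(self):
        elements = [_element("e0", "s", "c", 10000, 16000)]
        calls = {("s", "c"): [_its_call("c", 2000, 2100)]}
        (rec,) = classify_its(calls, elements)
        assert rec.context == "unassigned"

    def test_classification_recall_on_simulated_truth(self, templates):
        cfg = PipelineConfig()
        total = found = 0
        for seed in range(100):
            spec = SimulationSpec(
                n_strains=1,
                contigs_per_strain=1,
                core_len=4000,
                elements_per_end=(0.0, 0.3, 0.4, 0.3),
                its_junction_prob=0.7,
                seed=seed,
            )
            genomes, truth = simulate_genome(spec, templates)
            elements = [
                _element(f"t{i}", el.strain, el.interval.contig, el.interval.start,
                         el.interval.end, el.interval.orientation)
                for i, el in enumerate(truth.elements)
            ]
            calls = {
                (s, c): scan_contig(seq, c, cfg)
                for s, contigs in genomes.items()
                for c, seq in contigs.items()
            }
            records = classify_its(calls, elements)
            for its in truth.its:
                total += 1
                for rec in records:
                    if rec.interval.overlap(its.interval) > 0:
                        if rec.context == its.context:
                            found += 1
                        break
        assert total > 0
        assert found / total == 1.0


class TestDiversity:
    def test_within_strain_lower_than_between(self):
        rng = np.random.default_rng(1)
        base = random_dna(rng, 800)
        seqs = {}
        strains = {}
        for s in range(4):
            strain_variant = mutate_substitutions(base, 0.02, rng)
            for i in range(4):
                eid = f"s{s}.e{i}"
                seqs[eid] = mutate_substitutions(strain_variant, 0.005, rng)
                strains[eid] = f"s{s}"
        within, between = diversity_within_between(seqs, strains, backend="auto")
        assert np.median(within) < np.median(between)

    def test_identical_elements_zero_divergence(self):
        seqs = {f"e{i}": "ACGT" * 100 for i in range(4)}
        strains = {"e0": "a", "e1": "a", "e2": "b", "e3": "b"}
        within, between = diversity_within_between(seqs, strains, backend="internal")
        assert all(v == 0 for v in within + between)

    def test_single_strain_yields_empty_between(self):
        seqs = {"e0": "ACGT" * 50, "e1": "ACGT" * 50}
        strains = {"e0": "s", "e1": "s"}
        with pytest.warns(UserWarning):
            within, between = diversity_within_between(seqs, strains, backend="internal")
        assert between == [] and len(within) == 1


class TestAssociation:
    def test_normalization_means_one_per_strain(self):
        rng = np.random.default_rng(2)
        rows = [
            {"strain": f"s{i}", "extremity": f"c{j}.L", "length_bp": rng.uniform(200, 500)}
            for i in range(5)
            for j in range(8)
        ]
        norm = normalize_telomere_table(pd.DataFrame(rows))
        means = norm.groupby("strain")["normalized"].mean()
        assert np.allclose(means, 1.0)

    def test_small_group_gives_nan_p(self):
        rows = []
        classes = {}
        for j in range(10):
            rows.append({"strain": "s0", "extremity": f"c{j}.L", "length_bp": 300.0 + j})
            classes[("s0", f"c{j}.L")] = "long" if j == 0 else "no_yprime"
        results = telomere_association(pd.DataFrame(rows), classes)
        res = [r for r in results if r.comparison.startswith("long")][0]
        assert np.isnan(res.p_value)

    def test_planted_effect_direction_recovered(self, templates):
        spec = SimulationSpec(
            n_strains=8,
            contigs_per_strain=8,
            elements_per_end=(0.5, 0.5, 0.0, 0.0),
            class_mix={"long": 1.0},
            telomere_effects={"long": 0.15},
            seed=5,
        )
        genomes, truth = simulate_genome(spec, templates)
        table = simulate_telomere_table(spec, truth)
        elements = [
            _element(f"t{i}", el.strain, el.interval.contig, el.interval.start,
                     el.interval.end, el.interval.orientation)
            for i, el in enumerate(truth.elements)
        ]
        labels = {f"t{i}": el.class_name for i, el in enumerate(truth.elements)}
        lengths = {s: {c: len(seq) for c, seq in ctgs.items()} for s, ctgs in genomes.items()}
        classes = extremity_classes(elements, labels, lengths)
        results = telomere_association(table, classes)
        res = [r for r in results if r.comparison == "long vs no_yprime"][0]
        assert res.effect > 0.05
        assert res.p_value < 0.05


class TestContingency:
    def test_perfect_independence(self):
        res = contingency_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_perfect_association_no_continuity_correction(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = contingency_test([[20, 0], [0, 20]])
        assert res.statistic == pytest.approx(40.0)
        assert res.p_value < 1e-9

    def test_degenerate_tables_rejected(self):
        with pytest.raises(InputError):
            contingency_test([[1, 2]])
        with pytest.raises(InputError):
            contingency_test([[0, 0], [0, 0]])

    def test_low_expected_counts_warn(self):
        with pytest.warns(UserWarning):
            contingency_test([[2, 1], [1, 3]])
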