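"""Similarity, silhouette clustering, CA re-clustering, consensi."""
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from yprime.align import MsaResult, build_msa
from yprime.cluster import (
    SimilarityMatrix,
    build_consensus,
    cluster_elements,
    recluster_ca_elements,
    similarity_from_msa,
    summarize_and_filter,
)
from yprime.core import DegenerateInputError, InputError
from yprime.sequtil import mutate_substitutions, random_dna


def _rng(seed):
    return np.random.default_rng(seed)


def _brute_force_similarity(rows):
    n = len(rows)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            match = valid = 0
            for a, b in zip(rows[i], rows[j]):
                if a == "-" and b == "-":
                    continue
                valid += 1
                if a == b and a != "-":
                    match += 1
            out[i, j] = 100.0 * match / valid if valid else 0.0
    return out


class TestSimilarity:
    def test_identical_rows_score_100(self):
        m = similarity_from_msa(MsaResult(["a", "b"], ["ACGTAC", "ACGTAC"]))
        assert m.matrix[0, 1] == 100.0

    def test_three_quarters_match(self):
        m = similarity_from_msa(MsaResult(["a", "b"], ["ACGT", "ACGA"]))
        assert m.matrix[0, 1] == 75.0

    def test_shared_gap_columns_ignored(self):
        rows = ["AC-GTACGTA", "AC-GTACGTA", "ACCGTACGTA"]
        m = similarity_from_msa(MsaResult(["a", "b", "c"], rows))
        assert m.matrix[0, 1] == 100.0
        assert m.matrix[0, 2] == pytest.approx(90.0)

    def test_one_sided_gap_counts_as_difference(self):
        m = similarity_from_msa(MsaResult(["a", "b"], ["ACGT-", "ACGTA"]))
        assert m.matrix[0, 1] == pytest.approx(80.0)

    def test_matches_brute_force_on_random_msas(self):
        rng = _rng(1)
        for trial in range(8):
            n = int(rng.integers(3, 11))
            seqs = [
                random_dna(rng, int(rng.integers(50, 200))) for _ in range(n)
            ]
            msa = build_msa(seqs, backend="internal")
            got = similarity_from_msa(msa).matrix
            expected = _brute_force_similarity(msa.rows)
            expected = (expected + expected.T) / 2
            assert np.allclose(got, expected, atol=1e-9)

    def test_single_row_rejected(self):
        with pytest.raises(InputError):
            similarity_from_msa(MsaResult(["a"], ["ACGT"]))


def _block_matrix(sizes, within, between):
    n = sum(sizes)
    m = np.full((n, n), float(between))
    start = 0
    for s in sizes:
        m[start : start + s, start : start + s] = within
        start += s
    np.fill_diagonal(m, 100.0)
    ids = [f"e{i}" for i in range(n)]
    return SimilarityMatrix(ids, m)


class TestClustering:
    def test_two_tight_groups_give_k2(self):
        m = _block_matrix([8, 8], within=99.0, between=50.0)
        sol = cluster_elements(m, 2, 15)
        assert sol.k == 2
        labels = [sol.labels[f"e{i}"] for i in range(16)]
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1

    def test_four_planted_groups_recovered(self):
        rng = _rng(2)
        m = _block_matrix([6, 6, 6, 6], within=98.0, between=70.0)
        noisy = m.matrix + rng.normal(0, 0.2, m.matrix.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 100.0)
        noisy = np.clip(noisy, 0, 100)
        sol = cluster_elements(SimilarityMatrix(m.ids, noisy), 2, 23)
        assert sol.k == 4

    def test_identical_elements_degenerate(self):
        m = _block_matrix([6], within=100.0, between=100.0)
        with pytest.raises(DegenerateInputError):
            cluster_elements(m, 2, 5)

    def test_permutation_invariance_up_to_relabeling(self):
        rng = _rng(3)
        m = _block_matrix([5, 7, 6], within=97.0, between=60.0)
        noisy = m.matrix + rng.normal(0, 0.3, m.matrix.shape)
        noisy = np.clip((noisy + noisy.T) / 2, 0, 100)
        np.fill_diagonal(noisy, 100.0)
        sol = cluster_elements(SimilarityMatrix(m.ids, noisy), 2, 17)
        perm = rng.permutation(len(m.ids))
        shuffled = SimilarityMatrix(
            [m.ids[i] for i in perm], noisy[np.ix_(perm, perm)]
        )
        sol2 = cluster_elements(shuffled, 2, 17)
        a = [sol.labels[i] for i in m.ids]
        b = [sol2.labels[i] for i in m.ids]
        assert adjusted_rand_score(a, b) == 1.0

    def test_silhouette_curve_recorded(self):
        m = _block_matrix([6, 6], within=98.0, between=55.0)
        sol = cluster_elements(m, 2, 10)
        ks = [k for k, _ in sol.curve]
        assert ks == sorted(ks)
        assert all(-1 <= s <= 1 for _, s in sol.curve)


class TestReclusterCa:
    def test_two_ca_subtypes_separated(self):
        rng = _rng(4)
        base_a = random_dna(rng, 1500)
        base_b = random_dna(rng, 1500)
        labels = {}
        masked = {}
        for i in range(5):
            labels[f"a{i}"] = "C9"
            masked[f"a{i}"] = mutate_substitutions(base_a, 0.01, rng)
        for i in range(5):
            labels[f"b{i}"] = "C9"
            masked[f"b{i}"] = mutate_substitutions(base_b, 0.01, rng)
        labels["x0"] = "C1"
        out = recluster_ca_elements(labels, masked, backend="internal")
        assert out["x0"] == "C1"  # non-CA untouched
        a_labels = {out[f"a{i}"] for i in range(5)}
        b_labels = {out[f"b{i}"] for i in range(5)}
        assert len(a_labels) == 1 and len(b_labels) == 1
        assert a_labels != b_labels
        assert all(l.startswith("CA") for l in a_labels | b_labels)

    def test_zero_ca_elements_noop(self):
        labels = {"x": "C1"}
        assert recluster_ca_elements(labels, {}) == labels

    def test_too_few_ca_elements_warns_and_keeps_labels(self):
        labels = {"a": "C1", "b": "C1"}
        with pytest.warns(UserWarning):
            out = recluster_ca_elements(labels, {"a": "ACGT" * 100, "b": "ACGT" * 100})
        assert out == labels


class TestSummaries:
    def _matrix(self, ids):
        n = len(ids)
        m = np.full((n, n), 95.0)
        np.fill_diagonal(m, 100.0)
        return SimilarityMatrix(ids, m)

    def test_small_cluster_not_retained(self):
        ids = [f"e{i}" for i in range(4)]
        labels = {e: "C1" for e in ids}
        strains = {e: f"s{i}" for i, e in enumerate(ids)}
        (summary,) = summarize_and_filter(labels, strains, self._matrix(ids))
        assert summary.size == 4 and not summary.retained

    def test_single_strain_cluster_not_retained(self):
        ids = [f"e{i}" for i in range(8)]
        labels = {e: "C1" for e in ids}
        strains = {e: "s0" for e in ids}
        (summary,) = summarize_and_filter(labels, strains, self._matrix(ids))
        assert not summary.retained

    def test_heterogeneous_cluster_not_retained(self):
        ids = [f"e{i}" for i in range(6)]
        n = len(ids)
        m = np.full((n, n), 70.0)
        np.fill_diagonal(m, 100.0)
        labels = {e: "C1" for e in ids}
        strains = {e: f"s{i % 3}" for i, e in enumerate(ids)}
        (summary,) = summarize_and_filter(
            labels, strains, SimilarityMatrix(ids, m), heterogeneity_max=15.0
        )
        assert summary.heterogeneity == pytest.approx(30.0)
        assert not summary.retained

    def test_good_cluster_retained_and_sorted(self):
        ids = [f"e{i}" for i in range(9)]
        labels = {e: ("C1" if i < 6 else "C2") for i, e in enumerate(ids)}
        strains = {e: f"s{i % 3}" for i, e in enumerate(ids)}
        summaries = summarize_and_filter(labels, strains, self._matrix(ids))
        assert [s.cluster_id for s in summaries] == ["C1", "C2"]
        assert summaries[0].retained and not summaries[1].retained


class TestConsensus:
    def test_unanimous_copies_reproduce_template(self):
        tpl = random_dna(_rng(5), 800)
        cons, cov = build_consensus([tpl] * 10, backend="internal")
        assert cons == tpl
        assert np.allclose(cov, 1.0)

    def test_low_divergence_copies_close_to_template(self):
        rng = _rng(6)
        tpl = random_dna(rng, 2000)
        copies = [mutate_substitutions(tpl, 0.01, rng) for _ in range(10)]
        cons, _ = build_consensus(copies, backend="auto")
        assert len(cons) == len(tpl)
        ham = sum(1 for a, b in zip(cons, tpl) if a != b)
        assert ham / len(tpl) <= 0.002

    def test_shared_deletion_absent_from_consensus(self):
        rng = _rng(7)
        tpl = random_dna(rng, 1500)
        deleted = tpl[:500] + tpl[965:]  # 465 bp deletion
        members = [mutate_substitutions(deleted, 0.005, rng) for _ in range(6)]
        cons, _ = build_consensus(members, backend="auto")
        assert abs(len(cons) - len(deleted)) <= 5

    def test_single_member_passthrough_with_warning(self):
        with pytest.warns(UserWarning):
            cons, cov = build_consensus(["ACGTACGT"])
        assert cons == "ACGTACGT"
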