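"""Similarity matrix, silhouette-optimized hierarchical clustering,
CA re-clustering, cluster filtering and consensus construction.

Pairwise similarity between two rows of an MSA is the percentage of
identical residues over the columns covered by the union of the two
sequences: columns where both rows are gaps are ignored, columns where
exactly one row is gapped count as differences.  The similarity measure is
therefore dominated by structural differences (insertions/deletions)
rather than SNPs.  Clustering is average-linkage on distance
(100 - similarity); the cluster count is chosen by maximizing the mean
silhouette over a configurable range (ties resolve to the smallest k).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .align import MsaResult, build_msa
from .core import DegenerateInputError, InputError


@dataclass
class SimilarityMatrix:
    ids: list
    matrix: np.ndarray  # symmetric, diagonal 100, percent units

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(m, m.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(m), 100.0):
            raise ValueError("similarity diagonal must be 100")
        if m.min() < 0 or m.max() > 100 + 1e-9:
            raise ValueError("similarities must lie in [0, 100]")
        self.matrix = m

    def distance(self) -> np.ndarray:
        d = 100.0 - self.matrix
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class ClusterSolution:
    labels: dict  # element id -> cluster id (str)
    k: int
    silhouette: float
    curve: list  # [(k, silhouette), ...]
    linkage_method: str = "average"


@dataclass
class ClusterSummary:
    cluster_id: str
    size: int
    strains: set
    mean_intra_similarity: float
    heterogeneity: float
    retained: bool
    consensus: str | None = None
    coverage: np.ndarray | None = None
    domains: list = field(default_factory=list)


def pairwise_similarity(row_i: str, row_j: str) -> float:
    """Column-count similarity between two aligned rows (shared-gap columns
    ignored; one-sided gaps are differences)."""
    a = np.frombuffer(row_i.encode(), dtype=np.uint8)
    b = np.frombuffer(row_j.encode(), dtype=np.uint8)
    gap = ord("-")
    valid = ~((a == gap) & (b == gap))
    n = int(valid.sum())
    if n == 0:
        return 0.0
    match = int(((a == b) & valid & (a != gap)).sum())
    return 100.0 * match / n


def similarity_from_msa(msa: MsaResult) -> SimilarityMatrix:
    """Pairwise percent similarity over the union span of each row pair."""
    n = len(msa.rows)
    if n < 2:
        raise InputError("similarity requires at least 2 aligned sequences")
    rows = np.vstack(
        [np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows]
    )
    gap = ord("-")
    is_gap = rows == gap
    out = np.full((n, n), 100.0)
    for i in range(n):
        eq = rows == rows[i]
        both_gap = is_gap & is_gap[i]
        valid = ~both_gap
        match = (eq & valid & ~is_gap[i] & ~is_gap).sum(axis=1)
        denom = valid.sum(axis=1)
        denom[denom == 0] = 1
        sim = 100.0 * match / denom
        out[i, :] = sim
    out = (out + out.T) / 2.0  # exact symmetry against float noise
    np.fill_diagonal(out, 100.0)
    return SimilarityMatrix(list(msa.ids), out)


def cluster_elements(
    matrix: SimilarityMatrix, k_min: int = 2, k_max: int = 100
) -> ClusterSolution:
    """Average-linkage dendrogram cut at the silhouette-optimal k."""
    n = len(matrix.ids)
    if n < 3:
        raise InputError("clustering requires at least 3 elements")
    dist = matrix.distance()
    if np.allclose(dist, 0.0):
        raise DegenerateInputError(
            "all pairwise distances are zero; silhouette undefined"
        )
    condensed = squareform(dist, checks=False)
    Z = linkage(condensed, method="average")
    k_hi = min(k_max, n - 1)
    curve = []
    best = None
    for k in range(k_min, k_hi + 1):
        flat = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(flat)) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sil = float(silhouette_score(dist, flat, metric="precomputed"))
        curve.append((k, sil))
        if best is None or sil > best[0] + 1e-12:
            best = (sil, k, flat)
    if best is None:
        raise DegenerateInputError("no valid cluster cut in the k range")
    sil, k, flat = best
    # deterministic cluster ids: size descending, then first-member order
    order = {}
    groups: dict = {}
    for idx, c in enumerate(flat):
        groups.setdefault(int(c), []).append(idx)
    ranked = sorted(groups.values(), key=lambda idxs: (-len(idxs), idxs[0]))
    for rank, idxs in enumerate(ranked, start=1):
        for idx in idxs:
            order[idx] = f"C{rank}"
    labels = {matrix.ids[i]: order[i] for i in range(n)}
    return ClusterSolution(labels, int(k), float(sil), curve)


def recluster_ca_elements(
    solution_labels: dict,
    ca_masked_seqs: dict,
    k_min: int = 2,
    k_max: int = 100,
    backend: str = "auto",
) -> dict:
    """Replace the cluster assignment of CA-containing elements with a new
    clustering computed on their CA-masked sequences (new id namespace);
    all other labels are untouched."""
    labels = dict(solution_labels)
    ca_ids = sorted(ca_masked_seqs)
    if len(ca_ids) == 0:
        return labels
    if len(ca_ids) < 3:
        warnings.warn(
            "fewer than 3 CA-containing elements; keeping original labels"
        )
        return labels
    msa = build_msa([ca_masked_seqs[i] for i in ca_ids], ids=ca_ids, backend=backend)
    sim = similarity_from_msa(msa)
    try:
        sub = cluster_elements(sim, k_min=k_min, k_max=k_max)
    except DegenerateInputError:
        # all CA elements identical after masking: one CA cluster
        for eid in ca_ids:
            labels[eid] = "CA1"
        return labels
    for eid, cid in sub.labels.items():
        labels[eid] = f"CA{cid[1:]}"
    return labels


def summarize_and_filter(
    labels: dict,
    strains: dict,
    matrix: SimilarityMatrix,
    min_size: int = 5,
    heterogeneity_max: float = 15.0,
    min_strains: int = 2,
):
    """Per-cluster summaries with the retention filter: clusters are kept
    iff size >= min_size, spanning >= min_strains strains, and mean
    intra-cluster heterogeneity (100 - mean similarity) <= threshold.
    Sorted by size descending."""
    idx = {eid: i for i, eid in enumerate(matrix.ids)}
    clusters: dict = {}
    for eid, cid in labels.items():
        clusters.setdefault(cid, []).append(eid)
    out = []
    for cid in sorted(clusters):
        members = clusters[cid]
        ids = [idx[m] for m in members if m in idx]
        if len(ids) >= 2:
            sub = matrix.matrix[np.ix_(ids, ids)]
            triu = sub[np.triu_indices(len(ids), k=1)]
            mean_sim = float(triu.mean())
        else:
            mean_sim = 100.0
        strain_set = {strains[m] for m in members}
        het = 100.0 - mean_sim
        retained = (
            len(members) >= min_size
            and len(strain_set) >= min_strains
            and het <= heterogeneity_max
        )
        out.append(
            ClusterSummary(
                cluster_id=cid,
                size=len(members),
                strains=strain_set,
                mean_intra_similarity=mean_sim,
                heterogeneity=het,
                retained=retained,
            )
        )
    out.sort(key=lambda s: (-s.size, s.cluster_id))
    return out


_CONSENSUS_ORDER = "ACGT"  # deterministic tie-break, gap loses ties


def build_consensus(member_seqs, backend: str = "auto"):
    """Majority-rule consensus from the members' MSA.

    Per column the most frequent residue wins (ties: non-gap beats gap,
    then alphabetical); columns whose winner is the gap are dropped.
    Returns (consensus, per-kept-column coverage = non-gap fraction).
    """
    member_seqs = list(member_seqs)
    if len(member_seqs) == 0:
        raise InputError("consensus requires at least one member")
    if len(member_seqs) == 1:
        warnings.warn("single-member cluster: consensus is the member itself")
        return member_seqs[0].upper(), np.ones(len(member_seqs[0]))
    msa = build_msa(member_seqs, backend=backend)
    rows = np.vstack(
        [np.frombuffer(r.encode(), dtype=np.uint8) for r in msa.rows]
    )
    n, width = rows.shape
    consensus = []
    coverage = []
    gap = ord("-")
    alphabet = [ord(c) for c in _CONSENSUS_ORDER] + [gap]
    counts = np.vstack([(rows == a).sum(axis=0) for a in alphabet])
    for j in range(width):
        col = counts[:, j]
        best = int(np.argmax(col))  # argmax prefers bases over gap on ties
        if alphabet[best] == gap:
            continue
        consensus.append(chr(alphabet[best]))
        coverage.append(1.0 - col[-1] / n)
    return "".join(consensus), np.asarray(coverage)


def segment_domains(consensi: dict, min_identity: float = 80.0, min_len: int = 200):
    """Lightweight homology-domain segmentation between cluster consensi:
    for each ordered pair, the aligned blocks of >= min_len at
    >= min_identity (used to describe shared domain structure)."""
    from .align import map_spliced

    out = {}
    names = sorted(consensi)
    for a in names:
        domains = []
        for b in names:
            if a == b:
                continue
            try:
                hits = map_spliced(
                    consensi[a],
                    consensi[b],
                    min_identity=min_identity,
                    both_strands=False,
                )
            except InputError:
                continue
            for h in hits:
                if min(h.query_span, h.target_span) >= min_len:
                    domains.append(
                        (b, h.query_start, h.query_end, round(h.percent_identity, 2))
                    )
        out[a] = sorted(domains)
    return out
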