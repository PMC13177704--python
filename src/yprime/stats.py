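"""Distribution and association statistics: element counts, ITS context
classification, within- vs between-strain diversity, and telomere-length
association tests.

Telomere-length analyses normalize each extremity's mean length by the
average over all extremities of the same strain, then compare groups
defined by the cluster class of the telomere-adjacent element against
extremities devoid of Y' elements (two-sample t-test, Welch by default
with a pooled-variance switch), and correlate per-strain class copy
numbers with per-strain mean telomere length (Spearman).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GenomicInterval, InputError, FORWARD, nearest_side, extremity_name
from .telomeres import INTERSTITIAL


@dataclass
class ItsRecord:
    interval: GenomicInterval
    length: int
    context: str  # tandem_junction | centromere_proximal | unassigned
    distance_to_element: int
    flanking_elements: tuple  # element ids ('' when absent)


@dataclass
class AssociationResult:
    comparison: str
    group_sizes: tuple
    effect: float  # 1 - mean(group)/mean(reference), or rho for spearman
    statistic: float
    p_value: float  # nan when undefined (group too small)
    test_name: str  # t_two_tailed | spearman | chi_square


# ---------------------------------------------------------------------------
# distribution tables


def tabulate_distribution(elements, labels: dict, contig_lengths: dict):
    """Count tables: per strain, per extremity, cluster x strain, and the
    tandem-array size histogram (0 / 1 / 2 / 3+ elements per extremity).

    ``contig_lengths``: {strain: {contig: length}} defines the universe of
    extremities so zero rows are retained.
    """
    strains = sorted(contig_lengths)
    per_strain = {s: 0 for s in strains}
    per_extremity: dict = {}
    for s in strains:
        for contig in sorted(contig_lengths[s]):
            for side in ("L", "R"):
                per_extremity[(s, extremity_name(contig, side))] = 0
    cluster_strain: dict = {}
    for el in elements:
        per_strain[el.strain] += 1
        length = contig_lengths[el.strain][el.interval.contig]
        side = nearest_side(el.interval, length)
        key = (el.strain, extremity_name(el.interval.contig, side))
        per_extremity[key] += 1
        cid = labels.get(el.element_id, "unclustered")
        cluster_strain[(cid, el.strain)] = cluster_strain.get((cid, el.strain), 0) + 1

    strain_df = pd.DataFrame(
        {"strain": strains, "n_elements": [per_strain[s] for s in strains]}
    )
    ext_df = pd.DataFrame(
        [
            {"strain": s, "extremity": e, "n_elements": n}
            for (s, e), n in sorted(per_extremity.items())
        ]
    )
    cs_df = pd.DataFrame(
        [
            {"cluster": c, "strain": s, "n_elements": n}
            for (c, s), n in sorted(cluster_strain.items())
        ]
    )
    bins = {"0": 0, "1": 0, "2": 0, "3+": 0}
    for n in per_extremity.values():
        key = str(n) if n < 3 else "3+"
        bins[key] += 1
    tandem_df = pd.DataFrame(
        {"array_size": list(bins), "n_extremities": list(bins.values())}
    )
    return {
        "per_strain": strain_df,
        "per_extremity": ext_df,
        "cluster_by_strain": cs_df,
        "tandem_histogram": tandem_df,
    }


# ---------------------------------------------------------------------------
# ITS classification


def classify_its(telomere_calls, elements, association_window: int = 500):
    """Assign each interstitial telomeric call to its context.

    tandem_junction: between two elements of one array (both within the
    association window); centromere_proximal: within the window of exactly
    one element's centromere-proximal end; otherwise unassigned.
    """
    records = []
    by_contig: dict = {}
    for el in elements:
        by_contig.setdefault((el.strain, el.interval.contig), []).append(el)
    for (strain, contig), calls in sorted(telomere_calls.items()):
        els = sorted(
            by_contig.get((strain, contig), []), key=lambda e: e.interval.start
        )
        for call in calls:
            if call.kind != INTERSTITIAL:
                continue
            iv = call.interval
            left = [e for e in els if e.interval.end <= iv.start + 20]
            right = [e for e in els if e.interval.start >= iv.end - 20]
            left_el = max(left, key=lambda e: e.interval.end) if left else None
            right_el = min(right, key=lambda e: e.interval.start) if right else None
            dl = iv.start - left_el.interval.end if left_el else None
            dr = right_el.interval.start - iv.end if right_el else None
            context = "unassigned"
            distance = -1
            flanking = ("", "")
            if (
                left_el is not None
                and right_el is not None
                and dl <= association_window
                and dr <= association_window
            ):
                context = "tandem_junction"
                distance = min(dl, dr)
                flanking = (left_el.element_id, right_el.element_id)
            else:
                # centromere-proximal end: start for '+', end for '-'
                candidates = []
                if (
                    right_el is not None
                    and right_el.interval.orientation == FORWARD
                    and dr <= association_window
                ):
                    candidates.append((dr, right_el))
                if (
                    left_el is not None
                    and left_el.interval.orientation != FORWARD
                    and dl <= association_window
                ):
                    candidates.append((dl, left_el))
                if candidates:
                    candidates.sort(key=lambda c: c[0])
                    distance, el = candidates[0]
                    context = "centromere_proximal"
                    flanking = (el.element_id, "")
            records.append(
                ItsRecord(iv, iv.length, context, distance, flanking)
            )
    return records


def its_table(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": r.interval.contig,
                "start": r.interval.start,
                "end": r.interval.end,
                "length_bp": r.length,
                "context": r.context,
                "distance_to_element": r.distance_to_element,
                "flanking": ",".join(x for x in r.flanking_elements if x),
            }
            for r in records
        ]
    )


# ---------------------------------------------------------------------------
# diversity


def diversity_within_between(
    element_seqs: dict,
    element_strains: dict,
    backend: str = "auto",
):
    """Pairwise divergence (100 - similarity, shared-gap columns ignored)
    over an MSA of the given per-element sequences (typically a conserved
    region), partitioned into within-strain and between-strain pairs.

    Returns (within list, between list).  A single strain yields an empty
    between-strain distribution with a warning.
    """
    from .align import build_msa
    from .cluster import similarity_from_msa

    ids = sorted(element_seqs)
    if len(ids) < 2:
        raise InputError("diversity requires at least 2 elements")
    msa = build_msa([element_seqs[i] for i in ids], ids=ids, backend=backend)
    sim = similarity_from_msa(msa)
    within, between = [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            div = 100.0 - sim.matrix[i, j]
            if element_strains[ids[i]] == element_strains[ids[j]]:
                within.append(div)
            else:
                between.append(div)
    if not between:
        warnings.warn("single strain: between-strain distribution is empty")
    return within, between


# ---------------------------------------------------------------------------
# telomere-length association


def normalize_telomere_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``normalized`` column: extremity length over the strain mean."""
    out = table.copy()
    strain_mean = out.groupby("strain")["length_bp"].transform("mean")
    out["normalized"] = out["length_bp"] / strain_mean
    return out


def extremity_classes(elements, labels: dict, contig_lengths: dict) -> dict:
    """Map (strain, extremity) -> cluster label of the telomere-adjacent
    (distal-most) element, or 'no_yprime'."""
    classes: dict = {}
    for strain in contig_lengths:
        for contig in contig_lengths[strain]:
            for side in ("L", "R"):
                classes[(strain, extremity_name(contig, side))] = "no_yprime"
    per_ext: dict = {}
    for el in elements:
        length = contig_lengths[el.strain][el.interval.contig]
        side = nearest_side(el.interval, length)
        per_ext.setdefault(
            (el.strain, extremity_name(el.interval.contig, side), side), []
        ).append(el)
    for (strain, ext, side), els in per_ext.items():
        distal = (
            min(els, key=lambda e: e.interval.start)
            if side == "L"
            else max(els, key=lambda e: e.interval.end)
        )
        classes[(strain, ext)] = labels.get(distal.element_id, "unclustered")
    return classes


def telomere_association(
    table: pd.DataFrame,
    classes: dict,
    equal_var: bool = False,
    combined_groups: dict | None = None,
):
    """Class-wise two-tailed t-tests of normalized telomere length vs
    extremities devoid of Y', plus per-class Spearman correlations of
    strain copy number against strain mean telomere length.

    ``combined_groups`` optionally maps a label to a set of classes tested
    jointly.  Effect = 1 - mean(class)/mean(no-Y').
    """
    norm = normalize_telomere_table(table)
    norm["cls"] = [
        classes.get((s, e), "no_yprime")
        for s, e in zip(norm["strain"], norm["extremity"])
    ]
    ref = norm.loc[norm["cls"] == "no_yprime", "normalized"].to_numpy()
    results = []
    groups = {
        cls: {cls} for cls in sorted(set(norm["cls"])) if cls != "no_yprime"
    }
    if combined_groups:
        groups.update({k: set(v) for k, v in combined_groups.items()})
    for name in sorted(groups):
        member = norm.loc[norm["cls"].isin(groups[name]), "normalized"].to_numpy()
        if len(member) < 2 or len(ref) < 2:
            results.append(
                AssociationResult(
                    f"{name} vs no_yprime",
                    (len(member), len(ref)),
                    float("nan"),
                    float("nan"),
                    float("nan"),
                    "t_two_tailed",
                )
            )
            continue
        t, p = sps.ttest_ind(member, ref, equal_var=equal_var)
        effect = 1.0 - member.mean() / ref.mean()
        results.append(
            AssociationResult(
                f"{name} vs no_yprime",
                (len(member), len(ref)),
                float(effect),
                float(t),
                float(p),
                "t_two_tailed",
            )
        )
    # Spearman: per-strain copy number of each class vs strain mean length
    strain_mean = table.groupby("strain")["length_bp"].mean()
    copy_counts: dict = {}
    for (strain, _ext), cls in classes.items():
        if cls == "no_yprime":
            continue
        copy_counts.setdefault(cls, {}).setdefault(strain, 0)
        copy_counts[cls][strain] += 1
    for cls in sorted(copy_counts):
        xs = np.array([copy_counts[cls].get(s, 0) for s in strain_mean.index])
        ys = strain_mean.to_numpy()
        if len(set(xs)) < 2:
            continue
        rho, p = sps.spearmanr(xs, ys)
        results.append(
            AssociationResult(
                f"copy_number[{cls}] vs strain_mean_length",
                (len(xs), len(ys)),
                float(rho),
                float(rho),
                float(p),
                "spearman",
            )
        )
    return results


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted q-values (offered alongside raw p-values, never applied
    silently)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def contingency_test(table) -> AssociationResult:
    """Chi-square independence test on a contingency table of counts
    (no continuity correction); warns when any expected count < 5."""
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise InputError("contingency table must be at least 2x2")
    if (arr < 0).any() or not np.issubdtype(arr.dtype, np.number):
        raise InputError("contingency table must hold non-negative counts")
    if arr.sum() == 0:
        raise InputError("contingency table is all zero")
    chi2, p, _dof, expected = sps.chi2_contingency(arr, correction=False)
    if (expected < 5).any():
        warnings.warn("chi-square approximation dubious: expected count < 5")
    return AssociationResult(
        "contingency",
        tuple(arr.shape),
        float("nan"),
        float(chi2),
        float(p),
        "chi_square",
    )
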