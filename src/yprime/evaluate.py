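"""Self-contained evaluation experiments against planted truth and
independent oracles.

Each function regenerates its inputs from a seed, runs the relevant part
of the pipeline, and measures recovery.  They are shared by the test
suite and by ``scripts/acceptance.py``.  The oracles used here (brute
force ORF scan, Biopython local alignment, direct column counting) are
deliberately independent of the implementation paths they check.
"""
from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .align import build_msa, local_align, map_spliced
from .cluster import build_consensus, cluster_elements, similarity_from_msa
from .core import PipelineConfig, extremity_name
from .detect import (
    build_high_confidence_db,
    detect_elements,
    find_window_repeats,
    repeat_copy_intervals,
)
from .motifs import default_mer36_db
from .orfs import find_orfs
from .repeats import detect_36mer_stretch, mask_stretches
from .sequtil import random_dna, mutate_substitutions
from .simulate import (
    SimulationSpec,
    build_templates,
    ca_stretch,
    draw_length_table,
    mer36_stretch,
    reference_entries,
    sample_element_set,
    simulate_genome,
    telomere_tract,
)
from .stats import telomere_association
from .telomeres import INTERSTITIAL, TERMINAL, is_telomeric_tract, scan_contig


# ---------------------------------------------------------------------------
# detection recovery


def _match_intervals(detected, truth, min_reciprocal=0.9):
    """Greedy 1:1 matching of detected vs truth intervals."""
    tp = 0
    boundary_errors = []
    used = set()
    for t in truth:
        best = None
        for i, d in enumerate(detected):
            if i in used or d[0] != t[0]:
                continue
            ov = max(0, min(d[2], t[2]) - max(d[1], t[1]))
            if ov == 0:
                continue
            rec = min(ov / (d[2] - d[1]), ov / (t[2] - t[1]))
            if rec >= min_reciprocal and (best is None or rec > best[1]):
                best = (i, rec)
        if best is not None:
            used.add(best[0])
            tp += 1
            d = detected[best[0]]
            boundary_errors.extend([abs(d[1] - t[1]), abs(d[2] - t[2])])
    return tp, boundary_errors


def run_detection_once(seed: int, config: PipelineConfig | None = None):
    """One full detection round on a simulated strain (5 contigs, 0-3
    elements per end, 0.5% substitutions); returns (n_truth, n_detected,
    n_matched, boundary errors, orientation matches)."""
    cfg = config or PipelineConfig()
    templates = build_templates(0)
    spec = SimulationSpec(n_strains=1, contigs_per_strain=5, seed=seed)
    genomes, truth = simulate_genome(spec, templates)
    calls = {
        (s, c): scan_contig(seq, c, cfg)
        for s, contigs in genomes.items()
        for c, seq in contigs.items()
    }
    candidates = {
        key: repeat_copy_intervals(
            find_window_repeats(genomes[key[0]][key[1]], key[1], cfg, cl), key[1]
        )
        for key, cl in calls.items()
    }
    db = build_high_confidence_db(
        candidates, genomes, reference_entries(templates), calls, cfg
    )
    elements = detect_elements(db, genomes, calls, cfg)
    usable = [e for e in elements if not e.edge_truncated]
    det = [
        (e.interval.contig, e.interval.start, e.interval.end, e.interval.orientation)
        for e in usable
    ]
    tru = [
        (e.interval.contig, e.interval.start, e.interval.end, e.interval.orientation)
        for e in truth.elements
    ]
    tp, berr = _match_intervals(
        [d[:3] for d in det], [t[:3] for t in tru]
    )
    orient_ok = 0
    det_by_key = {d[:3]: d[3] for d in det}
    for t in tru:
        if t[:3] in det_by_key and det_by_key[t[:3]] == t[3]:
            orient_ok += 1
    return len(tru), len(det), tp, berr, orient_ok


def evaluate_detection(n_seeds: int, base_seed: int = 0):
    total_truth = total_det = total_tp = 0
    errors: list = []
    for i in range(n_seeds):
        nt, nd, tp, berr, _ = run_detection_once(base_seed + i)
        total_truth += nt
        total_det += nd
        total_tp += tp
        errors.extend(berr)
    recall = total_tp / total_truth if total_truth else 1.0
    precision = total_tp / total_det if total_det else 1.0
    return {
        "recall": recall,
        "precision": precision,
        "mean_boundary_error": float(np.mean(errors)) if errors else 0.0,
        "n_elements": total_truth,
    }


# ---------------------------------------------------------------------------
# 36-mer stretch recovery


def evaluate_stretch_recovery(n_elements: int, seed: int = 0, divergence: float = 0.10):
    """Planted stretches of 0-36 units at the given per-repeat divergence:
    exact unit-count recovery rate and mask length-accounting rate."""
    rng = np.random.default_rng(seed)
    db = default_mer36_db()
    exact = 0
    accounting = 0
    for _ in range(n_elements):
        n_units = int(rng.integers(0, 37))
        stretch = mer36_stretch(rng, n_units, divergence)
        left = random_dna(rng, 300)
        right = random_dna(rng, 300)
        seq = left + stretch + right
        found = detect_36mer_stretch(seq, db)
        count = found.unit_count if found is not None else 0
        if count == n_units:
            exact += 1
        masked = mask_stretches(seq, [found] if found else [])
        if (
            len(masked.masked_sequence)
            + sum(e - s for s, e, _, _ in masked.removed)
            == len(seq)
            and masked.reconstruct() == seq
        ):
            accounting += 1
    return {
        "exact_count_rate": exact / n_elements,
        "accounting_rate": accounting / n_elements,
        "n": n_elements,
    }


# ---------------------------------------------------------------------------
# cluster recovery


def run_cluster_once(seed: int, backend: str = "auto"):
    templates = build_templates(0)
    ids, seqs, labels = sample_element_set(
        templates, ["long", "short", "mid1", "mid2"], 15, 0.01, seed=seed
    )
    msa = build_msa(seqs, ids=ids, backend=backend)
    sim = similarity_from_msa(msa)
    sol = cluster_elements(sim, 2, 100)
    pred = [sol.labels[i] for i in ids]
    return sol.k, float(adjusted_rand_score(labels, pred))


def evaluate_cluster_recovery(n_seeds: int, base_seed: int = 0, backend: str = "auto"):
    hits = 0
    aris = []
    for i in range(n_seeds):
        k, ari = run_cluster_once(base_seed + i, backend=backend)
        aris.append(ari)
        if k == 4 and ari == 1.0:
            hits += 1
    return {
        "recovery_rate": hits / n_seeds,
        "mean_ari": float(np.mean(aris)),
        "n_seeds": n_seeds,
    }


# ---------------------------------------------------------------------------
# ORF oracle


def orf_oracle(sequence: str, orf_min_len: int = 300):
    """Exhaustive brute-force scan: for every stop codon of every forward
    frame, pair it with the first ATG after the previous stop; keep pairs
    of >= orf_min_len bases.  Independent of the streaming implementation."""
    seq = sequence.upper()
    n = len(seq)
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for frame in range(3):
        codon_pos = list(range(frame, n - 2, 3))
        stop_positions = [
            p for p in codon_pos if seq[p : p + 3] in stops and all(c in "ACGT" for c in seq[p:p+3])
        ]
        prev_stop_end = frame
        for sp in stop_positions:
            atgs = [
                p
                for p in codon_pos
                if prev_stop_end <= p < sp and seq[p : p + 3] == "ATG"
            ]
            if atgs:
                start = min(atgs)
                if sp + 3 - start >= orf_min_len:
                    out.append((start, sp + 3, frame))
            prev_stop_end = sp + 3
    return sorted(out)


def evaluate_orf_oracle(n_sequences: int = 200, seed: int = 0, length: int = 2000):
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_sequences):
        seq = random_dna(rng, length)
        ours = sorted((o.start, o.end, o.frame) for o in find_orfs(seq))
        if ours == orf_oracle(seq):
            agree += 1
    return {"agreement_rate": agree / n_sequences, "n": n_sequences}


# ---------------------------------------------------------------------------
# local-alignment oracle


def sw_oracle(query: str, target: str):
    """Top local alignment by Biopython's PairwiseAligner (affine Gotoh,
    same scoring scheme: match +1, mismatch -2, gap of length g costs
    4 + g)."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    alns = aligner.align(query, target)
    aln = alns[0]
    qs, qe = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
    ts, te = int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1])
    matches = 0
    cols = 0
    for (q0, q1), (t0, t1) in zip(aln.aligned[0], aln.aligned[1]):
        for dq in range(q1 - q0):
            cols += 1
            if query[q0 + dq] == target[t0 + dq]:
                matches += 1
    # add gap columns between blocks
    for i in range(len(aln.aligned[0]) - 1):
        cols += max(
            aln.aligned[0][i + 1][0] - aln.aligned[0][i][1],
            aln.aligned[1][i + 1][0] - aln.aligned[1][i][1],
        )
    identity = 100.0 * matches / cols if cols else 0.0
    return (qs, qe, ts, te, identity, float(aln.score))


def make_homologous_pair(rng: np.random.Generator, total_len: int = 300, divergence: float = 0.05):
    """A pair of sequences sharing one diverged segment inside random
    flanks (each sequence <= total_len)."""
    core_len = int(rng.integers(120, 220))
    flank_a = int(rng.integers(20, (total_len - core_len) - 20))
    flank_b = int(rng.integers(20, (total_len - core_len) - 20))
    core = random_dna(rng, core_len)
    a = random_dna(rng, flank_a) + core + random_dna(rng, total_len - core_len - flank_a)
    b = (
        random_dna(rng, flank_b)
        + mutate_substitutions(core, divergence, rng)
        + random_dna(rng, total_len - core_len - flank_b)
    )
    return a, b


def evaluate_local_align_oracle(n_pairs: int = 200, seed: int = 0):
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_pairs):
        a, b = make_homologous_pair(rng)
        ours = local_align(a, b, min_identity=0.0, k=11)
        oq0, oq1, ot0, ot1, oid, _ = sw_oracle(a, b)
        if not ours:
            continue
        top = max(ours, key=lambda h: h.score)
        if (
            abs(top.query_start - oq0) <= 2
            and abs(top.query_end - oq1) <= 2
            and abs(top.target_start - ot0) <= 2
            and abs(top.target_end - ot1) <= 2
            and abs(top.percent_identity - oid) <= 1.0
        ):
            agree += 1
    return {"agreement_rate": agree / n_pairs, "n": n_pairs}


# ---------------------------------------------------------------------------
# consensus fidelity


def evaluate_consensus(seed: int = 0, backend: str = "auto"):
    templates = build_templates(0)
    tpl = [t for t in templates if t.class_name == "short"][0].backbone
    rng = np.random.default_rng(seed)
    copies = [mutate_substitutions(tpl, 0.01, rng) for _ in range(10)]
    cons, _cov = build_consensus(copies, backend=backend)
    if len(cons) == len(tpl):
        ham = sum(1 for a, b in zip(cons, tpl) if a != b)
        err = ham / len(tpl)
    else:
        import edlib

        err = edlib.align(cons, tpl, task="distance")["editDistance"] / len(tpl)
    cons_exact, _ = build_consensus([tpl] * 10, backend=backend)
    return {"error_rate": err, "exact_identity": cons_exact == tpl}


# ---------------------------------------------------------------------------
# telomere-length association


def _random_classes(rng, n_strains=54, ends_per_strain=32, p_long=0.3):
    classes = {}
    for s in range(n_strains):
        strain = f"strain{s:02d}"
        for c in range(ends_per_strain // 2):
            for side in ("L", "R"):
                ext = extremity_name(f"chr{c + 1:02d}", side)
                classes[(strain, ext)] = "long" if rng.random() < p_long else None
    return classes


def evaluate_association_power(
    n_reps: int = 500, seed: int = 0, effect: float = 0.064
):
    """Power of the two-tailed t-test for a class-specific shortening
    effect at catalog scale (54 strains x 32 extremities); also the fraction of
    reps whose estimated effect is within 2 points of the planted one."""
    rng = np.random.default_rng(seed)
    spec = SimulationSpec(telomere_effects={"long": effect})
    rejections = 0
    effect_ok = 0
    for _ in range(n_reps):
        classes = _random_classes(rng)
        table = draw_length_table(classes, spec, rng)
        ext_classes = {k: (v if v else "no_yprime") for k, v in classes.items()}
        results = telomere_association(table, ext_classes)
        res = [r for r in results if r.comparison == "long vs no_yprime"][0]
        if res.p_value < 0.05:
            rejections += 1
        if abs(res.effect - effect) <= 0.02:
            effect_ok += 1
    return {
        "power": rejections / n_reps,
        "effect_within_2pts": effect_ok / n_reps,
        "n_reps": n_reps,
    }


def evaluate_association_null(n_reps: int = 1000, seed: int = 0):
    rng = np.random.default_rng(seed)
    spec = SimulationSpec()
    rejections = 0
    for _ in range(n_reps):
        classes = _random_classes(rng)
        table = draw_length_table(classes, spec, rng)
        ext_classes = {k: (v if v else "no_yprime") for k, v in classes.items()}
        results = telomere_association(table, ext_classes)
        res = [r for r in results if r.comparison == "long vs no_yprime"][0]
        if res.p_value < 0.05:
            rejections += 1
    return {"rejection_rate": rejections / n_reps, "n_reps": n_reps}


def evaluate_spearman_recovery(seed: int = 0, per_copy: float = 0.01):
    """Planted monotone copy-number -> strain mean length relation."""
    rng = np.random.default_rng(seed)
    classes = {}
    factors = {}
    for s in range(54):
        strain = f"strain{s:02d}"
        n_ca = int(rng.integers(0, 8))
        placed = 0
        for c in range(16):
            for side in ("L", "R"):
                ext = extremity_name(f"chr{c + 1:02d}", side)
                if placed < n_ca:
                    classes[(strain, ext)] = "ca_rich_a"
                    placed += 1
                else:
                    classes[(strain, ext)] = None
        factors[strain] = 1.0 + per_copy * n_ca
    spec = SimulationSpec()
    table = draw_length_table(classes, spec, rng, factors)
    ext_classes = {k: (v if v else "no_yprime") for k, v in classes.items()}
    results = telomere_association(table, ext_classes)
    res = [r for r in results if r.test_name == "spearman"][0]
    return {"rho": res.effect, "p_value": res.p_value}


# ---------------------------------------------------------------------------
# telomere / ITS calling


def evaluate_telomere_calling(n_seeds: int = 100, base_seed: int = 0):
    cfg = PipelineConfig()
    term_total = term_found = 0
    its_total = its_found = 0
    boundary = []
    for i in range(n_seeds):
        spec = SimulationSpec(
            n_strains=1,
            contigs_per_strain=2,
            core_len=4000,
            x_placeholder_len=500,
            elements_per_end=(0.2, 0.4, 0.3, 0.1),
            seed=base_seed + i,
        )
        genomes, truth = simulate_genome(spec)
        calls = {
            (s, c): scan_contig(seq, c, cfg)
            for s, contigs in genomes.items()
            for c, seq in contigs.items()
        }
        for tel in truth.telomeres:
            term_total += 1
            key = (tel.strain, tel.interval.contig)
            for call in calls[key]:
                if call.kind == TERMINAL and call.interval.overlap(tel.interval) > 0:
                    term_found += 1
                    break
        for its in truth.its:
            its_total += 1
            key = (its.strain, its.interval.contig)
            for call in calls[key]:
                if (
                    call.kind == INTERSTITIAL
                    and call.interval.overlap(its.interval) > 0
                ):
                    its_found += 1
                    boundary.append(abs(call.interval.start - its.interval.start))
                    boundary.append(abs(call.interval.end - its.interval.end))
                    break
    return {
        "terminal_recall": term_found / term_total if term_total else 1.0,
        "its_recall": its_found / its_total if its_total else 1.0,
        "its_boundary_error": float(np.mean(boundary)) if boundary else 0.0,
        "n_terminal": term_total,
        "n_its": its_total,
    }


def evaluate_tract_discrimination(n_per_class: int = 1000, seed: int = 0, length: int = 200):
    """Telomeric vs CA-rich tract classification by structural motif-run
    coverage."""
    rng = np.random.default_rng(seed)
    errors = 0
    for _ in range(n_per_class):
        tel = telomere_tract(rng, length)
        if not is_telomeric_tract(tel):
            errors += 1
    for _ in range(n_per_class):
        ca = ca_stretch(rng, max(2, length // 36), 0.08)
        if is_telomeric_tract(ca):
            errors += 1
    return {
        "misclassification_rate": errors / (2 * n_per_class),
        "n": 2 * n_per_class,
    }
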