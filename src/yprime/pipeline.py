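"""End-to-end orchestration: telomere scan, self-repeat discovery,
database construction, element detection, repeat profiling, clustering,
ORF profiling and statistics, with deterministic file outputs.

Stage order and semantics follow the bottom-up procedure described in
docs/methods.md; every stage logs its counts to the run manifest so the
detection funnel is auditable.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .align import build_msa
from .cluster import (
    build_consensus,
    cluster_elements,
    recluster_ca_elements,
    similarity_from_msa,
    summarize_and_filter,
)
from .core import (
    AnnotationRecord,
    DegenerateInputError,
    GenomicInterval,
    InputError,
    PipelineConfig,
    FORWARD,
    REVERSE,
)
from .detect import (
    build_high_confidence_db,
    detect_elements,
    find_window_repeats,
    repeat_copy_intervals,
)
from .gff3 import write_gff3
from .motifs import default_mer36_db
from .orfs import find_orfs, orf_probability_profile
from .repeats import (
    build_pfm,
    detect_36mer_stretch,
    detect_ca_region,
    mask_stretches,
    refine_motif_db,
)
from .sequtil import read_fasta, write_fasta
from .simulate import build_templates, reference_entries
from .stats import (
    classify_its,
    extremity_classes,
    its_table,
    tabulate_distribution,
    telomere_association,
)
from .telomeres import calls_to_records, scan_contig

log = logging.getLogger("yprime")


@dataclass
class PipelineResult:
    config: PipelineConfig
    genomes: dict
    telomere_calls: dict
    database: object
    elements: list
    stretches: dict  # element_id -> [RepeatStretch]
    masked: dict  # element_id -> MaskedElement
    similarity: object | None
    solution: object | None
    labels: dict
    summaries: list
    consensi: dict
    orf_profiles: dict
    tables: dict
    association: list
    manifest: dict
    out_dir: Path | None = None


def _element_local_to_contig(element, start: int, end: int) -> GenomicInterval:
    iv = element.interval
    if iv.orientation == FORWARD:
        return GenomicInterval(iv.contig, iv.start + start, iv.start + end, FORWARD)
    return GenomicInterval(iv.contig, iv.end - end, iv.end - start, REVERSE)


def load_genomes(paths) -> dict:
    genomes = {}
    for path in paths:
        path = Path(path)
        strain = path.stem
        genomes[strain] = read_fasta(path)
        if not genomes[strain]:
            raise InputError(f"genome FASTA {path} is empty")
    if not genomes:
        raise InputError("at least one genome FASTA is required")
    return genomes


def run_pipeline(
    config: PipelineConfig,
    genome_paths=None,
    genomes: dict | None = None,
    reference_fasta=None,
    telomere_table=None,
    out_dir=None,
) -> PipelineResult:
    """Run every stage on the given strain FASTAs (or an in-memory genome
    dict {strain: {contig: seq}}) and, when ``out_dir`` is set, write the
    full set of deterministic outputs."""
    config.validate()
    if genomes is None:
        if not genome_paths:
            raise InputError("at least one genome FASTA is required")
        genomes = load_genomes(genome_paths)
    if not genomes:
        raise InputError("at least one genome is required")
    genomes = {
        s: {c: seq.upper() for c, seq in contigs.items()}
        for s, contigs in genomes.items()
    }
    manifest: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "n_strains": len(genomes),
        "n_contigs": sum(len(c) for c in genomes.values()),
    }

    # stage 1: telomeres
    calls = {}
    for strain in sorted(genomes):
        for contig in sorted(genomes[strain]):
            calls[(strain, contig)] = scan_contig(
                genomes[strain][contig], contig, config
            )
    manifest["telomere_calls"] = sum(len(v) for v in calls.values())
    log.info("telomere calls: %d", manifest["telomere_calls"])

    # stage 2: window self-repeats
    candidates = {}
    for (strain, contig), cl in sorted(calls.items()):
        hits = find_window_repeats(genomes[strain][contig], contig, config, cl)
        candidates[(strain, contig)] = repeat_copy_intervals(hits, contig)
    manifest["repeat_candidates"] = sum(len(v) for v in candidates.values())

    # stage 3: high-confidence database
    if reference_fasta is not None:
        reference = (
            dict(reference_fasta)
            if isinstance(reference_fasta, dict)
            else read_fasta(reference_fasta)
        )
    else:
        reference = reference_entries(build_templates(config.seed))
    db = build_high_confidence_db(candidates, genomes, reference, calls, config)
    manifest["db_entries"] = len(db)
    manifest["db_window_entries"] = sum(
        1 for e in db.entries if e[2] == "window_repeat"
    )
    log.info("database: %d entries (%d from window repeats)", len(db), manifest["db_window_entries"])

    # stage 4: detection
    funnel: dict = {}
    elements = detect_elements(db, genomes, calls, config, funnel)
    manifest["funnel"] = funnel
    usable = [e for e in elements if not e.edge_truncated]
    manifest["elements_total"] = len(elements)
    manifest["elements_usable"] = len(usable)
    log.info(
        "elements: %d detected, %d edge-truncated excluded",
        len(elements),
        len(elements) - len(usable),
    )

    # stage 5: repeat profiling (two-pass 36-mer scan, then CA regions)
    seed_db = default_mer36_db()
    oriented = {e.element_id: e.oriented_sequence for e in usable}
    refined_db = refine_motif_db(
        list(oriented.values()),
        seed_db,
        peak_spacing=config.peak_spacing,
        peak_threshold=config.peak_threshold,
    )
    stretches: dict = {}
    masked: dict = {}
    units_pool = []
    for eid in sorted(oriented):
        seq = oriented[eid]
        found = []
        mer = detect_36mer_stretch(
            seq,
            refined_db,
            element_id=eid,
            peak_spacing=config.peak_spacing,
            peak_threshold=config.peak_threshold,
        )
        if mer is not None:
            found.append(mer)
            units_pool.extend(mer.units)
        ca = detect_ca_region(
            seq, window=config.ca_window, min_len=config.ca_min_len, element_id=eid
        )
        if ca is not None and not any(
            not (ca.end <= s.start or ca.start >= s.end) for s in found
        ):
            found.append(ca)
        stretches[eid] = found
        masked[eid] = mask_stretches(seq, found, element_id=eid)
    manifest["elements_with_36mer"] = sum(
        1 for v in stretches.values() if any(s.stretch_class == "mer36" for s in v)
    )
    manifest["elements_with_ca"] = sum(
        1 for v in stretches.values() if any(s.stretch_class == "ca_rich" for s in v)
    )

    # stage 6: clustering on 36-mer-masked sequences
    similarity = None
    solution = None
    labels: dict = {}
    summaries = []
    consensi: dict = {}
    orf_profiles: dict = {}
    mer_masked = {}
    for eid in sorted(oriented):
        mer_only = [s for s in stretches[eid] if s.stretch_class == "mer36"]
        mer_masked[eid] = mask_stretches(oriented[eid], mer_only, eid).masked_sequence
    if len(mer_masked) >= 3:
        ids = sorted(mer_masked)
        msa = build_msa(
            [mer_masked[i] for i in ids], ids=ids, backend=config.msa_backend
        )
        similarity = similarity_from_msa(msa)
        try:
            solution = cluster_elements(similarity, config.k_min, config.k_max)
            labels = dict(solution.labels)
        except DegenerateInputError:
            log.warning("degenerate similarity matrix; clustering skipped")
            labels = {eid: "C1" for eid in ids}
        # CA re-clustering on CA-masked sequences
        ca_masked = {}
        for eid in ids:
            if any(s.stretch_class == "ca_rich" for s in stretches[eid]):
                ca_masked[eid] = masked[eid].masked_sequence
        labels = recluster_ca_elements(
            labels,
            ca_masked,
            k_min=config.k_min,
            k_max=config.k_max,
            backend=config.msa_backend,
        )
        strain_of = {e.element_id: e.strain for e in usable}
        if similarity is not None:
            summaries = summarize_and_filter(
                labels,
                strain_of,
                similarity,
                min_size=config.cluster_min_size,
                heterogeneity_max=config.heterogeneity_max,
            )
        manifest["clusters_total"] = len(summaries)
        manifest["clusters_retained"] = sum(1 for s in summaries if s.retained)
        log.info(
            "clusters: %d total, %d retained",
            manifest.get("clusters_total", 0),
            manifest.get("clusters_retained", 0),
        )
        # consensus + ORF profile per retained cluster
        members_by_cluster: dict = {}
        for eid, cid in labels.items():
            members_by_cluster.setdefault(cid, []).append(eid)
        for summary in summaries:
            members = sorted(members_by_cluster.get(summary.cluster_id, []))
            if not summary.retained or len(members) < 2:
                continue
            seqs = [mer_masked[m] for m in members]
            cons, cov = build_consensus(seqs, backend=config.msa_backend)
            summary.consensus = cons
            summary.coverage = cov
            consensi[summary.cluster_id] = cons
            cmsa = build_msa(seqs, ids=members, backend=config.msa_backend)
            orf_profiles[summary.cluster_id] = orf_probability_profile(
                members, cmsa, config.orf_min_len, cluster_id=summary.cluster_id
            )
    for el in usable:
        el.cluster = labels.get(el.element_id)

    # stage 7: statistics
    contig_lengths = {
        s: {c: len(seq) for c, seq in contigs.items()}
        for s, contigs in genomes.items()
    }
    tables = tabulate_distribution(usable, labels, contig_lengths)
    its_records = classify_its(calls, usable, config.association_window)
    tables["its"] = its_table(its_records)
    association = []
    if telomere_table is not None:
        table = (
            telomere_table
            if isinstance(telomere_table, pd.DataFrame)
            else pd.read_csv(telomere_table, sep="\t")
        )
        table = table[~table["strain"].isin(config.excluded_strains)]
        classes = extremity_classes(usable, labels, contig_lengths)
        association = telomere_association(
            table, classes, equal_var=config.equal_variance_ttest
        )

    result = PipelineResult(
        config=config,
        genomes=genomes,
        telomere_calls=calls,
        database=db,
        elements=elements,
        stretches=stretches,
        masked=masked,
        similarity=similarity,
        solution=solution,
        labels=labels,
        summaries=summaries,
        consensi=consensi,
        orf_profiles=orf_profiles,
        tables=tables,
        association=association,
        manifest=manifest,
        out_dir=Path(out_dir) if out_dir else None,
    )
    if out_dir:
        write_outputs(result, Path(out_dir), units_pool)
    return result


# ---------------------------------------------------------------------------
# output writers


def element_records(result: PipelineResult):
    """All annotation records (per strain) for GFF3 emission."""
    per_strain: dict = {s: [] for s in result.genomes}
    for (strain, _contig), calls in sorted(result.telomere_calls.items()):
        per_strain[strain].extend(calls_to_records(calls))
    for el in sorted(result.elements, key=lambda e: (e.strain, e.interval)):
        attrs = {
            "ID": el.element_id,
            "length": str(el.length),
            "telomere_flanked": el.telomere_flanked,
            "edge_truncated": str(el.edge_truncated).lower(),
        }
        if el.cluster:
            attrs["cluster"] = el.cluster
        per_strain[el.strain].append(
            AnnotationRecord(el.interval, "yprime", attrs)
        )
        if el.edge_truncated:
            continue
        for stretch in result.stretches.get(el.element_id, []):
            iv = _element_local_to_contig(el, stretch.start, stretch.end)
            per_strain[el.strain].append(
                AnnotationRecord(
                    iv,
                    "stretch_36mer" if stretch.stretch_class == "mer36" else "stretch_ca",
                    {
                        "ID": f"{el.element_id}.{stretch.stretch_class}",
                        "element": el.element_id,
                        "unit_count": str(stretch.unit_count),
                    },
                )
            )
        for orf in find_orfs(el.oriented_sequence, result.config.orf_min_len, el.element_id):
            iv = _element_local_to_contig(el, orf.start, orf.end)
            per_strain[el.strain].append(
                AnnotationRecord(
                    iv,
                    "orf",
                    {
                        "ID": f"{el.element_id}.orf{orf.frame}.{orf.start}",
                        "element": el.element_id,
                        "frame": str(orf.frame),
                    },
                )
            )
    for strain in per_strain:
        per_strain[strain].sort(
            key=lambda r: (r.interval.contig, r.interval.start, r.feature_class)
        )
    return per_strain


def write_outputs(result: PipelineResult, out_dir: Path, units_pool=None) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    records = element_records(result)
    for strain, recs in sorted(records.items()):
        write_gff3(recs, out_dir / f"{strain}.annotations.gff3")
    usable = [e for e in result.elements if not e.edge_truncated]
    write_fasta(
        {e.element_id: e.oriented_sequence for e in sorted(usable, key=lambda e: e.element_id)},
        out_dir / "elements.fasta",
    )
    write_fasta(
        {eid: m.masked_sequence for eid, m in sorted(result.masked.items())},
        out_dir / "elements.masked.fasta",
    )
    write_fasta(
        {eid: seq for eid, seq, _ in result.database.entries},
        out_dir / "yprime_db.fasta",
    )
    if result.similarity is not None:
        pd.DataFrame(
            result.similarity.matrix,
            index=result.similarity.ids,
            columns=result.similarity.ids,
        ).round(4).to_csv(out_dir / "similarity.tsv", sep="\t")
    if result.solution is not None:
        pd.DataFrame(result.solution.curve, columns=["k", "silhouette"]).round(
            6
        ).to_csv(out_dir / "silhouette_curve.tsv", sep="\t", index=False)
    if result.labels:
        retained_ids = {s.cluster_id for s in result.summaries if s.retained}
        pd.DataFrame(
            [
                {
                    "element_id": eid,
                    "cluster": cid,
                    "retained": cid in retained_ids,
                }
                for eid, cid in sorted(result.labels.items())
            ]
        ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False)
    if result.summaries:
        pd.DataFrame(
            [
                {
                    "cluster": s.cluster_id,
                    "size": s.size,
                    "n_strains": len(s.strains),
                    "mean_intra_similarity": round(s.mean_intra_similarity, 4),
                    "heterogeneity": round(s.heterogeneity, 4),
                    "retained": s.retained,
                }
                for s in result.summaries
            ]
        ).to_csv(out_dir / "cluster_summary.tsv", sep="\t", index=False)
    if result.consensi:
        write_fasta(dict(sorted(result.consensi.items())), out_dir / "consensi.fasta")
    if result.orf_profiles:
        rows = []
        for cid, prof in sorted(result.orf_profiles.items()):
            for col, val in enumerate(prof.values):
                rows.append({"cluster": cid, "column": col, "fraction": round(float(val), 6)})
        pd.DataFrame(rows).to_csv(out_dir / "orf_profiles.tsv", sep="\t", index=False)
    if units_pool:
        pfm = build_pfm(units_pool)
        pfm.round(6).to_csv(out_dir / "mer36_pfm.tsv", sep="\t")
    for name, df in sorted(result.tables.items()):
        df.to_csv(out_dir / f"stats_{name}.tsv", sep="\t", index=False)
    if result.association:
        pd.DataFrame(
            [
                {
                    "comparison": r.comparison,
                    "n1": r.group_sizes[0],
                    "n2": r.group_sizes[1],
                    "effect": round(r.effect, 6) if r.effect == r.effect else "",
                    "statistic": round(r.statistic, 6) if r.statistic == r.statistic else "",
                    "p_value": r.p_value,
                    "test": r.test_name,
                }
                for r in result.association
            ]
        ).to_csv(out_dir / "associations.tsv", sep="\t", index=False)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
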