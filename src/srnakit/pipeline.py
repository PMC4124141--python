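"""End-to-end orchestration: simulate -> preprocess -> map -> miRNA -> phased
siRNA -> nat-siRNA -> quantify -> DE -> anti-correlated pairing.

Each stage writes its tabular outputs under the configured output
directory; the run log records every configuration key actually used, and
``summary.json`` holds candidate counts per class.  A stage failure aborts
the run with the stage name and cause.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from ._seq import to_dna
from .config import PipelineConfig
from .cisnat import call_nat_sirna, find_cis_nat_pairs, write_overlap_bed, write_pair_table
from .expression import (
    LibraryStats,
    call_de_mrna,
    call_de_sncrna,
    comparisons_for,
    normalize_sncrna,
    pair_anticorrelated,
    predict_sirna_targets,
    quantify_mrna,
    write_anticorrelated_edges,
    write_de_table,
)
from .gff import FeatureLine, parse_gff3, write_feature_gff3
from .mapping import AlignmentStore, ReferenceIndex, map_collapsed, write_alignment_table
from .mirna import discover_mirnas, read_known_mirnas, reannotate_known, write_candidate_table
from .phasing import (
    PhasCandidateLocus,
    cluster_21nt_loci,
    compute_phasing,
    detect_shifted_register,
    filter_candidates,
    region_interval,
    scan_target_sites,
    write_locus_table,
    write_register_histogram,
)
from .preprocess import process_fastq, write_collapsed_fasta, write_qc_report
from .simulate import SimulationSpec, generate_reference, simulate_libraries, transcript_sequences


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    outdir: Path
    summary: dict = field(default_factory=dict)
    mirna_candidates: list = field(default_factory=list)
    phas_loci: list = field(default_factory=list)
    cisnat_pairs: list = field(default_factory=list)
    natsirna_calls: dict = field(default_factory=dict)
    de_calls: list = field(default_factory=list)
    anticorrelated: list = field(default_factory=list)
    truth_path: Path | None = None


def _read_fasta_dict(path) -> dict[str, str]:
    return {rec.id: to_dna(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    for key, value in sorted(config.to_dict().items()):
        log_lines.append(f"config {key} = {value!r}")
    result = PipelineResult(outdir=outdir)

    # ------------------------------------------------------------- simulate
    try:
        if config.simulate:
            spec = SimulationSpec(
                seed=config.seed,
                conditions=tuple(config.conditions),
                adapter_sequence=config.adapter_sequence,
                **config.simulation_overrides,
            )
            genome, annotation, truth = generate_reference(spec)
            bundle = simulate_libraries(genome, annotation, truth, spec, outdir / "sim")
            fastqs = {c: bundle.fastq_paths[c] for c in config.conditions}
            mrna_counts_path = bundle.mrna_counts_path
            result.truth_path = bundle.truth_path
        else:
            genome = _read_fasta_dict(config.genome_fasta)
            annotation = parse_gff3(config.annotation_gff3)
            fastqs = {c: Path(p) for c, p in config.fastq_by_condition.items()}
            mrna_counts_path = config.mrna_counts_tsv
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    # ----------------------------------------------------------- preprocess
    try:
        collapsed_all = []
        reports = []
        for cond, path in fastqs.items():
            collapsed, report = process_fastq(
                path,
                config.adapter_sequence,
                library_id=cond,
                min_match=config.adapter_min_match,
                min_quality=config.min_quality,
            )
            collapsed_all.extend(collapsed)
            reports.append(report)
            write_collapsed_fasta(collapsed, outdir / f"collapsed_{cond}.fasta")
            log_lines.append(
                f"preprocess {cond}: raw={report.raw_reads} qualified={report.qualified_reads}"
            )
        write_qc_report(reports, outdir / "qc_report.tsv")
    except Exception as exc:
        raise StageError("preprocess", exc) from exc

    # ------------------------------------------------------------------ map
    try:
        index = ReferenceIndex(genome)
        alignments = map_collapsed(collapsed_all, index, max_mismatches=config.max_mismatches)
        write_alignment_table(alignments, outdir / "alignments.tsv")
        aligned_totals: dict[str, float] = defaultdict(float)
        seen: set[tuple[str, str]] = set()
        for a in alignments:
            key = (a.sequence, a.library_id)
            if key not in seen:
                seen.add(key)
                aligned_totals[a.library_id] += a.count
        exact = [a for a in alignments if a.mismatches == 0]
        log_lines.append(f"map: {len(alignments)} placements, {len(exact)} exact")
    except Exception as exc:
        raise StageError("map", exc) from exc

    # ---------------------------------------------------------------- mirna
    try:
        if config.known_mirna_fasta:
            known = read_known_mirnas(config.known_mirna_fasta)
            known_table, leftover = reannotate_known(known, collapsed_all)
            pd.DataFrame(known_table).T.fillna(0).astype(int).to_csv(
                outdir / "known_mirna_counts.tsv", sep="\t"
            )
            leftover_seqs = {(r.sequence, r.library_id) for r in leftover}
            discovery_alns = [a for a in exact if (a.sequence, a.library_id) in leftover_seqs]
        else:
            discovery_alns = exact
        candidates, rejections = discover_mirnas(
            discovery_alns,
            genome,
            min_reads=config.mirna_min_reads,
            min_mature_paired=config.min_mature_paired,
            max_bulge=config.max_duplex_bulge,
            extension=config.window_extension,
            window=config.window_size,
            step=config.window_step,
        )
        write_candidate_table(candidates, outdir / "mirna_candidates.tsv")
        gff_feats = []
        for i, c in enumerate(candidates, start=1):
            gff_feats.append(
                FeatureLine(c.contig, "miRNA_primary_transcript", c.hairpin_start, c.hairpin_end, c.strand,
                            {"ID": f"cand{i}"})
            )
            gff_feats.append(
                FeatureLine(c.contig, "miRNA", c.mature_start, c.mature_end, c.strand,
                            {"ID": f"cand{i}.mature", "Parent": f"cand{i}"})
            )
        write_feature_gff3(gff_feats, outdir / "mirna_candidates.gff3")
        log_lines.append(f"mirna: {len(candidates)} candidates, {len(rejections)} rejected clusters")
    except Exception as exc:
        raise StageError("mirna", exc) from exc

    # ----------------------------------------------------------------- phas
    try:
        hairpins = [(c.contig, c.hairpin_start, c.hairpin_end) for c in candidates]

        def in_mirna_locus(a) -> bool:
            return any(ct == a.contig and a.start < e and a.end > s for ct, s, e in hairpins)

        # reads aligned to miRNA loci are removed first: a read with *any*
        # placement inside a hairpin locus is excluded entirely (its other
        # placements are miRNA sequence re-occurrences, e.g. trigger sites)
        mirna_read_seqs = {a.sequence for a in exact if in_mirna_locus(a)}
        phas_input = [a for a in exact if a.sequence not in mirna_read_seqs]
        store_exact = AlignmentStore(exact)
        store_phas = AlignmentStore(phas_input)
        regions = cluster_21nt_loci(phas_input, window=config.phas_cluster_window)
        triggers = {f"cand{i}": c.mature_seq.replace("U", "T") for i, c in enumerate(candidates, start=1)}
        loci = []
        hist_dir = outdir / "register_histograms"
        for ri, region in enumerate(regions, start=1):
            passes, metrics = filter_candidates(
                region, min_reads=config.phas_min_reads, min_fraction_21nt=config.phas_min_fraction_21nt
            )
            if not passes:
                continue
            contig, r0, r1 = region_interval(region)
            pad = 40
            w0, w1 = max(0, r0 - pad), min(len(genome[contig]), r1 + pad)
            window_seq = genome[contig][w0:w1]
            sites = []
            for tid, tseq in triggers.items():
                for site in scan_target_sites(
                    tseq,
                    window_seq,
                    srna_id=tid,
                    transcript_id=contig,
                    threshold=config.target_score_threshold,
                    comparator=config.target_score_comparator,
                ):
                    site.start += w0
                    site.end += w0
                    site.cleavage += w0
                    sites.append(site)
            sites.sort(key=lambda s: (s.score, s.start))
            locus = PhasCandidateLocus(
                locus_id=f"PHAS-{ri}",
                contig=contig,
                start=r0,
                end=r1,
                total_reads=int(metrics["total_reads"]),
                fraction_21nt=metrics["fraction_21nt"],
                passes_filter=passes,
            )
            if sites:
                by_pos = sorted(sites, key=lambda s: s.start)
                site5, site3 = by_pos[0], by_pos[-1]
                if site3.start >= site5.end:
                    locus.trigger_sites = [site5, site3]
                    c5, c3 = site5.cleavage, site3.cleavage
                else:
                    locus.trigger_sites = [site5]
                    c5, c3 = site5.cleavage, None
                locus.cleavage_positions = [c for c in (c5, c3) if c is not None]
                hist, frac, names = compute_phasing(region, c5, c3)
                locus.histogram = hist
                locus.phased_fraction = frac
                locus.register_names = names
                flagged, sfrac = detect_shifted_register(
                    hist, min_fraction=config.shifted_register_min_fraction
                )
                locus.shifted_flagged = flagged
                locus.shifted_fraction = sfrac
                hist_dir.mkdir(exist_ok=True)
                write_register_histogram(locus, hist_dir / f"{locus.locus_id}.tsv")
            loci.append(locus)
        write_locus_table(loci, outdir / "phas_loci.tsv")
        log_lines.append(f"phas: {len(loci)} passing loci of {len(regions)} regions")
    except Exception as exc:
        raise StageError("phas", exc) from exc

    # ------------------------------------------------------------- natsirna
    try:
        pairs = find_cis_nat_pairs(annotation, min_overlap=config.cisnat_min_overlap)
        calls = {
            p.pair_id: call_nat_sirna(
                p,
                store_exact,
                min_reads=config.natsirna_min_reads,
                enrichment_fraction=config.natsirna_enrichment_fraction,
            )
            for p in pairs
        }
        write_pair_table(pairs, calls, outdir / "cisnat_pairs.tsv")
        write_overlap_bed(pairs, outdir / "cisnat_overlaps.bed")
        log_lines.append(
            f"natsirna: {len(pairs)} cis-NAT pairs, {sum(c.passes for c in calls.values())} nat-siRNA calls"
        )
    except Exception as exc:
        raise StageError("natsirna", exc) from exc

    # ------------------------------------------------------------- quantify
    try:
        conditions = list(config.conditions)
        lib_stats = LibraryStats(totals={c: aligned_totals.get(c, 1.0) for c in conditions})
        counts_by_lib: dict[str, dict[str, float]] = defaultdict(lambda: {c: 0.0 for c in conditions})
        mature_by_seq: dict[str, str] = {}
        for i, cand in enumerate(candidates, start=1):
            cid = f"cand{i}"
            mature_by_seq.setdefault(cand.mature_seq.replace("U", "T"), cid)
        for read in collapsed_all:
            cid = mature_by_seq.get(read.sequence)
            if cid is not None and read.library_id in counts_by_lib[cid]:
                counts_by_lib[cid][read.library_id] += read.count
        for locus in loci:
            for a in store_phas.within(locus.contig, locus.start, locus.end):
                if a.library_id in conditions:
                    counts_by_lib[locus.locus_id][a.library_id] += a.count
        for p in pairs:
            for a in store_exact.within(p.contig, p.overlap_start, p.overlap_end):
                if a.library_id in conditions:
                    counts_by_lib[p.pair_id][a.library_id] += a.count
        raw = pd.DataFrame(counts_by_lib).T.reindex(columns=conditions).fillna(0.0)
        raw.to_csv(outdir / "sncrna_counts.tsv", sep="\t")
        normalized = normalize_sncrna(raw, lib_stats)
        normalized.to_csv(outdir / "sncrna_normalized.tsv", sep="\t")
    except Exception as exc:
        raise StageError("quantify", exc) from exc

    # ------------------------------------------------------------------- de
    try:
        comparisons = comparisons_for(conditions)
        mirna_ids = [f"cand{i}" for i in range(1, len(candidates) + 1) if f"cand{i}" in normalized.index]
        phas_ids = [l.locus_id for l in loci]
        nat_ids = [p.pair_id for p in pairs if calls[p.pair_id].passes]
        de_calls = []
        de_calls += call_de_sncrna(
            normalized.loc[[i for i in mirna_ids if i in normalized.index]],
            "miRNA", comparisons, threshold=config.mirna_fold_threshold,
            pseudocount=config.sncrna_pseudocount,
        )
        de_calls += call_de_sncrna(
            normalized.loc[[i for i in phas_ids if i in normalized.index]],
            "siRNA-locus", comparisons, threshold=config.sirna_fold_threshold,
            pseudocount=config.sncrna_pseudocount,
        )
        de_calls += call_de_sncrna(
            normalized.loc[[i for i in nat_ids if i in normalized.index]],
            "nat-siRNA", comparisons, threshold=config.sirna_fold_threshold,
            pseudocount=config.sncrna_pseudocount,
        )
        mrna_expr = None
        de_mrna = []
        if mrna_counts_path is not None:
            mrna_counts = pd.read_csv(mrna_counts_path, sep="\t", index_col=0)
            mrna_expr = quantify_mrna(mrna_counts, expression_cpm=config.expression_cpm)
            de_mrna = call_de_mrna(
                mrna_expr,
                comparisons,
                fold_threshold=config.mrna_fold_threshold,
                onoff_cpm=config.onoff_cpm,
                expression_cpm=config.expression_cpm,
            )
        write_de_table(de_calls + de_mrna, outdir / "de_calls.tsv")
    except Exception as exc:
        raise StageError("de", exc) from exc

    # ----------------------------------------------------------------- pair
    try:
        anticorr = []
        if mrna_expr is not None:
            transcripts = transcript_sequences(genome, annotation)
            links: set[tuple[str, str]] = set()
            # siRNA targets: distinct locus reads above the read floor
            for locus in loci:
                seq_counts: dict[str, int] = defaultdict(int)
                for a in store_phas.within(locus.contig, locus.start, locus.end):
                    seq_counts[a.sequence] += a.count
                srnas = {f"{locus.locus_id}:{s}": s for s, n in seq_counts.items() if n > config.target_min_reads}
                for t in predict_sirna_targets(
                    srnas, transcripts, max_mismatches=config.target_max_mismatches, min_reads=0
                ):
                    links.add((locus.locus_id, t.transcript_id))
            for p in pairs:
                if not calls[p.pair_id].passes:
                    continue
                # a nat-siRNA's presumptive targets are the two overlapping genes
                links.add((p.pair_id, p.gene_plus.gene_id))
                links.add((p.pair_id, p.gene_minus.gene_id))
            for i, cand in enumerate(candidates, start=1):
                mature = cand.mature_seq.replace("U", "T")
                for tid, tseq in transcripts.items():
                    if scan_target_sites(mature, tseq, threshold=config.target_score_threshold,
                                         comparator=config.target_score_comparator):
                        links.add((f"cand{i}", tid))
            anticorr = pair_anticorrelated(
                de_calls, de_mrna, links,
                min_target_fold=config.anticorrelation_min_target_fold,
            )
            write_anticorrelated_edges(anticorr, outdir / "anticorrelated_pairs.tsv")
    except Exception as exc:
        raise StageError("pair", exc) from exc

    # -------------------------------------------------------------- summary
    de_features = {c.feature_class: set() for c in de_calls + de_mrna}
    for c in de_calls + de_mrna:
        de_features[c.feature_class].add(c.feature_id)
    summary = {
        "libraries": {r.library_id: {"raw": r.raw_reads, "qualified": r.qualified_reads} for r in reports},
        "mirna_candidates": len(candidates),
        "phas_loci_passing": len(loci),
        "cisnat_pairs": len(pairs),
        "cisnat_orientations": {
            o: sum(p.orientation == o for p in pairs) for o in ("convergent", "divergent", "enclosed")
        },
        "natsirna_calls": sum(c.passes for c in calls.values()),
        "de_features_per_class": {k: len(v) for k, v in sorted(de_features.items())},
        "anticorrelated_pairs": len(anticorr),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    with open(outdir / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    result.summary = summary
    result.mirna_candidates = candidates
    result.phas_loci = loci
    result.cisnat_pairs = pairs
    result.natsirna_calls = calls
    result.de_calls = de_calls + de_mrna
    result.anticorrelated = anticorr
    return result
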