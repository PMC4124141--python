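"""Recovery metrics against planted ground truth.

These helpers compare a pipeline run with the :class:`PlantedTruth` that
generated its input: locus-level precision/recall for miRNA discovery,
filter recovery for TAS-like loci, orientation accuracy for cis-NAT
pairs, and recall/false-positive rate for the rule-based DE calls.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pipeline import PipelineResult
from .simulate import PlantedTruth


@dataclass
class MirnaRecovery:
    recall: float
    precision: float
    n_planted: int
    n_candidate_loci: int


def _group_candidate_loci(candidates) -> list[list]:
    """Group mature/star candidate records that share a hairpin locus."""
    groups: list[list] = []
    for c in sorted(candidates, key=lambda c: (c.contig, c.hairpin_start)):
        for g in groups:
            ref = g[0]
            if ref.contig == c.contig and c.hairpin_start < ref.hairpin_end and c.hairpin_end > ref.hairpin_start:
                g.append(c)
                break
        else:
            groups.append([c])
    return groups


def mirna_recovery(result: PipelineResult, truth: PlantedTruth, tolerance: int = 3) -> MirnaRecovery:
    """Locus-level recall and precision of hairpin discovery.

    A candidate locus matches a planted hairpin when one of its reported
    mature intervals coincides (within ``tolerance`` nt) with the planted
    mature or star arm.
    """
    planted = []
    for r in truth.mirna_records:
        planted.append((r.feature_id, r.contig, r.mature_start, r.mature_end))
        planted.append((r.feature_id, r.contig, r.star_start, r.star_end))
    groups = _group_candidate_loci(result.mirna_candidates)
    matched: set[str] = set()
    true_groups = 0
    for g in groups:
        hit = None
        for c in g:
            for fid, contig, s, e in planted:
                if (
                    c.contig == contig
                    and abs(c.mature_start - s) <= tolerance
                    and abs(c.mature_end - e) <= tolerance
                ):
                    hit = fid
        if hit is not None:
            matched.add(hit)
            true_groups += 1
    n_planted = len(truth.mirna_records)
    recall = len(matched) / n_planted if n_planted else 1.0
    precision = true_groups / len(groups) if groups else 1.0
    return MirnaRecovery(recall=recall, precision=precision, n_planted=n_planted, n_candidate_loci=len(groups))


def tas_filter_recovery(result: PipelineResult, truth: PlantedTruth) -> float:
    """Fraction of planted TAS loci covered by a passing phased-siRNA locus."""
    if not truth.tas_records:
        return 1.0
    hit = 0
    for r in truth.tas_records:
        for l in result.phas_loci:
            if l.contig == r.contig and l.start < r.locus_end and l.end > r.locus_start and l.passes_filter:
                hit += 1
                break
    return hit / len(truth.tas_records)


def phas_locus_for(result: PipelineResult, contig: str, start: int, end: int):
    for l in result.phas_loci:
        if l.contig == contig and l.start < end and l.end > start:
            return l
    return None


def cisnat_orientation_accuracy(result: PipelineResult, truth: PlantedTruth) -> float:
    """Fraction of planted cis-NAT pairs found with the planted orientation."""
    if not truth.cisnat_records:
        return 1.0
    by_genes = {frozenset((p.gene_plus.gene_id, p.gene_minus.gene_id)): p for p in result.cisnat_pairs}
    correct = 0
    for r in truth.cisnat_records:
        p = by_genes.get(frozenset((r.gene_a[0], r.gene_b[0])))
        if p is not None and p.orientation == r.orientation:
            correct += 1
    return correct / len(truth.cisnat_records)


@dataclass
class DERecovery:
    recall: float
    false_positive_rate: float
    n_true: int
    n_null: int


def de_recovery(result: PipelineResult, truth: PlantedTruth, min_expected: float = 50.0) -> DERecovery:
    """Recall and FPR of DE calls over planted features.

    Only features whose baseline expectation reaches ``min_expected`` reads
    (or mRNA mean counts) enter the contingency: shallower features carry
    too little information for a fold-change rule by construction.
    """
    called = {c.feature_id for c in result.de_calls}

    cand_for_mature = {}
    for i, c in enumerate(result.mirna_candidates, start=1):
        cand_for_mature.setdefault(c.mature_seq.replace("U", "T"), f"cand{i}")

    tp = fn = fp = tn = 0

    def tally(feature_id: str, result_id: str | None, base: float):
        nonlocal tp, fn, fp, tn
        if base < min_expected:
            return
        is_de = feature_id in truth.de_features
        is_called = result_id is not None and result_id in called
        if is_de:
            tp += is_called
            fn += not is_called
        else:
            fp += is_called
            tn += not is_called

    for r in truth.mirna_records:
        base = truth.expected_counts[r.feature_id]["NC"] / max(
            truth.fold_change_table.get(r.feature_id, {}).get("NC", 1.0), 1e-9
        )
        tally(r.feature_id, cand_for_mature.get(r.mature_seq), base)
    for r in truth.tas_records:
        locus = phas_locus_for(result, r.contig, r.locus_start, r.locus_end)
        tally(r.feature_id, locus.locus_id if locus else None, truth.expected_counts[r.feature_id]["NC"])
    for r in truth.cisnat_records:
        if not r.sirna_emitting:
            continue
        pair_id = f"{r.gene_a[0]}|{r.gene_b[0]}"
        tally(r.feature_id, pair_id, truth.expected_counts[r.feature_id]["NC"])
    for gid, mean in truth.mrna_base_means.items():
        if not gid.startswith("gene-"):
            continue  # TAS/NAT transcripts are tallied through their sRNA class
        tally(gid, gid, mean)

    n_true, n_null = tp + fn, fp + tn
    return DERecovery(
        recall=tp / n_true if n_true else 1.0,
        false_positive_rate=fp / n_null if n_null else 0.0,
        n_true=n_true,
        n_null=n_null,
    )
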