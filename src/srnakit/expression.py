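"""Quantification, normalization and rule-based differential expression.

sncRNA counts are scaled by N * C / T, where T is the library's
qualified genome/cDNA-aligned read total and C is the mean of T over all
libraries; after scaling every library totals C.  mRNA tag counts are
expressed as CPM (>= 10 CPM defines an expressed gene) and upper-quartile
normalized over expressed genes.  DE is deterministic and rule-based:
miRNAs at >= 1.5-fold, siRNA loci and nat-siRNAs at >= 2-fold, mRNAs at
>= 4-fold or the on-off rule (< 10 CPM in one condition, > 40 CPM in the
other).  siRNA targets are placements of the reverse complement with at
most three substitutions; anti-correlated sncRNA-target pairs require
opposite DE directions and a target change of at least 2-fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import mismatch_scan, revcomp

SIX_COMPARISONS = [
    ("CA", "NC"),
    ("CCA", "NC"),
    ("CS", "NC"),
    ("CCA", "CA"),
    ("CS", "CA"),
    ("CS", "CCA"),
]

CLASS_THRESHOLDS = {"miRNA": 1.5, "siRNA-locus": 2.0, "nat-siRNA": 2.0, "mRNA": 4.0}
# pseudocount for fold changes: one normalized unit for sncRNA classes, none
# for mRNA where the on-off rule already covers off-states
CLASS_PSEUDOCOUNT = {"miRNA": 1.0, "siRNA-locus": 1.0, "nat-siRNA": 1.0, "mRNA": 0.0}


@dataclass
class LibraryStats:
    totals: dict[str, float]  # library id -> T (qualified aligned reads)

    def __post_init__(self):
        for lib, t in self.totals.items():
            if t <= 0:
                raise ValueError(f"library {lib} has non-positive aligned total")

    @property
    def mean_total(self) -> float:  # C
        return float(np.mean(list(self.totals.values())))

    def scale(self, library: str) -> float:
        return self.mean_total / self.totals[library]


def normalize_sncrna(
    raw_counts: pd.DataFrame, stats: LibraryStats
) -> pd.DataFrame:
    """N * C / T scaling, column per library."""
    scaled = raw_counts.astype(float).copy()
    for lib in scaled.columns:
        scaled[lib] = scaled[lib] * stats.scale(lib)
    return scaled


@dataclass
class MrnaExpression:
    counts: pd.DataFrame
    cpm: pd.DataFrame
    expressed: pd.DataFrame  # boolean per gene x condition
    normalized: pd.DataFrame  # upper-quartile scaled CPM (expressed genes)
    uq_factors: dict[str, float]


def quantify_mrna(counts: pd.DataFrame, expression_cpm: float = 10.0) -> MrnaExpression:
    """CPM, expression calls and upper-quartile normalization of a tag-count table.

    A gene is expressed in a condition iff its CPM is at least
    ``expression_cpm``.  Per condition, the upper-quartile factor is the
    75th percentile of CPM over that condition's expressed genes; columns
    are scaled by mean(q)/q so their upper quartiles agree.
    """
    if counts.empty:
        raise ValueError("empty mRNA count table")
    counts = counts.astype(float)
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("mRNA count table has an empty condition column")
    cpm = counts * 1e6 / totals
    expressed = cpm >= expression_cpm
    quartiles = {}
    for cond in counts.columns:
        vals = cpm.loc[expressed[cond], cond]
        quartiles[cond] = float(np.percentile(vals, 75)) if len(vals) else np.nan
    mean_q = float(np.nanmean(list(quartiles.values())))
    uq_factors = {c: (mean_q / q if q and not np.isnan(q) else 1.0) for c, q in quartiles.items()}
    normalized = cpm.copy()
    for cond in normalized.columns:
        normalized[cond] = normalized[cond] * uq_factors[cond]
    return MrnaExpression(counts=counts, cpm=cpm, expressed=expressed, normalized=normalized, uq_factors=uq_factors)


@dataclass(frozen=True)
class DECall:
    feature_id: str
    feature_class: str
    comparison: tuple[str, str]  # (a, b): fold = a over b
    fold: float
    direction: str  # 'up' or 'down' (of a relative to b)
    rule: str  # 'fold-rule' or 'on-off'


def fold_change(a: float, b: float, pseudocount: float) -> float:
    return (a + pseudocount) / (b + pseudocount)


def call_de_sncrna(
    normalized: pd.DataFrame,
    feature_class: str,
    comparisons: Sequence[tuple[str, str]] = tuple(SIX_COMPARISONS),
    threshold: float | None = None,
    pseudocount: float | None = None,
) -> list[DECall]:
    """Fold-rule DE calls for a normalized sncRNA table (features x conditions)."""
    thr = CLASS_THRESHOLDS[feature_class] if threshold is None else threshold
    psi = CLASS_PSEUDOCOUNT[feature_class] if pseudocount is None else pseudocount
    calls = []
    for fid, row in normalized.iterrows():
        for a, b in comparisons:
            if a not in row.index or b not in row.index:
                continue
            fc = fold_change(row[a], row[b], psi)
            if fc >= thr:
                calls.append(DECall(fid, feature_class, (a, b), float(fc), "up", "fold-rule"))
            elif fc <= 1.0 / thr:
                calls.append(DECall(fid, feature_class, (a, b), float(fc), "down", "fold-rule"))
    return calls


def call_de_mrna(
    expr: MrnaExpression,
    comparisons: Sequence[tuple[str, str]] = tuple(SIX_COMPARISONS),
    fold_threshold: float = 4.0,
    onoff_cpm: float = 40.0,
    expression_cpm: float = 10.0,
) -> list[DECall]:
    """mRNA DE calls: the 4-fold rule on upper-quartile-normalized values of
    genes expressed in both conditions, or the on-off rule (not expressed on
    one side, > ``onoff_cpm`` CPM on the other)."""
    calls = []
    for gid in expr.counts.index:
        for a, b in comparisons:
            cpm_a, cpm_b = expr.cpm.at[gid, a], expr.cpm.at[gid, b]
            exp_a, exp_b = bool(expr.expressed.at[gid, a]), bool(expr.expressed.at[gid, b])
            if exp_a and exp_b:
                fc = fold_change(expr.normalized.at[gid, a], expr.normalized.at[gid, b], 0.0)
                if fc >= fold_threshold:
                    calls.append(DECall(gid, "mRNA", (a, b), float(fc), "up", "fold-rule"))
                elif fc <= 1.0 / fold_threshold:
                    calls.append(DECall(gid, "mRNA", (a, b), float(fc), "down", "fold-rule"))
            elif exp_a and not exp_b and cpm_a > onoff_cpm:
                fc = fold_change(cpm_a, cpm_b, 1.0)
                calls.append(DECall(gid, "mRNA", (a, b), float(fc), "up", "on-off"))
            elif exp_b and not exp_a and cpm_b > onoff_cpm:
                fc = fold_change(cpm_a, cpm_b, 1.0)
                calls.append(DECall(gid, "mRNA", (a, b), float(fc), "down", "on-off"))
    return calls


@dataclass(frozen=True)
class SirnaTarget:
    srna_sequence: str
    transcript_id: str
    start: int
    end: int
    mismatches: int


def predict_sirna_targets(
    srnas: Mapping[str, str] | Mapping[str, tuple[str, int]],
    transcripts: Mapping[str, str],
    max_mismatches: int = 3,
    min_reads: int = 10,
    read_counts: Mapping[str, int] | None = None,
) -> list[SirnaTarget]:
    """Placements of each siRNA's reverse complement on the cDNA set.

    ``srnas`` maps an id to the siRNA sequence; siRNAs below the read floor
    (more than ``min_reads`` reads, when counts are supplied) are skipped.
    All placements with at most ``max_mismatches`` substitutions are
    reported as putative targets.
    """
    targets = []
    for sid, seq in srnas.items():
        if read_counts is not None and read_counts.get(sid, 0) <= min_reads:
            continue
        probe = revcomp(seq)
        for tid, tseq in transcripts.items():
            for pos, mm in mismatch_scan(tseq, probe, max_mismatches):
                targets.append(
                    SirnaTarget(
                        srna_sequence=seq,
                        transcript_id=tid,
                        start=pos,
                        end=pos + len(probe),
                        mismatches=mm,
                    )
                )
    return targets


@dataclass(frozen=True)
class AnticorrelatedPair:
    sncrna_id: str
    target_id: str
    comparison: tuple[str, str]
    sncrna_direction: str
    target_direction: str
    sncrna_fold: float
    target_fold: float


def pair_anticorrelated(
    de_sncrnas: Iterable[DECall],
    de_mrnas: Iterable[DECall],
    target_links: Iterable[tuple[str, str]],
    min_target_fold: float = 2.0,
) -> list[AnticorrelatedPair]:
    """Anti-correlated (sncRNA, target) pairs for matching comparisons.

    ``target_links`` holds (sncRNA feature id, transcript id) edges from
    target prediction.  A pair is emitted when both members are DE in the
    same comparison with strictly opposite directions and the target's fold
    change magnitude is at least ``min_target_fold``.
    """
    links = set(target_links)
    mrna_by_key: dict[tuple[str, tuple[str, str]], DECall] = {}
    for call in de_mrnas:
        mrna_by_key[(call.feature_id, call.comparison)] = call
    pairs = []
    for s_call in de_sncrnas:
        for (sid, tid) in links:
            if sid != s_call.feature_id:
                continue
            t_call = mrna_by_key.get((tid, s_call.comparison))
            if t_call is None or t_call.direction == s_call.direction:
                continue
            magnitude = t_call.fold if t_call.fold >= 1 else 1.0 / t_call.fold
            if magnitude < min_target_fold:
                continue
            pairs.append(
                AnticorrelatedPair(
                    sncrna_id=sid,
                    target_id=tid,
                    comparison=s_call.comparison,
                    sncrna_direction=s_call.direction,
                    target_direction=t_call.direction,
                    sncrna_fold=s_call.fold,
                    target_fold=t_call.fold,
                )
            )
    pairs.sort(key=lambda p: (p.sncrna_id, p.target_id, p.comparison))
    return pairs


def comparisons_for(conditions: Sequence[str]) -> list[tuple[str, str]]:
    """The condition pairings used for DE: the canonical six for the NC/CA/
    CCA/CS design, otherwise all ordered-by-position pairs."""
    if set(conditions) >= {"NC", "CA", "CCA", "CS"}:
        return list(SIX_COMPARISONS)
    return [(b, a) for a, b in combinations(conditions, 2)]


def write_de_table(calls: Iterable[DECall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tclass\tcomparison\tfold\tdirection\trule\n")
        for c in calls:
            fh.write(
                f"{c.feature_id}\t{c.feature_class}\t{c.comparison[0]}/{c.comparison[1]}\t"
                f"{c.fold:.4f}\t{c.direction}\t{c.rule}\n"
            )


def write_anticorrelated_edges(pairs: Iterable[AnticorrelatedPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sncrna_id\ttarget_id\tcomparison\tsncrna_direction\ttarget_direction\tsncrna_fold\ttarget_fold\n")
        for p in pairs:
            fh.write(
                f"{p.sncrna_id}\t{p.target_id}\t{p.comparison[0]}/{p.comparison[1]}\t"
                f"{p.sncrna_direction}\t{p.target_direction}\t{p.sncrna_fold:.4f}\t{p.target_fold:.4f}\n"
            )


def read_count_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df
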