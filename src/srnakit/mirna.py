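"""Novel miRNA discovery from alignment clusters and known-miRNA re-annotation.

Discovery follows the classic hairpin-evaluation recipe: genome-aligned
reads are merged into clusters wherever they share overlapping intervals;
each cluster is extended 300 nt on both ends; 250-nt windows are slid
across the extension and folded; and a cluster is reported as a miRNA
locus when four criteria hold together: (i) more than ``min_reads`` reads,
(ii) a qualifying hairpin, (iii) a star read stack on the arm opposite the
dominant (mature) stack, and (iv) a mature/star duplex with ~2-nt 3'
overhangs at both ends under the fold's pairing.

Folding is pluggable: the in-repo engine is a maximum-weight nested-pairing
dynamic program (Watson-Crick + G:U, minimum loop 3); when the ViennaRNA
Python bindings are importable the default engine delegates to RNAfold MFE
structure prediction behind the same ``FoldResult`` contract.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._seq import revcomp, to_dna, to_rna
from .mapping import Alignment, AlignmentStore
from .preprocess import CollapsedRead

try:  # optional plug-in folding engine (the conventional RNA-folding tool)
    import RNA as _vienna
except ImportError:  # pragma: no cover - bindings present in supported envs
    _vienna = None

PAIR_WEIGHTS = {
    ("G", "C"): 3,
    ("C", "G"): 3,
    ("A", "T"): 2,
    ("T", "A"): 2,
    ("G", "T"): 1,
    ("T", "G"): 1,
}
MIN_LOOP = 3


@dataclass
class FoldResult:
    sequence: str
    pairs: tuple[int, ...]  # pairs[i] = partner index, or -1 if unpaired

    @property
    def paired_fraction(self) -> float:
        return sum(p >= 0 for p in self.pairs) / len(self.pairs)

    def n_pairs(self) -> int:
        return sum(p >= 0 for p in self.pairs) // 2


def nussinov_fold(sequence: str) -> FoldResult:
    """Maximum-weight nested pairing via the Nussinov dynamic program.

    Weights: G:C 3, A:U 2, G:U 1; hairpin loops of at least ``MIN_LOOP``
    unpaired bases.  Deterministic traceback (prefers leaving i unpaired,
    then the smallest split point).
    """
    seq = to_dna(sequence)
    if not set(seq) <= set("ACGT"):
        raise ValueError("fold_hairpin: sequence contains non-ACGU characters")
    n = len(seq)
    dp = np.zeros((n + 1, n + 1), dtype=np.int32)  # dp[i][j] over seq[i:j]
    w = np.zeros((n, n), dtype=np.int32)
    for i in range(n):
        for j in range(i + MIN_LOOP + 1, n):
            w[i, j] = PAIR_WEIGHTS.get((seq[i], seq[j]), 0)
    # dp over span lengths; the pairing maximum is vectorized over k
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span  # seq[i:j]
            best = dp[i + 1, j]  # i unpaired
            arr = dp[i + 1, i + MIN_LOOP + 1 : j] + dp[i + MIN_LOOP + 2 : j + 1, j] + w[i, i + MIN_LOOP + 1 : j]
            if arr.size:
                best = max(best, int(arr.max()))
            dp[i, j] = best
    pairs = [-1] * n

    def traceback(i: int, j: int) -> None:
        while j - i >= 2:
            if dp[i, j] == dp[i + 1, j]:
                i += 1
                continue
            for k in range(i + MIN_LOOP + 1, j):
                wk = w[i, k]
                if wk and dp[i, j] == dp[i + 1, k] + dp[k + 1, j] + wk:
                    pairs[i] = k
                    pairs[k] = i
                    traceback(i + 1, k)
                    i, j = k + 1, j
                    break
            else:  # pragma: no cover - defensive; dp recurrence is exhaustive
                i += 1

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, n * 2 + 100))
    try:
        traceback(0, n)
    finally:
        sys.setrecursionlimit(old)
    return FoldResult(sequence=seq, pairs=tuple(pairs))


def vienna_fold(sequence: str) -> FoldResult:
    """MFE secondary structure from the ViennaRNA bindings (plug-in engine)."""
    if _vienna is None:  # pragma: no cover
        raise RuntimeError("ViennaRNA bindings are not importable")
    seq = to_dna(sequence)
    structure, _energy = _vienna.fold(seq.replace("T", "U"))
    stack: list[int] = []
    pairs = [-1] * len(seq)
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            j = stack.pop()
            pairs[i], pairs[j] = j, i
    return FoldResult(sequence=seq, pairs=tuple(pairs))


def default_fold_engine() -> Callable[[str], FoldResult]:
    return vienna_fold if _vienna is not None else nussinov_fold


def fold_hairpin(sequence: str, engine: Callable[[str], FoldResult] | None = None) -> FoldResult:
    """Fold a candidate window (50-300 nt) with the configured engine."""
    if not (50 <= len(sequence) <= 300):
        raise ValueError(f"fold_hairpin expects 50-300 nt, got {len(sequence)}")
    return (engine or nussinov_fold)(sequence)


# --------------------------------------------------------------------------
# clustering and windows
# --------------------------------------------------------------------------


@dataclass
class ReadCluster:
    contig: str
    start: int
    end: int
    alignments: list[Alignment] = field(default_factory=list)

    @property
    def total_reads(self) -> int:
        return sum(a.count for a in self.alignments)

    def stacks(self) -> dict[tuple[int, int, str], int]:
        """Summed counts per (start, end, strand) read stack."""
        out: dict[tuple[int, int, str], int] = {}
        for a in self.alignments:
            key = (a.start, a.end, a.strand)
            out[key] = out.get(key, 0) + a.count
        return out


def cluster_alignments(alignments: Iterable[Alignment]) -> list[ReadCluster]:
    """Merge reads into maximal clusters connected by interval overlap."""
    by_contig: dict[str, list[Alignment]] = {}
    for a in alignments:
        by_contig.setdefault(a.contig, []).append(a)
    clusters = []
    for contig in sorted(by_contig):
        alns = sorted(by_contig[contig], key=lambda a: (a.start, a.end))
        current: ReadCluster | None = None
        for a in alns:
            if current is not None and a.start < current.end:
                current.end = max(current.end, a.end)
                current.alignments.append(a)
            else:
                current = ReadCluster(contig=contig, start=a.start, end=a.end, alignments=[a])
                clusters.append(current)
    return clusters


def enumerate_windows(
    cluster: ReadCluster,
    contig_length: int,
    extension: int = 300,
    window: int = 250,
    step: int = 50,
) -> list[tuple[int, int]]:
    """250-nt candidate windows over the 300-nt-extended cluster span.

    Windows advance by ``step`` from the extended 5' end; a final window is
    clamped so the extended 3' end is always covered.
    """
    lo = max(0, cluster.start - extension)
    hi = min(contig_length, cluster.end + extension)
    span = hi - lo
    if span <= window:
        return [(lo, hi)]
    starts = list(range(0, span - window + 1, step))
    if starts[-1] != span - window:
        starts.append(span - window)
    return [(lo + s, lo + s + window) for s in starts]


# --------------------------------------------------------------------------
# candidate calling
# --------------------------------------------------------------------------


@dataclass
class MirnaCandidate:
    contig: str
    strand: str
    hairpin_start: int
    hairpin_end: int
    mature_seq: str  # RNA alphabet for reporting
    mature_arm: str
    mature_start: int
    mature_end: int
    mature_count: int
    star_seq: str
    star_start: int
    star_end: int
    star_count: int
    overhang_3p: tuple[int, int]  # (mature-end overhang, star-end overhang)
    criteria: dict[str, bool] = field(default_factory=dict)

    @property
    def accepted(self) -> bool:
        return all(self.criteria.values())


@dataclass
class Rejection:
    contig: str
    start: int
    end: int
    reason: str


def _dominant_helix(
    fold: FoldResult, x0: int, x1: int, max_bulge: int = 4
) -> tuple[list[tuple[int, int]], int] | None:
    """Longest consistent helix involving positions of [x0, x1).

    Groups the interval's base pairs into runs whose partners descend
    monotonically with gaps of at most ``max_bulge`` on either strand
    (bulges/internal loops); returns the longest run and its largest
    bulge.  Stray long-range pairs a folding engine may add around the
    duplex are thereby ignored.
    """
    paired = [(i, fold.pairs[i]) for i in range(x0, x1) if fold.pairs[i] >= 0]
    if not paired:
        return None
    runs: list[list[tuple[int, int]]] = []
    cur = [paired[0]]
    for (i1, j1), (i2, j2) in zip(paired, paired[1:]):
        if j2 < j1 and i2 - i1 - 1 <= max_bulge and j1 - j2 - 1 <= max_bulge:
            cur.append((i2, j2))
        else:
            runs.append(cur)
            cur = [(i2, j2)]
    runs.append(cur)
    helix = max(runs, key=len)
    bulge = 0
    for (i1, j1), (i2, j2) in zip(helix, helix[1:]):
        bulge = max(bulge, i2 - i1 - 1, j1 - j2 - 1)
    return helix, bulge


def _helix_arm(helix: list[tuple[int, int]], m0: int, m1: int) -> str | None:
    """'5p' when the duplex partners lie 3' of the mature, '3p' when 5',
    None when the mature spans the loop (partners on both sides)."""
    partners = [j for _, j in helix]
    if min(partners) >= m1:
        return "5p"
    if max(partners) < m0:
        return "3p"
    return None


def call_mirna(
    cluster: ReadCluster,
    store: AlignmentStore,
    genome: dict[str, str],
    min_reads: int = 10,
    min_mature_paired: int = 16,
    max_bulge: int = 4,
    overhang_tolerance: tuple[int, int] = (1, 3),
    dominance_floor: float = 0.3,
    dual_arm_floor: int = 10,
    fold_engine: Callable[[str], FoldResult] | None = None,
    extension: int = 300,
    window: int = 250,
    step: int = 50,
) -> list[MirnaCandidate] | Rejection:
    """Evaluate one read cluster as a miRNA locus.

    Returns accepted candidate(s) (two entries, -5p and -3p, when both arms
    pass ``dual_arm_floor``) or a ``Rejection`` with a machine-readable
    reason.  The dominant read stack must hold at least ``dominance_floor``
    of the cluster's reads before any window is folded: a hairpin-derived
    locus concentrates its reads on the mature, unlike phased or nat-siRNA
    loci.
    """
    engine = fold_engine or default_fold_engine()
    total = cluster.total_reads
    if total <= min_reads:
        return Rejection(cluster.contig, cluster.start, cluster.end, "insufficient-reads")
    stacks = cluster.stacks()
    (m_start, m_end, m_strand), m_count = max(stacks.items(), key=lambda kv: (kv[1], [-kv[0][0]]))
    if m_count / total < dominance_floor:
        return Rejection(cluster.contig, cluster.start, cluster.end, "no-dominant-stack")
    contig_seq = genome[cluster.contig]
    windows = enumerate_windows(cluster, len(contig_seq), extension, window, step)
    best_reason = "no-hairpin"
    for w0, w1 in windows:
        if not (w0 <= m_start and m_end <= w1):
            continue
        win_seq = contig_seq[w0:w1]
        if m_strand == "-":
            win_seq = revcomp(win_seq)
        fold = engine(win_seq)

        def to_win(g0: int, g1: int) -> tuple[int, int]:
            if m_strand == "+":
                return g0 - w0, g1 - w0
            return w1 - g1, w1 - g0

        def to_genome(x0: int, x1: int) -> tuple[int, int]:
            if m_strand == "+":
                return w0 + x0, w0 + x1
            return w1 - x1, w1 - x0

        m0, m1 = to_win(m_start, m_end)
        helix_result = _dominant_helix(fold, m0, m1, max_bulge)
        if helix_result is None:
            best_reason = "mature-underpaired"
            continue
        helix, bulge = helix_result
        if len(helix) < min_mature_paired:
            best_reason = "mature-underpaired"
            continue
        arm = _helix_arm(helix, m0, m1)
        if arm is None:
            best_reason = "mature-not-on-one-arm"
            continue
        # expected star: its 3' end sits 2 nt past the partner of the mature
        # 5' base; assume star length ~ mature length for the search window
        p = helix[0][1] + (helix[0][0] - m0)  # extrapolated partner of m0
        exp_end = p + 3  # exclusive end, canonical 2-nt 3' overhang
        exp_start = exp_end - (m1 - m0)
        star_g0, star_g1 = to_genome(exp_start, exp_end)
        star_candidates = [
            a
            for a in store.overlapping(cluster.contig, star_g0 - 4, star_g1 + 4)
            if a.strand == m_strand
            and abs(a.start - star_g0) <= 4
            and abs(a.end - star_g1) <= 4
            and not (a.start == m_start and a.end == m_end)
        ]
        if not star_candidates:
            best_reason = "no-star"
            continue
        star_stacks: dict[tuple[int, int], int] = {}
        for a in star_candidates:
            star_stacks[(a.start, a.end)] = star_stacks.get((a.start, a.end), 0) + a.count
        (sg0, sg1), star_count = max(star_stacks.items(), key=lambda kv: kv[1])
        sw0, sw1 = to_win(sg0, sg1)
        # duplex 3' overhangs under the fold's pairing: each strand's 3' end
        # should extend ~2 nt past the partner of the other strand's 5' base
        lo, hi = overhang_tolerance
        star_helix = _dominant_helix(fold, max(sw0, 0), min(sw1, len(fold.pairs)), max_bulge)
        if star_helix is not None:
            sh, _ = star_helix
            q = sh[0][1] + (sh[0][0] - sw0)  # extrapolated partner of the star 5' base
        else:
            q = None
        star_overhang = (sw1 - 1) - p
        mature_overhang = (m1 - 1) - q if q is not None else -99
        ok_overhang = lo <= star_overhang <= hi and lo <= mature_overhang <= hi
        mature_seq = contig_seq[m_start:m_end] if m_strand == "+" else revcomp(contig_seq[m_start:m_end])
        star_seq = contig_seq[sg0:sg1] if m_strand == "+" else revcomp(contig_seq[sg0:sg1])
        hp_lo, hp_hi = to_genome(min(m0, sw0), max(m1, sw1))
        criteria = {
            "min_reads": total > min_reads,
            "hairpin": True,
            "star_present": star_count >= 1,
            "duplex_overhangs": ok_overhang,
        }
        if not ok_overhang:
            best_reason = "bad-overhangs"
            continue
        arm_name = arm
        candidates = [
            MirnaCandidate(
                contig=cluster.contig,
                strand=m_strand,
                hairpin_start=hp_lo,
                hairpin_end=hp_hi,
                mature_seq=to_rna(mature_seq),
                mature_arm=arm_name,
                mature_start=m_start,
                mature_end=m_end,
                mature_count=m_count,
                star_seq=to_rna(star_seq),
                star_start=sg0,
                star_end=sg1,
                star_count=star_count,
                overhang_3p=(mature_overhang, star_overhang),
                criteria=criteria,
            )
        ]
        if star_count >= dual_arm_floor:
            other_arm = "3p" if arm_name == "5p" else "5p"
            candidates.append(
                MirnaCandidate(
                    contig=cluster.contig,
                    strand=m_strand,
                    hairpin_start=hp_lo,
                    hairpin_end=hp_hi,
                    mature_seq=to_rna(star_seq),
                    mature_arm=other_arm,
                    mature_start=sg0,
                    mature_end=sg1,
                    mature_count=star_count,
                    star_seq=to_rna(mature_seq),
                    star_start=m_start,
                    star_end=m_end,
                    star_count=m_count,
                    overhang_3p=(star_overhang, mature_overhang),
                    criteria=dict(criteria),
                )
            )
        return candidates
    return Rejection(cluster.contig, cluster.start, cluster.end, best_reason)


def discover_mirnas(
    alignments: Iterable[Alignment],
    genome: dict[str, str],
    min_reads: int = 10,
    fold_engine: Callable[[str], FoldResult] | None = None,
    **kwargs,
) -> tuple[list[MirnaCandidate], list[Rejection]]:
    """Run clustering + hairpin evaluation over a full alignment set.

    Candidates sharing a mature interval are reported once (the same hairpin
    can be reached from both the mature and the star cluster).
    """
    alns = list(alignments)
    store = AlignmentStore(alns)
    accepted: dict[tuple[str, int, int, str], MirnaCandidate] = {}
    rejections: list[Rejection] = []
    for cluster in cluster_alignments(alns):
        result = call_mirna(cluster, store, genome, min_reads=min_reads, fold_engine=fold_engine, **kwargs)
        if isinstance(result, Rejection):
            rejections.append(result)
        else:
            for cand in result:
                key = (cand.contig, cand.mature_start, cand.mature_end, cand.strand)
                prev = accepted.get(key)
                if prev is None or cand.mature_count > prev.mature_count:
                    accepted[key] = cand
    return sorted(accepted.values(), key=lambda c: (c.contig, c.hairpin_start, c.mature_start)), rejections


# --------------------------------------------------------------------------
# known-miRNA re-annotation
# --------------------------------------------------------------------------


def read_known_mirnas(path: str | Path) -> dict[str, str]:
    known: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in known:
            raise ValueError(f"duplicate miRNA id {rec.id!r} in {path}")
        known[rec.id] = to_dna(str(rec.seq))
    return known


def _matches_isomir(read: str, mature: str, shift: int = 2) -> bool:
    """Exact match allowing the read's 5'/3' ends to shift by <= ``shift`` nt.

    The read is slid against the mature; the overlapping core must match
    exactly and each dangling end may be at most ``shift`` nt.
    """
    for offset in range(-shift, shift + 1):
        # read position i sits at mature position i + offset
        lead = max(0, -offset)  # read bases hanging off the mature 5' end
        tail = max(0, (offset + len(read)) - len(mature))
        if lead > shift or tail > shift:
            continue
        core_read = read[lead : len(read) - tail]
        start = lead + offset
        if 0 <= start and start + len(core_read) <= len(mature):
            if mature[start : start + len(core_read)] == core_read and len(core_read) >= len(read) - 2 * shift:
                return True
    return False


def reannotate_known(
    known: dict[str, str],
    collapsed: Iterable[CollapsedRead],
    shift: int = 2,
) -> tuple[dict[str, dict[str, int]], list[CollapsedRead]]:
    """Per-known-miRNA expression counts per library, plus the leftover reads.

    A read is attributed to a known mature when it matches exactly or within
    a 2-nt 5'/3' isomiR shift window.  Matched reads are excluded from novel
    discovery input (the returned leftover list).
    """
    if not known:
        raise ValueError("known miRNA set is empty")
    table: dict[str, dict[str, int]] = {mid: {} for mid in known}
    leftovers: list[CollapsedRead] = []
    for read in collapsed:
        hit = None
        for mid, mature in known.items():
            if abs(len(read.sequence) - len(mature)) <= 2 * shift and _matches_isomir(
                read.sequence, mature, shift
            ):
                hit = mid
                break
        if hit is None:
            leftovers.append(read)
        else:
            lib = table[hit]
            lib[read.library_id] = lib.get(read.library_id, 0) + read.count
    return table, leftovers


def write_candidate_table(candidates: Sequence[MirnaCandidate], path: str | Path) -> None:
    """Mature-sequence table: sequence, reads, contig, coordinates, strand."""
    with open(path, "w") as fh:
        fh.write("mature_sequence\treads\tcontig\tstart\tend\tstrand\tarm\tstar_reads\n")
        for c in candidates:
            fh.write(
                f"{c.mature_seq}\t{c.mature_count}\t{c.contig}\t{c.mature_start}\t"
                f"{c.mature_end}\t{c.strand}\t{c.mature_arm}\t{c.star_count}\n"
            )
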