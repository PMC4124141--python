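"""Secondary/phased siRNA locus detection and 21-nt register analytics.

Candidate regions are read clusters built with a 50-bp start-distance
window; a region qualifies when it carries at least 10 reads and more than
70% of them (count-weighted) are exactly 21 nt.  Trigger small-RNA binding
sites on transcripts are scored with the standard plant target-penalty
scheme (mismatch 1, G:U wobble 0.5, bulge 1; penalties doubled over
small-RNA positions 2-13); a pair of sites defines a dsRNA template.
Phasing registers are the residue classes mod 21 of read 5' ends relative
to the predicted cleavage site; in-register reads are named D1+, D2+, ...
on the sense strand and Dk- on the antisense strand, whose 5' ends run two
nucleotides ahead of the sense register (duplex 3'-overhang geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._seq import revcomp
from .mapping import Alignment

CORE_START, CORE_END = 2, 13  # 1-based small-RNA positions with doubled penalty


@dataclass
class TargetSite:
    srna_id: str
    transcript_id: str
    start: int  # on transcript, 0-based
    end: int
    alignment: str  # one symbol per sRNA position: '|' match, 'o' G:U, 'x' mismatch
    score: float
    cleavage: int  # transcript coordinate of the first base 3' of the cut


@dataclass
class PhasCandidateLocus:
    locus_id: str
    contig: str
    start: int
    end: int
    total_reads: int
    fraction_21nt: float
    passes_filter: bool
    trigger_sites: list[TargetSite] = field(default_factory=list)
    cleavage_positions: list[int] = field(default_factory=list)
    histogram: np.ndarray | None = None
    phased_fraction: float = 0.0
    shifted_fraction: float = 0.0
    shifted_flagged: bool = False
    register_names: dict[str, int] = field(default_factory=dict)


def cluster_21nt_loci(alignments: Iterable[Alignment], window: int = 50) -> list[list[Alignment]]:
    """Chain reads whose start positions lie within ``window`` bp into regions."""
    by_contig: dict[str, list[Alignment]] = {}
    for a in alignments:
        by_contig.setdefault(a.contig, []).append(a)
    regions: list[list[Alignment]] = []
    for contig in sorted(by_contig):
        alns = sorted(by_contig[contig], key=lambda a: (a.start, a.end))
        current: list[Alignment] = []
        for a in alns:
            if current and a.start - current[-1].start <= window:
                current.append(a)
            else:
                if current:
                    regions.append(current)
                current = [a]
        if current:
            regions.append(current)
    return regions


def region_interval(region: Sequence[Alignment]) -> tuple[str, int, int]:
    return region[0].contig, min(a.start for a in region), max(a.end for a in region)


def filter_candidates(
    region: Sequence[Alignment],
    min_reads: int = 10,
    min_fraction_21nt: float = 0.70,
) -> tuple[bool, dict[str, float]]:
    """Pass iff total reads >= ``min_reads`` and the count-weighted 21-nt
    fraction strictly exceeds ``min_fraction_21nt``.  Metrics always returned."""
    total = sum(a.count for a in region)
    n21 = sum(a.count for a in region if a.end - a.start == 21)
    frac = n21 / total if total else 0.0
    metrics = {"total_reads": float(total), "fraction_21nt": frac}
    return total >= min_reads and frac > min_fraction_21nt, metrics


# --------------------------------------------------------------------------
# target-site scoring
# --------------------------------------------------------------------------


def _position_weight(pos_1based: int) -> float:
    return 2.0 if CORE_START <= pos_1based <= CORE_END else 1.0


def _score_ungapped(srna: str, target: str) -> tuple[float, str]:
    """Penalty of an ungapped duplex: sRNA position i (1-based, from the sRNA
    5' end) sits opposite target base end-i."""
    n = len(srna)
    score = 0.0
    symbols = []
    for i in range(n):
        pos = i + 1  # position from the sRNA 5' end
        t_base = target[n - 1 - i]
        s_base = srna[i]
        expected = revcomp(s_base)
        if t_base == expected:
            symbols.append("|")
        elif (s_base == "G" and t_base == "T") or (s_base == "T" and t_base == "G"):
            symbols.append("o")
            score += 0.5 * _position_weight(pos)
        else:
            symbols.append("x")
            score += 1.0 * _position_weight(pos)
    return score, "".join(symbols)


def score_target_site(
    srna: str,
    transcript_window: str,
    srna_id: str = "",
    transcript_id: str = "",
    window_offset: int = 0,
    threshold: float = 4.0,
    comparator: str = "le",
    allow_bulge: bool = True,
) -> TargetSite | None:
    """Best-scoring placement of a small RNA on a transcript window.

    Evaluates every ungapped offset and, optionally, every single-nucleotide
    bulge (on either strand, penalty 1.0, doubled in the core).  The site is
    returned iff its penalty satisfies the configured comparator against
    ``threshold`` (default: score <= 4.0; lower penalties mean better
    complementarity).  The predicted cleavage position is the transcript
    base opposite the boundary between small-RNA positions 10 and 11.
    """
    srna = srna.upper().replace("U", "T")
    if not (20 <= len(srna) <= 24):
        raise ValueError(f"small RNA length {len(srna)} outside [20, 24]")
    n = len(srna)
    best: tuple[float, int, int, str] | None = None  # (score, start, end, symbols)
    win = transcript_window.upper()
    for start in range(0, len(win) - n + 1):
        score, symbols = _score_ungapped(srna, win[start : start + n])
        if best is None or score < best[0]:
            best = (score, start, start + n, symbols)
    if allow_bulge:
        # one extra target base (target bulge, site length n+1)
        for start in range(0, len(win) - n):
            site = win[start : start + n + 1]
            for b in range(1, n):  # bulge between paired positions
                squeezed = site[: n - b] + site[n - b + 1 :]
                score, symbols = _score_ungapped(srna, squeezed)
                score += 1.0 * _position_weight(b + 1)
                if best is None or score < best[0]:
                    best = (score, start, start + n + 1, symbols)
        # one unpaired sRNA base (sRNA bulge, site length n-1)
        for start in range(0, len(win) - n + 2):
            site = win[start : start + n - 1]
            if len(site) < n - 1:
                continue
            for b in range(1, n - 1):
                squeezed_srna = srna[:b] + srna[b + 1 :]
                score, symbols = _score_ungapped(squeezed_srna, site)
                score += 1.0 * _position_weight(b + 1)
                if best is None or score < best[0]:
                    best = (score, start, start + n - 1, symbols)
    if best is None:
        return None
    score, s0, s1, symbols = best
    ok = score <= threshold if comparator == "le" else score >= threshold
    if not ok:
        return None
    return TargetSite(
        srna_id=srna_id,
        transcript_id=transcript_id,
        start=window_offset + s0,
        end=window_offset + s1,
        alignment=symbols,
        score=score,
        cleavage=window_offset + s1 - 10,
    )


def scan_target_sites(
    srna: str,
    transcript: str,
    srna_id: str = "",
    transcript_id: str = "",
    threshold: float = 4.0,
    comparator: str = "le",
) -> list[TargetSite]:
    """All ungapped sites on a full transcript below the penalty threshold.

    Vectorized over offsets; the genome/transcriptome-wide search is
    ungapped-anchored (bulged alignments are evaluated by
    :func:`score_target_site` at a specific window).
    """
    srna = srna.upper().replace("U", "T")
    n = len(srna)
    t = transcript.upper()
    if len(t) < n:
        return []
    rc = revcomp(srna)  # expected target sense sequence
    t_arr = np.frombuffer(t.encode(), dtype=np.uint8)
    n_pos = len(t) - n + 1
    penalty = np.zeros(n_pos)
    for j in range(n):
        # target index j corresponds to sRNA position n - j (1-based)
        w = _position_weight(n - j)
        col = t_arr[j : j + n_pos]
        exp = ord(rc[j])
        srna_base = srna[n - 1 - j]
        wobble = ord("T") if srna_base == "G" else (ord("G") if srna_base == "T" else 0)
        mism = col != exp
        if wobble:
            is_wob = col == wobble
            penalty += np.where(is_wob, 0.5 * w, np.where(mism, 1.0 * w, 0.0))
        else:
            penalty += np.where(mism, 1.0 * w, 0.0)
    if comparator == "le":
        hits = np.nonzero(penalty <= threshold)[0]
    else:
        hits = np.nonzero(penalty >= threshold)[0]
    sites = []
    for p in hits:
        score, symbols = _score_ungapped(srna, t[p : p + n])
        sites.append(
            TargetSite(
                srna_id=srna_id,
                transcript_id=transcript_id,
                start=int(p),
                end=int(p) + n,
                alignment=symbols,
                score=score,
                cleavage=int(p) + n - 10,
            )
        )
    return sites


def define_template(
    site5: TargetSite,
    site3: TargetSite,
    transcript_length: int,
    flank: int = 100,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """dsRNA template defined by a pair of trigger sites, with 100-nt flanks.

    Returns ``((start, end), (cleavage5, cleavage3))``; both sites are taken
    as cleaved (dual-cleavage geometry).
    """
    if site5.transcript_id != site3.transcript_id:
        raise ValueError("template sites must lie on one transcript")
    if site5.start >= site3.start or site5.end > site3.start:
        raise ValueError("site5 must lie strictly upstream of site3")
    start = max(0, site5.start - flank)
    end = min(transcript_length, site3.end + flank)
    return (start, end), (site5.cleavage, site3.cleavage)


# --------------------------------------------------------------------------
# register analytics
# --------------------------------------------------------------------------


def compute_phasing(
    reads: Sequence[Alignment],
    cleavage5: int,
    cleavage3: int | None = None,
    count_weighted: bool = True,
    only_21nt: bool = False,
) -> tuple[np.ndarray, float, dict[str, int]]:
    """Register histogram, phased fraction and register names for a locus.

    Sense-read offset: ``(start - c) mod 21``; antisense-read offset:
    ``(end - c - 2) mod 21`` (2-nt duplex overhang convention).  The
    histogram is computed against the 5'-site register; the phased fraction
    counts reads in register 0 with respect to *either* cleavage site, over
    all reads considered.  In-register reads are named D1+, D2+, ... by
    distance from the 5' cleavage site (Dk- on the antisense strand).
    """
    hist = np.zeros(21)
    phased = 0.0
    total = 0.0
    names: dict[str, int] = {}
    for a in reads:
        if only_21nt and a.end - a.start != 21:
            continue
        weight = a.count if count_weighted else 1
        total += weight
        if a.strand == "+":
            off5 = (a.start - cleavage5) % 21
            off3 = (a.start - cleavage3) % 21 if cleavage3 is not None else off5
        else:
            off5 = (a.end - cleavage5 - 2) % 21
            off3 = (a.end - cleavage3 - 2) % 21 if cleavage3 is not None else off5
        hist[off5] += weight
        if off5 == 0 or off3 == 0:
            phased += weight
            if off5 == 0:
                if a.strand == "+":
                    k = (a.start - cleavage5) // 21 + 1
                    name = f"D{k}+"
                else:
                    k = (a.end - 2 - cleavage5) // 21 + 1
                    name = f"D{k}-"
                names[name] = names.get(name, 0) + int(weight)
    fraction = phased / total if total else 0.0
    return hist, fraction, names


def detect_shifted_register(
    histogram: np.ndarray,
    min_fraction: float = 0.10,
) -> tuple[bool, float]:
    """Secondary-register report: combined histogram mass at offsets 10 and
    11 (the ~half-register shift set by a secondary cleavage), flagged when
    it reaches ``min_fraction`` and exceeds the uniform-null expectation 2/21."""
    total = histogram.sum()
    if total == 0:
        return False, 0.0
    frac = float((histogram[10] + histogram[11]) / total)
    return frac >= min_fraction and frac > 2 / 21, frac


def write_locus_table(loci: Sequence[PhasCandidateLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "locus_id\tcontig\tstart\tend\ttotal_reads\tfraction_21nt\tpass\t"
            "trigger\ttrigger_score\tphased_fraction\tshifted_fraction\n"
        )
        for l in loci:
            trig = l.trigger_sites[0].srna_id if l.trigger_sites else "."
            score = f"{l.trigger_sites[0].score:.1f}" if l.trigger_sites else "."
            fh.write(
                f"{l.locus_id}\t{l.contig}\t{l.start}\t{l.end}\t{l.total_reads}\t"
                f"{l.fraction_21nt:.4f}\t{int(l.passes_filter)}\t{trig}\t{score}\t"
                f"{l.phased_fraction:.4f}\t{l.shifted_fraction:.4f}\n"
            )


def write_register_histogram(locus: PhasCandidateLocus, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("register_offset\tcount\n")
        for i, v in enumerate(locus.histogram if locus.histogram is not None else np.zeros(21)):
            fh.write(f"{i}\t{v:.1f}\n")
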