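"""Short-read placement on genome and transcript sequences.

A k-mer seed-and-verify mapper reports *every* placement of a read on
either strand with at most a bounded number of substitutions (no indels),
which matches how 17-28 nt small-RNA reads are conventionally aligned.
For up to one mismatch the pigeonhole principle guarantees that one half
of the read is exact, so seeding with the k-mers at the start of each half
is lossless.  Larger mismatch budgets (used for siRNA target search) go
through a vectorized exhaustive scan instead.

Coordinates are 0-based half-open throughout; a minus-strand alignment's
interval is given on the forward strand of the reference.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ._seq import mismatch_scan, revcomp
from .preprocess import CollapsedRead


@dataclass(frozen=True)
class Alignment:
    sequence: str
    contig: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str  # '+' or '-'
    mismatches: int
    n_hits: int = 1  # total placements of this sequence on the reference
    count: int = 1  # collapsed read count carried through for locus sums
    library_id: str = ""


class ReferenceIndex:
    """k-mer index over a set of named sequences (genome contigs or cDNAs)."""

    def __init__(self, sequences: Mapping[str, str], k: int = 8):
        self.k = k
        self.sequences = dict(sequences)
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.sequences.items():
            for i in range(len(seq) - k + 1):
                self._index[seq[i : i + k]].append((name, i))

    def seed(self, kmer: str) -> list[tuple[str, int]]:
        return self._index.get(kmer, [])


def _verify(ref: str, pos: int, query: str, max_mm: int) -> int | None:
    if pos < 0 or pos + len(query) > len(ref):
        return None
    mm = 0
    for a, b in zip(ref[pos : pos + len(query)], query):
        if a != b:
            mm += 1
            if mm > max_mm:
                return None
    return mm


def map_read(
    read: CollapsedRead | str,
    index: ReferenceIndex,
    max_mismatches: int = 0,
) -> list[Alignment]:
    """All placements of a read with at most ``max_mismatches`` substitutions.

    Seeds with the k-mers at offsets 0 and len//2 of each orientation
    (lossless for <=1 mismatch given read length >= k + len//2), verifies
    against the reference, and sets ``n_hits`` on every reported placement.
    """
    if isinstance(read, CollapsedRead):
        seq, count, lib = read.sequence, read.count, read.library_id
    else:
        seq, count, lib = read, 1, ""
    length = len(seq)
    if length < index.k:
        raise ValueError(f"read shorter than index seed length {index.k}")
    if max_mismatches > 1:
        return _map_exhaustive(seq, count, lib, index, max_mismatches)
    half = length // 2
    offsets = (0, half) if half + index.k <= length else (0,)
    hits: dict[tuple[str, int, str], int] = {}
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        candidates: set[tuple[str, int]] = set()
        for off in offsets:
            for contig, pos in index.seed(oriented[off : off + index.k]):
                candidates.add((contig, pos - off))
        for contig, pos in candidates:
            mm = _verify(index.sequences[contig], pos, oriented, max_mismatches)
            if mm is not None:
                hits[(contig, pos, strand)] = mm
    n = len(hits)
    return [
        Alignment(seq, contig, pos, pos + length, strand, mm, n_hits=n, count=count, library_id=lib)
        for (contig, pos, strand), mm in sorted(hits.items())
    ]


def _map_exhaustive(seq, count, lib, index, max_mm) -> list[Alignment]:
    hits = []
    for strand, oriented in (("+", seq), ("-", revcomp(seq))):
        for contig, ref in index.sequences.items():
            for pos, mm in mismatch_scan(ref, oriented, max_mm):
                hits.append((contig, pos, strand, mm))
    n = len(hits)
    return [
        Alignment(seq, contig, pos, pos + len(seq), strand, mm, n_hits=n, count=count, library_id=lib)
        for contig, pos, strand, mm in sorted(hits)
    ]


def map_collapsed(
    reads: Iterable[CollapsedRead],
    index: ReferenceIndex,
    max_mismatches: int = 0,
) -> list[Alignment]:
    """Flat list of placements for a collapsed-read set (unmapped reads drop out)."""
    out: list[Alignment] = []
    for read in reads:
        out.extend(map_read(read, index, max_mismatches))
    return out


def classify_uniqueness(alignments: Iterable[Alignment]) -> dict[str, str]:
    """Per read sequence: 'unique' iff it has exactly one placement."""
    labels: dict[str, str] = {}
    for aln in alignments:
        labels[aln.sequence] = "unique" if aln.n_hits == 1 else "multi"
    return labels


class AlignmentStore:
    """Per-contig, start-sorted alignments with interval queries.

    Used by the locus-level stages (miRNA clusters, phased loci, cis-NAT
    overlaps) to fetch read stacks inside arbitrary windows.
    """

    def __init__(self, alignments: Iterable[Alignment]):
        by_contig: dict[str, list[Alignment]] = defaultdict(list)
        for aln in alignments:
            by_contig[aln.contig].append(aln)
        self._alns: dict[str, list[Alignment]] = {}
        self._starts: dict[str, list[int]] = {}
        for contig, alns in by_contig.items():
            alns.sort(key=lambda a: (a.start, a.end, a.strand, a.sequence, a.library_id))
            self._alns[contig] = alns
            self._starts[contig] = [a.start for a in alns]

    @property
    def contigs(self) -> list[str]:
        return sorted(self._alns)

    def all(self) -> list[Alignment]:
        return [a for c in self.contigs for a in self._alns[c]]

    def overlapping(self, contig: str, start: int, end: int) -> list[Alignment]:
        """Alignments overlapping [start, end) on a contig."""
        alns = self._alns.get(contig, [])
        starts = self._starts.get(contig, [])
        # reads are short: scan back a window of MAX read length from start
        lo = bisect_left(starts, start - 40)
        hi = bisect_right(starts, end)
        return [a for a in alns[lo:hi] if a.start < end and a.end > start]

    def within(self, contig: str, start: int, end: int) -> list[Alignment]:
        """Alignments fully inside [start, end)."""
        return [a for a in self.overlapping(contig, start, end) if a.start >= start and a.end <= end]


def write_bed6(alignments: Iterable[Alignment], path: str | Path) -> None:
    """BED6 with name=sequence and score=collapsed count."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f"{a.contig}\t{a.start}\t{a.end}\t{a.sequence}\t{a.count}\t{a.strand}\n")


def write_alignment_table(alignments: Iterable[Alignment], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcontig\tstart\tend\tstrand\tmismatches\tn_hits\tcount\tlibrary\n")
        for a in alignments:
            fh.write(
                f"{a.sequence}\t{a.contig}\t{a.start}\t{a.end}\t{a.strand}\t"
                f"{a.mismatches}\t{a.n_hits}\t{a.count}\t{a.library_id}\n"
            )


def read_alignment_table(path: str | Path) -> list[Alignment]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("sequence")
        for line in fh:
            seq, contig, start, end, strand, mm, n_hits, count, lib = line.rstrip("\n").split("\t")
            out.append(
                Alignment(seq, contig, int(start), int(end), strand, int(mm), int(n_hits), int(count), lib)
            )
    return out
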