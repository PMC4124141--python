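"""Adapter trimming, read qualification and collapsing for small-RNA libraries.

The trimming rule follows the recursive longest-adapter-substring idea: the
longest substring of the 3' adapter found anywhere in the read marks the end
of the insert.  A read without any adapter substring of at least
``min_match`` nucleotides is flagged as having no adapter and is discarded
during qualification.  Qualified reads are 17-28 nt, free of ambiguous
bases, and pass a per-base quality floor; identical sequences are collapsed
to (sequence, count) per library.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from ._seq import DNA_ALPHABET, to_dna

MIN_LEN = 17
MAX_LEN = 28


@dataclass(frozen=True)
class RawRead:
    id: str
    sequence: str
    quality: tuple[int, ...]  # Phred scores, one per base


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct qualified small-RNA sequence with its library read count."""

    sequence: str  # DNA alphabet (U normalized to T)
    count: int
    library_id: str

    def __post_init__(self):
        if not (MIN_LEN <= len(self.sequence) <= MAX_LEN):
            raise ValueError(f"collapsed read length {len(self.sequence)} outside [{MIN_LEN},{MAX_LEN}]")
        if self.count < 1:
            raise ValueError("collapsed read count must be >= 1")


@dataclass
class QCReport:
    library_id: str
    raw_reads: int = 0
    qualified_reads: int = 0
    discarded: Counter = field(default_factory=Counter)

    @property
    def qualified_fraction(self) -> float:
        return self.qualified_reads / self.raw_reads if self.raw_reads else 0.0

    def conserved(self) -> bool:
        return self.qualified_reads + sum(self.discarded.values()) == self.raw_reads


def trim_adapter(sequence: str, adapter: str, min_match: int = 7) -> str | None:
    """Trim the 3' adapter off a read; ``None`` flags a read with no adapter.

    Searches for the longest substring of ``adapter`` occurring in the read
    and truncates the read at the start of that occurrence.  Ties between
    equal-length occurrences are broken by the leftmost position in the
    read, which keeps the shortest (most conservative) insert.  Substrings
    shorter than ``min_match`` nucleotides do not count as adapter.
    """
    if not sequence:
        raise ValueError("empty read")
    if len(adapter) < min_match:
        raise ValueError(f"adapter shorter than min_match={min_match}")
    seq = to_dna(sequence)
    adapter = to_dna(adapter)
    max_l = min(len(adapter), len(seq))
    for length in range(max_l, min_match - 1, -1):
        substrings = {adapter[i : i + length] for i in range(len(adapter) - length + 1)}
        best = None
        for sub in substrings:
            pos = seq.find(sub)
            if pos != -1 and (best is None or pos < best):
                best = pos
        if best is not None:
            return seq[:best]
    return None


def qualify(
    reads: Iterable[RawRead],
    adapter: str,
    library_id: str,
    min_match: int = 7,
    min_quality: int = 20,
) -> tuple[list[CollapsedRead], QCReport]:
    """Trim, filter and collapse one library's raw reads.

    Discard rules (applied in order, each read charged to one rule):
    no adapter substring >= ``min_match`` nt; any base below ``min_quality``
    within the insert; ambiguous base (N); insert shorter than 17 nt or
    longer than 28 nt.
    """
    report = QCReport(library_id=library_id)
    counts: Counter[str] = Counter()
    for read in reads:
        report.raw_reads += 1
        insert = trim_adapter(read.sequence, adapter, min_match=min_match)
        if insert is None:
            report.discarded["no_adapter"] += 1
            continue
        quals = read.quality[: len(insert)]
        if any(q < min_quality for q in quals):
            report.discarded["low_quality"] += 1
            continue
        if not set(insert) <= DNA_ALPHABET or "N" in insert:
            report.discarded["ambiguous"] += 1
            continue
        if len(insert) < MIN_LEN:
            report.discarded["too_short"] += 1
            continue
        if len(insert) > MAX_LEN:
            report.discarded["too_long"] += 1
            continue
        counts[insert] += 1
        report.qualified_reads += 1
    collapsed = [
        CollapsedRead(sequence=seq, count=c, library_id=library_id)
        for seq, c in sorted(counts.items())
    ]
    return collapsed, report


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield RawRead(
            id=rec.id,
            sequence=str(rec.seq),
            quality=tuple(rec.letter_annotations["phred_quality"]),
        )


def process_fastq(
    path: str | Path,
    adapter: str,
    library_id: str | None = None,
    min_match: int = 7,
    min_quality: int = 20,
) -> tuple[list[CollapsedRead], QCReport]:
    lib = library_id or Path(path).stem
    return qualify(read_fastq(path), adapter, lib, min_match=min_match, min_quality=min_quality)


def composition_profile(collapsed: Iterable[CollapsedRead]) -> tuple[dict[int, float], dict[str, float]]:
    """Count-weighted length histogram (17-28) and first-nucleotide fractions."""
    length_counts: Counter[int] = Counter()
    first_counts: Counter[str] = Counter()
    total = 0
    for read in collapsed:
        length_counts[len(read.sequence)] += read.count
        first_counts[read.sequence[0]] += read.count
        total += read.count
    if total == 0:
        raise ValueError("empty collapsed-read set: no composition profile")
    lengths = {l: length_counts.get(l, 0) / total for l in range(MIN_LEN, MAX_LEN + 1)}
    first = {nt: first_counts.get(nt, 0) / total for nt in "ACGT"}
    return lengths, first


def write_collapsed_fasta(collapsed: Iterable[CollapsedRead], path: str | Path) -> None:
    """Write collapsed reads as FASTA with ``>seq<k>_x<count>`` headers."""
    with open(path, "w") as fh:
        for k, read in enumerate(collapsed, start=1):
            fh.write(f">seq{k}_x{read.count}\n{read.sequence}\n")


def read_collapsed_fasta(path: str | Path, library_id: str) -> list[CollapsedRead]:
    reads = []
    for rec in SeqIO.parse(str(path), "fasta"):
        count = int(rec.id.rsplit("_x", 1)[1])
        reads.append(CollapsedRead(sequence=to_dna(str(rec.seq)), count=count, library_id=library_id))
    return reads


def write_qc_report(reports: Iterable[QCReport], path: str | Path) -> None:
    rules = ["no_adapter", "low_quality", "ambiguous", "too_short", "too_long"]
    with open(path, "w") as fh:
        fh.write("library\traw\tqualified\tqualified_fraction\t" + "\t".join(rules) + "\n")
        for r in reports:
            vals = "\t".join(str(r.discarded.get(rule, 0)) for rule in rules)
            fh.write(f"{r.library_id}\t{r.raw_reads}\t{r.qualified_reads}\t{r.qualified_fraction:.4f}\t{vals}\n")
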