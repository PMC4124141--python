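"""cis-natural-antisense transcript pairs and nat-siRNA calling.

Two gene models on opposite strands of one contig form a cis-NAT pair when
their genomic intervals overlap by at least 25 nt.  Pairs are classified
as *enclosed* (one interval contains the other), *convergent* (3'-3'
overlap: the plus-strand gene starts first) or *divergent* (5'-5'
overlap).  A pair is called nat-siRNA-producing when the reads falling
entirely inside the overlap number more than 10, at least one of them maps
uniquely, and the count-weighted 21-nt fraction clears the enrichment rule
(by default a majority, >0.5, on at least one strand).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .gff import GeneModel
from .mapping import Alignment, AlignmentStore


@dataclass(frozen=True)
class CisNatPair:
    pair_id: str
    contig: str
    gene_plus: GeneModel
    gene_minus: GeneModel
    overlap_start: int
    overlap_end: int
    orientation: str  # convergent | divergent | enclosed

    @property
    def overlap_length(self) -> int:
        return self.overlap_end - self.overlap_start


@dataclass
class StrandMetrics:
    reads: int
    fraction_21nt: float


@dataclass
class NatSirnaCall:
    pair_id: str
    plus: StrandMetrics
    minus: StrandMetrics
    total_reads: int
    unique_read_present: bool
    enrichment_ok: bool
    passes: bool


def classify_orientation(plus: GeneModel, minus: GeneModel) -> str:
    """Orientation class from interval geometry (enclosed > convergent > divergent)."""
    if (plus.start <= minus.start and minus.end <= plus.end) or (
        minus.start <= plus.start and plus.end <= minus.end
    ):
        return "enclosed"
    # a plus-strand gene's 3' end is its right end; a minus-strand gene's 3'
    # end is its left end, so a 3'-3' overlap means the plus gene starts first
    if plus.start < minus.start:
        return "convergent"
    return "divergent"


def find_cis_nat_pairs(annotation: Iterable[GeneModel], min_overlap: int = 25) -> list[CisNatPair]:
    """Every opposite-strand gene pair overlapping by >= ``min_overlap`` nt."""
    by_contig: dict[str, list[GeneModel]] = {}
    for g in annotation:
        if g.strand not in "+-":
            raise ValueError(f"gene {g.gene_id} lacks strand annotation")
        by_contig.setdefault(g.contig, []).append(g)
    pairs: list[CisNatPair] = []
    for contig in sorted(by_contig):
        genes = by_contig[contig]
        tree = IntervalTree()
        for i, g in enumerate(genes):
            tree[g.start : g.end] = i
        seen: set[tuple[str, str]] = set()
        for g in genes:
            if g.strand != "+":
                continue
            for hit in tree[g.start : g.end]:
                other = genes[hit.data]
                if other.strand != "-":
                    continue
                key = (g.gene_id, other.gene_id)
                if key in seen:
                    continue
                seen.add(key)
                ov0, ov1 = max(g.start, other.start), min(g.end, other.end)
                if ov1 - ov0 < min_overlap:
                    continue
                pairs.append(
                    CisNatPair(
                        pair_id=f"{g.gene_id}|{other.gene_id}",
                        contig=contig,
                        gene_plus=g,
                        gene_minus=other,
                        overlap_start=ov0,
                        overlap_end=ov1,
                        orientation=classify_orientation(g, other),
                    )
                )
    pairs.sort(key=lambda p: (p.contig, p.overlap_start, p.pair_id))
    return pairs


def _strand_metrics(reads: Sequence[Alignment], strand: str) -> StrandMetrics:
    sel = [a for a in reads if a.strand == strand]
    total = sum(a.count for a in sel)
    n21 = sum(a.count for a in sel if a.end - a.start == 21)
    return StrandMetrics(reads=total, fraction_21nt=(n21 / total if total else 0.0))


def call_nat_sirna(
    pair: CisNatPair,
    store: AlignmentStore,
    min_reads: int = 10,
    enrichment_fraction: float = 0.5,
    enrichment_both_strands: bool = False,
) -> NatSirnaCall:
    """nat-siRNA call for one cis-NAT pair.

    Only reads lying entirely within the overlap interval count.  The read
    floor is strict (more than ``min_reads``); the 21-nt enrichment rule is
    a strict majority per strand on at least one strand by default
    (set ``enrichment_both_strands`` for the stringent variant).
    """
    if pair.overlap_length <= 0:
        raise ValueError(f"pair {pair.pair_id} has no overlap interval")
    reads = store.within(pair.contig, pair.overlap_start, pair.overlap_end)
    plus = _strand_metrics(reads, "+")
    minus = _strand_metrics(reads, "-")
    total = plus.reads + minus.reads
    unique_present = any(a.n_hits == 1 for a in reads)
    fractions = [m.fraction_21nt for m in (plus, minus) if m.reads > 0]
    if not fractions:
        enrichment_ok = False
    elif enrichment_both_strands:
        enrichment_ok = all(f > enrichment_fraction for f in fractions)
    else:
        enrichment_ok = any(f > enrichment_fraction for f in fractions)
    passes = total > min_reads and unique_present and enrichment_ok
    return NatSirnaCall(
        pair_id=pair.pair_id,
        plus=plus,
        minus=minus,
        total_reads=total,
        unique_read_present=unique_present,
        enrichment_ok=enrichment_ok,
        passes=passes,
    )


def overlap_read_fraction(pair: CisNatPair, store: AlignmentStore) -> float | None:
    """Count-weighted fraction of the pair's reads lying inside the overlap;
    ``None`` when the pair carries no reads at all."""
    span0 = min(pair.gene_plus.start, pair.gene_minus.start)
    span1 = max(pair.gene_plus.end, pair.gene_minus.end)
    all_reads = store.overlapping(pair.contig, span0, span1)
    total = sum(a.count for a in all_reads)
    if total == 0:
        return None
    inside = sum(
        a.count for a in all_reads if a.start >= pair.overlap_start and a.end <= pair.overlap_end
    )
    return inside / total


def write_pair_table(
    pairs: Sequence[CisNatPair],
    calls: dict[str, NatSirnaCall] | None,
    path: str | Path,
) -> None:
    """TSV mirroring the published per-pair layout: id, contig, type,
    overlap coordinates, per-strand reads-in-overlap and 21-nt%."""
    with open(path, "w") as fh:
        fh.write(
            "pair_id\tcontig\ttype\tstart\tend\t"
            "plus_reads_in_overlap\tplus_21nt_pct\tminus_reads_in_overlap\tminus_21nt_pct\tnat_sirna\n"
        )
        for p in pairs:
            call = calls.get(p.pair_id) if calls else None
            if call:
                row = (
                    f"{call.plus.reads}\t{100 * call.plus.fraction_21nt:.1f}%\t"
                    f"{call.minus.reads}\t{100 * call.minus.fraction_21nt:.1f}%\t{int(call.passes)}"
                )
            else:
                row = ".\t.\t.\t.\t."
            orient = {"convergent": "3'-3'", "divergent": "5'-5'", "enclosed": "enclosed"}[p.orientation]
            fh.write(f"{p.pair_id}\t{p.contig}\t{orient}\t{p.overlap_start}\t{p.overlap_end}\t{row}\n")


def write_overlap_bed(pairs: Sequence[CisNatPair], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            fh.write(f"{p.contig}\t{p.overlap_start}\t{p.overlap_end}\t{p.pair_id}\t0\t+\n")
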