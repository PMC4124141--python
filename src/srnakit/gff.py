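"""Gene models and GFF3 reading/writing.

GFF3 is 1-based inclusive on disk; everything in memory is 0-based
half-open.  Parsing goes through gffutils (in-memory database); writing is
plain formatted text so round-trips are byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    contig: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise AnnotationError(f"gene {self.gene_id} lacks a strand")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise AnnotationError(f"gene {self.gene_id}: exon [{s},{e}) outside gene interval")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


def parse_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (with attached exons) from a GFF3 file."""
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # pragma: no cover - gffutils wraps parse errors
        raise AnnotationError(f"malformed GFF3 {path}: {exc}") from exc
    genes = []
    for feat in db.features_of_type("gene"):
        if feat.strand not in "+-":
            raise AnnotationError(f"gene {feat.id} lacks a strand")
        exons = tuple(
            sorted((child.start - 1, child.end) for child in db.children(feat, featuretype="exon"))
        )
        genes.append(
            GeneModel(
                gene_id=feat.id,
                contig=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                exons=exons,
            )
        )
    genes.sort(key=lambda g: (g.contig, g.start, g.gene_id))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path, source: str = "srnakit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig, g.start, g.gene_id)):
            fh.write(
                f"{g.contig}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.contig}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


@dataclass
class FeatureLine:
    """A generic GFF3 feature line for annotation outputs (hairpins, loci)."""

    contig: str
    feature_type: str
    start: int  # 0-based
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    def format(self, source: str = "srnakit") -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items())
        return f"{self.contig}\t{source}\t{self.feature_type}\t{self.start + 1}\t{self.end}\t.\t{self.strand}\t.\t{attrs}"


def write_feature_gff3(features: Iterable[FeatureLine], path: str | Path, source: str = "srnakit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(f.format(source) + "\n")
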