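"""Pipeline configuration: every tunable threshold in one serializable place."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "srnakit_out"
    conditions: list[str] = field(default_factory=lambda: ["NC", "CA", "CCA", "CS"])

    # inputs; left None when the synthetic study is generated in-run
    simulate: bool = True
    simulation_overrides: dict = field(default_factory=dict)
    genome_fasta: str | None = None
    annotation_gff3: str | None = None
    fastq_by_condition: dict = field(default_factory=dict)
    mrna_counts_tsv: str | None = None
    known_mirna_fasta: str | None = None

    # preprocessing
    adapter_sequence: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_min_match: int = 7
    min_quality: int = 20

    # mapping
    max_mismatches: int = 1  # mapping bound; locus stages use the 0-mm subset

    # miRNA discovery
    mirna_min_reads: int = 10
    window_extension: int = 300
    window_size: int = 250
    window_step: int = 50
    min_mature_paired: int = 16
    max_duplex_bulge: int = 4

    # phased siRNA
    phas_cluster_window: int = 50
    phas_min_reads: int = 10
    phas_min_fraction_21nt: float = 0.70
    target_score_threshold: float = 4.0
    target_score_comparator: str = "le"  # penalty <= threshold accepts
    template_flank: int = 100
    shifted_register_min_fraction: float = 0.10

    # cis-NAT / nat-siRNA
    cisnat_min_overlap: int = 25
    natsirna_min_reads: int = 10
    natsirna_enrichment_fraction: float = 0.5

    # expression / DE
    mirna_fold_threshold: float = 1.5
    sirna_fold_threshold: float = 2.0
    mrna_fold_threshold: float = 4.0
    expression_cpm: float = 10.0
    onoff_cpm: float = 40.0
    sncrna_pseudocount: float = 1.0
    target_max_mismatches: int = 3
    target_min_reads: int = 10
    anticorrelation_min_target_fold: float = 2.0

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def to_dict(self) -> dict:
        return asdict(self)
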