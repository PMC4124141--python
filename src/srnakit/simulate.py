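"""Synthetic genome, annotation and small-RNA/mRNA library generator.

Builds a toy multi-contig genome with planted, machine-readable ground
truth for every downstream stage: miRNA hairpins with mature/star duplexes
carrying 2-nt 3' overhangs, TAS-like loci with two small-RNA trigger sites
and 21-nt phased products (plus a 10/11-nt shifted minor register),
cis-NAT gene pairs in all three orientations, background mRNA genes, and
condition-specific fold changes.  Libraries emulate the structure of a
chilling-stress experiment: four conditions (normal control NC, chilling
acclimation CA, chilling after acclimation CCA, chilling shock CS),
17-28-nt reads with a 21/24-nt length peak and a 5'-U bias, and a 3'
sequencing adapter on every read.

All randomness flows from ``SimulationSpec.seed``; regenerating with the
same spec is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from ._seq import revcomp
from .gff import GeneModel, write_gff3

MARGIN = 300  # minimum distance between a planted feature and anything else

# default fold applied per feature class to differentially expressed features
CLASS_FOLD = {"mirna": 1.5, "tas": 2.0, "cisnat": 2.0, "mrna": 4.0}


class PlacementError(RuntimeError):
    """Raised when a feature class cannot be placed without overlap."""


@dataclass
class SimulationSpec:
    seed: int = 0
    n_contigs: int = 4
    contig_length: int = 50_000
    n_mirna_loci: int = 20
    n_tas_loci: int = 5
    n_cisnat_pairs: int = 6
    n_mrna_genes: int = 60
    conditions: tuple[str, ...] = ("NC", "CA", "CCA", "CS")
    background_read_rate: float = 5.0  # reads per kb per library
    adapter_sequence: str = "TGGAATTCTCGGGTGCCAAGG"
    # per-feature base expression (expected reads per library at multiplier 1)
    mirna_expected_count: float = 100.0
    star_expected_count: float = 5.0
    tas_expected_count: float = 300.0
    cisnat_expected_count: float = 300.0
    shifted_register_fraction: float = 0.205  # of TAS reads, offset +10/11
    tas_sense_fraction: float = 0.7
    tas_21nt_fraction: float = 0.98  # rest are 22-nt isoforms
    cisnat_overlap_fraction: float = 0.8  # reads emitted inside the overlap
    five_prime_u_bias: float = 0.5  # P(force U at position 1 of background reads)
    de_fraction: float = 0.5  # fraction of features planted as DE
    mrna_mean_count: float = 5000.0
    fold_change_table: dict[str, dict[str, float]] | None = None

    def validate(self) -> None:
        if self.contig_length < 5000:
            raise ValueError("contig_length must be >= 5000")
        if not self.conditions:
            raise ValueError("at least one condition label required")
        if len(self.adapter_sequence) < 7:
            raise ValueError("adapter must be at least 7 nt")


@dataclass
class MirnaRecord:
    feature_id: str
    contig: str
    strand: str
    hairpin_start: int
    hairpin_end: int
    mature_arm: str  # '5p' or '3p'
    mature_start: int
    mature_end: int
    mature_seq: str  # DNA alphabet, 5'->3' on the transcribed strand
    star_start: int
    star_end: int
    star_seq: str


@dataclass
class TasRecord:
    feature_id: str
    contig: str
    strand: str
    locus_start: int
    locus_end: int
    site5: tuple[int, int]
    site3: tuple[int, int]
    cleavage5: int  # 0-based first base 3' of the 5'-site cut
    cleavage3: int
    trigger_seq: str
    phased_21mers: list[str] = field(default_factory=list)
    shifted_fraction: float = 0.0


@dataclass
class CisnatRecord:
    feature_id: str
    contig: str
    orientation: str  # convergent | divergent | enclosed
    gene_a: tuple[str, int, int, str]  # (id, start, end, strand)
    gene_b: tuple[str, int, int, str]
    overlap: tuple[int, int]
    sirna_emitting: bool = True


@dataclass
class PlantedTruth:
    mirna_records: list[MirnaRecord] = field(default_factory=list)
    tas_records: list[TasRecord] = field(default_factory=list)
    cisnat_records: list[CisnatRecord] = field(default_factory=list)
    expected_counts: dict[str, dict[str, float]] = field(default_factory=dict)
    fold_change_table: dict[str, dict[str, float]] = field(default_factory=dict)
    mrna_base_means: dict[str, float] = field(default_factory=dict)
    anticorrelated: list[tuple[str, str]] = field(default_factory=list)  # (sirna locus, target gene)
    de_features: dict[str, str] = field(default_factory=dict)  # feature -> up/down

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mirna_records": [asdict(r) for r in self.mirna_records],
            "tas_records": [asdict(r) for r in self.tas_records],
            "cisnat_records": [asdict(r) for r in self.cisnat_records],
            "expected_counts": self.expected_counts,
            "fold_change_table": self.fold_change_table,
            "mrna_base_means": self.mrna_base_means,
            "anticorrelated": self.anticorrelated,
            "de_features": self.de_features,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        truth = cls()
        for r in d["mirna_records"]:
            truth.mirna_records.append(MirnaRecord(**r))
        for r in d["tas_records"]:
            r["site5"] = tuple(r["site5"])
            r["site3"] = tuple(r["site3"])
            truth.tas_records.append(TasRecord(**r))
        for r in d["cisnat_records"]:
            r["gene_a"] = tuple(r["gene_a"])
            r["gene_b"] = tuple(r["gene_b"])
            r["overlap"] = tuple(r["overlap"])
            truth.cisnat_records.append(CisnatRecord(**r))
        truth.expected_counts = d["expected_counts"]
        truth.fold_change_table = d["fold_change_table"]
        truth.mrna_base_means = d["mrna_base_means"]
        truth.anticorrelated = [tuple(x) for x in d["anticorrelated"]]
        truth.de_features = d["de_features"]
        return truth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def plant_hairpin(
    mature: str,
    loop_len: int,
    seed: int,
    arm: str = "5p",
) -> tuple[str, dict[str, tuple[int, int]]]:
    """Construct a miRNA hairpin around a mature sequence.

    The star strand is ``revcomp(mature[:-2])`` plus two free 3' bases, so
    the mature/star duplex carries exactly 2-nt 3' overhangs on both
    strands: mature position i pairs with star position n-3-i for
    i in [0, n-3].  ``arm`` selects whether the mature sits on the 5' or
    3' arm of the hairpin.  Returns the hairpin sequence and the arm
    coordinates (half-open intervals within the hairpin).
    """
    n = len(mature)
    if not (20 <= n <= 24):
        raise ValueError(f"mature length {n} outside [20, 24]")
    if loop_len < 3:
        raise ValueError("hairpin loop must be at least 3 nt")
    rng = np.random.default_rng(seed)
    mature = mature.upper().replace("U", "T")
    core = revcomp(mature[: n - 2])
    # two star 3'-overhang bases; copying the opposing mature bases guarantees
    # they cannot form Watson-Crick or G:U pairs with them
    overhang = mature[1] + mature[0]
    star = core + overhang
    loop = _random_seq(rng, loop_len)
    if arm == "5p":
        hairpin = mature + loop + star
        coords = {
            "mature": (0, n),
            "star": (n + loop_len, n + loop_len + n),
        }
    elif arm == "3p":
        hairpin = star + loop + mature
        coords = {
            "star": (0, n),
            "mature": (n + loop_len, n + loop_len + n),
        }
    else:
        raise ValueError("arm must be '5p' or '3p'")
    return hairpin, coords


class _Placer:
    """Sequential non-overlapping feature placement with fixed margins."""

    def __init__(self, spec: SimulationSpec, rng: np.random.Generator):
        self.spec = spec
        self.rng = rng
        self.cursors = {f"contig{i + 1:02d}": MARGIN for i in range(spec.n_contigs)}
        self._order = list(self.cursors)
        self._next = 0

    def place(self, length: int, feature_class: str) -> tuple[str, int]:
        for _ in range(len(self._order)):
            contig = self._order[self._next % len(self._order)]
            self._next += 1
            gap = int(self.rng.integers(50, 300))
            pos = self.cursors[contig] + gap
            if pos + length + MARGIN <= self.spec.contig_length:
                self.cursors[contig] = pos + length
                return contig, pos
        raise PlacementError(f"cannot place {feature_class}: contigs exhausted")


def _default_fold_plan(
    feature_ids: dict[str, list[str]], spec: SimulationSpec
) -> tuple[dict[str, dict[str, float]], dict[str, str]]:
    """Graded fold-change plan: DE features change by their class fold per
    severity step (CA: f, CCA and CS: f^2).

    Directions are assigned greedily so the expected small-RNA read mass
    added by up-regulated features cancels the mass removed by
    down-regulated ones: total-count normalization (N * C / T) assumes the
    library composition stays balanced, as it does in a deep, diverse real
    library.  mRNA features do not enter the small-RNA totals and simply
    alternate directions.
    """
    table: dict[str, dict[str, float]] = {}
    directions: dict[str, str] = {}
    severity = {"CA": 1, "CCA": 2, "CS": 2}
    class_base = {
        "mirna": spec.mirna_expected_count + spec.star_expected_count,
        "tas": spec.tas_expected_count,
        "cisnat": spec.cisnat_expected_count,
    }

    de_list: list[tuple[str, str]] = []  # (class, feature id)
    for cls, ids in feature_ids.items():
        n_de = int(round(len(ids) * spec.de_fraction))
        for i, fid in enumerate(ids):
            table[fid] = {c: 1.0 for c in spec.conditions}
            if i < n_de:
                de_list.append((cls, fid))

    # balance the severity-2 mass shift across the small-RNA classes
    srna_de = sorted(
        (x for x in de_list if x[0] != "mrna"),
        key=lambda x: -class_base[x[0]],
    )
    imbalance = 0.0
    for cls, fid in srna_de:
        f, base = CLASS_FOLD[cls], class_base[cls]
        delta_up = base * (f**2 - 1)
        delta_down = -base * (1 - f**-2)
        up = abs(imbalance + delta_up) <= abs(imbalance + delta_down)
        imbalance += delta_up if up else delta_down
        directions[fid] = "up" if up else "down"
    for j, (cls, fid) in enumerate(x for x in de_list if x[0] == "mrna"):
        directions[fid] = "up" if j % 2 == 0 else "down"

    for (cls, fid) in de_list:
        f = CLASS_FOLD[cls]
        sign = 1 if directions[fid] == "up" else -1
        for cond in spec.conditions:
            step = severity.get(cond, 0)
            if step:
                table[fid][cond] = f ** (sign * step)
    return table, directions


def generate_reference(
    spec: SimulationSpec,
) -> tuple[dict[str, str], list[GeneModel], PlantedTruth]:
    """Generate the toy genome, gene annotation and planted truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = PlantedTruth()
    placer = _Placer(spec, rng)

    contig_arrays = {
        name: rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=spec.contig_length)
        for name in placer.cursors
    }

    def write_seq(contig: str, pos: int, seq: str) -> None:
        contig_arrays[contig][pos : pos + len(seq)] = np.frombuffer(seq.encode(), dtype="S1")

    def read_seq(contig: str, start: int, end: int) -> str:
        return contig_arrays[contig][start:end].tobytes().decode()

    genes: list[GeneModel] = []

    # ------------------------------------------------------------------ miRNAs
    for i in range(spec.n_mirna_loci):
        mature = "T" + _random_seq(rng, 20)  # 21 nt with the canonical 5'-U
        loop_len = int(rng.integers(8, 16))
        arm = "5p" if rng.random() < 0.5 else "3p"
        hairpin, coords = plant_hairpin(mature, loop_len, seed=int(rng.integers(2**31)), arm=arm)
        strand = "+" if rng.random() < 0.5 else "-"
        contig, pos = placer.place(len(hairpin), "mirna")
        planted = hairpin if strand == "+" else revcomp(hairpin)
        write_seq(contig, pos, planted)
        H = len(hairpin)

        def genomic(iv: tuple[int, int]) -> tuple[int, int]:
            return (pos + iv[0], pos + iv[1]) if strand == "+" else (pos + H - iv[1], pos + H - iv[0])

        m_iv, s_iv = genomic(coords["mature"]), genomic(coords["star"])
        star_seq = hairpin[coords["star"][0] : coords["star"][1]]
        truth.mirna_records.append(
            MirnaRecord(
                feature_id=f"MIR-{i + 1}",
                contig=contig,
                strand=strand,
                hairpin_start=pos,
                hairpin_end=pos + H,
                mature_arm=arm,
                mature_start=m_iv[0],
                mature_end=m_iv[1],
                mature_seq=mature,
                star_start=s_iv[0],
                star_end=s_iv[1],
                star_seq=star_seq,
            )
        )

    # --------------------------------------------------------------- TAS loci
    for i in range(spec.n_tas_loci):
        if i < len(truth.mirna_records):
            trigger = truth.mirna_records[i].mature_seq
        else:
            trigger = "T" + _random_seq(rng, 20)
        k = int(rng.integers(8, 11))  # inter-cleavage distance = 21 * k
        pad = 30
        site_len = len(trigger)
        length = pad + site_len + (21 * k - 11) + 10 + pad
        contig, pos = placer.place(length, "tas")
        site5 = (pos + pad, pos + pad + site_len)
        c5 = site5[1] - 10
        c3 = c5 + 21 * k
        site3 = (c3 - 11, c3 + 10)
        locus = (pos, site3[1] + pad)
        write_seq(contig, site5[0], revcomp(trigger))
        write_seq(contig, site3[0], revcomp(trigger))
        phased = [read_seq(contig, c5 + 21 * j, c5 + 21 * j + 21) for j in range(k)]
        rec = TasRecord(
            feature_id=f"TAS-{i + 1}",
            contig=contig,
            strand="+",
            locus_start=locus[0],
            locus_end=locus[1],
            site5=site5,
            site3=site3,
            cleavage5=c5,
            cleavage3=c3,
            trigger_seq=trigger,
            phased_21mers=phased,
            shifted_fraction=spec.shifted_register_fraction,
        )
        truth.tas_records.append(rec)
        genes.append(
            GeneModel(
                gene_id=rec.feature_id,
                contig=contig,
                start=locus[0],
                end=locus[1],
                strand="+",
                exons=((locus[0], locus[1]),),
            )
        )

    # ------------------------------------------------------------ cis-NAT pairs
    orientations = ["convergent", "divergent", "enclosed"]
    for i in range(spec.n_cisnat_pairs):
        orient = orientations[i % 3]
        la = int(rng.integers(400, 700))
        lb = int(rng.integers(400, 700)) if orient != "enclosed" else int(rng.integers(150, 250))
        ov = int(rng.integers(100, 200))
        if orient == "convergent":
            span = la + lb - ov
            a_iv, a_strand = (0, la), "+"
            b_iv, b_strand = (la - ov, la - ov + lb), "-"
        elif orient == "divergent":
            span = la + lb - ov
            b_iv, b_strand = (0, lb), "-"
            a_iv, a_strand = (lb - ov, lb - ov + la), "+"
        else:  # enclosed: minus-strand gene inside the plus-strand gene
            span = la
            off = int(rng.integers(50, la - lb - 50))
            a_iv, a_strand = (0, la), "+"
            b_iv, b_strand = (off, off + lb), "-"
        contig, pos = placer.place(span, "cisnat")
        a = (f"natA-{i + 1}", pos + a_iv[0], pos + a_iv[1], a_strand)
        b = (f"natB-{i + 1}", pos + b_iv[0], pos + b_iv[1], b_strand)
        ov_iv = (max(a[1], b[1]), min(a[2], b[2]))
        rec = CisnatRecord(
            feature_id=f"cisNAT-{i + 1}",
            contig=contig,
            orientation=orient,
            gene_a=a,
            gene_b=b,
            overlap=ov_iv,
            sirna_emitting=True,
        )
        truth.cisnat_records.append(rec)
        for gid, gs, ge, gstrand in (a, b):
            genes.append(
                GeneModel(gene_id=gid, contig=contig, start=gs, end=ge, strand=gstrand, exons=((gs, ge),))
            )

    # ------------------------------------------------------- background mRNAs
    mrna_ids = []
    for i in range(spec.n_mrna_genes):
        length = int(rng.integers(500, 1500))
        contig, pos = placer.place(length, "mrna")
        gid = f"gene-{i + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(gene_id=gid, contig=contig, start=pos, end=pos + length, strand=strand, exons=((pos, pos + length),))
        )
        mrna_ids.append(gid)

    # fold-change plan ---------------------------------------------------------
    feature_ids = {
        "mirna": [r.feature_id for r in truth.mirna_records],
        "tas": [r.feature_id for r in truth.tas_records],
        "cisnat": [r.feature_id for r in truth.cisnat_records if r.sirna_emitting],
        "mrna": mrna_ids,
    }
    if spec.fold_change_table is not None:
        table = {fid: dict(m) for fid, m in spec.fold_change_table.items()}
        for fid, mults in table.items():
            unknown = set(mults) - set(spec.conditions)
            if unknown:
                raise ValueError(f"unknown condition label(s) {sorted(unknown)} for {fid}")
        directions = {}
    else:
        table, directions = _default_fold_plan(feature_ids, spec)
    truth.fold_change_table = table
    truth.de_features = directions

    # mRNA base means: mixture of silent genes and an expressed lognormal bulk
    gene_lookup = {g.gene_id: g for g in genes}
    for gid in mrna_ids + [r.feature_id for r in truth.tas_records] + [
        g for r in truth.cisnat_records for g in (r.gene_a[0], r.gene_b[0])
    ]:
        if rng.random() < 0.2 and gid.startswith("gene-"):
            truth.mrna_base_means[gid] = 1.5  # below the 10-CPM expression call
        else:
            truth.mrna_base_means[gid] = float(
                spec.mrna_mean_count * rng.lognormal(mean=0.0, sigma=0.5)
            )

    # anti-correlation plants: a DE TAS locus's phased product gets a perfect
    # target site inside an mRNA gene regulated in the opposite direction
    de_tas = [r for r in truth.tas_records if r.feature_id in truth.de_features]
    target_pool = [
        gid for gid in mrna_ids
        if truth.fold_change_table.get(gid, {}) == {c: 1.0 for c in spec.conditions}
        and truth.mrna_base_means[gid] > 100
    ]
    severity = {"CA": 1, "CCA": 2, "CS": 2}
    for rec, gid in zip(de_tas[:2], target_pool[:2]):
        sirna = rec.phased_21mers[min(3, len(rec.phased_21mers) - 1)]  # D4-like product
        g = gene_lookup[gid]
        insert_at = g.start + (len(g) - 21) // 2
        # the gene's cDNA must contain revcomp(sirna): on a minus-strand gene
        # the genomic insert is therefore the siRNA sequence itself
        write_seq(g.contig, insert_at, revcomp(sirna) if g.strand == "+" else sirna)
        f = CLASS_FOLD["mrna"]
        sign = -1 if truth.de_features[rec.feature_id] == "up" else 1
        truth.fold_change_table[gid] = {
            c: float(f ** (sign * severity.get(c, 0))) for c in spec.conditions
        }
        truth.de_features[gid] = "down" if sign < 0 else "up"
        truth.mrna_base_means[gid] = max(truth.mrna_base_means[gid], 2000.0)
        truth.anticorrelated.append((rec.feature_id, gid))

    # expected sncRNA read counts per condition -------------------------------
    base = {}
    for r in truth.mirna_records:
        base[r.feature_id] = spec.mirna_expected_count
        base[r.feature_id + "*"] = spec.star_expected_count
    for r in truth.tas_records:
        base[r.feature_id] = spec.tas_expected_count
    for r in truth.cisnat_records:
        if r.sirna_emitting:
            base[r.feature_id] = spec.cisnat_expected_count
    for fid, b in base.items():
        parent = fid.rstrip("*")
        mults = truth.fold_change_table.get(parent, {c: 1.0 for c in spec.conditions})
        truth.expected_counts[fid] = {c: b * mults.get(c, 1.0) for c in spec.conditions}

    genome = {name: arr.tobytes().decode() for name, arr in contig_arrays.items()}
    genes.sort(key=lambda g: (g.contig, g.start, g.gene_id))
    # re-read planted sub-sequences that could have been overwritten (none by
    # construction: the placer spaces features by >= 50 nt)
    return genome, genes, truth


# --------------------------------------------------------------------------
# library emission
# --------------------------------------------------------------------------

_BG_LENGTHS = np.arange(17, 29)
_BG_WEIGHTS = np.array([1, 1, 1, 1, 2, 1, 1, 3, 1, 1, 1, 1], dtype=float)
_BG_WEIGHTS /= _BG_WEIGHTS.sum()


def emit_condition_reads(
    genome: dict[str, str],
    truth: PlantedTruth,
    spec: SimulationSpec,
    condition: str,
    rng: np.random.Generator,
) -> list[tuple[str, str | None]]:
    """Emit one condition library as (sequence, source-feature-id) tuples.

    Planted features are emitted at their expected counts (Poisson); the
    background is uniform over the genome and strand-symmetric.  Background
    reads carry the 5'-U bias; feature reads are exact genomic slices.
    """
    if condition not in spec.conditions:
        raise ValueError(f"unknown condition label {condition!r}")
    reads: list[tuple[str, str | None]] = []

    def slice_read(contig: str, start: int, end: int, strand: str) -> str:
        seq = genome[contig][start:end]
        return seq if strand == "+" else revcomp(seq)

    for rec in truth.mirna_records:
        n = rng.poisson(truth.expected_counts[rec.feature_id][condition])
        reads += [(rec.mature_seq, rec.feature_id)] * int(n)
        n_star = rng.poisson(truth.expected_counts[rec.feature_id + "*"][condition])
        reads += [(rec.star_seq, rec.feature_id + "*")] * int(n_star)

    for rec in truth.tas_records:
        n = int(rng.poisson(truth.expected_counts[rec.feature_id][condition]))
        k = (rec.cleavage3 - rec.cleavage5) // 21
        for _ in range(n):
            length = 21 if rng.random() < spec.tas_21nt_fraction else 22
            if rng.random() < rec.shifted_fraction:
                j = int(rng.integers(0, max(k - 1, 1)))
                start = rec.cleavage5 + 21 * j + int(rng.choice([10, 11]))
                seq = slice_read(rec.contig, start, start + length, "+")
            elif rng.random() < spec.tas_sense_fraction:
                j = int(rng.integers(0, k))
                start = rec.cleavage5 + 21 * j
                seq = slice_read(rec.contig, start, start + length, "+")
            else:
                j = int(rng.integers(0, k))
                end = rec.cleavage5 + 2 + 21 * j
                seq = slice_read(rec.contig, end - length, end, "-")
            reads.append((seq, rec.feature_id))

    for rec in truth.cisnat_records:
        if not rec.sirna_emitting:
            continue
        n = int(rng.poisson(truth.expected_counts[rec.feature_id][condition]))
        ov0, ov1 = rec.overlap
        outside: list[tuple[int, int]] = []
        for _, gs, ge, _s in (rec.gene_a, rec.gene_b):
            if gs < ov0 - 24:
                outside.append((gs, ov0 - 24))
            if ge > ov1 + 24:
                outside.append((ov1, ge - 24))
        weights = np.array([e - s for s, e in outside], dtype=float)
        for _ in range(n):
            length = 21 if rng.random() < 0.9 else int(rng.choice([20, 22, 23, 24]))
            strand = "+" if rng.random() < 0.5 else "-"
            if outside and rng.random() >= spec.cisnat_overlap_fraction:
                seg = outside[int(rng.choice(len(outside), p=weights / weights.sum()))]
                start = int(rng.integers(seg[0], seg[1]))
            else:
                start = int(rng.integers(ov0, ov1 - length + 1))
            reads.append((slice_read(rec.contig, start, start + length, strand), rec.feature_id))

    total_kb = sum(len(s) for s in genome.values()) / 1000.0
    n_bg = int(rng.poisson(spec.background_read_rate * total_kb))
    contigs = sorted(genome)
    lengths = np.array([len(genome[c]) for c in contigs], dtype=float)
    for _ in range(n_bg):
        ci = int(rng.choice(len(contigs), p=lengths / lengths.sum()))
        contig = contigs[ci]
        length = int(rng.choice(_BG_LENGTHS, p=_BG_WEIGHTS))
        start = int(rng.integers(0, len(genome[contig]) - length))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = slice_read(contig, start, start + length, strand)
        if rng.random() < spec.five_prime_u_bias:
            seq = "T" + seq[1:]
        reads.append((seq, None))
    return reads


def simulate_mrna_counts(
    truth: PlantedTruth, spec: SimulationSpec, rng: np.random.Generator
) -> dict[str, dict[str, int]]:
    """Per-condition mRNA tag counts (Poisson around base mean x multiplier)."""
    counts: dict[str, dict[str, int]] = {}
    for gid, mean in truth.mrna_base_means.items():
        mults = truth.fold_change_table.get(gid, {})
        counts[gid] = {
            c: int(rng.poisson(mean * mults.get(c, 1.0))) for c in spec.conditions
        }
    return counts


@dataclass
class LibraryBundle:
    genome_path: Path
    annotation_path: Path
    truth_path: Path
    fastq_paths: dict[str, Path]
    mrna_counts_path: Path
    known_mirna_path: Path


def simulate_libraries(
    genome: dict[str, str],
    annotation: list[GeneModel],
    truth: PlantedTruth,
    spec: SimulationSpec,
    outdir: str | Path,
) -> LibraryBundle:
    """Write the full synthetic study to ``outdir``.

    Produces the genome FASTA, annotation GFF3, truth manifest JSON,
    per-condition small-RNA FASTQ files (adapter appended, constant
    Phred+33 quality), the mRNA count TSV, and a known-miRNA FASTA (the
    planted matures, usable for re-annotation runs).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome_path = outdir / "genome.fasta"
    with open(genome_path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    annotation_path = outdir / "annotation.gff3"
    write_gff3(annotation, annotation_path)
    truth_path = outdir / "truth.json"
    truth.to_json(truth_path)

    fastq_paths: dict[str, Path] = {}
    for ci, condition in enumerate(spec.conditions):
        rng = np.random.default_rng([spec.seed, 1000 + ci])
        reads = emit_condition_reads(genome, truth, spec, condition, rng)
        path = outdir / f"{condition}.fastq"
        with open(path, "w") as fh:
            for i, (seq, _src) in enumerate(reads, start=1):
                full = seq + spec.adapter_sequence
                fh.write(f"@{condition}_r{i}\n{full}\n+\n{'I' * len(full)}\n")
        fastq_paths[condition] = path

    rng = np.random.default_rng([spec.seed, 2000])
    counts = simulate_mrna_counts(truth, spec, rng)
    mrna_path = outdir / "mrna_counts.tsv"
    with open(mrna_path, "w") as fh:
        fh.write("feature_id\t" + "\t".join(spec.conditions) + "\n")
        for gid in sorted(counts):
            fh.write(gid + "\t" + "\t".join(str(counts[gid][c]) for c in spec.conditions) + "\n")

    known_path = outdir / "known_mirnas.fasta"
    with open(known_path, "w") as fh:
        for rec in truth.mirna_records:
            fh.write(f">{rec.feature_id}\n{rec.mature_seq}\n")

    return LibraryBundle(
        genome_path=genome_path,
        annotation_path=annotation_path,
        truth_path=truth_path,
        fastq_paths=fastq_paths,
        mrna_counts_path=mrna_path,
        known_mirna_path=known_path,
    )


def transcript_sequences(genome: dict[str, str], genes: list[GeneModel]) -> dict[str, str]:
    """cDNA sequences (5'->3') for single- or multi-exon gene models."""
    out = {}
    for g in genes:
        parts = [genome[g.contig][s:e] for s, e in (g.exons or ((g.start, g.end),))]
        seq = "".join(parts)
        out[g.gene_id] = seq if g.strand == "+" else revcomp(seq)
    return out
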