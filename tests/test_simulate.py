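"""Synthetic-study generator: geometry, determinism and emission contracts."""

import numpy as np
import pytest

from srnakit._seq import revcomp
from srnakit.mirna import nussinov_fold
from srnakit.simulate import (
    PlacementError,
    SimulationSpec,
    emit_condition_reads,
    generate_reference,
    plant_hairpin,
    simulate_libraries,
    simulate_mrna_counts,
)


def _pairs_with(s_base, m_base):
    return {frozenset(p) for p in [("A", "T"), ("G", "C"), ("G", "T")]} >= {frozenset((s_base, m_base))}


class TestPlantHairpin:
    def test_duplex_carries_two_nt_three_prime_overhangs(self):
        mature = "TGGACGCCATTTTGACAGATG"  # a published novel mature sequence
        hairpin, coords = plant_hairpin(mature, loop_len=10, seed=3)
        m0, m1 = coords["mature"]
        s0, s1 = coords["star"]
        star = hairpin[s0:s1]
        n = len(mature)
        # star positions 0..n-3 are the reverse complement of mature[0:n-2]
        assert star[: n - 2] == revcomp(mature[: n - 2])
        # the two star 3'-end bases cannot pair with the mature 5' end
        assert not _pairs_with(star[n - 2], mature[1])
        assert not _pairs_with(star[n - 1], mature[0])
        assert hairpin[m0:m1] == mature

    def test_hairpin_length_arithmetic(self):
        mature = "A" * 10 + "TGCTGCAGGTC"  # 21 nt
        hairpin, _ = plant_hairpin(mature, loop_len=3, seed=0)
        assert len(hairpin) == 2 * 21 + 3

    @pytest.mark.parametrize("arm", ["5p", "3p"])
    def test_folding_pairs_mature_positions(self, arm):
        rng = np.random.default_rng(9)
        mature = "T" + "".join(rng.choice(list("ACGT"), size=20))
        hairpin, coords = plant_hairpin(mature, loop_len=8, seed=4, arm=arm)
        fold = nussinov_fold(hairpin)
        m0, m1 = coords["mature"]
        # exhaustive pair count of the constructed duplex: 19 designed pairs
        assert sum(fold.pairs[i] >= 0 for i in range(m0, m1)) >= 17

    def test_short_loop_rejected(self):
        with pytest.raises(ValueError):
            plant_hairpin("A" * 21, loop_len=2, seed=0)


class TestGenerateReference:
    def test_empty_plant_case(self):
        spec = SimulationSpec(seed=3, n_mirna_loci=0, n_tas_loci=0, n_cisnat_pairs=0, n_mrna_genes=0)
        genome, annotation, truth = generate_reference(spec)
        assert truth.mirna_records == [] and truth.tas_records == [] and truth.cisnat_records == []
        assert annotation == []
        assert len(genome) == spec.n_contigs

    def test_tas_intersite_distance_multiple_of_21(self, small_reference):
        _, _, truth = small_reference
        for rec in truth.tas_records:
            distance = rec.cleavage3 - rec.cleavage5
            assert distance % 21 == 0
            assert len(rec.phased_21mers) == distance // 21

    def test_phased_21mers_tile_intersite_region(self, small_reference):
        genome, _, truth = small_reference
        for rec in truth.tas_records:
            for j, mer in enumerate(rec.phased_21mers):
                start = rec.cleavage5 + 21 * j
                assert genome[rec.contig][start : start + 21] == mer

    def test_trigger_sites_are_complementary(self, small_reference):
        genome, _, truth = small_reference
        for rec in truth.tas_records:
            for s0, s1 in (rec.site5, rec.site3):
                assert genome[rec.contig][s0:s1] == revcomp(rec.trigger_seq)

    def test_mature_planted_at_recorded_interval(self, small_reference):
        genome, _, truth = small_reference
        for rec in truth.mirna_records:
            raw = genome[rec.contig][rec.mature_start : rec.mature_end]
            observed = raw if rec.strand == "+" else revcomp(raw)
            assert observed == rec.mature_seq

    def test_cisnat_orientation_matches_geometry(self, small_reference):
        _, _, truth = small_reference
        seen = set()
        for rec in truth.cisnat_records:
            seen.add(rec.orientation)
            a, b = rec.gene_a, rec.gene_b
            plus, minus = (a, b) if a[3] == "+" else (b, a)
            if rec.orientation == "enclosed":
                assert (plus[1] <= minus[1] and minus[2] <= plus[2]) or (
                    minus[1] <= plus[1] and plus[2] <= minus[2]
                )
            elif rec.orientation == "convergent":
                assert plus[1] < minus[1]
            else:
                assert minus[1] < plus[1]
            ov = (max(a[1], b[1]), min(a[2], b[2]))
            assert tuple(rec.overlap) == ov and ov[1] - ov[0] >= 25
        assert seen == {"convergent", "divergent", "enclosed"}

    def test_determinism_byte_identical(self, tmp_path):
        spec = SimulationSpec(seed=5, n_mirna_loci=3, n_tas_loci=1, n_cisnat_pairs=1, n_mrna_genes=4)
        outputs = []
        for sub in ("a", "b"):
            genome, annotation, truth = generate_reference(spec)
            bundle = simulate_libraries(genome, annotation, truth, spec, tmp_path / sub)
            outputs.append(
                {
                    "genome": bundle.genome_path.read_bytes(),
                    "gff": bundle.annotation_path.read_bytes(),
                    "fastq": {c: p.read_bytes() for c, p in bundle.fastq_paths.items()},
                    "mrna": bundle.mrna_counts_path.read_bytes(),
                    "truth": bundle.truth_path.read_bytes(),
                }
            )
        assert outputs[0] == outputs[1]

    def test_placement_failure_names_feature_class(self):
        spec = SimulationSpec(seed=0, n_contigs=1, contig_length=5000, n_mirna_loci=50)
        with pytest.raises(PlacementError, match="mirna"):
            generate_reference(spec)

    def test_unknown_condition_in_fold_table_rejected(self):
        spec = SimulationSpec(
            seed=0, n_mirna_loci=1, n_tas_loci=0, n_cisnat_pairs=0, n_mrna_genes=0,
            fold_change_table={"MIR-1": {"FROST": 2.0}},
        )
        with pytest.raises(ValueError, match="FROST"):
            generate_reference(spec)


class TestEmission:
    def test_no_background_reads_all_inside_features(self):
        spec = SimulationSpec(
            seed=8, n_mirna_loci=2, n_tas_loci=1, n_cisnat_pairs=1, n_mrna_genes=0,
            background_read_rate=0.0, de_fraction=0.0,
        )
        genome, _, truth = generate_reference(spec)
        reads = emit_condition_reads(genome, truth, spec, "NC", np.random.default_rng(1))
        assert reads and all(src is not None for _, src in reads)
        intervals = []
        for r in truth.mirna_records:
            intervals.append((r.contig, r.hairpin_start, r.hairpin_end))
        for r in truth.tas_records:
            intervals.append((r.contig, r.locus_start, r.locus_end))
        for r in truth.cisnat_records:
            intervals.append((r.contig, min(r.gene_a[1], r.gene_b[1]), max(r.gene_a[2], r.gene_b[2])))
        for seq, _src in reads:
            found = any(
                genome[c][s:e].find(seq) != -1 or genome[c][s:e].find(revcomp(seq)) != -1
                for c, s, e in intervals
            )
            assert found

    def test_tas_reads_are_dominantly_21nt(self, small_reference, small_spec):
        genome, _, truth = small_reference
        reads = emit_condition_reads(genome, truth, small_spec, "NC", np.random.default_rng(2))
        tas = [seq for seq, src in reads if src and src.startswith("TAS")]
        frac21 = sum(len(s) == 21 for s in tas) / len(tas)
        assert frac21 >= 0.95

    def test_in_register_sense_starts_on_phase(self):
        spec = SimulationSpec(
            seed=13, n_mirna_loci=0, n_tas_loci=1, n_cisnat_pairs=0, n_mrna_genes=0,
            background_read_rate=0.0, shifted_register_fraction=0.0, tas_sense_fraction=1.0,
            de_fraction=0.0,
        )
        genome, _, truth = generate_reference(spec)
        rec = truth.tas_records[0]
        reads = emit_condition_reads(genome, truth, spec, "NC", np.random.default_rng(3))
        for seq, _ in reads:
            start = genome[rec.contig].find(seq)
            assert start != -1 and (start - rec.cleavage5) % 21 == 0

    def test_shifted_register_fraction_binomial(self):
        spec = SimulationSpec(
            seed=21, n_mirna_loci=0, n_tas_loci=1, n_cisnat_pairs=0, n_mrna_genes=0,
            background_read_rate=0.0, shifted_register_fraction=0.2,
            tas_expected_count=1000.0, de_fraction=0.0,
        )
        genome, _, truth = generate_reference(spec)
        rec = truth.tas_records[0]
        reads = emit_condition_reads(genome, truth, spec, "NC", np.random.default_rng(4))
        n_shift = 0
        for seq, _ in reads:
            start = genome[rec.contig].find(seq)
            if start != -1 and (start - rec.cleavage5) % 21 in (10, 11):
                n_shift += 1
        n = len(reads)
        sd = (0.2 * 0.8 / n) ** 0.5
        assert abs(n_shift / n - 0.2) < 3 * sd + 1e-9

    def test_expected_counts_follow_fold_table(self, small_reference, small_spec):
        _, _, truth = small_reference
        for fid, per_cond in truth.expected_counts.items():
            parent = fid.rstrip("*")
            mults = truth.fold_change_table.get(parent, {})
            base = per_cond["NC"] / mults.get("NC", 1.0)
            for cond, value in per_cond.items():
                assert value == pytest.approx(base * mults.get(cond, 1.0))

    def test_mrna_counts_deterministic_and_scaled(self, small_reference, small_spec):
        _, _, truth = small_reference
        c1 = simulate_mrna_counts(truth, small_spec, np.random.default_rng(6))
        c2 = simulate_mrna_counts(truth, small_spec, np.random.default_rng(6))
        assert c1 == c2
        assert set(c1) == set(truth.mrna_base_means)
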