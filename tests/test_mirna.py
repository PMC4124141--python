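"""Clustering, window enumeration, folding and miRNA candidate calling."""

import numpy as np
import pytest

from srnakit.mapping import Alignment, AlignmentStore
from srnakit.mirna import (
    PAIR_WEIGHTS,
    ReadCluster,
    Rejection,
    call_mirna,
    cluster_alignments,
    enumerate_windows,
    fold_hairpin,
    nussinov_fold,
    reannotate_known,
    vienna_fold,
)
from srnakit.preprocess import CollapsedRead
from srnakit.simulate import SimulationSpec, generate_reference, plant_hairpin


def _aln(start, end, contig="c", strand="+", count=1, seq=None):
    return Alignment(seq or "A" * (end - start), contig, start, end, strand, 0, 1, count, "NC")


class TestClustering:
    def test_overlapping_reads_merge(self):
        clusters = cluster_alignments([_aln(100, 121), _aln(110, 131)])
        assert len(clusters) == 1
        assert (clusters[0].start, clusters[0].end) == (100, 131)

    def test_touching_half_open_intervals_do_not_merge(self):
        clusters = cluster_alignments([_aln(100, 121), _aln(121, 142)])
        assert len(clusters) == 2

    def test_equals_connected_components_oracle(self, rng):
        alns = []
        for _ in range(100):
            s = int(rng.integers(0, 2000))
            alns.append(_aln(s, s + int(rng.integers(18, 25))))
        clusters = cluster_alignments(alns)
        # union-find oracle over pairwise interval overlaps
        parent = list(range(len(alns)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(alns)):
            for j in range(i + 1, len(alns)):
                if alns[i].start < alns[j].end and alns[j].start < alns[i].end:
                    parent[find(i)] = find(j)
        n_components = len({find(i) for i in range(len(alns))})
        assert len(clusters) == n_components
        assert sum(len(c.alignments) for c in clusters) == len(alns)


class TestWindows:
    def _cluster(self, start, end):
        return ReadCluster(contig="c", start=start, end=end, alignments=[])

    def test_single_window_when_span_fits(self):
        # extended span exactly 250 nt
        w = enumerate_windows(self._cluster(300, 350), contig_length=10_000, extension=100, window=250)
        assert w == [(200, 450)]

    def test_four_windows_span_400(self):
        w = enumerate_windows(self._cluster(300, 500), contig_length=10_000, extension=100, window=250, step=50)
        assert w == [(200, 450), (250, 500), (300, 550), (350, 600)]

    def test_thirteen_windows_span_849_clamped(self):
        # cluster of 249 nt extended 300 on both ends: 849-nt span
        w = enumerate_windows(self._cluster(300, 549), contig_length=10_000, extension=300, window=250, step=50)
        assert len(w) == 13
        assert w[0] == (0, 250)
        assert w[-1] == (599, 849)


class TestFolding:
    def test_perfect_inverted_repeat(self):
        fold = nussinov_fold("GGGGGAAACCCCC")
        assert fold.n_pairs() == 5
        assert fold.paired_fraction == pytest.approx(10 / 13)
        for i in range(5):
            assert fold.pairs[i] == 12 - i

    def test_homopolymer_has_no_pairs(self):
        assert nussinov_fold("A" * 30).n_pairs() == 0

    def test_pairing_is_nested_and_loops_are_legal(self, rng):
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            fold = nussinov_fold(seq)
            opened = []
            for i, j in enumerate(fold.pairs):
                if j < 0:
                    continue
                if j > i:
                    opened.append((i, j))
                    assert j - i - 1 >= 3  # min hairpin loop
                    assert (seq[i], seq[j]) in PAIR_WEIGHTS
            # non-crossing: each pair nests within the enclosing one
            stack = []
            for i, j in enumerate(fold.pairs):
                if j > i:
                    while stack and stack[-1] < i:
                        stack.pop()
                    if stack:
                        assert j < stack[-1]
                    stack.append(j)

    def test_dp_weight_matches_exhaustive_recursion(self, rng):
        from functools import lru_cache

        for _ in range(8):
            seq = "".join(rng.choice(list("ACGT"), size=42))

            @lru_cache(maxsize=None)
            def best(i, j):  # max weight over seq[i:j]
                if j - i < 2:
                    return 0
                score = best(i + 1, j)
                for k in range(i + 4, j):
                    w = PAIR_WEIGHTS.get((seq[i], seq[k]), 0)
                    if w:
                        score = max(score, best(i + 1, k) + best(k + 1, j) + w)
                return score

            fold = nussinov_fold(seq)
            weight = sum(
                PAIR_WEIGHTS[(seq[i], seq[j])] for i, j in enumerate(fold.pairs) if j > i
            )
            assert weight == best(0, len(seq))
            best.cache_clear()

    def test_fold_hairpin_length_bounds_and_alphabet(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGT" * 5)  # below 50 nt
        with pytest.raises(ValueError):
            nussinov_fold("ACGTX" * 20)

    def test_vienna_engine_honours_contract(self):
        hairpin, coords = plant_hairpin("TGGACGCCATTTTGACAGATG", 10, seed=1)
        fold = vienna_fold(hairpin)
        assert len(fold.pairs) == len(hairpin)
        m0, m1 = coords["mature"]
        assert sum(fold.pairs[i] >= 0 for i in range(m0, m1)) >= 17


class TestCallMirna:
    def _planted(self, mature_count=100, star_count=5, arm="5p"):
        rng = np.random.default_rng(17)
        mature = "T" + "".join(rng.choice(list("ACGT"), size=20))
        hairpin, coords = plant_hairpin(mature, loop_len=9, seed=2, arm=arm)
        flank = "".join(rng.choice(list("ACGT"), size=300))
        flank2 = "".join(rng.choice(list("ACGT"), size=300))
        genome = {"c": flank + hairpin + flank2}
        off = len(flank)
        m0, m1 = (coords["mature"][0] + off, coords["mature"][1] + off)
        s0, s1 = (coords["star"][0] + off, coords["star"][1] + off)
        alns = [
            _aln(m0, m1, count=mature_count, seq=genome["c"][m0:m1]),
            _aln(s0, s1, count=star_count, seq=genome["c"][s0:s1]),
        ]
        store = AlignmentStore(alns)
        cluster = cluster_alignments(alns)[0]  # the mature cluster
        return genome, cluster, store, (m0, m1), mature

    def test_planted_hairpin_accepted_with_planted_arm(self):
        genome, cluster, store, (m0, m1), mature = self._planted()
        result = call_mirna(cluster, store, genome)
        assert not isinstance(result, Rejection)
        cand = result[0]
        assert (cand.mature_start, cand.mature_end) == (m0, m1)
        assert cand.mature_seq.replace("U", "T") == mature
        assert cand.accepted and all(cand.criteria.values())
        assert all(1 <= o <= 3 for o in cand.overhang_3p)

    def test_insufficient_reads_rejected(self):
        genome, cluster, store, _, _ = self._planted(mature_count=7, star_count=1)
        result = call_mirna(cluster, store, genome)
        assert isinstance(result, Rejection)
        assert result.reason == "insufficient-reads"

    def test_dual_arm_reported_as_5p_and_3p(self):
        genome, cluster, store, _, _ = self._planted(mature_count=100, star_count=60)
        result = call_mirna(cluster, store, genome)
        assert not isinstance(result, Rejection)
        assert len(result) == 2
        assert {c.mature_arm for c in result} == {"5p", "3p"}

    def test_no_star_rejected(self):
        genome, cluster, store, _, _ = self._planted()
        lonely = [a for a in cluster.alignments]
        cluster_only = cluster_alignments(lonely[:1])[0]
        store_only = AlignmentStore(lonely[:1])
        cluster_only.alignments[0] = lonely[0]
        result = call_mirna(cluster_only, store_only, genome, min_reads=10)
        assert isinstance(result, Rejection)
        assert result.reason in {"no-star", "no-hairpin"}


class TestReannotateKnown:
    def test_exact_match_counted(self):
        known = {"mir-a": "TACAGCCTGACACAGTATGGC"}
        reads = [CollapsedRead("TACAGCCTGACACAGTATGGC", 40, "NC")]
        table, leftover = reannotate_known(known, reads)
        assert table["mir-a"]["NC"] == 40
        assert leftover == []

    def test_absent_mirna_retained_with_zero(self):
        known = {"mir-a": "TACAGCCTGACACAGTATGGC"}
        table, leftover = reannotate_known(known, [CollapsedRead("A" * 21, 3, "NC")])
        assert table["mir-a"] == {}
        assert len(leftover) == 1

    def test_one_nt_shifted_isomir_counted(self):
        mature = "TACAGCCTGACACAGTATGGC"
        known = {"mir-a": mature}
        shifted = CollapsedRead("G" + mature[:-1], 5, "CA")  # 1-nt 5' shift
        table, leftover = reannotate_known(known, [shifted])
        assert table["mir-a"]["CA"] == 5 and leftover == []

    def test_three_nt_shift_not_counted(self):
        mature = "TACAGCCTGACACAGTATGGC"
        known = {"mir-a": mature}
        shifted = CollapsedRead("GGG" + mature[:-3], 5, "CA")
        table, leftover = reannotate_known(known, [shifted])
        assert table["mir-a"] == {} and len(leftover) == 1

    def test_duplicate_fasta_ids_rejected(self, tmp_path):
        from srnakit.mirna import read_known_mirnas

        path = tmp_path / "known.fa"
        path.write_text(">a\nACGTACGTACGTACGTACGTA\n>a\nTGCATGCATGCATGCATGCAT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_known_mirnas(path)

    def test_exclusivity_no_read_in_both_pools(self, small_reference):
        genome, _, truth = small_reference
        known = {r.feature_id: r.mature_seq for r in truth.mirna_records[:2]}
        reads = [CollapsedRead(r.mature_seq, 10, "NC") for r in truth.mirna_records]
        table, leftover = reannotate_known(known, reads)
        counted = {seq for fid, per_lib in table.items() if per_lib for seq in [known[fid]]}
        assert counted.isdisjoint({r.sequence for r in leftover})
        assert len(leftover) == len(reads) - len(counted)


class TestEndToEndRecovery:
    def test_planted_hairpins_recovered(self, default_run):
        from srnakit.evaluate import mirna_recovery

        config, result, truth = default_run
        rec = mirna_recovery(result, truth)
        assert rec.recall >= 0.9
        assert rec.precision >= 0.9

    def test_every_accepted_candidate_passes_all_criteria(self, default_run):
        _, result, _ = default_run
        for cand in result.mirna_candidates:
            assert set(cand.criteria) == {"min_reads", "hairpin", "star_present", "duplex_overhangs"}
            assert cand.accepted
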