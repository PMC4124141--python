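"""Normalization formulas, rule-based DE and anti-correlated pairing."""

import numpy as np
import pandas as pd
import pytest

from srnakit._seq import revcomp
from srnakit.expression import (
    SIX_COMPARISONS,
    DECall,
    LibraryStats,
    call_de_mrna,
    call_de_sncrna,
    normalize_sncrna,
    pair_anticorrelated,
    predict_sirna_targets,
    quantify_mrna,
)


class TestSncrnaNormalization:
    def test_formula_n_times_c_over_t(self):
        # N = 100, T = 2,000,000, C = mean(T) = 1,500,000 -> 100 * C/T = 75
        stats = LibraryStats(totals={"this": 2_000_000.0, "other": 1_000_000.0})
        df = pd.DataFrame({"this": [100.0], "other": [100.0]}, index=["x"])
        out = normalize_sncrna(df, stats)
        assert stats.mean_total == pytest.approx(1_500_000.0)
        assert out.at["x", "this"] == pytest.approx(75.0)
        assert out.at["x", "other"] == pytest.approx(150.0)

    def test_equal_totals_is_identity(self):
        stats = LibraryStats(totals={"a": 5e5, "b": 5e5})
        df = pd.DataFrame({"a": [10.0, 3.0], "b": [7.0, 1.0]}, index=["x", "y"])
        assert normalize_sncrna(df, stats).equals(df)

    def test_conservation_every_library_totals_c(self, rng):
        totals = {"NC": 1_000_000.0, "CA": 3_000_000.0}
        stats = LibraryStats(totals=totals)
        counts = pd.DataFrame(
            {lib: rng.integers(0, 1000, size=50).astype(float) * (t / 1e6) for lib, t in totals.items()}
        )
        # make each column sum exactly to its T so conservation is visible
        for lib, t in totals.items():
            counts[lib] *= t / counts[lib].sum()
        scaled = normalize_sncrna(counts, stats)
        for lib in totals:
            assert scaled[lib].sum() == pytest.approx(stats.mean_total)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            LibraryStats(totals={"a": 0.0})


class TestMrnaQuantification:
    def test_cpm_expression_boundary(self):
        counts = pd.DataFrame({"NC": [10, 9, 999_981]}, index=["on", "off", "filler"])
        counts["NC"] = [10, 9, 1_000_000 - 19]
        expr = quantify_mrna(counts)
        assert bool(expr.expressed.at["on", "NC"]) is True  # CPM exactly 10
        assert bool(expr.expressed.at["off", "NC"]) is False

    def test_proportional_columns_equalize_after_uq(self):
        base = np.array([50.0, 120.0, 800.0, 4000.0, 90.0])
        counts = pd.DataFrame({"NC": base, "CA": base * 3})
        expr = quantify_mrna(counts)
        assert np.allclose(expr.normalized["NC"], expr.normalized["CA"])

    def test_uq_factors_closed_form(self):
        base = np.array([100.0, 200.0, 300.0, 400.0])
        counts = pd.DataFrame({"NC": base, "CA": base * 2})
        expr = quantify_mrna(counts)
        # proportional columns have identical CPM, hence equal quartiles
        assert expr.uq_factors["NC"] == pytest.approx(expr.uq_factors["CA"])
        assert expr.uq_factors["NC"] == pytest.approx(1.0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            quantify_mrna(pd.DataFrame())


class TestRuleBasedDE:
    def test_mrna_on_off_rule(self):
        # column totals of one million make counts read directly as CPM:
        # 8 CPM (not expressed) in NC vs 45 CPM (> 40) in CA fires the rule
        counts = pd.DataFrame(
            {"NC": [8, 1_000_000 - 8], "CA": [45, 1_000_000 - 45]}, index=["g", "filler"]
        )
        expr = quantify_mrna(counts)
        calls = [c for c in call_de_mrna(expr, [("CA", "NC")]) if c.feature_id == "g"]
        assert len(calls) == 1
        assert calls[0].rule == "on-off" and calls[0].direction == "up"

    @pytest.mark.parametrize("a,b,expected", [(30.0, 20.0, "up"), (29.0, 20.0, None), (20.0, 30.0, "down")])
    def test_mirna_fold_boundary(self, a, b, expected):
        table = pd.DataFrame({"CA": [a], "NC": [b]}, index=["m"])
        calls = call_de_sncrna(table, "miRNA", [("CA", "NC")], pseudocount=0.0)
        if expected is None:
            assert calls == []
        else:
            assert calls[0].direction == expected and calls[0].rule == "fold-rule"

    def test_sirna_locus_uses_two_fold(self):
        table = pd.DataFrame({"CA": [30.0], "NC": [20.0]}, index=["locus"])
        assert call_de_sncrna(table, "siRNA-locus", [("CA", "NC")], pseudocount=0.0) == []
        table = pd.DataFrame({"CA": [40.0], "NC": [20.0]}, index=["locus"])
        calls = call_de_sncrna(table, "siRNA-locus", [("CA", "NC")], pseudocount=0.0)
        assert calls and calls[0].direction == "up"

    def test_threshold_monotonicity(self, rng):
        table = pd.DataFrame(
            {c: rng.uniform(1, 200, size=40) for c in ("NC", "CA", "CCA", "CS")},
            index=[f"f{i}" for i in range(40)],
        )
        n_calls = [
            len(call_de_sncrna(table, "miRNA", SIX_COMPARISONS, threshold=t))
            for t in (1.2, 1.5, 2.0, 4.0)
        ]
        assert n_calls == sorted(n_calls, reverse=True)

    def test_pseudocount_damps_low_counts(self):
        table = pd.DataFrame({"CA": [3.0], "NC": [1.0]}, index=["m"])
        with_psi = call_de_sncrna(table, "miRNA", [("CA", "NC")], pseudocount=1.0)
        assert with_psi and with_psi[0].fold == pytest.approx(2.0)


class TestTargetPrediction:
    SIRNA = "TACAGCCTGACACAGTATGGC"

    def test_exact_revcomp_found(self):
        transcripts = {"t1": "G" * 30 + revcomp(self.SIRNA) + "G" * 30}
        targets = predict_sirna_targets({"s": self.SIRNA}, transcripts)
        assert len(targets) == 1
        assert targets[0].mismatches == 0 and targets[0].start == 30

    def test_four_mismatches_rejected(self):
        site = list(revcomp(self.SIRNA))
        for i in (0, 5, 10, 15):
            site[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[site[i]]
        transcripts = {"t1": "G" * 10 + "".join(site) + "G" * 10}
        assert predict_sirna_targets({"s": self.SIRNA}, transcripts) == []

    def test_read_floor_applies(self):
        transcripts = {"t1": revcomp(self.SIRNA)}
        targets = predict_sirna_targets(
            {"s": self.SIRNA}, transcripts, read_counts={"s": 10}, min_reads=10
        )
        assert targets == []  # strictly more than 10 reads required

    def test_matches_exhaustive_scan(self, rng):
        transcript = "".join(rng.choice(list("ACGT"), size=2000))
        transcripts = {"t": transcript}
        for _ in range(30):
            sirna = "".join(rng.choice(list("ACGT"), size=21))
            got = {(t.start, t.mismatches) for t in predict_sirna_targets({"s": sirna}, transcripts)}
            probe = revcomp(sirna)
            expected = set()
            for pos in range(len(transcript) - 20):
                mm = sum(a != b for a, b in zip(transcript[pos : pos + 21], probe))
                if mm <= 3:
                    expected.add((pos, mm))
            assert got == expected


class TestAnticorrelation:
    def _de(self, fid, cls, comp, fold, direction):
        return DECall(fid, cls, comp, fold, direction, "fold-rule")

    def test_opposite_directions_emit_pair(self):
        s = self._de("s", "siRNA-locus", ("CA", "NC"), 3.0, "up")
        t = self._de("t", "mRNA", ("CA", "NC"), 0.4, "down")
        pairs = pair_anticorrelated([s], [t], [("s", "t")])
        assert len(pairs) == 1
        assert pairs[0].sncrna_direction == "up" and pairs[0].target_direction == "down"

    def test_same_direction_no_pair(self):
        s = self._de("s", "siRNA-locus", ("CA", "NC"), 3.0, "up")
        t = self._de("t", "mRNA", ("CA", "NC"), 5.0, "up")
        assert pair_anticorrelated([s], [t], [("s", "t")]) == []

    def test_target_two_fold_filter(self):
        s = self._de("s", "siRNA-locus", ("CA", "NC"), 3.0, "up")
        t = self._de("t", "mRNA", ("CA", "NC"), 1 / 1.8, "down")
        assert pair_anticorrelated([s], [t], [("s", "t")]) == []

    def test_untargeted_mrna_no_pair(self):
        s = self._de("s", "siRNA-locus", ("CA", "NC"), 3.0, "up")
        t = self._de("t", "mRNA", ("CA", "NC"), 0.2, "down")
        assert pair_anticorrelated([s], [t], [("s", "other")]) == []

    def test_referential_integrity_in_pipeline(self, default_run):
        _, result, _ = default_run
        de_ids = {(c.feature_id, c.comparison, c.direction) for c in result.de_calls}
        for p in result.anticorrelated:
            assert (p.sncrna_id, p.comparison, p.sncrna_direction) in de_ids
            assert (p.target_id, p.comparison, p.target_direction) in de_ids
            assert p.sncrna_direction != p.target_direction
            mag = p.target_fold if p.target_fold >= 1 else 1 / p.target_fold
            assert mag >= 2.0

    def test_planted_cascade_recovered(self, default_run):
        """The planted siRNA-producing locus / target-gene couples come back
        as anti-correlated pairs with opposite directions."""
        _, result, truth = default_run
        from srnakit.evaluate import phas_locus_for

        found = {(p.sncrna_id, p.target_id) for p in result.anticorrelated}
        for tas_id, gene_id in truth.anticorrelated:
            rec = next(r for r in truth.tas_records if r.feature_id == tas_id)
            locus = phas_locus_for(result, rec.contig, rec.locus_start, rec.locus_end)
            assert locus is not None
            assert (locus.locus_id, gene_id) in found
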