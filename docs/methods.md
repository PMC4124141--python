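# Methods

This note documents the models and procedures srnakit implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## Read preprocessing

Raw reads carry a 3′ sequencing adapter. The trimmer searches for the
longest substring of the adapter occurring anywhere in the read and
truncates the read at the start of that occurrence; a read without any
adapter substring of at least `min_match = 7` nt is flagged as having no
adapter and discarded. Ties between equal-length occurrences break to
the leftmost position, which keeps the most conservative insert and makes
trimming deterministic. Qualified reads are 17–28 nt inserts free of
ambiguous bases whose bases all reach Q20; the Q20/no-N rule is our
declared substitute for an otherwise unquantified "low quality" notion —
the synthetic generator emits constant quality, so tests never depend on
it. The lower length bound (17) and the gel-purification upper range
(28) are deliberately asymmetric at the bottom; we follow the discard
rule. Identical inserts collapse to `(sequence, count)` per library, and
count conservation (qualified + per-rule discards = raw) is asserted in
tests. Trimming is idempotent in the only meaningful sense: re-trimming
an insert that contains no 7-nt adapter substring yields the no-adapter
flag, never a shorter sequence.

## Read mapping

A k-mer (k = 8) index over the reference supports a seed-and-verify
search returning **all** placements on either strand with at most one
substitution; the pigeonhole split of the read into two halves makes the
seeding lossless at ≤ 1 mismatch. No indels are modeled — the
substitution-only contract matches how ≤ 28-nt reads are conventionally
aligned, keeps `end − start = read length`, and makes the exhaustive-scan
oracle exact. Larger budgets (the ≤ 3-mismatch target search) use a
vectorized full scan instead of seeding. Multi-mapped reads are reported
at every placement and counted fully at every locus; `n_hits` carries the
placement count for uniqueness rules. Coordinates are 0-based half-open
throughout; GFF3 I/O converts to and from 1-based inclusive.

## miRNA locus discovery

Alignments merge into clusters wherever intervals overlap (connected
components of the overlap graph). Each cluster is extended 300 nt on
both ends; 250-nt windows advance by 50 nt (the step is our choice — it
guarantees every 250-nt context containing the cluster is examined at
modest cost), with a final window clamped to cover the 3′ end.

Windows are folded with a pluggable engine. The in-repo engine is a
maximum-weight Nussinov dynamic program (G:C 3, A:U 2, G:U 1, minimum
loop 3) with a deterministic traceback, verified against an exhaustive
memoized recursion. When the ViennaRNA bindings are importable the
default engine is RNAfold MFE prediction behind the same pair-table
contract; thermodynamic folding resolves the tie ambiguity that pure
pair-count maximization has on 250-nt windows.

A cluster is reported as a miRNA locus when four criteria hold together:

1. more than `min_reads = 10` reads, pooled over all libraries (the
   pooled reading is declared, not inferred);
2. a qualifying hairpin: the dominant read stack (the mature) has ≥ 16
   of its positions paired within its **dominant helix** — the longest
   run of pairs whose partners descend monotonically with gaps ≤ 4 nt —
   and that helix places all partners on one arm (a mature spanning the
   loop is rejected). Using the dominant helix rather than the raw pair
   table makes the geometry robust to stray long-range pairs an MFE fold
   may add around the duplex;
3. a star stack of ≥ 1 read at the position the helix predicts for the
   star (partner of the mature 5′ base + 2-nt shift, ±4 nt);
4. mature/star duplex 3′ overhangs of 2 ± 1 nt at both ends under the
   fold's pairing (the tolerance encodes the "~2 nt" convention).

Additionally, the dominant stack must hold ≥ 30 % of the cluster's reads
before any window is folded. This mature-dominance prescreen is standard
practice in miRNA locus callers: hairpin loci concentrate reads on the
mature, whereas phased and nat-siRNA loci spread them across registers
and strands, so those clusters are rejected on read-distribution grounds
rather than by accident of folding. When both arms reach the count floor
(10 reads) the locus yields two records suffixed -5p/-3p; on an exact
count tie the arm with a 5′ U wins, else 5p. Known matures supplied as
FASTA are counted first (exact match within a ±2-nt isomiR shift window)
and their reads excluded from discovery, so no read is attributed twice.

## Phased (secondary) siRNA loci

Reads whose sequences align to any discovered miRNA locus are removed
first — by sequence, not by placement, since a trigger miRNA's reads also
align (antisense) to its complementary target sites inside a TAS-like
locus and would otherwise corrupt the register histogram. Remaining
reads chain into regions when start positions lie within 50 bp. A region
passes when it holds ≥ 10 reads and the count-weighted 21-nt fraction
strictly exceeds 0.70. Passing regions without a trigger site are still
reported as non-phased candidates.

Trigger binding sites use the standard plant target-penalty scheme:
mismatch 1.0, G:U wobble 0.5, 1-nt bulge 1.0, all doubled at small-RNA
positions 2–13; a site is accepted at penalty ≤ 4.0. The comparator is
configurable because score conventions differ between tools (the cited
threshold phrasing "no less than 4" is ambiguous against a lower-is-better
penalty; we implement penalty ≤ 4 and expose the direction). The
transcript-wide scan is ungapped and vectorized; single-bulge alignments
are evaluated only by the windowed scorer — a bulged site whose ungapped
anchor exceeds the threshold is missed at the scan level (known
limitation). Cleavage falls between the target bases opposite small-RNA
positions 10 and 11; `c` is the 0-based coordinate of the first base 3′
of the cut on the sense strand, so for a site ending at `t1`,
`c = t1 − 10`. A pair of sites defines the dsRNA template, extended 100
nt on both flanks; both sites are treated as cleaved.

Registers: sense-read offset `(start − c) mod 21`; antisense offset
`(end − c − 2) mod 21`, the fixed 2-nt shift reflecting duplex 3′
overhangs. The histogram is computed against the 5′-site register; the
phased fraction counts reads at offset 0 with respect to *either*
cleavage site, over **all** reads in the locus (a 21-nt-only denominator
is available via `only_21nt`). In-register reads are named D1+, D2+, …
(sense) and Dk− (antisense) by distance from the 5′ cleavage site. A
secondary register is flagged when the mass at offsets 10–11 reaches
0.10 (configurable) and exceeds the uniform-null expectation 2/21 — the
signature of a secondary cleavage set half a register away.

## cis-NAT pairs and nat-siRNAs

Opposite-strand gene pairs on one contig overlapping ≥ 25 nt are
classified: enclosed when one interval contains the other; else
convergent when the plus-strand gene starts first (3′ ends overlap);
else divergent. Overlap is computed on gene intervals (the genomic
overlap is what matters for dsRNA formation); an exon-aware mode is a
config flag away but not the default. A pair produces nat-siRNAs when
reads lying *entirely* inside the overlap number more than 10, at least
one maps uniquely, and a strand's count-weighted 21-nt fraction exceeds
a strict majority (0.5) on at least one strand. The majority default is
deliberate: published per-strand fractions as low as ~53 % are accepted
calls, so demanding 0.70 on both strands would contradict the calls the
rule is meant to reproduce; the 0.70 variant is available in config.

## Expression and differential expression

sncRNA counts are normalized as N·C/T with T the library's qualified
genome-aligned read total and C the mean of T over libraries; after
scaling, every library totals C (asserted). miRNA expression is the
summed count of the mature sequence; siRNA-locus and nat-siRNA expression
are the reads inside the locus/overlap per library. mRNA tag counts give
CPM; a gene is expressed at ≥ 10 CPM; upper-quartile normalization
scales each column by mean(q)/q where q is the column's 75th CPM
percentile over its expressed genes.

DE is deterministic and rule-based (the experimental design has no
replicates, so no statistical test is fitted): fold = (a + ψ)/(b + ψ)
with ψ = 1 normalized unit for sncRNA classes (zero denominators are
otherwise possible at shallow counts) and ψ = 0 for mRNA, where the
on–off rule already covers off states. Thresholds: miRNA ≥ 1.5, siRNA
locus and nat-siRNA ≥ 2, mRNA ≥ 4 or not-expressed vs \> 40 CPM. The six
comparisons are CA/NC, CCA/NC, CS/NC, CCA/CA, CS/CA, CS/CCA. siRNA
targets are all placements of the reverse complement on the cDNA set
with ≤ 3 substitutions, for siRNAs with more than 10 reads.
Anti-correlated pairs require both members DE in the same comparison with
opposite directions and a target change of at least 2-fold.

## The synthetic study

The generator emulates the *structure* of a four-condition chilling
experiment, not its biology. Defaults (one choice, fixed): 4 contigs ×
50 kb; 20 miRNA hairpins (mature 100 expected reads/library, star 5);
5 TAS-like loci (300 expected reads, 8–10 phased 21-mers between two
perfect trigger sites, 20.5 % shifted-register fraction matching the
observed secondary-cleavage signal, 70 % sense reads, ≥ 98 % exactly
21 nt); 6 cis-NAT pairs (two per orientation, 300 expected reads, 80 %
emitted inside the overlap — the published concentration); background
5 reads/kb, uniform and strand-symmetric, lengths 17–28 with a mild
24-nt peak and a 0.5 probability of a forced 5′ U; a count-level mRNA
table (~60 genes, lognormal means, 20 % silent) rather than simulated
mRNA reads, since the mRNA pipeline consumes tag counts.

Planted duplexes carry exact 2-nt 3′ overhangs; phased 21-mers tile the
inter-cleavage region exactly; inter-cleavage distances are multiples of
21 by construction. Condition effects are multiplicative on Poisson
means: a DE feature changes by its class fold f (1.5 miRNA, 2 siRNA
locus/nat-siRNA, 4 mRNA) graded with stress severity — f at CA, f² at
CCA and CS — emulating progressive chilling response and ensuring at
least one comparison sits clearly above the calling threshold.
Directions are assigned greedily so the expected read mass added by
up-regulated features cancels the mass removed by down-regulated ones:
total-count normalization assumes approximately balanced composition, an
assumption a deep, diverse real library satisfies naturally but a small
synthetic world must enforce. Two DE TAS loci donate a phased product
whose perfect complement is embedded in an oppositely regulated mRNA
gene, planting a recoverable siRNA→target cascade.

What passing tests therefore show: the rules and analytics recover
exactly the structures they define, at realistic depths and noise, with
deterministic byte-identical reruns. What they do not show: robustness
to sequencing error, isomiR heterogeneity, RNA degradation products,
spliced transcripts, repetitive genomes, or composition bias beyond the
balanced regime — none of which the generator emulates.

Recovery metrics condition on features whose baseline expectation
reaches 50 reads (or mRNA mean counts): below that, a fold-change rule
carries too little information by construction, and star-arm records
(expected 5 reads/library) would otherwise dominate both recall and
false-positive tallies with pure Poisson noise.

## Numerical and degenerate-input choices

Sorting keys make every stage deterministic (clusters by coordinate,
candidates by locus, stacks by count then position). Window enumeration
clamps at contig edges. `filter_candidates` treats its bounds strictly
as documented (≥ 10 reads, \> 0.70). Empty inputs raise typed errors
(empty profile, empty count table, zero library total, pair without
overlap); rejections in discovery carry machine-readable reasons instead
of exceptions. The position-weighted target score is deliberately
asymmetric between the small RNA's 5′ core and its 3′ end, so only the
unweighted match/mismatch classification — not the weighted penalty — is
invariant under jointly reverse-complementing both sequences; tests
check the former. All randomness flows from a single integer seed per
run; library emission derives one child generator per condition.

## Problem sizes

The default study used by the test suite and the acceptance analysis is
4 × 50 kb of genome and ~25k reads over four libraries — small enough
for the whole suite to run in well under a minute while leaving every
per-locus statistic (≥ 300 reads per planted locus) far above its
decision thresholds. The shifted-register analysis uses ~8.5k reads at
one locus, matching the scale at which the 20.5 % secondary register was
originally quantified.
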