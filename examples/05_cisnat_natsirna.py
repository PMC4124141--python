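"""Classify cis-NAT gene pairs and call nat-siRNA producers.

Opposite-strand genes overlapping by >= 25 nt form a cis-NAT pair:
convergent (3'-3' overlap), divergent (5'-5') or enclosed.  A pair
produces nat-siRNAs when the overlap holds more than 10 reads, at least
one maps uniquely, and a strand's 21-nt fraction clears the majority
enrichment rule.
"""

import numpy as np

from srnakit import ReferenceIndex, SimulationSpec, find_cis_nat_pairs, generate_reference
from srnakit.cisnat import call_nat_sirna, overlap_read_fraction
from srnakit.mapping import Alignment, AlignmentStore, map_read
from srnakit.simulate import emit_condition_reads

spec = SimulationSpec(seed=6, n_mirna_loci=0, n_tas_loci=0, n_cisnat_pairs=3,
                      n_mrna_genes=0, background_read_rate=1.0, de_fraction=0.0)
genome, annotation, truth = generate_reference(spec)
pairs = find_cis_nat_pairs(annotation)

counts: dict[str, int] = {}
for seq, _src in emit_condition_reads(genome, truth, spec, "NC", np.random.default_rng(3)):
    counts[seq] = counts.get(seq, 0) + 1
index = ReferenceIndex(genome)
alns = []
for seq, n in counts.items():
    for a in map_read(seq, index, 0):
        alns.append(Alignment(a.sequence, a.contig, a.start, a.end, a.strand, 0, a.n_hits, n, "NC"))
store = AlignmentStore(alns)

print(f"{len(pairs)} cis-NAT pairs found:")
for p in pairs:
    call = call_nat_sirna(p, store)
    frac = overlap_read_fraction(p, store)
    print(f"  {p.pair_id}: {p.orientation}, overlap {p.overlap_length} nt; "
          f"+ strand {call.plus.reads} reads ({call.plus.fraction_21nt:.0%} 21-nt), "
          f"- strand {call.minus.reads} ({call.minus.fraction_21nt:.0%}); "
          f"nat-siRNA {'PASS' if call.passes else 'fail'}; "
          f"{frac:.0%} of the pair's reads fall in the overlap")
print("The overlap concentration (~80%) is the signature that distinguishes "
      "nat-siRNA production from ordinary degradation of either transcript.")
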