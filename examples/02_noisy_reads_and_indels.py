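"""Map noisy reads carrying substitution errors and indel polymorphisms.

Indels are simulated as genomic variants shared by every read covering the
locus, which is what lets the context machinery pin down their exact
positions: reads where the indel sits too close to a read end for direct
discovery are re-split across the site established by their neighbours.
"""

from collections import Counter

from splicemap import evaluation as ev
from splicemap import map_reads
from splicemap import read_simulator as sim

genome = sim.simulate_genome(200_000, gc=0.5, seed=11)
models, genome = sim.simulate_genes(genome, 15, seed=12)
reads, truths = sim.simulate_reads(
    models, genome, n_reads=8_000, mismatch_rate=0.01, indel_rate=0.002,
    multi_junction_weights={0: 0.6, 1: 0.35, 2: 0.05}, seed=13,
)

result = map_reads([genome], reads)
recall, fdr = ev.splice_metrics(result.records, truths)
print(f"splice recall {recall:.4f}, FDR {fdr:.4f}")

metrics = ev.indel_metrics(result.records, truths)
n_loci = len(Counter((e.kind, e.ref_pos) for t in truths for e in t.indels))
print(f"indel loci simulated: {n_loci}")
print(f"overall indel recall (exact position/type/length): "
      f"{ev.overall_indel_recall(metrics):.4f}")
for kind, label in (("I", "insertions"), ("D", "deletions")):
    tp = sum(metrics[(kind, s)]["tp"] for s in range(1, 11))
    fn = sum(metrics[(kind, s)]["fn"] for s in range(1, 11))
    print(f"  {label}: {tp}/{tp + fn} events recovered")
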