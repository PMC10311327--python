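"""Genotype one synthetic sample end to end.

Simulates a small cohort, builds the pangenome bubble graph from the panel,
counts spaced k-mers in the sample's reads, estimates coverage and runs the
haplotype-pair HMM.  Prints the genotype calls next to the truth.
"""

from spacegt import (
    GenotypingParams,
    SimulationConfig,
    build_graph,
    calls_to_site_genotypes,
    contiguous_seed,
    count_sequences,
    estimate_coverage,
    genotype,
    index_unique_kmers,
    simulate_panel,
    simulate_reads,
)

cfg = SimulationConfig(ref_length=20_000, n_founders=6, n_haplotypes=10,
                       coverage=30.0, error_rate=0.001, rng_seed=4)
truth = simulate_panel(cfg)
print(f"simulated {len(truth.variants)} variants over {cfg.ref_length} bp, "
      f"{truth.n_samples} diploid samples")

seed = contiguous_seed(31)
graph = build_graph({truth.chrom: truth.reference}, truth.variants, seed)
reads = simulate_reads(truth.sample_haplotypes(0), cfg, rng_seed=99)
counts = count_sequences(reads, seed)
index = index_unique_kmers(graph, seed)
c = estimate_coverage(index, counts)
print(f"{len(reads)} reads, {index.n_kmers()} allele-unique k-mers, "
      f"estimated diploid k-mer coverage {c:.1f}")

calls = genotype(graph, counts, GenotypingParams(seed, c), index=index)
pred = calls_to_site_genotypes(calls, graph)
truth_gt = truth.truth_genotypes(0)
agree = sum(1 for k, v in truth_gt.items() if pred.get(k) == v)
print(f"genotype agreement with truth: {agree}/{len(truth_gt)} sites")
print("\nfirst five calls (pos, truth, called):")
for site in truth.variants[:5]:
    print(f"  {site.start + 1:>6} {truth_gt[site.key]} {pred.get(site.key)}")
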