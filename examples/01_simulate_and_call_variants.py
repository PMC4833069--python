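"""Simulate a small chloroplast panel and build the masked variant matrix.

Generates the toy8 dataset (8 genomes of 20 kb evolved along a known timed
tree, deep 2,000x pileups), calls haploid genotypes with the 90%-support
rule, masks inverted repeats and nuclear-homologous tracts, and compares the
calls with the planted truth.
"""

from plastidkit import io as pkio, pipeline, simulate, variants

cfg = pipeline.toy8_config(seed=1)
ds = simulate.simulate_dataset(cfg)
matrix = variants.build_variant_matrix(ds.pileups, ds.reference, ds.mask)
ann = variants.classify_variants(matrix, ds.genes, ds.reference)
summary = variants.summarize_variants(matrix, ann)

masked = pkio.interval_mask(ds.mask, cfg.genome_length)
truth = {
    p
    for vs in ds.truth.true_variants.values()
    for p, _, _, t in vs
    if t == "SNV" and not masked[p]
}
called = set(matrix.snv_positions())

print(f"variant positions: {summary['n_nonredundant']} "
      f"({summary['n_snv']} SNVs + {summary['n_indel']} indels)")
print(f"intergenic indel share: {summary['pct_indel_intergenic']}%")
print(f"SNV recall vs planted truth: {len(truth & called) / len(truth):.3f}")
print(f"SNV precision: {len(truth & called) / len(called):.3f}")
# Recall/precision near 1.0 show that at 2,000x depth the 90%-support rule
# recovers essentially every planted variant outside the masked regions.
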