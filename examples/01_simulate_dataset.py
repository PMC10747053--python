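"""Generate a synthetic three-group wild-soybean-style dataset.

Builds a small panel (3 eco-regional groups, 12 locations, 60 accessions)
with planted selective sweeps and environment-tracking loci, writes the
VCF + tables + ground truth, and prints where everything went.
"""

from sojapop.sim import SimConfig, simulate, write_outputs

cfg = SimConfig(seed=1, n_snps=4000, n_chrom=2, chrom_length=5_000_000,
                locations_per_group=4, samples_per_location=5)
result = simulate(cfg)
paths = write_outputs(result, "scratch/example_sim")

print(f"samples: {result.genotypes.n_samples}, SNPs: {result.genotypes.n_sites}")
print("planted sweep regions (chrom, start, end, swept group):")
for region in result.truth.sweep_regions:
    print("  ", region)
print(f"planted adaptive loci: {len(result.truth.adaptive_loci)}")
for name, path in paths.items():
    print(f"{name:14s} -> {path}")
# The sweep BED and adaptive-locus TSV are the ground truth downstream
# examples try to rediscover from the VCF alone.
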