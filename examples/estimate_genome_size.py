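"""Estimate a haploid genome size from the k-mer spectrum of diploid reads.

Builds a 1 Mbp diploid genome (heterozygosity 0.005, GC 0.70), sequences it
to 60x with error-free 300 bp reads, counts canonical 19-mers and reads the
genome size off the spectrum: total k-mer observations above the error
cutoff divided by the homozygous (2n) peak multiplicity.
"""

from crcurate import (
    GenomeSpec,
    ReadSimSpec,
    count_canonical_kmers,
    estimate_genome_size,
    generate_genome,
    simulate_reads,
)

spec = GenomeSpec(haploid_size=1_000_000, het_rate=0.005, gc_target=0.70,
                  contaminant_count=0, seed=11)
genome = generate_genome(spec)

# 30x over both haplotypes = 60x per haploid genome
reads = simulate_reads(genome.diploid(), ReadSimSpec(read_length=300, coverage=30, seed=12))
hist = count_canonical_kmers(reads, k=19)
est = estimate_genome_size(hist)

print(f"true haploid size : {spec.haploid_size:>12,} bp")
print(f"estimated size    : {est.haploid_size:>12,.0f} bp "
      f"({100 * abs(est.haploid_size - spec.haploid_size) / spec.haploid_size:.2f}% off)")
print(f"2n peak           : {est.homozygous_peak_coverage}x "
      f"(expected ~ 60 * (300-18)/300 = {60 * 282 / 300:.1f}x)")
print(f"1n peak           : {est.heterozygous_peak_coverage}x "
      "(haplotype-specific k-mers at half the 2n multiplicity)")
print(f"error cutoff      : multiplicity {est.error_cutoff}")
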