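# crcurate

Curation toolkit for draft genome assemblies of small eukaryotes — built for
the kind of project that produced the *Cafeteria roenbergensis* strain
genomes: a diploid, high-GC (~70%) protist of a few tens of Mbp, sequenced
with short and long reads from non-axenic cultures, assembled with a
long-read assembler and then cleaned up by hand-rolled scripts.  `crcurate`
turns those one-off curation steps into a tested, reusable library with a
thin command-line front end, plus a synthetic-data generator with full
ground truth so that every stage can be validated without touching public
archives.

## What it does

**Genome size from the k-mer spectrum** (`crcurate.kmers`).  Canonical
k-mer (default k=19) multiplicity histograms are counted exactly in memory.
For a diploid genome the spectrum shows a homozygous (2n) peak at the k-mer
coverage `c_k = c·(L−k+1)/L` and a heterozygous (1n) peak at `c_k/2`.  The
haploid size is estimated as

    G = Σ_{m ≥ m0} m·n(m) / peak2n

where `n(m)` is the number of distinct canonical k-mers seen `m` times,
`m0` the error cutoff (first valley of the smoothed histogram) and `peak2n`
the 2n-peak multiplicity.

**Misassembly breaking from coverage drops** (`crcurate.junctions`).
Chimeric contigs join regions that are not adjacent in the genome, so no
read spans the joint and depth collapses locally.  The caller finds maximal
runs of depth `< c` (default 5×) whose two `a`/`b` = 200 bp flanks both
average at least `d·c` (default 2×5 = 10×), outside `e`/`f` = 30 bp end
exclusion zones, and `break` removes the unsupported bases and splits the
contig.

**Taxonomic decontamination** (`crcurate.decontam`).  Contigs are split
into 500 bp fragments, each fragment's classifier taxon (Kaiju-style TSV)
is resolved to its superkingdom through an NCBI-style taxonomy, and a
contig is excluded when **strictly more than 50%** of its classified
fragments are bacterial.  GC, median coverage and canonical
tetranucleotide divergence are reported as corroborating evidence but
never drive the verdict; viral assignments never count toward exclusion
(endogenous viral elements are real genome content).

**Circular mitochondrial curation** (`crcurate.mito`).  The mito contig is
identified by canonical 21-mer containment against a reference, the
duplicated end overlap of the circular sequence is trimmed
(suffix–prefix alignment, ≥95% identity), and the circle is rotated — and
strand-flipped if needed — to start at a reference anchor, so any
presentation of the same circle yields byte-identical output.

**rDNA copy number and operon variation** (`crcurate.rdna`).  The tandem
rDNA operon (18S–ITS1–5.8S–ITS2–28S) collapses to one copy in assemblies;
its haploid copy number is estimated as median depth over the operon
divided by the median depth over the 50 longest contigs (ploidy cancels).
The module also counts strain-unique substitutions in an operon alignment
and summarises pileup base counts / minor-allele fractions at given sites.

**Assembly statistics and ANI** (`crcurate.stats`).  Contig count, total
size, N50 and GC%, plus fragment-based average nucleotide identity: 1 kb
query fragments are placed by shared-15-mer seeding, scored by edit
distance (edlib), and averaged over fragments above the 80% orthology
cutoff.

**Synthetic data with ground truth** (`crcurate.synth`).  Generates the
diploid nuclear genome (i.i.d. bases at target GC, substitution-only
heterozygosity), a tandem rDNA array, a circular mitochondrion emitted as
a linear contig with duplicated ends, AT-rich contaminant contigs,
chimeras with recorded breakpoints, uniform-coverage reads, SAM alignments
derived from true placements (reads spanning no single target region are
omitted — that is what makes planted misjoins look real), and classifier
tables of configurable accuracy.  Every planted feature lands in a
`TruthTable`.

## Worked example

```bash
python examples/estimate_genome_size.py
```

prints (1 Mbp diploid, heterozygosity 0.005, 60× error-free reads):

```
true haploid size :    1,000,000 bp
estimated size    :    1,007,138 bp (0.71% off)
2n peak           : 56x (expected ~ 60 * (300-18)/300 = 56.4x)
1n peak           : 28x (haplotype-specific k-mers at half the 2n multiplicity)
error cutoff      : multiplicity 3
```

The 2n peak sits at the expected k-mer coverage, the 1n peak at half of it
(those are the heterozygous k-mers present on only one haplotype), and the
size integral over the spectrum lands within 1% of the planted truth.  The
other scripts in `examples/` walk through misassembly breaking,
contamination screening, mitochondrial curation, rDNA copy number and
assembly comparison the same way.

The same operations are available from the shell:

```bash
crcurate simulate -o sim/ --haploid-size 1000000
crcurate khist sim/reads.fastq -o sim/histo.txt
crcurate gsize sim/histo.txt
crcurate stats sim/assembly.fasta
crcurate run config.yaml        # full pipeline from a YAML config
```

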