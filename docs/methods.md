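# Methods

This note records the models, parameter choices and numerical conventions
behind `crcurate`, and what the synthetic validation does and does not
demonstrate about real data.

## Synthetic data model

The generator emulates a small diploid protist genome and the artefacts the
curation pipeline exists to fix.

* **Base composition.** Nuclear sequence is i.i.d. with `P(G or C) =
  gc_target` (default 0.70, matching a high-GC protist), G/C and A/T
  equiprobable within each pair.  This is sufficient for composition-based
  screening (GC and tetranucleotide divergence between a 0.70-GC host and a
  0.45-GC contaminant dwarf the sampling noise of i.i.d. text) but carries
  none of the repeat structure, codon bias or isochore patterns of real
  genomes.
* **Diploidy.** Haplotype B is haplotype A with substitutions at `het_rate`
  per base (default 0.005; the real heterozygosity of the target organism is
  not published, so this is a declared free parameter).  No heterozygous
  indels or structural variants.
* **rDNA array.** `rdna_copies` byte-identical tandem units (default unit
  3 kb) at a single locus.  Real arrays carry low intra-array variation;
  identical units are the favourable case for the depth-ratio estimator and
  the validation should be read accordingly.
* **Mitochondrion.** A random AT-rich (GC 0.35) circle, emitted both as the
  true circle and as a linear contig rotated by a random offset with its
  first `mito_end_overlap` bases duplicated at the end — the canonical
  assembler presentation of a circular replicon.
* **Chimeras.** A misjoin is modelled by concatenating two whole unrelated
  contigs; the breakpoint is recorded.  Reads are always simulated from the
  *true* genome, and the alignment emitter drops any read that does not fit
  inside a single liftover segment, so a planted misjoin produces exactly
  the V-shaped coverage gap a real misassembly produces under a mapper that
  requires end-to-end alignments.
* **Reads.** Uniform start positions, strand-symmetric, i.i.d. substitution
  errors, constant Q40 qualities (qualities are never used downstream).
  Paired mode reads both ends of a fragment of twice the read length.  No
  indel errors — the PacBio-style error profile is out of scope, which is
  why the alignment emitter writes all-match CIGARs.
* **Classifier output.** Per 500 bp fragment: unclassified with probability
  `unclassified_rate`, otherwise the representative taxon of the true
  superkingdom with probability `accuracy`, else of the wrong superkingdom.
  Real classifiers err in more structured ways (conserved genes, horizontal
  transfer); the model only captures the error *rate*.

Determinism: every operation takes a seed and drives a single
`numpy.random.Generator`; fixed seeds give byte-identical FASTA/FASTQ/SAM/
TSV/JSON outputs.

## Genome-size estimation

Canonical k-mers (lexicographic min of a window and its reverse complement;
k odd so no window is its own reverse complement) are counted exactly by
packing windows into 64-bit integers, sorting, and run-length encoding.
Multiplicities above 10,000 are pooled into a cap bin so organelle/rDNA
k-mers cannot dominate memory; the pooled bin is excluded from peak search
but not from the weighted total.

Peak and valley detection run on a centred 3-bin moving average because raw
histograms from moderate-coverage simulations are noisy; since the smoothing
blurs sharp peaks by one bin, the peak is refined to the raw-count argmax
within ±1 bin of the smoothed argmax (this also makes a single-spike
histogram return its exact spike position).  The error cutoff is the first
`m ≥ 2` where the smoothed histogram rises — the valley separating the
error/contaminant component from the genomic peaks; a histogram that never
rises has no separation and is rejected.  The haploid size is
`Σ_{m≥cutoff} m·n(m) / peak2n`.  A 1n peak is reported when a local maximum
of the smoothed histogram exists between the cutoff and 0.75× the 2n peak.

Known biases: at low coverage the Poisson mode sits below the mean, inflating
the estimate by a few percent (visible as the ~0.7% overshoot at 60×);
k-mers from contaminating organisms above the cutoff inflate the estimate —
no contaminant correction is attempted.

## Junction calling

Depth is computed per base from primary, mapped, non-supplementary SAM
records over CIGAR M/=/X (deletions and reference skips add no depth), or
from PAF target intervals.  Medians use the lower median on even counts, a
convention applied uniformly (contig medians, operon and backbone medians)
so that results are integer-valued on integer depth.

A junction call is a maximal run of positions with depth `< c` — runs
separated by fewer than `d` bases are merged first — such that the run and
both **full** flank windows (`a` left, `b` right) lie inside `[e, len−f)`
and both flank means are `≥ d·c`.  The flag letters and defaults
(`a=b=200, c=5, d=2, e=f=30`) are the published ones; their semantics are
this package's own reconstruction and are deliberately explicit and tested.

Two design points deserve justification:

* **Full flank windows, not truncated ones.**  Near a contig end the
  expected depth ramps as `(coverage/read_length)·distance` because reads
  cannot extend past the end.  If flank windows were truncated at the
  exclusion-zone boundary, ordinary Poisson dips on that ramp would pass the
  flank test at a rate of several calls per hundred contig ends — spurious
  breaks of clean contigs.  Requiring the full `a`/`b` bases inside the
  evaluable zone removes that failure mode entirely and matches the
  operation's precondition (`length > a+b+e+f`).
* **Operating range of the defaults.**  With `c = 5`, marginal per-base
  depth is ~Poisson(coverage); at 20× an isolated sub-5 dip occurs every
  ~10^5 bases, at 30× every ~10^8.  The default thresholds are therefore
  calibrated for ≳25–30× short-read coverage, and the validation runs at
  30×.
* **Read length in the validation scenarios.**  The flank windows must
  clear the read-shadow ramp that surrounds any breakpoint (expected depth
  `(c/L_read)·d` at distance `d`).  With 300 bp reads the 200 bp flanks sit
  entirely inside that ramp (expected flank mean ~15× against the 10×
  threshold — a coin flip per junction under noise), so the alignment-based
  scenarios use 150 bp reads, for which flank means are ~22× and the test
  is stable.  This is a property of the scenario geometry, not a tuned
  constant.

Breaking removes the sub-threshold run itself (bases with almost no read
support are unreliable), names pieces `<contig>.1, .2, …` left to right
before length filtering, and drops pieces under `min_piece` (default
1000 bp — smaller fragments are uninformative at long-read contig scale).
Total bases are exactly conserved across output + removed + dropped.

## Decontamination

The hard rule is taxonomy-only: drop iff strictly more than 50% of
*classified* fragments are bacterial.  Choices within that rule:

* **Denominator = classified fragments.**  Unclassified fragments would
  dilute real contamination; the per-contig counts are all logged so the
  all-fragments variant is recomputable from the report.
* **Fragments above superkingdom** (e.g. resolved only to "cellular
  organisms") count as unclassified, not as a superkingdom.
* **Viral fragments never count toward exclusion** — genuine genomes carry
  endogenous viral elements.
* **Tail rule.**  A final window remainder is kept when ≥ half a window
  (≥250 bp of classifiable signal), else discarded.
* **Tetranucleotide score.**  Distance of each contig's canonical 4-mer
  profile (136 classes) to the length-weighted assembly centroid, scaled
  robustly (median/1.4826·MAD across contigs).  A robust scale is used
  because a plain standard deviation is itself inflated by the
  contaminants being scored, capping their score near
  `sqrt((1−w)/w)` for contaminant fraction `w`; with MAD the host noise
  sets the scale and true contaminants score in the tens.  The score is
  reported, never used for the verdict.

## Mitochondrial curation

Identification is by canonical 21-mer containment (fraction of the
reference's distinct 21-mers present in the contig), threshold 0.5 —
flanking or extra sequence in the contig cannot lower containment, and
random high-GC sequence shares essentially no 21-mers with a 0.35-GC
reference.  Overlap trimming anchors candidate suffix–prefix overlaps on
shared 15-mers, verifies each candidate ungapped, longest first, and
accepts at ≥95% identity and ≥50 bp (raw long-read assemblies keep residual
errors at contig ends; both thresholds are exposed).  Rotation locates the
anchor by semi-global edit-distance alignment against the doubled sequence
on both strands (the doubling catches matches spanning the origin),
requires ≥90% anchor identity, and rotates/flips so the anchor starts at
position 0 — making the output invariant to the input's rotation and
strand.

## rDNA analysis

Copy number = (lower) median depth over the operon ÷ (lower) median depth
over the pooled per-base depths of the 50 longest contigs.  The ratio is
reported raw: operon and backbone are both diploid, so ploidy cancels and
the ratio is already per-haploid.  Pooling (rather than
median-of-per-contig-medians) weights the backbone by contig length; with
fewer than 50 contigs all are used and a warning is logged.  Strain
substitution counts use the unique-variant definition — a strain scores a
column where it differs from a base unanimous in all other strains; columns
with gaps or any other pattern are skipped and surfaced as counts rather
than silently resolved.  Allele fractions are pileup base counts of primary
alignments at externally supplied sites (variant *calling* is out of
scope); the minor fraction is the count of the most frequent non-reference
base over site depth, undefined (null) at depth 0.

## Assembly statistics and ANI

N50 is the length at which the descending cumulative contig length first
reaches half the total.  GC excludes ambiguity codes from numerator and
denominator.  ANI cuts the query into non-overlapping **full** 1 kb
fragments (1000 bp balances identity resolution against orthology
specificity at desk scale; classic fragment-mapping tools default to 3 kb),
seeds each fragment to its best reference diagonal via strided 15-mers on
both strands, and scores it with an infix edit-distance alignment against
the implied window ±64 bp; identity is `100·(1 − edits/1000)`, fragments
≥80% identity are averaged.  Self-ANI is exactly 100.0 (zero edits), and
the estimate is direction-specific — the CLI prints both directions and
their mean.  Agreement with published fragment-mapping ANI values is
expected to a few tenths of a percent, not bit-exact.

## Validation scenarios and problem sizes

The scenarios in `crcurate.scenarios` fix the study conditions: a 5 Mbp
diploid at 60× for genome size; 20 chimeras among 100 contigs (20 kb
sources) at 30× for junction calling; 40 host + 20 contaminant contigs with
a perfect and a 90%/20% classifier for decontamination; end overlaps of
50–2000 bp for mito trimming; 5/20/80 planted tandem copies at 100× over a
55-contig backbone for copy number; a 1 Mbp genome and a 1%-substituted
copy for ANI.  These sizes keep a full validation run to a few minutes on
one CPU while leaving every statistical margin (binomial bounds, Poisson
dips, flank noise) at several sigma.

Passing these scenarios shows the *logic* of each stage is correct under
its stated model — uniform coverage, substitution-only errors, end-to-end
alignments, honest classifier error rates.  It does not demonstrate
robustness to mapper-specific artefacts (multi-mapping, clipped
alignments), GC-coverage bias, repeat-induced coverage structure, or
classifier errors correlated with genome content; on real data those are
exactly the places where the reported corroborating signals (GC, tetra
divergence, coverage) earn their keep.

## Known limitations

* Exact in-memory k-mer counting targets desk-scale inputs (hundreds of
  millions of k-mers); it is not a streaming counter.
* The junction caller uses coverage only — no split-read or discordant-pair
  evidence — and its parameter semantics are a reconstruction, not the
  original tool's code.
* The ANI seeding assumes assemblies of the same species (≥80% fragment
  identity); it is not a genus-level comparator.
* Mixture-model spectrum fitting (negative-binomial peak models,
  repeat-fraction estimation from 3n/4n peaks) is out of scope.
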