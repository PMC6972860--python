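"""Find and break chimeric contigs at unsupported coverage drops.

Joins pairs of unrelated contigs into chimeras, simulates reads from the
*true* genome, and lets the junction caller find the misjoins: no read can
span a misjoin, so depth collapses there while the flanks stay well covered.
"""

import tempfile
from pathlib import Path

from crcurate import (
    GenomeSpec,
    ReadSimSpec,
    break_contigs,
    depth_from_alignments,
    detect_junctions,
    emit_alignments,
    generate_genome,
    simulate_reads,
)
from crcurate.synth import make_chimeras

genome = generate_genome(GenomeSpec(haploid_size=400_000, n_chromosomes=20,
                                    rdna_copies=0, contaminant_count=0,
                                    het_rate=0.0, seed=21))
sources = genome.haplotype_a
chim = make_chimeras(sources, 4, seed=22)
reads = simulate_reads(sources, ReadSimSpec(read_length=150, coverage=30, seed=23))

with tempfile.TemporaryDirectory() as tmp:
    sam = Path(tmp) / "reads.sam"
    emit_alignments(reads, chim.contigs, sam, liftover=chim.liftover, write_seq=False)
    tracks = depth_from_alignments(sam, chim.contigs)

calls = [call for track in tracks.values() for call in detect_junctions(track)]
result = break_contigs(chim.contigs, calls)

print(f"planted misjoins : {len(chim.junctions)}")
print(f"junction calls   : {len(calls)}")
for call in calls:
    truth = next(p for n, p, _ in chim.junctions if n == call.contig)
    print(f"  {call.contig}: cut [{call.start}, {call.end}) around planted "
          f"breakpoint {truth}; flank depths {call.left_mean:.0f}/{call.right_mean:.0f}x")
print(f"contigs after breaking: {len(result.contigs)} "
      f"(each chimera split into its two source parts)")
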