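import numpy as np
import pytest

from crcurate import Contig, GenomeSpec, generate_genome
from crcurate._encode import decode
from crcurate.synth import _random_codes


@pytest.fixture(scope="session")
def small_genome():
    """A small diploid genome with rDNA array, mito and contaminants."""
    spec = GenomeSpec(
        haploid_size=300_000,
        n_chromosomes=6,
        rdna_copies=10,
        mito_length=15_000,
        mito_end_overlap=600,
        contaminant_count=3,
        contaminant_length=8_000,
        seed=7,
    )
    return generate_genome(spec)


@pytest.fixture()
def random_contigs():
    """Factory for random contigs of given lengths and GC."""

    def make(lengths, gc=0.5, seed=0, prefix="c"):
        rng = np.random.default_rng(seed)
        return [
            Contig(f"{prefix}{i:02d}", decode(_random_codes(rng, ln, gc)))
            for i, ln in enumerate(lengths)
        ]

    return make


def write_sam(path, contigs, records):
    """Minimal SAM writer for hand-built test records.

    ``records`` rows: (qname, flag, rname, pos1, cigar, seq).
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for c in contigs:
            fh.write(f"@SQ\tSN:{c.name}\tLN:{len(c)}\n")
        for qname, flag, rname, pos1, cigar, seq in records:
            fh.write(f"{qname}\t{flag}\t{rname}\t{pos1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\n")
    return path
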