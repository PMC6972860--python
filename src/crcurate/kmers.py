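"""Canonical k-mer histograms and genome-size estimation from the k-mer spectrum.

For a diploid genome sequenced to depth ``c`` (per haploid genome), the
multiplicity spectrum of canonical k-mers shows a homozygous (2n) peak near
``c * (L - k + 1) / L`` for read length ``L`` and a heterozygous (1n) peak at
half that multiplicity carrying haplotype-specific k-mers.  Low-multiplicity
k-mers come from sequencing errors and trace contamination and are cut away
at the first valley of the (smoothed) histogram.  The haploid genome size is
then the number of k-mer observations above the cutoff divided by the 2n peak
multiplicity.

Counting is exact and in-memory (sorted 2-bit-packed canonical codes), which
comfortably handles desk-scale inputs of a few hundred million k-mers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from ._encode import canonical_kmer_codes, encode, kmer_codes_2d
from .synth import ReadSet

DEFAULT_K = 19
DEFAULT_CAP = 10_000


@dataclass
class KmerHistogram:
    """Multiplicity -> number of distinct canonical k-mers.

    ``counts[m]`` is the number of distinct canonical k-mers seen exactly
    ``m`` times; multiplicities above ``max_multiplicity_cap`` are pooled into
    the cap bin (organelle and rDNA k-mers would otherwise dominate the tail).
    """

    k: int
    counts: np.ndarray  # index = multiplicity, counts[0] always 0
    max_multiplicity_cap: int = DEFAULT_CAP

    @property
    def total_kmers(self) -> int:
        """Total k-mer observations: sum over m of m * counts[m].

        Exact even for the pooled cap bin because pooling happens after the
        weighted total is accumulated.
        """
        return int(self._total)

    _total: int = 0

    def to_text(self, path: str | Path) -> None:
        """Write in the 2-column ``jellyfish histo`` layout (nonzero bins only)."""
        with open(path, "w") as fh:
            for m in np.flatnonzero(self.counts):
                fh.write(f"{m} {self.counts[m]}\n")

    @classmethod
    def from_text(cls, path: str | Path, k: int = DEFAULT_K, cap: int = DEFAULT_CAP) -> "KmerHistogram":
        ms, cs = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                m, c = line.split()
                ms.append(int(m))
                cs.append(int(c))
        counts = np.zeros(max(ms) + 1 if ms else 1, dtype=np.int64)
        counts[ms] = cs
        hist = cls(k=k, counts=counts, max_multiplicity_cap=cap)
        hist._total = int((np.arange(counts.size) * counts).sum())
        return hist


@dataclass
class GenomeSizeEstimate:
    haploid_size: float
    homozygous_peak_coverage: int
    heterozygous_peak_coverage: int | None
    error_cutoff: int
    total_kmers_used: int

    def to_dict(self) -> dict:
        return {
            "haploid_size": self.haploid_size,
            "homozygous_peak_coverage": self.homozygous_peak_coverage,
            "heterozygous_peak_coverage": self.heterozygous_peak_coverage,
            "error_cutoff": self.error_cutoff,
            "total_kmers_used": self.total_kmers_used,
        }


def _iter_sequences(source) -> Iterator[str]:
    if isinstance(source, (str, Path)):
        path = Path(source)
        fmt = "fastq" if path.suffix.lower() in {".fq", ".fastq"} else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            yield str(rec.seq)
    else:
        yield from source


def count_canonical_kmers(
    source: str | Path | Iterable[str] | ReadSet,
    k: int = DEFAULT_K,
    cap: int = DEFAULT_CAP,
) -> KmerHistogram:
    """Exact canonical k-mer multiplicity histogram of a read or contig set.

    ``source`` may be a FASTA/FASTQ path, an iterable of sequence strings, or
    a :class:`~crcurate.synth.ReadSet` (fast path over its encoded reads).
    Windows containing non-ACGT characters are skipped.  ``k`` must be odd so
    that no k-mer is its own reverse complement.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical palindrome ambiguity)")
    if not 3 <= k <= 31:
        raise ValueError("k must be in [3, 31]")

    chunks: list[np.ndarray] = []
    if isinstance(source, ReadSet):
        n, rl = source.codes.shape
        if rl < k:
            raise ValueError("reads shorter than k")
        per_read = rl - k + 1
        codes_all = np.empty(n * per_read, dtype=np.uint64)
        at = 0
        for lo in range(0, n, 20_000):
            block = kmer_codes_2d(source.codes[lo : lo + 20_000], k)
            codes_all[at : at + block.size] = block.ravel()
            at += block.size
        chunks = None
    else:
        for seq in _iter_sequences(source):
            c = canonical_kmer_codes(encode(seq), k)
            if c.size:
                chunks.append(c)
        if not chunks:
            raise ValueError("no k-mers in input (empty or too short)")
        codes_all = np.concatenate(chunks)
        chunks.clear()

    codes_all.sort()
    boundaries = np.flatnonzero(codes_all[1:] != codes_all[:-1]) + 1
    edges = np.concatenate(([0], boundaries, [codes_all.size]))
    mult = np.diff(edges)  # multiplicity per distinct canonical k-mer
    total = int(codes_all.size)
    del codes_all
    mult_capped = np.minimum(mult, cap)
    counts = np.bincount(mult_capped, minlength=cap + 1).astype(np.int64)
    counts[0] = 0
    hist = KmerHistogram(k=k, counts=counts, max_multiplicity_cap=cap)
    hist._total = total
    return hist


def smooth(counts: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average; edges padded with zeros (same length out)."""
    kernel = np.ones(window) / window
    return np.convolve(counts.astype(float), kernel, mode="same")


def find_error_cutoff(hist: KmerHistogram) -> int:
    """Smallest multiplicity m >= 2 where the smoothed histogram starts rising.

    This is the first valley separating the error/contaminant component from
    the genomic peaks.  A histogram that never rises again (monotonically
    decreasing) has no separation and raises ``ValueError``.
    """
    if np.count_nonzero(hist.counts) == 0 or hist.counts.size < 4:
        raise ValueError("histogram too small (need >= 3 bins)")
    s = smooth(hist.counts)
    for m in range(2, s.size - 1):
        if s[m] < s[m + 1]:
            return m
    raise ValueError("no error/signal separation (histogram monotonically decreasing)")


def estimate_genome_size(hist: KmerHistogram) -> GenomeSizeEstimate:
    """Haploid genome size from the diploid k-mer spectrum.

    The homozygous (2n) peak is the argmax of the smoothed histogram above the
    error cutoff (the pooled cap bin is excluded); the estimate is the total
    k-mer observations above the cutoff divided by the 2n peak multiplicity.
    A heterozygous (1n) peak is reported when a local maximum exists between
    the cutoff and 0.75x the 2n peak.
    """
    cutoff = find_error_cutoff(hist)
    s = smooth(hist.counts)
    cap = hist.max_multiplicity_cap
    search = s.copy()
    search[:cutoff] = -1.0
    if search.size > cap:
        search[cap] = -1.0  # pooled bin is not a real multiplicity
    peak = int(np.argmax(search))
    # smoothing blurs sharp peaks by one bin; refine to the raw mode next door
    lo, hi_ = max(peak - 1, cutoff), min(peak + 2, search.size)
    peak = lo + int(np.argmax(hist.counts[lo:hi_]))
    if peak <= cutoff:
        raise ValueError("no homozygous peak above the error cutoff")
    m = np.arange(hist.counts.size)
    used = int((m[cutoff:] * hist.counts[cutoff:]).sum())
    haploid = used / peak

    het_peak: int | None = None
    hi = int(0.75 * peak)
    if hi > cutoff + 1:
        window = s[cutoff:hi]
        cand = cutoff + int(np.argmax(window))
        # require a genuine interior local maximum, not the shoulder of the 2n peak
        if cutoff < cand < hi - 1 and s[cand] >= s[cand - 1] and s[cand] >= s[cand + 1] and s[cand] > 0:
            het_peak = cand
    return GenomeSizeEstimate(
        haploid_size=haploid,
        homozygous_peak_coverage=peak,
        heterozygous_peak_coverage=het_peak,
        error_cutoff=cutoff,
        total_kmers_used=used,
    )
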