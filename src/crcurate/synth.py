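"""Synthetic genomes, reads, alignments and classifier tables with known truth.

This module emulates the data a curation pipeline for a small diploid,
high-GC protist genome has to cope with: two haplotypes differing by
heterozygous substitutions, a tandem rDNA array of known copy number, a
circular mitochondrial replicon emitted as a linear contig with duplicated
ends, AT-richer bacterial contaminant contigs, chimeric contigs with known
misjoin positions, uniform-coverage reads with substitution errors, alignment
records derived from the true read placements, and a Kaiju-style classifier
table of configurable accuracy.  Every planted feature is recorded in a
:class:`TruthTable` so downstream stages can be scored against ground truth.

Reads are always simulated from the *true* genome, never from chimeric
contigs; planted misjoins therefore appear as genuine coverage gaps in the
emitted alignments, exactly as real misassemblies do.

All randomness flows through a single ``numpy`` generator per operation and a
fixed seed yields byte-identical FASTA/FASTQ/SAM/TSV output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._encode import BASE, encode, decode
from .seqio import Contig
from .taxonomy import REPRESENTATIVE

FASTQ_QUAL = "I"  # constant Q40; base qualities are never used downstream


# ---------------------------------------------------------------------------
# specifications and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSpec:
    """Properties of the simulated diploid genome.

    Defaults emulate the target organism: ~70% GC nuclear sequence, diploid
    with heterozygous substitutions at ``het_rate``, one tandem rDNA array,
    an AT-rich circular mitochondrion, and a handful of bacterial contaminant
    contigs of clearly distinct composition.
    """

    haploid_size: int
    gc_target: float = 0.70
    het_rate: float = 0.005
    rdna_unit_length: int = 3000
    rdna_copies: int = 20
    mito_length: int = 30_000
    mito_end_overlap: int = 500
    contaminant_count: int = 5
    contaminant_length: int = 20_000
    contaminant_gc: float = 0.45
    seed: int = 42
    n_chromosomes: int = 8
    mito_gc: float = 0.35

    def __post_init__(self) -> None:
        if self.haploid_size <= 0:
            raise ValueError("haploid_size must be positive")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must be in [0, 1]")
        if not 0.0 <= self.het_rate < 1.0:
            raise ValueError("het_rate must be in [0, 1)")
        if self.mito_end_overlap >= self.mito_length:
            raise ValueError("mito_end_overlap must be smaller than mito_length")
        if self.rdna_copies * self.rdna_unit_length > self.haploid_size:
            raise ValueError(
                "contradictory spec: rdna_copies * rdna_unit_length "
                f"({self.rdna_copies * self.rdna_unit_length}) exceeds haploid_size "
                f"({self.haploid_size})"
            )
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")


@dataclass(frozen=True)
class ReadSimSpec:
    """Read simulation parameters (length, fold coverage, substitution rate)."""

    read_length: int = 300
    coverage: float = 30.0
    error_rate: float = 0.0
    paired: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


@dataclass
class TruthTable:
    """Ground truth for everything planted by the generator."""

    contaminant_ids: list[str] = field(default_factory=list)
    junctions: list[tuple[str, int, int]] = field(default_factory=list)
    true_haploid_size: int = 0
    true_rdna_copies: int = 0
    mito_overlap: int = 0
    mito_rotation_offset: int = 0
    rdna_locus: tuple[str, int, int] | None = None

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["junctions"] = [list(j) for j in self.junctions]
        d["rdna_locus"] = list(self.rdna_locus) if self.rdna_locus else None
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        d = json.loads(Path(path).read_text())
        d["junctions"] = [tuple(j) for j in d["junctions"]]
        if d.get("rdna_locus"):
            d["rdna_locus"] = tuple(d["rdna_locus"])
        return cls(**d)


@dataclass
class SyntheticGenome:
    haplotype_a: list[Contig]
    haplotype_b: list[Contig]
    mito_circle: Contig
    mito_linear: Contig
    contaminants: list[Contig]
    truth: TruthTable

    def diploid(self) -> list[Contig]:
        """Both nuclear haplotypes (the substrate for k-mer read simulation)."""
        return self.haplotype_a + self.haplotype_b

    def assembly(self, include_mito: bool = True) -> list[Contig]:
        """A haploid draft 'assembly': haplotype A, linear mito, contaminants."""
        out = list(self.haplotype_a)
        if include_mito:
            out.append(self.mito_linear)
        out.extend(self.contaminants)
        return out


# ---------------------------------------------------------------------------
# sequence construction
# ---------------------------------------------------------------------------

def _random_codes(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """I.i.d. bases with P(G or C) = gc, G/C and A/T equiprobable within pair."""
    is_gc = rng.random(n) < gc
    pick = rng.integers(0, 2, n, dtype=np.uint8)
    codes = np.where(is_gc, np.uint8(1) + pick, np.uint8(3) * pick)  # C/G vs A/T
    return codes.astype(np.uint8)


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return codes.copy()
    out = codes.copy()
    sites = np.flatnonzero(rng.random(codes.size) < rate)
    shift = rng.integers(1, 4, sites.size, dtype=np.uint8)
    out[sites] = (out[sites] + shift) % 4
    return out


def generate_genome(spec: GenomeSpec) -> SyntheticGenome:
    """Build the diploid nuclear genome, mitochondrion, contaminants and truth."""
    rng = np.random.default_rng(spec.seed)

    unique_len = spec.haploid_size - spec.rdna_copies * spec.rdna_unit_length
    sizes = [unique_len // spec.n_chromosomes] * spec.n_chromosomes
    sizes[-1] += unique_len - sum(sizes)
    if min(sizes) < 1:
        raise ValueError("haploid_size too small for the requested chromosome count")

    unit = _random_codes(rng, spec.rdna_unit_length, spec.gc_target)
    array = np.tile(unit, spec.rdna_copies) if spec.rdna_copies else np.empty(0, np.uint8)

    hap_a: list[Contig] = []
    hap_b: list[Contig] = []
    rdna_locus: tuple[str, int, int] | None = None
    for i, size in enumerate(sizes):
        codes = _random_codes(rng, size, spec.gc_target)
        if i == 0 and spec.rdna_copies:
            at = size // 2
            codes = np.concatenate([codes[:at], array, codes[at:]])
            rdna_locus = (f"chr{i + 1:02d}a", at, at + array.size)
        alt = _mutate(rng, codes, spec.het_rate)
        hap_a.append(Contig(f"chr{i + 1:02d}a", decode(codes)))
        hap_b.append(Contig(f"chr{i + 1:02d}b", decode(alt)))

    circle_codes = _random_codes(rng, spec.mito_length, spec.mito_gc)
    offset = int(rng.integers(0, spec.mito_length))
    rotated = np.concatenate([circle_codes[offset:], circle_codes[:offset]])
    linear = np.concatenate([rotated, rotated[: spec.mito_end_overlap]])
    mito_circle = Contig("mito_circular", decode(circle_codes), circular=True)
    mito_linear = Contig("mito", decode(linear))

    contaminants = [
        Contig(f"contam{i + 1:02d}", decode(_random_codes(rng, spec.contaminant_length, spec.contaminant_gc)))
        for i in range(spec.contaminant_count)
    ]

    truth = TruthTable(
        contaminant_ids=[c.name for c in contaminants],
        junctions=[],
        true_haploid_size=spec.haploid_size,
        true_rdna_copies=spec.rdna_copies,
        mito_overlap=spec.mito_end_overlap,
        mito_rotation_offset=offset,
        rdna_locus=rdna_locus,
    )
    return SyntheticGenome(hap_a, hap_b, mito_circle, mito_linear, contaminants, truth)


# ---------------------------------------------------------------------------
# chimeras and coordinate liftover
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Segment:
    """Maps source interval [src_start, src_start+length) onto a target contig."""

    target: str
    tgt_start: int
    source: str
    src_start: int
    length: int


@dataclass
class ChimeraSet:
    contigs: list[Contig]
    junctions: list[tuple[str, int, int]]
    liftover: list[Segment]


def identity_liftover(contigs: Sequence[Contig]) -> list[Segment]:
    return [Segment(c.name, 0, c.name, 0, len(c)) for c in contigs]


def make_chimeras(contigs: Sequence[Contig], n_chimeras: int, seed: int) -> ChimeraSet:
    """Join pairs of source contigs into chimeras with recorded breakpoints.

    Each chimera concatenates two whole source contigs (non-adjacent regions of
    the true genome); the breakpoint coordinate — the length of the first
    part — is recorded as a zero-width truth junction.  The returned liftover
    maps true-genome coordinates onto the chimeric assembly so that alignment
    emission can drop reads that would span no single target region.
    """
    if n_chimeras == 0:
        return ChimeraSet(list(contigs), [], identity_liftover(contigs))
    if len(contigs) < 2:
        raise ValueError("need at least 2 source contigs")
    if 2 * n_chimeras > len(contigs):
        raise ValueError(
            f"n_chimeras={n_chimeras} exceeds available pairs ({len(contigs)//2})"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(contigs))
    used = order[: 2 * n_chimeras]
    rest = sorted(order[2 * n_chimeras :])

    out: list[Contig] = [contigs[i] for i in rest]
    segments: list[Segment] = [Segment(c.name, 0, c.name, 0, len(c)) for c in out]
    junctions: list[tuple[str, int, int]] = []
    for i in range(n_chimeras):
        a, b = contigs[used[2 * i]], contigs[used[2 * i + 1]]
        name = f"chimera{i + 1:03d}"
        out.append(Contig(name, a.seq + b.seq))
        junctions.append((name, len(a), len(a)))
        segments.append(Segment(name, 0, a.name, 0, len(a)))
        segments.append(Segment(name, len(a), b.name, 0, len(b)))
    return ChimeraSet(out, junctions, segments)


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Simulated reads plus their true placements.

    ``codes`` holds the sequenced bases (2-bit codes) row per read; ``start``
    is the leftmost 0-based reference coordinate and ``strand`` 0/1 for +/−.
    For paired simulations mates are consecutive rows and ``mate`` is 0/1.
    """

    codes: np.ndarray
    contig_idx: np.ndarray
    start: np.ndarray
    strand: np.ndarray
    contig_names: list[str]
    paired: bool = False
    mate: np.ndarray | None = None

    @property
    def n_reads(self) -> int:
        return self.codes.shape[0]

    @property
    def read_length(self) -> int:
        return self.codes.shape[1]

    @property
    def total_bases(self) -> int:
        return self.codes.size

    def name(self, i: int) -> str:
        if self.paired:
            return f"r{i // 2:08d}/{(i % 2) + 1}"
        return f"r{i:08d}"

    def sequences(self) -> Iterable[str]:
        ascii_rows = BASE[self.codes]
        for i in range(self.n_reads):
            yield ascii_rows[i].tobytes().decode("ascii")

    def write_fastq(self, path: str | Path, path2: str | Path | None = None) -> None:
        """Write FASTQ; paired sets require two paths (synchronized mates)."""
        qual = FASTQ_QUAL * self.read_length
        ascii_rows = BASE[self.codes]
        if self.paired:
            if path2 is None:
                raise ValueError("paired reads need two output paths")
            with open(path, "w") as f1, open(path2, "w") as f2:
                for i in range(0, self.n_reads, 2):
                    f1.write(f"@{self.name(i)}\n{ascii_rows[i].tobytes().decode()}\n+\n{qual}\n")
                    f2.write(f"@{self.name(i + 1)}\n{ascii_rows[i + 1].tobytes().decode()}\n+\n{qual}\n")
        else:
            with open(path, "w") as fh:
                for i in range(self.n_reads):
                    fh.write(f"@{self.name(i)}\n{ascii_rows[i].tobytes().decode()}\n+\n{qual}\n")

    def write_placements(self, path: str | Path) -> None:
        """True placements as TSV: read_id, contig, start0, strand."""
        with open(path, "w") as fh:
            for i in range(self.n_reads):
                fh.write(
                    f"{self.name(i)}\t{self.contig_names[self.contig_idx[i]]}\t"
                    f"{self.start[i]}\t{'-' if self.strand[i] else '+'}\n"
                )


def simulate_reads(genome: Sequence[Contig], spec: ReadSimSpec) -> ReadSet:
    """Uniform-start reads with i.i.d. substitution errors.

    Coverage is interpreted over the total length of ``genome``: the number of
    reads is chosen so that emitted bases are within rounding of
    ``coverage * total_length``.  Paired mode samples fragments of twice the
    read length and emits outward-synchronized mates.
    """
    if not genome:
        raise ValueError("empty genome")
    rng = np.random.default_rng(spec.seed)
    rl = spec.read_length
    flen = 2 * rl if spec.paired else rl
    shortest = min(len(c) for c in genome)
    if flen > shortest:
        raise ValueError(
            f"fragment length {flen} exceeds shortest contig ({shortest} bp)"
        )

    lengths = np.array([len(c) for c in genome], dtype=np.int64)
    n_frags_per_contig = np.maximum(
        np.rint(spec.coverage * lengths / flen).astype(np.int64), 0
    )
    n_frags = int(n_frags_per_contig.sum())
    n_reads = 2 * n_frags if spec.paired else n_frags

    codes = np.empty((n_reads, rl), dtype=np.uint8)
    contig_idx = np.empty(n_reads, dtype=np.int32)
    start = np.empty(n_reads, dtype=np.int64)
    strand = np.empty(n_reads, dtype=np.int8)
    mate = np.empty(n_reads, dtype=np.int8) if spec.paired else None

    row = 0
    offs = np.arange(flen)
    for ci, contig in enumerate(genome):
        n_i = int(n_frags_per_contig[ci])
        if n_i == 0:
            continue
        ref = encode(contig.seq)
        frag_starts = rng.integers(0, len(contig) - flen + 1, n_i)
        frag_strand = rng.integers(0, 2, n_i, dtype=np.int8)
        for lo in range(0, n_i, 50_000):
            hi = min(lo + 50_000, n_i)
            fs = frag_starts[lo:hi]
            st = frag_strand[lo:hi]
            win = ref[fs[:, None] + offs]  # (chunk, flen)
            if spec.paired:
                left = win[:, :rl]                     # + strand half
                right_rc = 3 - win[:, rl:][:, ::-1]    # − strand half, as sequenced
                flip = (st == 1)[:, None]
                r1 = np.where(flip, right_rc, left)
                r2 = np.where(flip, left, right_rc)
                n_c = hi - lo
                sl = slice(row, row + 2 * n_c)
                codes[row : row + 2 * n_c : 2] = r1
                codes[row + 1 : row + 1 + 2 * n_c : 2] = r2
                contig_idx[sl] = ci
                start[row : row + 2 * n_c : 2] = np.where(st == 1, fs + rl, fs)
                start[row + 1 : row + 1 + 2 * n_c : 2] = np.where(st == 1, fs, fs + rl)
                strand[row : row + 2 * n_c : 2] = st
                strand[row + 1 : row + 1 + 2 * n_c : 2] = 1 - st
                mate[row : row + 2 * n_c : 2] = 0
                mate[row + 1 : row + 1 + 2 * n_c : 2] = 1
                row += 2 * n_c
            else:
                r = win
                flip = st == 1
                r[flip] = 3 - r[flip][:, ::-1]
                n_c = hi - lo
                codes[row : row + n_c] = r
                contig_idx[row : row + n_c] = ci
                start[row : row + n_c] = fs
                strand[row : row + n_c] = st
                row += n_c

    if spec.error_rate > 0:
        for lo in range(0, n_reads, 50_000):
            hi = min(lo + 50_000, n_reads)
            block = codes[lo:hi]
            mask = rng.random(block.shape, dtype=np.float32) < spec.error_rate
            shift = rng.integers(1, 4, int(mask.sum()), dtype=np.uint8)
            block[mask] = (block[mask] + shift) % 4

    return ReadSet(
        codes=codes,
        contig_idx=contig_idx,
        start=start,
        strand=strand,
        contig_names=[c.name for c in genome],
        paired=spec.paired,
        mate=mate,
    )


# ---------------------------------------------------------------------------
# alignment emission
# ---------------------------------------------------------------------------

@dataclass
class AlignmentEmission:
    n_written: int
    n_dropped: int
    n_warnings: int


def emit_alignments(
    reads: ReadSet,
    targets: Sequence[Contig],
    path: str | Path,
    liftover: Sequence[Segment] | None = None,
    write_seq: bool = True,
) -> AlignmentEmission:
    """Write SAM records for every read that maps wholly inside one target region.

    Placements are lifted from true-genome coordinates through ``liftover``
    (identity over ``targets`` when omitted).  Reads spanning a segment
    boundary — e.g. a planted misjoin — are omitted, which is precisely what
    creates the coverage drop a junction caller looks for.  Records are
    primary, CIGAR all-match, MAPQ 60; SEQ is written in reference orientation
    unless ``write_seq`` is false (then '*').
    """
    if liftover is None:
        liftover = identity_liftover(targets)
    tgt_names = [c.name for c in targets]
    tgt_index = {n: i for i, n in enumerate(tgt_names)}
    tgt_len = {c.name: len(c) for c in targets}

    by_source: dict[str, list[Segment]] = {}
    for seg in liftover:
        if seg.target not in tgt_index:
            raise ValueError(f"liftover target {seg.target!r} not among targets")
        by_source.setdefault(seg.source, []).append(seg)
    src_tables: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list[Segment]]] = {}
    for src, segs in by_source.items():
        segs = sorted(segs, key=lambda s: s.src_start)
        starts = np.array([s.src_start for s in segs], dtype=np.int64)
        ends = np.array([s.src_start + s.length for s in segs], dtype=np.int64)
        tstarts = np.array([s.tgt_start for s in segs], dtype=np.int64)
        src_tables[src] = (starts, ends, tstarts, segs)

    rl = reads.read_length
    n = reads.n_reads
    cigar = f"{rl}M"

    # vectorised liftover: target index and 0-based position per read, -1 = dropped
    pos0_all = np.full(n, -1, dtype=np.int64)
    tgt_of = np.full(n, -1, dtype=np.int32)
    n_warn = 0
    for ci, src in enumerate(reads.contig_names):
        sel = np.flatnonzero(reads.contig_idx == ci)
        if sel.size == 0:
            continue
        table = src_tables.get(src)
        if table is None:
            continue
        starts, ends, tstarts, segs = table
        rstart = reads.start[sel]
        j = np.searchsorted(starts, rstart, side="right") - 1
        jc = np.maximum(j, 0)
        ok = (j >= 0) & (rstart + rl <= ends[jc])
        seg_tidx = np.array([tgt_index[s.target] for s in segs], dtype=np.int32)
        seg_tlen = np.array([tgt_len[s.target] for s in segs], dtype=np.int64)
        pos0 = tstarts[jc] + rstart - starts[jc]
        off_end = ok & (pos0 + rl > seg_tlen[jc])  # defensive: malformed segment
        n_warn += int(off_end.sum())
        ok &= ~off_end
        pos0_all[sel[ok]] = pos0[ok]
        tgt_of[sel[ok]] = seg_tidx[jc[ok]]

    n_written = int((tgt_of >= 0).sum())
    n_dropped = n - n_written - n_warn

    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name in tgt_names:
            fh.write(f"@SQ\tSN:{name}\tLN:{tgt_len[name]}\n")
        fh.write("@PG\tID:crcurate-synth\tPN:crcurate-synth\n")
        if write_seq:
            ascii_fwd = BASE[reads.codes]
            ascii_rev = BASE[(3 - reads.codes)[:, ::-1]]
        buf: list[str] = []
        for i in range(n):
            ti = tgt_of[i]
            if ti < 0:
                continue
            flag = 16 if reads.strand[i] else 0
            if write_seq:
                seq = (ascii_rev[i] if flag else ascii_fwd[i]).tobytes().decode("ascii")
            else:
                seq = "*"
            buf.append(
                f"{reads.name(i)}\t{flag}\t{tgt_names[ti]}\t{pos0_all[i] + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*"
            )
            if len(buf) >= 100_000:
                fh.write("\n".join(buf) + "\n")
                buf.clear()
        if buf:
            fh.write("\n".join(buf) + "\n")
    return AlignmentEmission(n_written, n_dropped, n_warn)


# ---------------------------------------------------------------------------
# classifier table
# ---------------------------------------------------------------------------

def emit_classifier_table(
    fragments: Sequence,
    truth: TruthTable,
    accuracy: float,
    unclassified_rate: float,
    seed: int,
    path: str | Path | None = None,
) -> list[tuple[str, str, int]]:
    """Kaiju-style 3-column classification of contig fragments.

    Each fragment is unclassified with probability ``unclassified_rate``;
    otherwise it receives the representative taxon of its true superkingdom
    with probability ``accuracy`` and of the wrong superkingdom otherwise
    (Bacteria for genuine host fragments, Eukaryota for contaminant ones).
    """
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    if not 0.0 <= unclassified_rate <= 1.0:
        raise ValueError("unclassified_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    contaminants = set(truth.contaminant_ids)
    rows: list[tuple[str, str, int]] = []
    u = rng.random(len(fragments))
    ok = rng.random(len(fragments))
    for i, frag in enumerate(fragments):
        if u[i] < unclassified_rate:
            rows.append(("U", frag.fragment_id, 0))
            continue
        is_contam = frag.contig in contaminants
        correct = ok[i] < accuracy
        bacterial = is_contam == correct
        taxid = REPRESENTATIVE["Bacteria"] if bacterial else REPRESENTATIVE["Eukaryota"]
        rows.append(("C", frag.fragment_id, taxid))
    if path is not None:
        with open(path, "w") as fh:
            for status, fid, taxid in rows:
                fh.write(f"{status}\t{fid}\t{taxid}\n")
    return rows
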