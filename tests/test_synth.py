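"""Synthetic data generator: determinism, planted truth, format contracts."""

import numpy as np
import pytest

import crcurate as cc
from crcurate._encode import revcomp
from crcurate.decontam import fragment_contigs, gc_fraction
from crcurate.synth import emit_classifier_table, make_chimeras
from crcurate.taxonomy import REPRESENTATIVE


def test_generation_is_deterministic(tmp_path):
    spec = cc.GenomeSpec(haploid_size=50_000, n_chromosomes=2, rdna_copies=3, seed=1)
    g1, g2 = cc.generate_genome(spec), cc.generate_genome(spec)
    p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
    cc.write_fasta(g1.assembly(), p1)
    cc.write_fasta(g2.assembly(), p2)
    assert p1.read_bytes() == p2.read_bytes()

    reads1 = cc.simulate_reads(g1.haplotype_a, cc.ReadSimSpec(read_length=100, coverage=5, seed=3))
    reads2 = cc.simulate_reads(g2.haplotype_a, cc.ReadSimSpec(read_length=100, coverage=5, seed=3))
    f1, f2 = tmp_path / "r1.fastq", tmp_path / "r2.fastq"
    reads1.write_fastq(f1)
    reads2.write_fastq(f2)
    assert f1.read_bytes() == f2.read_bytes()


def test_zero_heterozygosity_gives_identical_haplotypes():
    spec = cc.GenomeSpec(haploid_size=40_000, n_chromosomes=2, het_rate=0.0, rdna_copies=0, seed=2)
    g = cc.generate_genome(spec)
    for a, b in zip(g.haplotype_a, g.haplotype_b):
        assert a.seq == b.seq


def test_heterozygosity_rate_is_respected():
    spec = cc.GenomeSpec(haploid_size=200_000, n_chromosomes=2, het_rate=0.01, rdna_copies=0, seed=3)
    g = cc.generate_genome(spec)
    diffs = sum(
        sum(x != y for x, y in zip(a.seq, b.seq))
        for a, b in zip(g.haplotype_a, g.haplotype_b)
    )
    # binomial(200k, 0.01): mean 2000, 3 sigma ~ 133
    assert 1850 <= diffs <= 2150


def test_nuclear_gc_matches_target():
    spec = cc.GenomeSpec(haploid_size=500_000, gc_target=0.70, rdna_copies=0, seed=4)
    g = cc.generate_genome(spec)
    gc = gc_fraction("".join(c.seq for c in g.haplotype_a))
    assert 0.68 <= gc <= 0.72


def test_rdna_array_is_tandem_and_recorded(small_genome):
    contig, start, end = small_genome.truth.rdna_locus
    seq = next(c for c in small_genome.haplotype_a if c.name == contig).seq[start:end]
    unit_len = (end - start) // small_genome.truth.true_rdna_copies
    units = {seq[i : i + unit_len] for i in range(0, len(seq), unit_len)}
    assert len(units) == 1  # identical tandem copies


def test_mito_linear_has_duplicated_ends(small_genome):
    ov = small_genome.truth.mito_overlap
    lin = small_genome.mito_linear.seq
    assert lin[:ov] == lin[-ov:]
    assert len(lin) == len(small_genome.mito_circle) + ov


def test_contradictory_spec_rejected():
    with pytest.raises(ValueError, match="contradictory"):
        cc.GenomeSpec(haploid_size=10_000, rdna_copies=100, rdna_unit_length=3000)
    with pytest.raises(ValueError):
        cc.GenomeSpec(haploid_size=10_000, mito_length=100, mito_end_overlap=200)
    with pytest.raises(ValueError):
        cc.ReadSimSpec(coverage=0)
    with pytest.raises(ValueError):
        cc.ReadSimSpec(error_rate=1.0)


def test_truth_table_round_trip(tmp_path, small_genome):
    path = tmp_path / "truth.json"
    small_genome.truth.to_json(path)
    back = cc.TruthTable.from_json(path)
    assert back == small_genome.truth


# ---------------------------------------------------------------------------
# chimeras
# ---------------------------------------------------------------------------

def test_no_chimeras_returns_input(random_contigs):
    contigs = random_contigs([5000, 6000])
    ch = make_chimeras(contigs, 0, seed=1)
    assert ch.contigs == contigs
    assert ch.junctions == []


def test_chimera_construction_records_breakpoint(random_contigs):
    contigs = random_contigs([10_000, 10_000])
    ch = make_chimeras(contigs, 1, seed=1)
    assert len(ch.contigs) == 1
    chimera = ch.contigs[0]
    assert len(chimera) == 20_000
    name, start, end = ch.junctions[0]
    assert (name, start, end) == (chimera.name, 10_000, 10_000)
    # the chimera is the concatenation of the two sources in some order
    assert {chimera.seq[:10_000], chimera.seq[10_000:]} == {c.seq for c in contigs}


def test_chimera_junctions_strictly_internal(random_contigs):
    contigs = random_contigs([4000] * 50)
    ch = make_chimeras(contigs, 20, seed=9)
    assert len(ch.junctions) == 20
    lengths = {c.name: len(c) for c in ch.contigs}
    for name, start, _ in ch.junctions:
        assert 0 < start < lengths[name]


def test_too_many_chimeras_rejected(random_contigs):
    with pytest.raises(ValueError, match="exceeds"):
        make_chimeras(random_contigs([1000] * 4), 3, seed=0)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def test_error_free_reads_are_exact_substrings(random_contigs):
    contigs = random_contigs([10_000])
    reads = cc.simulate_reads(contigs, cc.ReadSimSpec(read_length=300, coverage=20, seed=5))
    seqs = list(reads.sequences())
    ref = contigs[0].seq
    for i in range(0, reads.n_reads, 37):  # sample
        window = ref[reads.start[i] : reads.start[i] + 300]
        expect = revcomp(window) if reads.strand[i] else window
        assert seqs[i] == expect


def test_total_bases_match_coverage(random_contigs):
    contigs = random_contigs([10_000, 20_000, 7_000])
    for cov in (5.0, 30.0):
        reads = cc.simulate_reads(contigs, cc.ReadSimSpec(read_length=150, coverage=cov, seed=6))
        ratio = reads.total_bases / (37_000 * cov)
        assert 0.98 <= ratio <= 1.02


def test_error_rate_applied(random_contigs):
    contigs = random_contigs([50_000])
    reads = cc.simulate_reads(
        contigs, cc.ReadSimSpec(read_length=150, coverage=10, error_rate=0.02, seed=7)
    )
    ref = contigs[0].seq
    mismatches = total = 0
    seqs = list(reads.sequences())
    for i in range(0, reads.n_reads, 11):
        window = ref[reads.start[i] : reads.start[i] + 150]
        expect = revcomp(window) if reads.strand[i] else window
        mismatches += sum(x != y for x, y in zip(seqs[i], expect))
        total += 150
    assert 0.015 <= mismatches / total <= 0.025


def test_paired_reads_written_synchronized(tmp_path, random_contigs):
    contigs = random_contigs([20_000])
    reads = cc.simulate_reads(
        contigs, cc.ReadSimSpec(read_length=100, coverage=4, paired=True, seed=8)
    )
    p1, p2 = tmp_path / "R1.fastq", tmp_path / "R2.fastq"
    reads.write_fastq(p1, p2)
    names1 = [l.split("/")[0] for l in p1.read_text().splitlines()[::4]]
    names2 = [l.split("/")[0] for l in p2.read_text().splitlines()[::4]]
    assert names1 == names2 and len(names1) == reads.n_reads // 2


def test_read_simulation_preconditions(random_contigs):
    with pytest.raises(ValueError, match="empty"):
        cc.simulate_reads([], cc.ReadSimSpec())
    with pytest.raises(ValueError, match="shortest"):
        cc.simulate_reads(random_contigs([100]), cc.ReadSimSpec(read_length=300, coverage=5))


# ---------------------------------------------------------------------------
# alignments
# ---------------------------------------------------------------------------

def test_sam_coordinate_convention(tmp_path, random_contigs):
    contigs = random_contigs([1000])
    reads = cc.simulate_reads(contigs, cc.ReadSimSpec(read_length=300, coverage=1, seed=9))
    reads.start[:] = 100
    reads.strand[:] = 0
    sam = tmp_path / "one.sam"
    cc.emit_alignments(reads, contigs, sam)
    body = [l for l in sam.read_text().splitlines() if not l.startswith("@")]
    cols = body[0].split("\t")
    assert cols[3] == "101" and cols[5] == "300M"


def test_no_alignment_spans_planted_junction(tmp_path, random_contigs):
    sources = random_contigs([8000, 8000])
    ch = make_chimeras(sources, 1, seed=2)
    reads = cc.simulate_reads(sources, cc.ReadSimSpec(read_length=150, coverage=30, seed=10))
    sam = tmp_path / "chim.sam"
    cc.emit_alignments(reads, ch.contigs, sam, liftover=ch.liftover)
    tracks = cc.depth_from_alignments(sam, ch.contigs)
    name, pos, _ = ch.junctions[0]
    # reads cannot span the joint: depth exactly at the breakpoint is 0
    assert tracks[name].depth[pos - 1 : pos + 1].max() == 0


def test_empty_placements_give_header_only_sam(tmp_path, random_contigs):
    contigs = random_contigs([1000])
    reads = cc.simulate_reads(contigs, cc.ReadSimSpec(read_length=100, coverage=1, seed=1))
    # retarget all reads at a contig absent from the liftover: all dropped
    em = cc.emit_alignments(reads, contigs, tmp_path / "empty.sam", liftover=[])
    assert em.n_written == 0
    lines = (tmp_path / "empty.sam").read_text().splitlines()
    assert lines and all(l.startswith("@") for l in lines)


# ---------------------------------------------------------------------------
# classifier table
# ---------------------------------------------------------------------------

def test_perfect_classifier_labels_all_contaminants(small_genome):
    frags = fragment_contigs(small_genome.assembly())
    rows = emit_classifier_table(frags, small_genome.truth, accuracy=1.0, unclassified_rate=0.0, seed=1)
    contam = set(small_genome.truth.contaminant_ids)
    for (status, fid, taxid), frag in zip(rows, frags):
        assert status == "C"
        if frag.contig in contam:
            assert taxid == REPRESENTATIVE["Bacteria"]
        else:
            assert taxid == REPRESENTATIVE["Eukaryota"]


def test_classifier_accuracy_within_binomial_bounds(random_contigs):
    spec = cc.GenomeSpec(
        haploid_size=100_000, n_chromosomes=2, rdna_copies=0,
        contaminant_count=1, contaminant_length=500_000, seed=5,
    )
    g = cc.generate_genome(spec)
    frags = [f for f in fragment_contigs(g.contaminants)][:1000]
    rows = emit_classifier_table(frags, g.truth, accuracy=0.9, unclassified_rate=0.0, seed=2)
    n_bact = sum(taxid == REPRESENTATIVE["Bacteria"] for _, _, taxid in rows)
    assert 870 <= n_bact <= 930  # 3 sigma around 900


def test_fully_unclassified_table(small_genome):
    frags = fragment_contigs(small_genome.assembly())[:50]
    rows = emit_classifier_table(frags, small_genome.truth, accuracy=1.0, unclassified_rate=1.0, seed=3)
    assert all(status == "U" for status, _, _ in rows)


def test_depth_matches_coverage_away_from_ends(tmp_path, random_contigs):
    """Reconstructed depth equals coverage within 3*sqrt(coverage) in the interior."""
    contigs = random_contigs([30_000])
    reads = cc.simulate_reads(contigs, cc.ReadSimSpec(read_length=150, coverage=30, seed=11))
    sam = tmp_path / "cov.sam"
    cc.emit_alignments(reads, contigs, sam, write_seq=False)
    track = cc.depth_from_alignments(sam, contigs)[contigs[0].name]
    interior = track.depth[300:-300]
    assert abs(np.median(interior) - 30) <= 3 * np.sqrt(30)
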