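"""End-to-end validation scenarios with planted ground truth.

Each function builds one synthetic study condition with the
:mod:`~crcurate.synth` generator, runs the corresponding curation stage, and
scores the result against the truth table.  The conditions (genome size,
heterozygosity, GC, coverages, copy numbers, classifier accuracy) are fixed
properties of the scenarios, shared between the test suite and the
reproduction script; only the seed varies.

Scenario read lengths: the k-mer scenario uses 300 bp reads (MiSeq-like);
the alignment-based scenarios use 150 bp reads so that the junction caller's
default 200 bp flank windows clear the read-shadow ramp that surrounds any
breakpoint (see the methods note for the arithmetic).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._encode import decode, encode
from .decontam import fragment_contigs, screen_contigs, apply_decontamination
from .junctions import (
    JunctionParams,
    break_contigs,
    depth_from_alignments,
    detect_junctions,
)
from .kmers import count_canonical_kmers, estimate_genome_size
from .mito import circ_restart, circ_trim
from .rdna import OperonAnnotation, allele_fraction_at_sites, operon_copy_number
from .seqio import Contig, total_length
from .stats import ani
from .synth import (
    GenomeSpec,
    ReadSimSpec,
    Segment,
    emit_alignments,
    emit_classifier_table,
    generate_genome,
    identity_liftover,
    make_chimeras,
    simulate_reads,
    _mutate,
)
from .taxonomy import toy_taxonomy


def _sub_seed(seed: int, tag: int) -> int:
    return (seed * 1_000_003 + tag) % (2**31 - 1)


# ---------------------------------------------------------------------------

def genome_size_scenario(seed: int, tmpdir: str | Path | None = None) -> dict:
    """5 Mbp diploid (het 0.005, GC 0.70), 60x error-free 300 bp reads, k=19.

    Reads are simulated from both haplotypes at 30x each, i.e. 60x per
    haploid genome.  Returns the estimate, its relative error, and the
    1n/2n peak positions.
    """
    spec = GenomeSpec(
        haploid_size=5_000_000,
        gc_target=0.70,
        het_rate=0.005,
        contaminant_count=0,
        seed=_sub_seed(seed, 1),
    )
    genome = generate_genome(spec)
    reads = simulate_reads(
        genome.diploid(),
        ReadSimSpec(read_length=300, coverage=30.0, error_rate=0.0, seed=_sub_seed(seed, 2)),
    )
    hist = count_canonical_kmers(reads, k=19)
    est = estimate_genome_size(hist)
    rel_err = abs(est.haploid_size - spec.haploid_size) / spec.haploid_size
    peak_ratio = (
        est.heterozygous_peak_coverage / est.homozygous_peak_coverage
        if est.heterozygous_peak_coverage
        else None
    )
    return {
        "true_haploid_size": spec.haploid_size,
        "estimate": est,
        "relative_error": rel_err,
        "het_to_hom_peak_ratio": peak_ratio,
        "total_kmers": hist.total_kmers,
    }


# ---------------------------------------------------------------------------

def junction_scenario(seed: int, tmpdir: str | Path) -> dict:
    """20 chimeras among 100 assembly contigs, 30x 150 bp synthetic alignments.

    120 clean 20 kb source contigs; 40 are joined pairwise into 20 chimeras,
    so the target assembly has 100 contigs.  Reads come from the clean
    genome, so each misjoin is a genuine coverage gap.  Scores recall
    (truth breakpoint inside a removed interval), false calls (any call
    > 500 bp from every truth breakpoint), and exact base conservation.
    """
    tmpdir = Path(tmpdir)
    spec = GenomeSpec(
        haploid_size=2_400_000,
        gc_target=0.70,
        het_rate=0.0,
        rdna_copies=0,
        contaminant_count=0,
        n_chromosomes=120,
        seed=_sub_seed(seed, 3),
    )
    genome = generate_genome(spec)
    sources = genome.haplotype_a
    chim = make_chimeras(sources, 20, seed=_sub_seed(seed, 4))
    reads = simulate_reads(
        sources, ReadSimSpec(read_length=150, coverage=30.0, seed=_sub_seed(seed, 5))
    )
    sam = tmpdir / "junction_scenario.sam"
    emit_alignments(reads, chim.contigs, sam, liftover=chim.liftover, write_seq=False)
    tracks = depth_from_alignments(sam, chim.contigs)
    calls = []
    for track in tracks.values():
        calls.extend(detect_junctions(track, JunctionParams()))
    result = break_contigs(chim.contigs, calls)

    truth_by_contig: dict[str, list[int]] = {}
    for name, pos, _ in chim.junctions:
        truth_by_contig.setdefault(name, []).append(pos)
    n_recovered = sum(
        any(name == c and s <= pos <= e for c, s, e in result.removed)
        for name, pos, _ in chim.junctions
    )
    false_calls = sum(
        not any(
            abs(pos - call.start) <= 500 or abs(pos - call.end) <= 500
            for pos in truth_by_contig.get(call.contig, [])
        )
        for call in calls
    )
    conserved = total_length(chim.contigs) == (
        total_length(result.contigs) + result.removed_bases + result.dropped_bases
    )
    return {
        "n_truth_junctions": len(chim.junctions),
        "n_calls": len(calls),
        "recall": n_recovered / len(chim.junctions),
        "false_calls": false_calls,
        "base_conservation": conserved,
    }


# ---------------------------------------------------------------------------

def decontam_scenario(seed: int, accuracy: float, unclassified_rate: float) -> dict:
    """40 host contigs (10 kb, GC 0.70) + 20 bacterial contigs (8 kb, GC 0.45).

    The classifier table is fabricated at the given accuracy/unclassified
    rate; precision and recall of contaminant removal are scored against the
    truth table.
    """
    spec = GenomeSpec(
        haploid_size=400_000,
        gc_target=0.70,
        het_rate=0.0,
        rdna_copies=0,
        n_chromosomes=40,
        contaminant_count=20,
        contaminant_length=8_000,
        contaminant_gc=0.45,
        seed=_sub_seed(seed, 6),
    )
    genome = generate_genome(spec)
    assembly = genome.haplotype_a + genome.contaminants
    frags = fragment_contigs(assembly)
    rows = emit_classifier_table(
        frags, genome.truth, accuracy, unclassified_rate, seed=_sub_seed(seed, 7)
    )
    screens = screen_contigs(assembly, rows, toy_taxonomy())
    kept, dropped, _ = apply_decontamination(assembly, screens)
    truth = set(genome.truth.contaminant_ids)
    dropped_names = {c.name for c in dropped}
    tp = len(dropped_names & truth)
    fp = len(dropped_names - truth)
    fn = len(truth - dropped_names)
    return {
        "precision": tp / (tp + fp) if tp + fp else 1.0,
        "recall": tp / (tp + fn) if tp + fn else 1.0,
        "n_dropped": len(dropped),
        "n_kept": len(kept),
        "screens": screens,
    }


# ---------------------------------------------------------------------------

def mito_scenario(seed: int, overlaps: tuple[int, ...] = (50, 100, 250, 500, 1000, 2000)) -> dict:
    """Planted circular end-overlaps recovered exactly by circ_trim.

    For each overlap length the generator emits the linear contig with
    duplicated ends; the scenario checks exact recovery of the circle length
    and idempotence of the trim.
    """
    max_err = 0
    all_idempotent = True
    for i, ov in enumerate(overlaps):
        spec = GenomeSpec(
            haploid_size=100_000,
            rdna_copies=0,
            contaminant_count=0,
            mito_length=20_000,
            mito_end_overlap=ov,
            seed=_sub_seed(seed, 10 + i),
        )
        genome = generate_genome(spec)
        trimmed, rec = circ_trim(genome.mito_linear)
        max_err = max(max_err, abs(rec.overlap_trimmed - ov), abs(len(trimmed) - spec.mito_length))
        again, rec2 = circ_trim(trimmed)
        all_idempotent &= rec2.overlap_trimmed == 0 and again.seq == trimmed.seq
    return {"max_overlap_error_bp": max_err, "idempotent": all_idempotent, "overlaps": overlaps}


# ---------------------------------------------------------------------------

def _collapse_rdna(genome, spec: GenomeSpec) -> tuple[list[Contig], list[Segment], OperonAnnotation]:
    """Collapse the planted tandem array to one unit, with liftover."""
    contig_name, at, end = genome.truth.rdna_locus
    unit = spec.rdna_unit_length
    copies = spec.rdna_copies
    src = next(c for c in genome.haplotype_a if c.name == contig_name)
    collapsed = Contig(contig_name, src.seq[:at] + src.seq[at : at + unit] + src.seq[end:])
    segments = [Segment(contig_name, 0, contig_name, 0, at)]
    for i in range(copies):
        segments.append(Segment(contig_name, at, contig_name, at + i * unit, unit))
    segments.append(Segment(contig_name, at + unit, contig_name, end, len(src) - end))
    targets = [collapsed] + [c for c in genome.haplotype_a if c.name != contig_name]
    segments += identity_liftover(targets[1:])
    annotation = OperonAnnotation(contig=contig_name, start=at, end=at + unit)
    return targets, segments, annotation


def rdna_scenario(seed: int, copies: int, tmpdir: str | Path, coverage: float = 100.0) -> dict:
    """Planted tandem array of ``copies`` units at uniform coverage.

    The true genome carries the full array; the assembly collapses it to a
    single unit, as real assemblers do, so its read depth is ``copies`` times
    the single-copy backbone.  55 backbone contigs of 4 kb feed the
    50-longest-contig baseline.
    """
    tmpdir = Path(tmpdir)
    unit = 3000
    n_contigs = 55
    spec = GenomeSpec(
        haploid_size=n_contigs * 4000 + copies * unit,
        rdna_unit_length=unit,
        rdna_copies=copies,
        n_chromosomes=n_contigs,
        contaminant_count=0,
        het_rate=0.0,
        seed=_sub_seed(seed, 20),
    )
    genome = generate_genome(spec)
    targets, liftover, annotation = _collapse_rdna(genome, spec)
    reads = simulate_reads(
        genome.haplotype_a,
        ReadSimSpec(read_length=150, coverage=coverage, seed=_sub_seed(seed, 21)),
    )
    sam = tmpdir / f"rdna_{copies}.sam"
    emit_alignments(reads, targets, sam, liftover=liftover, write_seq=False)
    tracks = depth_from_alignments(sam, targets)
    est = operon_copy_number(tracks, annotation)
    return {
        "true_copies": copies,
        "estimate": est,
        "relative_error": abs(est.haploid_copies - copies) / copies,
        "tracks": tracks,
        "annotation": annotation,
    }


def allele_fraction_scenario(seed: int, tmpdir: str | Path, ratio: float = 0.25, coverage: float = 100.0) -> dict:
    """Het-like site with a planted minor-allele ratio under uniform coverage.

    Four identical source copies of one contig, one of which carries the
    alternative base at five sites, are read-simulated and mapped onto a
    single target copy (ratio 0.25 = one copy in four).
    """
    tmpdir = Path(tmpdir)
    n_copies = int(round(1 / ratio))
    rng = np.random.default_rng(_sub_seed(seed, 30))
    target_codes = _random_codes_contig(rng, 20_000, 0.5)
    sites = sorted(int(p) for p in rng.choice(np.arange(2_000, 18_000), size=5, replace=False))
    alt_codes = target_codes.copy()
    for p in sites:
        alt_codes[p] = (alt_codes[p] + 1) % 4
    target = Contig("site_contig", decode(target_codes))
    sources = [Contig(f"copy{i}", target.seq) for i in range(n_copies - 1)]
    sources.append(Contig(f"copy{n_copies - 1}", decode(alt_codes)))
    liftover = [Segment("site_contig", 0, c.name, 0, len(c)) for c in sources]
    reads = simulate_reads(
        sources,
        ReadSimSpec(read_length=150, coverage=coverage / n_copies, seed=_sub_seed(seed, 31)),
    )
    sam = tmpdir / "allele_sites.sam"
    emit_alignments(reads, [target], sam, liftover=liftover)
    site_list = [("site_contig", p, decode(target_codes[p : p + 1])) for p in sites]
    counts = allele_fraction_at_sites(sam, site_list)
    return {"ratio": ratio, "sites": counts}


def _random_codes_contig(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    from .synth import _random_codes

    return _random_codes(rng, n, gc)


# ---------------------------------------------------------------------------

def ani_scenario(seed: int, substitution_rate: float = 0.01) -> dict:
    """Self-ANI and ANI against a copy with i.i.d. substitutions."""
    spec = GenomeSpec(
        haploid_size=1_000_000,
        gc_target=0.70,
        het_rate=0.0,
        rdna_copies=0,
        contaminant_count=0,
        n_chromosomes=5,
        seed=_sub_seed(seed, 40),
    )
    genome = generate_genome(spec)
    contigs = genome.haplotype_a
    rng = np.random.default_rng(_sub_seed(seed, 41))
    mutated = [
        Contig(c.name + "_mut", decode(_mutate(rng, encode(c.seq), substitution_rate)))
        for c in contigs
    ]
    self_ani = ani(contigs, contigs, query_name="self", reference_name="self")
    mut_ani = ani(contigs, mutated, query_name="orig", reference_name="mutated")
    return {"self": self_ani, "mutated": mut_ani, "substitution_rate": substitution_rate}
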