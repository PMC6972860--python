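"""rDNA operon copy number, strain-specific substitutions, allele fractions.

The ribosomal RNA operon (18S–ITS1–5.8S–ITS2–28S) is a tandem repeat that
assembles as a single collapsed copy, so its read depth relative to the
single-copy genome backbone measures its haploid copy number:
``copies = median depth over the operon / median depth over the 50 longest
contigs``.  Ploidy cancels in the ratio because operon and backbone are
equally diploid.

The module also counts strain-unique substitutions in an operon multiple
alignment (a strain scores one substitution in a column where it differs
from a base unanimous among all other strains) and summarises read base
counts at externally supplied SNP sites — the allele fraction of the minor
variant at an rDNA SNP reflects what fraction of the repeat copies carry it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
from Bio import SeqIO

from .junctions import DepthTrack, _lower_median

BACKBONE_CONTIGS = 50


@dataclass(frozen=True)
class OperonAnnotation:
    """Operon interval and named subregions, 0-based half-open on one contig."""

    contig: str
    start: int
    end: int
    subregions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = self.start
        for name, (s, e) in self.subregions.items():
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"subregion {name} not nested in operon")
            if s < prev_end:
                raise ValueError(f"subregion {name} overlaps or is out of order")
            prev_end = e

    @classmethod
    def from_bed(cls, path: str | Path) -> "OperonAnnotation":
        """BED (0-based half-open); the row named 'operon' is the outer interval."""
        operon = None
        subs: dict[str, tuple[int, int]] = {}
        contig = None
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                cols = line.rstrip("\n").split("\t")
                name = cols[3] if len(cols) > 3 else "operon"
                iv = (int(cols[1]), int(cols[2]))
                if name == "operon":
                    operon, contig = iv, cols[0]
                else:
                    subs[name] = iv
        if operon is None:
            raise ValueError("no 'operon' interval in BED")
        return cls(contig=contig, start=operon[0], end=operon[1], subregions=subs)

    @classmethod
    def from_gff3(cls, path: str | Path) -> "OperonAnnotation":
        """GFF3 (1-based closed, converted on read); feature type 'operon' is outer."""
        operon = None
        subs: dict[str, tuple[int, int]] = {}
        contig = None
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 5:
                    continue
                iv = (int(cols[3]) - 1, int(cols[4]))
                if cols[2] == "operon":
                    operon, contig = iv, cols[0]
                else:
                    subs[cols[2]] = iv
        if operon is None:
            raise ValueError("no 'operon' feature in GFF3")
        return cls(contig=contig, start=operon[0], end=operon[1], subregions=subs)


@dataclass
class CopyNumberEstimate:
    operon_median_depth: float
    backbone_median_depth: float
    haploid_copies: float
    n_backbone_contigs: int = BACKBONE_CONTIGS

    @property
    def rounded_copies(self) -> int:
        return int(round(self.haploid_copies))


def operon_copy_number(
    tracks: dict[str, DepthTrack],
    annotation: OperonAnnotation,
    n_backbone: int = BACKBONE_CONTIGS,
) -> CopyNumberEstimate:
    """Copy number as operon median depth over backbone median depth.

    The backbone median pools the per-base depths of the ``n_backbone``
    longest contigs (all contigs, when fewer are available).  Both medians
    use the lower median for even counts.
    """
    if annotation.contig not in tracks:
        raise ValueError(f"annotation contig {annotation.contig!r} has no depth track")
    op_track = tracks[annotation.contig]
    if not (0 <= annotation.start < annotation.end <= op_track.length):
        raise ValueError("operon interval outside contig")
    operon_median = _lower_median(op_track.depth[annotation.start : annotation.end])

    by_length = sorted(tracks.values(), key=lambda t: (-t.length, t.contig))
    backbone = by_length[:n_backbone]
    pooled = np.concatenate([t.depth for t in backbone])
    backbone_median = _lower_median(pooled)
    if backbone_median <= 0:
        raise ValueError("no coverage baseline (backbone median depth is 0)")
    return CopyNumberEstimate(
        operon_median_depth=operon_median,
        backbone_median_depth=backbone_median,
        haploid_copies=operon_median / backbone_median,
        n_backbone_contigs=len(backbone),
    )


# ---------------------------------------------------------------------------
# strain substitutions in the operon alignment
# ---------------------------------------------------------------------------

@dataclass
class SubstitutionCounts:
    per_strain: dict[str, dict[str, int]]  # strain -> region -> count
    ambiguous_columns: int
    gap_columns: int


def count_strain_substitutions(
    msa, regions: dict[str, tuple[int, int]] | None = None
) -> SubstitutionCounts:
    """Strain-unique substitutions per alignment region.

    ``msa`` is an aligned FASTA path or a Biopython alignment with >= 3 rows
    of equal length.  In each gap-free column, a strain scores one
    substitution when its base differs from a base unanimous among all other
    strains; columns with gaps are skipped (counted), as are columns with any
    other variant pattern (reported as ambiguous).  ``regions`` maps region
    names to 0-based half-open intervals in alignment coordinates; columns
    outside every region land in region ``"other"``.
    """
    if isinstance(msa, (str, Path)):
        msa = list(SeqIO.parse(str(msa), "fasta"))
    names = [rec.id for rec in msa]
    if len(names) < 3:
        raise ValueError("need at least 3 aligned sequences")
    rows = [str(rec.seq).upper() for rec in msa]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("aligned sequences have unequal lengths")
    length = len(rows[0])
    regions = regions or {}

    def region_of(col: int) -> str:
        for name, (s, e) in regions.items():
            if s <= col < e:
                return name
        return "other"

    per_strain: dict[str, dict[str, int]] = {n: {} for n in names}
    ambiguous = gaps = 0
    arr = np.array([list(r) for r in rows])
    for col in range(length):
        column = arr[:, col]
        if "-" in column:
            gaps += 1
            continue
        values, counts = np.unique(column, return_counts=True)
        if values.size == 1:
            continue
        if values.size == 2 and counts.min() == 1:
            strain = names[int(np.flatnonzero(column == values[np.argmin(counts)])[0])]
            region = region_of(col)
            per_strain[strain][region] = per_strain[strain].get(region, 0) + 1
        else:
            ambiguous += 1
    return SubstitutionCounts(per_strain=per_strain, ambiguous_columns=ambiguous, gap_columns=gaps)


# ---------------------------------------------------------------------------
# allele fractions at given sites
# ---------------------------------------------------------------------------

@dataclass
class SiteAlleleCounts:
    contig: str
    position: int  # 0-based
    ref_base: str
    counts: dict[str, int]
    depth: int
    minor_fraction: float | None  # fraction of the top non-reference base


def allele_fraction_at_sites(
    alignments: str | Path, sites: Sequence[tuple[str, int, str]]
) -> list[SiteAlleleCounts]:
    """Pileup base counts and minor-allele fraction at specific sites.

    Only primary, mapped, non-supplementary records contribute, and only
    bases aligned through CIGAR M/=/X (deletions and skips never cover a
    site).  Sites with zero depth report ``minor_fraction`` as None.
    """
    by_contig: dict[str, list[int]] = {}
    for contig, pos, _ in sites:
        by_contig.setdefault(contig, []).append(pos)
    counts: dict[tuple[str, int], dict[str, int]] = {
        (c, p): {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0} for c, p, _ in sites
    }
    with pysam.AlignmentFile(str(alignments), "r", check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            targets = by_contig.get(rec.reference_name)
            if not targets:
                continue
            rs, re_ = rec.reference_start, rec.reference_end
            hit = [p for p in targets if rs <= p < re_]
            if not hit:
                continue
            seq = rec.query_sequence
            if seq is None:
                continue
            qpos = 0
            rpos = rs
            spans: list[tuple[int, int, int]] = []  # (ref_start, ref_end, query_start)
            for op, ln in rec.cigartuples:
                if op in (0, 7, 8):
                    spans.append((rpos, rpos + ln, qpos))
                    rpos += ln
                    qpos += ln
                elif op in (2, 3):
                    rpos += ln
                elif op in (1, 4):
                    qpos += ln
            for p in hit:
                for s, e, q in spans:
                    if s <= p < e:
                        base = seq[q + (p - s)].upper()
                        counts[(rec.reference_name, p)][base if base in "ACGTN" else "N"] += 1
                        break

    out: list[SiteAlleleCounts] = []
    for contig, pos, ref in sites:
        c = counts[(contig, pos)]
        depth = sum(v for k, v in c.items() if k != "N")
        ref = ref.upper()
        if depth == 0:
            frac = None
        else:
            alt = max((v for k, v in c.items() if k not in ("N", ref)), default=0)
            frac = alt / depth
        out.append(SiteAlleleCounts(contig, pos, ref, c, depth, frac))
    return out
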