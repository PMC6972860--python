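"""Circular (mitochondrial) contig curation.

Assemblers emit circular replicons as linear contigs, usually with the two
ends overlapping because the walk around the circle overshoots its starting
point.  This module identifies the mitochondrial contig by k-mer containment
against a reference, trims the duplicated end overlap, and rotates the
resulting circle (flipping strand if needed) so that it starts at a chosen
anchor — conventionally the large-subunit rRNA gene, so that all curated
mitogenomes share coordinates with the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from ._encode import canonical_kmer_codes, encode, revcomp
from .seqio import Contig

_SEED_K = 15


@dataclass
class CircularCuration:
    contig: str
    overlap_trimmed: int = 0
    rotation_offset: int = 0
    strand_flipped: bool = False
    final_length: int = 0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def identify_mito_contig(
    assembly: Sequence[Contig], reference: Contig, k: int = 21, min_containment: float = 0.5
) -> tuple[str, float]:
    """Find the assembly contig containing the reference mitogenome.

    Containment is the fraction of the reference's distinct canonical k-mers
    present in a contig, so a mitochondrial contig with extra flanking
    sequence still scores 1.0.  Fails when no contig reaches
    ``min_containment`` (random sequence shares essentially no 21-mers).
    """
    if not reference.seq:
        raise ValueError("empty reference")
    ref_kmers = np.unique(canonical_kmer_codes(encode(reference.seq), k))
    if ref_kmers.size == 0:
        raise ValueError("reference shorter than k")
    best_name, best_score = "", -1.0
    for contig in assembly:
        ck = np.unique(canonical_kmer_codes(encode(contig.seq), k))
        score = float(np.isin(ref_kmers, ck, assume_unique=True).mean())
        if score > best_score:
            best_name, best_score = contig.name, score
    if best_score < min_containment:
        raise ValueError(
            f"no mitochondrial contig: best containment {best_score:.3f} < {min_containment}"
        )
    return best_name, best_score


def _ungapped_identity(a: np.ndarray, b: np.ndarray) -> float:
    return float((a == b).mean())


def circ_trim(
    contig: Contig, min_overlap: int = 50, min_identity: float = 0.95
) -> tuple[Contig, CircularCuration]:
    """Trim the duplicated end of a circular contig.

    Finds the longest suffix aligning ungapped to a prefix with identity >=
    ``min_identity`` and length >= ``min_overlap`` (candidates anchored by
    shared 15-mers between the two halves; ties on length broken toward
    higher identity, though deduplicated candidates make ties rare) and
    removes the suffix copy.  Without a qualifying overlap the contig is
    returned unchanged with ``overlap_trimmed = 0``.
    """
    L = len(contig)
    if L <= 2 * min_overlap:
        raise ValueError("contig too short for overlap trimming")
    codes = encode(contig.seq)
    max_ov = L // 2

    # 15-mer positions in the prefix half
    prefix_kmers: dict[int, list[int]] = {}
    fwd = np.zeros(max_ov - _SEED_K + 1, dtype=np.uint64)
    n = fwd.size
    for i in range(_SEED_K):
        fwd = fwd * 4 + codes[i : i + n].astype(np.uint64)
    for i, code in enumerate(fwd):
        prefix_kmers.setdefault(int(code), []).append(i)

    # candidate overlap lengths implied by seed matches in the suffix half
    suffix_lo = L - max_ov
    m = L - _SEED_K + 1 - suffix_lo
    sfwd = np.zeros(m, dtype=np.uint64)
    for i in range(_SEED_K):
        sfwd = sfwd * 4 + codes[suffix_lo + i : suffix_lo + i + m].astype(np.uint64)
    candidates: set[int] = set()
    for off, code in enumerate(sfwd):
        hits = prefix_kmers.get(int(code))
        if not hits:
            continue
        j = suffix_lo + off
        for i in hits:
            v = L - j + i
            if min_overlap <= v <= max_ov:
                candidates.add(v)

    best_v, best_id = 0, 0.0
    for v in sorted(candidates, reverse=True):
        ident = _ungapped_identity(codes[L - v :], codes[:v])
        if ident >= min_identity:
            best_v, best_id = v, ident
            break
    if best_v == 0:
        return contig, CircularCuration(contig.name, 0, 0, False, L)
    trimmed = Contig(contig.name, contig.seq[: L - best_v], circular=True)
    return trimmed, CircularCuration(contig.name, best_v, 0, False, L - best_v)


def circ_restart(
    contig: Contig, anchor: str, min_identity: float = 0.9
) -> tuple[Contig, CircularCuration]:
    """Rotate a circular contig so it starts at the anchor sequence.

    The anchor is located by semi-global alignment against the doubled
    sequence (so matches spanning the origin are found) on both strands; the
    contig is reverse-complemented when the anchor lies on the reverse strand
    and rotated so the anchor match starts at position 0.  Any rotation or
    strand presentation of the same circle therefore yields byte-identical
    output.  Fails when the best match identity is below ``min_identity``.
    """
    if len(anchor) < 20:
        raise ValueError("anchor must be at least 20 bp")
    L = len(contig)
    best = None  # (dist, flipped, start)
    for flipped, seq in ((False, contig.seq), (True, revcomp(contig.seq))):
        res = edlib.align(anchor, seq + seq, mode="HW", task="locations")
        if res["editDistance"] < 0:
            continue
        start = min(loc[0] % L for loc in res["locations"])
        cand = (res["editDistance"], flipped, start)
        if best is None or cand < best:
            best = cand
    if best is None or 1 - best[0] / len(anchor) < min_identity:
        got = "no alignment" if best is None else f"identity {1 - best[0]/len(anchor):.3f}"
        raise ValueError(f"anchor not found ({got} < {min_identity})")
    dist, flipped, off = best
    seq = revcomp(contig.seq) if flipped else contig.seq
    rotated = Contig(contig.name, seq[off:] + seq[:off], circular=True)
    return rotated, CircularCuration(
        contig.name,
        overlap_trimmed=0,
        rotation_offset=off,
        strand_flipped=flipped,
        final_length=L,
    )
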