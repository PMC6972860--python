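"""Per-base depth from alignments and coverage-drop misassembly breaking.

A chimeric contig joins regions that are not adjacent in the genome, so no
read spans the joint: read depth collapses to ~0 in a short window around it
while staying near the genome-wide average elsewhere.  ``detect_junctions``
finds maximal runs of sub-threshold depth whose flanking windows are well
covered, and ``break_contigs`` cuts the contigs there, removing the
unreliable low-coverage bases themselves.

All coordinates are 0-based half-open internally; SAM input is converted on
read, BED output stays 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .seqio import Contig

log = logging.getLogger(__name__)


@dataclass
class DepthTrack:
    contig: str
    depth: np.ndarray  # int32 per-base read depth

    @property
    def length(self) -> int:
        return self.depth.size


@dataclass(frozen=True)
class JunctionParams:
    """Thresholds of the junction caller (letters follow the CLI flags).

    a/b: flank windows (bp) left/right of a candidate low-coverage run;
    c: depth below which a base counts as part of a drop (fold);
    d: flank-to-threshold ratio (flank mean must be >= d*c) and the merge
    distance for nearby runs; e/f: exclusion zones at contig start/end (bp).
    """

    a: int = 200
    b: int = 200
    c: float = 5.0
    d: float = 2.0
    e: int = 30
    f: int = 30

    def __post_init__(self) -> None:
        if self.a < 1 or self.b < 1:
            raise ValueError("flank windows a, b must be >= 1")
        if self.c < 1 or self.d < 1:
            raise ValueError("thresholds c, d must be >= 1")
        if self.e < 0 or self.f < 0:
            raise ValueError("exclusion zones e, f must be >= 0")


@dataclass
class JunctionCall:
    contig: str
    start: int
    end: int
    left_mean: float
    right_mean: float
    min_depth: float


# ---------------------------------------------------------------------------
# depth computation
# ---------------------------------------------------------------------------

def _depth_diffs_from_sam(path: str | Path, diffs: dict[str, np.ndarray]) -> int:
    skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name not in diffs:
                raise ValueError(f"unknown alignment target {rec.reference_name!r}")
            cig = rec.cigartuples
            if not cig:
                skipped += 1
                continue
            d = diffs[rec.reference_name]
            pos = rec.reference_start
            for op, ln in cig:
                if op in (0, 7, 8):  # M, =, X cover the reference
                    d[pos] += 1
                    d[pos + ln] -= 1
                    pos += ln
                elif op in (2, 3):  # D, N consume reference but add no depth
                    pos += ln
                # I, S, H, P consume no reference
    return skipped


def _depth_diffs_from_paf(path: str | Path, diffs: dict[str, np.ndarray]) -> int:
    skipped = 0
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 12:
                skipped += 1
                continue
            tname, tstart, tend = cols[5], int(cols[7]), int(cols[8])
            if tname not in diffs:
                raise ValueError(f"unknown alignment target {tname!r}")
            d = diffs[tname]
            d[tstart] += 1
            d[tend] -= 1
    return skipped


def depth_from_alignments(
    path: str | Path, contigs: dict[str, int] | Sequence[Contig]
) -> dict[str, DepthTrack]:
    """Per-base depth per contig from a SAM/BAM or PAF file.

    SAM: primary, mapped, non-supplementary records contribute +1 at reference
    positions consumed by CIGAR M/=/X (deletions and skips excluded).  PAF
    (minimap2 dialect, 12 mandatory columns): +1 over [target_start,
    target_end).  Records with malformed CIGARs are skipped and counted.
    """
    if not isinstance(contigs, dict):
        contigs = {c.name: len(c) for c in contigs}
    diffs = {name: np.zeros(length + 1, dtype=np.int32) for name, length in contigs.items()}
    if str(path).endswith(".paf"):
        skipped = _depth_diffs_from_paf(path, diffs)
    else:
        skipped = _depth_diffs_from_sam(path, diffs)
    if skipped:
        log.warning("skipped %d malformed alignment records", skipped)
    return {
        name: DepthTrack(name, np.cumsum(d[:-1], dtype=np.int64).astype(np.int32))
        for name, d in diffs.items()
    }


def _lower_median(values: np.ndarray) -> float:
    """Median with the lower of the two middle values for even lengths."""
    if values.size == 0:
        raise ValueError("empty depth array")
    idx = (values.size - 1) // 2
    return float(np.partition(values, idx)[idx])


def median_contig_coverage(tracks: dict[str, DepthTrack] | Iterable[DepthTrack]) -> dict[str, float]:
    """Per-contig median of the per-base depth (lower median on even lengths)."""
    if isinstance(tracks, dict):
        tracks = tracks.values()
    tracks = list(tracks)
    if not tracks:
        raise ValueError("no depth tracks")
    return {t.contig: _lower_median(t.depth) for t in tracks}


# ---------------------------------------------------------------------------
# junction detection and breaking
# ---------------------------------------------------------------------------

def _runs_below(depth: np.ndarray, c: float) -> list[tuple[int, int]]:
    low = depth < c
    if not low.any():
        return []
    edges = np.flatnonzero(np.diff(low.astype(np.int8)))
    starts = list(edges[low[edges + 1]] + 1) if edges.size else []
    if low[0]:
        starts = [0] + starts
    ends = list(edges[~low[edges + 1]] + 1) if edges.size else []
    if low[-1]:
        ends = ends + [low.size]
    return list(zip(starts, ends))


def detect_junctions(track: DepthTrack, params: JunctionParams = JunctionParams()) -> list[JunctionCall]:
    """Call well-supported internal coverage drops on one contig.

    A call is a maximal run of positions with depth < ``c`` (runs separated by
    fewer than ``d`` bases are merged first) such that the run and both full
    flank windows (``a``/``b`` bases) lie inside the evaluable zone
    ``[e, length - f)`` and both flank means are >= ``d * c``.  Requiring the
    full flank windows keeps the read-shadow ramps at contig ends — where
    depth falls off simply because reads cannot extend past the end — from
    mimicking misassembly drops.  Contigs too short to evaluate return no
    calls.
    """
    p = params
    L = track.length
    if L <= p.a + p.b + p.e + p.f:
        return []
    depth = track.depth
    runs = _runs_below(depth, p.c)
    merged: list[tuple[int, int]] = []
    for s, t in runs:
        if merged and s - merged[-1][1] < p.d:
            merged[-1] = (merged[-1][0], t)
        else:
            merged.append((s, t))
    calls: list[JunctionCall] = []
    for s, t in merged:
        if s - p.a < p.e or t + p.b > L - p.f:
            continue
        left = float(depth[s - p.a : s].mean())
        right = float(depth[t : t + p.b].mean())
        if min(left, right) < p.d * p.c:
            continue
        calls.append(
            JunctionCall(
                contig=track.contig,
                start=int(s),
                end=int(t),
                left_mean=left,
                right_mean=right,
                min_depth=float(depth[s:t].min()),
            )
        )
    return calls


@dataclass
class BreakResult:
    contigs: list[Contig]
    removed: list[tuple[str, int, int]]  # BED-style intervals cut out
    dropped: list[tuple[str, int]]       # (piece name, length) below min_piece
    #: kept piece -> source interval: (piece, source contig, src_start, src_end)
    piece_map: list[tuple[str, str, int, int]] = None

    @property
    def removed_bases(self) -> int:
        return sum(e - s for _, s, e in self.removed)

    @property
    def dropped_bases(self) -> int:
        return sum(ln for _, ln in self.dropped)


def break_contigs(
    contigs: Sequence[Contig],
    calls: Sequence[JunctionCall],
    min_piece: int = 1000,
) -> BreakResult:
    """Cut contigs at junction calls, removing the low-coverage run bases.

    Pieces are named ``<contig>.1``, ``.2``, ... left to right (numbering
    before filtering); pieces shorter than ``min_piece`` are dropped and
    logged.  Contigs without calls pass through byte-identical.  Overlapping
    calls on one contig are merged before cutting.
    """
    by_contig: dict[str, list[JunctionCall]] = {}
    names = {c.name for c in contigs}
    for call in calls:
        if call.contig not in names:
            raise ValueError(f"junction call references unknown contig {call.contig!r}")
        by_contig.setdefault(call.contig, []).append(call)

    out: list[Contig] = []
    removed: list[tuple[str, int, int]] = []
    dropped: list[tuple[str, int]] = []
    piece_map: list[tuple[str, str, int, int]] = []
    for contig in contigs:
        mine = by_contig.get(contig.name)
        if not mine:
            out.append(contig)
            piece_map.append((contig.name, contig.name, 0, len(contig)))
            continue
        ivals = sorted((c.start, c.end) for c in mine)
        cuts: list[tuple[int, int]] = []
        for s, t in ivals:
            if cuts and s <= cuts[-1][1]:
                cuts[-1] = (cuts[-1][0], max(cuts[-1][1], t))
            else:
                cuts.append((s, t))
        removed.extend((contig.name, s, t) for s, t in cuts)
        prev = 0
        piece_no = 0
        for s, t in cuts + [(len(contig), len(contig))]:
            if s > prev:
                piece_no += 1
                name = f"{contig.name}.{piece_no}"
                if s - prev < min_piece:
                    dropped.append((name, s - prev))
                    log.info("dropping short piece %s (%d bp)", name, s - prev)
                else:
                    out.append(Contig(name, contig.seq[prev:s]))
                    piece_map.append((name, contig.name, prev, s))
            prev = t
    return BreakResult(out, removed, dropped, piece_map)
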