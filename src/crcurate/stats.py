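"""Assembly summary statistics and fragment-based average nucleotide identity.

ANI here follows the classic fragment-mapping recipe: the query assembly is
cut into non-overlapping fragments, each fragment is placed in the reference
by shared-k-mer seeding and scored by banded edit-distance alignment, and the
ANI is the mean identity over fragments whose best identity reaches the
orthology cutoff (80% by default; ~95% ANI conventionally delimits species).
The estimate is direction-specific; compute both directions for a symmetric
picture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import edlib
import numpy as np

from ._encode import encode, revcomp
from .seqio import Contig

_SEED_K = 15
_SEED_STRIDE = 5
_PAD = 64


@dataclass
class AssemblyStats:
    n_contigs: int
    total_bp: int
    n50: int
    gc_percent: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def assembly_stats(contigs: Sequence[Contig]) -> AssemblyStats:
    """Contig count, total size, N50 and GC% (over unambiguous bases only)."""
    if not contigs:
        raise ValueError("empty assembly")
    lengths = sorted((len(c) for c in contigs), reverse=True)
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for ln in lengths:
        acc += ln
        if 2 * acc >= total:
            n50 = ln
            break
    gc = at = 0
    for c in contigs:
        codes = encode(c.seq)
        gc += int(((codes == 1) | (codes == 2)).sum())
        at += int(((codes == 0) | (codes == 3)).sum())
    gc_percent = 100.0 * gc / (gc + at) if gc + at else float("nan")
    return AssemblyStats(len(contigs), total, n50, gc_percent)


@dataclass
class ANIResult:
    query: str
    reference: str
    ani_percent: float
    n_fragments_used: int
    n_fragments_total: int


class _ReferenceIndex:
    """Sorted 15-mer (strided) index over the concatenated reference."""

    def __init__(self, contigs: Sequence[Contig]):
        parts = []
        bounds = [0]
        for c in contigs:
            parts.append(encode(c.seq))
            parts.append(np.full(1, 255, np.uint8))  # separator invalidates k-mers
            bounds.append(bounds[-1] + len(c) + 1)
        self.concat = np.concatenate(parts)
        self.bounds = np.array(bounds[:-1] + [self.concat.size], dtype=np.int64)
        n = self.concat.size - _SEED_K + 1
        fwd = np.zeros(n, dtype=np.uint64)
        valid = np.ones(n, dtype=bool)
        for i in range(_SEED_K):
            c = self.concat[i : i + n]
            valid &= c < 4
            fwd = fwd * 4 + c.astype(np.uint64)
        pos = np.arange(0, n, _SEED_STRIDE)
        pos = pos[valid[pos]]
        codes = fwd[pos]
        order = np.argsort(codes, kind="stable")
        self.codes = codes[order]
        self.pos = pos[order]

    def window(self, anchor: int, lo: int, hi: int) -> str:
        """Reference substring clipped to the contig containing ``anchor``."""
        anchor = min(max(anchor, 0), self.concat.size - 1)
        ci = int(np.searchsorted(self.bounds, anchor, side="right")) - 1
        lo = max(lo, int(self.bounds[ci]))
        hi = min(hi, int(self.bounds[ci + 1]) - 1)  # exclude separator
        if hi <= lo:
            return ""
        from ._encode import decode

        return decode(self.concat[lo:hi])


def _best_diagonal(index: _ReferenceIndex, frag_codes: np.ndarray) -> int | None:
    n = frag_codes.size - _SEED_K + 1
    if n <= 0:
        return None
    fwd = np.zeros(n, dtype=np.uint64)
    for i in range(_SEED_K):
        fwd = fwd * 4 + frag_codes[i : i + n].astype(np.uint64)
    lo = np.searchsorted(index.codes, fwd, side="left")
    hi = np.searchsorted(index.codes, fwd, side="right")
    diags = []
    for q in range(n):
        span = min(int(hi[q] - lo[q]), 8)  # cap hits per repetitive seed
        for t in range(span):
            diags.append(int(index.pos[lo[q] + t]) - q)
    if not diags:
        return None
    diags_arr = np.array(diags)
    bins = diags_arr // 200
    ub, counts = np.unique(bins, return_counts=True)
    best_bin = ub[int(np.argmax(counts))]
    members = diags_arr[bins == best_bin]
    return int(np.median(members))


def ani(
    query: Sequence[Contig],
    reference: Sequence[Contig],
    fragment: int = 1000,
    min_identity_orth: float = 80.0,
    query_name: str = "query",
    reference_name: str = "reference",
) -> ANIResult:
    """Average nucleotide identity of ``query`` against ``reference``.

    The query is cut into non-overlapping full-length fragments; each is
    seeded to its best diagonal in the reference (both strands) and scored by
    infix edit-distance alignment against the implied window; identity is
    ``100 * (1 - edits / fragment_length)``.  Fragments reaching
    ``min_identity_orth`` are averaged into the ANI.
    """
    if not query or not reference:
        raise ValueError("empty assembly")
    index = _ReferenceIndex(reference)
    identities: list[float] = []
    n_total = 0
    for contig in query:
        for s in range(0, len(contig) - fragment + 1, fragment):
            frag = contig.seq[s : s + fragment]
            n_total += 1
            best_ident: float | None = None
            for strand_seq in (frag, revcomp(frag)):
                codes = encode(strand_seq)
                diag = _best_diagonal(index, codes)
                if diag is None:
                    continue
                window = index.window(diag, diag - _PAD, diag + fragment + _PAD)
                if not window:
                    continue
                res = edlib.align(strand_seq, window, mode="HW", task="distance")
                if res["editDistance"] < 0:
                    continue
                ident = 100.0 * (1.0 - res["editDistance"] / fragment)
                if best_ident is None or ident > best_ident:
                    best_ident = ident
            if best_ident is not None and best_ident >= min_identity_orth:
                identities.append(best_ident)
    if not identities:
        raise ValueError("assemblies too divergent: no orthologous fragments")
    return ANIResult(
        query=query_name,
        reference=reference_name,
        ani_percent=float(np.mean(identities)),
        n_fragments_used=len(identities),
        n_fragments_total=n_total,
    )
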