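"""Fragment-wise taxonomic decontamination of draft assemblies.

Contigs are split into 500 bp fragments which an external protein-level
classifier (Kaiju-style output: status C/U, fragment id, taxon id) assigns to
taxa.  Each fragment's taxon is resolved to its superkingdom by walking the
taxonomy tree, and a contig is dropped when strictly more than half of its
classified fragments are bacterial.  Three corroborating composition signals
— canonical tetranucleotide frequencies, GC content and median read coverage
— are reported per contig but never drive the verdict: in practice taxonomy,
composition and coverage agree, and the taxonomy rule is the one that is
crisp enough to apply automatically.  Viral assignments never count toward
exclusion (genuine genomes can carry endogenous viral elements).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._encode import canonical_kmer_codes, encode
from .seqio import Contig
from .taxonomy import TaxonomyTree, resolve_superkingdom

WINDOW_DEFAULT = 500


@dataclass(frozen=True)
class FragmentRecord:
    fragment_id: str
    contig: str
    start: int
    end: int
    sequence: str


def fragment_contigs(contigs: Sequence[Contig], window: int = WINDOW_DEFAULT) -> list[FragmentRecord]:
    """Consecutive non-overlapping windows per contig.

    The final remainder is kept as a short fragment when it is at least half a
    window (enough sequence to classify) and silently dropped otherwise.
    Fragment ids are ``<contig>:<start0>-<end0>`` and deterministic.
    """
    if window < 100:
        raise ValueError("window must be >= 100")
    frags: list[FragmentRecord] = []
    tail_min = window // 2
    for contig in contigs:
        L = len(contig)
        pos = 0
        while pos + window <= L:
            frags.append(
                FragmentRecord(f"{contig.name}:{pos}-{pos + window}", contig.name, pos, pos + window, contig.seq[pos : pos + window])
            )
            pos += window
        if L - pos >= tail_min:
            frags.append(FragmentRecord(f"{contig.name}:{pos}-{L}", contig.name, pos, L, contig.seq[pos:]))
    return frags


# ---------------------------------------------------------------------------
# tetranucleotide composition
# ---------------------------------------------------------------------------

def _canonical_4mer_classes() -> tuple[np.ndarray, int]:
    codes = np.arange(256, dtype=np.uint64)
    rc = np.zeros(256, dtype=np.uint64)
    tmp = codes.copy()
    for _ in range(4):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    canon = np.minimum(codes, rc)
    classes, inverse = np.unique(canon, return_inverse=True)
    return inverse.astype(np.int64), classes.size


_CLASS_OF_4MER, N_TETRA_CLASSES = _canonical_4mer_classes()  # 136 classes


def tetranucleotide_profile(sequence: str) -> np.ndarray:
    """Canonical 4-mer frequency vector (136 components, summing to 1).

    4-mers are pooled with their reverse complements, making the profile
    strand-independent; windows containing non-ACGT characters are skipped.
    """
    if len(sequence) < 4:
        raise ValueError("sequence shorter than 4")
    kmers = canonical_kmer_codes(encode(sequence), 4)
    if kmers.size == 0:
        raise ValueError("no valid 4-mer window in sequence")
    counts = np.bincount(_CLASS_OF_4MER[kmers.astype(np.int64)], minlength=N_TETRA_CLASSES)
    return counts / counts.sum()


def tetra_distance_scores(contigs: Sequence[Contig]) -> dict[str, float]:
    """Robust standard score of each contig's tetranucleotide divergence.

    Distance is the Euclidean distance between a contig's canonical 4-mer
    profile and the length-weighted mean profile of the whole assembly
    (dominated by the genuine host sequence); scores are centred on the
    median distance and scaled by 1.4826*MAD so that a minority of
    compositionally alien contigs cannot inflate the scale they are judged
    against.
    """
    profiles = {c.name: tetranucleotide_profile(c.seq) for c in contigs}
    lengths = np.array([len(c) for c in contigs], dtype=float)
    mat = np.vstack([profiles[c.name] for c in contigs])
    centroid = (mat * lengths[:, None]).sum(axis=0) / lengths.sum()
    dist = np.linalg.norm(mat - centroid, axis=1)
    med = float(np.median(dist))
    mad = float(np.median(np.abs(dist - med)))
    scale = 1.4826 * mad if mad > 0 else (dist.std() or 1.0)
    return {c.name: float((dist[i] - med) / scale) for i, c in enumerate(contigs)}


def gc_fraction(sequence: str) -> float:
    """GC over A/C/G/T bases only (ambiguity codes excluded from both sides)."""
    codes = encode(sequence)
    valid = codes < 4
    n = int(valid.sum())
    if n == 0:
        return float("nan")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return gc / n


# ---------------------------------------------------------------------------
# screening
# ---------------------------------------------------------------------------

@dataclass
class ContigScreen:
    contig: str
    n_fragments: int
    n_classified: int
    n_bacterial: int
    frac_bacterial: float
    gc: float
    median_coverage: float
    tetra_distance_z: float
    verdict: str  # "keep" | "drop"
    reason: str


def _iter_classification_rows(classifications) -> Iterable[tuple[str, str, int]]:
    if isinstance(classifications, (str, Path)):
        with open(classifications) as fh:
            for line in fh:
                cols = line.rstrip("\n").split("\t")
                if len(cols) < 2:
                    continue
                status, fid = cols[0], cols[1]
                taxid = int(cols[2]) if len(cols) > 2 and cols[2] else 0
                yield status, fid, taxid
    else:
        for status, fid, taxid in classifications:
            yield status, fid, int(taxid)


def screen_contigs(
    contigs: Sequence[Contig],
    classifications,
    tree: TaxonomyTree,
    coverage: dict[str, float] | None = None,
    window: int = WINDOW_DEFAULT,
) -> list[ContigScreen]:
    """Per-contig contamination screen combining all four criteria.

    ``classifications`` is a Kaiju-style TSV path or an iterable of
    ``(status, fragment_id, taxid)`` rows whose fragment ids follow the
    :func:`fragment_contigs` convention.  The verdict is ``drop`` iff strictly
    more than 50% of the contig's classified fragments resolve to Bacteria;
    a fragment counts as classified only when its taxon resolves to a real
    superkingdom.  GC, median coverage and the tetranucleotide divergence
    score are carried along for the report.
    """
    names = {c.name for c in contigs}
    frags = fragment_contigs(contigs, window=window)
    frag_count: dict[str, int] = {}
    for fr in frags:
        frag_count[fr.contig] = frag_count.get(fr.contig, 0) + 1

    n_classified: dict[str, int] = {c.name: 0 for c in contigs}
    n_bacterial: dict[str, int] = {c.name: 0 for c in contigs}
    for status, fid, taxid in _iter_classification_rows(classifications):
        contig = fid.rsplit(":", 1)[0]
        if contig not in names:
            raise ValueError(f"classified fragment {fid!r} references unknown contig")
        if status != "C":
            continue
        label = resolve_superkingdom(taxid, tree)
        if label == "unclassified":
            continue
        n_classified[contig] += 1
        if label == "Bacteria":
            n_bacterial[contig] += 1

    tetra_z = tetra_distance_scores(contigs)
    screens: list[ContigScreen] = []
    for c in contigs:
        ncl = n_classified[c.name]
        nb = n_bacterial[c.name]
        frac = nb / ncl if ncl else 0.0
        drop = frac > 0.5
        if ncl == 0:
            reason = "no classified fragments"
        elif drop:
            reason = f"{nb}/{ncl} classified fragments bacterial"
        else:
            reason = "majority non-bacterial"
        screens.append(
            ContigScreen(
                contig=c.name,
                n_fragments=frag_count.get(c.name, 0),
                n_classified=ncl,
                n_bacterial=nb,
                frac_bacterial=frac,
                gc=gc_fraction(c.seq),
                median_coverage=float(coverage.get(c.name, float("nan"))) if coverage else float("nan"),
                tetra_distance_z=tetra_z[c.name],
                verdict="drop" if drop else "keep",
                reason=reason,
            )
        )
    return screens


def screens_to_frame(screens: Sequence[ContigScreen]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in screens])


def apply_decontamination(
    contigs: Sequence[Contig], screens: Sequence[ContigScreen]
) -> tuple[list[Contig], list[Contig], pd.DataFrame]:
    """Partition contigs into kept/dropped according to the screen verdicts."""
    verdict = {s.contig: s.verdict for s in screens}
    missing = [c.name for c in contigs if c.name not in verdict]
    if missing:
        raise ValueError(f"screens do not cover contigs: {missing[:5]}")
    kept = [c for c in contigs if verdict[c.name] == "keep"]
    dropped = [c for c in contigs if verdict[c.name] == "drop"]
    return kept, dropped, screens_to_frame(screens)
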