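"""NCBI-style taxonomy tree and superkingdom resolution.

Decontamination only needs one thing from the taxonomy: to map a classifier's
taxon id to its superkingdom (Bacteria, Archaea, Eukaryota, Viruses) by
walking parent links.  The tree can be loaded from NCBI taxdump ``nodes.dmp``
/ ``names.dmp`` files (pipe-delimited) or from a simplified 4-column TSV
(taxid, parent, rank, name).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

SUPERKINGDOMS = ("Bacteria", "Archaea", "Eukaryota", "Viruses")
UNCLASSIFIED = "unclassified"

# Real NCBI taxids used by the synthetic classifier as superkingdom representatives.
BACTERIA_TAXID = 2
ARCHAEA_TAXID = 2157
EUKARYOTA_TAXID = 2759
VIRUSES_TAXID = 10239
REPRESENTATIVE = {
    "Bacteria": 562,     # Escherichia coli
    "Archaea": 2287,     # Sulfolobus acidocaldarius
    "Eukaryota": 9606,   # Homo sapiens (any species-level eukaryote works)
    "Viruses": 10239,
}


@dataclass
class TaxonomyTree:
    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str]
    root: int = 1
    _cache: dict[int, str] = field(default_factory=dict, repr=False)

    @classmethod
    def from_ncbi_dumps(cls, nodes_path: str | Path, names_path: str | Path) -> "TaxonomyTree":
        parent: dict[int, int] = {}
        rank: dict[int, str] = {}
        name: dict[int, str] = {}
        with open(nodes_path) as fh:
            for line in fh:
                cols = [c.strip() for c in line.split("|")]
                taxid, par, rk = int(cols[0]), int(cols[1]), cols[2]
                parent[taxid] = par
                rank[taxid] = rk
        with open(names_path) as fh:
            for line in fh:
                cols = [c.strip() for c in line.split("|")]
                if len(cols) > 3 and cols[3] == "scientific name":
                    name[int(cols[0])] = cols[1]
        return cls(parent=parent, rank=rank, name=name)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyTree":
        parent: dict[int, int] = {}
        rank: dict[int, str] = {}
        name: dict[int, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                taxid_s, par_s, rk, nm = line.split("\t")[:4]
                taxid = int(taxid_s)
                parent[taxid] = int(par_s)
                rank[taxid] = rk
                name[taxid] = nm
        return cls(parent=parent, rank=rank, name=name)

    def write_ncbi_dumps(self, nodes_path: str | Path, names_path: str | Path) -> None:
        with open(nodes_path, "w") as fh:
            for taxid in sorted(self.parent):
                fh.write(f"{taxid}\t|\t{self.parent[taxid]}\t|\t{self.rank.get(taxid, 'no rank')}\t|\n")
        with open(names_path, "w") as fh:
            for taxid in sorted(self.parent):
                fh.write(f"{taxid}\t|\t{self.name.get(taxid, str(taxid))}\t|\t\t|\tscientific name\t|\n")


def resolve_superkingdom(taxid: int, tree: TaxonomyTree) -> str:
    """Superkingdom name of the first superkingdom-ranked ancestor (inclusive).

    Unknown taxids, or lineages that never pass through a superkingdom node
    (e.g. a hit resolved only to "cellular organisms" or the root), return
    ``"unclassified"``.  A cyclic parent chain other than the root self-loop
    raises ``ValueError``.
    """
    cached = tree._cache.get(taxid)
    if cached is not None:
        return cached
    label = UNCLASSIFIED
    node = taxid
    seen: set[int] = set()
    while node in tree.parent:
        if node in seen:
            raise ValueError(f"cyclic parent links at taxid {node}")
        seen.add(node)
        if tree.rank.get(node) == "superkingdom":
            label = tree.name.get(node, UNCLASSIFIED)
            break
        par = tree.parent[node]
        if par == node:  # root self-loop
            break
        node = par
    tree._cache[taxid] = label
    return label


def toy_taxonomy() -> TaxonomyTree:
    """A miniature NCBI-shaped tree with one representative lineage per superkingdom."""
    rows = [
        # taxid, parent, rank, name
        (1, 1, "no rank", "root"),
        (131567, 1, "no rank", "cellular organisms"),
        (BACTERIA_TAXID, 131567, "superkingdom", "Bacteria"),
        (ARCHAEA_TAXID, 131567, "superkingdom", "Archaea"),
        (EUKARYOTA_TAXID, 131567, "superkingdom", "Eukaryota"),
        (VIRUSES_TAXID, 1, "superkingdom", "Viruses"),
        (543, BACTERIA_TAXID, "family", "Enterobacteriaceae"),
        (561, 543, "genus", "Escherichia"),
        (562, 561, "species", "Escherichia coli"),
        (2287, ARCHAEA_TAXID, "species", "Sulfolobus acidocaldarius"),
        (9605, EUKARYOTA_TAXID, "genus", "Homo"),
        (9606, 9605, "species", "Homo sapiens"),
    ]
    return TaxonomyTree(
        parent={t: p for t, p, _, _ in rows},
        rank={t: r for t, _, r, _ in rows},
        name={t: n for t, _, _, n in rows},
    )
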