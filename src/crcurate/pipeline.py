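"""End-to-end curation pipeline: depth -> junction breaking -> decontamination
-> mitochondrial curation -> summary statistics.

Each stage reads the previous stage's FASTA and persists its own outputs, so
every number in the consolidated report can be recomputed from the files on
disk; the report is a view, never the source of truth.  Stages are
individually toggleable and the pipeline never invokes external binaries —
alignments and classifier tables are inputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import __version__
from .decontam import apply_decontamination, screen_contigs
from .junctions import (
    JunctionParams,
    break_contigs,
    depth_from_alignments,
    detect_junctions,
    median_contig_coverage,
)
from .kmers import count_canonical_kmers, estimate_genome_size
from .mito import circ_restart, circ_trim, identify_mito_contig
from .rdna import OperonAnnotation, operon_copy_number
from .seqio import read_fasta, write_fasta
from .stats import assembly_stats
from .taxonomy import TaxonomyTree

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    assembly: str
    outdir: str
    reads: str | None = None            # FASTA/FASTQ for k-mer genome size
    alignments: str | None = None       # SAM/BAM/PAF of reads vs assembly
    classifier_tsv: str | None = None   # Kaiju-style fragment classifications
    taxonomy_nodes: str | None = None   # nodes.dmp (with taxonomy_names) or 4-col TSV
    taxonomy_names: str | None = None
    mito_reference: str | None = None   # FASTA with the reference mitogenome
    mito_anchor: str | None = None      # FASTA with the restart anchor
    rdna_annotation: str | None = None  # BED/GFF3 with the operon interval

    run_gsize: bool = False
    run_junctions: bool = True
    run_decontam: bool = True
    run_mito: bool = True
    run_rdna: bool = False
    run_stats: bool = True

    k: int = 19
    junction_params: JunctionParams = field(default_factory=JunctionParams)
    min_piece: int = 1000
    fragment_window: int = 500
    seed: int = 42

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        jp = data.pop("junction_params", None)
        data.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**data)
        if jp:
            cfg.junction_params = JunctionParams(**jp)
        return cfg


@dataclass
class CurationReport:
    version: str = __version__
    parameters: dict = field(default_factory=dict)
    genome_size: dict | None = None
    junctions: dict | None = None
    decontamination: dict | None = None
    mito: dict | None = None
    rdna: dict | None = None
    stats: dict | None = None
    started: str = ""
    finished: str = ""

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True) + "\n")

    def to_text(self) -> str:
        lines = [f"crcurate {self.version} curation report"]
        for label in ("genome_size", "junctions", "decontamination", "mito", "rdna", "stats"):
            section = getattr(self, label)
            lines.append(f"[{label}]")
            if section is None:
                lines.append("  (disabled)")
            else:
                for k, v in section.items():
                    lines.append(f"  {k}: {v}")
        return "\n".join(lines) + "\n"


def _remap_classifier_rows(path: str | Path, piece_map) -> list[tuple[str, str, int]]:
    """Re-address classifier fragments onto post-break contig pieces.

    The classifier ran on the pre-break assembly; each fragment is attributed
    to the kept piece containing its midpoint (fragments whose midpoint falls
    in a removed or dropped interval are discarded with the sequence).
    """
    by_src: dict[str, list[tuple[int, int, str]]] = {}
    for piece, src, s, e in piece_map:
        by_src.setdefault(src, []).append((s, e, piece))
    rows: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                continue
            status, fid = cols[0], cols[1]
            taxid = int(cols[2]) if len(cols) > 2 and cols[2] else 0
            contig, span = fid.rsplit(":", 1)
            fs, fe = (int(x) for x in span.split("-"))
            mid = (fs + fe) // 2
            for s, e, piece in by_src.get(contig, ()):
                if s <= mid < e:
                    rows.append((status, f"{piece}:{max(fs - s, 0)}-{min(fe, e) - s}", taxid))
                    break
    return rows


def _load_taxonomy(config: PipelineConfig) -> TaxonomyTree:
    if config.taxonomy_names:
        return TaxonomyTree.from_ncbi_dumps(config.taxonomy_nodes, config.taxonomy_names)
    return TaxonomyTree.from_tsv(config.taxonomy_nodes)


def run_pipeline(config: PipelineConfig) -> CurationReport:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = CurationReport(
        parameters={
            k: (asdict(v) if isinstance(v, JunctionParams) else v)
            for k, v in asdict(config).items()
        },
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    contigs = read_fasta(config.assembly)

    if config.run_gsize:
        if not config.reads:
            raise ValueError("genome-size stage enabled but no reads given")
        hist = count_canonical_kmers(config.reads, k=config.k)
        hist.to_text(outdir / "kmer_histogram.txt")
        est = estimate_genome_size(hist)
        report.genome_size = est.to_dict()

    coverage = None
    if config.run_junctions or config.run_decontam or config.run_rdna:
        if config.alignments:
            tracks = depth_from_alignments(config.alignments, contigs)
            coverage = median_contig_coverage(tracks)
        elif config.run_junctions:
            raise ValueError("junction stage enabled but no alignments given")
        elif config.run_rdna:
            raise ValueError("rDNA stage enabled but no alignments given")

    if config.run_rdna:
        # copy number is measured on the input assembly coordinates, before
        # any contig renaming by the junction stage
        if not config.rdna_annotation:
            raise ValueError("rDNA stage enabled but no operon annotation given")
        ann_path = str(config.rdna_annotation)
        annotation = (
            OperonAnnotation.from_gff3(ann_path)
            if ann_path.endswith((".gff", ".gff3"))
            else OperonAnnotation.from_bed(ann_path)
        )
        est = operon_copy_number(tracks, annotation)
        report.rdna = {
            "operon_median_depth": est.operon_median_depth,
            "backbone_median_depth": est.backbone_median_depth,
            "haploid_copies": est.haploid_copies,
            "rounded_copies": est.rounded_copies,
            "n_backbone_contigs": est.n_backbone_contigs,
        }

    piece_map = None
    if config.run_junctions:
        calls = []
        for track in tracks.values():
            calls.extend(detect_junctions(track, config.junction_params))
        result = break_contigs(contigs, calls, min_piece=config.min_piece)
        piece_map = result.piece_map
        with open(outdir / "removed_junctions.bed", "w") as fh:
            for name, s, e in result.removed:
                fh.write(f"{name}\t{s}\t{e}\n")
        contigs = result.contigs
        write_fasta(contigs, outdir / "01_broken.fasta")
        report.junctions = {
            "n_calls": len(calls),
            "n_removed_intervals": len(result.removed),
            "n_dropped_pieces": len(result.dropped),
            "n_contigs_out": len(contigs),
        }
        # depth tracks refer to pre-break contig names; per-contig medians for
        # the decontamination report are carried over from the source contig
        if coverage is not None:
            coverage = {
                c.name: coverage.get(c.name, coverage.get(c.name.rsplit(".", 1)[0], float("nan")))
                for c in contigs
            }

    if config.run_decontam:
        if not (config.classifier_tsv and config.taxonomy_nodes):
            raise ValueError("decontamination enabled but classifier/taxonomy inputs missing")
        tree = _load_taxonomy(config)
        classifications = (
            _remap_classifier_rows(config.classifier_tsv, piece_map)
            if piece_map is not None
            else config.classifier_tsv
        )
        screens = screen_contigs(
            contigs, classifications, tree, coverage, window=config.fragment_window
        )
        kept, dropped, frame = apply_decontamination(contigs, screens)
        frame.to_csv(outdir / "screen_report.tsv", sep="\t", index=False)
        write_fasta(kept, outdir / "02_decontaminated.fasta")
        if dropped:
            write_fasta(dropped, outdir / "02_dropped.fasta")
        report.decontamination = {
            "n_in": len(contigs),
            "n_kept": len(kept),
            "n_dropped": len(dropped),
            "dropped": [c.name for c in dropped],
        }
        contigs = kept

    if config.run_mito:
        if not config.mito_reference:
            raise ValueError("mito stage enabled but no reference given")
        reference = read_fasta(config.mito_reference)[0]
        name, containment = identify_mito_contig(contigs, reference)
        mito = next(c for c in contigs if c.name == name)
        trimmed, trim_rec = circ_trim(mito)
        restart_rec = None
        if config.mito_anchor:
            anchor = read_fasta(config.mito_anchor)[0]
            trimmed, restart_rec = circ_restart(trimmed, anchor.seq)
        contigs = [c for c in contigs if c.name != name] + [trimmed.rename(f"{name}_mito")]
        write_fasta([trimmed], outdir / "03_mito.fasta")
        report.mito = {
            "contig": name,
            "containment": containment,
            "trim": trim_rec.to_dict(),
            "restart": restart_rec.to_dict() if restart_rec else None,
        }

    if config.run_stats:
        st = assembly_stats(contigs)
        report.stats = st.to_dict()

    write_fasta(contigs, outdir / "final.fasta")
    report.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    report.to_json(outdir / "report.json")
    (outdir / "report.txt").write_text(report.to_text())
    return report
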