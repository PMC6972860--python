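"""Fragmentation, taxonomy resolution, screening rule and decontamination."""

import numpy as np
import pytest

import crcurate as cc
from crcurate._encode import revcomp
from crcurate.decontam import fragment_contigs, gc_fraction, tetra_distance_scores
from crcurate.scenarios import decontam_scenario
from crcurate.seqio import Contig
from crcurate.taxonomy import TaxonomyTree, resolve_superkingdom, toy_taxonomy


# ---------------------------------------------------------------------------
# fragmentation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "length,expected",
    [
        (1250, [(0, 500), (500, 1000), (1000, 1250)]),  # 250 bp tail kept
        (1100, [(0, 500), (500, 1000)]),                # 100 bp tail dropped
        (499, [(0, 499)]),                              # whole contig >= window/2
        (249, []),                                      # below half-window
    ],
)
def test_fragmentation_tail_rule(length, expected, random_contigs):
    contigs = random_contigs([length])
    frags = fragment_contigs(contigs)
    assert [(f.start, f.end) for f in frags] == expected
    for f in frags:
        assert f.fragment_id == f"c00:{f.start}-{f.end}"
        assert f.sequence == contigs[0].seq[f.start : f.end]


def test_fragment_window_validation(random_contigs):
    with pytest.raises(ValueError):
        fragment_contigs(random_contigs([1000]), window=50)


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def test_superkingdom_resolution_toy_tree():
    tree = toy_taxonomy()
    assert resolve_superkingdom(562, tree) == "Bacteria"   # E. coli -> ... -> Bacteria
    assert resolve_superkingdom(2, tree) == "Bacteria"     # inclusive
    assert resolve_superkingdom(9606, tree) == "Eukaryota"
    assert resolve_superkingdom(99999, tree) == "unclassified"  # unknown taxid
    assert resolve_superkingdom(1, tree) == "unclassified"      # root
    assert resolve_superkingdom(131567, tree) == "unclassified"  # above superkingdom


def test_cyclic_taxonomy_raises():
    tree = TaxonomyTree(parent={5: 6, 6: 5}, rank={}, name={}, root=1)
    with pytest.raises(ValueError, match="cyclic"):
        resolve_superkingdom(5, tree)


def test_ncbi_dump_round_trip(tmp_path):
    tree = toy_taxonomy()
    nodes, names = tmp_path / "nodes.dmp", tmp_path / "names.dmp"
    tree.write_ncbi_dumps(nodes, names)
    back = TaxonomyTree.from_ncbi_dumps(nodes, names)
    assert back.parent == tree.parent
    assert back.rank == tree.rank
    assert back.name == tree.name
    assert resolve_superkingdom(562, back) == "Bacteria"


# ---------------------------------------------------------------------------
# screening rule
# ---------------------------------------------------------------------------

def _rows(contig, n_bact, n_euk, n_unclassified=0):
    rows = []
    i = 0
    for taxid, count in ((562, n_bact), (9606, n_euk)):
        for _ in range(count):
            rows.append(("C", f"{contig}:{i * 500}-{i * 500 + 500}", taxid))
            i += 1
    for _ in range(n_unclassified):
        rows.append(("U", f"{contig}:{i * 500}-{i * 500 + 500}", 0))
        i += 1
    return rows


def test_majority_bacterial_dropped(random_contigs):
    contigs = random_contigs([5000])
    screens = cc.screen_contigs(contigs, _rows("c00", 6, 4), toy_taxonomy())
    assert screens[0].frac_bacterial == pytest.approx(0.6)
    assert screens[0].verdict == "drop"


def test_half_bacterial_kept_strict_boundary(random_contigs):
    contigs = random_contigs([5000])
    screens = cc.screen_contigs(contigs, _rows("c00", 5, 5), toy_taxonomy())
    assert screens[0].frac_bacterial == pytest.approx(0.5)
    assert screens[0].verdict == "keep"


def test_unclassified_contig_kept_with_reason(random_contigs):
    contigs = random_contigs([5000])
    screens = cc.screen_contigs(contigs, [], toy_taxonomy())
    assert screens[0].verdict == "keep"
    assert "no classified" in screens[0].reason


def test_viral_fragments_never_count_toward_exclusion(random_contigs):
    contigs = random_contigs([5000])
    rows = [("C", f"c00:{i * 500}-{i * 500 + 500}", 10239) for i in range(10)]
    screens = cc.screen_contigs(contigs, rows, toy_taxonomy())
    assert screens[0].n_bacterial == 0
    assert screens[0].verdict == "keep"


def test_unknown_contig_in_classification_raises(random_contigs):
    with pytest.raises(ValueError, match="unknown contig"):
        cc.screen_contigs(random_contigs([5000]), [("C", "ghost:0-500", 562)], toy_taxonomy())


def test_monotonicity_more_bacterial_never_flips_to_keep(random_contigs):
    contigs = random_contigs([20_000])
    dropped_seen = False
    for n_bact in range(0, 21):
        screens = cc.screen_contigs(contigs, _rows("c00", n_bact, 20 - n_bact), toy_taxonomy())
        if dropped_seen:
            assert screens[0].verdict == "drop"
        dropped_seen = screens[0].verdict == "drop"
    assert dropped_seen  # 20/20 bacterial is certainly dropped


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def test_tetra_profile_strand_symmetric(random_contigs):
    seq = random_contigs([3000], gc=0.6)[0].seq
    p1 = cc.tetranucleotide_profile(seq)
    p2 = cc.tetranucleotide_profile(revcomp(seq))
    assert np.allclose(p1, p2)
    assert p1.size == 136
    assert abs(p1.sum() - 1.0) < 1e-9


def test_tetra_profile_validation():
    with pytest.raises(ValueError):
        cc.tetranucleotide_profile("ACG")
    with pytest.raises(ValueError):
        cc.tetranucleotide_profile("NNNNNNNN")


def test_gc_fraction_strand_symmetric(random_contigs):
    seq = random_contigs([2000], gc=0.7)[0].seq
    assert gc_fraction(seq) == pytest.approx(gc_fraction(revcomp(seq)))


def test_contaminant_tetra_scores_separate(small_genome):
    """GC 0.45 contaminants score tetra z > 3 against the GC 0.70 host profile."""
    contigs = small_genome.haplotype_a + small_genome.contaminants
    scores = tetra_distance_scores(contigs)
    contam = set(small_genome.truth.contaminant_ids)
    assert min(scores[n] for n in contam) > 3
    assert max(s for n, s in scores.items() if n not in contam) < 3


# ---------------------------------------------------------------------------
# decontamination end to end
# ---------------------------------------------------------------------------

def test_partition_property(small_genome):
    assembly = small_genome.assembly()
    screens = cc.screen_contigs(assembly, [], toy_taxonomy())
    kept, dropped, frame = cc.apply_decontamination(assembly, screens)
    names = sorted(c.name for c in kept) + sorted(c.name for c in dropped)
    assert sorted(names) == sorted(c.name for c in assembly)
    assert len(frame) == len(assembly)


def test_all_bacterial_assembly_emptied(random_contigs):
    contigs = random_contigs([5000, 5000])
    rows = _rows("c00", 10, 0) + _rows("c01", 10, 0)
    screens = cc.screen_contigs(contigs, rows, toy_taxonomy())
    kept, dropped, _ = cc.apply_decontamination(contigs, screens)
    assert kept == [] and len(dropped) == 2


def test_no_classifications_drops_nothing(random_contigs):
    contigs = random_contigs([5000, 5000])
    screens = cc.screen_contigs(contigs, [], toy_taxonomy())
    kept, dropped, _ = cc.apply_decontamination(contigs, screens)
    assert dropped == [] and len(kept) == 2


def test_incomplete_screens_raise(random_contigs):
    contigs = random_contigs([5000, 5000])
    screens = cc.screen_contigs(contigs[:1], [], toy_taxonomy())
    with pytest.raises(ValueError, match="cover"):
        cc.apply_decontamination(contigs, screens)


def test_perfect_classifier_perfect_removal():
    result = decontam_scenario(3, accuracy=1.0, unclassified_rate=0.0)
    assert result["precision"] == 1.0
    assert result["recall"] == 1.0
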