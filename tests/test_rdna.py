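"""rDNA copy number, strain substitutions and allele fractions."""

import numpy as np
import pytest

import crcurate as cc
from crcurate.junctions import DepthTrack
from crcurate.rdna import OperonAnnotation, SubstitutionCounts
from crcurate.scenarios import allele_fraction_scenario, rdna_scenario

from conftest import write_sam


def tracks_from(depths):
    return {name: DepthTrack(name, np.asarray(d, dtype=np.int32)) for name, d in depths.items()}


# ---------------------------------------------------------------------------
# copy number
# ---------------------------------------------------------------------------

def test_copy_number_closed_form():
    tracks = tracks_from({
        "op": [100] * 2000,
        **{f"b{i:02d}": [10] * 3000 for i in range(10)},
    })
    ann = OperonAnnotation(contig="op", start=0, end=2000)
    est = cc.operon_copy_number(tracks, ann)
    assert est.operon_median_depth == 100
    assert est.backbone_median_depth == 10
    assert est.haploid_copies == pytest.approx(10.0)
    assert est.rounded_copies == 10


def test_backbone_uses_all_when_fewer_than_50():
    tracks = tracks_from({"op": [40] * 1000, "b": [20] * 2000})
    est = cc.operon_copy_number(tracks, OperonAnnotation("op", 0, 1000))
    assert est.n_backbone_contigs == 2


def test_zero_backbone_raises():
    tracks = tracks_from({"op": [0] * 1000})
    with pytest.raises(ValueError, match="baseline"):
        cc.operon_copy_number(tracks, OperonAnnotation("op", 0, 1000))


def test_copy_number_scale_invariance(tmp_path):
    result = rdna_scenario(5, copies=5, tmpdir=tmp_path, coverage=40)
    tracks, ann = result["tracks"], result["annotation"]
    est = cc.operon_copy_number(tracks, ann)
    scaled = {n: DepthTrack(n, t.depth * 7) for n, t in tracks.items()}
    est7 = cc.operon_copy_number(scaled, ann)
    assert est7.haploid_copies == pytest.approx(est.haploid_copies)


def test_planted_copy_number_recovered(tmp_path):
    result = rdna_scenario(6, copies=20, tmpdir=tmp_path, coverage=60)
    assert result["relative_error"] <= 0.1


def test_annotation_validation_and_parsing(tmp_path):
    with pytest.raises(ValueError, match="nested"):
        OperonAnnotation("c", 100, 200, {"18S": (50, 150)})
    with pytest.raises(ValueError, match="order"):
        OperonAnnotation("c", 0, 1000, {"28S": (500, 900), "18S": (100, 400)})

    bed = tmp_path / "op.bed"
    bed.write_text("ctg\t100\t900\toperon\nctg\t100\t300\t18S\nctg\t300\t400\tITS1\n")
    ann = OperonAnnotation.from_bed(bed)
    assert (ann.contig, ann.start, ann.end) == ("ctg", 100, 900)
    assert ann.subregions == {"18S": (100, 300), "ITS1": (300, 400)}

    gff = tmp_path / "op.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "ctg\tx\toperon\t101\t900\t.\t+\t.\tID=op\n"
        "ctg\tx\t18S\t101\t300\t.\t+\t.\tID=a\n"
    )
    ann2 = OperonAnnotation.from_gff3(gff)
    assert (ann2.start, ann2.end) == (100, 900)
    assert ann2.subregions["18S"] == (100, 300)


# ---------------------------------------------------------------------------
# strain substitutions
# ---------------------------------------------------------------------------

def _msa(rows, tmp_path):
    path = tmp_path / "msa.fasta"
    path.write_text("".join(f">{name}\n{seq}\n" for name, seq in rows))
    return path


def test_identical_sequences_count_zero(tmp_path):
    msa = _msa([(f"s{i}", "ACGTACGTACGTACGTACGT") for i in range(4)], tmp_path)
    result = cc.count_strain_substitutions(msa)
    assert all(not counts for counts in result.per_strain.values())
    assert result.ambiguous_columns == 0


def test_unique_variant_assigned_to_region(tmp_path):
    base = "ACGTACGTACGTACGTACGT"
    variant = base[:10] + "T" + base[11:]  # column 10: A->T in s2 only
    msa = _msa([("s0", base), ("s1", base), ("s2", variant), ("s3", base)], tmp_path)
    result = cc.count_strain_substitutions(msa, regions={"28S": (5, 15)})
    assert result.per_strain["s2"] == {"28S": 1}
    assert all(not result.per_strain[s] for s in ("s0", "s1", "s3"))


def test_two_variant_column_is_ambiguous(tmp_path):
    rows = [("s0", "AAAA"), ("s1", "AAAA"), ("s2", "ACAA"), ("s3", "AGAA")]
    result = cc.count_strain_substitutions(_msa(rows, tmp_path))
    assert result.ambiguous_columns == 1
    assert all(not counts for counts in result.per_strain.values())


def test_gap_columns_skipped(tmp_path):
    rows = [("s0", "A-GT"), ("s1", "AAGT"), ("s2", "AAGT")]
    result = cc.count_strain_substitutions(_msa(rows, tmp_path))
    assert result.gap_columns == 1


def test_unequal_lengths_rejected(tmp_path):
    rows = [("s0", "ACGT"), ("s1", "ACG"), ("s2", "ACGT")]
    with pytest.raises(ValueError, match="unequal"):
        cc.count_strain_substitutions(_msa(rows, tmp_path))


def test_fewer_than_three_rows_rejected(tmp_path):
    with pytest.raises(ValueError, match="at least 3"):
        cc.count_strain_substitutions(_msa([("a", "ACGT"), ("b", "ACGT")], tmp_path))


def test_substitution_counts_permutation_equivariant(tmp_path):
    base = "ACGTACGTACGTACGTACGT"
    variant = base[:3] + "C" + base[4:]
    rows = [("s0", base), ("s1", variant), ("s2", base), ("s3", base)]
    r1 = cc.count_strain_substitutions(_msa(rows, tmp_path))
    r2 = cc.count_strain_substitutions(_msa(rows[::-1], tmp_path))
    assert r1.per_strain == r2.per_strain


# ---------------------------------------------------------------------------
# allele fractions
# ---------------------------------------------------------------------------

def test_allele_fraction_arithmetic(tmp_path, random_contigs):
    contigs = random_contigs([500])
    ref = contigs[0].seq
    site = 100
    alt_base = "A" if ref[site] != "A" else "C"
    records = []
    for i in range(30):
        base = alt_base if i < 8 else ref[site]
        seq = ref[50:100] + base + ref[101:150]
        records.append((f"r{i}", 0, "c00", 51, "100M", seq))
    sam = write_sam(tmp_path / "af.sam", contigs, records)
    out = cc.allele_fraction_at_sites(sam, [("c00", site, ref[site])])
    assert out[0].depth == 30
    assert out[0].minor_fraction == pytest.approx(8 / 30)
    assert out[0].counts[alt_base] == 8


def test_all_reference_reads_give_zero_fraction(tmp_path, random_contigs):
    contigs = random_contigs([500])
    ref = contigs[0].seq
    records = [(f"r{i}", 0, "c00", 1, "200M", ref[:200]) for i in range(10)]
    sam = write_sam(tmp_path / "ref.sam", contigs, records)
    out = cc.allele_fraction_at_sites(sam, [("c00", 50, ref[50])])
    assert out[0].minor_fraction == 0.0


def test_zero_depth_site_reports_none(tmp_path, random_contigs):
    contigs = random_contigs([500])
    sam = write_sam(tmp_path / "empty.sam", contigs, [])
    out = cc.allele_fraction_at_sites(sam, [("c00", 50, "A")])
    assert out[0].depth == 0
    assert out[0].minor_fraction is None


def test_deletion_does_not_cover_site(tmp_path, random_contigs):
    contigs = random_contigs([500])
    ref = contigs[0].seq
    # read aligns 40M20D40M from pos 1: reference positions 40..59 deleted
    seq = ref[0:40] + ref[60:100]
    sam = write_sam(tmp_path / "del.sam", contigs, [("r1", 0, "c00", 1, "40M20D40M", seq)])
    out = cc.allele_fraction_at_sites(sam, [("c00", 50, ref[50]), ("c00", 70, ref[70])])
    assert out[0].depth == 0
    assert out[1].depth == 1


def test_planted_quarter_ratio_recovered(tmp_path):
    result = allele_fraction_scenario(2, tmpdir=tmp_path, ratio=0.25, coverage=100)
    for site in result["sites"]:
        assert site.depth > 50
        # binomial 3 sigma around 0.25 at the observed depth
        sigma = np.sqrt(0.25 * 0.75 / site.depth)
        assert abs(site.minor_fraction - 0.25) <= 3 * sigma + 1e-9
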