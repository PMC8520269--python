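"""Format readers/writers: VCF, PHYLIP, bgc and Introgress dialects."""

import dataclasses

import numpy as np
import pytest

from clinekit import formats
from clinekit.matrix import MISSING, GenotypeMatrix

MINIMAL_VCF = """\
##fileformat=VCFv4.2
##contig=<ID=chr1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1
chr1\t100\tsnp1\tA\tC\t.\tPASS\t.\tGT:AD\t0/1:3,5
chr1\t200\tsnp2\tG\tT\t.\tPASS\t.\tGT:AD\t./.:.
"""


@pytest.fixture
def minimal_vcf(tmp_path):
    vcf = tmp_path / "m.vcf"
    vcf.write_text(MINIMAL_VCF)
    pm = tmp_path / "m.popmap"
    pm.write_text("s1\tP0\n")
    return vcf, pm


def test_vcf_het_call_and_allele_depths(minimal_vcf):
    gm, rc = formats.read_vcf(*minimal_vcf)
    assert gm.genotypes[0, 0] == 1
    assert tuple(rc.counts[0, 0]) == (3, 5)
    assert gm.positions[0] == ("chr1", 100)
    assert gm.alleles[0] == ("A", "C")


def test_vcf_missing_genotype_is_sentinel(minimal_vcf):
    gm, _ = formats.read_vcf(*minimal_vcf)
    assert gm.genotypes[0, 1] == MISSING


def test_vcf_sample_absent_from_popmap_is_hard_error(minimal_vcf, tmp_path):
    vcf, _ = minimal_vcf
    bad = tmp_path / "bad.popmap"
    bad.write_text("other\tP0\n")
    with pytest.raises(ValueError, match="s1"):
        formats.read_vcf(vcf, bad)


def test_vcf_round_trips_fixture_matrix(geno_dataset):
    res, outdir = geno_dataset
    gm, rc = formats.read_vcf(outdir / "sim.vcf", outdir / "sim.popmap")
    ref = dataclasses.replace(res["matrix"])
    assert gm.equals(ref)
    assert rc is not None
    # depths are consistent with genotypes: homozygotes carry one-sided depth
    called = gm.genotypes != MISSING
    hom0 = (gm.genotypes == 0) & called
    assert (rc.counts[..., 1][hom0] == 0).all()


def test_phylip_iupac_decoding(tmp_path):
    phy = tmp_path / "t.phy"
    phy.write_text("2 2\nind1  AA\nind2  AR\n")
    pm = tmp_path / "t.popmap"
    pm.write_text("ind1\tP0\nind2\tP1\n")
    gm = formats.read_phylip(phy, pm)
    # locus 2: ind1=A/A, ind2=R=A/G -> alleles (A,G), genotypes [0, 1]
    assert gm.alleles[1] == ("A", "G")
    assert list(gm.genotypes[:, 1]) == [0, 1]


def test_phylip_n_dash_query_are_missing(tmp_path):
    phy = tmp_path / "t.phy"
    phy.write_text("2 3\nind1  N-?\nind2  ACG\n")
    pm = tmp_path / "t.popmap"
    pm.write_text("ind1\tP0\nind2\tP1\n")
    gm = formats.read_phylip(phy, pm)
    assert (gm.genotypes[0] == MISSING).all()


def test_phylip_multibase_ambiguity_is_missing_with_warning(tmp_path, caplog):
    phy = tmp_path / "t.phy"
    phy.write_text("2 1\nind1  B\nind2  A\n")
    pm = tmp_path / "t.popmap"
    pm.write_text("ind1\tP0\nind2\tP1\n")
    with caplog.at_level("WARNING"):
        gm = formats.read_phylip(phy, pm)
    assert gm.genotypes[0, 0] == MISSING
    assert any("ambiguity" in r.message for r in caplog.records)


def test_phylip_dimension_mismatch_errors(tmp_path):
    phy = tmp_path / "t.phy"
    phy.write_text("3 2\nind1  AA\nind2  CC\n")
    pm = tmp_path / "t.popmap"
    pm.write_text("ind1\tP0\nind2\tP1\n")
    with pytest.raises(ValueError, match="declares 3"):
        formats.read_phylip(phy, pm)


def test_phylip_round_trips_fixture_up_to_polarity(geno_dataset):
    res, outdir = geno_dataset
    gm = formats.read_phylip(outdir / "sim.phy", outdir / "sim.popmap")
    ref = dataclasses.replace(res["matrix"], locus_ids=gm.locus_ids, positions=None)
    assert gm.equals(ref, allow_polarity_flip=True)


# -------------------------------------------------------------- bgc dialect

def test_bgc_genotype_line_coding():
    assert formats._bgc_genotype_line(0) == "2 0"
    assert formats._bgc_genotype_line(1) == "1 1"
    assert formats._bgc_genotype_line(2) == "0 2"
    assert formats._bgc_genotype_line(MISSING) == "-9 -9"


def test_bgc_round_trip_preserves_genotypes_and_structure(geno_dataset, tmp_path):
    res, _ = geno_dataset
    gm = res["matrix"]
    paths = formats.write_bgc_input(gm, None, tmp_path, mode="genotype")
    back = formats.read_bgc_input(*paths)
    assert back.n_loci == gm.n_loci
    # writer orders samples P0, P1, then admixed pops; compare in that order
    order = (
        list(gm.sample_indices("P0"))
        + list(gm.sample_indices("P1"))
        + [i for lab in gm.admixed_labels for i in gm.sample_indices(lab)]
    )
    assert np.array_equal(back.genotypes, gm.genotypes[order, :])
    assert back.pop_labels[: len(gm.sample_indices("P0"))] == ["P0"] * len(
        gm.sample_indices("P0")
    )


def test_bgc_missing_line_reads_back_missing(tmp_path):
    (tmp_path / "p0").write_text("locus_0\n-9 -9\n")
    (tmp_path / "p1").write_text("locus_0\n2 0\n")
    (tmp_path / "adm").write_text("locus_0\npop_0\n1 1\n")
    gm = formats.read_bgc_input(tmp_path / "p0", tmp_path / "p1", tmp_path / "adm")
    assert gm.genotypes[0, 0] == MISSING


def test_bgc_empty_admixed_section_errors(tmp_path):
    (tmp_path / "p0").write_text("locus_0\n2 0\n")
    (tmp_path / "p1").write_text("locus_0\n0 2\n")
    (tmp_path / "adm").write_text("locus_0\n")
    with pytest.raises(ValueError, match="admixed"):
        formats.read_bgc_input(tmp_path / "p0", tmp_path / "p1", tmp_path / "adm")


def test_bgc_locus_count_disagreement_errors(tmp_path):
    (tmp_path / "p0").write_text("locus_0\n2 0\nlocus_1\n2 0\n")
    (tmp_path / "p1").write_text("locus_0\n0 2\n")
    (tmp_path / "adm").write_text("locus_0\npop_0\n1 1\n")
    with pytest.raises(ValueError, match="disagree"):
        formats.read_bgc_input(tmp_path / "p0", tmp_path / "p1", tmp_path / "adm")


def test_bgc_export_requires_admixed_individuals(toy_matrix, tmp_path):
    gm = dataclasses.replace(toy_matrix, pop_labels=["P0", "P0", "P1", "P1"])
    with pytest.raises(ValueError, match="admixed"):
        formats.write_bgc_input(gm, None, tmp_path)


def test_bgc_readcount_mode_writes_depths(geno_dataset, tmp_path):
    res, outdir = geno_dataset
    gm, rc = formats.read_vcf(outdir / "sim.vcf", outdir / "sim.popmap")
    paths = formats.write_bgc_input(gm, rc, tmp_path, mode="readcount")
    first_data = paths[0].read_text().splitlines()[1]
    assert len(first_data.split()) == 2


# -------------------------------------------------------- introgress dialect

def test_introgress_cells_and_loci_table(toy_matrix, tmp_path):
    paths = formats.write_introgress_input(toy_matrix, tmp_path)
    admix, p1, p2, loci = paths
    lines = p1.read_text().splitlines()
    # s1, s2 are P0; locus L1 genotypes 0 and 1 with alleles (A, C)
    assert lines[1].split("\t") == ["A/A", "A/C"]
    # L2: s1, s2 are MISSING
    assert lines[2].split("\t") == ["NA/NA", "NA/NA"]
    loci_rows = loci.read_text().splitlines()
    assert len(loci_rows) == 1 + toy_matrix.n_loci
    assert loci_rows[1] == "L1\tC"
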