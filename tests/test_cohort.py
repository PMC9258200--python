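"""Cohort containers, TSV/VCF ingestion, stratified splitting, observed maps."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import varmodnet as vm
from varmodnet import io

TSV = "patient\tv1\tv2\nP1\t1\t0\nP2\t0\t1\n"

VCF = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tP1\tP2\tP3
chr1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\t./.
chr1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t1/1\t0/1\t0/0
"""


def test_read_carrier_tsv(tmp_path):
    p = tmp_path / "c.tsv"
    p.write_text(TSV)
    cohort = io.read_carrier_matrix(p, format="tsv")
    assert cohort.patients == ["P1", "P2"]
    assert cohort.variants == ["v1", "v2"]
    assert cohort.carriers.tolist() == [[1, 0], [0, 1]]


def test_read_carrier_tsv_errors(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("patient\tv1\nP1\t2\n")
    with pytest.raises(vm.ParseError, match="P1.*v1"):
        io.read_carrier_matrix(bad, format="tsv")
    dup = tmp_path / "dup.tsv"
    dup.write_text("patient\tv1\nP1\t1\nP1\t0\n")
    with pytest.raises(vm.ValidationError):
        io.read_carrier_matrix(dup, format="tsv")


def test_read_carrier_vcf(tmp_path):
    """Zygosity-blind carriers: het and hom-alt are 1; missing genotype is 0."""
    p = tmp_path / "c.vcf"
    p.write_text(VCF)
    cohort = io.read_carrier_matrix(p, format="vcf")
    assert cohort.variants == ["chr1:100:A:G", "chr1:200:C:T"]
    got = {
        (pat, var): int(cohort.carriers[i, j])
        for i, pat in enumerate(cohort.patients)
        for j, var in enumerate(cohort.variants)
    }
    assert got[("P1", "chr1:100:A:G")] == 1  # 0/1
    assert got[("P2", "chr1:100:A:G")] == 0  # 0/0
    assert got[("P3", "chr1:100:A:G")] == 0  # ./. -> non-carrier
    assert got[("P1", "chr1:200:C:T")] == 1  # 1/1


def test_attach_phenotype_alignment_and_errors():
    base = vm.Cohort(["P1", "P2"], ["v1"], np.array([[1], [0]]))
    attached = vm.attach_phenotype(base, {"P2": 0, "P1": 1})
    assert attached.phenotype.tolist() == [1, 0]
    with pytest.raises(vm.ValidationError, match="P2"):
        vm.attach_phenotype(base, {"P1": 1})
    with pytest.raises(vm.ValidationError):
        vm.attach_phenotype(base, {"P1": 2, "P2": 0})


def test_split_stratification_and_determinism():
    phen = np.array([1] * 4 + [0] * 16, dtype=np.uint8)
    cohort = vm.Cohort(
        [f"P{i}" for i in range(20)], ["v"], np.ones((20, 1), np.uint8), phen
    )
    train, test = vm.split_cohort(cohort, 0.5, seed=42)
    assert int(train.phenotype.sum()) == 2 and train.n_patients == 10
    train2, test2 = vm.split_cohort(cohort, 0.5, seed=42)
    assert train.patients == train2.patients and test.patients == test2.patients
    # exact partition
    assert sorted(train.patients + test.patients) == sorted(cohort.patients)
    assert not set(train.patients) & set(test.patients)


def test_split_remainder_goes_to_test():
    """Odd class counts put the extra patient in the test split."""
    phen = np.array([1] * 5 + [0] * 9, dtype=np.uint8)
    cohort = vm.Cohort(
        [f"P{i}" for i in range(14)], ["v"], np.zeros((14, 1), np.uint8), phen
    )
    train, test = vm.split_cohort(cohort, 0.5, seed=0)
    assert int(train.phenotype.sum()) == 2 and int(test.phenotype.sum()) == 3
    assert train.n_patients == 6 and test.n_patients == 8


@given(
    n_cases=st.integers(2, 40),
    n_controls=st.integers(2, 60),
    fraction=st.floats(0.1, 0.9),
    seed=st.integers(0, 2**16),
)
def test_split_partition_property(n_cases, n_controls, fraction, seed):
    """Per class the train share differs from the requested fraction by <1 patient."""
    import math

    n = n_cases + n_controls
    phen = np.array([1] * n_cases + [0] * n_controls, dtype=np.uint8)
    cohort = vm.Cohort([f"P{i}" for i in range(n)], ["v"], np.zeros((n, 1), np.uint8), phen)
    train, test = vm.split_cohort(cohort, fraction, seed)
    assert int(train.phenotype.sum()) == math.floor(fraction * n_cases)
    assert train.n_patients + test.n_patients == n
    assert set(train.patients).isdisjoint(test.patients)


def test_restrict_to_observed_and_idempotence():
    carriers = np.array([[1, 0, 0, 0], [1, 0, 1, 0]], dtype=np.uint8)
    cohort = vm.Cohort(["P1", "P2"], ["a", "b", "c", "d"], carriers)
    gm = vm.GeneMap({"G1": ["a", "b", "c"], "G2": ["d"]})
    observed = vm.restrict_to_observed(cohort, gm)
    assert observed.genes == {"G1": ["a", "c"]}  # b unobserved; G2 fully dropped
    again = vm.restrict_to_observed(cohort, observed)
    assert again.genes == observed.genes
    # fully observed map passes through unchanged
    full = vm.GeneMap({"G1": ["a", "c"]})
    assert vm.restrict_to_observed(cohort, full).genes == full.genes


def test_gene_map_rejects_shared_variant():
    with pytest.raises(vm.ValidationError):
        vm.GeneMap({"G1": ["a"], "G2": ["a"]})


def test_round_trip_carriers_phenotype_genemap(tmp_path, toy_cohort):
    io.write_carrier_matrix(toy_cohort, tmp_path / "c.tsv")
    back = io.read_carrier_matrix(tmp_path / "c.tsv", format="tsv")
    assert back.patients == toy_cohort.patients
    assert back.variants == toy_cohort.variants
    assert np.array_equal(back.carriers, toy_cohort.carriers)

    io.write_phenotype(toy_cohort, tmp_path / "p.tsv")
    back = io.attach_phenotype(back, tmp_path / "p.tsv")
    assert np.array_equal(back.phenotype, toy_cohort.phenotype)

    gm = vm.GeneMap({"G1": ["v1", "v2"], "G2": ["v3", "v4"]})
    io.write_gene_map(gm, tmp_path / "g.tsv")
    assert io.read_gene_map(tmp_path / "g.tsv").genes == gm.genes
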