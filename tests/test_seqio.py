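import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitosignal import composition, seqio
from mitosignal.errors import (
    AlignmentShapeError,
    AlphabetError,
    FrameError,
    TaxonSetError,
    TranslationWarning,
)


def _write(tmp_path, text, name="a.fasta"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_two_identical_records(self, tmp_path):
        aln = seqio.read_fasta(_write(tmp_path, ">a\nACGT\n>b\nACGT\n"))
        assert aln.n_taxa == 2 and aln.n_sites == 4
        assert aln.alphabet_kind == "nucleotide"
        assert aln.sequence("a") == "ACGT"

    def test_unequal_lengths_raise(self, tmp_path):
        with pytest.raises(AlignmentShapeError):
            seqio.read_fasta(_write(tmp_path, ">a\nACGT\n>b\nACGTT\n"))

    def test_illegal_residue_raises(self, tmp_path):
        with pytest.raises(AlphabetError):
            seqio.read_fasta(
                _write(tmp_path, ">a\nAC!T\n>b\nACGT\n"), alphabet_kind="nucleotide"
            )

    def test_description_after_whitespace_ignored(self, tmp_path):
        aln = seqio.read_fasta(_write(tmp_path, ">a some description\nACGT\n>b\nACGT\n"))
        assert aln.taxon_names == ["a", "b"]

    def test_case_normalised(self, tmp_path):
        aln = seqio.read_fasta(_write(tmp_path, ">a\nacgt\n>b\nACgT\n"))
        assert aln.sequence("a") == "ACGT"


@settings(deadline=None, derandomize=True, max_examples=25)
@given(
    n_taxa=st.integers(2, 6),
    n_sites=st.integers(1, 40),
    data=st.data(),
)
def test_fasta_round_trip_preserves_everything(tmp_path_factory, n_taxa, n_sites, data):
    rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
    mat = rng.choice(list("ACGT-"), size=(n_taxa, n_sites))
    names = [f"tx{i}" for i in range(n_taxa)]
    aln = seqio.Alignment(names, mat)
    path = tmp_path_factory.mktemp("rt") / "x.fasta"
    seqio.write_fasta(aln, path)
    back = seqio.read_fasta(path)
    assert back.taxon_names == names
    assert np.array_equal(back.matrix, aln.matrix)


class TestCodonPositions:
    def test_keep_first_two_positions(self):
        aln = seqio.Alignment(["a"], np.array([list("ACGTGA")]),
                              partition_map={"g": np.arange(1, 7)})
        out = seqio.extract_codon_positions(aln, {1, 2})
        assert out.sequence("a") == "ACTG"  # original 1-based columns 1,2,4,5

    def test_keep_all_is_identity(self, tiny_nt_aln):
        out = seqio.extract_codon_positions(tiny_nt_aln, {1, 2, 3})
        assert np.array_equal(out.matrix, tiny_nt_aln.matrix)
        assert set(out.partition_map) == set(tiny_nt_aln.partition_map)

    def test_two_thirds_length_per_gene(self, tiny_nt_aln):
        out = seqio.extract_codon_positions(tiny_nt_aln, {1, 2})
        for gene, cols in tiny_nt_aln.partition_map.items():
            assert len(out.partition_map[gene]) == 2 * len(cols) // 3

    def test_out_of_frame_partition_raises(self):
        aln = seqio.Alignment(["a"], np.array([list("ACGT")]),
                              partition_map={"g": np.arange(1, 5)})
        with pytest.raises(FrameError):
            seqio.extract_codon_positions(aln, {1, 2})


class TestTranslate:
    def test_invertebrate_mito_codons(self):
        aln = seqio.Alignment(["a"], np.array([list("ATGGCT")]))
        assert seqio.translate(aln).sequence("a") == "MA"

    def test_gap_codon_becomes_x(self):
        aln = seqio.Alignment(["a"], np.array([list("ATG---")]))
        assert seqio.translate(aln).sequence("a") == "MX"

    def test_aga_is_serine_under_table5(self):
        aln = seqio.Alignment(["a"], np.array([list("AGA")]))
        assert seqio.translate(aln).sequence("a") == "S"
        assert seqio.translate(aln, code=1).sequence("a") == "R"

    def test_internal_stop_warns_not_fatal(self):
        aln = seqio.Alignment(["a"], np.array([list("TAAATG")]))
        with pytest.warns(TranslationWarning):
            out = seqio.translate(aln)
        assert out.sequence("a") == "*M"

    def test_translate_commutes_with_concatenate(self, tiny_nt_aln):
        g1, g2 = tiny_nt_aln.gene("g1"), tiny_nt_aln.gene("g2")
        a = seqio.translate(seqio.concatenate([g1, g2]))
        b = seqio.concatenate([seqio.translate(g1), seqio.translate(g2)])
        assert np.array_equal(a.matrix, b.matrix)


class TestConcatenate:
    def test_lengths_and_spans_add(self):
        a = seqio.Alignment(["x", "y"], np.array([list("ACGT"), list("ACGT")]),
                            partition_map={"g1": np.arange(1, 5)})
        b = seqio.Alignment(["x", "y"], np.array([list("AAATTT"), list("CCCGGG")]),
                            partition_map={"g2": np.arange(1, 7)})
        out = seqio.concatenate([a, b])
        assert out.n_sites == 10
        assert out.partition_map["g1"].tolist() == [1, 2, 3, 4]
        assert out.partition_map["g2"].tolist() == [5, 6, 7, 8, 9, 10]

    def test_single_input_unchanged(self, tiny_nt_aln):
        out = seqio.concatenate([tiny_nt_aln])
        assert np.array_equal(out.matrix, tiny_nt_aln.matrix)

    def test_taxon_mismatch_raises(self):
        a = seqio.Alignment(["x"], np.array([list("ACG")]))
        b = seqio.Alignment(["y"], np.array([list("ACG")]))
        with pytest.raises(TaxonSetError):
            seqio.concatenate([a, b])

    def test_gene_order_does_not_change_per_gene_statistics(self, tiny_nt_aln):
        g1, g2 = tiny_nt_aln.gene("g1"), tiny_nt_aln.gene("g2")
        fwd = seqio.concatenate([g1, g2])
        rev = seqio.concatenate([g2, g1])
        for gene in ("g1", "g2"):
            at_f = composition.base_composition(fwd.matrix[:, fwd.columns0(gene)]).at_content
            at_r = composition.base_composition(rev.matrix[:, rev.columns0(gene)]).at_content
            assert at_f == pytest.approx(at_r)


def test_partition_round_trip(tmp_path, tiny_nt_aln):
    path = tmp_path / "parts.tsv"
    seqio.write_partitions(tiny_nt_aln.partition_map, path)
    back = seqio.read_partitions(path)
    for gene, cols in tiny_nt_aln.partition_map.items():
        assert back[gene].tolist() == cols.tolist()
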