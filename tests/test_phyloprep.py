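"""Translation, back-alignment, RY recoding, matrix construction."""

import pytest
from hypothesis import given, settings, strategies as st

from mitocomp.phyloprep import (
    GeneAlignment, InternalStopError, TranslationMismatchError, back_align,
    build_matrix, partition_table, read_fasta_alignment, ry_recode, translate,
    write_fasta, write_nexus, write_phylip,
)


@pytest.mark.parametrize("nt,aa", [
    ("ATA", "M"),        # table 5: ATA is Met
    ("AGA", "S"),        # table 5: AGA is Ser, not Arg/stop
    ("TGA", "W"),        # table 5: TGA is Trp
    ("ATGTAA", "M"),     # terminal stop stripped
    ("ATGTA", "M"),      # truncated TA stop stripped
    ("ATGT", "M"),       # truncated T stop stripped
    ("ATG---TTT", "M-F"),
])
def test_translate(nt, aa):
    assert translate(nt) == aa


def test_translate_internal_stop_raises():
    with pytest.raises(InternalStopError, match="1"):
        translate("ATGTAATTT")


def test_back_align_expands_gaps():
    out = back_align({"t1": "ATGTTT"}, {"t1": "M-F"})
    assert out == {"t1": "ATG---TTT"}


def test_back_align_identity_without_gaps():
    out = back_align({"t1": "ATGTTTGGA"}, {"t1": "MFG"})
    assert out["t1"] == "ATGTTTGGA"


def test_back_align_order_independent():
    nts = {"a": "ATGTTT", "b": "ATAGGA", "c": "GTGTTT"}
    aas = {"a": "M-F", "b": "MG-", "c": "V-F"}
    out1 = back_align(nts, aas)
    out2 = back_align(dict(reversed(list(nts.items()))), aas)
    assert out1 == out2


def test_back_align_mismatch_raises():
    with pytest.raises(TranslationMismatchError):
        back_align({"t1": "ATGTTT"}, {"t1": "MG"})


def test_translate_back_align_round_trip():
    nts = {"a": "ATGTTTAAA", "b": "ATGGGATTT"}
    aas = {"a": "MF-K", "b": "MG-F"}
    # pad the aa rows consistently: 4 columns each
    aas = {"a": "MF-K", "b": "MGF-"}
    out = back_align(nts, aas)
    for taxon, row in out.items():
        assert translate(row) == aas[taxon]


def test_ry_recode_examples():
    assert ry_recode("ACGT") == "RYRY"
    assert ry_recode("R-N") == "R-?"


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGTRYN-", max_size=60))
def test_ry_recode_idempotent_and_closed(s):
    once = ry_recode(s)
    assert ry_recode(once) == once
    assert set(once) <= {"R", "Y", "-", "?"}


def _toy_alignments():
    # two genes of 6 and 9 codons; cox1 precedes nad5 in ancestral order
    g1 = GeneAlignment("cox1", {
        "t1": "ATGTTTGGATTAATTCAT",
        "t2": "ATATTCGGGTTGATCCAC",
    })
    g2 = GeneAlignment("nad5", {
        "t1": "ATTCAAATAGGTTGATTAACTCAT",
        "t2": "ATCCAGATGGGATGACTTACACAC",
    })
    assert g1.length == 18 and g2.length == 24  # 6 and 8 codons
    return [g1, g2]


def test_build_matrix_pos123_dimensions():
    g1, g2 = _toy_alignments()
    # make gene 2 nine codons to match the 6+9 construction
    g2 = GeneAlignment("nad5", {t: s + "TTT" for t, s in g2.seqs.items()})
    m = build_matrix([g1, g2], "pos123")
    assert m.n_columns == 45
    assert len(m.partitions) == 6  # 2 genes x 3 positions
    m.check_tiling()


def test_build_matrix_pos12_is_two_thirds():
    alns = _toy_alignments()
    m123 = build_matrix(alns, "pos123")
    m12 = build_matrix(alns, "pos12")
    assert m12.n_columns * 3 == m123.n_columns * 2


def test_build_matrix_pos12ry3_same_length_as_pos123():
    alns = _toy_alignments()
    m123 = build_matrix(alns, "pos123")
    mry = build_matrix(alns, "pos12ry3")
    assert mry.n_columns == m123.n_columns
    # third positions are RY-recoded
    for t in mry.taxa:
        thirds = mry.sequences[t][2::3]
        assert set(thirds) <= {"R", "Y", "-", "?"}
    ry_parts = [p for p in mry.partitions if p.char_type == "ry"]
    assert len(ry_parts) == 2  # one pos3RY partition per gene


def test_build_matrix_aa():
    alns = _toy_alignments()
    m = build_matrix(alns, "aa")
    assert m.n_columns == (18 + 24) // 3
    assert all(p.char_type == "aa" for p in m.partitions)


def test_build_matrix_concatenates_in_ancestral_order():
    g1, g2 = _toy_alignments()
    m = build_matrix([g2, g1], "pos123")  # deliberately out of order
    assert m.provenance["genes"] == ["cox1", "nad5"]
    for t in m.taxa:
        assert m.sequences[t] == g1.seqs[t] + g2.seqs[t]


def test_build_matrix_excludes_gene_and_shifts_partitions():
    alns = _toy_alignments()
    m = build_matrix(alns, "pos123", exclude_genes=["nad5"])
    assert m.provenance["genes"] == ["cox1"]
    assert m.n_columns == 18
    assert all(p.end <= 18 for p in m.partitions)
    m.check_tiling()


def test_build_matrix_pads_missing_taxa():
    g1, g2 = _toy_alignments()
    g2 = GeneAlignment("nad5", {"t1": g2.seqs["t1"]})
    m = build_matrix([g1, g2], "pos123")
    assert m.sequences["t2"].endswith("?" * 24)
    assert m.provenance["padded"] == {"t2": ["nad5"]}


def test_build_matrix_applies_masks():
    g1, g2 = _toy_alignments()
    m = build_matrix([g1, g2], "pos123", masks={"cox1": [(0, 3)]})
    assert m.n_columns == 15 + 24
    for t in m.taxa:
        assert m.sequences[t] == g1.seqs[t][3:] + g2.seqs[t]


def test_matrix_column_content_equivalence(genome):
    """Concatenated Pos123 characters equal the per-gene concatenation."""
    alns = []
    for f in genome.primary_features():
        if f.kind != "PCG":
            continue
        seq = genome.feature_seq(f)
        seq = seq[:len(seq) // 3 * 3]
        alns.append(GeneAlignment(f.name, {"taxon1": seq}))
    m = build_matrix(alns, "pos123")
    expected = "".join(a.seqs["taxon1"] for a in sorted(
        alns, key=lambda a: m.provenance["genes"].index(a.gene)))
    assert m.sequences["taxon1"] == expected
    m.check_tiling()


def test_writers_round_trip(tmp_path):
    alns = _toy_alignments()
    m = build_matrix(alns, "pos12ry3")
    fasta = tmp_path / "m.fasta"
    phylip = tmp_path / "m.phy"
    nexus = tmp_path / "m.nex"
    write_fasta(m, fasta)
    write_phylip(m, phylip)
    write_nexus(m, nexus)
    back = read_fasta_alignment(fasta)
    assert back.seqs == m.sequences
    phy_lines = phylip.read_text().splitlines()
    assert phy_lines[0].split() == [str(len(m.taxa)), str(m.n_columns)]
    assert phy_lines[1].split()[1] == m.sequences[m.taxa[0]]
    nex = nexus.read_text()
    assert f"NCHAR={m.n_columns}" in nex
    for p in m.partitions:
        assert f"CHARSET {p.name}" in nex
    table = partition_table(m)
    assert len(table) == len(m.partitions)


def test_nexus_charset_strides_cover_matrix(tmp_path):
    m = build_matrix(_toy_alignments(), "pos123")
    nexus = tmp_path / "m.nex"
    write_nexus(m, nexus)
    text = nexus.read_text()
    covered = set()
    for line in text.splitlines():
        line = line.strip()
        if not line.startswith("CHARSET"):
            continue
        spec = line.split("=")[1].strip().rstrip(";")
        rng, _, step = spec.partition("\\")
        a, b = (int(x) for x in rng.split("-"))
        covered.update(range(a, b + 1, int(step or 1)))
    assert covered == set(range(1, m.n_columns + 1))
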