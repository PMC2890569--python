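import pytest

from mitocomp.synthetic import GeneratorConfig, make_ancestral


@pytest.fixture(scope="session")
def ancestral():
    """A complete synthetic mitogenome in the ancestral arrangement."""
    genome, truth = make_ancestral(GeneratorConfig(seed=11))
    return genome, truth


@pytest.fixture(scope="session")
def genome(ancestral):
    return ancestral[0]


@pytest.fixture(scope="session")
def truth(ancestral):
    return ancestral[1]


TOY_GENBANK = """\
LOCUS       toy                       20 bp    DNA     circular INV 01-JAN-2000
DEFINITION  three-gene toy record.
FEATURES             Location/Qualifiers
     CDS             1..9
                     /gene="COI"
     tRNA            complement(10..12)
                     /product="tRNA-Lys"
                     /anticodon="(pos:10..12,aa:Lys,seq:ttt)"
     misc_feature    13..20
                     /note="A+T-rich region"
ORIGIN
        1 atgaaataat ttaattatta
//
"""


@pytest.fixture()
def toy_genbank(tmp_path):
    path = tmp_path / "toy.gb"
    path.write_text(TOY_GENBANK)
    return path


def wrap_genbank(tmp_path):
    """A 100 bp circle with a gene annotated across the origin."""
    seq = "ATGC" * 25
    lines = []
    for i in range(0, 100, 60):
        chunk = seq[i:i + 60].lower()
        sub = " ".join(chunk[j:j + 10] for j in range(0, len(chunk), 10))
        lines.append(f"{i + 1:>9} {sub}")
    text = (
        "LOCUS       wrap                     100 bp    DNA     circular "
        "INV 01-JAN-2000\n"
        "FEATURES             Location/Qualifiers\n"
        "     CDS             join(95..100,1..5)\n"
        '                     /gene="cox1"\n'
        "ORIGIN\n" + "\n".join(lines) + "\n//\n")
    path = tmp_path / "wrap.gb"
    path.write_text(text)
    return path, seq
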