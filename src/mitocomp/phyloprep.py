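"""Construction of codon-partitioned phylogenetic supermatrices.

From per-gene codon alignments this module builds the four matrix flavours
used in mitogenomic phylogenetics:

* ``aa``       - translated amino acids (invertebrate mitochondrial code);
* ``pos123``   - all three codon positions as nucleotides;
* ``pos12``    - first and second codon positions only;
* ``pos12ry3`` - first and second positions as nucleotides plus the third
                 position RY-recoded (purines -> R, pyrimidines -> Y), the
                 standard remedy for third-position saturation and
                 compositional bias.

Genes are concatenated following their ancestral order in the insect
mitochondrial genome; partitions are emitted per gene and codon position and
always tile the matrix exactly.  Matrices are written as FASTA, relaxed
PHYLIP, or NEXUS with a sets block of charsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .evolrates import CODON_TO_AA, STOP_CODONS
from .rearrangement import ANCESTRAL_ORDER

MATRIX_KINDS = ("aa", "pos12", "pos123", "pos12ry3")

_ANCESTRAL_RANK = {label: i for i, (label, _s) in enumerate(ANCESTRAL_ORDER)}


class InternalStopError(ValueError):
    pass


class TranslationMismatchError(ValueError):
    pass


def translate(nt: str, allow_terminal_stop: bool = True) -> str:
    """Translate a coding nucleotide sequence with NCBI table 5.

    Fully gapped codons become ``-``; codons containing partial gaps or
    ambiguity become ``X``.  A terminal (possibly truncated, TA/T) stop is
    dropped.  An internal stop raises :class:`InternalStopError` naming the
    codon position.
    """
    nt = nt.upper().replace("U", "T")
    rem = len(nt) % 3
    if rem and not nt.endswith("TA"[:rem]):
        raise ValueError(f"length {len(nt)} not a multiple of 3 and the "
                         f"overhang {nt[-rem:]!r} is not a truncated stop")
    if rem:
        nt = nt[:-rem]
    aa = []
    n = len(nt) // 3
    for i in range(n):
        codon = nt[3 * i:3 * i + 3]
        if codon == "---":
            aa.append("-")
        elif codon in STOP_CODONS:
            if i == n - 1 and allow_terminal_stop:
                break
            raise InternalStopError(f"internal stop codon at codon {i}")
        elif codon in CODON_TO_AA:
            aa.append(CODON_TO_AA[codon])
        else:
            aa.append("X")
    return "".join(aa)


def back_align(nt_seqs: Mapping[str, str], aa_aln: Mapping[str, str]
               ) -> dict[str, str]:
    """Expand an amino-acid alignment to a codon alignment.

    Each taxon's unaligned coding sequence must translate to its amino-acid
    row with gaps removed; each amino-acid gap becomes the codon gap ``---``.
    """
    out: dict[str, str] = {}
    for taxon, aa_row in aa_aln.items():
        if taxon not in nt_seqs:
            raise TranslationMismatchError(f"no nucleotide sequence for {taxon}")
        nt = nt_seqs[taxon].upper().replace("U", "T")
        rem = len(nt) % 3
        if rem:
            nt = nt[:-rem]
        expect = translate(nt)
        got = aa_row.replace("-", "")
        if expect != got:
            pos = next((i for i, (x, y) in enumerate(zip(expect, got)) if x != y),
                       min(len(expect), len(got)))
            raise TranslationMismatchError(
                f"{taxon}: translation mismatch at aa position {pos}")
        codons = [nt[3 * i:3 * i + 3] for i in range(len(expect))]
        row = []
        k = 0
        for ch in aa_row:
            if ch == "-":
                row.append("---")
            else:
                row.append(codons[k])
                k += 1
        out[taxon] = "".join(row)
    return out


_RY = str.maketrans("AGagCTctUu", "RRrrYYyyYy")


def ry_recode(seq: str) -> str:
    """Purines -> R, pyrimidines -> Y; gaps kept; other ambiguity -> ``?``."""
    out = []
    for ch in seq.translate(_RY):
        if ch.upper() in "RY-":
            out.append(ch.upper() if ch != "-" else "-")
        else:
            out.append("?")
    return "".join(out)


# --------------------------------------------------------------------------
# alignments and matrices


@dataclass
class GeneAlignment:
    """A per-gene alignment keyed by taxon (codon-aligned nt or aa)."""

    gene: str
    seqs: dict[str, str]
    residue_type: str = "nucleotide"  # nucleotide | amino_acid
    mask: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.seqs.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: unequal aligned lengths {lengths}")

    @property
    def length(self) -> int:
        return len(next(iter(self.seqs.values()))) if self.seqs else 0

    def masked(self) -> "GeneAlignment":
        """Drop masked columns (0-based half-open column intervals)."""
        if not self.mask:
            return self
        drop = set()
        for a, b in self.mask:
            drop.update(range(a, b))
        keep = [i for i in range(self.length) if i not in drop]
        if self.residue_type == "nucleotide" and len(keep) % 3:
            raise ValueError(f"{self.gene}: mask leaves length not divisible by 3")
        seqs = {t: "".join(s[i] for i in keep) for t, s in self.seqs.items()}
        return GeneAlignment(self.gene, seqs, self.residue_type, [])


@dataclass(frozen=True)
class Partition:
    name: str
    start: int       # 0-based half-open column range in the final matrix
    end: int
    step: int        # 1 for contiguous, 2/3 for codon-position strides
    char_type: str   # nt | aa | ry

    def columns(self) -> range:
        return range(self.start, self.end, self.step)


@dataclass
class PhyloMatrix:
    kind: str
    taxa: tuple[str, ...]
    sequences: dict[str, str]
    partitions: list[Partition]
    provenance: dict

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def check_tiling(self) -> None:
        """Every column covered by exactly one partition."""
        seen: dict[int, str] = {}
        for p in self.partitions:
            for c in p.columns():
                if c in seen:
                    raise AssertionError(
                        f"column {c} in both {seen[c]} and {p.name}")
                seen[c] = p.name
        missing = set(range(self.n_columns)) - set(seen)
        if missing:
            raise AssertionError(f"columns not covered: {sorted(missing)[:5]}...")


def read_fasta_alignment(path, gene: Optional[str] = None) -> GeneAlignment:
    from Bio import SeqIO
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    name = gene or str(path)
    return GeneAlignment(name, seqs)


def read_mask(path) -> list[tuple[int, int]]:
    """Mask file: one 0-based half-open column interval per line."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#")[0].strip()
            if not line:
                continue
            a, b = line.split()[:2]
            intervals.append((int(a), int(b)))
    return intervals


def build_matrix(alignments: Iterable[GeneAlignment], kind: str,
                 exclude_genes: Iterable[str] = (),
                 masks: Optional[Mapping[str, list[tuple[int, int]]]] = None,
                 ry3_split: bool = False) -> PhyloMatrix:
    """Concatenate per-gene alignments into one of the four matrix kinds.

    Genes are ordered by the ancestral mitochondrial gene order; taxa missing
    a gene are padded with ``?`` and reported in the provenance.  For
    ``pos12ry3`` the third position is RY-recoded and emitted as a single
    partition per gene (``ry3_split=True`` emits nothing extra; the switch is
    reserved for downstream tools that want pos3RY broken out per gene -
    partitions are already per gene here).
    """
    if kind not in MATRIX_KINDS:
        raise ValueError(f"kind must be one of {MATRIX_KINDS}")
    excl = set(exclude_genes)
    alns = [a for a in alignments if a.gene not in excl]
    if not alns:
        raise ValueError("no alignments left after exclusion")
    alns.sort(key=lambda a: _ANCESTRAL_RANK.get(a.gene, len(_ANCESTRAL_RANK)))

    taxa: list[str] = []
    for a in alns:
        for t in a.seqs:
            if t not in taxa:
                taxa.append(t)
    if not taxa:
        raise ValueError("empty taxon set")

    parts: list[Partition] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    padded: dict[str, list[str]] = {}
    col = 0
    for a in alns:
        aln = a.masked() if not masks else GeneAlignment(
            a.gene, a.seqs, a.residue_type,
            masks.get(a.gene, a.mask)).masked()
        L = aln.length
        if a.residue_type == "amino_acid" and kind != "aa":
            raise ValueError(f"{a.gene}: amino-acid alignment cannot build {kind}")
        if kind == "aa":
            if a.residue_type == "amino_acid":
                rows = dict(aln.seqs)
                width = L
            else:
                rows = {t: translate(s, allow_terminal_stop=False)
                        for t, s in aln.seqs.items()}
                width = L // 3
            parts.append(Partition(f"{a.gene}", col, col + width, 1, "aa"))
            col += width
        else:
            n_codons = L // 3
            if kind == "pos123":
                rows = dict(aln.seqs)
                width = L
                for p in range(3):
                    parts.append(Partition(f"{a.gene}_pos{p+1}",
                                           col + p, col + width, 3, "nt"))
            elif kind == "pos12":
                rows = {t: "".join(s[3 * i:3 * i + 2] for i in range(n_codons))
                        for t, s in aln.seqs.items()}
                width = 2 * n_codons
                for p in range(2):
                    parts.append(Partition(f"{a.gene}_pos{p+1}",
                                           col + p, col + width, 2, "nt"))
            else:  # pos12ry3
                rows = {}
                for t, s in aln.seqs.items():
                    codons = [s[3 * i:3 * i + 3] for i in range(n_codons)]
                    rows[t] = "".join(c[:2] + ry_recode(c[2]) for c in codons)
                width = L
                for p in range(2):
                    parts.append(Partition(f"{a.gene}_pos{p+1}",
                                           col + p, col + width, 3, "nt"))
                parts.append(Partition(f"{a.gene}_pos3RY",
                                       col + 2, col + width, 3, "ry"))
            col += width
        missing_char = "?"
        for t in taxa:
            if t in rows:
                chunks[t].append(rows[t])
            else:
                chunks[t].append(missing_char * width)
                padded.setdefault(t, []).append(a.gene)

    sequences = {t: "".join(c) for t, c in chunks.items()}
    matrix = PhyloMatrix(
        kind=kind, taxa=tuple(taxa), sequences=sequences, partitions=parts,
        provenance={
            "genes": [a.gene for a in alns],
            "excluded": sorted(excl),
            "padded": {t: gs for t, gs in padded.items()},
            "masks": {g: m for g, m in (masks or {}).items()},
        })
    matrix.check_tiling()
    return matrix


# --------------------------------------------------------------------------
# writers ("?" is missing, "-" is gap, bit-exact across formats)


def write_fasta(matrix: PhyloMatrix, path) -> None:
    with open(path, "w") as fh:
        for t in matrix.taxa:
            fh.write(f">{t}\n{matrix.sequences[t]}\n")


def write_phylip(matrix: PhyloMatrix, path) -> None:
    """Relaxed PHYLIP: full names, two-space separator, one line per taxon."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.taxa)} {matrix.n_columns}\n")
        pad = max(len(t) for t in matrix.taxa) + 2
        for t in matrix.taxa:
            fh.write(f"{t:<{pad}}{matrix.sequences[t]}\n")


def write_nexus(matrix: PhyloMatrix, path) -> None:
    """NEXUS with a data block and a sets block of charsets.

    Codon-position partitions use the stride notation ``start-end\\3``.
    """
    dt = "PROTEIN" if matrix.kind == "aa" else "DNA"
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(matrix.taxa)} "
                 f"NCHAR={matrix.n_columns};\n")
        fh.write(f"  FORMAT DATATYPE={dt} MISSING=? GAP=-;\n  MATRIX\n")
        pad = max(len(t) for t in matrix.taxa) + 2
        for t in matrix.taxa:
            fh.write(f"    {t:<{pad}}{matrix.sequences[t]}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for p in matrix.partitions:
            if p.step == 1:
                spec = f"{p.start + 1}-{p.end}"
            else:
                spec = f"{p.start + 1}-{p.end}\\{p.step}"
            fh.write(f"  CHARSET {p.name} = {spec};\n")
        names = " , ".join(f"{p.name}:{p.name}" for p in matrix.partitions)
        fh.write(f"  CHARPARTITION byposition = {names};\nEND;\n")


def partition_table(matrix: PhyloMatrix) -> pd.DataFrame:
    rows = [{"name": p.name, "start": p.start, "end": p.end, "step": p.step,
             "char_type": p.char_type} for p in matrix.partitions]
    return pd.DataFrame(rows)
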