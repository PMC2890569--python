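"""Reading, validation and normalization of annotated mitochondrial genomes.

The module maps heterogeneous GenBank annotations onto a closed set of 38
canonical labels (13 protein-coding genes, 22 tRNAs with the two leucine and
two serine isoacceptors disambiguated, two rRNAs, and the A+T-rich control
region ``CR``), converts all coordinates to 0-based half-open intervals on the
plus strand, and merges features that cross the origin of the circular
molecule into a single span.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

UNMAPPED = "unmapped"

PCG_LABELS = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)
RRNA_LABELS = ("rrnL", "rrnS")
TRNA_LABELS = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
    "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR", "trnS1",
    "trnS2", "trnT", "trnV", "trnW", "trnY",
)
CANONICAL_LABELS = frozenset(PCG_LABELS + RRNA_LABELS + TRNA_LABELS + ("CR",))

#: Canonical anticodons reported for rearrangement-associated tRNAs.
EXPECTED_ANTICODONS = {"trnK": "TTT", "trnS2": "TCT"}


class GenomeFormatError(ValueError):
    """Raised when an input record cannot be parsed into the data model."""


def kind_of(label: str) -> str:
    if label in PCG_LABELS:
        return "PCG"
    if label in RRNA_LABELS:
        return "rRNA"
    if label.startswith("trn"):
        return "tRNA"
    if label == "CR":
        return "control_region"
    raise ValueError(f"unknown canonical label: {label}")


# --------------------------------------------------------------------------
# gene-name normalization


_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}

_LEU_SER_CODONS = {
    # Leu(CUN) -> trnL1, Leu(UUR) -> trnL2, Ser(AGY) -> trnS1, Ser(UCN) -> trnS2
    "cun": "trnL1", "ctn": "trnL1", "cua": "trnL1", "cug": "trnL1",
    "uur": "trnL2", "ttr": "trnL2", "uua": "trnL2", "uug": "trnL2",
    "tta": "trnL2", "ttg": "trnL2",
    "agy": "trnS1", "agn": "trnS1", "agc": "trnS1", "agt": "trnS1",
    "agu": "trnS1",
    "ucn": "trnS2", "tcn": "trnS2", "uca": "trnS2", "tca": "trnS2",
    "ucu": "trnS2", "tct": "trnS2", "tga": "trnS2", "uga": "trnS2",
}


def _clean(raw: str) -> str:
    return re.sub(r"[^a-z0-9]", "", raw.lower())


def _alias_table() -> dict[str, str]:
    table: dict[str, str] = {}
    for i, roman in enumerate(("i", "ii", "iii"), start=1):
        for stem in (f"co{i}", f"co{roman}", f"cox{i}", f"cox{roman}",
                     f"mtco{i}", f"cytochromecoxidasesubunit{i}",
                     f"cytochromecoxidasesubunit{roman}",
                     f"cytochromeoxidasesubunit{i}",
                     f"cytochromeoxidasesubunit{roman}"):
            table[stem] = f"cox{i}"
    for i in range(1, 7):
        for stem in (f"nd{i}", f"nad{i}", f"nadh{i}",
                     f"nadhdehydrogenasesubunit{i}"):
            table[stem] = f"nad{i}"
    for stem in ("nd4l", "nad4l", "nadhdehydrogenasesubunit4l"):
        table[stem] = "nad4l"
    for stem in ("cytb", "cob", "cb", "cytochromeb", "cytochromebapoenzyme"):
        table[stem] = "cob"
    for i in (6, 8):
        for stem in (f"atp{i}", f"atpase{i}", f"atpase{i}gene",
                     f"atpsynthasef0subunit{i}", f"atpsynthasesubunit{i}"):
            table[stem] = f"atp{i}"
    for stem in ("rrnl", "lrrna", "lsurrna", "16s", "16srrna",
                 "16sribosomalrna", "largesubunitribosomalrna"):
        table[stem] = "rrnL"
    for stem in ("rrns", "srrna", "ssurrna", "12s", "12srrna",
                 "12sribosomalrna", "smallsubunitribosomalrna"):
        table[stem] = "rrnS"
    for stem in ("cr", "dloop", "atrichregion", "atrich", "controlregion",
                 "putativecontrolregion", "atregion"):
        table[stem] = "CR"
    return table


_ALIASES = _alias_table()


def normalize_gene_name(raw: str) -> str:
    """Map a free-text gene/product string onto a canonical label.

    Total function: anything unrecognized (including Leu/Ser tRNAs lacking a
    codon-family qualifier) returns the sentinel ``"unmapped"``.
    """
    if not raw:
        return UNMAPPED
    text = raw.strip().lower()

    # tRNA spellings: "tRNA-Leu(UUR)", "trnL2", "trnW", "transfer RNA-Lys" ...
    m = re.match(
        r"^(?:trna|transferrna|trn|t)[-_ ]?"
        r"(?:(?P<aa3>[a-z]{3})|(?P<aa1>[a-z]))"
        r"(?P<iso>[12])?"
        r"(?:\s*\(\s*(?P<codon>[a-z]{3})\s*\))?$",
        re.sub(r"[^a-z0-9()]", "", text),
    )
    if m:
        aa3, aa1, iso, codon = m.group("aa3"), m.group("aa1"), m.group("iso"), m.group("codon")
        one = None
        if aa3 in _AA3_TO_1:
            one = _AA3_TO_1[aa3]
        elif aa1 is not None:
            one = aa1.upper()
        if one in ("L", "S"):
            if iso in ("1", "2"):
                return f"trn{one}{iso}"
            if codon in _LEU_SER_CODONS:
                lbl = _LEU_SER_CODONS[codon]
                return lbl if lbl[3] == one else UNMAPPED
            return UNMAPPED
        if one is not None and f"trn{one}" in CANONICAL_LABELS:
            return f"trn{one}"

    key = _clean(text)
    if key in _ALIASES:
        return _ALIASES[key]
    # exact canonical spellings (case-insensitive)
    for label in CANONICAL_LABELS:
        if key == label.lower():
            return label
    return UNMAPPED


# --------------------------------------------------------------------------
# data model


@dataclass(frozen=True)
class GeneFeature:
    """A typed gene feature on the plus strand of a circular genome.

    ``start``/``end`` are 0-based half-open; for a feature crossing the
    origin, ``end`` exceeds the genome length and the span wraps.
    """

    name: str
    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str    # PCG | tRNA | rRNA | control_region
    anticodon: Optional[str] = None
    duplicate: bool = False
    raw_name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"empty interval for {self.name}")

    def __len__(self) -> int:
        return self.end - self.start

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length


@dataclass
class AnnotatedGenome:
    """A circular (or partial) mitochondrial genome with typed gene features."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    circular: bool = True
    completeness: str = "complete"  # complete | partial

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for f in self.features:
            if f.start < 0 or f.start >= len(self.sequence):
                raise ValueError(f"{f.name}: start {f.start} outside genome")
            if f.end > f.start + len(self.sequence):
                raise ValueError(f"{f.name}: span longer than genome")

    @property
    def length(self) -> int:
        return len(self.sequence)

    # -- feature access ----------------------------------------------------

    def primary_features(self) -> list[GeneFeature]:
        """Features sorted by start, excluding duplicate-flagged copies."""
        return sorted((f for f in self.features if not f.duplicate),
                      key=lambda f: f.start)

    def get(self, label: str) -> GeneFeature:
        for f in self.primary_features():
            if f.name == label:
                return f
        raise KeyError(label)

    def plus_span(self, feature: GeneFeature) -> str:
        """Plus-strand image of the feature's span (wrap-aware)."""
        if feature.end <= self.length:
            return self.sequence[feature.start:feature.end]
        return self.sequence[feature.start:] + self.sequence[:feature.end - self.length]

    def feature_seq(self, feature: GeneFeature) -> str:
        """Coding-orientation sequence of the feature."""
        span = self.plus_span(feature)
        return revcomp(span) if feature.strand == "-" else span

    def intergenic_intervals(self, min_length: int = 1) -> list[tuple[int, int]]:
        """Feature-free intervals around the circle (wrap-aware).

        The wrap-around gap, if any, is reported with ``end > length``.
        """
        L = self.length
        if not self.features:
            return [(0, L)] if L >= min_length else []
        occupied: list[tuple[int, int]] = []
        for f in self.features:
            if f.end <= L:
                occupied.append((f.start, f.end))
            else:
                occupied.append((f.start, L))
                occupied.append((0, f.end - L))
        occupied.sort()
        merged = [list(occupied[0])]
        for s, e in occupied[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        gaps = [(e1, s2) for (s1, e1), (s2, e2) in zip(merged, merged[1:])
                if s2 - e1 >= min_length]
        covers_origin = merged[0][0] == 0 and merged[-1][1] == L
        if self.circular and not covers_origin:
            wrap = (merged[0][0] + L) - merged[-1][1]
            if wrap >= min_length:
                gaps.append((merged[-1][1], merged[0][0] + L))
        elif not self.circular:
            if merged[0][0] >= min_length:
                gaps.append((0, merged[0][0]))
            if L - merged[-1][1] >= min_length:
                gaps.append((merged[-1][1], L))
        return gaps

    def interval_seq(self, start: int, end: int) -> str:
        if end <= self.length:
            return self.sequence[start:end]
        return self.sequence[start:] + self.sequence[:end - self.length]

    # -- whole-genome transforms ------------------------------------------

    def rotated(self, offset: int) -> "AnnotatedGenome":
        """Rotate the circular genome so position ``offset`` becomes 0."""
        if not self.circular:
            raise ValueError("cannot rotate a non-circular genome")
        L = self.length
        offset %= L
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            start = (f.start - offset) % L
            feats.append(replace(f, start=start, end=start + len(f)))
        return AnnotatedGenome(self.id, seq, feats, self.circular, self.completeness)

    def reverse_complemented(self) -> "AnnotatedGenome":
        L = self.length
        seq = revcomp(self.sequence)
        feats = []
        for f in self.features:
            start = (L - f.end) % L
            feats.append(replace(
                f, start=start, end=start + len(f),
                strand="-" if f.strand == "+" else "+",
            ))
        return AnnotatedGenome(self.id, seq, feats, self.circular, self.completeness)


@dataclass
class ValidationReport:
    genome_id: str
    missing: list[str] = field(default_factory=list)
    duplicated: list[str] = field(default_factory=list)
    codon_anomalies: list[tuple[str, str, str]] = field(default_factory=list)
    anticodon_anomalies: list[tuple[str, str]] = field(default_factory=list)
    overlaps: list[tuple[str, str, int]] = field(default_factory=list)
    unmapped: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not (self.missing or self.duplicated or self.codon_anomalies
                    or self.anticodon_anomalies or self.overlaps)

    def to_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "missing": self.missing,
            "duplicated": self.duplicated,
            "codon_anomalies": self.codon_anomalies,
            "anticodon_anomalies": self.anticodon_anomalies,
            "overlaps": self.overlaps,
            "unmapped": self.unmapped,
        }


# --------------------------------------------------------------------------
# GenBank I/O


_ANTICODON_RE = re.compile(r"seq\s*:\s*([acgtu]{3})", re.IGNORECASE)


def _feature_name(bio_feature) -> Optional[str]:
    q = bio_feature.qualifiers
    for key in ("gene", "product", "note", "standard_name"):
        for value in q.get(key, []):
            label = normalize_gene_name(value)
            if label != UNMAPPED:
                return label
    return None


def _raw_name(bio_feature) -> str:
    q = bio_feature.qualifiers
    for key in ("gene", "product", "note"):
        if q.get(key):
            return q[key][0]
    return bio_feature.type


def _span_from_location(loc, genome_length: int) -> tuple[int, int]:
    """0-based half-open span; origin-crossing joins become a wrapped span."""
    parts = getattr(loc, "parts", [loc])
    if len(parts) > 1:
        parts = sorted(parts, key=lambda p: int(p.start))
        first, last = parts[0], parts[-1]
        if int(last.end) == genome_length and int(first.start) == 0:
            # join(X..L, 1..Y): feature crosses the origin
            total = sum(int(p.end) - int(p.start) for p in parts)
            return int(last.start), int(last.start) + total
        return int(parts[0].start), int(parts[-1].end)
    return int(loc.start), int(loc.end)


def read_genbank(path, unmapped_sink: Optional[list] = None) -> AnnotatedGenome:
    """Read a GenBank flat record into an :class:`AnnotatedGenome`.

    Features whose qualifiers match no canonical label are collected as
    warnings (retrievable through ``unmapped_sink`` or ``validate_genome``),
    never fatal.  When both a ``gene`` feature and a ``CDS``/``tRNA``/``rRNA``
    feature describe the same locus, the specific feature wins.  Extra copies
    of a label are retained but flagged as duplicates (the longest copy is
    primary).
    """
    try:
        record = SeqIO.read(str(path), "genbank")
    except Exception as exc:  # noqa: BLE001 - normalize parser errors
        raise GenomeFormatError(f"cannot parse GenBank record {path}: {exc}") from exc

    seq = str(record.seq).upper()
    L = len(seq)
    topology = record.annotations.get("topology", "circular")
    circular = topology != "linear"

    picked: dict[tuple[str, int], tuple[int, GeneFeature]] = {}
    unmapped: list[str] = []
    candidates: list[tuple[int, GeneFeature]] = []
    specificity = {"CDS": 2, "tRNA": 2, "rRNA": 2, "misc_feature": 1,
                   "D-loop": 2, "gene": 0}

    for bf in record.features:
        if bf.type not in specificity:
            continue
        label = _feature_name(bf)
        if label is None:
            if bf.type != "gene":
                unmapped.append(_raw_name(bf))
            continue
        start, end = _span_from_location(bf.location, L)
        if end <= start:
            continue
        strand = "-" if (bf.location.strand or 1) < 0 else "+"
        anticodon = None
        for val in bf.qualifiers.get("anticodon", []):
            m = _ANTICODON_RE.search(val)
            if m:
                anticodon = m.group(1).upper().replace("U", "T")
        candidates.append((specificity[bf.type], GeneFeature(
            name=label, start=start, end=end, strand=strand,
            kind=kind_of(label), anticodon=anticodon, raw_name=_raw_name(bf),
        )))

    # collapse gene/CDS pairs: for overlapping same-label features keep the
    # most specific (then longest) one
    by_label: dict[str, list[tuple[int, GeneFeature]]] = {}
    for spec_rank, feat in candidates:
        by_label.setdefault(feat.name, []).append((spec_rank, feat))

    features: list[GeneFeature] = []
    for label, group in by_label.items():
        clusters: list[list[tuple[int, GeneFeature]]] = []
        for item in sorted(group, key=lambda t: t[1].start):
            placed = False
            for cluster in clusters:
                if any(_spans_overlap(item[1], other, L) for _, other in cluster):
                    cluster.append(item)
                    placed = True
                    break
            if not placed:
                clusters.append([item])
        reps = [max(c, key=lambda t: (t[0], len(t[1])))[1] for c in clusters]
        reps.sort(key=len, reverse=True)
        features.append(reps[0])
        for extra in reps[1:]:
            features.append(replace(extra, duplicate=True))

    features.sort(key=lambda f: f.start)
    if unmapped_sink is not None:
        unmapped_sink.extend(unmapped)
    genome = AnnotatedGenome(record.id or record.name, seq, features,
                             circular=circular)
    genome._unmapped = unmapped  # type: ignore[attr-defined]
    return genome


def _spans_overlap(a: GeneFeature, b: GeneFeature, L: int) -> bool:
    def segs(f):
        if f.end <= L:
            return [(f.start, f.end)]
        return [(f.start, L), (0, f.end - L)]
    return any(s1 < e2 and s2 < e1 for (s1, e1) in segs(a) for (s2, e2) in segs(b))


def to_seqrecord(genome: AnnotatedGenome) -> SeqRecord:
    """Convert to a Biopython SeqRecord (deterministic annotations)."""
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = "circular" if genome.circular else "linear"
    record.annotations["data_file_division"] = "INV"
    record.annotations["date"] = "01-JAN-2000"
    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
               "control_region": "misc_feature"}
    L = genome.length
    for f in sorted(genome.features, key=lambda f: f.start):
        strand = -1 if f.strand == "-" else 1
        if f.end <= L:
            loc = FeatureLocation(f.start, f.end, strand)
        else:
            loc = CompoundLocation([FeatureLocation(f.start, L, strand),
                                    FeatureLocation(0, f.end - L, strand)])
        quals = {"gene": [f.name]}
        if f.anticodon:
            quals["anticodon"] = [f"(seq:{f.anticodon.lower()})"]
        if f.duplicate:
            quals["note"] = ["duplicated copy"]
        record.features.append(SeqFeature(loc, type=type_of[f.kind],
                                          qualifiers=quals))
    return record


def write_genbank(genome: AnnotatedGenome, path) -> None:
    SeqIO.write([to_seqrecord(genome)], str(path), "genbank")


# --------------------------------------------------------------------------
# FASTA + feature-table I/O (alternative plain-text interface)


def read_fasta_table(fasta_path, table_path) -> AnnotatedGenome:
    """Read a genome from FASTA plus a TSV feature table.

    Table columns: gene, start, end, strand, kind[, anticodon]; coordinates
    are 0-based half-open on the plus strand.
    """
    record = SeqIO.read(str(fasta_path), "fasta")
    features = []
    with open(table_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            parts = line.split("\t")
            gene, start, end, strand, kind = parts[:5]
            anticodon = parts[5] if len(parts) > 5 and parts[5] else None
            label = normalize_gene_name(gene)
            if label == UNMAPPED:
                label = gene
            features.append(GeneFeature(label, int(start), int(end), strand,
                                        kind, anticodon=anticodon))
    return AnnotatedGenome(record.id, str(record.seq), features)


def write_feature_table(genome: AnnotatedGenome, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tstart\tend\tstrand\tkind\tanticodon\n")
        for f in sorted(genome.features, key=lambda f: f.start):
            fh.write(f"{f.name}\t{f.start}\t{f.end}\t{f.strand}\t{f.kind}\t"
                     f"{f.anticodon or ''}\n")


# --------------------------------------------------------------------------
# validation


def validate_genome(genome: AnnotatedGenome, overlap_tolerance: int = 10) -> ValidationReport:
    """Report-only consistency checks against the canonical mitogenome model.

    Flags protein-coding genes that do not start with ATN or do not end with
    TAA (or the truncated stops TA/T), tRNAs whose annotated anticodon departs
    from the canonical trnK=TTT / trnS2=TCT, missing or duplicated canonical
    genes, and feature overlaps beyond ``overlap_tolerance``.
    """
    report = ValidationReport(genome.id)
    report.unmapped = list(getattr(genome, "_unmapped", []))

    primary = genome.primary_features()
    present: dict[str, int] = {}
    for f in primary:
        present[f.name] = present.get(f.name, 0) + 1

    report.missing = sorted(lbl for lbl in CANONICAL_LABELS if lbl not in present)
    report.duplicated = sorted(lbl for lbl, n in present.items() if n > 1)

    for f in primary:
        if f.kind == "PCG":
            seq = genome.feature_seq(f)
            start_codon = seq[:3]
            rem = len(seq) % 3
            stop = seq[-3:] if rem == 0 else seq[-rem:]
            bad_start = not (len(start_codon) == 3 and start_codon[:2] == "AT")
            if rem == 0:
                bad_stop = stop != "TAA"
            elif rem == 2:
                bad_stop = stop != "TA"
            else:
                bad_stop = stop != "T"
            if bad_start or bad_stop:
                report.codon_anomalies.append((f.name, start_codon, stop))
        elif f.kind == "tRNA" and f.anticodon and f.name in EXPECTED_ANTICODONS:
            if f.anticodon.upper() != EXPECTED_ANTICODONS[f.name]:
                report.anticodon_anomalies.append((f.name, f.anticodon))

    L = genome.length
    for i, a in enumerate(primary):
        for b in primary[i + 1:]:
            if a.name == b.name:
                continue
            ov = _overlap_length(a, b, L)
            if ov > overlap_tolerance:
                report.overlaps.append((a.name, b.name, ov))
    return report


def _overlap_length(a: GeneFeature, b: GeneFeature, L: int) -> int:
    def segs(f):
        if f.end <= L:
            return [(f.start, f.end)]
        return [(f.start, L), (0, f.end - L)]
    total = 0
    for (s1, e1) in segs(a):
        for (s2, e2) in segs(b):
            total += max(0, min(e1, e2) - max(s1, s2))
    return total
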