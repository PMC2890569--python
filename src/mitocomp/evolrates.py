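"""Nei-Gojobori Ka/Ks estimation under the invertebrate mitochondrial code.

The classic (unweighted) Nei-Gojobori method: each codon position contributes
a fractional count of synonymous sites (the fraction of its possible changes
that are synonymous, with changes into stop codons excluded from the
denominator); differences between codon pairs are partitioned into synonymous
and nonsynonymous steps by averaging over all orderings of the single-base
steps, excluding pathways through stop codons.  Proportions are corrected for
multiple hits with the Jukes-Cantor formula K = -(3/4) ln(1 - (4/3) p).

Translation uses the invertebrate mitochondrial genetic code (NCBI table 5),
in which TGA encodes tryptophan and AGA/AGG encode serine, leaving TAA and
TAG as the only stop codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Iterable, Mapping, Optional

from Bio.Data import CodonTable

from .genome_io import AnnotatedGenome

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]
CODON_TO_AA: dict[str, str] = dict(_TABLE5.forward_table)
STOP_CODONS = frozenset(_TABLE5.stop_codons)
BASES = "ACGT"


class CodonSkip(ValueError):
    """Codon cannot contribute (stop codon or ambiguity): skip the site."""


class NoValidPathway(ValueError):
    """Every mutational pathway between two codons passes through a stop."""


class SaturationError(ValueError):
    """Synonymous or nonsynonymous proportion at or beyond the JC limit 3/4."""


class InsufficientDataError(ValueError):
    """Fewer comparable codons than the minimum required."""


def _is_sense(codon: str) -> bool:
    return codon in CODON_TO_AA


def codon_sites(codon: str) -> tuple[float, float]:
    """Fractional synonymous and nonsynonymous site counts of a sense codon.

    ``s`` sums, over the three positions, the fraction of possible single-base
    changes that are synonymous; changes creating stop codons are excluded
    from the denominator.  ``n = 3 - s``.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise CodonSkip(f"ambiguous codon {codon!r}")
    if codon in STOP_CODONS:
        raise CodonSkip(f"stop codon {codon}")
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if CODON_TO_AA[alt] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


# cache: 62 sense codons
_SITES: dict[str, tuple[float, float]] = {}
for _c1 in BASES:
    for _c2 in BASES:
        for _c3 in BASES:
            _cod = _c1 + _c2 + _c3
            if _cod not in STOP_CODONS:
                _SITES[_cod] = codon_sites(_cod)


def codon_diffs(a: str, b: str) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous difference counts.

    All orderings of the differing positions are enumerated; a pathway is
    discarded if any intermediate codon is a stop.  With at least one valid
    pathway, sd + nd equals the Hamming distance.
    """
    a, b = a.upper(), b.upper()
    if not (_is_sense(a) and _is_sense(b)):
        raise CodonSkip(f"non-sense codon pair {a}/{b}")
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    total_sd = total_nd = 0.0
    valid = 0
    for path in permutations(diff):
        cur = a
        sd = nd = 0
        ok = True
        for pos in path:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            total_sd += sd
            total_nd += nd
            valid += 1
    if valid == 0:
        raise NoValidPathway(f"no stop-free pathway between {a} and {b}")
    return total_sd / valid, total_nd / valid


def jukes_cantor(p: float) -> float:
    """JC69 distance for a difference proportion ``p`` (< 3/4)."""
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} at or beyond the JC limit")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class RateEstimate:
    label: str
    reference: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    ps: float
    pn: float
    Ks: float
    Ka: float

    @property
    def ratio(self) -> Optional[float]:
        """Ka/Ks; undefined (None) when Ks == 0."""
        return None if self.Ks == 0 else self.Ka / self.Ks


def _codon_iter(a: str, b: str) -> Iterable[tuple[str, str]]:
    n = min(len(a), len(b)) // 3
    for i in range(n):
        yield a[3 * i:3 * i + 3], b[3 * i:3 * i + 3]


def nei_gojobori(seq_a: str, seq_b: str, label: str = "",
                 reference: str = "", min_codons: int = 30) -> RateEstimate:
    """Nei-Gojobori rate estimate for a pair of aligned coding sequences.

    Codons containing gaps, ambiguity, or stops in either sequence are
    excluded pairwise.  Site counts are averaged over the two sequences.
    """
    S_a = S_b = Sd = Nd = 0.0
    n_codons = 0
    for ca, cb in _codon_iter(seq_a.upper(), seq_b.upper()):
        if ca not in _SITES or cb not in _SITES:
            continue
        try:
            sd, nd = codon_diffs(ca, cb)
        except NoValidPathway:
            continue
        sa, _ = _SITES[ca]
        sb, _ = _SITES[cb]
        S_a += sa
        S_b += sb
        Sd += sd
        Nd += nd
        n_codons += 1
    if n_codons < min_codons:
        raise InsufficientDataError(
            f"{label or 'alignment'}: only {n_codons} comparable codons "
            f"(minimum {min_codons})")
    S = (S_a + S_b) / 2.0
    N = 3.0 * n_codons - S
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    try:
        Ks = jukes_cantor(ps)
        Ka = jukes_cantor(pn)
    except SaturationError as exc:
        raise SaturationError(f"{label or 'alignment'}: {exc}") from exc
    return RateEstimate(label, reference, n_codons, S, N, Sd, Nd, ps, pn, Ks, Ka)


# --------------------------------------------------------------------------
# genome-vs-reference rates


def _paired_coding(genome: AnnotatedGenome, ref: AnnotatedGenome,
                   gene: str) -> tuple[str, str]:
    """Gap-free codon pairing of one gene from two genomes.

    Sequences are trimmed to the shared codon count from the start (the
    deterministic fallback used when no externally computed codon alignment
    is supplied; adequate for indel-free comparisons).
    """
    a = genome.feature_seq(genome.get(gene))
    b = ref.feature_seq(ref.get(gene))
    n = min(len(a) // 3, len(b) // 3)
    return a[:3 * n], b[:3 * n]


def genome_rates(genome: AnnotatedGenome, ref: AnnotatedGenome,
                 genes: Optional[Iterable[str]] = None,
                 exclude: Iterable[str] = (),
                 alignments: Optional[Mapping[str, tuple[str, str]]] = None,
                 min_codons: int = 30):
    """Per-gene and concatenated Ka/Ks of a genome against a reference.

    Uses all protein-coding genes annotated in both genomes unless ``genes``
    is given.  Saturated genes are flagged and excluded from the
    concatenated estimate.  Returns ``(overall, per_gene, flagged)`` where
    ``per_gene`` maps gene -> RateEstimate and ``flagged`` maps gene -> reason.
    """
    have_g = {f.name for f in genome.primary_features() if f.kind == "PCG"}
    have_r = {f.name for f in ref.primary_features() if f.kind == "PCG"}
    shared = sorted((have_g & have_r) - set(exclude))
    if genes is not None:
        shared = [g for g in genes if g in shared]
    if not shared:
        raise ValueError(f"no shared protein-coding genes between "
                         f"{genome.id} and {ref.id}")

    per_gene: dict[str, RateEstimate] = {}
    flagged: dict[str, str] = {}
    concat_a: list[str] = []
    concat_b: list[str] = []
    for gene in shared:
        if alignments is not None and gene in alignments:
            a, b = alignments[gene]
        else:
            a, b = _paired_coding(genome, ref, gene)
        try:
            per_gene[gene] = nei_gojobori(a, b, label=gene, reference=ref.id,
                                          min_codons=min_codons)
        except (SaturationError, InsufficientDataError) as exc:
            flagged[gene] = str(exc)
            continue
        concat_a.append(a)
        concat_b.append(b)
    if not concat_a:
        raise InsufficientDataError(
            f"all shared genes flagged: {sorted(flagged)}")
    overall = nei_gojobori("".join(concat_a), "".join(concat_b),
                           label=genome.id, reference=ref.id,
                           min_codons=min_codons)
    return overall, per_gene, flagged
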