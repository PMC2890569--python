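"""Nucleotide composition, AT/GC skew, and strand-asymmetry calls.

AT skew = (A-T)/(A+T) and GC skew = (G-C)/(G+C), computed on the majority
strand (the strand encoding most genes).  In most insects the majority-strand
GC skew is negative; a positive value indicates reversal of strand asymmetry,
the condition associated with inversion of the replication origin inside the
A+T-rich region.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from ._seq import revcomp
from .genome_io import AnnotatedGenome, PCG_LABELS


class UndefinedCompositionError(ValueError):
    """Raised for empty or all-ambiguous sequences."""


@dataclass(frozen=True)
class SkewProfile:
    genome_id: str
    scope: str
    at_skew: Optional[float]
    gc_skew: Optional[float]
    at_content: float          # percent of unambiguous bases
    counts: tuple[int, int, int, int, int]  # A, T, G, C, N

    def rounded(self, ndigits: int = 2) -> tuple:
        """Report-style rounding; internal values are never rounded."""
        r = lambda x: None if x is None else round(x, ndigits)
        return (r(self.at_skew), r(self.gc_skew), round(self.at_content, ndigits))


@dataclass(frozen=True)
class AsymmetryCall:
    genome_id: str
    gc_skew_majority: float
    call: str  # normal | reversed | indeterminate
    epsilon: float


def base_counts(sequence: str) -> tuple[int, int, int, int, int]:
    c = Counter(sequence.upper())
    a, t, g, cc = c["A"], c["T"], c["G"], c["C"]
    n = len(sequence) - (a + t + g + cc)
    return a, t, g, cc, n


def skew(sequence: str) -> tuple[Optional[float], Optional[float], float]:
    """Return (at_skew, gc_skew, at_content%) of a sequence.

    Ambiguity characters are excluded from every count.  A skew whose
    denominator is zero is returned as ``None`` (absent), not as 0.
    """
    a, t, g, c, _ = base_counts(sequence)
    total = a + t + g + c
    if total == 0:
        raise UndefinedCompositionError("no unambiguous bases in sequence")
    at = (a - t) / (a + t) if a + t else None
    gc = (g - c) / (g + c) if g + c else None
    return at, gc, 100.0 * (a + t) / total


def majority_strand(genome: AnnotatedGenome) -> str:
    """Strand ('+'/'-') encoding the greater number of genes (CR excluded).

    Ties break toward the strand carrying cox1.
    """
    feats = [f for f in genome.primary_features() if f.kind != "control_region"]
    if not feats:
        raise ValueError("genome has no gene features")
    plus = sum(1 for f in feats if f.strand == "+")
    minus = len(feats) - plus
    if plus != minus:
        return "+" if plus > minus else "-"
    for f in feats:
        if f.name == "cox1":
            return f.strand
    return "+"


ScopeType = Union[str, tuple]


def profile(genome: AnnotatedGenome, scope: ScopeType = "whole",
            pcg_orientation: str = "majority") -> SkewProfile:
    """Skew profile of a genome for a named scope.

    Scopes: ``"whole"`` (majority strand of the full circular sequence),
    ``"pcg"`` (the 13 protein-coding genes concatenated), ``("gene", label)``
    (one gene, coding orientation), ``("region", (start, end))`` (plus-strand
    interval).  For the ``pcg`` scope each gene is read in majority-strand
    orientation by default (the strand-referenced convention of
    whole-genome composition tables); ``pcg_orientation="sense"`` reads each
    gene in its own coding orientation instead.
    """
    maj = majority_strand(genome)
    if scope == "whole":
        seq = genome.sequence if maj == "+" else revcomp(genome.sequence)
        name = "whole_genome_majority_strand"
    elif scope == "pcg":
        feats = [f for f in genome.primary_features() if f.kind == "PCG"]
        missing = sorted(set(PCG_LABELS) - {f.name for f in feats})
        if not feats:
            raise ValueError(f"no protein-coding genes annotated; missing {missing}")
        parts = []
        for f in feats:
            if pcg_orientation == "sense":
                parts.append(genome.feature_seq(f))
            else:
                span = genome.plus_span(f)
                parts.append(span if maj == "+" else revcomp(span))
        seq = "".join(parts)
        name = "all_PCGs"
    elif isinstance(scope, tuple) and scope[0] == "gene":
        label = scope[1]
        try:
            feat = genome.get(label)
        except KeyError:
            raise ValueError(f"scope error: gene {label} absent from {genome.id}")
        seq = genome.feature_seq(feat)
        name = f"single_gene:{label}"
    elif isinstance(scope, tuple) and scope[0] == "region":
        start, end = scope[1]
        seq = genome.interval_seq(start, end)
        name = f"region:{start}-{end}"
    else:
        raise ValueError(f"unknown scope {scope!r}")

    at, gc, atc = skew(seq)
    return SkewProfile(genome.id, name, at, gc, atc, base_counts(seq))


def call_asymmetry(p: Union[SkewProfile, float], epsilon: float = 0.02,
                   genome_id: str = "") -> AsymmetryCall:
    """Call reversal of strand asymmetry from the majority-strand GC skew.

    The ancestral insect condition is a negative majority-strand GC skew, so
    a GC skew above ``+epsilon`` is called ``reversed``, below ``-epsilon``
    ``normal``, and ``indeterminate`` within the guard band.
    """
    if isinstance(p, SkewProfile):
        if p.gc_skew is None:
            raise ValueError("GC skew undefined for this profile")
        value, gid = p.gc_skew, p.genome_id
    else:
        value, gid = float(p), genome_id
    if value > epsilon:
        call = "reversed"
    elif value < -epsilon:
        call = "normal"
    else:
        call = "indeterminate"
    return AsymmetryCall(gid, value, call, epsilon)


def composition_table(genomes: Sequence[AnnotatedGenome], ndigits: int = 2,
                      pcg_orientation: str = "majority") -> pd.DataFrame:
    """Whole-genome and all-PCG skews per genome, rounded for reporting."""
    rows = []
    for g in genomes:
        whole = profile(g, "whole")
        pcg = profile(g, "pcg", pcg_orientation=pcg_orientation)
        w = whole.rounded(ndigits)
        p = pcg.rounded(ndigits)
        rows.append({
            "genome": g.id,
            "AT_skew": w[0], "GC_skew": w[1], "AT_pct": w[2],
            "PCG_AT_skew": p[0], "PCG_GC_skew": p[1], "PCG_AT_pct": p[2],
            "asymmetry": call_asymmetry(whole).call,
        })
    return pd.DataFrame(rows)
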