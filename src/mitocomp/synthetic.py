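"""Synthetic annotated mitogenomes with ground-truth event logs.

The generator builds a 37-gene + control-region circular genome in the
ancestral hexapod arrangement with configurable A+T content and
majority-strand skews, applies scripted rearrangement events (shuffle, local
inversion, translocation, remote inversion, block inversion, duplication)
with optional pseudogene or spacer remnants at the source locus, builds
control regions containing the five canonical elements in either orientation,
and evolves codon sequences to a target synonymous divergence at a chosen
dN/dS (omega).  Every output is a deterministic function of the seed, and
each operation returns the ground truth the analysis modules are expected to
recover.

tRNA and rRNA sequences are composition-matched random strings without
folding constraints: the downstream analyses consume only position, strand
and composition.  Defaults mirror the braconid study conditions: ~85% A+T,
slightly negative majority-strand AT skew and positive (reversed)
majority-strand GC skew.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from ._seq import revcomp
from .genome_io import AnnotatedGenome, GeneFeature, kind_of
from .rearrangement import ANCESTRAL_ORDER, GeneOrder
from .evolrates import CODON_TO_AA, STOP_CODONS, _SITES

BASES = "ACGT"

#: Coding lengths (bp) typical of insect mitochondrial genes.
DEFAULT_GENE_LENGTHS = {
    "cox1": 1536, "cox2": 684, "cox3": 789, "cob": 1140, "nad1": 939,
    "nad2": 1023, "nad3": 354, "nad4": 1338, "nad4l": 294, "nad5": 1719,
    "nad6": 522, "atp6": 678, "atp8": 162, "rrnL": 1350, "rrnS": 800,
}
TRNA_LENGTH = 66

#: Intergenic spacer presets mirroring observed remnant spacer lengths.
SPACER_PRESETS = {"short": 23, "long": 52}


class ConfigError(ValueError):
    pass


class ScriptError(ValueError):
    pass


class IterationLimitError(RuntimeError):
    pass


# --------------------------------------------------------------------------
# events


@dataclass(frozen=True)
class Remnant:
    kind: str = "none"          # none | spacer | pseudogene
    length: int = 23            # spacer length
    identity: float = 0.9       # pseudogene identity


@dataclass(frozen=True)
class Shuffle:
    gene: str
    offset: int                  # signed, in gene ranks; |offset| <= window W


@dataclass(frozen=True)
class LocalInvert:
    gene: str


@dataclass(frozen=True)
class Translocate:
    gene: str
    dest: tuple[str, str]        # insert at the junction between these genes
    remnant: Remnant = Remnant()


@dataclass(frozen=True)
class RemoteInvert:
    gene: str
    dest: tuple[str, str]
    remnant: Remnant = Remnant()


@dataclass(frozen=True)
class BlockInvert:
    first: str
    last: str


@dataclass(frozen=True)
class Duplicate:
    first: str
    last: str
    dest: tuple[str, str]
    invert: bool = False


Event = Union[Shuffle, LocalInvert, Translocate, RemoteInvert, BlockInvert,
              Duplicate]


@dataclass
class GroundTruth:
    expected_order: Optional[GeneOrder]
    statuses: dict[str, str]
    remnants: list[dict]
    cr_orientation: str
    omega: dict[str, float] = field(default_factory=dict)
    events: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        d = {
            "expected_order": list(self.expected_order.order)
            if self.expected_order else None,
            "statuses": self.statuses,
            "remnants": self.remnants,
            "cr_orientation": self.cr_orientation,
            "omega": self.omega,
            "events": self.events,
        }
        return json.dumps(d, indent=1)


# --------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    at_content: float = 0.85
    at_skew_majority: float = -0.06
    gc_skew_majority: float = 0.15
    gene_lengths: dict = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    trna_length: int = TRNA_LENGTH
    cr_length: int = 575
    cr_orientation: str = "forward"     # forward | inverted
    cr_elements: bool = True
    cr_repeats: Optional[tuple[int, int]] = None  # (unit_length, copies)
    spacer_max: int = 5
    composition_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if not 0.5 < self.at_content < 1.0:
            raise ConfigError("at_content must be in (0.5, 1)")
        for s in (self.at_skew_majority, self.gc_skew_majority):
            if not -1.0 < s < 1.0:
                raise ConfigError("skews must be in (-1, 1)")
        if self.cr_orientation not in ("forward", "inverted"):
            raise ConfigError("cr_orientation must be forward or inverted")


def _base_probs(cfg: GeneratorConfig) -> np.ndarray:
    """Plus-strand base probabilities (A, C, G, T) hitting the targets."""
    at, gc = cfg.at_content, 1.0 - cfg.at_content
    a = at / 2 * (1 + cfg.at_skew_majority)
    t = at / 2 * (1 - cfg.at_skew_majority)
    g = gc / 2 * (1 + cfg.gc_skew_majority)
    c = gc / 2 * (1 - cfg.gc_skew_majority)
    return np.array([a, c, g, t])


def _complement_probs(p: np.ndarray) -> np.ndarray:
    a, c, g, t = p
    return np.array([t, g, c, a])


def _random_seq(rng: np.random.Generator, n: int, probs: np.ndarray,
                max_run: int = 7) -> str:
    """Random sequence with homopolymer runs capped at ``max_run``.

    The cap keeps background sequence from spawning spurious polyT/polyA
    element hits; real intergenic spacers are similarly run-poor compared to
    the control region's signal elements.
    """
    out = rng.choice(list(BASES), size=n, p=probs).tolist()
    run = 1
    for i in range(1, n):
        if out[i] == out[i - 1]:
            run += 1
            if run > max_run:
                alternatives = [b for b in BASES if b != out[i]]
                w = np.array([probs[BASES.index(b)] for b in alternatives])
                out[i] = rng.choice(alternatives, p=w / w.sum())
                run = 1
        else:
            run = 1
    return "".join(out)


def _random_cds(rng: np.random.Generator, n_codons: int, probs: np.ndarray) -> str:
    """Random coding sequence: ATN start, TAA stop, no internal stops."""
    codons = ["AT" + rng.choice(list(BASES), p=probs / probs.sum())]
    p = probs / probs.sum()
    while len(codons) < n_codons - 1:
        cod = "".join(rng.choice(list(BASES), size=3, p=p))
        if cod in STOP_CODONS:
            continue
        codons.append(cod)
    codons.append("TAA")
    return "".join(codons)


# --------------------------------------------------------------------------
# control-region construction


def _build_cr(rng: np.random.Generator, cfg: GeneratorConfig) -> tuple[str, str]:
    """A control region with the five canonical elements, (seq, orientation)."""
    probs = _base_probs(cfg)
    # background run cap of 4 keeps the filler from spawning spurious polyT
    # hits that would blur the orientation signal
    fill = lambda n: _random_seq(rng, n, probs, max_run=4)
    parts = [
        "T" * int(rng.integers(15, 19)),                     # polyT stretch
        fill(int(rng.integers(8, 15))),
        "TAA" * int(rng.integers(6, 9)) + "TA" * 2,          # [TA(A)]n stretch
        fill(int(rng.integers(8, 15))),
        "TATA",                                              # TATA motif
        fill(int(rng.integers(3, 8))),
    ]
    stem = _random_seq(rng, int(rng.integers(16, 21)), np.array([.25] * 4))
    loop = fill(int(rng.integers(5, 9)))
    parts.append(stem + loop + revcomp(stem))                # stem-loop
    parts.append(fill(int(rng.integers(3, 8))))
    parts.append("G" + "A" * int(rng.integers(2, 5)) + "T")  # G(A)nT motif
    parts.append(fill(int(rng.integers(5, 10))))
    ga = rng.choice(list("GA"), size=24, p=[0.35, 0.65])     # G+A-rich tract
    parts.append("".join(ga))
    if cfg.cr_repeats:
        unit_len, copies = cfg.cr_repeats
        unit = _random_seq(rng, unit_len, probs, max_run=4)
        parts.append(fill(6))
        parts.append(unit * copies)
    core = "".join(parts)
    if len(core) < cfg.cr_length:
        core += fill(cfg.cr_length - len(core))
    if not cfg.cr_elements:
        core = _random_seq(rng, max(len(core), cfg.cr_length), probs, max_run=4)
    if cfg.cr_orientation == "inverted":
        core = revcomp(core)
    return core, cfg.cr_orientation


def make_control_region(seed: int, orientation: str = "forward",
                        config: Optional[GeneratorConfig] = None) -> str:
    """A standalone control-region sequence with the five canonical elements."""
    cfg = replace(config or GeneratorConfig(), cr_orientation=orientation)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 211]))
    seq, _ = _build_cr(rng, cfg)
    return seq


def random_at_rich(rng_or_seed, length: int = 575,
                   at_content: float = 0.93) -> str:
    """An element-free A+T-matched random string (null model for CR scans)."""
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    at = at_content
    probs = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    return _random_seq(rng, length, probs, max_run=6)


# --------------------------------------------------------------------------
# genome assembly from blocks


@dataclass
class _Block:
    label: Optional[str]        # None for anonymous spacers/remnants
    plus_seq: str               # sequence as it appears on the plus strand
    strand: str = "+"
    kind: str = "spacer"
    anticodon: Optional[str] = None
    duplicate: bool = False


def _blocks_to_genome(blocks: list[_Block], genome_id: str) -> AnnotatedGenome:
    seq_parts = []
    features = []
    pos = 0
    for b in blocks:
        if b.label is not None:
            features.append(GeneFeature(
                b.label, pos, pos + len(b.plus_seq), b.strand, b.kind,
                anticodon=b.anticodon, duplicate=b.duplicate))
        seq_parts.append(b.plus_seq)
        pos += len(b.plus_seq)
    return AnnotatedGenome(genome_id, "".join(seq_parts), features)


def _genome_to_blocks(genome: AnnotatedGenome) -> list[_Block]:
    """Decompose a genome into gene blocks and anonymous spacer blocks."""
    feats = sorted(genome.features, key=lambda f: f.start)
    blocks: list[_Block] = []
    pos = 0
    for f in feats:
        if f.start > pos:
            blocks.append(_Block(None, genome.sequence[pos:f.start]))
        blocks.append(_Block(f.name, genome.plus_span(f), f.strand, f.kind,
                             f.anticodon, f.duplicate))
        pos = max(pos, f.end)
    if pos < genome.length:
        blocks.append(_Block(None, genome.sequence[pos:]))
    return blocks


def make_ancestral(config: GeneratorConfig = GeneratorConfig()
                   ) -> tuple[AnnotatedGenome, GroundTruth]:
    """A complete synthetic mitogenome in the ancestral hexapod arrangement.

    37 genes plus the control region; protein-coding genes begin ATN, end TAA
    and contain no internal stops; composition on the majority strand matches
    the configured A+T content within the configured tolerance
    (rejection-sampled); the control region contains the five canonical
    elements in the configured orientation.
    """
    for attempt in range(20):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed & 0x7FFFFFFF, attempt]))
        genome, truth = _make_ancestral_once(rng, config)
        from .composition import profile  # local import avoids a cycle
        measured = profile(genome, "whole").at_content / 100.0
        if abs(measured - config.at_content) <= config.composition_tolerance:
            return genome, truth
    raise ConfigError(
        f"could not reach A+T {config.at_content:.2%} within "
        f"{config.composition_tolerance:.2%} after 20 attempts")


def _make_ancestral_once(rng: np.random.Generator, cfg: GeneratorConfig
                         ) -> tuple[AnnotatedGenome, GroundTruth]:
    probs_plus = _base_probs(cfg)
    probs_minus = _complement_probs(probs_plus)
    blocks: list[_Block] = []
    cr_orientation = "forward"
    for label, sign in ANCESTRAL_ORDER:
        strand = "+" if sign > 0 else "-"
        kind = kind_of(label)
        # coding-strand composition chosen so the plus-strand image matches
        # the majority-strand targets
        coding_probs = probs_plus if strand == "+" else probs_minus
        anticodon = None
        if kind == "PCG":
            n_codons = cfg.gene_lengths[label] // 3
            coding = _random_cds(rng, n_codons, coding_probs)
        elif kind == "rRNA":
            coding = _random_seq(rng, cfg.gene_lengths[label], coding_probs)
        elif kind == "tRNA":
            coding = _random_seq(rng, cfg.trna_length, coding_probs)
            anticodon = {"trnK": "TTT", "trnS2": "TCT"}.get(label)
        else:  # control region
            coding, cr_orientation = _build_cr(rng, cfg)
        plus_seq = coding if strand == "+" else revcomp(coding)
        blocks.append(_Block(label, plus_seq, strand, kind, anticodon))
        if cfg.spacer_max > 0:
            gap = int(rng.integers(0, cfg.spacer_max + 1))
            if gap:
                blocks.append(_Block(None, _random_seq(rng, gap, probs_plus)))
    genome = _blocks_to_genome(blocks, f"synthetic-{cfg.seed}")
    truth = GroundTruth(
        expected_order=GeneOrder.from_genome(genome),
        statuses={lbl: "ancestral" for lbl, _ in ANCESTRAL_ORDER},
        remnants=[], cr_orientation=cr_orientation)
    return genome, truth


# --------------------------------------------------------------------------
# scripted rearrangement


def _gene_index(blocks: list[_Block], label: str) -> int:
    for i, b in enumerate(blocks):
        if b.label == label and not b.duplicate:
            return i
    raise ScriptError(f"gene {label} not found")


def _gene_positions(blocks: list[_Block]) -> list[int]:
    return [i for i, b in enumerate(blocks)
            if b.label is not None and not b.duplicate]


def _invert_block(b: _Block) -> _Block:
    return _Block(b.label, revcomp(b.plus_seq),
                  "-" if b.strand == "+" else "+", b.kind, b.anticodon,
                  b.duplicate)


def _make_remnant(rng: np.random.Generator, source: _Block, remnant: Remnant,
                  inverted_event: bool) -> Optional[_Block]:
    if remnant.kind == "none":
        return None
    if remnant.kind == "spacer":
        probs = np.array([0.45, 0.05, 0.05, 0.45])
        return _Block(None, _random_seq(rng, remnant.length, probs))
    if remnant.kind == "pseudogene":
        # the remnant keeps the ancestral plus-strand image; when the event
        # inverts the moved gene, the remnant therefore lies in the opposite
        # orientation to the moved copy (an "inverted pseudogene")
        seq = source.plus_seq
        n_mut = int(round(len(seq) * (1 - remnant.identity)))
        arr = list(seq)
        for i in rng.choice(len(arr), size=n_mut, replace=False):
            arr[i] = rng.choice([b for b in BASES if b != arr[i]])
        return _Block(None, "".join(arr))
    raise ScriptError(f"unknown remnant kind {remnant.kind}")


def apply_script(genome: AnnotatedGenome, script: Sequence[Event],
                 truth: Optional[GroundTruth] = None, seed: int = 0,
                 window: int = 3) -> tuple[AnnotatedGenome, GroundTruth]:
    """Apply scripted rearrangement events; return genome + ground truth.

    Moved genes carry their sequence; inversions reverse-complement.
    Remnant options leave a mutated pseudogene copy or an anonymous spacer at
    the source locus.  Expected per-gene statuses follow the adjacency
    semantics of the rearrangement classifier (see that module's docstring);
    an offset of +-1 in a shuffle is an adjacent transposition and marks both
    participants.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 917]))
    blocks = _genome_to_blocks(genome)
    truth = truth or GroundTruth(None, {}, [], "unknown")
    statuses = dict(truth.statuses) or {
        b.label: "ancestral" for b in blocks if b.label and not b.duplicate}
    remnants = list(truth.remnants)
    touched: set[str] = set()

    def claim(*genes: str) -> None:
        for g in genes:
            if g in touched:
                raise ScriptError(f"conflicting events on gene {g}")
            touched.add(g)

    for ev in script:
        if isinstance(ev, Shuffle):
            claim(ev.gene)
            if ev.offset == 0 or abs(ev.offset) > window:
                raise ScriptError(f"shuffle offset must be 1..{window} in "
                                  f"magnitude, got {ev.offset}")
            i = _gene_index(blocks, ev.gene)
            gp = _gene_positions(blocks)
            r = gp.index(i)
            target_rank = (r + ev.offset) % len(gp)
            block = blocks.pop(i)
            gp2 = _gene_positions(blocks)
            if ev.offset > 0:
                # insert after the gene now occupying the target rank
                anchor = gp2[(r + ev.offset - 1) % len(gp2)]
                blocks.insert(anchor + 1, block)
            else:
                anchor = gp2[(r + ev.offset) % len(gp2)]
                blocks.insert(anchor, block)
            statuses[ev.gene] = "shuffled"
            if abs(ev.offset) == 1:
                # adjacent transposition: the hopped-over gene is equally
                # displaced, and the classifier cannot (and should not)
                # prefer one participant
                hopped = blocks[anchor].label if ev.offset > 0 else \
                    blocks[anchor + 1].label
                if hopped:
                    statuses[hopped] = "shuffled"
        elif isinstance(ev, LocalInvert):
            claim(ev.gene)
            i = _gene_index(blocks, ev.gene)
            blocks[i] = _invert_block(blocks[i])
            statuses[ev.gene] = "local_inversion"
        elif isinstance(ev, (Translocate, RemoteInvert)):
            inverted = isinstance(ev, RemoteInvert)
            claim(ev.gene)
            i = _gene_index(blocks, ev.gene)
            block = blocks.pop(i)
            rem = _make_remnant(rng, block, ev.remnant, inverted)
            if rem is not None:
                blocks.insert(i, rem)
                remnants.append({"gene": ev.gene, "kind": ev.remnant.kind,
                                 "identity": ev.remnant.identity
                                 if ev.remnant.kind == "pseudogene" else None,
                                 "strand": "-" if inverted else "+"})
            if inverted:
                block = _invert_block(block)
            left, right = ev.dest
            li = _gene_index(blocks, left)
            ri = _gene_index(blocks, right)
            if not _adjacent_genes(blocks, li, ri):
                raise ScriptError(f"destination {ev.dest} is not a junction")
            blocks.insert(ri, block)
            statuses[ev.gene] = ("remote_inversion" if inverted
                                 else "translocation")
        elif isinstance(ev, BlockInvert):
            i = _gene_index(blocks, ev.first)
            j = _gene_index(blocks, ev.last)
            if j < i:
                raise ScriptError("block must not cross the origin")
            segment = blocks[i:j + 1]
            genes = [b.label for b in segment if b.label and not b.duplicate]
            claim(*genes)
            inverted_seg = [_invert_block(b) for b in reversed(segment)]
            blocks[i:j + 1] = inverted_seg
            if len(genes) == 1:
                statuses[genes[0]] = "local_inversion"
            else:
                for g in genes[1:-1]:
                    statuses[g] = "local_inversion"
                statuses[genes[0]] = "remote_inversion"
                statuses[genes[-1]] = "remote_inversion"
        elif isinstance(ev, Duplicate):
            i = _gene_index(blocks, ev.first)
            j = _gene_index(blocks, ev.last)
            if j < i:
                raise ScriptError("duplicated region must not cross the origin")
            copies = [replace(b) for b in blocks[i:j + 1]]
            copies = [_Block(b.label, b.plus_seq, b.strand, b.kind,
                             b.anticodon, duplicate=b.label is not None)
                      for b in copies]
            if ev.invert:
                copies = [_invert_block(b) for b in reversed(copies)]
            left, right = ev.dest
            ri = _gene_index(blocks, right)
            blocks[ri:ri] = copies
        else:
            raise ScriptError(f"unknown event {ev!r}")
        truth.events.append(repr(ev))

    result = _blocks_to_genome(blocks, genome.id)
    new_truth = GroundTruth(
        expected_order=GeneOrder.from_genome(result),
        statuses=statuses, remnants=remnants,
        cr_orientation=truth.cr_orientation, omega=dict(truth.omega),
        events=list(truth.events))
    return result, new_truth


def _adjacent_genes(blocks: list[_Block], li: int, ri: int) -> bool:
    """True when no gene block lies strictly between positions li and ri."""
    if ri < li:
        return False
    return all(blocks[k].label is None or blocks[k].duplicate
               for k in range(li + 1, ri))


# --------------------------------------------------------------------------
# sequence divergence at a target Ka/Ks


def _inverse_jc(k: float) -> float:
    """Difference proportion realizing JC distance ``k``."""
    return 0.75 * (1.0 - math.exp(-4.0 * k / 3.0))


def diverge_codons(codons: list[str], omega: float, target_ks: float,
                   rng: np.random.Generator,
                   max_factor: int = 400) -> list[str]:
    """Evolve a codon list to a target synonymous divergence.

    Uniform single-base codon changes are proposed; synonymous proposals are
    always accepted, nonsynonymous ones with probability ``omega``;
    stop-creating proposals are rejected.  Proposals continue until the
    number of accepted synonymous substitutions reaches the target implied by
    inverting the Jukes-Cantor correction of ``target_ks``, so multiple hits
    are accounted for.
    """
    if omega <= 0:
        raise ConfigError("omega must be positive")
    if not 0 <= target_ks < 0.7:
        raise ConfigError("target_ks must be in [0, 0.7)")
    if target_ks == 0:
        return list(codons)
    work = list(codons)
    S = sum(_SITES[c][0] for c in work if c in _SITES)
    target_syn = int(round(_inverse_jc(target_ks) * S))
    if target_syn == 0:
        return work
    n = len(work)
    accepted_syn = 0
    proposals = 0
    limit = max_factor * max(target_syn, 1) * 10
    while accepted_syn < target_syn:
        proposals += 1
        if proposals > limit:
            raise IterationLimitError(
                f"target Ks {target_ks} unreachable after {proposals} proposals")
        idx = int(rng.integers(n))
        cod = work[idx]
        if cod not in CODON_TO_AA:
            continue
        pos = int(rng.integers(3))
        base = BASES[int(rng.integers(4))]
        if base == cod[pos]:
            continue
        alt = cod[:pos] + base + cod[pos + 1:]
        if alt in STOP_CODONS:
            continue
        if CODON_TO_AA[alt] == CODON_TO_AA[cod]:
            work[idx] = alt
            accepted_syn += 1
        elif rng.random() < omega:
            work[idx] = alt
    return work


def diverge_pair(genome: AnnotatedGenome, omega, target_ks: float,
                 seed: int = 0) -> tuple[AnnotatedGenome, GroundTruth]:
    """A diverged copy of a genome at a target Ks and dN/dS.

    ``omega`` is a scalar or a per-gene mapping.  Protein-coding genes evolve
    codon-wise; non-coding positions (tRNAs, rRNAs, control region, spacers)
    substitute at the synonymous-equivalent per-site rate.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 31]))
    omega_of = (lambda g: float(omega[g])) if isinstance(omega, dict) \
        else (lambda g: float(omega))
    seq = list(genome.sequence)
    truth_omega: dict[str, float] = {}
    coding_mask = [False] * genome.length

    for f in genome.primary_features():
        if f.kind != "PCG":
            continue
        w = omega_of(f.name)
        truth_omega[f.name] = w
        coding = genome.feature_seq(f)
        n = len(coding) // 3
        codons = [coding[3 * i:3 * i + 3] for i in range(n)]
        evolved = diverge_codons(codons, w, target_ks, rng)
        new_coding = "".join(evolved) + coding[3 * n:]
        plus = new_coding if f.strand == "+" else revcomp(new_coding)
        for k, ch in enumerate(plus):
            p = (f.start + k) % genome.length
            seq[p] = ch
            coding_mask[p] = True

    p_site = _inverse_jc(target_ks)
    for i in range(genome.length):
        if not coding_mask[i] and rng.random() < p_site:
            seq[i] = rng.choice([b for b in BASES if b != seq[i]])

    out = AnnotatedGenome(genome.id + "-derived", "".join(seq),
                          list(genome.features), genome.circular,
                          genome.completeness)
    return out, GroundTruth(expected_order=GeneOrder.from_genome(out),
                            statuses={}, remnants=[],
                            cr_orientation="unknown", omega=truth_omega)


def random_codons(n_codons: int, rng_or_seed,
                  at_content: float = 0.85) -> list[str]:
    """Random sense codons with mitogenome-like composition (no stops)."""
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    at = at_content
    p = np.array([at / 2, (1 - at) / 2, (1 - at) / 2, at / 2])
    out = []
    while len(out) < n_codons:
        cod = "".join(rng.choice(list(BASES), size=3, p=p))
        if cod not in STOP_CODONS:
            out.append(cod)
    return out
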