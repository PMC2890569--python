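"""Structural annotation of the insect mitochondrial A+T-rich (control) region.

The region is scanned for the five canonical elements of the insect control
region: a polyT stretch near the 5' end, a [TA(A)]n-like stretch, a stem-loop
structure flanked by TATA and G(A)nT motifs, and a G+A-rich tract downstream
of the stem-loop.  Tandem repeats are found by k-mer diagonal self-comparison.
Because every element is strand-specific, the strand on which the canonical
5'->3' layout is best realised gives the region's orientation; an inverted
layout is the structural signature of a control-region inversion, as seen in
braconid wasps.

Element thresholds are heuristics calibrated against the synthetic generator
and an A+T-matched random null model, not biological constants; all are
exposed in :class:`ScanConfig`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ._seq import revcomp
from .composition import skew
from .genome_io import AnnotatedGenome

ELEMENT_KINDS = ("polyT", "TAA_repeat", "TATA_motif", "stem_loop",
                 "GAnT_motif", "GA_rich")
_CANONICAL_RANK = {k: i for i, k in enumerate(ELEMENT_KINDS)}


class RegionNotFoundError(ValueError):
    """No annotated control region and no plausible feature-free span."""


@dataclass(frozen=True)
class ScanConfig:
    """Element thresholds.

    Defaults are deliberately strict: in ~90% A+T sequence, short TATA-like
    motifs and weak hairpins occur constantly by chance, so the polyT
    stretch must be long, the stem perfect and at least 12 bp, and the TATA /
    G(A)nT motifs only count when anchored next to a stem-loop.
    """

    min_polyt: int = 14            # minimum T count, <=1 interruption allowed
    taa_min_copies: int = 5
    stem_range: tuple[int, int] = (12, 25)
    loop_range: tuple[int, int] = (3, 30)
    stem_max_mismatch: int = 0
    motif_flank: int = 30          # TATA / G(A)nT must be this close to the stem
    ga_min_window: int = 20
    ga_min_purine: float = 0.7


@dataclass(frozen=True)
class ElementHit:
    kind: str
    start: int
    end: int
    strand: str
    score: float


@dataclass(frozen=True)
class RepeatTrack:
    unit_length: int
    copy_number: float
    unit: str
    start: int
    end: int
    identity: float


@dataclass
class ControlRegionAnnotation:
    genome_id: str
    region: tuple[int, int]
    length: int
    at_content: float
    elements: list[ElementHit]
    repeats: list[RepeatTrack]
    orientation: str               # forward | inverted | indeterminate
    layout_scores: tuple[int, int]  # (plus, minus)


# --------------------------------------------------------------------------
# region location


def locate_region(genome: AnnotatedGenome, min_span: int = 100) -> tuple[int, int]:
    """Interval of the control region.

    Returns the annotated CR feature when present; otherwise the largest
    feature-free span (the usual location of an unannotated A+T-rich region).
    """
    for f in genome.primary_features():
        if f.kind == "control_region":
            return (f.start, f.end)
    gaps = genome.intergenic_intervals(min_length=min_span)
    if not gaps:
        raise RegionNotFoundError(
            f"{genome.id}: no CR feature and no feature-free span >= {min_span} bp")
    return max(gaps, key=lambda g: g[1] - g[0])


# --------------------------------------------------------------------------
# element scanning


def _poly_t(s: str, cfg: ScanConfig) -> Optional[tuple[int, int, int]]:
    """Longest T run allowing at most one single-base interruption."""
    runs = [(m.start(), m.end()) for m in re.finditer(r"T+", s)]
    best = None
    for i, (a, b) in enumerate(runs):
        cand = (b - a, a, b)
        if best is None or cand > best:
            best = cand
        if i + 1 < len(runs):
            c, d = runs[i + 1]
            if c - b == 1:  # single-character interruption
                cand = ((b - a) + (d - c), a, d)
                if cand > best:
                    best = cand
    if best and best[0] >= cfg.min_polyt:
        return best[1], best[2], best[0]
    return None


def _taa_copies(segment: str) -> int:
    """Maximum number of TA/TAA units tiling the segment exactly."""
    n = len(segment)
    INF = -1
    f = [INF] * (n + 1)
    f[0] = 0
    for i in range(n):
        if f[i] == INF:
            continue
        if segment[i:i + 2] == "TA" and f[i] + 1 > f[i + 2]:
            f[i + 2] = f[i] + 1
        if segment[i:i + 3] == "TAA" and f[i] + 1 > f[i + 3]:
            f[i + 3] = f[i] + 1
    return f[n] if f[n] != INF else 0


_BASE2COMP = np.zeros(256, dtype=np.uint8)
for _x, _y in zip(b"ACGTN", b"TGCAN"):
    _BASE2COMP[_x] = _y


def _best_hairpin(s: str, cfg: ScanConfig) -> Optional[tuple[int, int, int, int]]:
    """Best (start, end, stem_len, mismatches) hairpin, longest stem first."""
    n = len(s)
    k_lo, k_hi = cfg.stem_range
    l_lo, l_hi = cfg.loop_range
    if n < 2 * k_lo + l_lo:
        return None
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    rc = _BASE2COMP[arr]
    for k in range(min(k_hi, (n - l_lo) // 2), k_lo - 1, -1):
        sw = sliding_window_view(arr, k)
        swr = sliding_window_view(rc, k)[:, ::-1]
        best = None
        for loop in range(l_lo, min(l_hi, n - 2 * k) + 1):
            off = k + loop
            m = n - 2 * k - loop + 1
            if m <= 0:
                break
            mism = np.count_nonzero(sw[:m] != swr[off:off + m], axis=1)
            ok = np.flatnonzero(mism <= cfg.stem_max_mismatch)
            if ok.size:
                i = int(ok[mism[ok].argmin()])
                cand = (-int(mism[i]), -i, loop)
                if best is None or cand > best:
                    best = cand
        if best is not None:
            mismatches, i, loop = -best[0], -best[1], best[2]
            return i, i + 2 * k + loop, k, mismatches
    return None


def _scan_one_strand(s: str, cfg: ScanConfig) -> list[ElementHit]:
    """Element hits on one strand, in that strand's local 5'->3' coordinates."""
    hits: list[ElementHit] = []

    pt = _poly_t(s, cfg)
    if pt:
        hits.append(ElementHit("polyT", pt[0], pt[1], "+", pt[2]))

    for m in re.finditer(r"(?:TAA|TA)+", s):
        copies = _taa_copies(m.group())
        if copies >= cfg.taa_min_copies:
            hits.append(ElementHit("TAA_repeat", m.start(), m.end(), "+", copies))

    hp = _best_hairpin(s, cfg)
    if hp:
        start, end, stem, _mism = hp
        hits.append(ElementHit("stem_loop", start, end, "+", stem))
        lo = max(0, start - cfg.motif_flank)
        hi = min(len(s), end + cfg.motif_flank)
        for m in re.finditer(r"TATA", s[lo:start]):
            hits.append(ElementHit("TATA_motif", lo + m.start(), lo + m.end(), "+", 4))
        for m in re.finditer(r"GA{1,6}T", s[end:hi]):
            hits.append(ElementHit("GAnT_motif", end + m.start(), end + m.end(), "+",
                                   m.end() - m.start()))
        ga = _ga_rich(s, end, cfg)
        if ga:
            hits.append(ElementHit("GA_rich", ga[0], ga[1], "+", ga[2]))

    hits.sort(key=lambda h: (h.start, _CANONICAL_RANK[h.kind]))
    return hits


def _ga_rich(s: str, from_pos: int, cfg: ScanConfig) -> Optional[tuple[int, int, float]]:
    """Longest purine-rich window downstream of ``from_pos``."""
    tail = s[from_pos:]
    if len(tail) < cfg.ga_min_window:
        return None
    pur = np.frombuffer(tail.encode(), dtype=np.uint8)
    is_pur = ((pur == ord("G")) | (pur == ord("A"))).astype(np.int32)
    best = None
    left = 0
    count = 0
    for right in range(len(is_pur)):
        count += is_pur[right]
        while count < cfg.ga_min_purine * (right - left + 1) and left < right:
            count -= is_pur[left]
            left += 1
        width = right - left + 1
        if width >= cfg.ga_min_window:
            frac = count / width
            cand = (width, frac, left)
            if best is None or cand > best:
                best = cand
    if best is None:
        return None
    width, frac, left = best
    return from_pos + left, from_pos + left + width, frac


def scan_elements(region_seq: str, config: ScanConfig = ScanConfig()) -> list[ElementHit]:
    """Scan both strands of a control-region sequence for the five elements.

    Minus-strand hits are reported in plus-strand coordinates with
    ``strand='-'``.
    """
    if len(region_seq) < 50:
        raise ValueError("control region shorter than 50 bp")
    region_seq = region_seq.upper()
    L = len(region_seq)
    hits = list(_scan_one_strand(region_seq, config))
    for h in _scan_one_strand(revcomp(region_seq), config):
        hits.append(ElementHit(h.kind, L - h.end, L - h.start, "-", h.score))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


# --------------------------------------------------------------------------
# tandem repeats


def find_repeats(region_seq: str, min_unit: int = 20, min_copies: float = 2.0,
                 min_identity: float = 0.85) -> list[RepeatTrack]:
    """Tandem arrays via self-comparison over k-mer diagonals.

    For every candidate unit length ``d`` the sequence is compared with
    itself shifted by ``d``; the longest window whose match fraction stays at
    or above ``min_identity`` and which spans at least ``min_copies`` units
    defines a track.  Overlapping tracks are merged keeping the highest
    copy-number x identity product.
    """
    s = region_seq.upper()
    n = len(s)
    if n < 2 * min_unit:
        return []
    arr = np.frombuffer(s.encode(), dtype=np.uint8)
    candidates: list[RepeatTrack] = []
    mismatch_penalty = 3.0  # random ~41%-identity background scores negative
    for d in range(min_unit, n // 2 + 1):
        eq = arr[:-d] == arr[d:]
        scores = np.where(eq, 1.0, -mismatch_penalty)
        # best-scoring window on this diagonal (Kadane), so the track ends
        # where the self-similarity ends instead of degrading to the
        # identity floor
        best = None
        run_score = 0.0
        run_start = 0
        run_matches = 0
        for right in range(len(scores)):
            if run_score <= 0:
                run_score = 0.0
                run_start = right
                run_matches = 0
            run_score += scores[right]
            run_matches += int(eq[right])
            width = right - run_start + 1
            if run_score > 0 and width >= d * (min_copies - 1):
                ident = run_matches / width
                if ident >= min_identity:
                    cand = (run_score, width, ident, run_start)
                    if best is None or cand > best:
                        best = cand
        if best is not None:
            _score, width, ident, left = best
            span = width + d
            candidates.append(RepeatTrack(
                unit_length=d, copy_number=span / d, unit=s[left:left + d],
                start=left, end=left + span, identity=ident))
    candidates.sort(key=lambda t: -(t.copy_number * t.identity))
    kept: list[RepeatTrack] = []
    for t in candidates:
        if all(t.end <= k.start or t.start >= k.end for k in kept):
            kept.append(t)
    kept.sort(key=lambda t: t.start)
    return kept


# --------------------------------------------------------------------------
# orientation


def _layout_score(hits: list[ElementHit], strand: str) -> int:
    """Number of distinct element kinds on one strand in canonical order.

    Computed as the longest chain of hits whose canonical ranks strictly
    increase along the strand's own 5'->3' direction.  The chain must be
    anchored at a polyT hit: the polyT stretch defines the region's 5' end,
    and without that anchor a scatter of weak downstream motifs carries no
    orientation information.
    """
    mine = [h for h in hits if h.strand == strand]
    mine.sort(key=lambda h: h.start, reverse=(strand == "-"))
    best = 0
    scores: list[int] = []
    for i, h in enumerate(mine):
        if h.kind == "polyT":
            s = 1
        else:
            s = 0  # chains must start at polyT
            for j in range(i):
                if scores[j] and _CANONICAL_RANK[mine[j].kind] < _CANONICAL_RANK[h.kind]:
                    s = max(s, scores[j] + 1)
        scores.append(s)
        best = max(best, s)
    return best


def infer_orientation(region_seq: str, config: ScanConfig = ScanConfig()
                      ) -> tuple[str, tuple[int, int]]:
    """Orientation of the control region from its element layout.

    Returns ``(orientation, (plus_score, minus_score))`` where orientation is
    ``forward`` / ``inverted`` / ``indeterminate`` (tie or no elements).
    """
    hits = scan_elements(region_seq, config)
    plus = _layout_score(hits, "+")
    minus = _layout_score(hits, "-")
    if plus == minus:
        return "indeterminate", (plus, minus)
    return ("forward" if plus > minus else "inverted"), (plus, minus)


def annotate(genome: AnnotatedGenome, config: ScanConfig = ScanConfig(),
             min_unit: int = 20, min_identity: float = 0.85
             ) -> ControlRegionAnnotation:
    """Full control-region annotation for one genome.

    Element and repeat coordinates are local to the region interval.
    """
    region = locate_region(genome)
    seq = genome.interval_seq(*region)
    _, _, at = skew(seq)
    hits = scan_elements(seq, config)
    orientation, layout = infer_orientation(seq, config)
    repeats = find_repeats(seq, min_unit=min_unit, min_identity=min_identity)
    return ControlRegionAnnotation(
        genome_id=genome.id, region=region, length=len(seq), at_content=at,
        elements=hits, repeats=repeats, orientation=orientation,
        layout_scores=layout)
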