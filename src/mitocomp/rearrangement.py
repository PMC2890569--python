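"""Signed circular gene orders and rearrangement classification.

A mitochondrial gene order is modelled as a signed circular permutation of
canonical gene labels, normalized so that cox1 comes first with positive
sign (cox1 is unrearranged in all study taxa, making it a stable anchor; the
normalization also makes the order invariant under rotation of the circular
molecule and under reverse-complementing the whole genome).

Each gene is compared with the ancestral hexapod arrangement and assigned one
of five statuses:

* ``ancestral``       - still in place, same strand;
* ``shuffled``        - moved a short distance (<= window W gene ranks)
                        without changing strand;
* ``translocation``   - moved a long distance without changing strand;
* ``local_inversion`` - strand flipped but still between the same neighbours
                        ("inverted but remaining in the position");
* ``remote_inversion``- strand flipped and moved ("translocated and
                        inverted").

Positional identity is judged strand-blind on neighbour labels.  A gene
counts as *in place* when either both ancestral neighbours still flank it
(in any order: the interior of an inverted block keeps its neighbours), or
at least one oriented adjacency (same predecessor or same successor, reading
the circle in a fixed direction) survives.  The oriented clause keeps
bystander genes at an excision or insertion junction from being flagged,
while an adjacent transposition (the classic trnK/trnD swap) still marks
both participants as shuffled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import edlib
import pandas as pd

from ._seq import revcomp
from .genome_io import AnnotatedGenome, kind_of, PCG_LABELS, RRNA_LABELS

#: The ancestral hexapod (pancrustacean ground plan) signed gene order,
#: anchored at trnI with the control region closing the circle.
ANCESTRAL_ORDER: tuple[tuple[str, int], ...] = (
    ("trnI", +1), ("trnQ", -1), ("trnM", +1), ("nad2", +1), ("trnW", +1),
    ("trnC", -1), ("trnY", -1), ("cox1", +1), ("trnL2", +1), ("cox2", +1),
    ("trnK", +1), ("trnD", +1), ("atp8", +1), ("atp6", +1), ("cox3", +1),
    ("trnG", +1), ("nad3", +1), ("trnA", +1), ("trnR", +1), ("trnN", +1),
    ("trnS1", +1), ("trnE", +1), ("trnF", -1), ("nad5", -1), ("trnH", -1),
    ("nad4", -1), ("nad4l", -1), ("trnT", +1), ("trnP", -1), ("nad6", +1),
    ("cob", +1), ("trnS2", +1), ("nad1", -1), ("trnL1", -1), ("rrnL", -1),
    ("trnV", -1), ("rrnS", -1), ("CR", +1),
)

STATUSES = ("ancestral", "shuffled", "local_inversion", "translocation",
            "remote_inversion")


class AnchorError(ValueError):
    """cox1 missing: the order cannot be normalized."""


class OrderError(ValueError):
    """Unresolved duplicate labels or mismatched label sets."""


@dataclass(frozen=True)
class GeneOrder:
    """A signed circular gene order, canonically normalized."""

    genome_id: str
    order: tuple[tuple[str, int], ...]

    @staticmethod
    def normalize(entries: Sequence[tuple[str, int]], genome_id: str = "") -> "GeneOrder":
        labels = [lbl for lbl, _ in entries]
        if len(set(labels)) != len(labels):
            dups = sorted({l for l in labels if labels.count(l) > 1})
            raise OrderError(f"duplicate labels in order: {dups}")
        if "cox1" not in labels:
            raise AnchorError("cox1 absent: cannot anchor gene order")
        entries = list(entries)
        i = labels.index("cox1")
        if entries[i][1] < 0:
            entries = [(lbl, -s) for lbl, s in reversed(entries)]
            i = len(entries) - 1 - i
        entries = entries[i:] + entries[:i]
        return GeneOrder(genome_id, tuple(entries))

    @classmethod
    def from_genome(cls, genome: AnnotatedGenome, include_cr: bool = True,
                    projection: str = "full") -> "GeneOrder":
        feats = genome.primary_features()
        entries = []
        for f in feats:
            if f.kind == "control_region" and not include_cr:
                continue
            entries.append((f.name, +1 if f.strand == "+" else -1))
        order = cls.normalize(entries, genome.id)
        if projection != "full":
            order = order.project(projection, include_cr=include_cr)
        return order

    def project(self, projection: str, include_cr: bool = True) -> "GeneOrder":
        """Restrict to a label subset; ``pcg`` keeps PCGs + rRNAs (+ CR)."""
        if projection == "full":
            return self
        if projection != "pcg":
            raise ValueError(f"unknown projection {projection!r}")
        keep = set(PCG_LABELS) | set(RRNA_LABELS)
        if include_cr:
            keep.add("CR")
        entries = [(l, s) for l, s in self.order if l in keep]
        return GeneOrder.normalize(entries, self.genome_id)

    def restrict(self, labels) -> "GeneOrder":
        entries = [(l, s) for l, s in self.order if l in labels]
        return GeneOrder.normalize(entries, self.genome_id)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(l for l, _ in self.order)

    def signs(self) -> dict[str, int]:
        return dict(self.order)

    def adjacencies(self) -> set[tuple[tuple[str, int], tuple[str, int]]]:
        """Canonical signed circular adjacencies.

        The adjacency ((x, sx), (y, sy)) is equivalent to its reading on the
        other strand ((y, -sy), (x, -sx)); the lexicographically smaller form
        is stored.
        """
        adj = set()
        n = len(self.order)
        for i in range(n):
            x, y = self.order[i], self.order[(i + 1) % n]
            a = (x, y)
            b = ((y[0], -y[1]), (x[0], -x[1]))
            adj.add(min(a, b))
        return adj

    def __len__(self) -> int:
        return len(self.order)


#: The normalized ancestral order (anchored at cox1).
ANCESTRAL = GeneOrder.normalize(ANCESTRAL_ORDER, "ancestral")


def extract_order(genome: AnnotatedGenome, include_cr: bool = True) -> GeneOrder:
    """Signed circular gene order of a genome (duplicates excluded)."""
    return GeneOrder.from_genome(genome, include_cr=include_cr)


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of signed circular adjacencies of ``a`` absent from ``b``."""
    if set(a.labels) != set(b.labels):
        only_a = sorted(set(a.labels) - set(b.labels))
        only_b = sorted(set(b.labels) - set(a.labels))
        raise OrderError(f"label sets differ: only in a {only_a}, only in b {only_b}")
    return len(a.adjacencies() - b.adjacencies())


# --------------------------------------------------------------------------
# classification


@dataclass
class BlockEvent:
    event: str                 # local_inversion, remote_inversion, shuffled,
                               # translocation, or block_inversion etc.
    genes: tuple[str, ...]
    source_junction: tuple[Optional[str], Optional[str]]
    dest_junction: tuple[Optional[str], Optional[str]]
    notes: str = ""


@dataclass
class RearrangementReport:
    genome_id: str
    statuses: dict[str, str]
    skipped: list[str]
    blocks: list[BlockEvent]
    window: int
    projection: str

    @property
    def changed(self) -> list[str]:
        return [g for g, s in self.statuses.items() if s != "ancestral"]

    def changed_counts(self) -> dict[str, int]:
        counts = {"PCG": 0, "tRNA": 0, "rRNA": 0, "control_region": 0}
        for g in self.changed:
            counts[kind_of(g)] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gene": g, "kind": kind_of(g), "status": s}
                for g, s in self.statuses.items()]
        return pd.DataFrame(rows)


def _circular_maps(order: GeneOrder):
    labels = order.labels
    n = len(labels)
    pred = {labels[i]: labels[i - 1] for i in range(n)}
    succ = {labels[i]: labels[(i + 1) % n] for i in range(n)}
    rank = {labels[i]: i for i in range(n)}
    return pred, succ, rank


def classify(observed: GeneOrder, ancestral: Optional[GeneOrder] = None,
             window: int = 3, projection: str = "full",
             include_cr: bool = True) -> RearrangementReport:
    """Classify each gene's rearrangement status against an ancestral order.

    Genes absent from the observed order (unsequenced regions) are skipped
    and listed; the neighbours of a skipped gene bridge over the gap in both
    orders before comparison.  ``window`` is the shuffle-vs-translocation
    rank threshold W.
    """
    anc = ancestral if ancestral is not None else ANCESTRAL
    if projection != "full":
        observed = observed.project(projection, include_cr=include_cr)
        anc = anc.project(projection, include_cr=include_cr)
    elif not include_cr:
        observed = observed.restrict([l for l in observed.labels if l != "CR"])
        anc = anc.restrict([l for l in anc.labels if l != "CR"])

    common = set(observed.labels) & set(anc.labels)
    if len(common) < 3:
        raise OrderError("fewer than three genes shared with the ancestral order")
    skipped = sorted(set(anc.labels) - common)
    obs = observed.restrict(common)
    ref = anc.restrict(common)

    # The anchor normalization (cox1 positive) cannot distinguish "cox1
    # inverted in place" from "all other genes inverted": evaluate both
    # reflection interpretations and keep the more parsimonious one.
    reflected = GeneOrder(obs.genome_id,
                          tuple((l, -s) for l, s in reversed(obs.order)))
    best = None
    for candidate in (obs, reflected):
        statuses = _gene_statuses(candidate, ref, window)
        n_changed = sum(1 for s in statuses.values() if s != "ancestral")
        if best is None or n_changed < best[0]:
            best = (n_changed, candidate, statuses)
    _n, obs, statuses = best
    _rescue_bystanders(obs, ref, statuses)

    o_pred, o_succ, _ = _circular_maps(obs)
    a_pred, a_succ, _ = _circular_maps(ref)
    blocks = _block_events(obs, ref, statuses, a_pred, a_succ, o_pred, o_succ)
    return RearrangementReport(observed.genome_id, statuses, skipped, blocks,
                               window, projection)


def _gene_statuses(obs: GeneOrder, ref: GeneOrder, window: int) -> dict[str, str]:
    o_pred, o_succ, _o_rank = _circular_maps(obs)
    a_pred, a_succ, a_rank = _circular_maps(ref)
    o_sign, a_sign = obs.signs(), ref.signs()
    n = len(obs)

    def circ_dist(x: str, y: str) -> int:
        d = abs(a_rank[x] - a_rank[y])
        return min(d, n - d)

    statuses: dict[str, str] = {}
    for g in obs.labels:
        both_kept = {o_pred[g], o_succ[g]} == {a_pred[g], a_succ[g]}
        oriented_kept = (o_pred[g] == a_pred[g]) or (o_succ[g] == a_succ[g])
        in_place = both_kept or oriented_kept
        same_sign = o_sign[g] == a_sign[g]
        if in_place:
            statuses[g] = "ancestral" if same_sign else "local_inversion"
        elif not same_sign:
            statuses[g] = "remote_inversion"
        else:
            disp = min(circ_dist(g, o_pred[g]), circ_dist(g, o_succ[g]))
            statuses[g] = "shuffled" if disp <= window else "translocation"
    return statuses


def _rescue_bystanders(obs: GeneOrder, ref: GeneOrder,
                       statuses: dict[str, str]) -> None:
    """Unflag stationary genes stranded by the departure of both neighbours.

    A gene that never moved still loses both ancestral adjacencies when both
    of its flanking genes translocate away.  Such a gene is re-examined with
    every *other* changed gene bridged out of both orders: if its reduced
    neighbourhood is ancestral, it is reclassified as ancestral.  The rescue
    is refused when one of the bridged-out genes is an observed neighbour of
    the candidate (as in an adjacent transposition, where both participants
    are genuinely displaced relative to each other).
    """
    changed = {g for g, s in statuses.items() if s in ("shuffled",
                                                       "translocation")}
    o_pred, o_succ, _ = _circular_maps(obs)
    a_pred, a_succ, _ = _circular_maps(ref)
    for g in sorted(changed):
        removed = changed - {g}
        if not removed:
            continue
        # a changed observed neighbour blocks the rescue only when it is
        # also an ancestral neighbour: then the two genes are displaced
        # relative to each other (adjacent transposition), not bystander
        # and newcomer
        anc_nbrs = {a_pred[g], a_succ[g]}
        if any(n in removed and n in anc_nbrs
               for n in (o_pred[g], o_succ[g])):
            continue
        keep = [l for l in obs.labels if l not in removed]
        r_obs = GeneOrder(obs.genome_id,
                          tuple(e for e in obs.order if e[0] in keep))
        r_ref = GeneOrder(ref.genome_id,
                          tuple(e for e in ref.order if e[0] in keep))
        ro_pred, ro_succ, _ = _circular_maps(r_obs)
        ra_pred, ra_succ, _ = _circular_maps(r_ref)
        both = {ro_pred[g], ro_succ[g]} == {ra_pred[g], ra_succ[g]}
        oriented = ro_pred[g] == ra_pred[g] or ro_succ[g] == ra_succ[g]
        if both or oriented:
            statuses[g] = "ancestral"


_FAMILY = {"local_inversion": "inversion", "remote_inversion": "inversion",
           "shuffled": "shuffle", "translocation": "translocation"}


def _block_events(obs: GeneOrder, ref: GeneOrder, statuses: dict[str, str],
                  a_pred, a_succ, o_pred, o_succ) -> list[BlockEvent]:
    """Greedily merge observed runs of adjacent same-family changed genes.

    Genes merge into one block only when they are also neighbours in the
    ancestral order, so independent events that happen to land next to each
    other stay separate.
    """
    labels = obs.labels
    n = len(labels)
    changed_idx = [i for i, g in enumerate(labels) if statuses[g] != "ancestral"]
    if not changed_idx:
        return []
    in_run = set(changed_idx)

    def mergeable(i: int, j: int) -> bool:
        gi, gj = labels[i], labels[j]
        if _FAMILY[statuses[gi]] != _FAMILY[statuses[gj]]:
            return False
        return gj in (a_pred[gi], a_succ[gi])

    runs: list[list[int]] = []
    visited = set()
    for i in changed_idx:
        if i in visited:
            continue
        run = [i]
        visited.add(i)
        j = (i + 1) % n
        while j in in_run and j not in visited and mergeable(run[-1], j):
            run.append(j)
            visited.add(j)
            j = (j + 1) % n
        k = (i - 1) % n
        while k in in_run and k not in visited and mergeable(run[0], k):
            run.insert(0, k)
            visited.add(k)
            k = (k - 1) % n
        runs.append(run)

    events = []
    for run in runs:
        genes = tuple(labels[i] for i in run)
        fam = _FAMILY[statuses[genes[0]]]
        if len(genes) == 1:
            ev = statuses[genes[0]]
        else:
            ev = f"block_{fam}"
        src = (a_pred[genes[0]], a_succ[genes[-1]])
        dst = (o_pred[genes[0]], o_succ[genes[-1]])
        events.append(BlockEvent(ev, genes, src, dst))
    return events


# --------------------------------------------------------------------------
# pseudogene remnants


@dataclass(frozen=True)
class PseudogeneHit:
    query: str
    interval: tuple[int, int]
    strand: str        # '+': same orientation as the query's coding sequence
    identity: float
    span: tuple[int, int]  # hit location within the genome (plus strand)


def find_pseudogene(genome: AnnotatedGenome, gene: str,
                    min_identity: float = 0.6,
                    min_interval: int = 20) -> list[PseudogeneHit]:
    """Search feature-free intervals for degenerate copies of a gene.

    The gene's coding sequence and its reverse complement are aligned
    (infix/local alignment) against every intergenic interval of at least
    ``min_interval`` bp; hits at or above ``min_identity`` are reported with
    the strand of the match.  The gene's own annotated copy is never hit
    because only feature-free intervals are searched.
    """
    feat = genome.get(gene)
    query = genome.feature_seq(feat)
    queries = {"+": query, "-": revcomp(query)}
    hits = []
    for (start, end) in genome.intergenic_intervals(min_length=min_interval):
        target = genome.interval_seq(start, end)
        for strand, q in queries.items():
            res = edlib.align(q, target, mode="HW", task="locations")
            if res["editDistance"] < 0:
                continue
            identity = 1.0 - res["editDistance"] / len(q)
            if identity >= min_identity and res["locations"]:
                s, e = res["locations"][0]
                hits.append(PseudogeneHit(
                    query=gene, interval=(start, end), strand=strand,
                    identity=identity,
                    span=(start + s, start + e + 1),
                ))
    # the forward and reverse alignments of one locus are alternative
    # interpretations: keep only the better one where spans overlap
    hits.sort(key=lambda h: -h.identity)
    kept: list[PseudogeneHit] = []
    for h in hits:
        if any(k.span[0] < h.span[1] and h.span[0] < k.span[1] for k in kept):
            continue
        kept.append(h)
    return kept
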