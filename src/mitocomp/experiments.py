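"""Recovery experiments on synthetic data.

Each experiment generates data with the synthetic module, runs the
corresponding analysis module, and scores the result against the generator's
ground truth.  They are the package's primary validation surface (no external
data needed) and are consumed both by the test suite and by the acceptance
script.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import control_region, evolrates, synthetic
from .rearrangement import ANCESTRAL_ORDER, classify, extract_order
from .synthetic import (GeneratorConfig, LocalInvert, RemoteInvert, Shuffle,
                        Translocate, make_ancestral, apply_script)

_GENES = [lbl for lbl, _ in ANCESTRAL_ORDER if lbl != "CR"]
_RANK = {lbl: i for i, (lbl, _) in enumerate(ANCESTRAL_ORDER)}
_N = len(ANCESTRAL_ORDER)


def _circ_dist(a: str, b: str) -> int:
    d = abs(_RANK[a] - _RANK[b])
    return min(d, _N - d)


def _junctions_avoiding(used: set[str], gene: str, min_dist: int) -> list[tuple[str, str]]:
    """Ancestral junctions far from a gene and not touching used genes.

    The wrap junction (CR -> trnI) is excluded so scripted insertions never
    cross the sequence origin.
    """
    out = []
    labels = [lbl for lbl, _ in ANCESTRAL_ORDER]
    for i in range(len(labels) - 1):
        left, right = labels[i], labels[i + 1]
        if gene in (left, right):
            continue
        if left in used or right in used:
            continue
        if min(_circ_dist(gene, left), _circ_dist(gene, right)) <= min_dist:
            continue
        out.append((left, right))
    return out


def _sample_event(rng: np.random.Generator, used: set[str], window: int = 3
                  ) -> Optional[synthetic.Event]:
    """One random rearrangement event avoiding genes in ``used``.

    Shuffle offsets are drawn from {2..W}: an offset of 1 is an adjacent
    transposition whose "moved gene" is ambiguous (see the generator's
    docstring), so the single-event recovery experiment avoids it.
    """
    kind = rng.choice(["shuffle", "local_invert", "translocate",
                       "remote_invert"])
    free = [g for g in _GENES if g not in used]
    rng.shuffle(free)
    for gene in free:
        neighbours = {labels for labels in _GENES
                      if _circ_dist(gene, labels) <= 1}
        if neighbours & used:
            continue
        if kind == "shuffle":
            offset = int(rng.integers(2, window + 1)) * (1 if rng.random() < 0.5 else -1)
            # reserve the hopped-over span plus one flank on each side, and
            # keep the move away from the origin wrap
            gi = _RANK[gene]
            lo, hi = min(gi, gi + offset), max(gi, gi + offset)
            if lo - 1 < 0 or hi + 1 > _N - 2:
                continue
            touched = {lbl for lbl, _ in ANCESTRAL_ORDER[lo - 1:hi + 2]}
            if (touched - {gene}) & used:
                continue
            used.update(touched)
            return Shuffle(gene, offset)
        if kind == "local_invert":
            used.update({gene} | neighbours)
            return LocalInvert(gene)
        dests = _junctions_avoiding(used | neighbours, gene, window + 1)
        if not dests:
            continue
        left, right = dests[int(rng.integers(len(dests)))]
        used.update({gene, left, right} | neighbours)
        if kind == "translocate":
            return Translocate(gene, (left, right))
        return RemoteInvert(gene, (left, right))
    return None


@dataclass
class RecoveryResult:
    n_scripts: int
    status_exact: float       # fraction of scripts with per-gene status == truth
    changed_exact: float      # fraction with changed/unchanged sets == truth
    type_accuracy: float      # per changed gene, status label accuracy


def single_event_recovery(n_scripts: int = 200, seed: int = 0,
                          window: int = 3) -> RecoveryResult:
    """Classify genomes carrying exactly one scripted event."""
    base, base_truth = make_ancestral(GeneratorConfig(seed=seed))
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 101]))
    exact = changed_ok = 0
    type_hits = type_total = 0
    done = 0
    while done < n_scripts:
        ev = _sample_event(rng, set(), window)
        if ev is None:
            continue
        genome, truth = apply_script(base, [ev], truth=base_truth,
                                     seed=int(rng.integers(2 ** 31)),
                                     window=window)
        report = classify(extract_order(genome), window=window)
        exact += report.statuses == truth.statuses
        obs_changed = {g for g, s in report.statuses.items() if s != "ancestral"}
        true_changed = {g for g, s in truth.statuses.items() if s != "ancestral"}
        changed_ok += obs_changed == true_changed
        for g in true_changed:
            type_total += 1
            type_hits += report.statuses.get(g) == truth.statuses[g]
        done += 1
    return RecoveryResult(done, exact / done, changed_ok / done,
                          type_hits / type_total if type_total else 1.0)


def multi_event_recovery(n_scripts: int = 100, max_events: int = 5,
                         seed: int = 0, window: int = 3) -> RecoveryResult:
    """Classify genomes carrying up to ``max_events`` non-adjacent events."""
    base, base_truth = make_ancestral(GeneratorConfig(seed=seed))
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 103]))
    exact = changed_ok = 0
    type_hits = type_total = 0
    done = 0
    while done < n_scripts:
        used: set[str] = set()
        script = []
        n_events = int(rng.integers(1, max_events + 1))
        for _ in range(n_events):
            ev = _sample_event(rng, used, window)
            if ev is not None:
                script.append(ev)
        if not script:
            continue
        genome, truth = apply_script(base, script, truth=base_truth,
                                     seed=int(rng.integers(2 ** 31)),
                                     window=window)
        report = classify(extract_order(genome), window=window)
        exact += report.statuses == truth.statuses
        obs_changed = {g for g, s in report.statuses.items() if s != "ancestral"}
        true_changed = {g for g, s in truth.statuses.items() if s != "ancestral"}
        changed_ok += obs_changed == true_changed
        for g in true_changed:
            type_total += 1
            type_hits += report.statuses.get(g) == truth.statuses[g]
        done += 1
    return RecoveryResult(done, exact / done, changed_ok / done,
                          type_hits / type_total if type_total else 1.0)


def omega_recovery(omegas: Sequence[float] = (0.05, 0.1, 0.5, 1.0),
                   n_reps: int = 50, n_codons: int = 3000,
                   target_ks: float = 0.3, seed: int = 0
                   ) -> dict[float, float]:
    """Median Nei-Gojobori omega estimate per true omega."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 107]))
    medians = {}
    for omega in omegas:
        estimates = []
        for _ in range(n_reps):
            codons = synthetic.random_codons(n_codons, rng)
            derived = synthetic.diverge_codons(codons, omega, target_ks, rng)
            est = evolrates.nei_gojobori("".join(codons), "".join(derived))
            estimates.append(est.ratio)
        medians[omega] = statistics.median(estimates)
    return medians


def cr_orientation_experiment(n: int = 100, seed: int = 0,
                              config: Optional[control_region.ScanConfig] = None
                              ) -> float:
    """Fraction of generated control regions whose orientation is recovered."""
    cfg = config or control_region.ScanConfig()
    hits = 0
    for i in range(n):
        orientation = "forward" if i % 2 == 0 else "inverted"
        seq = synthetic.make_control_region(seed * 100003 + i, orientation)
        call, _scores = control_region.infer_orientation(seq, cfg)
        hits += call == orientation
    return hits / n


def cr_null_experiment(n: int = 100, seed: int = 0,
                       config: Optional[control_region.ScanConfig] = None
                       ) -> float:
    """Fraction of element-free A+T-matched strings left indeterminate."""
    cfg = config or control_region.ScanConfig()
    indeterminate = 0
    for i in range(n):
        seq = synthetic.random_at_rich(seed * 100003 + i, 575, 0.93)
        call, _scores = control_region.infer_orientation(seq, cfg)
        indeterminate += call == "indeterminate"
    return indeterminate / n
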