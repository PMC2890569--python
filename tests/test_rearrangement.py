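"""Gene-order extraction, breakpoint distance, event classification."""

import numpy as np
import pytest

from mitocomp.rearrangement import (
    ANCESTRAL, ANCESTRAL_ORDER, AnchorError, GeneOrder, OrderError,
    breakpoint_distance, classify, extract_order, find_pseudogene,
)
from mitocomp.synthetic import (
    BlockInvert, GeneratorConfig, LocalInvert, Remnant, RemoteInvert, Shuffle,
    Translocate, apply_script, make_ancestral,
)


def test_ancestral_order_constant():
    assert len(ANCESTRAL_ORDER) == 38
    assert ANCESTRAL.order[0] == ("cox1", 1)
    signs = dict(ANCESTRAL_ORDER)
    assert signs["trnQ"] == -1 and signs["nad5"] == -1 and signs["cox1"] == 1


def test_extract_order_identity(genome):
    assert extract_order(genome).order == ANCESTRAL.order


def test_extract_order_rotation_invariant(genome):
    assert extract_order(genome.rotated(5000)).order == ANCESTRAL.order


def test_extract_order_reflection_invariant(genome):
    assert extract_order(genome.reverse_complemented()).order == ANCESTRAL.order


def test_extract_order_requires_cox1(genome):
    from mitocomp.genome_io import AnnotatedGenome
    feats = [f for f in genome.primary_features() if f.name != "cox1"]
    g = AnnotatedGenome(genome.id, genome.sequence, feats)
    with pytest.raises(AnchorError):
        extract_order(g)


def _edited(order, edit):
    """Apply a label-level edit function to the ancestral entry list."""
    return GeneOrder.normalize(edit(list(order.order)), "edited")


def test_breakpoint_distance_identity():
    assert breakpoint_distance(ANCESTRAL, ANCESTRAL) == 0


def test_breakpoint_distance_single_inversion():
    def invert_nad3(entries):
        i = [l for l, _ in entries].index("nad3")
        entries[i] = ("nad3", -entries[i][1])
        return entries
    other = _edited(ANCESTRAL, invert_nad3)
    assert breakpoint_distance(ANCESTRAL, other) == 2
    assert breakpoint_distance(other, ANCESTRAL) == 2


def test_breakpoint_distance_single_translocation():
    def move_trnF(entries):
        i = [l for l, _ in entries].index("trnF")
        item = entries.pop(i)
        j = [l for l, _ in entries].index("cob")
        entries.insert(j, item)
        return entries
    other = _edited(ANCESTRAL, move_trnF)
    assert breakpoint_distance(ANCESTRAL, other) == 3


def test_breakpoint_distance_label_mismatch():
    smaller = ANCESTRAL.restrict([l for l in ANCESTRAL.labels if l != "CR"])
    with pytest.raises(OrderError):
        breakpoint_distance(ANCESTRAL, smaller)


def test_classify_self_is_all_ancestral():
    rng = np.random.default_rng(5)
    entries = list(ANCESTRAL_ORDER)
    for _ in range(10):
        rng.shuffle(entries)
        order = GeneOrder.normalize(
            [(l, int(s) * (1 if rng.random() < 0.5 else -1))
             for l, s in entries], "x")
        report = classify(order, ancestral=order)
        assert set(report.statuses.values()) == {"ancestral"}


def test_classify_ancestral_reports_no_change(genome):
    report = classify(extract_order(genome))
    assert set(report.statuses.values()) == {"ancestral"}
    assert sum(report.changed_counts().values()) == 0
    assert report.blocks == []


def test_classify_remote_inversion_of_trnH(genome, truth):
    g, t = apply_script(genome, [RemoteInvert("trnH", ("cox2", "trnK"))],
                        truth=truth, seed=1)
    report = classify(extract_order(g))
    assert report.statuses["trnH"] == "remote_inversion"
    changed = {k for k, v in report.statuses.items() if v != "ancestral"}
    assert changed == {"trnH"}


def test_classify_local_inversion_of_trnY(genome, truth):
    g, t = apply_script(genome, [LocalInvert("trnY")], truth=truth, seed=1)
    report = classify(extract_order(g))
    assert report.statuses["trnY"] == "local_inversion"


def test_classify_trnk_trnd_swap_marks_both_shuffled(genome, truth):
    g, t = apply_script(genome, [Shuffle("trnD", -1)], truth=truth, seed=1)
    report = classify(extract_order(g))
    assert report.statuses["trnK"] == "shuffled"
    assert report.statuses["trnD"] == "shuffled"


def test_classify_block_inversion(genome, truth):
    g, t = apply_script(genome, [BlockInvert("trnE", "cob")], truth=truth,
                        seed=1)
    report = classify(extract_order(g))
    block_genes = ("trnE", "trnF", "nad5", "trnH", "nad4", "nad4l", "trnT",
                   "trnP", "nad6", "cob")
    for gname in block_genes:
        assert report.statuses[gname] in ("local_inversion", "remote_inversion")
    events = [b for b in report.blocks if b.event == "block_inversion"]
    assert len(events) == 1
    assert set(events[0].genes) == set(block_genes)
    # adjacency inside the block is preserved, so breakpoints stay at the ends
    assert breakpoint_distance(extract_order(g), ANCESTRAL) == 2


def test_classify_missing_genes_are_skipped_and_bridged(genome, truth):
    from mitocomp.genome_io import AnnotatedGenome
    feats = [f for f in genome.primary_features()
             if f.name not in ("nad2", "trnW")]
    g = AnnotatedGenome(genome.id, genome.sequence, feats)
    report = classify(extract_order(g))
    assert report.skipped == ["nad2", "trnW"]
    assert set(report.statuses.values()) == {"ancestral"}


def test_classify_pcg_projection_ignores_trna_movement(genome, truth):
    # a tRNA translocation must not mark any protein-coding gene as changed
    g, t = apply_script(genome, [Translocate("trnF", ("cob", "trnS2"))],
                        truth=truth, seed=1)
    full = classify(extract_order(g), projection="full")
    pcg = classify(extract_order(g), projection="pcg")
    assert full.statuses["trnF"] == "translocation"
    assert set(pcg.statuses.values()) == {"ancestral"}


def test_classify_report_frame(genome):
    df = classify(extract_order(genome)).to_frame()
    assert set(df.columns) == {"gene", "kind", "status"}
    assert len(df) == 38


def test_classification_invariant_under_rotation_and_reflection(genome, truth):
    g, t = apply_script(
        genome,
        [RemoteInvert("trnH", ("cox2", "trnK")), Shuffle("trnW", 2)],
        truth=truth, seed=9)
    base = classify(extract_order(g)).statuses
    assert classify(extract_order(g.rotated(4000))).statuses == base
    assert classify(extract_order(g.reverse_complemented())).statuses == base


def test_breakpoint_distance_symmetry_and_growth(genome, truth):
    from mitocomp.experiments import _sample_event
    rng = np.random.default_rng(21)
    for _ in range(25):
        used = set()
        first = _sample_event(rng, used, 3)
        second = _sample_event(rng, used, 3)
        if first is None or second is None:
            continue
        g1, t1 = apply_script(genome, [first], truth=truth, seed=3)
        g2, t2 = apply_script(genome, [first, second], truth=truth, seed=3)
        o0, o1, o2 = ANCESTRAL, extract_order(g1), extract_order(g2)
        d01 = breakpoint_distance(o0, o1)
        assert d01 == breakpoint_distance(o1, o0)
        assert d01 > 0
        # appending a non-overlapping event never reduces the distance
        assert breakpoint_distance(o0, o2) >= d01


def test_find_pseudogene_inverted_remnant(genome, truth):
    g, t = apply_script(
        genome,
        [RemoteInvert("trnH", ("cox2", "trnK"),
                      remnant=Remnant("pseudogene", identity=0.9))],
        truth=truth, seed=4)
    hits = find_pseudogene(g, "trnH", min_identity=0.6)
    assert len(hits) == 1
    assert hits[0].strand == "-"
    assert hits[0].identity >= 0.85
    # the remnant sits in the ancestral trnH position: between nad4 and nad5
    nad4, nad5 = g.get("nad4"), g.get("nad5")
    lo, hi = sorted([nad4.start, nad4.end, nad5.start, nad5.end])[1:3]
    assert lo <= hits[0].span[0] <= hits[0].span[1] <= hi


def test_find_pseudogene_spacer_only_is_empty(genome, truth):
    g, t = apply_script(
        genome,
        [RemoteInvert("trnH", ("cox2", "trnK"),
                      remnant=Remnant("spacer", length=23))],
        truth=truth, seed=4)
    assert find_pseudogene(g, "trnH", min_identity=0.6) == []


def test_find_pseudogene_no_self_hit(genome):
    # an unrearranged gene must not match its own annotated copy
    assert find_pseudogene(genome, "trnH", min_identity=0.6) == []
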