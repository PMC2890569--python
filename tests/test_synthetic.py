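"""Generator determinism, closure, composition targets, scripted events."""

import numpy as np
import pytest

from mitocomp.composition import majority_strand, profile
from mitocomp.genome_io import validate_genome, write_genbank
from mitocomp.rearrangement import ANCESTRAL, extract_order
from mitocomp.synthetic import (
    BlockInvert, ConfigError, Duplicate, GeneratorConfig, LocalInvert,
    Remnant, RemoteInvert, ScriptError, Shuffle, Translocate, apply_script,
    diverge_codons, diverge_pair, make_ancestral, random_codons,
)


def test_generator_is_deterministic(tmp_path):
    g1, t1 = make_ancestral(GeneratorConfig(seed=99))
    g2, t2 = make_ancestral(GeneratorConfig(seed=99))
    p1, p2 = tmp_path / "a.gb", tmp_path / "b.gb"
    write_genbank(g1, p1)
    write_genbank(g2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert t1.statuses == t2.statuses


def test_generator_seeds_differ():
    g1, _ = make_ancestral(GeneratorConfig(seed=1))
    g2, _ = make_ancestral(GeneratorConfig(seed=2))
    assert g1.sequence != g2.sequence


def test_generator_closure_passes_validation(genome):
    report = validate_genome(genome)
    assert report.ok


def test_generator_order_is_ancestral(genome):
    assert extract_order(genome).order == ANCESTRAL.order


def test_generator_hits_composition_targets():
    g, _ = make_ancestral(GeneratorConfig(seed=31, at_content=0.85))
    p = profile(g, "whole")
    assert 84.0 <= p.at_content <= 86.0


def test_generator_hits_negative_gc_skew_target():
    # an ichneumonid-like (ancestral-asymmetry) genome
    g, _ = make_ancestral(GeneratorConfig(seed=32, gc_skew_majority=-0.20))
    p = profile(g, "whole")
    assert p.gc_skew == pytest.approx(-0.20, abs=0.03)
    assert majority_strand(g) == "+"


def test_generator_rejects_bad_config():
    with pytest.raises(ConfigError):
        GeneratorConfig(at_content=0.2)
    with pytest.raises(ConfigError):
        GeneratorConfig(cr_orientation="sideways")


def test_empty_script_is_identity(genome, truth):
    g2, t2 = apply_script(genome, [], truth=truth, seed=1)
    assert g2.sequence == genome.sequence
    assert extract_order(g2).order == extract_order(genome).order
    assert t2.statuses == truth.statuses


def test_script_moves_carry_sequence(genome, truth):
    before = genome.feature_seq(genome.get("trnH"))
    g2, _ = apply_script(genome, [Translocate("trnH", ("cox2", "trnK"))],
                         truth=truth, seed=1)
    assert g2.feature_seq(g2.get("trnH")) == before


def test_script_inversion_reverse_complements(genome, truth):
    before = genome.feature_seq(genome.get("trnY"))
    g2, _ = apply_script(genome, [LocalInvert("trnY")], truth=truth, seed=1)
    after = g2.get("trnY")
    assert g2.feature_seq(after) == before  # coding sequence preserved
    assert after.strand != genome.get("trnY").strand


def test_block_invert_preserves_internal_adjacency(genome, truth):
    g2, t2 = apply_script(genome, [BlockInvert("trnE", "cob")], truth=truth,
                          seed=1)
    order = extract_order(g2)
    labels = list(order.labels)
    i = labels.index("cob")
    block = labels[i:i + 10]
    assert block == ["cob", "nad6", "trnP", "trnT", "nad4l", "nad4", "trnH",
                     "nad5", "trnF", "trnE"]
    signs = order.signs()
    anc = dict(ANCESTRAL.order)
    assert all(signs[g] == -anc[g] for g in block)


def test_conflicting_events_raise(genome, truth):
    with pytest.raises(ScriptError):
        apply_script(genome, [LocalInvert("trnY"), LocalInvert("trnY")],
                     truth=truth, seed=1)


def test_trni_trnm_cr_inversion_pattern(genome, truth):
    """The braconid-like derived pattern around the control region."""
    g2, t2 = apply_script(
        genome,
        [BlockInvert("trnI", "trnM")],
        truth=truth, seed=1)
    order = list(extract_order(g2).order)
    labels = [l for l, _ in order]
    i = labels.index("trnM")
    assert labels[i:i + 4] == ["trnM", "trnQ", "trnI", "nad2"]
    signs = dict(order)
    assert signs["trnI"] == -1 and signs["trnM"] == -1


def test_duplicate_event_flags_copies(genome, truth):
    g2, _ = apply_script(genome, [Duplicate("cob", "cob", ("rrnS", "CR"))],
                         truth=truth, seed=1)
    cobs = [f for f in g2.features if f.name == "cob"]
    assert len(cobs) == 2
    assert sum(f.duplicate for f in cobs) == 1
    # the duplicate is excluded from the gene order
    assert extract_order(g2).labels.count("cob") == 1


def test_pseudogene_remnant_identity(genome, truth):
    g2, t2 = apply_script(
        genome,
        [RemoteInvert("trnH", ("cox2", "trnK"),
                      remnant=Remnant("pseudogene", identity=0.9))],
        truth=truth, seed=2)
    assert t2.remnants[0]["gene"] == "trnH"
    assert t2.remnants[0]["strand"] == "-"
    # the moved gene keeps its sequence and the remnant copy is added
    assert g2.length == genome.length + len(genome.get("trnH"))


def test_spacer_remnant_changes_length(genome, truth):
    g2, _ = apply_script(
        genome,
        [Translocate("trnH", ("cox2", "trnK"),
                     remnant=Remnant("spacer", length=52))],
        truth=truth, seed=2)
    # the gene keeps its sequence at the destination; the spacer is added
    assert g2.length == genome.length + 52


def test_diverge_zero_ks_is_identity(genome):
    derived, _ = diverge_pair(genome, 0.5, 0.0, seed=1)
    assert derived.sequence == genome.sequence


def test_diverge_codons_rejects_bad_targets():
    codons = random_codons(100, 1)
    with pytest.raises(ConfigError):
        diverge_codons(codons, 0.0, 0.3, np.random.default_rng(1))
    with pytest.raises(ConfigError):
        diverge_codons(codons, 0.5, 0.9, np.random.default_rng(1))


def test_diverge_codons_never_creates_stops():
    from mitocomp.evolrates import STOP_CODONS
    rng = np.random.default_rng(12)
    codons = random_codons(500, rng)
    derived = diverge_codons(codons, 1.0, 0.5, rng)
    assert not any(c in STOP_CODONS for c in derived)


def test_diverge_pair_keeps_annotations(genome):
    derived, truth = diverge_pair(genome, 0.1, 0.2, seed=7)
    assert derived.length == genome.length
    assert [f.name for f in derived.primary_features()] == \
        [f.name for f in genome.primary_features()]
    assert validate_genome(derived).missing == []
    assert truth.omega["cox1"] == 0.1
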