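"""Nei-Gojobori site counting, pathway averaging, JC correction.

The brute-force oracles here are independent re-derivations: site fractions
are enumerated straight from Biopython's table-5 translation, and pathway
averages from explicit permutation enumeration.
"""

import math
from itertools import permutations, product

import numpy as np
import pytest
from Bio.Seq import Seq

from mitocomp.evolrates import (
    CodonSkip, InsufficientDataError, NoValidPathway, SaturationError,
    codon_diffs, codon_sites, genome_rates, jukes_cantor, nei_gojobori,
)
from mitocomp.synthetic import (
    GeneratorConfig, diverge_codons, diverge_pair, make_ancestral,
    random_codons,
)

BASES = "ACGT"


def _aa(codon):
    return str(Seq(codon).translate(table=5))


def _is_stop(codon):
    return _aa(codon) == "*"


def oracle_sites(codon):
    """Independent enumeration of synonymous site fractions."""
    s = 0.0
    for pos in range(3):
        syn = valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1:]
            if _is_stop(alt):
                continue
            valid += 1
            syn += _aa(alt) == _aa(codon)
        if valid:
            s += syn / valid
    return s


def oracle_diffs(a, b):
    """Independent pathway enumeration of sd/nd."""
    diff = [i for i in range(3) if a[i] != b[i]]
    results = []
    for path in permutations(diff):
        cur, sd, nd = a, 0, 0
        ok = True
        for pos in path:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if _is_stop(nxt):
                ok = False
                break
            if _aa(nxt) == _aa(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((sd, nd))
    if not results:
        return None
    return (sum(r[0] for r in results) / len(results),
            sum(r[1] for r in results) / len(results))


def all_sense_codons():
    return [a + b + c for a, b, c in product(BASES, repeat=3)
            if not _is_stop(a + b + c)]


def test_codon_sites_against_oracle_for_all_sense_codons():
    for codon in all_sense_codons():
        s, n = codon_sites(codon)
        assert s == pytest.approx(oracle_sites(codon))
        assert s + n == pytest.approx(3.0)


@pytest.mark.parametrize("codon,s", [
    ("TTT", 1 / 3),   # Phe: only third-position TTC is synonymous
    ("GGG", 1.0),     # Gly: fourfold-degenerate third position
])
def test_codon_sites_known_values(codon, s):
    assert codon_sites(codon)[0] == pytest.approx(s)


def test_tga_is_sense_under_mito_code():
    # tryptophan in the invertebrate mitochondrial code, not a stop
    s, n = codon_sites("TGA")
    assert s + n == pytest.approx(3.0)


def test_codon_sites_rejects_stop_and_ambiguity():
    for bad in ("TAA", "TAG", "TTN", "TT"):
        with pytest.raises(CodonSkip):
            codon_sites(bad)


def test_codon_diffs_examples():
    assert codon_diffs("TTT", "TTC") == (1.0, 0.0)
    assert codon_diffs("TTT", "TTT") == (0.0, 0.0)
    sd, nd = codon_diffs("TTT", "GTC")
    assert sd + nd == pytest.approx(2.0)
    assert (sd, nd) == oracle_diffs("TTT", "GTC")


def test_codon_diffs_against_oracle_random_pairs():
    rng = np.random.default_rng(17)
    sense = all_sense_codons()
    checked = 0
    for _ in range(300):
        a, b = rng.choice(sense, size=2)
        expected = oracle_diffs(a, b)
        if expected is None:
            with pytest.raises(NoValidPathway):
                codon_diffs(a, b)
        else:
            assert codon_diffs(a, b) == pytest.approx(expected)
            checked += 1
    assert checked > 250


def test_jukes_cantor_correction_properties():
    for p in (0.01, 0.1, 0.3, 0.5, 0.7):
        assert jukes_cantor(p) > p
    assert jukes_cantor(0.0) == 0.0
    # monotone increasing
    grid = [jukes_cantor(p) for p in np.linspace(0, 0.7, 20)]
    assert all(a < b for a, b in zip(grid, grid[1:]))
    with pytest.raises(SaturationError):
        jukes_cantor(0.75)


def test_nei_gojobori_identical_sequences():
    seq = "".join(random_codons(100, 3))
    est = nei_gojobori(seq, seq)
    assert est.Ks == est.Ka == 0.0
    assert est.ratio is None
    assert est.S + est.N == pytest.approx(3 * est.n_codons)


def test_nei_gojobori_single_synonymous_change_closed_form():
    a = "TTT" * 100
    b = "TTC" + "TTT" * 99
    est = nei_gojobori(a, b)
    # S averages the two sequences: both give 100 * (1/3)
    S = 100 / 3
    assert est.S == pytest.approx(S)
    assert est.Sd == pytest.approx(1.0)
    assert est.Nd == pytest.approx(0.0)
    assert est.Ks == pytest.approx(-0.75 * math.log(1 - (4 / 3) * (1 / S)))
    assert est.Ka == 0.0


def test_nei_gojobori_symmetry():
    rng = np.random.default_rng(5)
    a = random_codons(200, rng)
    b = diverge_codons(a, 0.5, 0.2, rng)
    e1 = nei_gojobori("".join(a), "".join(b))
    e2 = nei_gojobori("".join(b), "".join(a))
    assert (e1.S, e1.N, e1.Sd, e1.Nd, e1.Ks, e1.Ka) == \
        (e2.S, e2.N, e2.Sd, e2.Nd, e2.Ks, e2.Ka)


def test_nei_gojobori_excludes_gap_codons_pairwise():
    a = "TTT" * 40
    b = "---" + "TTT" * 39
    est = nei_gojobori(a, b)
    assert est.n_codons == 39


def test_nei_gojobori_insufficient_data():
    with pytest.raises(InsufficientDataError):
        nei_gojobori("TTT" * 10, "TTT" * 10)


def test_omega_recovery_small_median():
    # single 3000-codon pairs scatter around the truth with a slight upward
    # bias (two-state degeneracy classes saturate faster than Jukes-Cantor
    # assumes); the median of a handful stays within [0.08, 0.12] for a
    # true omega of 0.1
    rng = np.random.default_rng(8)
    estimates = []
    for _ in range(15):
        codons = random_codons(3000, rng)
        derived = diverge_codons(codons, 0.1, 0.3, rng)
        estimates.append(nei_gojobori("".join(codons), "".join(derived)).ratio)
    assert 0.08 <= float(np.median(estimates)) <= 0.12


def test_genome_rates_self_is_zero(genome):
    overall, per_gene, flagged = genome_rates(genome, genome)
    assert overall.Ks == overall.Ka == 0.0
    assert len(per_gene) == 13
    assert flagged == {}


def test_genome_rates_concatenated_between_per_gene_omegas(genome):
    omega = {f.name: (0.05 if i % 2 == 0 else 0.2)
             for i, f in enumerate(genome.primary_features())
             if f.kind == "PCG"}
    derived, truth = diverge_pair(genome, omega, 0.25, seed=3)
    overall, per_gene, flagged = genome_rates(genome, derived)
    assert flagged == {}
    assert 0.05 <= overall.ratio <= 0.2
    lows = [per_gene[g].ratio for g, w in omega.items() if w == 0.05
            and per_gene[g].ratio is not None]
    highs = [per_gene[g].ratio for g, w in omega.items() if w == 0.2
            and per_gene[g].ratio is not None]
    assert np.median(lows) < np.median(highs)


def test_genome_rates_flags_insufficient_gene(genome):
    derived, _ = diverge_pair(genome, 0.2, 0.2, seed=5)
    # atp8 has ~54 codons; with a 60-codon floor it must be flagged and
    # excluded while the concatenated estimate still succeeds
    overall, per_gene, flagged = genome_rates(genome, derived, min_codons=60)
    assert "atp8" in flagged
    assert "atp8" not in per_gene
    assert overall.n_codons > 3000
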