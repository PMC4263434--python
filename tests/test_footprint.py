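"""Substring-parsimony footprinting: oracles, planted recovery, invariants."""

import itertools

import pytest

from orchidcis.footprint import (
    FootprintParams,
    motif_map,
    pairwise_conserved,
    substring_parsimony,
    truncate_upstream,
)
from orchidcis.promoter import PromoterRecord
from orchidcis.simulate import PlantedMotif, PromoterSimSpec, gen_promoters

from conftest import random_seq

QUARTET = "((PeMADS3,PeMADS4),(PeMADS2,PeMADS5));"


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def kmers(seq, k):
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def oracle_pairwise_d0(a, b, k):
    """Brute force: k-mers occurring verbatim in both sequences."""
    return set(kmers(a, k)) & set(kmers(b, k))


def test_pairwise_identity_single_kmer():
    m = pairwise_conserved("ACGTACGTACG", "ACGTACGTACG", k=11, d=0)
    assert len(m) == 1
    assert m[0].ancestral == "ACGTACGTACG"
    assert m[0].parsimony_score == 0


def test_pairwise_disjoint_alphabets_share_nothing(rng):
    a = random_seq(rng, 200, alphabet="AC")
    b = random_seq(rng, 200, alphabet="GT")
    assert pairwise_conserved(a, b, k=11, d=0) == []


def test_pairwise_equals_bruteforce_enumeration(rng):
    for _ in range(10):
        a, b = random_seq(rng, 200), random_seq(rng, 200)
        got = {m.ancestral for m in pairwise_conserved(a, b, k=8, d=0, merge=False)}
        assert got == oracle_pairwise_d0(a, b, 8)


def test_pairwise_d1_scores_match_bruteforce(rng):
    for _ in range(5):
        a, b = random_seq(rng, 60), random_seq(rng, 60)
        got = {m.ancestral: m.parsimony_score
               for m in pairwise_conserved(a, b, k=6, d=1, merge=False)}
        # independent oracle: same candidate rule, direct double minimisation
        cands = set()
        for w in kmers(a, 6) + kmers(b, 6):
            cands.add(w)
            for i, base in enumerate(w):
                for nb in "ACGT":
                    cands.add(w[:i] + nb + w[i + 1 :])
        expect = {}
        for c in cands:
            da = min(hamming(c, w) for w in kmers(a, 6))
            db = min(hamming(c, w) for w in kmers(b, 6))
            if da + db <= 1:
                expect[c] = float(da + db)
        assert got == expect


def test_pairwise_merges_maximal_shared_run():
    core = "ACGTTGCAACTGGAT"  # non-repetitive 15-bp shared run
    a = "TTTT" + core + "GGGG"
    b = "CCAA" + core + "TTCC"
    merged = pairwise_conserved(a, b, k=11, d=0)
    assert any(m.ancestral == core and m.length == 15 for m in merged)
    raw = pairwise_conserved(a, b, k=11, d=0, merge=False)
    assert len(raw) >= len(merged)


def test_pairwise_rejects_oversized_k():
    with pytest.raises(ValueError, match="k="):
        pairwise_conserved("ACGT", "ACGTACGT", k=6, d=0)


def _promoters(seqs):
    return {name: seq for name, seq in seqs.items()}


def test_two_leaf_reduction_matches_pairwise(rng):
    tree = "(A,B);"
    for k, d in [(6, 0), (6, 1), (8, 0)]:
        for _ in range(7):
            a, b = random_seq(rng, 80), random_seq(rng, 80)
            pw = {m.ancestral: m.parsimony_score
                  for m in pairwise_conserved(a, b, k=k, d=d, merge=False)}
            tp = {m.ancestral: m.parsimony_score
                  for m in substring_parsimony(
                      {"A": a, "B": b}, tree,
                      FootprintParams(k=k, max_mutations=d, merge=False))}
            assert pw == tp


def test_planted_motif_recovered_at_score_zero(rng):
    spec = PromoterSimSpec(
        tree=QUARTET, root_length=200, per_branch_substitution_prob=0.1,
        planted_motifs=[PlantedMotif("ACGTTGCAACT", -100)], seed=11,
    )
    recs, _ = gen_promoters(spec)
    motifs = substring_parsimony(recs, QUARTET, FootprintParams(k=11))
    zero = [m for m in motifs if m.parsimony_score == 0]
    assert any("ACGTTGCAACT" in m.ancestral for m in zero)


def test_single_leaf_substitution_needs_budget_or_loss():
    base = "TTTTTTTTTTTTTTTTTTTT"
    planted = "ACGTTGCAACT"
    mutated = "ACGTTGCATCT"  # one substitution
    seqs = {
        "PeMADS3": base + planted + base,
        "PeMADS4": base + planted + base,
        "PeMADS2": base + planted + base,
        "PeMADS5": base + mutated + base,
    }
    strict = substring_parsimony(seqs, QUARTET, FootprintParams(k=11, max_mutations=0))
    assert not any(planted in m.ancestral for m in strict)
    with_loss = substring_parsimony(
        seqs, QUARTET, FootprintParams(k=11, max_mutations=0, max_losses=1)
    )
    hit = [m for m in with_loss if planted in m.ancestral]
    assert hit and hit[0].lost_leaves == frozenset({"PeMADS5"})
    assert hit[0].parsimony_score == 1  # loss_cost = D + 1 = 1
    relaxed = substring_parsimony(
        seqs, QUARTET, FootprintParams(k=11, max_mutations=1, merge=False)
    )
    hit = [m for m in relaxed if m.ancestral == planted]
    assert hit and hit[0].parsimony_score == 1 and not hit[0].lost_leaves


@pytest.mark.parametrize("m_subs,d", [(0, 0), (1, 0), (1, 1), (2, 1)])
def test_planted_recovery_iff_within_mutation_allowance(m_subs, d):
    """Over seeded replicates a motif planted with m substitutions is
    recovered exactly when m <= D."""
    recovered = 0
    reps = 25
    for seed in range(reps):
        spec = PromoterSimSpec(
            tree=QUARTET, root_length=150, per_branch_substitution_prob=0.15,
            planted_motifs=[
                PlantedMotif("GATTACACGTA", -80, substitutions={"PeMADS5": m_subs})
            ],
            seed=1000 + seed,
        )
        recs, truth = gen_promoters(spec)
        motifs = substring_parsimony(
            recs, QUARTET, FootprintParams(k=11, max_mutations=d, merge=False)
        )
        if any(m.ancestral == "GATTACACGTA" for m in motifs):
            recovered += 1
    if m_subs <= d:
        assert recovered == reps
    else:
        # chance re-creation of the planted k-mer by background mutation is
        # possible in principle but effectively never observed
        assert recovered <= 1


def test_monotonic_in_mutation_allowance(rng):
    for _ in range(5):
        seqs = {"A": random_seq(rng, 60), "B": random_seq(rng, 60),
                "C": random_seq(rng, 60)}
        tree = "(A,(B,C));"
        sets = []
        for d in (0, 1, 2):
            motifs = substring_parsimony(
                seqs, tree, FootprintParams(k=5, max_mutations=d, merge=False)
            )
            sets.append({m.ancestral for m in motifs})
        assert sets[0] <= sets[1] <= sets[2]


def test_motif_at_k_plus_one_implies_both_subwindows_at_k(rng):
    for _ in range(5):
        seqs = {"A": random_seq(rng, 120), "B": random_seq(rng, 120)}
        tree = "(A,B);"
        big = substring_parsimony(seqs, tree, FootprintParams(k=7, merge=False))
        small = {
            m.ancestral
            for m in substring_parsimony(seqs, tree, FootprintParams(k=6, merge=False))
        }
        for m in big:
            assert m.ancestral[:-1] in small and m.ancestral[1:] in small


def test_loss_never_hurts_remaining_leaves(rng):
    # the substitution part of the score over surviving leaves can only
    # shrink when a leaf is excused
    seqs = {"A": random_seq(rng, 80), "B": random_seq(rng, 80),
            "C": random_seq(rng, 80), "D": random_seq(rng, 80)}
    tree = "((A,B),(C,D));"
    no_loss = {
        m.ancestral: m.parsimony_score
        for m in substring_parsimony(
            seqs, tree, FootprintParams(k=4, max_mutations=2, merge=False))
    }
    with_loss = substring_parsimony(
        seqs, tree, FootprintParams(k=4, max_mutations=2, max_losses=1, merge=False)
    )
    for m in with_loss:
        subs = m.parsimony_score - 3 * len(m.lost_leaves)  # loss_cost = D+1 = 3
        if m.ancestral in no_loss:
            assert subs <= no_loss[m.ancestral]


def test_deterministic_output(rng):
    seqs = {"A": random_seq(rng, 100), "B": random_seq(rng, 100),
            "C": random_seq(rng, 100)}
    tree = "(A,(B,C));"
    params = FootprintParams(k=5, max_mutations=1)
    first = substring_parsimony(seqs, tree, params)
    second = substring_parsimony(seqs, tree, params)
    assert first == second


def test_leaf_sequence_mismatch_rejected(rng):
    with pytest.raises(ValueError, match="leaves"):
        substring_parsimony(
            {"A": "ACGTACGT"}, "(A,B);", FootprintParams(k=4)
        )


def test_motif_map_preserves_per_promoter_order():
    m1 = "AAAACCCC"
    m2 = "GGGGTTTT"
    seqs = {"p1": m1 + "ACGT" + m2, "p2": m2 + "ACGT" + m1}
    motifs = substring_parsimony(seqs, "(p1,p2);", FootprintParams(k=8))
    track = motif_map(seqs, motifs)
    p1 = track[track["promoter"] == "p1"]["ancestral"].tolist()
    p2 = track[track["promoter"] == "p2"]["ancestral"].tolist()
    assert p1 == [m1, m2] and p2 == [m2, m1]
    empty = motif_map(seqs, [])
    assert len(empty) == 0


def test_truncate_upstream_window():
    p = PromoterRecord("p", "A" * 1500 + "CGTA" * 25, 1500)
    t = truncate_upstream(p, 1300)
    assert len(t) == 1300 and t.tss_offset == 1300
    small = PromoterRecord("q", "ACGTACGT", 8)
    assert truncate_upstream(small, 1300) is small
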