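"""Bisulfite calling and methylation-sensitive digestion prediction."""

import re
from collections import Counter

import edlib
import numpy as np
import pytest

from orchidcis.methylation import (
    BisulfiteCloneSet,
    align_clone,
    call_methylation,
    cytosine_context,
    digest_predict,
)
from orchidcis.simulate import EpiSimSpec, gen_bisulfite

from conftest import random_seq


def test_align_identity(rng):
    ref = random_seq(rng, 120)
    ac = align_clone(ref, ref)
    assert ac.bases == ref and ac.identity == 1.0 and ac.ok


def test_align_fully_converted_clone(rng):
    ref = random_seq(rng, 120)
    clone = ref.replace("C", "T")
    ac = align_clone(ref, clone)
    assert ac.identity == 1.0
    for r, c in zip(ref, ac.bases):
        assert c == ("T" if r == "C" else r)


def test_align_internal_deletion_anchors_rest(rng):
    ref = random_seq(rng, 150)
    clone = ref[:60] + ref[70:]  # 10-bp internal deletion
    ac = align_clone(ref, clone)
    assert ac.bases.count("-") == 10
    anchored = [(r, c) for r, c in zip(ref, ac.bases) if c != "-"]
    assert all(r == c for r, c in anchored)
    # generic edit-distance oracle: treating C->T as free, the clone is
    # within one 10-bp deletion of the reference
    d = edlib.align(clone, ref, task="distance",
                    additionalEqualities=[("C", "T")])["editDistance"]
    assert d == 10


def test_low_identity_clone_flagged(rng):
    ref = random_seq(rng, 100, alphabet="AG")
    junk = random_seq(rng, 100, alphabet="CT")
    assert not align_clone(ref, junk).ok


def test_call_all_reference_clones_fully_methylated(rng):
    ref = "AACGTCCATG" * 5
    cs = BisulfiteCloneSet(ref, [(f"c{i}", ref) for i in range(5)])
    prof = call_methylation(cs)
    assert len(prof.calls) == ref.count("C")
    assert all(c.fraction == 1.0 for c in prof.calls)


def test_call_fully_converted_clones_unmethylated():
    ref = "AACGTCCATG" * 5
    conv = ref.replace("C", "T")
    cs = BisulfiteCloneSet(ref, [(f"c{i}", conv) for i in range(5)])
    prof = call_methylation(cs)
    assert all(c.fraction == 0.0 for c in prof.calls)
    assert all(c.n_total == 5 for c in prof.calls)


def test_caller_recovers_exact_truth_without_noise():
    spec = EpiSimSpec(reference_length=300, conversion_efficiency=1.0,
                      error_rate=0.0, seed=9)
    ref, clones, truth = gen_bisulfite(spec)
    prof = call_methylation(BisulfiteCloneSet(ref, clones))
    frame = prof.to_frame().set_index("position")
    for row in truth.itertuples():
        states = [int(s) for s in row.clone_states]
        assert frame.loc[row.position, "fraction"] == pytest.approx(np.mean(states))
        assert frame.loc[row.position, "context"] == row.context


def test_caller_within_binomial_bound_of_planted_probability():
    # per-site Bernoulli(0.8), 10 clones: mean absolute deviation of the
    # called fractions stays within 2*sqrt(p(1-p)/n)
    spec = EpiSimSpec(reference_length=400, p_cpg=0.8, p_chg=0.8, p_chh=0.8,
                      conversion_efficiency=1.0, error_rate=0.0,
                      n_clones=10, seed=17)
    ref, clones, _ = gen_bisulfite(spec)
    prof = call_methylation(BisulfiteCloneSet(ref, clones))
    fracs = prof.to_frame()["fraction"]
    mad = float(np.abs(fracs - 0.8).mean())
    assert mad <= 2 * np.sqrt(0.8 * 0.2 / 10)


def test_context_partition_and_examples(rng):
    assert cytosine_context("ACGT", 1) == "CpG"
    assert cytosine_context("ACTGA", 1) == "CHG"
    assert cytosine_context("ACTTA", 1) == "CHH"
    assert cytosine_context("AAC", 2) == "CHH"  # truncated 3' context
    seq = random_seq(rng, 500)
    for i, b in enumerate(seq):
        if b == "C":
            assert cytosine_context(seq, i) in {"CpG", "CHG", "CHH"}
    with pytest.raises(ValueError):
        cytosine_context("AAAA", 0)


def test_digest_blocking_truth_table():
    ref = "AACCGGTT"
    # unmethylated: both isoschizomers cut
    p = digest_predict(ref, [], ["HpaII", "MspI"])
    assert not any(p["HpaII"].blocked) and not any(p["MspI"].blocked)
    assert p["HpaII"].fragments == (3, 5)
    # inner C methylated (C mCGG): HpaII blocked, MspI cuts
    p = digest_predict(ref, [3], ["HpaII", "MspI"])
    assert p["HpaII"].blocked == (True,) and p["MspI"].blocked == (False,)
    # outer C methylated (mC CGG): both blocked
    p = digest_predict(ref, [2], ["HpaII", "MspI"])
    assert p["HpaII"].blocked == (True,) and p["MspI"].blocked == (True,)
    # stricter internal-only convention: outer methylation alone lets HpaII cut
    p = digest_predict(ref, [2], ["HpaII"], hpaii_rule="internal")
    assert p["HpaII"].blocked == (False,)
    # DraI ignores methylation entirely
    ref2 = "GGTTTAAACC"
    p = digest_predict(ref2, [9], ["DraI"])
    assert p["DraI"].fragments == (5, 5)


def test_digest_rejects_bad_input():
    with pytest.raises(ValueError, match="unknown enzyme"):
        digest_predict("AACCGG", [], ["EcoRI"])
    with pytest.raises(ValueError, match="not a reference C"):
        digest_predict("AACCGG", [0], ["HpaII"])


def oracle_fragments(ref, meth, enzymes, hpaii_rule="either"):
    """Independent cut-and-measure: regex site finding + list slicing."""
    cuts = set()
    for e in enzymes:
        site, off = {"HpaII": ("CCGG", 1), "MspI": ("CCGG", 1),
                     "DraI": ("TTTAAA", 3)}[e]
        for m in re.finditer(f"(?={site})", ref):
            i = m.start()
            if e == "HpaII":
                blocked = (i in meth or i + 1 in meth) if hpaii_rule == "either" \
                    else (i + 1 in meth)
            elif e == "MspI":
                blocked = i in meth
            else:
                blocked = False
            if not blocked:
                cuts.add(i + off)
    pieces = []
    prev = 0
    for c in sorted(cuts) + [len(ref)]:
        pieces.append(ref[prev:c])
        prev = c
    return Counter(len(p) for p in pieces if p)


def test_fragment_multiset_matches_oracle_on_long_random_sequence(rng):
    ref = random_seq(rng, 10_000)
    c_pos = [i for i, b in enumerate(ref) if b == "C"]
    meth = set(rng.choice(c_pos, size=len(c_pos) // 3, replace=False).tolist())
    for combo in (["HpaII"], ["MspI"], ["DraI"], ["DraI+HpaII"], ["HpaII+MspI"]):
        pred = digest_predict(ref, meth, combo)
        parts = combo[0].split("+")
        assert Counter(pred[combo[0]].fragments) == oracle_fragments(ref, meth, parts)
        assert sum(pred[combo[0]].fragments) == len(ref)


def test_methylation_monotonically_blocks_hpaii(rng):
    ref = random_seq(rng, 3000)
    c_pos = [i for i, b in enumerate(ref) if b == "C"]
    rng.shuffle(c_pos)
    meth = set()
    prev_cuts = None
    for i in range(0, len(c_pos), max(1, len(c_pos) // 10)):
        meth.update(c_pos[i : i + max(1, len(c_pos) // 10)])
        cuts = len(digest_predict(ref, meth, ["HpaII"])["HpaII"].cut_positions)
        if prev_cuts is not None:
            assert cuts <= prev_cuts
        prev_cuts = cuts
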