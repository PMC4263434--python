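"""Phylogenetic footprinting by substring parsimony.

Regulatory elements evolve more slowly than the non-coding background,
so short motifs unusually conserved across paralogous promoters are
candidate binding sites. Given promoter sequences at the leaves of a
phylogeny, a candidate ancestral k-mer is scored by the total number of
substitutions needed for every (non-lost) leaf sequence to contain a
descendant occurrence; whole clades may be excused ("motif loss") at a
penalty. Motifs whose substitution total stays within the mutation
allowance ``D`` are reported.

Scoring model
-------------
With a single candidate ancestral k-mer ``c`` the tree-wide score used
here is ``sum_over_leaves(min Hamming distance of c to any window of the
leaf) + loss_cost * n_lost_clades``. Candidates are the k-mers observed
in the leaves, extended by their 1-substitution neighbourhoods when
``D >= 1``; this is provably exact for ``D <= 1``, which covers the
settings used in practice (10/11-mers at D = 0, 12-mers at D = 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from orchidcis.promoter import PromoterRecord, revcomp

_BASES = "ACGT"


@dataclass(frozen=True)
class FootprintParams:
    """Search parameters for conserved-motif discovery.

    ``k`` is the motif size in bp; ``max_mutations`` (D) bounds the total
    substitutions over all retained leaves; ``loss_cost`` (default D+1)
    prices the loss of one clade so that at D=0 a loss can never stand in
    for a substitution unless explicitly budgeted; ``max_losses`` bounds
    the number of *leaves* excusable via clade losses (default 0).
    """

    k: int
    max_mutations: int = 0
    loss_cost: float | None = None
    max_losses: int = 0
    strands: Literal["forward", "both"] = "forward"
    merge: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_mutations < 0:
            raise ValueError("max_mutations must be >= 0")
        if self.loss_cost is None:
            object.__setattr__(self, "loss_cost", self.max_mutations + 1)
        if self.loss_cost <= 0:
            raise ValueError("loss_cost must be positive")
        if self.strands not in ("forward", "both"):
            raise ValueError("strands must be 'forward' or 'both'")


@dataclass(frozen=True)
class ConservedMotif:
    """A k-mer conserved across promoters under the parsimony budget.

    ``occurrences`` maps each non-lost leaf to its leftmost best
    occurrence ``(local_start, observed_kmer, substitutions)``;
    ``parsimony_score`` is total substitutions plus loss penalties.
    ``length`` exceeds ``len(ancestral) == k`` never; merged runs carry
    the maximal shared extension in ``ancestral`` with ``length`` set
    accordingly.
    """

    ancestral: str
    occurrences: Mapping[str, tuple[int, str, int]]
    lost_leaves: frozenset[str] = frozenset()
    parsimony_score: float = 0.0
    length: int = 0

    def __post_init__(self) -> None:
        if self.length == 0:
            object.__setattr__(self, "length", len(self.ancestral))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _windows(seq: str, k: int) -> list[str]:
    return [seq[i : i + k] for i in range(len(seq) - k + 1)]


def _min_hamming_hit(candidate: str, seq: str) -> tuple[int, int, str]:
    """Leftmost window of ``seq`` minimising Hamming distance to candidate."""
    best = (len(candidate) + 1, -1, "")
    k = len(candidate)
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        d = _hamming(candidate, w)
        if d < best[0]:
            best = (d, i, w)
            if d == 0:
                break
    return best


def _one_neighbourhood(kmer: str) -> set[str]:
    out = {kmer}
    for i, base in enumerate(kmer):
        for b in _BASES:
            if b != base:
                out.add(kmer[:i] + b + kmer[i + 1 :])
    return out


def _as_sequences(
    promoters: Sequence[PromoterRecord] | Mapping[str, str]
) -> dict[str, str]:
    if isinstance(promoters, Mapping):
        return {name: seq.upper() for name, seq in promoters.items()}
    return {p.id: p.sequence for p in promoters}


def _candidates(
    sequences: Mapping[str, str], k: int, d: int, strands: str
) -> set[str]:
    obs: set[str] = set()
    for seq in sequences.values():
        obs.update(_windows(seq, k))
        if strands == "both":
            obs.update(_windows(revcomp(seq), k))
    if d >= 1:
        obs = set().union(*(_one_neighbourhood(m) for m in obs))
    return obs


def _loss_sets(
    tree: dendropy.Tree, max_losses: int
) -> list[tuple[frozenset[str], int]]:
    """All ways to excuse clades: (lost leaf set, number of lost clades).

    Clades (internal or leaf nodes, root excluded) are dropped in
    disjoint combinations whose total leaf count stays within
    ``max_losses``.
    """
    clades: list[frozenset[str]] = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 0 < len(leaves) <= max_losses:
            clades.append(leaves)
    out: list[tuple[frozenset[str], int]] = [(frozenset(), 0)]
    for r in range(1, len(clades) + 1):
        for combo in itertools.combinations(clades, r):
            union: set[str] = set()
            total = 0
            ok = True
            for c in combo:
                if union & c:
                    ok = False
                    break
                union |= c
                total += len(c)
            if ok and total <= max_losses:
                out.append((frozenset(union), r))
    # dedupe by leaf set, keeping the fewest clades
    best: dict[frozenset[str], int] = {}
    for leaves, n in out:
        if leaves not in best or n < best[leaves]:
            best[leaves] = n
    return sorted(best.items(), key=lambda kv: (len(kv[0]), sorted(kv[0])))


def parse_tree(newick: str, leaf_names: Iterable[str] | None = None) -> dendropy.Tree:
    """Parse a Newick tree; optionally check its leaf set."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    if leaf_names is not None:
        have = {lf.taxon.label for lf in tree.leaf_node_iter()}
        want = set(leaf_names)
        if have != want:
            raise ValueError(
                f"tree leaves {sorted(have)} != promoter ids {sorted(want)}"
            )
    return tree


def substring_parsimony(
    promoters: Sequence[PromoterRecord] | Mapping[str, str],
    tree: dendropy.Tree | str,
    params: FootprintParams,
) -> list[ConservedMotif]:
    """Conserved k-mers across the tree's leaf promoters.

    Returns motifs whose total substitution count over non-lost leaves is
    at most ``params.max_mutations``, using at most ``params.max_losses``
    lost leaves (whole clades only). Results are sorted by parsimony
    score, then ancestral k-mer; identical inputs yield identical output.
    """
    sequences = _as_sequences(promoters)
    if isinstance(tree, str):
        tree = parse_tree(tree, sequences)
    else:
        parse_tree(tree.as_string(schema="newick"), sequences)
    short = min(map(len, sequences.values()))
    if params.k > short:
        raise ValueError(f"k={params.k} exceeds shortest sequence ({short} bp)")
    d = params.max_mutations
    cands = _candidates(sequences, params.k, d, params.strands)
    losses = _loss_sets(tree, params.max_losses)

    # exact-occurrence index per leaf: kmer -> leftmost (0, pos, kmer);
    # lets the D=0 case avoid any Hamming scan
    exact: dict[str, dict[str, tuple[int, int, str]]] = {}
    for leaf, seq in sequences.items():
        idx: dict[str, tuple[int, int, str]] = {}
        for i in range(len(seq) - params.k, -1, -1):
            w = seq[i : i + params.k]
            idx[w] = (0, i, w)
            if params.strands == "both":
                idx.setdefault(revcomp(w), (0, i, w))
        exact[leaf] = idx

    # window matrices for the vectorised Hamming search used when D >= 1
    win_mats: dict[str, np.ndarray] = {}
    if d >= 1:
        for leaf, seq in sequences.items():
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            win_mats[leaf] = np.lib.stride_tricks.sliding_window_view(arr, params.k)

    hit_cache: dict[tuple[str, str], tuple[int, int, str]] = {}

    def _scan_windows(cand: str, leaf: str) -> tuple[int, int, str]:
        cand_arr = np.frombuffer(cand.encode(), dtype=np.uint8)
        dists = (win_mats[leaf] != cand_arr).sum(axis=1)
        i = int(dists.argmin())  # leftmost minimum
        return int(dists[i]), i, sequences[leaf][i : i + params.k]

    def best_hit(cand: str, leaf: str) -> tuple[int, int, str]:
        found = exact[leaf].get(cand)
        if found is not None:
            return found
        if d == 0:
            return (1, -1, "")  # any positive distance disqualifies at D=0
        key = (cand, leaf)
        if key not in hit_cache:
            fwd = _scan_windows(cand, leaf)
            if params.strands == "both":
                rc = _scan_windows(revcomp(cand), leaf)
                hit_cache[key] = min(fwd, rc)
            else:
                hit_cache[key] = fwd
        return hit_cache[key]

    motifs: list[ConservedMotif] = []
    for cand in sorted(cands):
        best: ConservedMotif | None = None
        for lost, n_clades in losses:
            kept = [lf for lf in sorted(sequences) if lf not in lost]
            if not kept:
                continue
            subs = 0
            occ: dict[str, tuple[int, str, int]] = {}
            for leaf in kept:
                dist, pos, obs = best_hit(cand, leaf)
                subs += dist
                occ[leaf] = (pos, obs, dist)
                if subs > d:
                    break
            if subs > d:
                continue
            score = subs + params.loss_cost * n_clades
            cur = ConservedMotif(cand, occ, frozenset(lost), score)
            if best is None or (cur.parsimony_score, len(cur.lost_leaves)) < (
                best.parsimony_score,
                len(best.lost_leaves),
            ):
                best = cur
        if best is not None:
            motifs.append(best)
    motifs.sort(key=lambda m: (m.parsimony_score, m.ancestral))
    if params.merge:
        motifs = merge_motifs(motifs)
    return motifs


def pairwise_conserved(
    seq_a: str | PromoterRecord,
    seq_b: str | PromoterRecord,
    k: int,
    d: int = 0,
    merge: bool = True,
) -> list[ConservedMotif]:
    """Conserved k-mers between two sequences (two-leaf parsimony).

    For ``d = 0`` these are exactly the k-mers occurring verbatim in
    both sequences; a shared run longer than ``k`` is merged into one
    motif of maximal shared extension (disable with ``merge=False``).
    For ``d >= 1`` candidate k-mers (observed plus 1-neighbourhoods) are
    kept when the two minimal Hamming distances sum to at most ``d`` —
    for an observed candidate this is the pairwise Hamming distance to
    the other sequence's closest window.

    Implemented by direct enumeration over windows, independent of the
    tree machinery in :func:`substring_parsimony`.
    """
    a = seq_a.sequence if isinstance(seq_a, PromoterRecord) else seq_a.upper()
    b = seq_b.sequence if isinstance(seq_b, PromoterRecord) else seq_b.upper()
    if k > min(len(a), len(b)):
        raise ValueError(f"k={k} exceeds shortest sequence")
    if d == 0:
        cands = set(_windows(a, k)) & set(_windows(b, k))
    else:
        cands = set(_windows(a, k)) | set(_windows(b, k))
        cands = set().union(*(_one_neighbourhood(m) for m in cands))
    motifs = []
    for cand in sorted(cands):
        if d == 0:
            da, pa, wa = 0, a.find(cand), cand
            db, pb, wb = 0, b.find(cand), cand
        else:
            da, pa, wa = _min_hamming_hit(cand, a)
            db, pb, wb = _min_hamming_hit(cand, b)
        if da + db <= d:
            motifs.append(
                ConservedMotif(
                    cand,
                    {"A": (pa, wa, da), "B": (pb, wb, db)},
                    frozenset(),
                    float(da + db),
                )
            )
    motifs.sort(key=lambda m: (m.parsimony_score, m.ancestral))
    if merge:
        motifs = merge_motifs(motifs)
    return motifs


def merge_motifs(motifs: Sequence[ConservedMotif]) -> list[ConservedMotif]:
    """Merge overlapping k-mers arising from one longer shared substring.

    Two motifs chain when the second's ancestral is the first's shifted
    by one (suffix/prefix overlap of k-1), every leaf occurrence shifts
    by exactly +1, per-occurrence substitution counts and lost leaves
    agree. Each maximal chain is reported once with the maximal
    extension as ``ancestral`` and ``length`` set to its size; scores
    are taken from the chain's first motif.
    """
    if not motifs:
        return []
    by_key = {(m.ancestral, _occ_key(m)): m for m in motifs}
    successor: dict[tuple, tuple] = {}
    has_pred: set[tuple] = set()
    for key, m in by_key.items():
        nxt_occ = {
            leaf: (pos + 1, obs, subs) for leaf, (pos, obs, subs) in m.occurrences.items()
        }
        for key2, m2 in by_key.items():
            if key2 == key or m2.lost_leaves != m.lost_leaves:
                continue
            if m2.ancestral[: len(m.ancestral) - 1] != m.ancestral[1:]:
                continue
            if all(
                m2.occurrences.get(leaf, (None,))[0] == nxt_occ[leaf][0]
                and m2.occurrences[leaf][2] == m.occurrences[leaf][2]
                for leaf in m.occurrences
            ) and set(m2.occurrences) == set(m.occurrences):
                successor[key] = key2
                has_pred.add(key2)
                break
    merged: list[ConservedMotif] = []
    for key, m in by_key.items():
        if key in has_pred:
            continue
        chain = [m]
        cur = key
        while cur in successor:
            cur = successor[cur]
            chain.append(by_key[cur])
        ext = chain[0].ancestral + "".join(c.ancestral[-1] for c in chain[1:])
        first = chain[0]
        occ = {
            leaf: (pos, _extend_obs(chain, leaf), subs)
            for leaf, (pos, _, subs) in first.occurrences.items()
        }
        merged.append(
            replace(first, ancestral=ext, occurrences=occ, length=len(ext))
        )
    merged.sort(key=lambda m: (m.parsimony_score, m.ancestral))
    return merged


def _occ_key(m: ConservedMotif) -> tuple:
    return tuple(sorted((lf, pos) for lf, (pos, _, _) in m.occurrences.items()))


def _extend_obs(chain: Sequence[ConservedMotif], leaf: str) -> str:
    first = chain[0].occurrences[leaf][1]
    return first + "".join(c.occurrences[leaf][1][-1] for c in chain[1:])


def truncate_upstream(
    promoter: PromoterRecord, window: int = 1300
) -> PromoterRecord:
    """Restrict a promoter to the ``window`` bp immediately 5' of the TSS.

    Promoters shorter than the window are returned unchanged. The
    1.3-kb default matches the region conventionally analysed for these
    paralogous promoters.
    """
    upstream = promoter.sequence[: promoter.tss_offset]
    if len(upstream) <= window:
        return promoter
    return PromoterRecord(promoter.id, upstream[-window:], window)


def motif_map(
    promoters: Sequence[PromoterRecord] | Mapping[str, str],
    motifs: Sequence[ConservedMotif],
) -> pd.DataFrame:
    """Per-promoter ordered track of motif occurrences (Fig-style map).

    Motifs are labelled ``m1, m2, ...`` in their given order; rows are
    sorted by promoter then position, preserving each promoter's own
    occurrence order (which may differ between promoters).
    """
    sequences = _as_sequences(promoters)
    rows = []
    for idx, m in enumerate(motifs, start=1):
        for leaf, (pos, obs, subs) in m.occurrences.items():
            if leaf in sequences:
                rows.append(
                    {
                        "promoter": leaf,
                        "position": pos,
                        "motif": f"m{idx}",
                        "ancestral": m.ancestral,
                        "observed": obs,
                        "substitutions": subs,
                    }
                )
    frame = pd.DataFrame(
        rows,
        columns=["promoter", "position", "motif", "ancestral", "observed", "substitutions"],
    )
    return frame.sort_values(["promoter", "position"], kind="stable").reset_index(
        drop=True
    )


def plot_motif_map(track: pd.DataFrame, path: str, seq_lengths: Mapping[str, int]):
    """Render a simple box-track figure of a motif map to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    promoters = sorted(seq_lengths)
    labels = sorted(track["motif"].unique()) if len(track) else []
    cmap = plt.get_cmap("tab10")
    colors = {m: cmap(i % 10) for i, m in enumerate(labels)}
    fig, ax = plt.subplots(figsize=(8, 0.8 * max(len(promoters), 1) + 1))
    for y, prom in enumerate(promoters):
        ax.hlines(y, 0, seq_lengths[prom], color="0.7", lw=2)
        sub = track[track["promoter"] == prom]
        for _, row in sub.iterrows():
            ax.barh(
                y,
                len(row["observed"]),
                left=row["position"],
                height=0.5,
                color=colors[row["motif"]],
            )
    ax.set_yticks(range(len(promoters)), promoters)
    ax.set_xlabel("position (bp, local)")
    handles = [plt.Rectangle((0, 0), 1, 1, color=colors[m]) for m in labels]
    if labels:
        ax.legend(handles, labels, loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
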