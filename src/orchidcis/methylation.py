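"""Bisulfite methylation calling and methylation-sensitive digestion.

Bisulfite treatment deaminates unmethylated cytosine to uracil (read as
T after PCR) and leaves 5-methylcytosine intact, so comparing cloned
bisulfite products against the untreated reference calls methylation per
reference cytosine. Plant methylation is summarised in three sequence
contexts: CpG, CHG and CHH (H = A, C or T).

The same methylation state feeds an in-silico digestion model for the
isoschizomers HpaII and MspI (both cut CCGG but differ in methylation
sensitivity) plus the methylation-insensitive DraI (TTTAAA), predicting
the fragment patterns probed on Southern blots.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

H_BASES = frozenset("ACT")

#: enzyme -> (recognition site, cut offset within the site)
ENZYMES: dict[str, tuple[str, int]] = {
    "HpaII": ("CCGG", 1),  # C^CGG
    "MspI": ("CCGG", 1),  # C^CGG
    "DraI": ("TTTAAA", 3),  # TTT^AAA
}


@dataclass(frozen=True)
class CytosineCall:
    """Methylation call at one reference cytosine (top strand)."""

    ref_position: int
    context: str  # CpG / CHG / CHH
    n_methylated: int
    n_total: int

    @property
    def fraction(self) -> float:
        return self.n_methylated / self.n_total if self.n_total else float("nan")


@dataclass
class BisulfiteCloneSet:
    """An untreated reference plus bisulfite-converted clone sequences."""

    reference: str
    clones: list[tuple[str, str]]
    region_label: str = ""

    def __post_init__(self) -> None:
        self.reference = self.reference.upper()
        self.clones = [(cid, seq.upper()) for cid, seq in self.clones]
        if not self.clones:
            raise ValueError("at least one clone is required")


@dataclass(frozen=True)
class AlignedClone:
    """Per-reference-position clone bases ('-' where the clone has a gap)."""

    clone_id: str
    bases: str
    identity: float
    ok: bool


@dataclass(frozen=True)
class DigestPrediction:
    """Predicted cuts and fragments for one enzyme (or combination)."""

    enzyme: str
    site_positions: tuple[int, ...]
    blocked: tuple[bool, ...]
    cut_positions: tuple[int, ...]
    fragments: tuple[int, ...]


def _conversion_aware_aligner() -> Align.PairwiseAligner:
    # Global alignment where reference-C vs clone-T scores as a match,
    # since full bisulfite conversion is the expected signal, not noise.
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if "N" in (x, y):
                mat[x, y] = 0.0
            elif x == y or (x == "C" and y == "T"):
                mat[x, y] = 1.0
            else:
                mat[x, y] = -1.5
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = mat
    aligner.mode = "global"
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    aligner.end_gap_score = -1.0
    return aligner


_ALIGNER = _conversion_aware_aligner()


def align_clone(
    reference: str, clone: str, clone_id: str = "", min_identity: float = 0.8
) -> AlignedClone:
    """Anchor a bisulfite clone to its reference, tolerant of C->T changes.

    Returns the clone base over every reference position ('-' at clone
    gaps; clone insertions are dropped). ``identity`` counts reference
    positions whose clone base is compatible (equal, or C->T) among
    aligned positions; clones below ``min_identity`` are flagged
    ``ok=False`` so callers can exclude them.
    """
    reference = reference.upper()
    clone = clone.upper()
    aln = _ALIGNER.align(reference, clone)[0]
    bases = ["-"] * len(reference)
    for (rs, re_), (qs, qe) in zip(*aln.aligned):
        for off in range(re_ - rs):
            bases[rs + off] = clone[qs + off]
    aligned = [(r, c) for r, c in zip(reference, bases) if c != "-"]
    if aligned:
        compatible = sum(
            r == c or (r == "C" and c == "T") or "N" in (r, c) for r, c in aligned
        )
        identity = compatible / len(aligned)
    else:
        identity = 0.0
    ok = identity >= min_identity
    if not ok:
        logger.warning(
            "clone %s excluded: identity %.3f below floor %.2f",
            clone_id or "<unnamed>",
            identity,
            min_identity,
        )
    return AlignedClone(clone_id, "".join(bases), identity, ok)


def cytosine_context(reference: str, i: int) -> str:
    """CpG / CHG / CHH context of the cytosine at ``reference[i]``.

    Determined solely from the reference top strand; cytosines too close
    to the 3' end for their context to be resolved are classed CHH.
    """
    if reference[i] != "C":
        raise ValueError(f"position {i} is {reference[i]!r}, not C")
    nxt = reference[i + 1] if i + 1 < len(reference) else ""
    nxt2 = reference[i + 2] if i + 2 < len(reference) else ""
    if nxt == "G":
        return "CpG"
    if nxt in H_BASES and nxt2 == "G":
        return "CHG"
    return "CHH"


@dataclass
class MethylationProfile:
    """Per-cytosine methylation fractions for one region."""

    region_label: str
    calls: list[CytosineCall]
    n_clones_used: int
    excluded_clones: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "position": c.ref_position,
                    "context": c.context,
                    "n_methylated": c.n_methylated,
                    "n_total": c.n_total,
                    "fraction": c.fraction,
                }
                for c in self.calls
            ],
            columns=["position", "context", "n_methylated", "n_total", "fraction"],
        )

    def context_summary(self) -> pd.DataFrame:
        """Weighted mean methylation per context (conversion diagnostic:
        high CHH levels usually indicate incomplete conversion)."""
        frame = self.to_frame()
        rows = []
        for ctx in ("CpG", "CHG", "CHH"):
            sub = frame[frame["context"] == ctx]
            meth, tot = sub["n_methylated"].sum(), sub["n_total"].sum()
            rows.append(
                {
                    "context": ctx,
                    "n_sites": len(sub),
                    "fraction": meth / tot if tot else float("nan"),
                }
            )
        return pd.DataFrame(rows)


def call_methylation(
    cloneset: BisulfiteCloneSet, min_identity: float = 0.8
) -> MethylationProfile:
    """Call methylation at every reference cytosine from aligned clones.

    Clone base C at a reference C counts as methylated, T as
    unmethylated; any other base or a gap removes that clone from that
    site's denominator. Clones below the alignment identity floor are
    excluded wholesale (logged).
    """
    ref = cloneset.reference
    c_positions = [i for i, b in enumerate(ref) if b == "C"]
    if not c_positions:
        logger.warning("region %s: reference contains no cytosine", cloneset.region_label)
    aligned, excluded = [], []
    for cid, seq in cloneset.clones:
        ac = align_clone(ref, seq, cid, min_identity)
        (aligned if ac.ok else excluded).append(ac)
    calls = []
    for i in c_positions:
        counts = Counter(ac.bases[i] for ac in aligned)
        n_meth = counts["C"]
        n_total = counts["C"] + counts["T"]
        calls.append(CytosineCall(i, cytosine_context(ref, i), n_meth, n_total))
    return MethylationProfile(
        cloneset.region_label, calls, len(aligned), [a.clone_id for a in excluded]
    )


def _sites(reference: str, site: str) -> list[int]:
    out, start = [], 0
    while True:
        i = reference.find(site, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def _is_blocked(
    enzyme: str, pos: int, methylated: frozenset[int], hpaii_rule: str
) -> bool:
    # CCGG at pos: outer C = pos, inner C = pos + 1. Methylation is taken
    # as symmetric across strands, so a top-strand mark suffices to block.
    if enzyme == "DraI":
        return False
    outer, inner = pos, pos + 1
    if enzyme == "MspI":
        return outer in methylated
    if enzyme == "HpaII":
        if hpaii_rule == "either":
            return outer in methylated or inner in methylated
        if hpaii_rule == "internal":
            return inner in methylated
        raise ValueError(f"unknown HpaII rule {hpaii_rule!r}")
    raise ValueError(f"unknown enzyme {enzyme!r}")


def digest_predict(
    reference: str,
    methylated_positions: Iterable[int],
    enzymes: Sequence[str],
    hpaii_rule: str = "either",
) -> dict[str, DigestPrediction]:
    """Predict digestion fragments under a methylation state.

    ``enzymes`` may contain single enzymes (``"HpaII"``) or ``+``-joined
    double digests (``"DraI+HpaII"``), which cut at the union of the
    components' unblocked sites. HpaII is blocked when either cytosine
    of CCGG is methylated (``hpaii_rule="either"``; the stricter
    internal-C-only convention is available as ``"internal"``); MspI is
    blocked only by methylation of the outer (first) cytosine; DraI is
    insensitive. Fragment lengths always sum to the reference length
    (linear molecule).
    """
    reference = reference.upper()
    meth = frozenset(methylated_positions)
    for p in meth:
        if not (0 <= p < len(reference)) or reference[p] != "C":
            raise ValueError(f"methylated position {p} is not a reference C")
    out: dict[str, DigestPrediction] = {}
    for combo in enzymes:
        parts = [e.strip() for e in combo.split("+")]
        for e in parts:
            if e not in ENZYMES:
                raise ValueError(f"unknown enzyme {e!r}")
        sites: list[int] = []
        blocked: list[bool] = []
        cuts: set[int] = set()
        for e in parts:
            site, offset = ENZYMES[e]
            for pos in _sites(reference, site):
                b = _is_blocked(e, pos, meth, hpaii_rule)
                sites.append(pos)
                blocked.append(b)
                if not b:
                    cuts.add(pos + offset)
        cut_list = sorted(cuts)
        bounds = [0, *cut_list, len(reference)]
        fragments = tuple(
            b - a for a, b in zip(bounds, bounds[1:]) if b > a
        )
        out[combo] = DigestPrediction(
            combo, tuple(sites), tuple(blocked), tuple(cut_list), fragments
        )
    return out
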