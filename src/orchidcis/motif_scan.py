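"""Degenerate CArG-box consensus scanning.

MADS-domain transcription factors bind the quasi-palindromic CArG box.
Two published consensus rules are bundled:

- ``CCW6GG`` — the core consensus CC(A/T)6GG relaxed to a 9-of-10 match
  (one mismatch allowed);
- ``CW8G`` — the relaxed C(A/T)8G decamer, required to match exactly.

Both patterns are their own reverse complements as degenerate strings,
so forward-strand scanning already covers both strands for them; a
both-strand mode is retained for arbitrary patterns.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pandas as pd

from orchidcis.promoter import PromoterRecord, revcomp

# Allowed bases per pattern symbol. An N in the *sequence* matches only a
# pattern N (conservative calling).
SYMBOL_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "W": frozenset("AT"),
    "N": frozenset("ACGTN"),
}

_REV_SYMBOL = str.maketrans("ACGTWN", "TGCAWN")


@dataclass(frozen=True)
class ConsensusPattern:
    """A degenerate consensus with a mismatch budget.

    ``symbols`` is a string over ``{A, C, G, T, W, N}`` with W = A/T and
    N = any base; a window matches when the number of symbol violations
    is at most ``max_mismatches``.
    """

    name: str
    symbols: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", self.symbols.upper())
        if not self.symbols:
            raise ValueError("pattern must be non-empty")
        bad = set(self.symbols) - set(SYMBOL_SETS)
        if bad:
            raise ValueError(f"{self.name}: invalid pattern symbols {sorted(bad)!r}")
        if not 0 <= self.max_mismatches < len(self.symbols):
            raise ValueError(
                f"{self.name}: max_mismatches must lie in [0, {len(self.symbols)})"
            )

    def __len__(self) -> int:
        return len(self.symbols)

    def reverse_complement(self) -> "ConsensusPattern":
        rc = self.symbols.translate(_REV_SYMBOL)[::-1]
        return ConsensusPattern(f"{self.name}_rc", rc, self.max_mismatches)


#: Core CArG consensus CC(A/T)6GG at a 9-of-10 match standard.
CCW6GG = ConsensusPattern("CCW6GG", "CCWWWWWWGG", max_mismatches=1)
#: Relaxed CArG consensus C(A/T)8G, exact decamer match.
CW8G = ConsensusPattern("CW8G", "CWWWWWWWWG", max_mismatches=0)

PATTERNS = {p.name: p for p in (CCW6GG, CW8G)}


@dataclass(frozen=True)
class MotifHit:
    """One consensus match, anchored at the 5'-most base of the window."""

    promoter_id: str
    tss_position: int
    local_start: int
    strand: str
    observed: str
    mismatches: int
    pattern_name: str


def mismatch_count(window: str, pattern: ConsensusPattern) -> int:
    """Count positions of ``window`` violating the pattern's symbol sets."""
    window = window.upper()
    if len(window) != len(pattern.symbols):
        raise ValueError(
            f"window length {len(window)} != pattern length {len(pattern.symbols)}"
        )
    return sum(
        base not in SYMBOL_SETS[sym] for base, sym in zip(window, pattern.symbols)
    )


def matches(window: str, pattern: ConsensusPattern) -> bool:
    """True iff the window passes within the pattern's mismatch budget."""
    return mismatch_count(window, pattern) <= pattern.max_mismatches


def scan(
    promoter: PromoterRecord,
    pattern: ConsensusPattern,
    strands: Literal["forward", "both"] = "forward",
) -> list[MotifHit]:
    """Report every matching window of ``promoter``, sorted by position.

    Overlapping hits are all reported. With ``strands="both"`` the
    reverse complement of each window is also tested and reported on
    strand ``-``; when forward and reverse hits coincide on the same
    genomic interval only the forward hit is kept.
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    k = len(pattern)
    seq = promoter.sequence
    hits: list[MotifHit] = []
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        mm = mismatch_count(window, pattern)
        if mm <= pattern.max_mismatches:
            hits.append(
                MotifHit(
                    promoter.id, promoter.to_tss(i), i, "+", window, mm, pattern.name
                )
            )
        elif strands == "both":
            mm_rc = mismatch_count(revcomp(window), pattern)
            if mm_rc <= pattern.max_mismatches:
                hits.append(
                    MotifHit(
                        promoter.id,
                        promoter.to_tss(i),
                        i,
                        "-",
                        window,
                        mm_rc,
                        pattern.name,
                    )
                )
    hits.sort(key=lambda h: h.local_start)
    return hits


def classify_decamers(
    entries: Sequence[tuple[str, str]],
    rules: Sequence[ConsensusPattern],
) -> dict[str, int]:
    """Count, per rule, how many labelled decamer entries satisfy it.

    Entries are rows, not unique sequences: duplicated decamers count
    separately. An entry may satisfy zero, one, or both rules.
    """
    for label, dec in entries:
        for rule in rules:
            if len(dec) != len(rule.symbols):
                raise ValueError(
                    f"entry {label!r}: sequence {dec!r} is not a "
                    f"{len(rule.symbols)}-mer"
                )
    return {
        rule.name: sum(matches(dec, rule) for _, dec in entries) for rule in rules
    }


def load_carg_catalog() -> pd.DataFrame:
    """Published catalogue of CArG-box decamers in the PeMADS2-6 promoters.

    Columns: ``promoter`` (gene label), ``sequence`` (decamer),
    ``location`` (TSS-relative position of the reported box) and
    ``predicted_by`` (``consensus`` for the CC(A/T)6GG 9-of-10 rule,
    ``place`` for the exact C(A/T)8G rule).
    """
    with resources.files("orchidcis.data").joinpath("carg_boxes.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def hits_to_frame(hits: Iterable[MotifHit]) -> pd.DataFrame:
    """Tabulate hits (one row per hit) for TSV export."""
    return pd.DataFrame(
        [
            {
                "promoter_id": h.promoter_id,
                "tss_position": h.tss_position,
                "local_start": h.local_start,
                "strand": h.strand,
                "observed": h.observed,
                "mismatches": h.mismatches,
                "pattern": h.pattern_name,
            }
            for h in hits
        ],
        columns=[
            "promoter_id",
            "tss_position",
            "local_start",
            "strand",
            "observed",
            "mismatches",
            "pattern",
        ],
    )


def hits_to_bed6(hits: Iterable[MotifHit], path: str | Path) -> None:
    """Write hits as BED6 (0-based half-open local coordinates).

    The name field carries ``pattern@TSS-position`` so the biological
    coordinate convention survives the conversion; score is the
    mismatch count.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for h in hits:
            w.writerow(
                [
                    h.promoter_id,
                    h.local_start,
                    h.local_start + len(h.observed),
                    f"{h.pattern_name}@{h.tss_position}",
                    h.mismatches,
                    h.strand,
                ]
            )
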