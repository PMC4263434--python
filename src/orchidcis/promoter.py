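"""Promoter sequences anchored to a transcription start site.

Promoter positions follow the convention used throughout the plant
promoter literature: the transcription start site (TSS) is +1, the base
immediately 5' of it is -1, and there is no position 0.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PromoterRecord:
    """A promoter sequence with a declared transcription start site.

    Parameters
    ----------
    id
        Label of the promoter (e.g. ``"PeMADS2p"``).
    sequence
        Nucleotide string, 5'->3', over ``{A, C, G, T, N}``. Stored
        uppercased.
    tss_offset
        0-based index such that ``sequence[tss_offset]`` is position +1
        (the TSS). ``tss_offset == len(sequence)`` is allowed and means
        the whole record lies upstream of the TSS.
    """

    id: str
    sequence: str
    tss_offset: int = field(default=-1)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"{self.id}: sequence is empty")
        bad = set(seq) - ALPHABET
        if bad:
            raise ValueError(f"{self.id}: invalid characters {sorted(bad)!r}")
        offset = self.tss_offset if self.tss_offset >= 0 else len(seq)
        object.__setattr__(self, "tss_offset", offset)
        if not 0 <= self.tss_offset <= len(seq):
            raise ValueError(
                f"{self.id}: tss_offset {self.tss_offset} outside [0, {len(seq)}]"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def declared_length(self) -> int:
        """Number of bases strictly 5' of the TSS base."""
        return self.tss_offset

    def to_tss(self, local_start: int) -> int:
        """Map a 0-based sequence index to a signed TSS-relative position.

        Bases 5' of the TSS map to -1, -2, ... counting toward the 5'
        end; the TSS base itself is +1. Position 0 does not exist.
        """
        if not 0 <= local_start < len(self.sequence):
            raise IndexError(
                f"{self.id}: local_start {local_start} outside sequence of "
                f"length {len(self.sequence)}"
            )
        if local_start >= self.tss_offset:
            return local_start - self.tss_offset + 1
        return local_start - self.tss_offset

    def from_tss(self, tss_position: int) -> int:
        """Inverse of :meth:`to_tss`; rejects the non-existent position 0."""
        if tss_position == 0:
            raise ValueError("TSS coordinate 0 does not exist (-1 abuts +1)")
        if tss_position > 0:
            local = self.tss_offset + tss_position - 1
        else:
            local = self.tss_offset + tss_position
        if not 0 <= local < len(self.sequence):
            raise IndexError(
                f"{self.id}: TSS position {tss_position} outside sequence"
            )
        return local


def to_tss_coordinate(local_start: int, promoter: PromoterRecord) -> int:
    """Functional alias for :meth:`PromoterRecord.to_tss`."""
    return promoter.to_tss(local_start)


def from_tss_coordinate(tss_position: int, promoter: PromoterRecord) -> int:
    """Functional alias for :meth:`PromoterRecord.from_tss`."""
    return promoter.from_tss(tss_position)


_TSS_TAG = re.compile(r"tss_offset=(\d+)")


def read_promoters(
    fasta_path: str | Path,
    tss_offsets: Mapping[str, int] | str | Path | None = None,
) -> list[PromoterRecord]:
    """Read promoters from FASTA with TSS offsets from a sidecar or header tag.

    The TSS offset of each record is resolved in order of precedence:

    1. an explicit mapping ``{record_id: offset}`` or a YAML/JSON sidecar
       file with that mapping, passed as ``tss_offsets``;
    2. a ``tss_offset=N`` tag anywhere in the FASTA description line;
    3. the record length (the whole sequence is treated as upstream).
    """
    mapping: Mapping[str, int] = {}
    if tss_offsets is not None:
        if isinstance(tss_offsets, (str, Path)):
            text = Path(tss_offsets).read_text()
            mapping = (
                json.loads(text)
                if str(tss_offsets).endswith(".json")
                else yaml.safe_load(text)
            )
        else:
            mapping = tss_offsets
    out = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in mapping:
            offset = int(mapping[rec.id])
        else:
            m = _TSS_TAG.search(rec.description)
            offset = int(m.group(1)) if m else len(rec.seq)
        out.append(PromoterRecord(rec.id, str(rec.seq), offset))
    return out


def write_promoters(records: Iterable[PromoterRecord], fasta_path: str | Path) -> None:
    """Write promoters to FASTA, carrying the TSS offset as a header tag."""
    seqrecs = [
        SeqRecord(
            Seq(r.sequence), id=r.id, description=f"tss_offset={r.tss_offset}"
        )
        for r in records
    ]
    SeqIO.write(seqrecs, str(fasta_path), "fasta")
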