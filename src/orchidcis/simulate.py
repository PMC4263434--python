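"""Seeded synthetic inputs with ground truth for every pipeline stage.

Three generators emulate the data the analysis modules consume:

- :func:`gen_promoters` — promoter sequences evolved along a phylogeny
  under an i.i.d. uniform substitution model (Jukes–Cantor-like, no
  indels by default), with CArG-box decamers and conserved k-mers
  planted at declared TSS positions. Motifs are planted *after* branch
  evolution so their divergence is exactly the declared per-leaf
  substitution count.
- :func:`gen_bisulfite` — clone sequences from per-cytosine Bernoulli
  methylation with imperfect bisulfite conversion and sequencing error.
- :func:`gen_assays` — qPCR Ct tables with Gaussian noise around true
  log2 abundances, and firefly/Renilla luminometer readings with
  multiplicative (log-normal) noise.

Every generator consumes one integer seed; sub-streams are derived
deterministically per output, so identical specs and seeds give
byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from orchidcis.footprint import parse_tree
from orchidcis.motif_scan import PATTERNS, matches
from orchidcis.promoter import PromoterRecord, write_promoters
from orchidcis.methylation import cytosine_context

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# sub-stream tags, one per generated artifact
_STREAM_PROMOTERS = 11
_STREAM_BISULFITE = 22
_STREAM_ASSAY_CHIP = 33
_STREAM_ASSAY_LUC = 44


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), stream])


# ---------------------------------------------------------------------------
# promoters

@dataclass(frozen=True)
class PlantedCarg:
    """A CArG decamer planted at a TSS position in every (non-lost) leaf."""

    decamer: str
    tss_position: int
    rule: str  # name in motif_scan.PATTERNS, validated at generation


@dataclass(frozen=True)
class PlantedMotif:
    """A conserved k-mer planted with declared per-leaf divergence."""

    kmer: str
    tss_position: int
    substitutions: Mapping[str, int] = field(default_factory=dict)
    lost_leaves: frozenset[str] = frozenset()


@dataclass
class PromoterSimSpec:
    """Simulation design for a set of paralogous promoters.

    ``root_length`` defaults to 1300 bp, the upstream window
    conventionally analysed for these promoters;
    ``per_branch_substitution_prob`` is the per-site substitution
    probability on every tree edge.
    """

    tree: str  # newick
    root_length: int = 1300
    per_branch_substitution_prob: float = 0.1
    planted_carg: Sequence[PlantedCarg] = ()
    planted_motifs: Sequence[PlantedMotif] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.per_branch_substitution_prob <= 1:
            raise ValueError("substitution probability must lie in [0, 1]")
        intervals = []
        for pc in self.planted_carg:
            if not matches(pc.decamer, PATTERNS[pc.rule]):
                raise ValueError(
                    f"planted decamer {pc.decamer} does not satisfy rule {pc.rule}"
                )
            intervals.append(self._interval(pc.tss_position, len(pc.decamer)))
        for pm in self.planted_motifs:
            intervals.append(self._interval(pm.tss_position, len(pm.kmer)))
        intervals.sort()
        for (a0, a1), (b0, b1) in zip(intervals, intervals[1:]):
            if b0 < a1:
                raise ValueError(
                    f"planted items overlap: [{a0},{a1}) and [{b0},{b1})"
                )

    def _interval(self, tss_position: int, length: int) -> tuple[int, int]:
        if tss_position == 0:
            raise ValueError("TSS position 0 does not exist")
        local = self.root_length + tss_position if tss_position < 0 else None
        if local is None or local < 0 or local + length > self.root_length:
            raise ValueError(
                f"planted item at {tss_position} (length {length}) does not fit "
                f"in a {self.root_length}-bp upstream region"
            )
        return (local, local + length)


def _evolve(seq: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of i.i.d. substitutions to a uniformly chosen other base."""
    out = seq.copy()
    hit = np.nonzero(rng.random(len(seq)) < p)[0]
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _substitute(kmer: str, n: int, rng: np.random.Generator) -> str:
    """Apply exactly ``n`` substitutions at distinct positions."""
    if n == 0:
        return kmer
    pos = rng.choice(len(kmer), size=n, replace=False)
    out = list(kmer)
    for i in pos:
        out[i] = chr(rng.choice([b for b in b"ACGT" if chr(b) != out[i]]))
    return "".join(out)


def gen_promoters(
    spec: PromoterSimSpec,
) -> tuple[list[PromoterRecord], pd.DataFrame]:
    """Evolve promoters down the tree and plant the declared elements.

    Returns the leaf promoters (TSS at the 3' end of each record, i.e.
    ``tss_offset == root_length``) and a truth table with one row per
    planted item per leaf (``lost`` marks leaves where a motif was
    omitted).
    """
    rng = _rng(spec.seed, _STREAM_PROMOTERS)
    tree = parse_tree(spec.tree)
    root = rng.choice(_BASES, size=spec.root_length)
    # evolve in a deterministic node order
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root}
    leaves: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent = seqs[id(node.parent_node)]
        child = _evolve(parent, spec.per_branch_substitution_prob, rng)
        seqs[id(node)] = child
        if node.is_leaf():
            leaves[node.taxon.label] = child
    truth_rows = []
    for leaf in sorted(leaves):
        seq = leaves[leaf]
        for pc in spec.planted_carg:
            start = spec.root_length + pc.tss_position
            seq[start : start + len(pc.decamer)] = np.frombuffer(
                pc.decamer.encode(), dtype="S1"
            )
            truth_rows.append(
                {
                    "kind": "carg",
                    "leaf": leaf,
                    "tss_position": pc.tss_position,
                    "local_start": start,
                    "planted": pc.decamer,
                    "observed": pc.decamer,
                    "substitutions": 0,
                    "lost": False,
                    "rule": pc.rule,
                }
            )
        for pm in spec.planted_motifs:
            start = spec.root_length + pm.tss_position
            lost = leaf in pm.lost_leaves
            if lost:
                observed = ""
            else:
                observed = _substitute(
                    pm.kmer, int(pm.substitutions.get(leaf, 0)), rng
                )
                seq[start : start + len(pm.kmer)] = np.frombuffer(
                    observed.encode(), dtype="S1"
                )
            truth_rows.append(
                {
                    "kind": "motif",
                    "leaf": leaf,
                    "tss_position": pm.tss_position,
                    "local_start": start,
                    "planted": pm.kmer,
                    "observed": observed,
                    "substitutions": int(pm.substitutions.get(leaf, 0)),
                    "lost": lost,
                    "rule": "",
                }
            )
    records = [
        PromoterRecord(leaf, leaves[leaf].tobytes().decode(), spec.root_length)
        for leaf in sorted(leaves)
    ]
    return records, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# bisulfite

@dataclass
class EpiSimSpec:
    """Simulation design for bisulfite clone sequencing of one region.

    Context-specific methylation probabilities default to plant-typical
    levels (CpG high, CHG intermediate, CHH low);
    ``conversion_efficiency`` is the probability that an unmethylated C
    reads as T.
    """

    reference_length: int = 500
    p_cpg: float = 0.8
    p_chg: float = 0.3
    p_chh: float = 0.05
    conversion_efficiency: float = 0.99
    n_clones: int = 10
    error_rate: float = 0.001
    seed: int = 0
    reference: str | None = None  # supply instead of generating

    def __post_init__(self) -> None:
        for p in (self.p_cpg, self.p_chg, self.p_chh, self.conversion_efficiency):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_clones < 1:
            raise ValueError("need at least one clone")


def gen_bisulfite(
    spec: EpiSimSpec,
) -> tuple[str, list[tuple[str, str]], pd.DataFrame]:
    """Simulate bisulfite clones of one genomic region.

    Returns ``(reference, clones, truth)``, where ``truth`` has one row
    per reference cytosine with its context, true methylation
    probability and the realised per-clone methylation states (a string
    of 0/1 over clones).
    """
    rng = _rng(spec.seed, _STREAM_BISULFITE)
    if spec.reference is not None:
        ref = spec.reference.upper()
    else:
        ref = rng.choice(_BASES, size=spec.reference_length).tobytes().decode()
    p_by_context = {"CpG": spec.p_cpg, "CHG": spec.p_chg, "CHH": spec.p_chh}
    c_positions = [i for i, b in enumerate(ref) if b == "C"]
    contexts = {i: cytosine_context(ref, i) for i in c_positions}
    clones: list[tuple[str, str]] = []
    states = {i: [] for i in c_positions}
    for c in range(spec.n_clones):
        out = list(ref)
        for i in c_positions:
            methylated = rng.random() < p_by_context[contexts[i]]
            states[i].append(int(methylated))
            if not methylated and rng.random() < spec.conversion_efficiency:
                out[i] = "T"
        if spec.error_rate > 0:
            for j in np.nonzero(rng.random(len(out)) < spec.error_rate)[0]:
                out[j] = chr(rng.choice([b for b in b"ACGT" if chr(b) != out[j]]))
        clones.append((f"clone{c + 1:02d}", "".join(out)))
    truth = pd.DataFrame(
        [
            {
                "position": i,
                "context": contexts[i],
                "true_p": p_by_context[contexts[i]],
                "clone_states": "".join(map(str, states[i])),
            }
            for i in c_positions
        ]
    )
    return ref, clones, truth


# ---------------------------------------------------------------------------
# assays

@dataclass
class AssaySimSpec:
    """Simulation design for ChIP-qPCR and dual-luciferase assays.

    ``chip_true_ratios`` maps (tissue, antibody, region) to the true
    abundance of the target region relative to the antibody's internal
    control (defaults mirror the studied design: H3K9K14ac at the
    translation start 4.9-fold higher in lip than petal, all other
    marks/regions flat). Replicate design defaults to two biological x
    three technical replicates for ChIP and n = 6 per organ for
    luciferase with organ means in the ratio 3 : 3 : 1 : 1
    (lip : column : sepal : petal).
    """

    chip_true_ratios: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: {
            ("petal", "H3K9K14ac", "ATG"): 1.0,
            ("lip", "H3K9K14ac", "ATG"): 4.9,
            ("petal", "H3K4me3", "ATG"): 1.0,
            ("lip", "H3K4me3", "ATG"): 1.0,
            ("petal", "H3K9me2", "ATG"): 1.0,
            ("lip", "H3K9me2", "ATG"): 1.0,
            ("petal", "H3K9K14ac", "intron5"): 1.0,
            ("lip", "H3K9K14ac", "intron5"): 1.0,
            ("petal", "H3K4me3", "intron5"): 1.0,
            ("lip", "H3K4me3", "intron5"): 1.0,
            ("petal", "H3K9me2", "intron5"): 1.0,
            ("lip", "H3K9me2", "intron5"): 1.0,
        }
    )
    ct_sd: float = 0.15
    base_ct: float = 24.0
    n_bio: int = 2
    n_tech: int = 3
    luc_organ_means: Mapping[str, float] = field(
        default_factory=lambda: {"lip": 3.0, "column": 3.0, "sepal": 1.0, "petal": 1.0}
    )
    luc_cv: float = 0.2
    luc_n: int = 6
    luc_construct: str = "pJD-Pe4p-375"
    renilla_base: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(r <= 0 for r in self.chip_true_ratios.values()):
            raise ValueError("true abundance ratios must be positive")
        if self.ct_sd < 0 or self.luc_cv < 0:
            raise ValueError("noise parameters must be non-negative")


def gen_assays(spec: AssaySimSpec) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate a ChIP-qPCR Ct table and a luminometer table.

    Ct values are ``base_ct - log2(true abundance) + N(0, ct_sd)``; the
    internal control of each antibody has true abundance 1. Firefly
    readings are ``organ_mean x renilla x LogNormal(cv)`` so the
    firefly/Renilla ratio estimates the organ mean. Returns
    ``(chip_table, luciferase_table, truth)``.
    """
    from orchidcis.quant import CONTROL_FOR  # local import avoids a cycle

    rng_chip = _rng(spec.seed, _STREAM_ASSAY_CHIP)
    rows = []
    design = dict(spec.chip_true_ratios)
    tissues = sorted({t for t, _, _ in design})
    antibodies = sorted({a for _, a, _ in design})
    for tissue in tissues:
        for antibody in antibodies:
            regions = sorted({r for t, a, r in design if t == tissue and a == antibody})
            if not regions:
                continue
            for region in [*regions, CONTROL_FOR[antibody]]:
                abundance = design.get((tissue, antibody, region), 1.0)
                true_ct = spec.base_ct - np.log2(abundance)
                for bio in range(1, spec.n_bio + 1):
                    for tech in range(1, spec.n_tech + 1):
                        rows.append(
                            {
                                "tissue": tissue,
                                "antibody": antibody,
                                "region": region,
                                "bio_rep": bio,
                                "tech_rep": tech,
                                "ct": float(
                                    true_ct + rng_chip.normal(0.0, spec.ct_sd)
                                ),
                            }
                        )
    chip = pd.DataFrame(rows)

    rng_luc = _rng(spec.seed, _STREAM_ASSAY_LUC)
    sigma = float(np.sqrt(np.log1p(spec.luc_cv**2)))
    luc_rows = []
    for organ in sorted(spec.luc_organ_means):
        mean = spec.luc_organ_means[organ]
        for rep in range(1, spec.luc_n + 1):
            renilla = spec.renilla_base * rng_luc.lognormal(-sigma**2 / 2, sigma)
            firefly = mean * renilla * rng_luc.lognormal(-sigma**2 / 2, sigma)
            luc_rows.append(
                {
                    "construct": spec.luc_construct,
                    "organ": organ,
                    "replicate_id": rep,
                    "firefly": float(firefly),
                    "renilla": float(renilla),
                }
            )
    luc = pd.DataFrame(luc_rows)
    truth = {
        "chip_true_ratios": {
            "|".join(k): v for k, v in spec.chip_true_ratios.items()
        },
        "luc_organ_means": dict(spec.luc_organ_means),
    }
    return chip, luc, truth


# ---------------------------------------------------------------------------
# file output (CLI backend)

def write_promoter_sim(spec: PromoterSimSpec, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = gen_promoters(spec)
    write_promoters(records, outdir / "promoters.fasta")
    (outdir / "tree.nwk").write_text(spec.tree.strip() + "\n")
    truth.to_csv(outdir / "promoters.truth.tsv", sep="\t", index=False)


def write_bisulfite_sim(spec: EpiSimSpec, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref, clones, truth = gen_bisulfite(spec)
    (outdir / "reference.fasta").write_text(f">reference\n{ref}\n")
    with open(outdir / "clones.fasta", "w") as fh:
        for cid, seq in clones:
            fh.write(f">{cid}\n{seq}\n")
    truth.to_csv(outdir / "bisulfite.truth.tsv", sep="\t", index=False)


def write_assay_sim(spec: AssaySimSpec, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chip, luc, truth = gen_assays(spec)
    chip.to_csv(outdir / "chip.csv", index=False)
    luc.to_csv(outdir / "luciferase.csv", index=False)
    (outdir / "assays.truth.json").write_text(json.dumps(truth, indent=2) + "\n")
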