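"""ChIP-qPCR enrichment and dual-luciferase reporter quantification.

ChIP-qPCR abundances are normalised to an internal control by the
delta-Ct rule: ``relative_amount = E^-(mean Ct_target - mean Ct_control)``
with amplification efficiency ``E = 2`` by default. Each antibody has a
fixed control locus: *ACTIN2* for the active-chromatin marks H3K4me3 and
H3K9K14ac, the retrotransposon *Ta3* for the repressive H3K9me2.
Technical replicates are averaged within each biological replicate
before statistics (avoids pseudo-replication); uncertainties are
propagated by the first-order delta method.

Dual-luciferase promoter activities are firefly/Renilla ratios; groups
of organs are compared by all pairwise two-sample t-tests and summarised
as a compact letter display (groups sharing a letter are not
significantly different at the chosen alpha).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: antibody -> internal control locus used for normalisation
CONTROL_FOR: dict[str, str] = {
    "H3K4me3": "ACTIN2",
    "H3K9K14ac": "ACTIN2",
    "H3K9me2": "Ta3",
}


@dataclass(frozen=True)
class EnrichmentEstimate:
    """Internal-control-normalised ChIP-qPCR abundance for one tissue."""

    tissue: str
    antibody: str
    region: str
    relative_amount: float
    sd: float
    n_bio: int
    n_tech: int

    def __post_init__(self) -> None:
        if self.relative_amount <= 0:
            raise ValueError("relative_amount must be positive")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class FoldChange:
    """Ratio of two enrichment estimates with delta-method uncertainty."""

    antibody: str
    region: str
    tissue_numerator: str
    tissue_denominator: str
    fold: float
    sd: float


@dataclass
class GroupComparison:
    """Pairwise t-test matrix and compact letter display over groups."""

    means: dict[str, float]
    pairwise_p: pd.DataFrame
    alpha: float
    letters: dict[str, str]

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


def relative_enrichment(
    wells: pd.DataFrame,
    tissue: str,
    antibody: str,
    region: str,
    efficiency: float = 2.0,
) -> EnrichmentEstimate:
    """Delta-Ct relative abundance of ``region`` vs its internal control.

    ``wells`` holds one technical replicate per row with columns
    ``tissue, antibody, region, bio_rep, ct``. Within each biological
    replicate the technical Ct values of target and control are averaged,
    ``relative = efficiency**-(Ct_target - Ct_control)`` is formed, and
    biological replicates are then averaged. The reported ``sd``
    combines the delta-method propagation of technical Ct variance with
    the between-biological-replicate spread.
    """
    control = CONTROL_FOR.get(antibody)
    if control is None:
        raise ValueError(
            f"unknown antibody {antibody!r}; expected one of {sorted(CONTROL_FOR)}"
        )
    sub = wells[(wells["tissue"] == tissue) & (wells["antibody"] == antibody)]
    tgt = sub[sub["region"] == region]
    ctl = sub[sub["region"] == control]
    if tgt.empty:
        raise ValueError(f"no wells for target region {region!r} in {tissue}/{antibody}")
    if ctl.empty:
        raise ValueError(
            f"missing control wells: antibody {antibody!r} requires region "
            f"{control!r} in tissue {tissue!r}"
        )
    ln_e = math.log(efficiency)
    rel, var_rel, n_tech = [], [], 0
    for bio in sorted(set(tgt["bio_rep"])):
        t_ct = tgt.loc[tgt["bio_rep"] == bio, "ct"].to_numpy(float)
        c_ct = ctl.loc[ctl["bio_rep"] == bio, "ct"].to_numpy(float)
        if len(c_ct) == 0:
            raise ValueError(f"bio_rep {bio!r}: control wells missing")
        n_tech = max(n_tech, len(t_ct))
        dct = t_ct.mean() - c_ct.mean()
        var_dct = (t_ct.var(ddof=1) / len(t_ct) if len(t_ct) > 1 else 0.0) + (
            c_ct.var(ddof=1) / len(c_ct) if len(c_ct) > 1 else 0.0
        )
        r = efficiency ** (-dct)
        rel.append(r)
        var_rel.append((ln_e * r) ** 2 * var_dct)  # first-order delta method
    n_bio = len(rel)
    amount = float(np.mean(rel))
    var_tech = float(np.sum(var_rel)) / n_bio**2
    var_bio = float(np.var(rel, ddof=1)) / n_bio if n_bio > 1 else 0.0
    return EnrichmentEstimate(
        tissue, antibody, region, amount, math.sqrt(var_tech + var_bio), n_bio, n_tech
    )


def fold_between(est_a: EnrichmentEstimate, est_b: EnrichmentEstimate) -> FoldChange:
    """Tissue fold change ``A / B`` for matched antibody and region."""
    if est_a.antibody != est_b.antibody or est_a.region != est_b.region:
        raise ValueError(
            f"estimates are not comparable: {est_a.antibody}/{est_a.region} vs "
            f"{est_b.antibody}/{est_b.region}"
        )
    fold = est_a.relative_amount / est_b.relative_amount
    sd = fold * math.sqrt(
        (est_a.sd / est_a.relative_amount) ** 2
        + (est_b.sd / est_b.relative_amount) ** 2
    )
    return FoldChange(est_a.antibody, est_a.region, est_a.tissue, est_b.tissue, fold, sd)


def luciferase_ratio(firefly: float, renilla: float) -> float:
    """Relative promoter activity: firefly / Renilla luminescence.

    Renilla (driven by a constitutive promoter) controls for
    transfection efficiency; a non-positive reading marks a failed
    transfection and is rejected.
    """
    if renilla <= 0:
        raise ValueError(f"Renilla reading must be positive (failed control): {renilla}")
    if firefly < 0:
        raise ValueError(f"firefly reading must be non-negative: {firefly}")
    return firefly / renilla


def luciferase_activities(table: pd.DataFrame) -> pd.DataFrame:
    """Add a ``relative_activity`` column to a luminometer table.

    Expects columns ``construct, organ, replicate_id, firefly, renilla``.
    """
    out = table.copy()
    out["relative_activity"] = [
        luciferase_ratio(f, r) for f, r in zip(out["firefly"], out["renilla"])
    ]
    return out


def _pairwise_p(
    groups: Mapping[str, np.ndarray], order: Sequence[str], equal_var: bool
) -> pd.DataFrame:
    p = pd.DataFrame(np.ones((len(order), len(order))), index=order, columns=order)
    for a, b in itertools.combinations(order, 2):
        xa, xb = groups[a], groups[b]
        if xa.std(ddof=1) == 0 and xb.std(ddof=1) == 0:
            # degenerate: no within-group variance on either side
            pval = 1.0 if xa.mean() == xb.mean() else 0.0
            logger.warning(
                "groups %r and %r have zero variance; exact-equality rule applied",
                a,
                b,
            )
        else:
            pval = float(stats.ttest_ind(xa, xb, equal_var=equal_var).pvalue)
        p.loc[a, b] = p.loc[b, a] = pval
    return p


def letter_groups(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.01,
    equal_var: bool = True,
    holm: bool = False,
) -> GroupComparison:
    """Compact letter display from all pairwise two-sample t-tests.

    Groups are ordered by decreasing mean (ties broken by name) and
    letters assigned by insert-and-absorb so that two groups share a
    letter iff their two-tailed t-test p-value is >= ``alpha``. Student's
    equal-variance test is the default; set ``equal_var=False`` for
    Welch. ``holm=True`` applies a Holm step-down correction to the
    p-matrix before letters are formed (off by default).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {g: np.asarray(list(v), dtype=float) for g, v in groups.items()}
    for g, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} needs >= 2 replicates")
    order = sorted(arrays, key=lambda g: (-arrays[g].mean(), g))
    pmat = _pairwise_p(arrays, order, equal_var)
    if holm:
        pairs = list(itertools.combinations(order, 2))
        raw = np.array([pmat.loc[a, b] for a, b in pairs])
        idx = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        running = 0.0
        for rank, i in enumerate(idx):
            running = max(running, (m - rank) * raw[i])
            adj[i] = min(1.0, running)
        for (a, b), p in zip(pairs, adj):
            pmat.loc[a, b] = pmat.loc[b, a] = p

    # insert-and-absorb: maintain letter columns (sets of mutually
    # non-distinct groups); split any column containing a significant pair
    columns: list[set[str]] = [set(order)]
    for a, b in itertools.combinations(order, 2):
        if pmat.loc[a, b] >= alpha:
            continue
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        columns = [
            c for c in columns if not any(c < other for other in columns if c is not other)
        ]
        # drop exact duplicates
        seen: list[set[str]] = []
        for c in columns:
            if c and c not in seen:
                seen.append(c)
        columns = seen
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for i, col in enumerate(columns):
        for g in order:
            if g in col:
                letters[g] += alphabet[i % len(alphabet)]
    means = {g: float(arrays[g].mean()) for g in order}
    return GroupComparison(means, pmat, alpha, letters)
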