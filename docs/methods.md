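# Methods

## Promoter coordinates

A `PromoterRecord` couples a nucleotide string (A/C/G/T/N) to a TSS
offset: the base at that 0-based index is position +1, bases 5' of it
are −1, −2, … and position 0 does not exist. The offset may equal the
sequence length, meaning the whole record is upstream sequence.
Coordinate conversion is exactly invertible and is property-tested on
random positions.

## CArG-box scanning

Patterns are degenerate strings over A/C/G/T/W/N (W = A/T, N = any) with
an integer mismatch budget. The two bundled rules are the core MADS
binding consensus `CCWWWWWWGG` at ≤ 1 mismatch — "9 of 10" is read as a
floor, so a perfect 10/10 window also passes — and the relaxed
`CWWWWWWWWG` at 0 mismatches. An N in the *sequence* is counted as a
mismatch against any non-N symbol (conservative calling). Every matching
window is reported, overlaps included, anchored at the 5'-most base.

Both bundled patterns equal their own reverse complements as degenerate
strings, so forward-strand scanning is the default and is provably
equivalent (and asserted in tests) to both-strand scanning for them; the
both-strand mode remains available for arbitrary patterns, reporting
reverse hits on strand − and keeping only the forward hit when both
strands match the same interval.

The published decamer catalogue for the PeMADS2–6 promoters ships with
the package (`load_carg_catalog`). Rows are counted as entries —
duplicated decamers at different positions count separately. One
catalogue position is printed ambiguously in the original table
(−1,9128); the value −1912 from the running text is stored.

## Substring-parsimony footprinting

For a candidate ancestral k-mer `c`, the tree-wide score is

    score(c) = Σ_leaf min_window Hamming(c, window) + loss_cost × n_lost_clades

over non-lost leaves; a motif is reported when its substitution total is
≤ the mutation allowance D and the lost leaves (whole clades only,
counted as leaves) fit within `max_losses`. Candidates are the k-mers
observed in any leaf, extended by their 1-substitution neighbourhoods
when D ≥ 1. This candidate restriction makes the search exact for
D ≤ 1 — any ancestral k-mer achieving total distance ≤ 1 must be
observed or one substitution away from an observed k-mer — which covers
the settings of interest (10/11-mers at D = 0, 12-mers at D = 1). The
default `loss_cost = D + 1` guarantees a loss can never substitute for a
permitted mutation unless explicitly budgeted; `max_losses` defaults
to 0.

Ties are broken deterministically: leftmost occurrence per leaf, loss
assignments preferring lower score then fewer lost leaves, output sorted
by score then ancestral k-mer. Identical inputs give identical output.

Overlapping shared k-mers arising from one longer shared substring are
merged by default into a single motif with the maximal shared extension
(the rule that matches how discrete motif boxes are conventionally
drawn); because the counting convention of the original footprinting
software is not documented, counts under merging are
convention-sensitive, and the raw un-merged k-mer list is available with
`merge=False` / `--no-merge`. `pairwise_conserved` implements the
two-leaf case by direct window enumeration, independent of the tree
code, and the two routes are asserted equal in tests.

`truncate_upstream` restricts promoters to the window immediately 5' of
the TSS (default 1.3 kb), the region conventionally compared across
these paralogs. The default quartet topology groups
(PeMADS3,PeMADS4) against (PeMADS2,PeMADS5), the split implied by the
two *AP3*-lineage clades.

## Bisulfite methylation calling

Clones are globally aligned to the untreated reference with a
substitution matrix in which reference-C vs clone-T scores as a match
(full conversion is signal, not error); other substitutions cost −1.5,
gaps −4/−1 with cheap end gaps. Clones whose compatible-base identity
falls below a floor (default 80%) are excluded and logged. Calling is
top-strand only: clone C at a reference C counts methylated, T
unmethylated, anything else (or a gap) removes that clone from that
site's denominator — per-site, not per-clone, exclusion. Contexts are
assigned from the reference alone: CG → CpG, C-H-G → CHG, otherwise CHH
(H = A/C/T); cytosines too close to the 3' end to resolve are classed
CHH. Incomplete conversion is reported, not corrected: the non-CpG
(especially CHH) fraction is the conventional conversion diagnostic, and
no statistical correction is applied because none was applied in the
original workflow.

## Digestion prediction

CCGG sites are enumerated on the reference; cuts fall after the first C
(C^CGG) for HpaII/MspI and after TTT (TTT^AAA) for DraI. Methylation is
treated as symmetric across strands, so a top-strand mark suffices to
block. HpaII is blocked when *either* cytosine of CCGG is methylated —
the broader reading of the enzyme's sensitivity; the canonical
internal-C-only convention is available via `hpaii_rule="internal"`.
MspI is blocked only by methylation of the outer (first) cytosine. DraI
is insensitive. Double digests cut at the union of the components'
unblocked cut positions. Fragment lengths always sum to the reference
length (linear molecule); this is property-tested against an independent
cut-and-measure oracle.

## ChIP-qPCR quantification

Within each biological replicate, technical Ct values of target and
control are averaged and `relative = E^-ΔCt` formed with amplification
efficiency E = 2 by default (per-primer efficiency is a parameter);
biological replicates are then averaged. The reported SD combines the
first-order delta-method propagation of technical Ct variance,
`var(R) ≈ (ln E · R)² var(ΔCt)`, with the between-biological-replicate
spread of the per-replicate ratios. Tissue folds are ratios of the
normalised means (a per-replicate-ratio alternative was considered; the
ratio of means is the default because the replicate pairing across
tissues is not meaningful), with delta-method uncertainty. Adding any
constant to all Ct values leaves every estimate unchanged.

## Luciferase statistics

Relative activity is firefly/Renilla; a non-positive Renilla reading
marks a failed transfection control and is rejected. Organ groups are
compared by all pairwise two-tailed two-sample t-tests — Student's
equal-variance test by default, matching the era's standard "t-test"
(Welch by flag) — at α = 0.01 with no multiple-testing correction by
default (a Holm option exists but is off, matching the stated original
procedure). The compact letter display is built by insert-and-absorb:
starting from one column holding all groups, each significant pair
splits every column containing both, absorbed columns are dropped, and
letters are assigned in order of decreasing group mean (ties by name),
so the output is invariant to input order. A pair with zero within-group
variance on both sides falls back to an exact-equality rule (same letter
iff equal means) and is logged. Type-I behaviour is calibrated in tests:
under the null the display separates two groups in ≤ 2% of 1000
simulations at α = 0.01.

## Synthetic data

`gen_promoters` draws a uniform-composition root sequence (1300 bp by
default, the conventional analysis window), evolves it along each tree
edge under i.i.d. per-site substitution to a uniformly chosen other base
(Jukes–Cantor-like; probability 0.1 per branch by default — substantial
but footprint-preserving divergence for paralogous promoters; no indels
by default), then plants declared elements *after* evolution so planted
divergence is exactly the declared per-leaf substitution count: CArG
decamers (validated against their declared rule at spec construction)
and conserved k-mers with optional per-leaf substitutions and lost
leaves. Planted intervals may not overlap. A truth table records every
planted item per leaf.

`gen_bisulfite` methylates each reference cytosine per clone as a
Bernoulli draw at its context's probability (defaults 0.8 CpG / 0.3
CHG / 0.05 CHH, plant-typical), converts unmethylated C→T with
probability `conversion_efficiency` (default 0.99), and applies a
uniform sequencing-error rate (default 10⁻³). Ten clones by default.
The truth table stores both the per-site probability and the realised
per-clone states, so the caller can be checked exactly in the noiseless
limit and within binomial bounds otherwise.

`gen_assays` produces Ct = base − log₂(abundance) + N(0, sd) per
technical replicate (sd 0.15, two biological × three technical
replicates by default) with the antibody's internal control at
abundance 1, and luminometer readings with multiplicative log-normal
noise (CV 20%, n = 6 per organ) around organ means in the ratio
3 : 3 : 1 : 1 (lip : column : sepal : petal). The default ChIP design
sets the lip/petal H3K9K14ac ratio at the translation-start amplicon to
4.9 and all other marks/regions to 1.

One integer seed governs all randomness; per-output sub-streams are
derived deterministically from it, so identical specs and seeds give
byte-identical outputs.

## What the simulations do and do not show

The generators reproduce the *statistical structure* each analysis stage
assumes — planted motifs with known divergence, Bernoulli methylation
with imperfect conversion, Gaussian Ct noise, multiplicative luminometer
noise — so passing tests demonstrate that each stage recovers known
truth under its stated model. They do not emulate real orchid genome
composition, repeat structure, CpG islands, indel-rich promoter
divergence, primer efficiency differences, or amplification-curve
artefacts; agreement on synthetic data therefore validates the
algorithms, not the biological conclusions drawn from any particular
real dataset. Checks that require the deposited promoter accessions run
only when those sequences are supplied locally.

## Problem sizes

Default test and reproduction scales: 100 random 500-bp sequences for
scanner-oracle equivalence; 1000 random decamers for the
reverse-complement symmetry; quartets of 150–300-bp promoters over 25–50
seeded replicates for footprint recovery; 400–500-bp bisulfite regions
with 10 clones; 100 replicate ChIP simulations for fold recovery; 1000
null simulations for type-I calibration.
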