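# Methods

This note documents the models, rules and numerical choices behind `termtk`,
what the synthetic-data generator does and does not emulate, and the design
decisions taken where the procedure was genuinely open.

## Coordinates and strands

All in-memory coordinates are 1-based inclusive on the forward genome.
Minus-strand features keep forward coordinates plus a strand flag; "upstream"
and "downstream" always refer to the direction of transcription. A 3'-end
position `x` denotes the 3'-terminal transcribed nucleotide on either strand.
BED/bedGraph files are converted to and from 0-based half-open coordinates
only at the I/O boundary, and replicate tracks are merged by summation (never
averaged), so merged values may be fractional.

## 3'-end calling

The coverage-variation statistic is defined as the one-step coverage drop in
the direction of transcription, clipped at zero (`C_V(i) = max(0, cov(i) −
cov(i+1))` on the plus strand, mirrored on the minus strand, with 0 for the
out-of-range neighbour). This is the minimal statistic whose magnitude at a
3' end tracks 3'-end abundance. Two interchangeable landscapes are supported:
coverage drops from RNA-seq-style tracks, and Term-seq 3'-end pileup counts
used directly as the landscape (`kind="termseq_ends"`); which signal the
original data carry cannot be decided from coverage alone, so both backends
exist and are tested.

Calling partitions positions into maximal runs with `C_V ≥ threshold`
(default 10) and emits the run's argmax. Genomic regions typically hold
several adjacent 3' ends; ends are clustered by single linkage with gap ≤ 3
nt and the most abundant end represents each region. Tie-breaks are: greater
raw end count, then greater C_V, then the most downstream position in the
direction of transcription — downstream because exonucleolytic trimming
biases steady-state ends upstream of the nascent POT. The 3-nt radius reuses
the `[x−3, x+3]` cross-dataset reconciliation window so the pipeline carries
a single clustering/matching constant.

## Terminator anatomy

**U-tract anchor.** The U-rich tract is assumed to start at the first U
residue within the 12 nt ending at `x` (transcript sense). A 9-nt tract
window is then read from the position after the hairpin's last stem
nucleotide; it is viable when it begins with at least two consecutive Us
(`n_us` = length of that leading run). The weakest admissible tract is a
bare UU lead, e.g. `UUCCGCACG`.

**Hairpin folding.** The 50 nt upstream of the tract start are folded with a
single stem-loop model: a contiguous, bulge-free stem closing a terminal
loop, scored as the sum of nearest-neighbor stack energies (Turner-2004-style
Watson-Crick and G-U values; approximate tandem-G-U terms, symmetrised so
`E(p,q) = E(rev q, rev p)`) plus a hairpin-loop initiation penalty for loop
sizes 3–12 nt. Accepted hairpins need stem ≥ 4 bp, loop 3–12 nt and
`ΔG < 0`. The model deliberately omits bulges, internal loops and
multibranch structures: terminator hairpins are short contiguous stems, and
classification needs relative, not absolute, stabilities. The folding
backend is pluggable; the ViennaRNA bindings can be used as a full-MFE
alternative, and the test suite cross-checks the built-in folder against
ViennaRNA on a designed stem.

"Iterative" folding is operationalised as a three-window retry: if the best
structure's 3'-most paired base lies more than 3 nt upstream of the window
end, windows ending 1 and 2 nt further upstream are folded as well and the
best-ΔG structure whose 3' stem base lies within 3 nt of its window end is
kept. At the genome edge the available suffix is folded when ≥ 15 nt,
otherwise no hairpin is returned.

Because the hairpin is taken to end before the first U, the primary
prediction never pairs U-tract residues — so A-U pairs that a real
terminator forms against its tract are invisible at this stage (their stems
appear shorter and the hairpin-to-end distance longer). The revised,
nascent-end-anchored prediction (below) restores them.

**A-tract and confirmation.** An upstream A-tract is called when a run of
≥ 3 consecutive A lies within the 10 nt upstream of the stem's 5' base. A 3'
end is confirmed as an intrinsic terminator when a hairpin was found, the
tract is viable and `%T ≥ 5` in the WT strain. The hairpin-to-3'-end
distance `d = x − last stem nt` is recorded; `d` outside 7–9 nt (the span
set by the RNA-DNA hybrid length) is flagged *atypical* but not rejected.

## Termination efficiency and factor dependence

`%T = 100·(U − D)/U` with `U`/`D` the median coverage over `[x−9, x]` /
`[x+1, x+10]` (transcript sense). The upstream window includes `x` itself so
the terminated transcript's last nucleotide stays upstream; this choice is
configurable. %T is undefined when `U = 0`, never clipped (readthrough above
upstream coverage yields negative values), and windows are never truncated —
ends whose windows leave the genome raise instead of silently shrinking.

`Δ%T = %T_WT − %T_mutant`. Dependence bands: *dependent* ⇔ `Δ%T ≥ 25`;
*independent* ⇔ `−10 ≤ Δ%T ≤ 10`; otherwise *intermediate*. Subpopulations
evaluate the three mutant categories with the Req rules before SI: Req A and
G (dependent in all three), Req A / Req G (dependent in the matching single
mutant and the double), Req A or G (dependent in the double only), SI
(`%T_WT ≥ 70` and independent in the double). "SI of a factor" uses the
corresponding single mutant only.

Dataset matching is greedy one-to-one nearest-position matching on the same
strand; the 4-nt steady-state window is interpreted as the explicitly stated
`[x−3, x+3]` half-width and the 15-nt in-silico window as `|Δ| ≤ 7` (both
configurable; the 4-nt wording is ambiguous between half-width 2 and 3, and
the explicit reconciliation window governs). When the partner set is a prior
study, its coordinate is reported for matched pairs. Group comparisons are
two-sided: Wilcoxon signed-rank (paired, zero differences rank-split so
identical vectors give p = 1), Mann–Whitney U, and a hand-written
Fisher–Pitman permutation test on the mean difference (exhaustive when the
number of label assignments is ≤ 20 000, otherwise Monte-Carlo with the
add-one estimator). P-values are reported raw; a Holm step-down helper is
available but off by default, matching how pairwise p-values are tabulated.

## RNET-seq integration

For each terminator `x`, nascent 3'-end counts are read over the proximal
window `[x, x+4]` and the upstream window `[x−150, x+4]` (which includes the
proximal window, as specified). A peak is assigned only when the proximal
window holds a nascent end and the 75th percentile of end counts across the
upstream window is > 0; the most abundant proximal position wins (ties go
downstream). Percentiles interpolate linearly between order statistics, and
zero-count positions inside the dense upstream window are included by
default (a flag excludes them). Normalised abundance is peak count / p75;
the cohort keeps peaks strictly above the cohort's 25th percentile, so a
cohort of identical norms empties — a documented consequence of the strict
inequality. NusG dependency is `log2(norm_WT / norm_ΔnusG)`; the 0.01 floor
replaces only *absent* ΔnusG peaks, never an observed abundance.

Revision re-anchors the U-tract search and fold at the nascent 3' end, then
extends the stem bottom outward with any canonical or wobble pair while the
hairpin-to-end distance stays ≥ 7 nt — the biophysical floor — so revised
stems may gain the terminal A-U/G-U pairs (often against an upstream
A-tract) that the primary prediction excludes. Weak-pair enrichment
tabulates revised stems with ≥ 1 vs 0 consecutive terminal A-U/G-U pairs
into a 2×2 table; the two-sided Fisher exact p sums hypergeometric
probabilities ≤ the observed table's (the standard convention; alternatives
exist), with p = 1 for degenerate margins and an undefined odds ratio on
zero cells.

## Pause motif and logos

The pause register requires U at transcript positions −12, −11, −8, −7 and
−6 (3' end = −1); −10 and −9 never influence the match. The six-letter
TTNTTT label implies a different register than this explicit position list;
the explicit list governs. PFMs are column frequencies over (A, C, G, U)
with T mapped to U and no pseudo-counts by default (a Laplace option exists
for tiny cohorts). Jensen–Shannon divergence is computed per position in
bits (`H(m) − (H(p)+H(q))/2`, `m = (p+q)/2`); a nats option exists because
logo-diff implementations differ in their entropy base.

## Synthetic data: what it emulates and what it does not

The generator is the package's study-conditions definition, not a tuning
surface. It plants, per terminator: a GC-weighted reverse-complement stem
(6–12 bp; loops 3–8 nt of non-pairing A so the planted register is exact), a
9-nt all-U tract starting immediately after the stem, a POT 7–9 nt from the
hairpin, an optional upstream AAAA tract (probability 0.5), and — for the
Req G / Req A and G subpopulations — a pause motif realised as three
terminal A-U pairs (U at −12/−11, POT at 9 nt, stems ≥ 7 bp so the primary
prediction keeps ≥ 4 pairs after stopping at the first U). The bottom five
5'-arm positions are kept A-free on non-motif stems so no stray U enters the
12-nt first-U search window. Terminators are placed one per genome block
with ≥ 300 nt between POTs (spacing ≥ 200 enforced), subpopulations cycle
through a fixed release-fraction table chosen to sit squarely inside the
dependence/independence bands:

| subpopulation | WT | nusA_dep | ΔnusG | double |
| --- | --- | --- | --- | --- |
| SI | 0.9 | 0.9 | 0.9 | 0.9 |
| Req A | 0.8 | 0.3 | 0.8 | 0.3 |
| Req G | 0.8 | 0.8 | 0.3 | 0.3 |
| Req A and G | 0.8 | 0.4 | 0.4 | 0.1 |
| Req A or G | 0.8 | 0.75 | 0.75 | 0.2 |

Each transcription unit spans 160 nt upstream to 50 nt downstream of its
POT; coverage is the expression level upstream and `expression × (1 −
release fraction)` downstream, so noiseless %T equals the planted release
fraction exactly and the 10-nt windows never straddle units. Term-seq
pileups put `release × expression` counts at the POT, with ≤ 10 % of the
mass jittered to ±1 nt when noise is on — the minimal model of "multiple
adjacent 3' ends" that still exercises the most-abundant-end rule. RNET
tracks place a nascent pileup at POT + δ (δ drawn once per terminator from
0–4, shared across strains) over a background of 4 end counts per nt across
the upstream window so the p75 normaliser is well defined; pause-motif
terminators carry 4× the pileup mass in WT relative to ΔnusG. Poisson noise,
when enabled, is applied per nucleotide from a generator seeded by (seed,
strain, strand), making every track a pure function of the configuration.

Not emulated: read-level artifacts (FASTQ, mapping bias, sequencing error),
RNA decay beyond the step drop, enzyme kinetics of 3'–5' trimming (only its
0–4 nt offset), operonic structure, RNET-seq library depletion at
terminators, and genuine %T variation within a subpopulation. Passing tests
therefore demonstrate correctness of the statistics and rules under the
assumed signal model, not robustness to real-library artifacts.

Default problem sizes used by the validation suite — 100 kb genomes with 50
terminators (250 for the classification check) at 200× depth — were chosen
as the smallest cohorts at which every subpopulation appears many times and
Poisson sampling error on windowed medians is representative (≈ 1–3
percentage points of %T).

## Known limitations

* The built-in folder ignores bulges and internal loops; a terminator whose
  real stem is interrupted folds shorter here. The ViennaRNA backend relaxes
  this but extracts only the 3'-most bulge-free ladder.
* Stem length is reported in base pairs; arm-length conventions (nt per arm)
  differ by one unit of accounting and are noted where relevant.
* With a large trimming offset (δ ≥ 3) the revised, nascent-anchored
  annotation can legitimately land on a different fold register (e.g. an
  A-tract:U-tract duplex), so weak-pair recovery is only guaranteed for
  small offsets.
* %T windows raise at genome boundaries instead of truncating; circular
  genomes are not wrapped.
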