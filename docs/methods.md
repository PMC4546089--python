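# Methods

This note documents the models, algorithms, parameter choices and
known limitations of `repeatscape`, in the order the pipeline runs.

## Read filtering

A mate pair survives filtering only if **both** mates pass every test
after right-end N trimming (downstream clustering relies on intact
mate links, so singleton survivors would be useless).  Defaults:

| parameter           | default | meaning                                    |
|---------------------|---------|--------------------------------------------|
| `min_len`           | 40 bp   | post-trimming length floor                 |
| `min_mean_qual`     | 15      | mean Phred; kept when exactly at threshold |
| `entropy_threshold` | 60      | trinucleotide-entropy score floor (0–100)  |
| `trim_ns_right`     | 10      | max trailing N's removed before testing    |
| `max_n_percent`     | 20 %    | N fraction ceiling                         |
| `drop_non_iupac`    | on      | reject symbols outside {A,C,G,T,N}         |

The low-complexity score is `100·H₃/ln(min(64, L−2))`, where `H₃` is
the natural-log Shannon entropy of overlapping trinucleotide
frequencies.  This formula is normative for this package: a
homopolymer scores 0, a read whose 3-mers are all distinct scores 100,
and `(AT)ₙ` scores `100·ln2/ln(L−2)`.  Periodic sequences with period
≤ ~10 score below 60 and are removed, which is the intended behavior
for microsatellite-like reads.

The contaminant screen drops a pair when **either** mate has a local
alignment to any contaminant sequence covering ≥ 50 bp at ≥ 90 %
identity (conservative organelle-screen values; both configurable).
An empty contaminant database is an error, never a silent no-op.

## Alignment engine

All sequence comparison uses one scoring scheme: match +1,
mismatch −3, affine gaps costing `open + (k−1)·extend` with
open = −5, extend = −2.  The mismatch/match constants follow the
WU-BLAST-style `M=1 N=-3` convention; the gap penalties are this
package's stated choice.  N bases never match.

Candidate pairs are found by shared canonical 12-mers (strand-minimum
encoding, so reverse-complement overlaps are found without a second
index).  Each candidate is aligned by a numba-compiled Smith–Waterman/
Gotoh dynamic program **banded to ±12 diagonals around the seed
match**, on the strand the seed orientation indicates.  For read-scale
inputs (≈100 bp, indel rates ≪ 1 %/bp) the optimal local alignment
lies on the seed diagonal, and the banded result equals the exhaustive
O(nm) DP — the test suite verifies this against an independent
pure-Python full DP on hundreds of randomized overlap constructions,
and an unbanded exact path (`align.local_align`) remains available.
The banding is a heuristic for diverged sequences with large indels,
which are outside this pipeline's operating range.

Hit thresholds for clustering: alignment ≥ 55 bp, identity ≥ 90 %,
and aligned columns ≥ 0.55 of the shorter read.  Annotation reuses the
same 55 bp / 90 % thresholds by default; both are independently
configurable.

## Clustering

Edges carry the alignment score of the best qualifying hit; isolated
reads are tallied as *unclustered*, so reads are conserved through
every stage (clustered + unclustered = sampled).

Louvain is implemented in-package: standard two-phase weighted
modularity maximization, node visit order shuffled by the seed,
equal-gain moves resolved to the lowest community index so results are
deterministic given a seed.  On graphs ≤ 200 nodes the search is
strengthened by 10 seeded restarts plus iterated local search (kick
two nodes, re-optimize, keep the best partition): plain greedy Louvain
provably cannot reach some small-graph optima by single-node moves,
and the acceptance suite requires agreement with exhaustive partition
enumeration on ≤ 8-node graphs.  Large graphs run a single pass —
at pipeline scale community structure is strong and restarts change
nothing measurable.  Only resolution 1.0 is supported.

Mate-pair merging unions clusters spanned by ≥ `min_links` mate pairs,
transitively until fixpoint, logging each union.  The default
`min_links = 100` is deliberately conservative: with short inserts a
TE cluster emits a steady trickle of links into adjacent single-copy
regions (fragments spanning a copy boundary), and a permissive
threshold (e.g. 2) was observed to collapse distinct families and
background into one cluster at 1× coverage.  Family fractions are
summed over clusters sharing an annotation, so leaving a long family
split across clusters is harmless for composition; merging exists for
cluster-level bookkeeping and should stay strict.  Tiny test scenarios
pass `min_links = 2` explicitly.

## Annotation and composition

Each read votes for the family of its single best-scoring qualifying
library hit (score ties → earlier library entry); a cluster takes the
plurality family (ties → earlier library entry) with
`hit_fraction` = winning votes / cluster size.  A family's genomic
fraction is `Σ_clusters (size/total)·hit_fraction`; the
`(1−hit_fraction)` residue accrues to *unannotated* rather than being
rescaled, so per-replicate fractions sum to exactly 1
(family + unannotated + unclustered).  Replicate tables report mean
and sample SD per row; SD is clamped to exactly 0 when all replicate
values are identical (the naive mean-subtraction otherwise leaves an
ulp-level residue), and reported as not-available for a single
replicate.

The coverage-titration experiment samples each level as a **fraction
of the available read pool**, 3 replicates per level, and reports each
family's CV = SD/mean plus a per-level summary (mean CV over families
with nonzero mean; zero-mean families are excluded and the summary is
NaN if none remain).  At the 1 Mb test scale the levels are 5 % and
0.05 % of an 8×-coverage pool: this keeps a 100× span between the
extreme sampling levels while keeping even the lowest level
large enough (~20 pairs) to detect the dominant family — 0.05 % of a
1× pool would mean 2–3 pairs, where composition is undefined rather
than merely noisy.

## Genome size

Each read contributes the aligned length of its best qualifying
alignment (≥ 60 bp, ≥ 70 % identity by default) to exactly one
transcript (best score; ties → lowest transcript index, no
multi-mapping split, which would double-count read bases and bias
`Cval` low).  Zero-coverage transcripts are excluded, the top
`ceil(0.10·count)` transcripts by depth are trimmed (absorbing
multi-copy or repeat-contaminated transcripts), and
`Cval = P·n·l/mean(Cov_i)`.  When trimming would empty the set,
nothing is trimmed and a warning is issued.  `threshold_grid`
re-evaluates the estimate over a length × identity grid against a
user-supplied truth (synthetic ledger or flow-cytometry value) and
returns the error surface with the argmin first; alignments are
computed once at the loosest settings and re-filtered per grid point.

On synthetic 200 kb genomes with 40 embedded transcripts
(1–3 kb) at 2× depth the estimator lands within ~6 % of truth (median
over 20 seeds); the residual positive bias comes from the top-decile
trim and from transcript-edge reads that fail the 60 bp floor, both of
which depress `mean(Cov_i)`.

## Rank-abundance models

All five models share one Poisson log-likelihood
`Σ_r (a_r·ln â_r − â_r)` — the `ln a_r!` term is dropped, which shifts
every model's log-likelihood equally and therefore cannot change BIC
order (tested).  `BIC = −2·logL + k·ln S`.  Abundances may be
fractional (genome fractions × a scale, default reads-per-million),
since the pipeline's abundances are read fractions.  Rank ties are
broken by family label for determinism.

Fitting is bounded quasi-Newton (L-BFGS-B, ftol 1e-12) from ≥ 5
deterministic starts; the preemption model uses bounded scalar
minimization at 1e-12 tolerance.  The Mandelbrot fit always includes
the fitted Zipf optimum (β = 0) among its starts and falls back to it
if the optimizer ends below, so `logL(Mandelbrot) ≥ logL(Zipf)` holds
structurally; Mandelbrot's β is weakly identified and large fitted
(c, β, |γ|) excursions along its likelihood ridge are normal.  The
lognormal rank-to-quantile map uses `(S−r+0.5)/S` plotting positions;
R `vegan` uses `ppoints` (a = 3/8 for S ≤ 10), which is why fitted
lognormal parameters differ slightly from vegan's while Preemption,
Zipf and Null agree to printed precision.

`simulate_rad` draws Poisson counts around a chosen model's expected
rank curve (dropping zero ranks), which is the generative process the
model-selection recovery tests use.  Two caveats discovered while
validating: (i) generating Zipf data with `p·Σr^γ ≠ 1` makes the
nominal `p` unidentifiable — the recoverable dominance share is the
normalized `p_eff = p·r^γ` share of the realized total; (ii) *iid*
lognormal draws (rather than Poisson noise around the lognormal rank
curve) are best-fit by Mandelbrot about half the time under BIC — a
property of the model family, reproduced with vegan itself, not an
implementation artifact.

Diversity: `H = −Σ p_i ln p_i` (natural log), `E = H/ln S`, `E`
reported as NaN for S = 1.

## Phylogenetic signal

PIC follows Felsenstein's pruning: contrast
`(x_L − x_R)/√(b_L + b_R)`, ancestral value the branch-length-weighted
average, parent branch extended by `b_L·b_R/(b_L+b_R)`.
Multifurcations are resolved arbitrarily with zero-length branches;
for contrasts, non-positive branch lengths are then replaced by
ε = 1e-8 (logged).  Because contrasts are linear in the trait, the
implementation exposes the (n−1)×n coefficient matrix, which lets the
permutation test evaluate hundreds of trait shuffles as one matrix
product.

Blomberg's K uses the Brownian covariance `C` (root-to-MRCA path
lengths): `K = (MSE₀/MSE) / E[MSE₀/MSE]` with the GLS phylogenetic
mean, `E[·] = (tr C − n/(1ᵀC⁻¹1))/(n−1)`.  The covariance matrix is
built **without** ε padding, so a star phylogeny gives exactly
diagonal `C` and the algebraic identities hold to machine precision
(K = 1 for any trait; PGLS = OLS).  A constant trait raises a defined
error rather than returning NaN.  Significance is one-sided on the PIC
variance (low variance = signal): `p = (1 + #{null ≤ obs})/(n_perm+1)`
over seeded trait shuffles, warning below 99 permutations.

PGLS solves `β̂ = (XᵀC⁻¹X)⁻¹XᵀC⁻¹y` (via statsmodels GLS) with a
t-test on the slope; r² is `1 − RSS/TSS` on Cholesky-whitened
residuals with TSS from the intercept-only GLS fit, guaranteeing
r² ∈ [0, 1].  The trend test regresses a trait on an ordinal
phylogenetic position (caller-supplied; default 0…n−1) with identity
covariance — a constant trait reports slope 0 and r² not-available.
No branch-length transforms (λ, κ, δ) are estimated.

## Synthetic data

`make_genome` draws i.i.d. background at the requested GC (default
0.40, a plant-like value), a random consensus per family, and places
independently mutated copies (substitutions at the divergence rate,
single-base indels at the indel rate, random strand) at uniform
non-overlapping positions by rejection sampling; transcripts can be
embedded once each the same way.  The truth ledger records 0-based
half-open coordinates, strand, per-family fractions and round-trips
through JSON losslessly.  Copies are non-nested by default so truth
fractions are unambiguous.

`simulate_reads` emulates paired-end sequencing: 100 bp reads, 400 bp
mean insert (SD 40), uniform fragment positions, R2
reverse-complemented, uniform substitution errors at 0.5 %/base, flat
Q35 qualities.  `round(coverage·G/(2·read_len))` pairs are produced
and each read's true source interval is ledgered.  The canned study
genome (`planted_superfamily_spec`) is 1 Mb with three superfamilies
at 30/15/5 % (1 kb consensus, 2 % per-copy divergence) over 50 %
single-copy background — a Gypsy-dominated plant-like composition.

What the generator does **not** emulate: nested/fragmented insertions
(available behind a flag but off by default), solo-LTR formation,
quality ramps or indel-heavy sequencing error profiles, GC bias, and
real library-insert distributions.  Passing recovery tests therefore
demonstrate correctness of the machinery under clean planted truth,
not performance on degraded real libraries.

Trees are pure-birth (Yule) with exponential waiting times, made
ultrametric, tips `t1…tn`; traits evolve by recursive Brownian motion
(`child = parent + N(0, σ²·branch)`), starting at the root split so
the stem adds no variance.

## Problem sizes used in the checks

Composition recovery runs the full filter→sample→cluster→annotate
chain on the 1 Mb planted genome at 1× coverage (≈5,000 pairs) for 20
seeds; replicate/CV machinery uses an 8× pool of the same genome;
genome-size recovery uses 20 seeds of 200 kb genomes at 2×; RAD model
selection uses 100 simulated vectors per scenario; Blomberg's K
calibration uses 500 Brownian traits on a 32-tip tree and 200 null
datasets × 999 permutations.  These sizes were chosen so the full
check battery completes in minutes on one CPU while leaving every
statistical margin wide.

## Known limitations

- The banded aligner assumes seed-colinear, low-indel alignments;
  highly diverged or rearranged repeats need the exact DP path.
- Louvain at full scale runs one seeded pass; global optimality is
  only enforced (and only enforceable) at oracle scale.
- Cluster annotation is plurality-vote per cluster; chimeric clusters
  contribute their minority reads to *unannotated* rather than being
  split.
- The genome-size estimator inherits the trimmed-mean's small upward
  bias (see above) and assumes transcripts are single-copy.
- `K` is reported per trait; aggregation across TE families (means ±
  SD of K over families) is left to the caller.
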