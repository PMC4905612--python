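# Methods

This note documents the statistical model behind each component, the
defaults and why they are what they are, the numerical choices, and what
the synthetic benchmarks do and do not establish.

## Periodicity model and score

A feature set is *N* named 1-based positions on one chromosome of length
*G* (circular or linear). The alternative hypothesis is a positional
lattice: features near offset + *k·P* for a spacing *P*. For a candidate
*P*, phases φ = position mod *P* become angles on the circle and the score
is the Rayleigh concentration *S = N·R²* with *R* the mean resultant
length. Properties used downstream: *S* ∈ [0, *N*]; invariance under
global translation; per-feature decomposability (leave-one-out); and the
divisor structure — an exact lattice at *T* scores *S = N* at every
divisor *T/k*, so true signals surface as harmonic families.

A proximity pre-filter (greedy keep-first scan, threshold in bp; wrap pair
checked on circular chromosomes) removes tightly packed genes, which would
otherwise contribute many near-identical phases and inflate significance.
The threshold is a user parameter (CLI default 1000 bp ≈ one bacterial
gene; the library applies no filter unless asked).

## Null model and p-values

The null is *N* positions i.i.d. uniform on [1, *G*], scored at the same
*P*. Monte-Carlo (default for single periods, `n_mc` = 10,000, add-one
estimator, exactly valid at finite `n_mc`) is the reference. The analytic
route has two ingredients:

1. **Wrap bias.** Uniform positions give uniform phases only when *P*
   divides *G*. In general the resultant has null mean |μ| =
   |sin(π*G*/*P*)/(π*G*/*P*)|, which is negligible for *P* ≪ *G* but
   substantial when *P* is a sizeable fraction of *G* (at *P* = 2 Mb,
   *G* = 4.64 Mb, *N* = 50 the true tail is ~20× the classical Rayleigh
   value). The resultant sum is treated as complex normal with that mean,
   so 2*S* follows a noncentral χ² with 2 df and noncentrality 2*N*|μ|²;
   the tail was validated against 2×10⁵-replicate simulations at five
   (*P*, *G*, *N*) configurations (agreement within ~5 % relative down to
   p = 10⁻³).
2. **Finite-N correction.** The noncentral tail is multiplied by the ratio
   of Wilkie's finite-*N* Rayleigh approximation to the asymptotic
   e^(−S), so the formula reduces exactly to the classical finite-*N*
   approximation when the bias vanishes. Monte-Carlo and analytic p-values
   agree within 0.01 for *N* ≥ 30 (tested), and the raw p-values are
   uniform under the null (KS distance < 0.05 over 1000 draws).

## Multiple-testing correction

Two multiplicities act on a scan. First, a period *P* fits ⌊*G*/*P*⌋ full
repetitions into the genome — each an independent chance of spurious
alignment — giving the per-period Šidák correction
p_corr = 1 − (1 − p_raw)^m with m = max(1, ⌊*G*/*P*⌋). `correct_pvalue`
implements exactly this for a single pre-registered period.

Second, an exhaustive scan tests many effectively independent frequencies.
Simulation of full scans under the uniform null shows the law
P(min_P p_raw·*G*/*P* < t) ≈ C·t with C ≈ 2.2–3.0 per natural-log unit of
scanned period range, stably across genome sizes, feature counts and
window scales. Scans therefore scale the Šidák count by
f = 3.5·ln(p_max/p_min) (the constant chosen once, on the conservative
side of every configuration measured), making the *minimum* corrected
p-value over a scan an honest family-wise quantity: on 200 uniform draws
at the default configuration, ~5 % of scans report any corrected p < 0.05,
and a planted 93-kb lattice (40 sites, σ = 2 kb jitter, 30 background) is
still recovered within 3 % with p < 0.05 in ≥ 95 % of seeds — the
corrections cost essentially no power because genuine lattice signals sit
many orders of magnitude below threshold.

`CIRC` mode tests the real-valued divisors *G*/*k* in range; `DOM` combs
[p_min, p_max] in 3-bp steps (defaults: [10 kbp, *G*/2]). Argmax ties
break toward the smaller period.

## Phase clustering and positional scores

DBSCAN runs on the phase coordinates with the circular distance
min(|Δφ|, *P*−|Δφ|) (precomputed matrix) and radius
eps = *P*^(1−e)·*d*^e, e ∈ (0, 1]: e = 1 recovers the plain proximity
threshold *d*, smaller e widens the radius toward *P*, a single
sensitivity dial. minPts is the minimum cluster size (default 2). Points
are visited in sorted phase order, labels renumbered 1..k by first
appearance along the phase axis; noise carries label 0. Determinism
follows from the fixed visiting order.

The positional score of feature *i* is c_i = *S*(all) − *S*(all∖{i}),
computed in closed form from the complex resultant, then min-max
normalised to [0, 1] per period (all-equal contributions ⇒ all scores 1).
Scores are translation- and order-invariant, and lattice members outscore
uniform background members in every tested seed.

## Region mapping

Window sizes start at 10 kbp and grow by a factor 1.5 until capped at
0.95·*G*; each slides by half its size (windows wrap on circular
chromosomes). Windows holding ≥ 8 features run a period scan over
[5 kbp, w]. Because the score decorrelates over a frequency shift of
~1/w, the within-window grid is uniform in frequency at 8× that
resolution rather than a fixed-bp comb — orders of magnitude cheaper at
large periods with no loss of resolution relative to the 5 % tolerances
used downstream. Window p-values use the same noncentral null (with
*G* → w) and the same scan-breadth correction.

Three guards make the reported regions meaningful:

- **Fundamental promotion.** A lattice of spacing *T* also aligns at
  divisors, and unrelated-feature noise can hand the window minimum to
  *T*/2; if an integer multiple (2× or 3×, within 5 %) of the best period
  is significant to within two orders of magnitude of the best p-value,
  the window reports the multiple — the physical spacing.
- **Periodic-run trimming.** The candidate region is the largest run of
  features with positive leave-one-out contribution at the best period
  whose consecutive gaps stay within two periods, so a window much larger
  than the periodic segment does not inflate the reported interval with
  unrelated features.
- **Minimum repetitions.** The run must occupy ≥ 4 distinct period
  repetitions; fewer would make the "period" indistinguishable from a
  single clump of features.

Overlapping candidates whose periods agree within 5 % (the same tolerance
used for "common" periods across regulons) merge by connected components —
order-independent and idempotent — keeping the best p-value and recounting
features in the union span. Regions wrapping the origin are reported split
in the chromogram table. At the default mapping cutoff of 0.0005, uniform
genomes yield on average < 1 (measured: ≈ 0) regions, and a planted 20-kb
lattice confined to a 300-kb segment is recovered with Jaccard ≥ 0.5 in a
clear majority of seeds; the misses are windows whose alignment with the
segment leaves too few sites for the strict cutoff — a power limit, not a
calibration one.

## Multi-view boosting

Views are feature tables over the same genes: sequence (best PWM log-odds
over both strands per motif variant; windows containing N are skipped;
motif variants are the full matrix plus versions trimmed of their
lowest-information flanking columns) and position (positional score per
candidate period, computed jointly over all genes). Weak learners are
decision stumps; the threshold grid is the midpoints of sorted unique
scores (a degenerate float midpoint falls back to the lower value — the
same partition — keeping the error bookkeeping exact). Initial weights are
½/N⁺ and ½/N⁻ per class, absorbing class imbalance. Each iteration both
views propose their best stump; the lower-error view wins (ties to the
position view, deterministically), receives α = ½ ln((1−ε)/ε), and the
weights update multiplicatively. Training stops when no stump beats
chance (ε ≥ ½) or a stump is perfect (ε floored at 10⁻¹² for the α
computation only). The provably non-increasing quantity under this
initialisation is the class-weighted exponential loss
Σ w⁰_i·exp(−y_i F(x_i)), which the tests assert.

Prediction is F(x) = Σ α_t·h_t(x) with per-view partial sums that add to F
exactly. The interplay analysis splits the per-iteration weighted outputs
α_t·h_t(x) into a position-selected block X and a sequence-selected block
Y and runs CCA with a ridge on both block covariances (default 0.1 when
either block has ≥ rows/2 columns, else 0; whitening by inverse square
root, SVD, correlations clipped to [0, 1]). Loadings are the correlations
of each variable with the averaged canonical variate (u+v)/2 of the first
two pairs — the quantities drawn on a correlation-circle plot, where an
obtuse angle means negative association.

## Synthetic benchmarks — what they emulate

The generators are pure functions of configuration and seed.

- `generate_periodic_positions`: lattice at offset + k·P with Gaussian
  jitter, uniform background, optional confinement to a sub-region; the
  offset is drawn uniformly per seed so no test can overfit phase 0;
  position collisions resolve by +1-bp shifts.
- `generate_null_positions`: the scan's uniform null.
- `generate_regulon_dataset`: target promoters receive a motif instance
  sampled from the matrix at a uniform offset with probability
  `implant_prob`, and target positions follow the lattice; non-targets get
  i.i.d. background promoters (uniform base composition, adjustable GC)
  and uniform positions. `coupling="negative"` splits targets into
  strong-sequence/off-lattice and on-lattice/no-implant halves, creating
  anti-correlated views by construction.

Defaults mirror the study conditions used throughout: *G* = 4,641,652 bp
(an *E. coli*-sized circular chromosome), lattice 93 kb with 40 sites and
2-kb jitter over 30 background sites for whole-genome scans; a 20-kb
lattice of 12 sites confined to [1.0, 1.3] Mb over 30 background sites for
region mapping; regulons of 50–150 genes per class with 200-bp (150-bp in
the one-view regimes) promoters and a 10-bp, 88 %-consensus motif.

What they do *not* emulate: operon structure and gene clustering beyond
the proximity filter's reach, non-uniform background gene density
(replication-associated skews), motif variants diverging from a single
matrix, overlapping regulons, or noisy/incomplete target labels. Passing
benchmarks therefore demonstrates correctness and calibration of the
statistics under their stated model, not performance on curated regulon
databases.

## Problem sizes in the test and acceptance runs

The test suite uses the full study conditions (e.g. 200 null scans, 100
planted-recovery seeds, 50-seed cluster/score checks, 20-seed boosting and
CCA checks) and completes in a few minutes on one CPU. The acceptance
script re-measures the same quantities at moderately reduced replicate
counts (1000 null draws, 100 null scans, 50 recovery seeds, 10–25 seeds for
the remaining checks) — sizes chosen so a full from-scratch run stays
around two minutes while keeping Monte-Carlo error well inside the
tolerances of interest.

## Known limitations

- The analytic null treats the resultant as complex normal; below ~15
  features per window the Monte-Carlo route is preferable (the region
  mapper's `min_features` default of 8 is a floor, not an optimum).
- The scan-breadth constant (3.5 per ln unit of range) was calibrated on
  uniform nulls with up to ~100 features; extremely dense feature sets
  were not profiled.
- Harmonic-family grouping is greedy from the smallest period and
  considers ratios 2–4× only.
- One chromosome per analysis; multi-chromosome or joint scans are out of
  scope, as are spectral estimators (Lomb–Scargle/Fourier) and any
  statistical test of macrodomain-boundary coincidence (boundaries are a
  plot overlay only).
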