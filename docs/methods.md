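# Methods

## Model and assumptions

Cell length is counted in units of the characteristic size l₀ set by the
division machinery, and time in units of the time t₀ needed to grow one
unit. The state is the integer size n ∈ {1..N}; each step a cell grows
exactly one unit and, with probability α ∈ [0, 1] (the division
efficiency), the step ends in an instantaneous division. Small
fluctuations around l₀ are deliberately neglected: the model addresses the
regime where the dominant size fluctuations are of order l₀ itself
(anomalous growth, filamentation), not the sub-l₀ variability that drives
size convergence in regular growth. Growth of filamentous cells is assumed
linear in time, division sites are quantized at l₀ spacing, multiple
simultaneous divisions and cell death are excluded, and t₀ does not enter
any stationary size statistic. Consequences: the model cannot describe
continuous growth, sub-l₀ fluctuations, or memory effects in which the
division efficiency itself changes during filamentation.

### Transition matrix and the boundary state

States are 1-based; `P[n-1, m-1]` is the m→n probability (columns are
sources). Interior columns are `(1−α)·δ_{n,m+1} + α·kernel(m)`, with the
kernel the daughter-size law of a mother that grew from m to m+1 and
divided (support 1..m, symmetric under n ↔ m+1−n in all four patterns).
The chain is truncated at a maximal size N: a size-N cell cannot grow, so
its column is the kernel evaluated at m = N with division probability
forced to one. Under this rule the two daughters of a size-N mother sum to
N rather than N+1, and the n = N outcome plays the role of "remain at the
maximal size". This is a deliberate bookkeeping choice at an intrinsically
ambiguous boundary; because the top state is barely recurrent it has no
visible effect on the size statistics away from n = N. The "middle"
kernel's parity branch uses the parity of the pre-growth size m (odd m:
the single central site of the m+1 mother; even m: the two sites flanking
the centre) — the only reading that makes the two branches exhaustive and
exclusive.

### Stationary solution

(I − P)p = 0 is singular, so one equation is replaced by the
normalization Σp = 1 and the square system solved directly (least squares
as a fallback). This remains well-posed for reducible chains — e.g. at
α = 1 under the middle kernel all states above 1 are transient and
receive zero mass. Entries in [−1e−12, 0) are clipped to zero, the vector
renormalized, and the fixed-point residual ‖Pp − p‖∞ checked against
1e−10; failure raises rather than returning a silently bad vector. Power
iteration is used as an independent oracle in the tests, restricted to
aperiodic parameter points (α = 0 with the middle kernel yields a
period-2 cycle where plain power iteration does not converge).

## Derived laws and the per-step convention

All derived quantities are *per growth step* of the whole population:

* newborn law π_n — probability that the cell observed after a step is a
  newborn of size n. Only the division channel contributes (α·kernel for
  interior columns, the whole boundary column at m = N); 1 − Σπ is the
  growing-cell fraction. Taking instead the full transition matrix would
  count growing cells as newborns and break the reconstruction identity
  p_n = π_n + Σ_{m<n} π_m Π P_{(k+1)k}, which the tests verify to 1e−10.
* birth-size law π*_n — probability that the cell observed at a step *was
  born* with size n. This is a per-step census: cells with longer
  interdivision times are represented at every step they are alive,
  exactly as in a population snapshot. It is **not** the frequency of
  daughter sizes per division event (that law is π/Σπ); the two differ by
  up to ~20% at α = 0.1 and by a negligible amount near α = 0.9. The
  simulator's empirical π̂* therefore tabulates, at each post-burn-in
  step, the birth size of the live cell, counting a step spent
  "remaining" at N as a rebirth at N (that is what the boundary column's
  n = N entry means in the newborn law). The synthetic generator's
  *birth-length sample*, by contrast, is per division event — that is
  what a segmentation pipeline actually measures — and the fit compares
  it with the normalized π*; at wild-type efficiencies the conflation is
  far below the sampling noise, which is also why fits of real
  birth-size histograms against π* are legitimate there.
* joint law p*_{m,n} of birth size m and increment n at division, with
  the boundary term collecting cells that reach N and are then forced to
  divide; it is intentionally unnormalized (row and column sums < 1).
* mean increment <n>_m = (1 − (1−α)^(N−m))/α, independent of the kernel,
  and the adder slope δn = (1−α)^(N−1) ln(1−α)/α ≤ 0. Both have explicit
  N → ∞ evaluators (1/α and 0) rather than numerical extrapolation.
  `mean_increment` accepts non-integer m as the analytic continuation so
  that derivative checks can use centred differences. α = 0 (increment
  undefined, deterministic limit N − m) and α ∈ {0, 1} for the slope are
  rejected as domain errors with the one-sided limits documented.

## Lineage Monte Carlo

A single lineage is followed: at interior sizes the step is a
Bernoulli(α) choice between growth and growth+division; on division the
followed cell's next size is drawn from the kernel itself, which is
exactly the dynamics the population recursion propagates (following a
uniformly chosen daughter would be a different, wrong, weighting for
asymmetric kernels). At N the boundary column applies; an n = N draw
leaves the cell in place and is not recorded as a division event, and a
cell that waits at N keeps its original birth size for increment
bookkeeping (its eventual increment is N − m, matching the boundary term
of the joint law). Increments are division length minus birth length.
Two clocks are kept: growth steps (stationary statistics) and
generations (division counts, used for convergence experiments). Each
lineage uses `numpy.random.default_rng(seed)`; lineage i of a bundle
uses seed + i, making multi-lineage figures reproducible. Default
burn-in is one third of the run. Typical problem sizes: 2–3·10⁵ steps
for steady-state statistics (≈10⁵–2·10⁵ division events at wild-type α),
150 lineages × 40 generations for convergence — a single lineage of
3·10⁵ steps takes well under a second.

## Estimation pipeline

* **l₀ from births.** Mean and standard deviation of the *full*
  size-at-birth sample give a single cutoff ⟨l_b⟩ + σ (a one-pass
  Z-score filter, not iterated); the retained subsample's mean and sd
  are l₀ ± Δl₀. The filter isolates the non-filamentous subpopulation;
  cells between one and two sd are "transitioning" and excluded.
* **l₀ from mother/daughter lengths.** Difference of histogram modes
  (Freedman–Diaconis bin width; multimodal ties warn and take the first)
  and difference of means; the mean difference includes transitioning
  cells and is reported as an upper bound.
* **l₀ from fluorescence periodicity.** Profiles are mean-subtracted,
  resampled to the finest sampling interval present, zero-padded to the
  next power of two ≥ twice the longest profile, and their FFT moduli
  averaged; the dominant interior local maximum (q > 0) is refined by a
  three-point parabola. λ = 1/q*, and l₀ = λ/2 because the spacing of
  central division rings doubles in long cells. No taper is applied by
  default (a Hann window is available); a constant profile raises
  peak-not-found. Default sampling emulates a 65 nm pixel.
* **Binning.** State n = ⌊l/l₀ + ½⌋ (boxes of unit width centred on
  integer multiples, left-closed edges, lengths below l₀/2 to state 1).
  The scheme presumes Δl₀/l₀ small; the generator warns above 0.3.
* **α fit.** ε²(α) = (1/(N−1)) Σ (π*_exp − π*_theo)² + (1/N) Σ
  (p_exp − p_theo)², with the experimental histograms padded with zeros
  up to N (default 20) and the theoretical laws recomputed per candidate
  α. The asymmetric 1/(N−1) vs 1/N weights are kept as stated even
  though their rationale is unclear; they change the minimizer only
  marginally. Minimization: coarse grid step 0.01 on [0.01, 1], then
  bounded golden-section refinement to 1e−4; a flat error curve raises
  fit-degenerate. Uncertainty: nonparametric bootstrap over cells (1000
  resamples by default) refitted on a cached fine grid (step 0.005).
* **Histogram collapse.** Candidate l₀ scanned in 0.05 μm steps over
  [0.5, 1.5]·l₀_ref (the reference value always included, so collapsing
  a histogram against itself is exact); ε² = (1/N) Σ (p_ref − p_other)²;
  a boundary minimum warns.
* **Sensitivity.** Raw samples rebinned and refitted at l₀ − Δ, l₀,
  l₀ + Δ; coefficients of variation (sample sd / mean over the three
  values) compared; the verdict is robust when CV(α̂) < CV(l₀).

## Division-pattern inference

Observed division events are binned to l₀ states (mother = sum of
daughters; a recorded mother deviating from that sum by more than l₀/2
is rejected and logged); the ratio r = n_daughter1/n_mother uses one
labelled daughter per event. A mother measured *at division* with s
binned units is post-growth, so its null daughters are drawn from the
kernel at pre-growth size s − 1. For each candidate kernel, the observed
census (events per mother class) is replayed 10⁴ times (configurable)
and each simulated ratio sample is compared with the observed one by a
two-sample KS test (asymptotic p-values; the event counts here are in
the thousands). The null is rejected when the *mean* p-value over the
ensemble falls below the significance level (5%); the per-sample
rejection fraction is also reported so stricter rules can be applied.
The middle kernel never produces ratios beyond one unit from ½, so
pole-biased data reject it categorically.

## Synthetic data generator

The generator maps a simulated lineage to continuous lengths:
state s ↦ s·l₀ + N(0, Δl₀·√s), the √s scaling expressing that unit-scale
noise accumulates with the number of units; draws are redrawn when
nonpositive, and daughter jitters are redrawn (rare) when a division
length would not exceed the dividing cell's birth length, since cells
cannot shrink. Each division event carries both daughters (discrete
sizes summing to the post-growth mother), and the emitted mother length
is the sum of the two jittered daughter lengths, so event tables are
exactly mass-consistent. Defaults are the wild-type study conditions:
α = 0.87, N = 20, binomial kernel, l₀ = 3.6 μm, Δl₀ = 0.5 μm, 3000
cells — under which the natural tail already puts ~10% of cells beyond
2·l₀; an optional `filament_fraction` adds explicit long-birth
contaminants for stress-testing the Z-score filter (default 0).
Fluorescence profiles are sums of Gaussian peaks (width λ/10) at
λ/2 + kλ from the pole, sampled every 65 nm, with multiplicative
Gaussian noise. What the generator does **not** emulate: sub-l₀ size
regulation, correlated segmentation errors, uneven illumination or
photobleaching in profiles, density-dependent growth-rate changes, and
division-efficiency drift during filamentation. Passing round-trip tests
therefore show that the pipeline inverts the model faithfully under its
own assumptions, not that those assumptions hold for any given strain.

## Numerical choices and degenerate inputs

Probabilities are validated at construction (column sums to 1e−12,
distribution sums to 1e−10); N = 2, α = 0 and α = 1 are all supported;
empty or single-element samples, nonpositive lengths, cyclic mother
links, mother classes of one unit, zero-variance KS inputs and
flat fit objectives raise typed errors or warnings rather than
propagating NaNs. Seeds are explicit everywhere randomness exists;
identical configurations give byte-identical tables.

## Problem sizes used by the tests and the acceptance script

Steady-state and increment checks use single lineages of 2·10⁵ steps
(2·10⁴ burn-in) at α = 0.1, N = 20, and 3·10⁵ steps (10⁵ burn-in) at
α = 0.87; convergence uses 150 lineages × 40 generations at N = 100;
estimation round-trips use 3000-cell populations, 165 noisy profiles,
and 200–300 bootstrap or KS resamples; the acceptance script's Monte
Carlo quantity uses one 3·10⁵-step lineage. These sizes reproduce the
quoted statistics comfortably; all stochastic comparisons are made in
units of the corresponding Monte Carlo standard error (batch means for
correlated trajectories), never as bare percentage slack.
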