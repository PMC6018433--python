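# sizechain

A discrete Markov chain model of bacterial cell-size control at the large
length scale, with the estimation pipeline needed to fit it to single-cell
microscopy data.

Rod-shaped bacteria such as *E. coli* occasionally fail to divide and grow
into filaments several times their typical length. The division machinery
(FtsZ ring positioning under Min/nucleoid-occlusion control) sets a
characteristic unit length l₀ and quantizes the prospective cleavage sites of
long cells, so at this scale growth and division are well described by a
chain on the integer cell sizes n = 1..N (in l₀ units): each time step a cell
grows one unit, and with probability α — the *division efficiency* — the step
ends in a division whose daughter sizes follow a *division pattern*. The
model explains how populations adapt to and recover from filamentation, and
why a sizer-like mechanism at the single-cell level still produces the
adder-like correlation (constant mean size increment, independent of size at
birth) observed at the population level.

`sizechain` is aimed at quantitative microbiologists and systems biologists
who have single-cell length tables (e.g. from Oufti or similar segmentation
tools) and want to estimate the unit size l₀ and division efficiency α of a
strain, or to ask which division pattern long cells follow.

## The model

The size distribution **p**(t) over states 1..N evolves as
**p**(t+1) = P **p**(t) with a column-stochastic transition matrix

    P_nm = (1 − α) δ_{n,m+1} + α P^{g+d}_nm,

where the growth+division kernel P^{g+d} for a mother of pre-growth size m
(post-growth m + 1, daughters n and m + 1 − n) is one of

* **binomial** — all prospective septa equiprobable:
  `C(m−1, n−1) / 2^(m−1)`,
* **middle** — cleavage at the centre (one or two central sites depending on
  parity),
* **inverse binomial** — `(1 − C(m−1,n−1)/2^(m−1)) / (m−1)`, favouring the
  poles,
* **uniform** — `1/m` on n = 1..m.

A cell at the maximal size N cannot grow: its column is the kernel at m = N
with division probability forced to one (the n = N outcome means "remain").
The stationary law solves (I − P)p = 0 with Σp = 1. Closed forms follow for
the newborn-size law π, the birth-size law π*, the joint law of birth size
and increment, and the mean increment of cells born with m units,

    <n>_m = (1 − (1 − α)^(N−m)) / α  →  1/α   as N → ∞,

which is independent of the division pattern; its slope in m vanishes for
N ≫ 1 — the adder correlation, without assuming an adder. In physical units
this is the relation Δl = ⟨l_b⟩ = l₀/α.

The estimation pipeline implements three estimators of l₀ (filtered
size-at-birth mean, mother−daughter length differences, and the spectral
septum spacing λ of fluorescence profiles with l₀ = λ/2), binning of
continuous lengths into l₀ states, a double-regression fit of α against the
stationary and birth-size laws, histogram collapse across growth media, an
l₀-sensitivity analysis, and a Kolmogorov–Smirnov procedure that tests
observed division ratios against each kernel's simulated null.

## Worked example

`examples/estimate_efficiency.py` generates a synthetic wild-type population
(α = 0.87, l₀ = 3.6 μm, jitter 0.5 μm, 3000 cells) and runs the pipeline on
it end to end:

```text
unit size from births: l0 = 3.61 +/- 0.52 um (kept 2589/3002 cells below 5.84 um)
ballpark alpha = l0/<l_b> = 0.86
binned size histogram: states 1-3 carry 99.2% of the mass
division efficiency: alpha = 0.872 (bootstrap 95% CI [0.865, 0.875])
sensitivity: CV(alpha) = 0.6% vs CV(l0) = 14.5% -> robust
```

Reading the numbers: the Z-score filter removes the filamentous tail and the
retained mean recovers the generating unit size; cells of one to three units
carry ~99% of the stationary mass; the double regression recovers the
generating efficiency α = 0.87 inside its bootstrap interval; and the fitted
α varies far less than the l₀ it is conditioned on, so the binning is robust.

The other examples each exercise one capability: `stationary_sizes.py`
(exact stationary laws per kernel), `adder_correlation.py` (simulated vs
closed-form mean increment), `filamentation_recovery.py` (size convergence
from filamentous and unit starts), `septum_spacing.py` (spectral l₀), and
`which_division_pattern.py` (KS pattern inference). A thin CLI mirrors the
library: `sizechain stationary|analytics|simulate|synth|estimate-l0|fit-alpha|collapse|sensitivity|pattern-test --help`.

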