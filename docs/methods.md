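# Methods

## Scope and model

`pmfbind` implements the free-energy inference chain used to quantify
state-dependent drug block of the hERG (Kv11.1) potassium channel:

1. umbrella-sampling window data along a 1-D reaction coordinate z (ligand
   centre of mass relative to the selectivity-filter anchor, in angstrom;
   more negative z is further down the permeation pathway toward the
   intracellular bulk);
2. reconstruction of the potential of mean force w(z) by the weighted
   histogram analysis method (WHAM);
3. conversion of the bulk-anchored PMF into an effective dissociation
   constant and standard binding free energy under a flat-bottom cylindrical
   restraint;
4. the drug-ionization (Henderson–Hasselbalch) calculation that frames the
   pH dependence of block; and
5. the three reduced patch-clamp measurement models (Hill
   concentration–response, single-exponential use-dependent block, Boltzmann
   conductance–voltage activation).

No molecular mechanics is performed. A synthetic-data module generates
biased Boltzmann samples from analytic ground-truth potentials so that every
downstream stage can be tested against a known answer.

## Synthetic umbrella sampling

**Ground-truth potentials.** Analytic 1-D potentials (sums of Gaussian
wells) stand in for the unknown true w(z). The `open-like` preset has two
moderate wells (−8 and −7 kcal/mol near z = −16 and −10 Å), mimicking the
two-site profile of the neutral ligand in the open channel; the
`inactivated-like` preset has one deep well (−18 kcal/mol at z = −10 Å) plus
a shallow outer minimum, mimicking the lock-in profile of the cationic
ligand in the open-inactivated channel. All presets are exactly zero over a
declared bulk plateau at the most-negative (intracellular-bulk) end of their
domain, so bulk-anchored reconstructions are directly comparable to the
preset. `flat`, `harmonic` and `square-well` presets support analytic
limit tests.

**Window layout.** Windows are spaced every 0.5 Å with a harmonic force
constant of 10 kcal mol⁻¹ Å⁻²: −49.5 … −7.5 Å (85 windows) for the
open-channel geometry and −38.0 … −8.5 Å (60 windows) for the
open-inactivated geometry. The bias is U = (k/2)(z−z₀)²; a `full-k`
convention (U = k(z−z₀)², the dialect of some WHAM tools) is accepted as a
configuration switch everywhere the bias enters.

**Sampler.** Each window is sampled by Metropolis-adjusted overdamped
Langevin dynamics (MALA): an Euler–Maruyama proposal with diffusion
coefficient D and step dt followed by a Metropolis–Hastings correction. The
correction makes the chain's stationary law *exactly* the biased Boltzmann
density exp(−[u(z)+U_bias(z)]/k_BT), so WHAM tests probe WHAM rather than
integrator discretisation error; uncorrected Langevin is available for
comparison. Defaults: D = 1 Å²/τ, dt = 0.01 τ (proposal sd 0.141 Å, ~98%
acceptance against the 0.248 Å stationary width of a k = 10 window at
310.15 K), 2.2×10⁵ steps per window in reduced time units. With the default
burn-in fraction 2/22, 2×10⁵ samples survive per window — the synthetic
analogue of keeping the last 20 ns of a 22 ns window. The sampling
frequency of the underlying study's collective-variable series is not
knowable from the reported methods; this per-window sample count is a
package choice, documented here once and fixed. Chains start at the argmin
of the biased potential on a 0.001 Å grid. A trajectory leaving the
potential domain by more than 5 Å aborts with advice to reduce dt.

A master seed deterministically derives one sub-31-bit seed per window
(numpy `SeedSequence`), and each window consumes only its own random
stream, so a window's trajectory is identical whether sampled alone or in a
batch and full pipeline runs are byte-reproducible.

## WHAM

Histograms share one uniform grid (default bin width 0.1 Å — five bins per
window spacing, enough to preserve PMF curvature), with half-open
[left, right) bins and a right-closed last bin so retained counts are
conserved exactly; out-of-range samples are counted and reported, never
silently dropped. Bins with no samples are flagged missing, not
interpolated.

The WHAM self-consistency equations are iterated in log space
(`scipy.special.logsumexp`) on the reduced window constants g_i = f_i/k_BT,
gauge-fixed to f₁ = 0. Convergence is declared when the largest per-sweep
change of any f_i falls to the tolerance, 10⁻⁷ kcal/mol by default. (The
tolerance is applied to the f_i, not to the density; this is the stated
semantics of the package.) Direct iteration is wrapped in type-II Anderson
acceleration (order 5, least squares on residual differences, restart after
five consecutive residual increases); on the 85-window problem this cuts
~3×10⁴ plain sweeps to under 10³. Because the stopping rule bounds the
per-sweep change rather than the distance to the fixed point, tests that
compare two solution routes solve to 10⁻¹⁰ first. Unconverged runs return a
flagged result rather than raising, so diagnostics can still be inspected;
extracting a PMF from one requires an explicit override. Before solving,
the window-overlap graph (edges where two windows share at least
`min_count` = 1 samples in some bin) must be connected; a disconnected
graph is an error listing the components.

The PMF is w(z) = −k_BT ln ρ(z) on supported bins and is conventionally
offset so that its *mean over a declared bulk range* is exactly zero
(`bulk-zero`); the offset is a pure gauge shift and leaves per-bin
uncertainties untouched. At least three supported bulk bins are required.

**Uncertainties.** The exact error formula used alongside the original
simulations is not restated in the available text, so the package documents
its own standard scheme rather than claiming equivalence: each window's
statistical inefficiency g = 1 + 2Σ(1−t/n)ρ(t) is estimated from the
integrated autocorrelation time (initial-positive-sequence cutoff, FFT
autocovariance); the window then carries n/g effective samples. A seeded
bootstrap redraws every window's histogram multinomially with n/g counts,
re-solves WHAM warm-started from the base solution, applies the bulk offset
per replicate, and reports the per-bin standard deviation across replicates.
Windows shorter than 10g are flagged. Under i.i.d. sampling the stderr
scales as 1/√n (tested: quadrupling n halves it), and duplicating every
sample doubles g while leaving the stderr unchanged.

## Binding thermodynamics

With the ligand confined laterally by a flat-bottom cylinder of radius R
(default 10 Å), the effective 1-D dissociation constant is

    K_D = [ πR² N_A ∫_site exp(−w(z)/k_BT) dz ]⁻¹   (mol/L),

with the integral a trapezoid over the bin grid (Å³ → L via 10⁻²⁷; tests
document agreement with Simpson quadrature on smooth wells), and

    ΔG = k_BT ln(K_D / c⁰),   c⁰ = 1 mol/L.

A raw-offset PMF is refused — the integral is only meaningful with w = 0 in
bulk. Physical constants are pinned (k_B = 1.9872041×10⁻³ kcal mol⁻¹ K⁻¹,
N_A = 6.02214076×10²³ mol⁻¹, T = 310.15 K) so conversions reproduce
bit-for-bit across platforms. Every `BindingResult` satisfies
ΔG = k_BT ln(K_D/c⁰) exactly by construction and records its site bounds,
parameters and a provenance hash. These are *effective one-dimensional*
estimates: the lateral volume enters only as πR², and no
orientational/conformational restraint corrections are applied — the
binding report says so explicitly.

**Site bounds.** No published bound for the spatial integral exists, so the
default rule is: starting from the cavity-side end of the profile and moving
toward bulk, the site ends where w(z) first rises above −1·k_BT. Bins with
fewer than 1% of the best-sampled bin's counts (minimum 10) are excluded
from the rule — the nearly-empty tail bins beyond the outermost window
carry large w noise that would otherwise truncate or inflate the site. Deep
wells dominate the Boltzmann integral, so the result is insensitive to the
cutoff: for the deep-well preset, K_D moves by under 5% as the threshold
sweeps 0.5–2 k_BT (tested). Bounds are overridable per run and always
recorded.

**Ionization.** The protonated fraction of the ligand's basic amine is
f = 1/(1 + 10^(pH − pKa)). The ligand's pKa is an explicit argument with no
shipped default (it is a property of the compound, not of this method);
pKa 7.0 gives 28.5% protonated at pH 7.4 and 86% at pH 6.2.

**Error propagation.** stderr_ΔG comes from a seeded parametric bootstrap:
each replicate perturbs every site bin by an independent Gaussian with that
bin's stderr and recomputes ΔG. For small errors this scales linearly
(tested). Per-bin errors are treated as independent, which overstates the
effective noise relative to the correlated errors a full resampling of
trajectories would give; the bootstrap route through
`estimate_uncertainty` is the primary uncertainty path.

## Measurement models

All three fits are ordinary least squares (`scipy.optimize.curve_fit`,
tolerances 10⁻¹⁴, bounded parameters), deterministic given the data and
start, and invariant to row order. Standard errors come from the fit
covariance and are omitted when the number of points does not exceed the
number of parameters.

* **Hill**: block(c) = 1/(1 + (IC50/c)^n_H), parameterised as fractional
  *block* (adapters convert current amplitudes as 1 − I/I_baseline). With no
  start given, a deterministic multi-start grid (9 log-spaced IC50 ×
  4 Hill-coefficient values) selects the best residual.
* **Exponential decay**: I(t) = A·exp(−t/τ) + C. The steady-state offset C
  is included by default and declared on the result (switchable); τ is the
  use-dependent block time constant. Non-decaying data (fitted A ≤ 0) is
  flagged unconverged; constant data is an error.
* **Boltzmann activation**: g/g_max = 1/(1 + exp((V½ − V)/k_s)); positive
  slope factor means activation with depolarisation. g_max may optionally
  be fitted. A fitted midpoint outside the sampled voltage range flags the
  result as one-sided.

Condition comparisons use Welch's unequal-variance t-test on per-cell
parameter values, two-sided, with no multiple-testing correction (single
planned comparisons). Both per-cell and pooled concentration–response fits
are supported; which was used should be stated alongside results.

## What the synthetic generators do and do not show

The generators emulate (a) biased Boltzmann sampling of a 1-D coordinate at
310.15 K and (b) noisy Hill/exponential/Boltzmann measurement curves with
additive Gaussian noise. They do not emulate force-field error, slow
orthogonal degrees of freedom, hidden hysteresis between windows,
cell-to-cell variability structure, or rundown in recordings. Passing tests
therefore demonstrate the *estimators* are correct and well-calibrated on
their stated models — not that microsecond MD or patch-clamp data would
yield the published numbers; the published PMFs, IC50s, time constants and
V½ values are not reproducible at desk scale and enter only as generator
parameters and round-trip targets.

## Problem sizes and numerical choices

Default synthetic studies use the full window layouts (85 and 60 windows)
at 2.2×10⁵ steps per window; a full pipeline runs in well under a minute on
one CPU. At these sizes WHAM reconstructs the open-like preset with RMS
error ≈ 0.04 kcal/mol (acceptance threshold 0.2) and recovers the preset's
closed-form K_D within a few percent (threshold: factor of 2; an RMS PMF
error of 0.2 kcal/mol exponentiates to at most ≈ 1.4×). Consistency tests
at reduced sizes (10³–10⁵ samples) verify that the PMF error falls as
sampling grows. The deep-well preset's minimum is recovered at
18.1 kcal/mol against the −18 kcal/mol truth.

Degenerate inputs are handled explicitly: empty windows after burn-in name
the window; a flat profile with no bins below the site threshold refuses to
auto-select a site; K_D/ΔG conversions reject non-positive K_D;
zero-temperature and steep-slope limits saturate cleanly.

## Known limitations

* Strictly 1-D: the cylindrical restraint enters analytically as πR²; no
  lateral sampling, no multidimensional WHAM, no replica exchange.
* MBAR-family estimators are out of scope as the primary method (the
  independent oracle used in tests is a direct fixed-point WHAM
  implementation).
* The uncertainty scheme is a documented standard stand-in
  (autocorrelation-based effective sample size + histogram bootstrap), not
  a reproduction of any specific published error formula.
* Raw-trace processing (leak/capacitance correction, tail-current windows)
  is out of scope; measurement fits consume already-reduced tidy tables.
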