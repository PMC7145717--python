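# Methods

`oligosas` infers the distribution of oligomeric states (monomer through
pentamer) of a flexible multi-domain protein in solution from a single
1-D small-angle scattering curve. The workflow mirrors the
flexible-oligomer ensemble analyses used for self-associating proteins
such as the *E. coli* replication initiator DnaA: coarse-grained
conformer pools per association state, Debye-formula model curves, a
χ² refinement, and genetic-algorithm (EOM/GAJOE-style) selection of a
best-fitting sub-ensemble whose per-state selection frequencies are the
readout.

## Primary analytics

**Guinier fit.** ln I is regressed on Q² over a low-Q window with
weights (I/σ)²; Rg = √(−3·slope), I(0) = exp(intercept), standard errors
from the weighted-least-squares covariance. The window grows from the
lowest usable Q (first contiguous run of I > 0) and the largest window
whose own fit satisfies Q_max·Rg ≤ `qrg_limit` (default 1.3, the
conventional validity bound) is kept. Windows too short or too noisy to
show decay are skipped rather than treated as failures; only when no
window anywhere shows decay is a "non-Guinier behaviour" error raised.

**P(r) by regularized indirect Fourier transform.** The linear model
I(Q_k) ≈ 4π Σ_j P(r_j) sinc(Q_k r_j) Δr (trapezoid quadrature, uniform
grid of `n_r` = 101 points, endpoints pinned to zero at r = 0 and
r = Dmax) is solved as uncertainty-weighted non-negative least squares
with a second-difference smoothness penalty α‖D₂p‖². Positivity is a
hard constraint (NNLS) because physical P(r) of a single contrast sign
is non-negative. For α = "auto" a 25-point log-spaced scan of
α ∈ [10⁻⁴, 10⁴] × α₀ (α₀ balances the Gram traces of the data and
penalty operators) is evaluated and the *largest* α whose reduced χ²
stays within max(1, 1.05·χ²_min) is chosen — a discrepancy rule. An
L-curve corner criterion was tried first and degenerates on noise-free
curves (the residual branch is flat), picking absurd over-smoothing;
the discrepancy rule is deterministic and robust on both noisy and
clean data.

Real-space quantities follow from quadrature: I(0) = 4π∫P dr and
Rg² = ∫r²P dr / (2∫P dr).

**Dmax selection.** Each candidate Dmax is scored by a composite quality
in [0, 1], the product of: (i) misfit — 1 for χ² ≤ 1, 1/χ² above (a fit
better than the stated uncertainties is never penalized, since σ may be
nominal); (ii) positivity (1 by construction, kept for the record);
(iii) smoothness — penalizing an excessive fraction of sign changes in
successive differences of P(r); and (iv) tail support — the ratio of the
effective size (99.9% of the cumulative P mass) to Dmax, which
discriminates an over-large Dmax whose χ² is otherwise just as good.
A grossly undersized Dmax shows up as χ² ≫ 1 and is flagged through the
quality score rather than raised as an exception.

## Coarse-grained models

One bead per residue at Cα resolution, uniform scattering amplitude
f = 1. The architecture is three contiguous spans: a rigid N-terminal
head (residues 1–108), a flexible linker (109–129) and a rigid core
(130–467), the DnaA domain I / II / III–IV layout. Rigid bodies are by
default programmatic self-avoiding globules (uniform rejection sampling
in a ball sized so Rg ≈ 2.4·n^⅓ Å, minimum bead separation 3.0 Å); real
Cα coordinates can be substituted from PDB files. The linker-attachment
bead of a generated globule is swapped to the position farthest from the
centroid — a stand-in for the fact that a terminal residue sits on the
domain surface; without this the linker would have to thread out of the
globule interior and sampling stalls.

Conformers hold the core fixed (bit-identical across a state) while the
linker is resampled as a fixed-step random walk whose per-step direction
deviates from the previous one by an angle uniform in [0°, 120°], with
clash rejection, and the head is rigidly re-attached at the linker's
free end with a uniformly random orientation (bond direction drawn in a
90° cone continuing the walk), rejected on clash. This emulates
"domains I and II mobile, III–IV fixed" Monte-Carlo sampling at desk
cost; it is *not* a reimplementation of an all-atom torsion sampler, and
its conformer distribution is a declared stand-in.

Oligomers place `order` copies of the core head-to-tail by a helical
interface transform — rotation of 60° about the z axis plus a
translation of one core diameter per step. The default diameter is
twice the core's maximal radial extent plus the clash distance, which
provably keeps all copies clash-free for any core; the tighter "maximal
pairwise extent" definition occasionally clashed for specific globules.
The true oligomer interface geometry of DnaA-like AAA+ proteins is not
modelled; the transform is config-exposed. Each protomer receives its
own independently sampled linker and head. Mean Rg is strictly
increasing with oligomer order by construction (ring growth), matching
the qualitative ordering of per-state Rg histograms in flexible-oligomer
studies.

**Pools.** `generate_pool` builds `n_per_state` conformers per requested
state with per-particle Debye curves precomputed on the analysis Q grid
(default 150 log-spaced points in [0.008, 0.35] Å⁻¹, an artifact choice
— instrument binning is not modelled). Full-scale pools are 10 000 per
state; the desk scale used throughout the tests is 200–500.

## Scattering and fitting

**Debye sums.** Exact pairwise evaluation (q-chunked to bound memory)
and a pair-distance-histogram mode with mass-weighted bin centers
(default bin width 0.25 Å, ≤ 1% relative deviation from the exact sum
for the models used here; 0.5 Å bins with midpoint centers miss that
contract near intensity minima). `auto` switches to the histogram above
400 beads. Comparisons against the analytic sphere form factor are made
on I(0)-normalized curves: the form factor's zero at QR ≈ 4.49 makes a
pointwise ratio unbounded for *any* finite bead model, whose incoherent
n-bead floor does not vanish.

**χ².** Reduced χ² with the analytic least-squares scale factor
c = Σ(I_m I_d/σ²)/Σ(I_m²/σ²) and N−1 normalization (one fitted
parameter, the scale).

## Ensemble inference

Per state, the `keep` conformers with lowest single-model χ² are
retained (default 40 of 200 — the same 20% retention ratio as the
full-scale 2000 of 10 000; keeping everything measurably worsens
fraction recovery because poorly matched decoy shapes inflate
state-leakage). The refined states are merged and a genetic algorithm
searches multisets of `ensemble_size` conformers (desk default 50;
full-scale 1000) drawn with replacement; fitness is the χ² of the
equal-weight average curve. Equal member weights follow the EOM
"ensemble average" convention; no per-member weight optimization.

GA design: population 100, ≤ 500 generations, elitism 2, tournament
parent selection (size 2), uniform crossover (rate 0.5), per-slot
mutation to a uniformly random pool member (rate 0.05), early stop
after 100 stagnant generations. Initialization is half random multisets
of the 100 best single conformers, half uniform over the pool — mixed on
purpose: an all-top-singles start biases the final composition toward
whichever state happens to contain the best single curve. One initial
candidate is N copies of the best single conformer, so with elitism the
final ensemble can never fit worse than the best single model. The GA
winner is polished by an exchange (coordinate) descent that tries every
pool curve in every slot with an incremental χ² update.

**Discrepancy stop.** Both the GA and the descent halt once reduced
χ² ≤ 1. Minimizing below the noise level only fits the noise
realization, and measurably drags the recovered composition toward
degenerate near-equal mixtures (the χ² landscape has many deep
overfit minima at compositions far from the truth). Stopping at the
noise level keeps the estimate near the composition-profile minimum.
Smaller populations/budgets (the first design iteration used population
50, 200 generations, mutation 0.1, patience 30, top-singles-only
initialization and no descent) failed to converge at all on desk-scale
mixtures — ensemble χ² stalled at 4–17 with run-to-run fraction SD
≈ 0.17.

`n_runs` independent GA runs (default 3) give per-state
selection-frequency fractions with across-run SD. An auxiliary
intensity-share metric (each state's share of the summed zero-angle
intensities of the selected members) is reported alongside, because a
dimer contributes ~4× the forward scattering of a monomer; when the
number-fraction readout is near its resolution limit the intensity
share is often the more decisive quantity.

## Synthetic ground truth

`make_mixture_profile` draws `n_draws` = 10 000 conformers multinomially
across states by the truth fractions, averages their per-particle
curves with equal weights (the same convention the fit uses) and adds
Gaussian noise σ(Q) = a·I(Q) + b, defaults a = 0.02 and
b = 10⁻⁴·I(0) — a standard relative-plus-floor model; the originating
experiments give no error model. The draw count is deliberately large:
a real measurement averages ~10¹² particles, and at 1000 draws the
realized composition itself fluctuates by SD ≈ 0.016, an artificial
noise source comparable to the recovery tolerances. Named presets
encode the reported DnaA oligomer distributions (apo 69.4/28.4/2.2;
0.5 mM ADP 71/28/0.9 renormalized; 0.5 mM AMP-PNP 49/52 renormalized —
the printed values sum to 101; D₂O AMP-PNP fixed once at
1/70/17/8/4 — only "~70% dimer, monomers almost absent" is reported,
the remainder is spread over higher states). The D₂O/SANS condition is
represented only as a fraction vector; no neutron contrast or
instrument effects are computed.

What the generator does *not* emulate: inter-particle interference
(structure factor), concentration effects, hydration-shell contrast,
atomic form factors, instrument smearing, or any mismatch between the
fitting pool and the data-generating ensemble. Passing recovery tests
therefore demonstrate the correctness and stability of the inference
machinery under matched-model conditions, not performance on real
curves, where model mismatch dominates.

## Accuracy at desk scale, and a known limitation

With the defaults above (pool 200/state, ensemble 50, keep 40, 2%
noise), replicate-averaged benchmarks give per-state recovery biases of
≤ 0.06 absolute for the apo-like mixture with across-run SD ≤ 0.05, and
monomer-only data is recovered at fraction 1.0. The composition
resolution of the estimator, measured across noise realizations, is
roughly ±0.04–0.05 per state. Consequently the AMP-PNP-like condition —
whose true monomer/dimer split differs by only 0.03 — sits at the
resolution limit of the *number-fraction* readout: whether the
recovered dimer fraction exceeds the monomer fraction depends on the
noise realization. The intensity-share readout is robustly
dimer-dominant (≈ 0.65–0.77 vs ≈ 0.2) in the same fits. Resolving a
0.03 number-fraction split reliably would need lower noise, larger
ensembles, or full-scale pools.

## Reproducibility

Every stochastic stage takes an explicit seed; derived seeds are mixed
through `numpy.random.SeedSequence` and kept below 2³¹. Identical
configuration plus seed reproduces reports bit-for-bit. Pipeline runs
echo their full configuration into the output directory.
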