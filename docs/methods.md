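# Methods

This note documents the models implemented in `foldsaxs`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
benchmarks do and do not demonstrate.

## Conformational-state assignment

Flexible foldamers interconvert between compact (folded) and extended
(unfolded) ensembles on nanosecond timescales, so classifying individual
MD frames by instantaneous Rg would be dominated by sub-ns fluctuations.
The trajectory is instead partitioned into consecutive intervals of fixed
length (default 1 ns; must be at least one frame), each summarised by the
arithmetic mean Rg of its own frames. A trailing partial interval is kept
as its own interval — dropping it would silently bias short trajectories —
and its mean uses only its own frames. Intervals with mean Rg at or below
the threshold are folded (`fc`); the tie goes to folded because the folded
state is the compact, low-Rg one. The MD folded fraction counts frames,
not intervals, so unequal interval lengths weight correctly.

The threshold is physically meaningful only when the interval-Rg
distribution is bimodal, which it is when state dwell times exceed the
interval length. The `auto_threshold` convenience runs 1D 2-means (Lloyd
iteration initialised deterministically at the min and max, hence seed-free
and reproducible) and returns the centroid midpoint together with a
bimodality diagnostic, the between- to within-cluster variance ratio;
values ≳ 4 indicate well-separated populations. A user-supplied threshold
is the authoritative path for real systems, where the cutoff should be
chosen by inspecting the Rg time series.

Rg supports mass weighting (the MD-analysis convention, the default) and
electron-count weighting (what SAXS actually probes). For organic
molecules the two differ by well under the other uncertainties of the
protocol; both are exposed so the choice is explicit.

## Forward scattering model

Atomic form factors use the standard Cromer–Mann 4-Gaussian parametrisation
(International Tables for Crystallography Vol. C), shipped as a text table
for H, C, N, O, Na, P, S, Cl with q in Å⁻¹ and b-coefficients in Å². Each
entry is validated on load: f(0) = c + Σaₖ must agree with the element's
atomic number to within 0.2 e.

Solvent contrast is implicit. `vacuum` mode ignores the solvent entirely;
`excluded_volume` mode subtracts per atom a Gaussian dummy of the bulk
solvent electron density (334 e/nm³, liquid water) occupying the atom's
Fraser displaced volume:

    f_eff(q) = f(q) − ρ_s V_j exp(−q² V_j^{2/3} / 4π).

Hydrogen's contrast is negative in water (V_H ρ_s > f_H(0) ≈ 1), which is
physical, not a bug. Explicit-solvent approaches that model the hydration
layer from solvated simulation boxes are deliberately out of scope: this
package consumes solute-only trajectories. The solvent mode is recorded in
every curve's metadata for transparency. Displaced volumes are not
tabulated for Na and Cl; using them in excluded-volume mode is an error
rather than a silent guess.

Two orientational averages are implemented and cross-checked against each
other in the tests:

* the exact Debye double sum, O(N²) per q, with the i = j and q → 0 limits
  of sin(x)/x taken as 1 — practical for up to a few thousand atoms;
* a Monte-Carlo average of |Σⱼ fⱼ exp(i q⃗·r⃗ⱼ)|² over directions on the
  sphere, O(N) per direction, 500 directions per |q| by default. The
  default direction set is a deterministic Fibonacci lattice (lower
  variance, reproducible without a seed); a uniform-random sampler with a
  seed is available, and it reports the per-direction standard error in the
  curve's σ column. The estimator is unbiased for the Debye value; the
  i.i.d. error bars are meaningful only for the random sampler.

Ensemble curves are unweighted means of per-frame intensities, optionally
strided; the stride trades statistical sampling of the ensemble against
O(N² · frames · n_q) cost and is recorded in the output metadata.

## Guinier and Kratky analysis

`guinier_fit` fits ln I = ln I₀ − (Rg²/3) q² by weighted least squares
(ln-space weights (I/σ)² when σ is present) over the largest contiguous
low-q window satisfying q·Rg ≤ 1.3 self-consistently: the window is
enlarged or shrunk and the fit repeated until the limit holds at
convergence. The 1.3 default is the standard validity heuristic for
globular particles and is configurable; the window actually used is
recorded in the result. Data after the first non-positive intensity are
never used. A non-decaying low-q region raises a dedicated error rather
than returning an imaginary Rg.

A known systematic documented by the tests: for shapes with a strong q⁴
term in their low-q expansion the fitted Rg over the full q·Rg ≤ 1.3
window carries a shape-dependent bias — about +2% for a solid sphere,
several percent (negative) for elongated hairpins. The bias is a property
of the Guinier approximation itself, not of the fitting; analyses that
need sub-percent Rg accuracy on known-anisotropic particles should lower
`qrg_limit`. The cross-module consistency test therefore uses a
Gaussian-density bead cloud, the shape whose Guinier plot is exactly
linear, where the fit recovers the geometric electron-weighted Rg to
better than 1%.

The Kratky transform is q²·I(q) with σ propagated as q²·σ; compact
particles give a bell-shaped curve, extended chains a rising one.

## Population fitting

The experimental curve is modelled as s · Σ_s w_s I_s(q) + b. Weights are
constrained to the simplex so they read directly as populations; the
global scale s (always fitted) absorbs the arbitrary intensity units, and
the additive background b is off by default (enable `fit_background` when
the buffer subtraction is uncertain). For fixed weights, (s, b) have a
closed weighted-least-squares form, so the optimisation runs over the
weight simplex only: SLSQP from a deterministic multi-start (simplex
vertices plus barycenter), with the data, basis and σ rescaled to O(1)
magnitudes internally — SLSQP's line search is unreliable when the
objective is ~10⁵ — without changing the reported χ²/N, scale or
background. σ-weighted least squares is used when the experimental curve
carries uncertainties, unweighted otherwise.

Identifiability: when the state curves are identical up to scale the
weights are meaningless; the fit warns and reports weight uncertainty
intervals spanning [0, 1]. Weight uncertainties are otherwise estimated by
a seeded residual-resampling bootstrap (default 200 replicates, 2.5/97.5
percentiles). An unconstrained least-squares solution normalised post hoc
is always reported alongside (`free_weights`) as a consistency diagnostic:
large disagreement with the simplex solution signals that the basis curves
do not bracket the data.

Fits restricted to the overall-shape regime use `truncate_q_range`
(e.g. q ≤ 0.4 Å⁻¹ for larger constructs, where higher-q detail reflects
internal structure the two-state basis cannot describe).

## Synthetic two-state generator

The generator emulates exactly the statistical structure the protocol
relies on, and nothing more chemical than that:

* an 18-bead chain of alternating C/O atoms at 0.5 nm spacing (glycosidic
  scale); folded template a two-leg antiparallel hairpin at 0.45 nm strand
  separation, unfolded template a straight chain — so folded Rg < unfolded
  Rg for every chain length ≥ 4;
* two-state Markov switching with prescribed stationary occupancy p and
  mean dwell m, realised as state dwell times τ_fc = 2pm and τ_uf =
  2(1−p)m (default m = 5 ns, well above the 1 ns interval, so the
  interval-Rg histogram is strongly bimodal);
* i.i.d. Gaussian coordinate jitter (0.05 nm SD) on the templates;
* pseudo-experiments I_exp = s·Σ w_s I_s + b + ε with ε ~ N(0, 0.02·I) by
  default and the true noise level written to the σ column.

Everything is seeded and bit-reproducible. What these benchmarks show:
the pipeline recovers known mixing weights and occupancies to ±0.05 under
2% noise when the states are genuinely distinct and the basis curves come
from the same ensembles that generated the data. What they do not show:
robustness to force-field error, to hydration-layer scattering, to more
than two states, or to basis curves computed from simulations that do not
sample the experimentally populated conformers — on real systems those are
the dominant error sources.

Benchmark problem sizes: end-to-end runs use 2000–4000 ns of trajectory
(20 000–40 000 frames at 0.1 ns), chosen so the Markov sampling error of
the occupancy estimate (SE ≈ √(4m·p²(1−p)²/T)) is ~0.01–0.02, comfortably
inside the ±0.05 recovery bands; state curves are evaluated on 120 q
points in [0.01, 0.45] Å⁻¹ with the ensembles strided to ~120 frames,
matching the point density of measured SAXS curves.

## Numerical and interface conventions

* Lengths are nm internally; q is Å⁻¹ and Guinier Rg is Å at interfaces
  (1 Å⁻¹ = 10 nm⁻¹, applied exactly once in the forward model).
* Torsions follow the IUPAC sign convention via
  atan2((n₁×n₂)·b̂₂, n₁·n₂), reported in (−180°, 180°]; collinear central
  bonds raise an error rather than returning NaN.
* CH···O contacts are favourable iff C–O < 0.4 nm AND C–H···O > 150°,
  both strict — boundary values are excluded.
* File formats are text only: PDB (ATOM/HETATM, MODEL/ENDMDL), GRO
  (single or concatenated frames), whitespace-delimited q/I[/σ] curves
  with `#` comments. Curve writers round-trip to 6 significant digits.
  Element resolution: explicit element column wins; otherwise PDB
  name-based inference (a name starting in column 14 is a one-letter
  element, so sugar "CA" is carbon; names filling column 13 prefer valid
  two-letter symbols, so "NA" is sodium); unknown elements are an error
  unless explicitly overridden or allowed.
* The frame time step is user-supplied: PDB/GRO carry no reliable time
  metadata.
* The pipeline derives all stage seeds from one top-level seed; reruns on
  identical inputs produce byte-identical reports.

## Known limitations

* Two states are first-class; the fitting API accepts ≥ 2 basis curves but
  the assignment stage is strictly binary by design.
* No explicit-solvent scattering, no hydration-shell density fitting, no
  P(r) inversion, no WAXS beyond q ≈ 1 Å⁻¹.
* A high-q intensity decay caused by conformers absent from the simulated
  ensembles cannot be modelled by any weighting of the available basis
  curves; restricting the fit window (q_max) is the supported mitigation.
* The Debye path is O(N²) per frame per q; beyond a few thousand atoms use
  the Monte-Carlo average or stride the ensemble.
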