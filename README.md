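# foldsaxs

Quantifying how *folded* a flexible molecule is in solution is hard:
ensemble-averaged observables (NMR chemical shifts, a single Rg from SAXS)
collapse a mixture of conformers into one number. `foldsaxs` implements a
semiautomated protocol for estimating conformational populations — the
**degree of folding** — of flexible (glyco)foldamers by combining MD
trajectories with small-angle X-ray scattering:

1. **State identification.** The trajectory's per-frame radius of gyration
   R_g(t) is averaged over fixed time intervals (1 ns by default) and each
   interval is classified folded (`fc`, compact) or unfolded (`uf`,
   extended) against a threshold, either user-supplied or found by 1D
   2-means clustering of the interval means.
2. **Forward SAXS per state.** Frames of like-labelled intervals are
   concatenated and each ensemble's theoretical scattering curve is the
   unweighted frame average of

   I(q) = Σᵢ Σⱼ fᵢ(q) fⱼ(q) · sin(q·rᵢⱼ)/(q·rᵢⱼ)

   (Debye equation), with Cromer–Mann atomic form factors
   f(q) = c + Σₖ aₖ·exp(−bₖ (q/4π)²) and optional implicit excluded-volume
   solvent contrast (Fraser dummy atoms at 334 e/nm³). A Monte-Carlo
   orientational average over q-vector directions (default 500 per |q|) is
   available as a cross-checked alternative to the exact double sum.
3. **Population fit.** The experimental curve is modelled as
   s·Σ_s w_s I_s(q) + b with the weights constrained to the simplex
   (w_s ≥ 0, Σ w_s = 1), so w_fc is directly the folded population.

Guinier fitting (Rg from ln I = ln I₀ − q²Rg²/3 at q·Rg ≤ 1.3), the Kratky
transform q²·I(q), CH···O hydrogen-bond geometry (favourable when
C–O < 0.4 nm and C–H···O > 150°), and glycosidic Φ/Ψ torsions are included
as turn-unit diagnostics. A synthetic-data module generates two-state
bead-polymer trajectories (hairpin ⇌ extended chain, Markov switching with
prescribed occupancy and dwell time) and pseudo-experimental curves with
known mixing weights, so the entire pipeline is testable against ground
truth without any external data.

Units: lengths in nm internally; q in Å⁻¹ and Guinier Rg in Å at every
interface (1 Å⁻¹ = 10 nm⁻¹).

## Worked example

Generate a two-state trajectory with 75% folded occupancy, run the
protocol, and fit a pseudo-experimental curve mixed at w_fc = 0.75 with
2% noise:

```python
import numpy as np
import foldsaxs as fs

spec = fs.TwoStateSpec(occupancy_folded=0.75, seed=11)
traj, labels = fs.generate_two_state_trajectory(spec, n_frames=20_000, frame_time_step=0.1)

rg = fs.rg_series(traj)
intervals = fs.partition_intervals(rg, frame_time_step=0.1, interval_length=1.0)
cut = fs.auto_threshold([iv.mean_rg for iv in intervals])
assignment = fs.assign_states(intervals, cut.threshold)
print(f"threshold {cut.threshold:.3f} nm, bimodality {cut.bimodality:.1f}")
print(f"MD folded frame fraction: {fs.md_folded_fraction(assignment):.3f}")

q = np.linspace(0.01, 0.45, 120)
curves = {}
for state in ("fc", "uf"):
    ensemble = fs.concatenate_state_frames(traj, assignment, state)
    curves[state] = fs.ensemble_intensity(ensemble, q, stride=ensemble.n_frames // 120)

experiment = fs.generate_pseudo_experiment(
    curves, {"fc": 0.75, "uf": 0.25}, noise_fraction=0.02, seed=12)
result = fs.fit_populations(experiment, curves)
print(f"degree of folding: {result.degree_of_folding:.3f}  (chi2/N = {result.chi2_reduced:.2f})")
print(fs.report_degree_of_folding(result)["populations_percent"])
```

prints

```
threshold 1.906 nm, bimodality 11.6
MD folded frame fraction: 0.752
degree of folding: 0.742  (chi2/N = 0.85)
{'fc': '74%', 'uf': '26%'}
```

The 2-means threshold (1.906 nm) separates the bimodal interval-Rg
distribution cleanly (between/within variance ratio 11.6); the frame
fraction recovers the generator's 75% occupancy, and the SAXS mixture fit
recovers the mixing weight to within its noise-limited precision (about
±0.03 at 2% intensity noise). `chi2/N ≈ 1` indicates the two-state model
describes the pseudo-experiment to within its error bars.

The same workflow runs from the shell on files (multi-model PDB or
concatenated GRO trajectories, 2–3-column ASCII curves):

```sh
foldsaxs simulate --n-frames 2000 --occupancy-folded 0.75 --out-prefix toy
foldsaxs assign-states toy.pdb --frame-time-step 0.1 --auto-threshold
foldsaxs predict-saxs toy.pdb --frame-time-step 0.1 --method debye --out pred.dat
foldsaxs guinier experiment.dat
foldsaxs fit-populations --exp experiment.dat --state fc=fc.dat --state uf=uf.dat --qmax 0.4
foldsaxs run-protocol config.yaml --out-dir run   # everything, from a YAML config
```

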