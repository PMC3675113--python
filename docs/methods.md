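# Methods

## Equilibrium model

The protein is modelled as two independent 1:1 metal-binding sites, the
EF-hand pair of a parvalbumin domain: a high-affinity EF site and a CD
site ~5–6-fold weaker. When only an EF-site constant is supplied, the
CD constant defaults to EF × 5.5, the midpoint of that range. No
cooperativity, ionic-strength/activity corrections or pH dependence are
modelled, and no kinetics — everything is equilibrium thermodynamics.

With independent sites, the occupancy of each site and chelator is
analytic given the free metal concentrations, so speciation reduces to
solving the metal mass balances. `solve_speciation` iterates a damped
fixed point on the free metal concentrations in log space (geometric
damping keeps iterates positive; the damping factor halves whenever a
step increases the residual, which handles the oscillatory regime), with
an iteration cap of 10,000 and a default relative mass-balance tolerance
of 1e-12 (must close within at most 1e-3; tests verify ≤ 1e-9).
Non-convergence raises an error carrying the final residual rather than
returning a half-converged state.

The terbium luminescence signal is a weighted linear sum of site-bound
Tb³⁺ with default weights EF:CD = 5:1 — the EF site dominates the
sensitised emission — which is what makes the chelator-competition
curve look quasi-cooperative and motivates the Hill parameterisation of
its midpoint.

### Apparent ↔ true dissociation constants

A competition titration yields an apparent midpoint
K_app = K_D·(1 + [competitor]/K_D,competitor). Two conversions are
provided:

* `cheng_prusoff_true_kd(kapp, conc, kd_comp)` — the titrated species'
  true K_D (used for the Gd³⁺/Ca²⁺ displacement titrations, with the
  Tb³⁺ EF-site constant 3 × 10⁻¹³ M: the EF site dominates the signal,
  so its constant is the relevant one).
* `competitor_kd_from_kapp(kapp, conc, kd_titrator)` — the transposed
  form giving the competitor's K_D (used when a chelator of known
  affinity, e.g. NTA:Tb³⁺ at 5.6 × 10⁻¹² M, is the titrant and the
  protein the competitor). It requires K_app > K_D,titrator; otherwise
  there is no competition signal to interpret and the call errors.

Antibody binding to the probe is modelled 1:1 with the exact
ligand-depletion quadratic isotherm (the ~120 nM probe is not
negligible against a ~470 nM K_D), even though an IgG has two potential
binding regions; a single K_D is fitted, matching how such anisotropy
data are conventionally analysed.

Internal unit is mol/L; µM interfaces convert explicitly.

## Curve fitting

All fits are unweighted nonlinear least squares (lmfit/Levenberg–
Marquardt); no weighting scheme is assumed for the detector. Initial
values are derived from the data — midpoint seeded at the titrant value
where the signal crosses mid-range, amplitudes from the first/last
points — which is robust for monotone curves. Fits are deterministic
given identical inputs. The chelator-competition (Hill) path applies
normalise-and-invert preprocessing first (signal → 1 − (s−min)/(max−min));
the other models fit on the raw scale. The Hill coefficient floats by
default and can be fixed (n = 1 recovers the rectangular hyperbola).

Melting points are the interior extremum of the centered-difference
first derivative of the melting curve, smoothed by a moving average of
half-width 5 points (configurable). A flat or purely linear curve has
no interior extremum and is an explicit error; the returned Tm is
grid-resolution limited, so melting curves should be sampled at ≤ 0.5 °C
steps for sub-degree Tm.

## Relaxometry

The nulling time of an inversion-recovery magnitude series and the T1 of
the plain buffer are distinct quantities (both conventionally written
T_I(0)); the code keeps them apart by name. T1 = TI_null/ln 2;
magnitude model |s₀(1 − 2e^(−TI/T1))|. The null is located by a
parabola through the minimum-magnitude point and its two neighbours —
appropriate because the protocol's 20–2500 ms grid is coarse relative
to T1 — and a minimum at the grid edge is an error (null not
bracketed). Times are ms internally; rates are reported in s⁻¹, so
r1 = (1000/T1_sample − 1000/T1_ref)/c with c in mM.

Measured relaxivities depend on the buffer T1 at each field, which is a
lab quantity; the formulas are therefore validated on synthetic series
generated from known (r1, buffer T1) pairs rather than against
published numbers. Gd³⁺ concentrations of the dilution series are taken
as the stated list (39.5, 19.7, 9.9, … µM), not derived from a
stoichiometric factor. The receptor-density detectability model treats
the cell as a sphere: c = N/(N_A·(π/6)d³), giving the ceiling on the
cell-averaged concentration of a receptor-targeted agent. Voxel volume
follows the imaging-protocol convention of rounding the pixel size
(FOV/matrix) to one decimal before multiplying; exact arithmetic is
available by disabling rounding. NMRD profiles are consumed as tables
and only referenced ((R1_obs − R1_solvent)/c); no Solomon–Bloembergen–
Morgan fitting is attempted.

## Trajectory operators

Lengths are Å throughout. Water molecules are represented by their
oxygen position. The first coordination shell is counted with an
inclusive cutoff at 3.4 Å — the stated maximum ion–water distance of
the first shell. COM distances are mass-weighted (unit masses when no
masses are given). RMSD uses centering plus the closed-form Kabsch
rotation (SVD of the covariance with a determinant correction enforcing
a proper rotation). Clustering is the greedy neighbour-count algorithm:
the conformer with the most RMSD-neighbours within the cutoff (default
1.7 Å) becomes a centroid, its neighbourhood is removed, and the count
repeats; ties go to the lowest index, a choice the original scheme
leaves open. RMSF superposes each frame onto the iteratively
self-consistent average structure before accumulating per-atom
deviations. No periodic-boundary imaging is performed: toy inputs are
whole and centered, and real unwrapping belongs to the MD engine that
produced the data.

## Synthetic data

Generators are pure functions of (parameters, seed) and are the exact
forward models of the corresponding analyses; with `noise_sd = 0` their
output is bit-identical to the noiseless operators. Noise is Gaussian
and homoscedastic, parameterised as a fraction of the signal amplitude
(default 2%, a convention — instrument noise magnitudes are not
specified by the protocols being emulated). Titration grids default to
log-spacing over ±1.5 decades around the relevant midpoint, which is
where a competition curve carries its information.

The toy trajectory draws a per-frame inner-shell water count from
configured probabilities and places that many waters uniformly (in
volume) in the 2.2–3.4 Å band, the rest at ≥ 4.5 Å; the default state
probabilities are one water 62% and two waters 1/3 of frames, with the
zero-water probability the remainder (≈ 4.7%), so ≥ 1 water is expected
in > 95% of frames. Domain pairs are rigid 5-point groups at a COM
separation drawn from a clipped normal law. Conformer sets plant
k template shapes (resampled until pairwise superposed RMSD exceeds the
requested separation), perturb members isotropically, then apply random
rotations and translations so that recovering the clusters genuinely
requires superposition; generation requires inter-cluster separation
> 4× the intra-cluster spread.

What the generators do **not** emulate: photobleaching and lamp drift,
baseline drift in titrations, B₀/B₁ inhomogeneity and partial-volume
effects in imaging, heteroscedastic detector noise, periodic images and
solvent structure in trajectories. Passing recovery loops therefore
demonstrate correctness of the estimators under the stated statistical
model, not robustness to instrument artefacts.

## Problem sizes

The test suite runs the recovery loops at deliberately moderate sizes —
50 noisy replicates for bias/median-error checks, 2000-frame
trajectories for coordination statistics (3-binomial-SE agreement),
8-item brute-force clustering oracles — sizes at which the statistical
checks are already well-powered while the whole suite stays fast. The
analysis drivers use 25-point titrations, 40-point IR grids, 2000-frame
trajectories and 50 conformers.

## Known limitations

* Independent-site model: no inter-site cooperativity or conformational
  coupling, although EF-hand pairs are known to couple in some systems.
* The hyperbolic competition fit treats K_app as a phenomenological
  midpoint; it is exact only in the probe ≪ K_app regime (the
  speciation model is available when depletion matters).
* Parabolic null-time interpolation assumes the magnitude minimum is
  locally quadratic; very coarse grids or very short T1 bias it.
* Daura-style clustering is O(n²) in RMSD evaluations; fine for the
  tens-of-conformers regime it is meant for.
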