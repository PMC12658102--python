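# Methods

This note documents the models, numerical choices and synthetic-data
conditions behind `helixmer`. The package targets the quantitative
machinery used to characterize weak, helix-mediated self-association of
the TDP-43 C-terminal domain (CTD) and its conserved region (CR,
residues 319–341), but every component is generic.

## Mass-action speciation (`equilibria`)

A self-association scheme is an ordered species list (monomer, dimer,
tetramer, ...) with *stepwise, species-molar* dissociation constants:
step *j* is `p · reactant ⇌ product` with `p = n_product/n_reactant`
and `Kd_j = [reactant]^p/[product]`. For the canonical
monomer–dimer–tetramer chain this is `Kd1 = [M]²/[D]`,
`Kd2 = [D]²/[T]`. This is the only convention under which a mM-weak
first step and a µM-tight second step yield the few-µM dimer and
low-tens-µM tetramer populations observed at ~100 µM total loadings; it
is therefore stated prominently wherever Kds appear. "Concentration in
the n-mer form" always means the monomer-equivalent concentration
`n·[S_n]`.

The free monomer at a given total is the unique nonnegative root of the
monotone mass balance `Σ n_j [M]^{n_j}/K_j = total`; we bracket it on
`[0, total]` with Brent's method and apply one closed-form Newton
polish (mass balance holds to 1e-9 relative). The solver is
deterministic; no seed is involved. The vectorized variant used inside
the transport solver runs a clamped Newton iteration warm-started from
the previous time step.

`expected_s_nmer(n) = n^(2/3)` is the smooth-sphere expectation for the
s-ratio of an n-mer at equal partial specific volume and frictional
ratio (mass ∝ n, Stokes radius ∝ n^(1/3)).

## Lamm forward solver (`lamm_forward`)

The Lamm equation is discretized with a conservative finite-volume
scheme on a uniform radial grid (default 500 cells) spanning meniscus
to bottom, with zero total flux at both walls:

* advection (`s ω² r` drift): explicit second-order MUSCL
  reconstruction with a van Leer limiter, upwinded outward;
* diffusion: Crank–Nicolson, with one tridiagonal operator per species
  factorized once per run;
* time step: `dt = CFL·Δr / (s_cap ω² r_bottom)` with CFL 0.5 by
  default. `s_cap` can be pinned to a parameter-independent bound
  (default: the largest species s, or the fit's upper s bound during
  optimization) so that the discretization does not move with the
  fitted parameters — this keeps least-squares objectives smooth.

Sector mass `∫ c r dr` is conserved to machine precision by
construction and checked to 0.1% at the end of every run. Associating
systems are propagated in the rapid-equilibrium limit by operator
splitting: each species is transported with its own (s, D), then every
cell's composition is projected back onto the mass-action manifold,
conserving local monomer-equivalents. The rapid-equilibrium choice
matches the fast-exchange regime of weak helical multimerization and
avoids unconstrained kinetic rate parameters. When the local oligomer
population is below 1e-15 of the local total the projection is skipped
entirely, so the infinitely-weak limit reproduces the uncoupled
solution bit for bit.

Species diffusion coefficients follow from s via the Svedberg relation
when the molar mass is known (`D = s R T / M(1−v̄ρ)`), or from a
frictional ratio via the Stokes–Einstein/sphere-volume triplet. The
signal model assumes an equal per-monomer extinction across oligomers
(identical chromophore count per monomer unit); the default signal
coefficient, 0.014 AU/(µM·cm), corresponds to a ~14 kDa
single-tryptophan chain at 280 nm, and pathlength (3 or 12 mm cells)
enters as a linear scale.

Accuracy: against the analytic zero-diffusion boundary law
(`r_mid = r_m e^{sω²t}`, plateau dilution `e^{−2sω²t}`) the solver is
accurate to ~1e-5 relative at 2000 cells; inside the usable radial
window (which excludes the back-diffusion spike at the bottom),
doubling 150 → 300 cells changes signals by well under 0.1% of the
plateau.

`standardize_s` applies the usual viscosity/buoyancy correction to
water at 20 °C (ρ = 0.998203 g/mL, η = 1.002 cP), with water properties
from the Kell density polynomial and a CRC viscosity correlation.

## c(s) inversion (`cs_inversion`)

Scan sets are decomposed over a library of noise-free unit
single-species Lamm solutions sharing one frictional ratio (default
grid 0.5–10 S, 100 points; D from s via f/f0). Amplitudes come from
nonnegative least squares with a second-difference Tikhonov penalty;
the penalty weight is bisected in log space until the penalized
chi-square exceeds the unpenalized minimum by the one-standard-
deviation F-ratio (P = 0.683), the standard regularization criterion
for sedimentation-coefficient distributions. The default f/f0 is 1.4 —
appropriate for a disordered chain whose monomer sediments well below
the compact-sphere expectation (a 14 kDa chain at ~1.5 S implies an
elevated frictional ratio) — and can instead be scanned over a grid.
Peak boundaries for integration are local minima of c(s), ties broken
toward lower s. Early scans can be dropped (`skip_scans`) to remove
fast-sedimenting aggregate signal.

## Global boundary fitting (`boundary_fit`)

Association models are fitted to one or more multi-scan sets by
nonlinear least squares (trust-region reflective) on the full radial
profiles using the reacting solver as forward model. Stepwise Kds are
fitted in log10 space (their plausible range spans decades); per-set
loadings are free nuisance parameters; meniscus and bottom are fixed
from geometry; species D follows the fitted s via the Svedberg relation
with the known monomer mass. Multistart (default 5 starts): the first
start combines a boundary-midpoint estimate of the weighted-average s
(monomer s ≈ 0.9× the lowest-concentration sw, n-mer s from n^(2/3))
with plateau-derived loadings and order-of-magnitude Kd guesses; the
remaining starts are seeded perturbations (±1 decade in log Kd, ±15% in
s). An optional non-participating "aggregate" species (free s, trace
amplitude per set) can be co-fitted. Time-invariant/radial-invariant
noise elimination is available in principle through baseline terms but
is off by default for synthetic data.

Confidence intervals use error-surface projection: the parameter is
scanned outward from the optimum, all other parameters re-optimized,
and the interval bounded where
`χ² = χ²_min (1 + p/(N−p) F(p, N−p; level))` (level 0.683 for 1σ).
This joint-F convention is conservative for a single parameter; the
convention is declared rather than inferred from any external fitting
package. Model comparison (`compare_schemes`) ranks schemes by rmsd and
flags "physically unreasonable" s-ladders: an s-ratio off n^(2/3) by
more than 1.5× either way, or s not increasing with stoichiometry.

## Trajectory statistics (`traj_analysis`)

* **dRMS** — superposition-free:
  `sqrt(2/(N(N−1)) Σ_{i<j} (d_ij − d_ij^ref)²)` over all selected heavy
  atoms (default residues 320–341, all chains, intra- and inter-chain
  pairs); frames with dRMS > 1 nm are flagged as having lost the
  starting fold.
* **Contacts** — residues are in contact when any two heavy atoms are
  within 0.6 nm; the sequence-separation rule |i−j| > 3 applies within
  a chain only (inter-chain pairs are always eligible, which is the
  only reading under which intermolecular maps are meaningful).
  Equilibration frames (e.g. the first 250 ns of a replica) are dropped
  before averaging. `N_contact(i)` is the row sum of the map; SEM is
  taken across replicas or across 5 contiguous equal time blocks.
* **Helicity** — our own Kabsch–Sander assignment: backbone H-bond when
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol`
  (distances in Å), minimal α-helix from two consecutive i→i+4 turns.
  Only state H counts as "helix fraction"; 3₁₀/π are not folded in.
  Missing amide hydrogens are placed geometrically (1.01 Å from N,
  opposite the bisector of N–C(prev) and N–Cα); residues missing
  backbone atoms are reported as NaN, never silently zero. The
  assignment is cross-checked in the tests against an independent DSSP
  implementation (mdtraj) on generated ideal helices.
* **Minimum inter-chain distance** — per-frame minimum over heavy-atom
  pairs; dissociation episodes are maximal runs above a threshold
  (default 0.6 nm, our convention, matching the contact cutoff) with a
  configurable minimum dwell.
* **GROMOS clustering** — pairwise backbone RMSD (residues 320–341)
  after Kabsch superposition, default cutoff 0.3 nm, typically applied
  to the last stretch of a trajectory; greedy neighbor-count
  clustering, ties broken toward the earliest frame, so the result is
  invariant to frame reordering up to tie-breaks.
* **AF2 confidence** — `0.8·ipTM + 0.2·pTM`, inputs validated to [0, 1].

## NMR metrics (`nmr_metrics`)

Secondary shifts `ΔδCα = δ_obs − δ_rc` use a user-supplied random-coil
table (literature scales differ; none is hardcoded); positive values
indicate helix. The concentration-dependent CSP is ¹⁵N-only by
definition: `Δδ¹⁵N = |δ_N(high) − δ_N(low)|` for the probe residue
(A328 by default — a CR reporter between a high concentration where
intermolecular contacts form and a low, monomeric reference), divided
by the wild-type value (`CSP_norm`). Variants whose probe resonance
broadened beyond detection yield an explicit exclusion object that
refuses truthiness — an excluded variant can never be mistaken for
CSP = 0. sPRE attenuation is `I_para/I_ref` per residue; ratios at or
below 0.1 (0 = complete signal loss) flag solvent exposure.

## Correlations (`integration`)

`c_sat` is estimated as mean ± sample SD of supernatant replicates per
salt condition, with flags for increasing-with-salt behavior and for
"no phase separation" (supernatant ≈ loading everywhere). Correlations
are plain Pearson/Spearman on mean values; measurement SDs are reported
alongside but not used as weights. Exclusions are named flags
(`broadened_NMR`, `no_droplets`, `irregular_morphology`) applied
pairwise and echoed in the result, and WT normalization of both axes is
provided for presentation even though, being affine, it cannot change
r.

## Synthetic data (`synthetic_data`)

The generators define the study conditions used throughout the tests:

* **AUC scans** — forward simulation plus i.i.d. Gaussian noise of
  0.005 AU (a typical absorbance-optics noise floor), default 300
  radial cells, scan radii covering the usable window
  (meniscus + 0.03 cm to bottom − 0.15 cm). The recovery experiments
  use the best-fit generating model (Kds 2.4 mM / 2.7 µM, s =
  1.54/2.43/3.94 S, 14 kDa monomer) at 58 and 107 µM loadings, 50 scans
  over 300–30,000 s at 50,000 rpm, 3 mm pathlength.
* **Helical bundles** — ideal α-helix backbones built from standard
  internal coordinates (N–Cα 1.458 Å, Cα–C 1.525 Å, C–N 1.329 Å,
  φ = −57°, ψ = −47°, ω = 180°), which reproduce the textbook 1.5 Å
  rise and ~100° twist per residue and a 3.8 Å Cα–Cα virtual bond;
  chains are placed on a regular polygon at a set axis spacing, with
  the antiparallel arrangement alternating chain direction around the
  polygon (the four-fold tetramer topology with antiparallel
  neighbors). Frames add Gaussian coordinate jitter; a scripted radial
  displacement of one chain provides ground truth for dissociation
  episodes. The default sequence is polyalanine — these are geometric
  reference structures, not physically realistic ensembles: they have
  no side-chain packing, solvent, or thermal correlations, so passing
  tests demonstrate correctness of the *measures*, not realism of the
  ensemble.
* **Mutant tables** — (c_sat, CSP_norm) pairs drawn from a bivariate
  normal with prescribed correlation ρ, mapped affinely onto positive
  WT-normalized scales (spread 0.15 about 1), with a WT row anchored at
  exactly (1, 1) flagged as the normalization anchor (it is not a
  datum). The default panel size is 18, matching the number of CR
  positions assayed in an alanine scan.

All generators are bit-reproducible for a given seed and emit a
ground-truth manifest.

## Problem sizes in the shipped tests and acceptance script

The acceptance recovery experiment uses the full stated conditions
(50 scans × 2 loadings, 300 radial cells, 0.005 AU noise, 3 seeds) with
a single heuristic optimizer start per seed — the noise-free version of
the same fit recovers the generating parameters to ~8 significant
figures, so multistart adds nothing there. Unit tests use reduced grids
(100–200 cells, 12 scans) chosen so each fitted quantity is still
resolved far above its tolerance.

## Known limitations

* Rapid-equilibrium coupling only; kinetically limited reaction
  boundaries (finite on/off rates) are out of scope.
* No flotation, solvent compressibility or dynamic density gradients.
* c(s) is 1-D (no size-and-shape c(s, f/f0) surface, no Bayesian
  prior).
* The 1σ intervals from `profile_interval` use the joint-F threshold,
  which over-covers single parameters by design.
* DSSP states G/I are not counted as helix; assignments at chain
  termini can differ by one residue from other DSSP implementations.
* The two-state monomer–tetramer alternative is supported (generalized
  stepwise Kd with p = 4) and compared via `compare_schemes`; the
  package exposes the equal-population crossover concentration
  (`equal_population_total`) but does not target a particular value
  for it.
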