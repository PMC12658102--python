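# helixmer

Quantitative analysis of weak, helix-mediated protein multimerization —
the kind of marginal self-association that drives phase separation of
prion-like low-complexity domains such as the TDP-43 C-terminal domain
(CTD) and its conserved region (CR, residues 319–341). Assemblies like
these are too weak and too dynamic for crystallography or cryo-EM, so
their characterization rests on sedimentation-velocity analytical
ultracentrifugation (SV-AUC), concentration-dependent NMR, molecular-
dynamics ensembles of predicted multimer models, and mutagenesis panels
— and on the statistical machinery connecting them. `helixmer`
implements that machinery as a tested, reusable package.

## What it computes

**Mass-action speciation** (`helixmer.equilibria`). An
`AssociationScheme` holds oligomer stoichiometries and *stepwise,
species-molar* dissociation constants, `Kd_j = [reactant]^p/[product]`
with `p = n_product/n_reactant` (so `Kd1 = [M]²/[D]`,
`Kd2 = [D]²/[T]`). `solve_speciation` finds the unique equilibrium
composition at a given total by bracketed root finding on the monotone
mass balance. `expected_s_nmer(n) = n^(2/3)` gives the smooth-sphere
s-ratio expectation; `signal_weighted_s` forms
`s_w = Σ s_j n_j c_j / Σ n_j c_j`.

**Lamm-equation forward modeling** (`helixmer.lamm_forward`). A
conservative finite-volume solver for

    ∂c/∂t = (1/r) ∂/∂r [ r D ∂c/∂r − s ω² r² c ]

with no-flux walls, flux-limited advection and Crank–Nicolson
diffusion; self-associating species are coupled in the
rapid-equilibrium limit (per-cell projection onto the mass-action
manifold). Plus the standard conversions: s → s20,w, and the
Svedberg/Stokes–Einstein sphere triplet (M, v̄, f/f0) ↔ (R0, D, s).

**c(s) analysis** (`helixmer.cs_inversion`) — regularized continuous
distributions of sedimentation coefficients (NNLS + second-derivative
Tikhonov at the P = 0.683 F-ratio level), peak splitting and
integration to loadings and weighted-average s.

**Direct global fitting** (`helixmer.boundary_fit`) — multi-
concentration, multi-scan fits of association schemes with log-space
Kds, multistart, optional trace aggregate species; error-surface
projection confidence intervals; scheme ranking with
physical-plausibility flags on fitted s-ladders.

**Trajectory statistics** (`helixmer.traj_analysis`) — superposition-
free dRMS with a >1 nm instability flag, heavy-atom contact maps
(0.6 nm cutoff, |i−j|>3 within chains), per-residue contact totals with
replica/block SEM, Kabsch–Sander α-helix fractions, minimum inter-chain
distances with dissociation episodes, GROMOS clustering, and the
AlphaFold2-Multimer confidence score 0.8·ipTM + 0.2·pTM.

**NMR metrics** (`helixmer.nmr_metrics`) — secondary Cα shifts against
a user-supplied random-coil table, ¹⁵N chemical-shift perturbations of
a probe residue normalized to wild type (CSP_norm), and solvent-PRE
attenuation with exposure flags.

**Correlation analysis** (`helixmer.integration`) — saturation-
concentration estimates from supernatant replicates and
Pearson/Spearman correlations across mutant panels with named,
auditable exclusion flags.

**Synthetic data** (`helixmer.synthetic_data`) — seeded generators for
noisy absorbance boundaries from a known association scheme, ideal
helical-bundle trajectories (parallel or antiparallel-alternating, with
jitter and scripted dissociation), and mutant tables with a prescribed
true correlation. Every generator writes a ground-truth manifest.

I/O for the documented plain-text scan format, Beckman-style dialects,
(multi-model) PDB ensembles, and provenance-stamped reports lives in
`helixmer.scanio`; a thin `helixmer` CLI (`speciate`, `simulate-auc`,
`fit-cs`, `fit-model`, `analyze-traj`, `nmr-metrics`, `correlate`,
`gen-synth`) wraps it all.

## Worked example

Solve the monomer–dimer–tetramer equilibrium of a CTD-like chain with a
weak 2.4 mM monomer–dimer step and a cooperative 2.7 µM dimer–tetramer
step, at a 107 µM loading:

```python
from helixmer import AssociationScheme, solve_speciation, signal_weighted_s

scheme = AssociationScheme.monomer_dimer_tetramer(2400.0, 2.7)  # µM
sp = solve_speciation(107.0, scheme)
print(f"free monomer : {sp.free_monomer_uM:6.2f} uM")
print(f"dimer form   : {sp.monomer_equiv('dimer'):6.2f} uM")
print(f"tetramer form: {sp.monomer_equiv('tetramer'):6.2f} uM")
print(f"weighted s   : {signal_weighted_s(sp, [1.54, 2.43, 3.94]):.2f} S")
```

prints

```
free monomer :  86.43 uM
dimer form   :   6.22 uM
tetramer form:  14.35 uM
weighted s   :   1.91 S
```

i.e. at ~100 µM only ~6 µM of monomer-equivalents populate the dimer
while ~14 µM already sit in the tetramer — the dimer is a weakly
populated intermediate on the way to a cooperatively formed tetramer —
and with per-species sedimentation coefficients of 1.54/2.43/3.94 S the
mixture would sediment with a weighted-average s of about 1.9 S.

The same model can be pushed through the full SV-AUC pipeline:
forward-simulate noisy boundaries at two loadings
(`gen_auc_scans`), then refit them globally
(`fit_association_model`) to recover the Kds and s-values from the
boundary shapes alone.

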