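# saxsemble

Conformational-ensemble analysis for proteins whose function depends on a
large-scale internal motion — the motivating case being a PLP-dependent
cysteine desulfurase (SspA) whose catalytic cysteine sits ~8.9 Å from its
cysteine substrate in the crystal and must swing toward it for sulfur
transfer.  The package provides, as a tested reusable library plus CLI,
the computational chain used to demonstrate such intrinsic motions:

1. **Distance-matrix clustering** of a structural ensemble (e.g. 20,000 MD
   frames).  Frames *i*, *j* are compared through their internal Cα–Cα
   distance matrices,

   D(i,j) = √[ (1/N₂) Σ_{m<n} (dᵢ_{mn} − dⱼ_{mn})² ],

   with N₂ the number of residue pairs — invariant under per-frame rigid
   motion, so no prior superposition is needed.  Average-linkage
   agglomerative clustering cut at a 1.5 Å cutoff yields clusters and
   populations.
2. **Debye-equation scattering profiles** from coordinates,
   I(q) = Σ_j Σ_k f_j f_k sin(q·r_jk)/(q·r_jk), with a coarse residue-bead
   form-factor model (one bead per residue at the Cα, f = heavy-atom
   count), averaged per cluster.
3. **Metropolis Monte-Carlo population fitting**: simplex weights P_i of
   the cluster profiles are fitted to an experimental SAXS curve by
   minimising the reduced χ² = (1/(L−1)) Σ_s (Σ_i P_i I_i(q_s) −
   I_exp(q_s))²/σ²(q_s) over 20,000 Metropolis steps.
4. **Elastic-network (ANM) normal modes** on Cα nodes, with a directional
   score: the cosine between a residue's displacement in the first
   internal mode (mode 7, after the six rigid-body zero modes) and the
   direction toward a target site — the quantitative form of "the
   catalytic residue intrinsically moves toward its substrate".
5. **Superposition / RMSD observables**: SVD-based Kabsch superposition
   with iterative outlier rejection, named-atom and closest-heavy-atom
   distance conventions, per-frame distance trajectories.

A synthetic-data generator (two-lobe hinge proteins, discrete-state
ensembles with Gaussian jitter and planted populations, simulated SAXS
curves with known mixture weights and per-point σ) makes every stage
testable without any downloads.

## Worked example

The bundled demo plants a three-state hinge ensemble with populations
8 / 75 / 17 %, simulates a SAXS experiment from the same weights at 1 %
noise, and runs the full chain:

```sh
saxsemble run-all --out demo_out --seed 1
```

`demo_out/report.json` then contains (seed 1):

```
clusters.populations        [0.768, 0.158, 0.073]   # planted 0.75/0.17/0.08
fit.weights                 [0.763, 0.167, 0.069]   # recovered populations
fit.chi_square              0.911                   # ≈1: fits within noise
model_comparison            ensemble χ² 0.91  <  single structure χ² 6.89
modes.n_zero_modes          6
modes.cosine_toward_target  0.767                   # mode-7 motion closes the hinge
```

Reading: clustering recovers the three planted states and their
populations; the Monte-Carlo fit recovers the planted mixture weights from
the scattering curve alone with reduced χ² near 1; the weighted ensemble
model fits the "experimental" curve far better than the single reference
structure (the solution-ensemble signature); and the first internal normal
mode moves the catalytic marker toward the substrate marker.

Individual stages are available as `saxsemble distances | align | cluster
| profile | fit | modes | simulate`, and as library functions
(`saxsemble.cluster_ensemble`, `saxsemble.debye_profile`,
`saxsemble.fit_populations`, `saxsemble.directional_motion_score`, …).

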