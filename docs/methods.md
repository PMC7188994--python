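# Methods

This note documents the models implemented in `saxsemble`, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that affect results.

## Structures and selection

PDB files are parsed and written through biotite.  Alternate locations
are resolved at read time by keeping the highest-occupancy conformer (ties
by altloc identifier order), so all downstream math sees a single
coordinate per atom.  Insertion codes are carried as part of residue
identity.  Waters are dropped on reading by default — every analysis here
concerns the protein plus its cofactor/substrate ligands.  Multi-model
files become `Ensemble` objects; frames must share atom identities in
identical order, and the writer always emits MODEL/ENDMDL blocks (also for
one frame) so ensemble files have a uniform dialect.  Coordinates
round-trip at the fixed-width PDB precision of 0.001 Å.

## Superposition and RMSD

`kabsch_superpose` is the standard SVD least-squares fit with the
determinant correction that excludes reflections; collinear point sets are
rejected (the rotation would be underdetermined).  `iterative_align`
repeats superpose → drop pairs deviating more than `reject_multiplier` ×
current RMSD (default 2.0) → re-superpose, up to `max_cycles` (default 5)
or until the aligned set is stable.  This mirrors the common "align"
behaviour that reports an RMSD over a *subset* of Cα atoms.  Pairing is by
(chain, residue number, insertion code) for same-numbering comparisons; an
explicit `{residue_a: residue_b}` mapping supports cross-protein
comparisons where the user has a sequence correspondence (the package
itself contains no sequence alignment).  An RMSD below 1e-8 Å stops the
rejection loop — at that level deviations are floating-point noise, not
outliers.

Distance observables support three conventions: `named-atom-pair` (both
selectors must resolve to exactly one atom; ambiguity is an error, not a
guess), `closest-heavy-atom` (minimum over non-hydrogen pairs) and
`centroid`.  For active-site geometry of the desulfurase family the
natural named pair is the residue-314 terminal side-chain atom (Oγ in the
C314S background, Sγ in the wild type) against the substrate-cysteine Sγ
or the PLP C4A atom; the closest-heavy-atom convention differs from it by
less than a bond length at these sites, and both are accepted by the
tests within ±0.6 Å of the reference values.

## Ensemble clustering

The frame-to-frame dissimilarity is the root-mean-square difference of
internal Cα–Cα distance matrices over unordered residue pairs (N₂ = number
of pairs m<n).  Working on the root scale makes the Å cutoff dimensionally
meaningful; the alternative normalisation by (residue count)² differs only
by a constant factor ≈ 2 in N₂ and would amount to rescaling the cutoff.
Because internal distances are rigid-motion invariant, no superposition
precedes clustering.

The clustering algorithm is average-linkage agglomerative clustering on
the dissimilarity, cut at the cutoff (default 1.5 Å); a deterministic
single-pass leader algorithm is available behind `method="leader"`.  Both
are deterministic for a fixed input.  Cluster indices are relabelled by
descending population (ties by first frame) so outputs are stable.  For
ensembles beyond `max_exact_frames` (default 5,000) the full dissimilarity
is computed on an evenly strided subsample and the remaining frames are
assigned to the nearest cluster medoid; for well-separated states this
preserves populations within sampling error (tested).  The full condensed
matrix of a 20,000-frame ensemble (~2×10⁸ entries) is why the threshold
exists.

## Debye profiles and χ²

The scattering profile of a rigid structure is the exact orientationally
averaged Debye double sum; the self terms contribute Σf².  Two scatterer
representations:

* `residue-bead` (default): one bead per residue at the Cα position, form
  factor f = number of heavy atoms of that residue type (ligand residues:
  bead at the heavy-atom centroid, f = heavy-atom count).  A standard
  coarse proxy — q-independent f, no excluded-solvent or hydration-layer
  terms.
* `all-atom-constant-f`: every heavy atom with f = atomic number.

Consequences: I(q→0) → (Σf)², profiles are rigid-motion invariant and
strictly positive for positive f, but absolute χ² values against real
experimental data are **not** comparable to hydrated-atom calculators
(CRYSOL-class); only relative comparisons and mixture fits are meaningful,
which is all the pipeline uses.  The double sum is evaluated exactly
(O(N²) pair distances); at the residue-bead resolution used here
(≤ ~2,000 beads) this needs no histogram approximation.

Experimental curves are 2–3-column whitespace text (q, I, optional σ);
non-numeric rows are skipped and counted.  Curves are trimmed to the
usable momentum-transfer window — default 0.01–0.2 Å⁻¹, the range where
solution data of this kind are informative before noise dominates.  Model
curves are interpolated linearly onto the experimental grid (the grids
are dense and the curves smooth at these q).  The goodness of fit is the
reduced χ² normalised by L−1 with per-point experimental σ; a curve
without σ is refused rather than assigned an invented uncertainty, and no
scale factor or constant background is fitted by default (the χ²
definition used contains neither).

## Population fitting

Cluster populations P_i are fitted by Metropolis Monte Carlo with χ² as
the energy at unit temperature: start from uniform weights; each step
picks one cluster index uniformly, perturbs its weight by N(0,
`proposal_scale`=0.05), clips at zero and renormalises to the simplex;
accepts with min(1, exp(−Δχ²)).  Default 20,000 steps.  The *best-so-far*
weights are reported, which makes the answer robust to the temperature
choice (an optional geometric cooling flag exists).  The proposal is
ergodic on the simplex and the best-so-far trace is monotone; on
noise-free synthetic mixtures the recovered weights converge to the
planted ones as steps grow.  All randomness flows from one explicit seed,
recorded in the output; identical seeds give bit-identical trajectories.

`compare_models` scores single structures directly and multi-cluster
bases at their fitted weights, returning an ascending-χ² ranking — the
ensemble-versus-crystal comparison in one call.

## Elastic-network modes

The anisotropic network model on Cα nodes: springs of stiffness γ
(default 1, arbitrary units) connect nodes within a cutoff (default 12 Å —
standard Cα-ANM practice; the directional conclusions are checked at
10/12/15 Å).  Off-diagonal Hessian blocks are −(γ/r²)(r⊗r); diagonal
blocks close the row sums.  Masses are uniform (usual for Cα networks).
The dense 3M×3M Hessian is diagonalised exactly, which is tractable to a
couple of thousand nodes; no rotation-translation-block approximation is
used.  A connected non-collinear network has exactly six zero modes
(five for the two-node case); more indicates a disconnected network and
is raised as an error.  Zero modes are counted with a relative threshold
of 1e-8 × the largest eigenvalue.  Mode ranks are 1-based over the full
spectrum, so the first internal motion is mode 7.

The directional score for node n toward target t is the cosine between
the node's 3-vector displacement in the chosen mode and the unit vector
n→t.  Eigenvector signs are arbitrary, so the mode is oriented to make
this projection non-negative ("toward" convention); the oriented cosine,
the raw (unoriented) cosine and the displacement amplitude are all
reported.  Under this convention the score is zero only when the motion
is orthogonal to the target direction.

## Synthetic data

The generator emulates exactly the statistical structure the analyses
assume, with planted truth returned beside every output:

* **Hinge protein**: two rigid ideal-helix Cα traces (rise 1.5 Å, 100°
  twist, radius chosen so consecutive Cα are exactly 3.8 Å apart) joined
  at a vertex with a configurable inter-lobe angle; HETATM markers
  (`CAT`, `SUB`, atom SG) sit on the lobe axes just beyond the tips, so
  their separation is 2L·sin(angle/2) — strictly monotone in the angle.
* **State ensembles**: frames copy one of the discrete state structures
  (chosen with the planted probabilities) plus isotropic per-atom
  Gaussian jitter (default σ = 0.1 Å).  Jitter is not a physical force
  field; the clustering criterion only requires within-state spread ≪
  between-state separation, which these defaults control explicitly.
* **Simulated experiments**: I_exp = Σ P_i I_i + N(0, σ(q)) with σ(q) a
  fixed fraction of the mixture intensity (default 1 %, a typical
  solution-scattering noise level).  With the noise fraction set to zero
  a nominal 0.1 % σ floor keeps the σ-weighted χ² defined while the
  intensities remain exact.

The demo/acceptance conditions: three hinge states at 165°/110°/55°
(open/intermediate/closed) with populations 8/75/17 % — the wide angular
spread keeps the three profiles linearly well-separated, so the mixture
weights are identifiable at 1 % noise; 100-point q grid on 0.01–0.2 Å⁻¹;
2,000 frames for the clustering recovery and 5 simulated experiments for
the seed-averaged fit (problem sizes at which the whole chain runs in
seconds while sampling errors stay well inside the tested tolerances).

What passing on synthetic data does **not** show: recovery on real MD
ensembles, where states are neither discrete nor isotropically jittered,
cluster profiles are less distinct, and the coarse form-factor model
meets real electron-density contrast.  The pipeline's numerical
machinery is validated; its biophysical fidelity on a given real system
is not implied.

## Known limitations

* Debye calculator: coarse form factors, no hydration shell — absolute
  χ² against real data is implementation-specific.
* Cross-protein RMSD needs a user-supplied residue correspondence; there
  is no built-in sequence alignment.
* Clustering has no automatic cutoff selection; the cutoff is a physical
  choice on the Å scale of the dissimilarity.
* ENM γ is arbitrary, so eigenvalues (and mode amplitudes) have no
  absolute units; only ratios and directions are meaningful.
* The Monte-Carlo fit reports a point estimate (best-so-far), not a
  posterior; the seed-to-seed spread on repeated simulated experiments is
  the provided variability measure.
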