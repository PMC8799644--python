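# Methods

This note documents the models and procedures implemented in
`mdresidence`, the parameter choices that matter, what the synthetic-data
generators do and do not emulate, and the numerical decisions taken where
a convention was genuinely open.

## Scope and data model

The package analyses protein–ligand MD trajectories at a fixed stride
(default 1 ns per analysed frame). It does not run production MD, prepare
structures, or compute inhomogeneous-solvation-theory water
thermodynamics; hydration-site free energies are primarily an *input*
(TSV of x, y, z, ΔG), with a clearly labelled inverse-Boltzmann estimator
as a fallback.

Coordinates are Å throughout. Every distance criterion is inclusive at
the cutoff (a pair at exactly the cutoff satisfies it), implemented with
a 1e-9 Å / 1e-7° guard so that exactly-constructed boundary geometries
are not lost to floating-point rounding. Residue numbering follows the
input PDB verbatim, so catalytic and hinge residues keep their
crystallographic numbers (Lys53, Met109, Thr175, …). Van der Waals radii
come from a fixed internal Bondi table so surface areas are reproducible
bit-for-bit across machines.

PDB reading is a strict fixed-column parser that reports the offending
line number on malformed records and rejects duplicate serials. Chemical
roles (donors, acceptors, charged centers, aromatic rings, backbone vs
sidechain, waters) are assigned from residue templates for standard amino
acids and waters (HOH/WAT/SPC/T3P); ligand roles come from a small YAML
sidecar (atom name → roles, plus ring member lists). Connectivity is
inferred by distance (H ≤ 1.25 Å, heavy ≤ 1.95 Å, S ≤ 2.1 Å) unless
CONECT records are present; bond orders and protonation are out of scope.
Aromatic rings must be planar within 0.15 Å out-of-plane RMS at
construction.

## Interaction fingerprints

Detector criteria (all configurable through `InteractionCriteria`):

| interaction | criterion (defaults) |
|---|---|
| hydrogen bond | H···A ≤ 2.5 Å, D–H···A ≥ 120°, H···A–X ≥ 90° for some heavy neighbor X of A |
| π–cation | charged center to ring centroid ≤ 4.5 Å |
| π–π face-to-face | centroid ≤ 4.4 Å, interplanar angle ≤ 30° |
| π–π edge-to-face | centroid ≤ 5.5 Å, interplanar angle in 60–120° |
| water bridge | relaxed H-bond to both partners: ≤ 2.8 Å, ≥ 110°, ≥ 90° |
| salt bridge | charged-group N/O heavy-atom pair ≤ 4.0 Å |

The 2.5 Å hydrogen-bond distance is interpreted hydrogen→acceptor (a
2.5 Å heavy–heavy donor–acceptor distance would be physically
impossible), matching the convention of standard simulation-interaction
diagrams. The π–π and salt-bridge thresholds follow the common
conventions; both are config-exposed because no single community standard
exists. Interplanar angles are folded to [0°, 90°] since ring normals are
sign-free. For acceptors without a heavy neighbor (water oxygen) the
acceptor-angle test is vacuous.

Frequencies use fingerprint semantics: a (kind, residue pair) is
"interacting in a frame" if at least one event of that kind exists in the
frame — two waters bridging the same pair in one frame count once. The
reporting filter is strict (> 0.15 drops a pair at exactly 15%). Water
bridges are counted per residue pair, not per bridging water; the
per-water alternative would only inflate pairs bridged by multiple
simultaneous waters.

## Surface decomposition

SASA uses Shrake–Rupley sphere sampling at radius r_vdW + probe
(probe 1.4 Å) with a deterministic Fibonacci lattice (default 960 points
per atom; doubling the count moves 50-atom totals by < 0.5%). The
ligand's SASA is evaluated in the complex with waters excluded from the
occluders — the solvent defines the probe, it does not occlude itself.

MolSA (the solvent-excluded/Connolly area) is computed numerically: grid
points are probe-accessible when outside every inflated sphere; the
molecular volume is the set of points whose Euclidean distance to the
accessible region is ≥ probe, and its boundary is extracted by marching
cubes (default grid 0.12 Å). The Euclidean distance transform measures to
the nearest accessible *voxel center*, which would bias the surface
outward by up to half a voxel; this is corrected per voxel by subtracting
the nearest voxel's own analytic clearance min_i(|x − c_i| − R_i). The
corrected level set reproduces the single-sphere closed form and a
closed-form two-sphere oracle (contact zones plus the toroidal surface of
revolution) within 1%.

MolSA and PSA are evaluated on the isolated ligand conformer of each
frame: burial is then conformer-consistent and the decomposition is
well-defined even when the binding site deforms. Polar shares count
surface owned by N, O, and (by default, flag-controlled) hydrogens bonded
to them; mesh triangles are assigned to the atom whose surface they are
closest to. Buried and buried-polar areas are reported exactly as
MolSA − SASA and PSA − SAPSA, which can be slightly negative for a fully
solvated molecule because the two surfaces are different geometric
objects; they are not clipped.

## Solvent exposure

A residue's exposure in a frame is the number of distinct water molecules
whose **oxygen** lies within 3 Å of any **sidechain heavy atom**;
exposed ⇔ count ≥ 1. Both conventions (oxygen-only proximity,
heavy-atoms-only sidechain) are config-exposed because the underlying
3 Å prescription does not fix them; the defaults avoid a dependence on
hydrogen placement. Counting is per molecule, not per contact.

## Markov state models

Featurization encodes backbone φ/ψ torsions as (cos, sin) pairs, which
respects angular periodicity; chain breaks drop the affected torsions
with a warning, and per-residue exclusions are supported. The VAMP-2
score is the sum of squared singular values of the half-weighted
time-lagged covariance operator with the constant function included, so
the score of pure noise tends to 1 and a two-state process with
eigenvalue λ₂ scores 1 + λ₂². TICA solves the symmetrized generalized
eigenproblem C_τ v = λ C₀ v (reversible assumption, no kinetic-map
scaling; both are toggles) with a ridge fallback on rank deficiency, and
by default retains 2 independent components.

Microstates come from k-means++ (fixed seed, default 2022) with
k = round(√n_frames); transition counts use a sliding window at the lag;
estimation restricts to the largest strongly connected set. The
reversible maximum-likelihood transition matrix is found by fixed-point
iteration on the symmetric flux variables and satisfies detailed balance
to 1e-8 and row-stochasticity to 1e-10. The Bayesian mode keeps the MLE
as the point estimate and resamples row-multinomial counts (default 100
draws) for π error bars only.

Implied timescales are t_i(τ) = −τ/ln λ_i(τ); non-positive or
non-decaying eigenvalues are reported absent, and a convergence flag
fires when the slowest timescale changes < 10% across successive lags.
The Chapman–Kolmogorov test compares coarse-grained T(τ)^k with
re-estimated T(kτ) on the PCCA++ sets and passes when every per-state
occupation prediction lies inside a 95% bootstrap band (resampled
trajectory blocks, 30 replicates by default).

PCCA++ takes the top right eigenvectors in the π-weighted inner product,
locates simplex vertices with the inner-simplex algorithm, maps rows
through the vertex inverse and clips/renormalizes to memberships.
Equilibrium probabilities π_i sum the stationary mass of each state's
crisp members and conserve to 1e-10. Representative frames (3 per state
by default, matching the downstream hydration protocol) come from the
most populated member microstates, taking the frame nearest each center
with lowest-index tie-breaks, so selection is deterministic and
permutation-invariant.

## Hydration sites and resolvation scoring

Water-oxygen observations within the 10 Å inclusion shell of the ligand
are clustered greedily: repeatedly found a site at the centroid of the
densest 1 Å neighborhood and remove its members, until no point has the
minimum occupancy. Site ΔG values are supplied externally in normal use;
the built-in estimator ΔG = −kT ln(ρ_site/ρ_bulk) (kT = 0.616 kcal/mol at
310 K, site volume = the clustering sphere) is an explicitly labelled
excess-occupancy approximation, not an inhomogeneous-solvation-theory
result.

The overlap factor of a site is the fraction of its member observations
lying within (r_vdW + 1.4 Å) of any ligand heavy atom — positions a water
center could not occupy with the ligand bound. A site is displaced iff
overlap > 0.5 strictly; exactly 0.5 does not count. The ligand score is
−Σ ΔG over displaced sites, whole sites rather than partial-overlap
weights, so displacing unstable (ΔG > 0) water scores favorably
(negative). Scores over the three representative structures of a
metastable state are averaged within the state first, then combined
across states as Σ π_i s_i / Σ π_i alongside the plain mean.

## Metadynamics dissociation analysis

The collective variable is the distance between mass-weighted centroids
of the ligand and of the binding-site residues (defaults Val38, Ala51,
Leu75, Ile84, Thr106, Met109). A replica is fully dissociated iff its CV
**reaches** 15 Å (inclusive) at any point; classification is therefore
monotone in the threshold. Count tables report per-start-state
dissociated/bound with totals. Trace files are two-column
(time_ns, cv_Å) text with `#` comments and tolerated header lines.

## Synthetic data: what it emulates, and what it does not

`gen_metastable_trajectory` plants a reversible 3-basin macro chain with
stationary distribution (0.43, 0.32, 0.25) by default and relaxation
timescales of exactly 22 and 11 frames (the exchange rates are solved for
at construction; a degenerate spectrum would make "the slowest timescale"
an ill-posed recovery target). Each basin holds 4 microstates resampled
every frame, so macro lumping is exact; emissions are 2-D Gaussians
(σ = 0.8 around microstate centers jittered with σ = 0.3, basin
separation 4) plus 2 pure-noise dimensions, giving ≈ 2% basin
misassignment — enough overlap that PCCA++ recovery is non-trivial, not
enough to make it unreliable. The default analysis protocol on these data
is TICA lag 10 frames, MSM lag 15 frames, k = round(√n).

`gen_interaction_fixture` builds minimal annotated atom sets realizing
one interaction at an exact geometry, with a trajectory variant toggling
it on a prescribed fraction of frames. `gen_water_ensemble` scatters
site-bound observations (Gaussian σ 0.3 Å) plus uniform bulk noise and
returns the planted site table. `gen_metad_traces` integrates overdamped
Langevin dynamics on a 1-D double well (bound well at 2 Å, unbound at
15 Å, barrier 4 kcal/mol, kT = 0.616 kcal/mol, dt = 0.01 ps, 30,000
steps) with well-tempered deposition h_k = h₀ exp(−V_bias/kTemp) using
the production bias parameters (0.2 kcal/mol, 0.03 Å width, 1 ps
interval, kTemp 3.4, wall 35 Å); paired seeds let biased and unbiased
ensembles share noise histories.

These generators reproduce the *statistical structure* each stage
assumes, not molecular physics: no force field, no explicit solvent
structure, no coupling between stages' observables. Passing tests
demonstrate that the estimators and classifiers recover planted ground
truth under realistic noise — they do not certify agreement with any
specific experimental system, whose analyses additionally depend on
sampling quality and force-field fidelity.

## Numerical and protocol choices

- Cutoff equality counts as satisfied everywhere; ε-guards 1e-9 Å / 1e-7°.
- Superposition reference frame for cross-structure Cα distances:
  backbone atoms of residues common to both structures, excluding the
  A-loop (residues 170–185) and G-loop (30–38) — loop displacement is
  measured against a stable core. The original choice of frame is not
  recoverable from the source material, so it is configurable.
- k-means: k = round(√n) with empty clusters pruned; seed logged.
- Reversible MLE: convergence 1e-13 on the stationary vector, 10,000
  iteration cap.
- Quartile convention: type-7 (linear interpolation of order statistics);
  whiskers at the furthest datum within 1.5·IQR; outliers listed.
- Degenerate inputs: empty selections, zero-occupancy sites, empty CV
  traces, glycine sidechains and k > n clusterings raise informative
  errors; disconnected count matrices restrict with a warning.
- Acceptance-scale problem sizes: 100,000 frames for MSM recovery,
  100-frame ensembles for hydration and interaction checks, 20 replicas
  per metadynamics arm — large enough for tight recovery bounds on a
  single CPU.

## Known limitations

- The SES grid method carries a ~0.5% systematic area bias at the default
  0.12 Å spacing; halve the spacing for tighter work.
- PCCA++ memberships use the feasible inner-simplex solution without the
  subsequent constrained optimization of the transform; for
  well-separated metastable states (the intended regime) the crisp
  partitions coincide.
- The hydration-energy estimator ignores enthalpy/entropy decomposition
  and water-water correlations entirely.
- Periodic-boundary imaging is assumed already applied to input
  trajectories; mmCIF input is not supported.
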