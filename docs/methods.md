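# Methods

## The problem

NMR can measure interproton distances (from NOE/ROE cross-peak volumes) and,
in weakly aligning media, residual dipolar couplings (RDCs).  For a small
molecule with several contiguous stereocenters, the question is which of the
2^(n-1) relative configurations (diastereomers) is consistent with those
data — ideally without trusting a force field, a DFT conformer pool, or the
modeller's starting geometry, any of which can smuggle in the answer.

`fcdg` implements the floating-chirality restrained distance-geometry /
distance-bounds-driven-dynamics approach (fc-rDG/DDD): candidate structures
are generated purely from distance information, stereocenters are left free
to invert during the calculation, and the experimental data alone decide
which configurations survive in the low-pseudo-energy region of the ranked
ensemble.

## Model and procedure

1. **Holonomic bounds** (`moltop.build_bounds`).  Bonded (1-2) and geminal
   (1-3) distances, and all pairs inside declared planar fragments, are
   pinned to the guess-geometry value within ±1% (`slack=0.01`).  Everything
   else is free between a scaled van der Waals contact
   (`vdw_factor=0.7` × sum of Bondi radii) and a molecular-diameter cap
   (2 Å × n).  1-4 and longer pairs are deliberately *not* derived from the
   guess: that is what makes the bounds configuration-agnostic.  The factor
   0.7 (rather than a harder 0.8) keeps the genuinely congested contacts of
   realistic strained geometries admissible; both knobs are arguments.

2. **Calibration** (`calib`).  Distances from volume ratios,
   d = d_ref (V_ref/V)^(1/6); windows d(1∓m) with margin m (default 10%);
   additive pseudo-atom corrections on the upper bound only, for restraints
   anchored on the centroid of an isochronous group (+1.0 Å methyl, +0.9 Å
   methylene pair, +2.0 Å equivalent aromatic pairs — conventional values,
   overridable, since sources differ).  The module also carries the two
   analytic side results used as sanity anchors: the homonuclear NOE zero
   crossing at ω₀τc = √5/2 ≈ 1.12, and the r⁻⁶ damping of volume errors
   (±10% volume → ≈1.8% distance, i.e. well below ±5%).

3. **Chiral volumes** (`stereo`).  V = (r₁−r₄)·((r₂−r₄)×(r₃−r₄)) over the
   substituents of a center, ordered by ascending atom index.  The ordering
   convention is arbitrary but fixed; only *relative* configurations are
   ever reported, so any self-consistent convention gives the same answer.
   Restraints: planarity (V=0) on sp² frames, tetrahedrality on methyls
   (ideal-geometry magnitude, sign from the guess — methyl protons are
   interchangeable so the sign carries no information), one fixed-sign
   restraint on a single reference center to remove the global enantiomer,
   and nothing at all on the remaining stereocenters (floating chirality).
   Fingerprints are sign vectors normalized so the reference reads '+';
   centers with |V| < 0.01 Å³ are flagged indeterminate rather than guessed.

4. **Embedding** (`embed`).  Triangle / inverse-triangle smoothing (iterated
   Floyd–Warshall to a fixed point), full randomized metrization (uniform
   draw in the current window, random pair order, local re-smoothing through
   the fixed pair after each draw; a full-re-smoothing mode exists for
   verification), and classical metric-matrix embedding in 4D.  Negative
   eigenvalue mass is truncated into `embed_error`.

5. **Dynamics** (`ddd`).  E = k_dist Σ(window violations)² +
   k_chir Σ(V−V_t)² + k_rdc Σ w(D_obs−D_calc)², with analytic gradients as
   forces.  Velocity-rescaled leapfrog with unit masses: hot plateau at
   300 K, linear cooling to 0 K; the thermostat scale (kb = 2·10⁻³
   pseudo-energy per K per degree of freedom) is a search parameter chosen
   so that thermal violation amplitudes at 300 K are comparable to a ±10%
   restraint window.  The 4D stage ends in a zero-Kelvin quench (the
   reference protocol likewise interleaves optimization with dynamics);
   a proper 4D rotation then moves the least-populated axis into the fourth
   coordinate before truncation, because rotations are free while
   truncation is not.  After projection, structures whose fixed reference
   center has the wrong sign are mirrored (a global reflection is no longer
   reachable by 3D dynamics).  The 3D stage repeats the schedule and ends in
   a FIRE (fast inertial relaxation engine) quench to gradient-norm 1e-8
   (capped iterations), which proved far more reliable than plain steepest
   descent on this rugged sum-of-penalties landscape.  Force constants:
   k_dist = 1, k_chir = 10 (planarity/tetrahedrality violations must not be
   traded against sparse NOE violations), k_rdc = 0.02 (so Hz-scale RDC
   residuals weigh comparably to Å-scale distance violations).

6. **RDCs** (`rdc`).  D = D_max(pair) uᵀS u with the 5-parameter symmetric
   traceless Saupe matrix fit by linear least squares per evaluation;
   unassigned methylene protons contribute only the *sum* of their two C–H
   couplings (summed design rows).  The gradient treats the refit tensor as
   locally constant (Gauss–Newton convention) — exact derivatives through
   the SVD are unnecessary for a search dynamics.  RDC forces act only in
   3D and ramp in linearly during the cooling phase: early in the 3D stage
   the geometry is too distorted for the tensor fit to mean anything, and
   full-strength RDC forces at that point demonstrably trap the search.

7. **Ranking** (`rank`).  Ensembles sort ascending by e_total.  The
   discrimination report gives the 1-based rank of the first structure whose
   fingerprint differs from a reference, and ΔE = (its e_total) − (max
   e_total of the preceding correct block); when the correct block is flat
   this is exactly the visible step height.  Energy steps are consecutive
   gaps above `gap_tol` (default 0.05).  Conformer subfamilies within a
   fingerprint family come from single-linkage clustering of
   reflection-allowed superposition RMSD (default cut 1.0 Å over heavy
   atoms; rotamer-scale subfamilies surface near 0.5 Å).

## Synthetic scenarios

No experimental dataset ships with the package; `fixtures` builds scenarios
whose statistical shape matches published small-molecule studies, with known
ground truth:

* **bicyclic** — fused bicyclo[3.3.0]octane, cis or trans ring fusion
  selectable, methyl substituents up to 8 stereocenters; the rigid
  workhorse.  Default restraint budget 12 contacts.
* **chain** — a methyl-substituted chain (2–6 centers), flexible; budget 25.
* **macrocycle** — a bicyclo[3.3.0]octane core whose flanking carbons are
  bridged by an eight-carbon chain, closing a flexible 10-membered ring
  fused to the rigid bicycle (4–6 centers).  This mirrors the architecture
  that makes anisotropic data useful in real macrocyclic natural products:
  stereocenters on a rigid frame, flexibility elsewhere.  The unsubstituted
  scaffold offers exactly 28 one-bond C–H couplings (methylenes counted
  pairwise and emitted as summed rows).  Budget 9 contacts.

Truth geometries come from RDKit's ETKDG conformer generator (itself a
distance-geometry method; no physical force field touches the truth).
NOE tables are sampled from the truth coordinates among proton-group pairs
whose carriers are ≥2 bonds apart and within 4 Å, preferring contacts whose
distance spreads by more than ~0.5 Å across single-flip and full-flip
variants of the template (a restraint set that cannot distinguish
configurations would make every recovery experiment meaningless); purely
random selection is available as a negative control.  Multiplicative noise
is uniform ±`noise` (default 0 — the experiments probe window widths, not
calibration noise).  RDC tables are back-calculated from the truth and a
seeded random tensor (eigenvalue scale 10⁻³, giving tens of Hz for one-bond
C–H).

What the fixtures do **not** emulate: conformational averaging of NOEs and
RDCs in flexible molecules (the truth is a single conformer), spectral
artifacts, diastereotopic assignment ambiguity beyond methyl groups, and
heteroatom-rich constitutions.  Passing recovery experiments therefore show
that the engine extracts the configuration encoded in ideal single-conformer
data of realistic sparsity — not that any real spectrum of a flexible
natural product would behave as cleanly.

## Problem sizes and schedules

The reference protocol (1000 structures, 5000+5000 steps of 10 fs per
stage) is the `DDDParams` default.  The repository's own experiments and
tests run a scaled-down protocol chosen as the smallest that gives stable
statistics on the fixture scenarios: 200 hot + 400 cooling steps of 30 fs
per stage, FIRE quench capped at 2000 iterations, ensembles of 60–200
structures and 5 seeds per condition.  Convergence was judged by the best
structures of correct-configuration ensembles reaching e_total ≲ 10⁻³
(the truth geometry itself quenches to ~10⁻²⁰).  Quench depth matters
more than annealing length for the ΔE diagnostics: an under-converged
ensemble inflates the apparent gap of NOE-only runs (wrong-configuration
structures carry unrelaxed excess energy) and drowns the genuine RDC
contribution in residual noise; the deep quench deflates both to their
systematic values.

## Numerical choices and degenerate inputs

* Metrization restarts (fresh random order) on a mid-draw window collapse,
  10 attempts, then an error naming the offending pair.
* Embedding with all non-positive eigenvalues raises; per-structure
  generation failures are retried with a fresh derived RNG stream (bounded)
  so the ensemble size is exact.
* Per-structure RNG streams are seeded `[master_seed, structure_index,
  attempt]`, making ensembles reproducible and independent of batching.
* Ties in e_total break by generation index.
* The thermostat sets velocities to zero at a 0 K target; a satisfied system
  started cold is an exact fixed point.
* The batched tensor refit adds a relative 1e-10 ridge for solvability;
  the public `fit_tensor` instead raises on rank < 5.

## Known limitations

* ΔE values on the synthetic fixtures are an order of magnitude smaller
  than published values for real rigid polycyclics with richer restraint
  sets — sparse ideal data on small templates produce shallower steps.
  Trends (margin washout, RDC synergy), not absolute ΔE, are the meaningful
  output.
* Single-conformer truth: see above.
* The 4D→3D reduction truncates after a principal-axes rotation; a gradual
  compression of the fourth coordinate (`compress_w`) is implemented but
  experimental and off by default.
* Tetrangle-level smoothing and sparse-matrix scalability beyond a few
  hundred atoms are out of scope.
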