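# fcdg — floating-chirality distance geometry for NMR configurational analysis

`fcdg` determines the **relative configuration** (and conformation) of small
organic molecules directly from NMR-derived restraints — NOE/ROE interproton
distances, optionally augmented with residual dipolar couplings (RDCs) —
with no physical force field, no DFT conformer pool, and no dependence on
the starting geometry.  It is aimed at natural-product and synthetic
chemists facing molecules with several contiguous stereocenters, where
n centers mean 2^(n−1) candidate diastereomers.

## The method

The engine implements floating-chirality restrained distance geometry with
distance-bounds-driven dynamics (fc-rDG/DDD):

1. The constitution plus a guess geometry yields *holonomic* distance
   bounds: 1-2/1-3 distances and planar fragments pinned at ±1%, everything
   else free between van der Waals contact and a diameter cap.  Calibrated
   NOE windows d(1 ± m) (default m = 10%, pseudo-atom corrections for
   isochronous groups) tighten the matrix further.
2. Triangle smoothing, randomized metrization, and metric-matrix embedding
   produce start structures in **4D**, where configurational inversion is a
   rotation and costs nothing.
3. Simulated annealing drives each structure with forces that are gradients
   of a dimensionless pseudo-energy

   E = k_dist Σ viol(d, [l,u])² + k_chir Σ (V_chir − V_target)² + k_rdc Σ w (D_obs − D_calc)²

   Chiral-volume restraints keep methyls tetrahedral and sp² frames planar
   and fix exactly one reference center; all other stereocenters **float**.
   After projection to 3D, annealing repeats and a zero-Kelvin quench
   converges every structure; RDC terms (with a freshly least-squares-fitted
   alignment tensor per evaluation) join during the 3D cooling phase.
4. Structures are ranked by total pseudo-energy.  The rank of the first
   structure with a *wrong* configuration and the energy gap ΔE to it
   quantify how confidently the data pick the diastereomer.

## Worked example

Generate a synthetic 4-stereocenter *trans*-fused bicyclo[3.3.0]octane
scenario, sample 12 discriminating NOE contacts from its ground truth, and
run the full pipeline on 200 structures:

```python
from fcdg.calib import build_restraints
from fcdg.ddd import DDDParams, generate_ensemble
from fcdg.fixtures import make_fixture_molecule, synth_noe_table, _proton_group_table
from fcdg.moltop import build_bounds
from fcdg.rank import first_wrong_configuration
from fcdg.stereo import standard_chiral_restraints

scen = make_fixture_molecule("bicyclic", 4, fusion="trans", seed=7)
table = synth_noe_table(scen, n_contacts=12)
groups = {gid: m for gid, m, _ in _proton_group_table(scen.molecule)}
restraints = build_restraints(table, margin=0.10, groups=groups)
chiral = standard_chiral_restraints(scen.molecule, scen.reference.center, centers=scen.centers)

params = DDDParams(hot_steps=200, cool_steps=400, dt=30.0, quench_max_iter=2000, seed=1)
ens = generate_ensemble(
    scen.molecule, build_bounds(scen.molecule), list(restraints) + list(chiral),
    n_structures=200, params=params, centers=scen.centers, reference=scen.reference,
)
report = first_wrong_configuration(ens, scen.truth_fingerprint)
print("truth fingerprint:   ", scen.truth_fingerprint.text)
print("best structure:      ", ens.fingerprints[0].text, f"(e_total = {ens.e_totals[0]:.4f})")
print("first wrong config at rank", report.first_wrong_rank, f"with dE = {report.delta_e:.4f}")
```

Output:

```
truth fingerprint:    +---
best structure:       +--- (e_total = 0.0002)
first wrong config at rank 22 with dE = 0.0098
```

Reading it: the lowest-pseudo-energy structure already carries the true
relative configuration (`+---` over the four centers, reference normalized
to `+`), the 21 best structures all agree on it, and the first structure
proposing any other diastereomer is separated by a visible pseudo-energy
step.  Widening the restraint windows to ±20–30% erodes that step — the
package's margin-scan experiment quantifies exactly that washout — while
adding RDCs to a sparse NOE set widens it.

A command-line interface wraps the same pipeline for file-based work
(`fcdg run --mol mol.sdf --restraints noe.tsv --fix-center 1 ...`) and for
emitting synthetic scenarios (`fcdg synth --label bicyclic --centers 4
--fusion trans ...`).

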