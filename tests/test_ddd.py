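import numpy as np
import pytest

from fcdg.calib import DistanceRestraint
from fcdg.ddd import (
    DDDParams,
    RestraintSystem,
    anneal_stage,
    energy_gradient,
    generate_ensemble,
    pseudo_energy,
    reduce_dimension,
)
from fcdg.embed import smooth_bounds
from fcdg.moltop import Atom, Bond, Molecule, BoundsMatrix, build_bounds
from fcdg.stereo import ChiralRestraint


def linear_molecule(n=4, spacing=1.5):
    atoms = [Atom(i + 1, "C", 1.7) for i in range(n)]
    bonds = [Bond(i + 1, i + 2) for i in range(n - 1)]
    coords = np.zeros((n, 3))
    coords[:, 0] = np.arange(n) * spacing
    return Molecule(atoms, bonds, guess_coords=coords)


@pytest.fixture()
def simple_system():
    mol = linear_molecule()
    bounds = build_bounds(mol, slack=0.01)
    return mol, smooth_bounds(bounds)


class TestPseudoEnergy:
    def test_satisfied_system_is_zero(self, simple_system):
        mol, sm = simple_system
        e = pseudo_energy(mol.guess_coords, mol, sm)
        assert e.e_total == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_quadratic_penalty(self):
        mol = linear_molecule(2)
        lo = np.array([[0.0, 1.0], [1.0, 0.0]])
        up = np.array([[0.0, 2.0], [2.0, 0.0]])
        delta = 0.3
        coords = np.array([[0.0, 0, 0], [2.0 + delta, 0, 0]])
        e = pseudo_energy(coords, mol, BoundsMatrix(lo, up), k_dist=1.0)
        assert e.e_dist == pytest.approx(delta**2, rel=1e-12)

    def test_terms_are_additive(self, simple_system):
        mol, sm = simple_system
        coords = mol.guess_coords.copy()
        coords[3, 0] += 1.0  # distance violation
        chir = ChiralRestraint(atoms=(1, 2, 3, 4), target_volume=0.5, mode="fixed-sign")
        rest = DistanceRestraint("1", "4", target=3.0, lower=2.9, upper=3.1)
        e_both = pseudo_energy(coords, mol, sm, [chir, rest])
        e_dist_only = pseudo_energy(coords, mol, sm, [rest])
        e_chir_only = pseudo_energy(coords, mol, sm, [chir])
        assert e_both.e_total == pytest.approx(
            e_dist_only.e_dist + e_chir_only.e_chir, rel=1e-12
        )
        assert e_both.e_total == e_both.e_dist + e_both.e_chir + e_both.e_rdc

    def test_energy_rotation_invariance(self, simple_system, rng):
        from scipy.spatial.transform import Rotation

        mol, sm = simple_system
        coords = mol.guess_coords + rng.normal(0, 0.3, (4, 3))
        rest = [DistanceRestraint("1", "4", target=3.0, lower=2.9, upper=3.1)]
        e0 = pseudo_energy(coords, mol, sm, rest).e_total
        rot = Rotation.from_euler("xyz", [33, -71, 12], degrees=True).as_matrix()
        e1 = pseudo_energy(coords @ rot.T + 2.0, mol, sm, rest).e_total
        assert e1 == pytest.approx(e0, rel=1e-10)


class TestGradient:
    def test_zero_at_satisfied_minimum(self, simple_system):
        mol, sm = simple_system
        g = energy_gradient(mol.guess_coords, mol, sm)
        assert np.abs(g).max() < 1e-12

    @pytest.mark.parametrize("dim", [3, 4])
    def test_matches_central_differences(self, simple_system, rng, dim):
        mol, sm = simple_system
        coords = np.c_[mol.guess_coords, np.zeros(4)][:, :dim] + rng.normal(0, 0.4, (4, dim))
        restraints = [
            DistanceRestraint("1", "4", target=2.0, lower=1.9, upper=2.1),
            ChiralRestraint(atoms=(1, 2, 3, 4), target_volume=0.7, mode="fixed-sign"),
        ]
        g = energy_gradient(coords, mol, sm, restraints)
        h = 1e-6

        def e(c):
            return pseudo_energy(c, mol, sm, restraints).e_total

        for a in range(4):
            for d in range(dim):
                p1, p2 = coords.copy(), coords.copy()
                p1[a, d] += h
                p2[a, d] -= h
                fd = (e(p1) - e(p2)) / (2 * h)
                assert g[a, d] == pytest.approx(fd, rel=2e-6, abs=1e-9)

    def test_net_translational_force_vanishes(self, simple_system, rng):
        mol, sm = simple_system
        coords = mol.guess_coords + rng.normal(0, 0.5, (4, 3))
        g = energy_gradient(coords, mol, sm, [DistanceRestraint("1", "3", 2.0, 1.9, 2.1)])
        np.testing.assert_allclose(g.sum(axis=0), 0.0, atol=1e-10)


class TestAnnealStage:
    def test_satisfied_zero_kelvin_fixed_point(self, simple_system):
        mol, sm = simple_system
        system = RestraintSystem(mol, sm)
        params = DDDParams(t_high=0.0, hot_steps=10, cool_steps=10, dt=10.0)
        out, trace = anneal_stage(mol.guess_coords.copy(), system, params, dim=3)
        np.testing.assert_allclose(out, mol.guess_coords, atol=1e-12)
        np.testing.assert_allclose(trace, 0.0, atol=1e-12)

    def test_statistical_descent(self, simple_system):
        """Annealing lowers the pseudo-energy for nearly every seed."""
        mol, sm = simple_system
        system = RestraintSystem(mol, sm)
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            start = mol.guess_coords + rng.normal(0, 0.6, (4, 3))
            e0 = pseudo_energy(start, mol, sm).e_total
            params = DDDParams(hot_steps=50, cool_steps=150, dt=20.0, seed=seed)
            out, trace = anneal_stage(start, system, params, dim=3)
            wins += trace[-1] < e0
        assert wins >= 19

    def test_cooling_schedule_non_increasing(self):
        params = DDDParams(hot_steps=100, cool_steps=100)
        temps = params.schedule()
        assert np.all(np.diff(temps[params.hot_steps :]) <= 0)
        assert temps[0] == params.t_high and temps[-1] == 0.0


class TestReduceDimension:
    def test_null_fourth_axis_preserves_distances(self, rng):
        c4 = np.c_[rng.normal(size=(6, 3)), np.zeros(6)]
        c3 = reduce_dimension(c4)
        d4 = np.linalg.norm(c4[:, None] - c4[None], axis=-1)
        d3 = np.linalg.norm(c3[:, None] - c3[None], axis=-1)
        np.testing.assert_allclose(d3, d4, atol=1e-12)

    def test_projection_shrinks_distances(self, rng):
        c4 = rng.normal(size=(6, 4))
        c3 = reduce_dimension(c4)
        d4 = np.linalg.norm(c4[:, None] - c4[None], axis=-1)
        d3 = np.linalg.norm(c3[:, None] - c3[None], axis=-1)
        assert np.all(d3 <= d4 + 1e-12)

    def test_wrong_dimensionality_rejected(self):
        with pytest.raises(ValueError):
            reduce_dimension(np.zeros((5, 3)))


class TestGenerateEnsemble:
    def run(self, scen, n=10, seed=3, **kw):
        from fcdg.fixtures import _proton_group_table, synth_noe_table
        from fcdg.calib import build_restraints
        from fcdg.stereo import standard_chiral_restraints

        mol = scen.molecule
        table = synth_noe_table(scen, n_contacts=12)
        groups = {gid: m for gid, m, _ in _proton_group_table(mol)}
        restraints = build_restraints(table, margin=0.10, groups=groups)
        chiral = standard_chiral_restraints(mol, scen.reference.center, centers=scen.centers)
        params = DDDParams(hot_steps=60, cool_steps=120, dt=30.0, quench_max_iter=200, seed=seed)
        return generate_ensemble(
            mol,
            build_bounds(mol),
            list(restraints) + list(chiral),
            n_structures=n,
            params=params,
            centers=scen.centers,
            reference=scen.reference,
            **kw,
        )

    def test_exact_count_sorted_ascending(self, bicyclic_cis):
        ens = self.run(bicyclic_cis, n=10)
        assert len(ens) == 10
        es = ens.e_totals
        assert np.all(np.diff(es) >= -1e-12)

    def test_same_seed_reproducible_different_seed_not(self, bicyclic_cis):
        e1 = self.run(bicyclic_cis, n=6, seed=5)
        e2 = self.run(bicyclic_cis, n=6, seed=5)
        e3 = self.run(bicyclic_cis, n=6, seed=6)
        np.testing.assert_array_equal(e1.e_totals, e2.e_totals)
        for a, b in zip(e1.structures, e2.structures):
            np.testing.assert_array_equal(a.coords, b.coords)
        assert not np.array_equal(e1.e_totals, e3.e_totals)

    def test_fingerprints_populate_multiple_configs(self, bicyclic_cis):
        """Floating centers + configuration-agnostic bounds sample several diastereomers."""
        ens = self.run(bicyclic_cis, n=16)
        assert len({fp.text for fp in ens.fingerprints}) >= 2
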