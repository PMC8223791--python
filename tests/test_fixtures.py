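import numpy as np
import pytest

from fcdg.calib import PeakVolume, build_restraints, calibrate_distances
from fcdg.ddd import DDDParams, pseudo_energy
from fcdg.embed import smooth_bounds
from fcdg.fixtures import (
    DEFAULT_BUDGETS,
    _proton_group_table,
    make_fixture_molecule,
    recovery_experiment,
    synth_noe_table,
    synth_rdc_table,
    write_scenario,
)
from fcdg.moltop import build_bounds
from fcdg.rdc import fit_tensor, random_tensor
from fcdg.stereo import fingerprint


class TestMakeFixture:
    def test_trans_fingerprint_roundtrips(self, bicyclic_trans):
        scen = bicyclic_trans
        fp = fingerprint(scen.truth_coords, scen.centers, scen.reference)
        assert fp.text == scen.truth_fingerprint.text

    def test_cis_trans_same_constitution_different_fingerprint(self, bicyclic_cis, bicyclic_trans):
        bonds_cis = {(min(b.i, b.j), max(b.i, b.j)) for b in bicyclic_cis.molecule.bonds}
        bonds_trans = {(min(b.i, b.j), max(b.i, b.j)) for b in bicyclic_trans.molecule.bonds}
        assert bonds_cis == bonds_trans
        assert bicyclic_cis.truth_fingerprint.text != bicyclic_trans.truth_fingerprint.text

    def test_chain_two_centers_enumerates_two_configs(self):
        scen = make_fixture_molecule("chain", 2, seed=3)
        from fcdg.stereo import enumerate_relative_configs

        assert enumerate_relative_configs(len(scen.centers)) == 2

    def test_invalid_requests_rejected(self):
        with pytest.raises(ValueError, match="supports"):
            make_fixture_molecule("bicyclic", 12, fusion="cis")
        with pytest.raises(ValueError, match="fusion"):
            make_fixture_molecule("bicyclic", 4)
        with pytest.raises(ValueError, match="unknown scenario"):
            make_fixture_molecule("helix", 4)

    def test_truth_satisfies_own_holonomic_bounds(self, macrocycle):
        b = build_bounds(macrocycle.molecule)
        d = np.linalg.norm(
            macrocycle.truth_coords[:, None] - macrocycle.truth_coords[None], axis=-1
        )
        assert np.all(d <= b.upper + 1e-9)
        assert np.all(d >= b.lower - 1e-9)


class TestSynthNoe:
    def test_zero_noise_reproduces_truth_distances(self, bicyclic_cis):
        table = synth_noe_table(bicyclic_cis, n_contacts=10, noise=0.0)
        groups = {gid: m for gid, m, _ in _proton_group_table(bicyclic_cis.molecule)}
        for row in table.itertuples():
            mi = groups[row.group_i]
            mj = groups[row.group_j]
            ci = bicyclic_cis.truth_coords[[m - 1 for m in mi]].mean(axis=0)
            cj = bicyclic_cis.truth_coords[[m - 1 for m in mj]].mean(axis=0)
            assert row.distance_A == pytest.approx(float(np.linalg.norm(ci - cj)), rel=1e-12)

    def test_volume_backconversion_roundtrips(self, bicyclic_cis):
        table, vols = synth_noe_table(bicyclic_cis, n_contacts=10, volumes=True)
        ref_idx = table["distance_A"].idxmin()
        ref_pair = (table.loc[ref_idx, "group_i"], table.loc[ref_idx, "group_j"])
        pv = [PeakVolume(r.group_i, r.group_j, r.volume, r.mixing_time_ms) for r in vols.itertuples()]
        back = calibrate_distances(pv, ref_pair, table.loc[ref_idx, "distance_A"])
        merged = table.merge(back, on=["group_i", "group_j"])
        np.testing.assert_allclose(merged["distance_A_x"], merged["distance_A_y"], rtol=1e-12)

    def test_sparse_budget_on_dense_template(self):
        scen = make_fixture_molecule("bicyclic", 6, fusion="trans", seed=5)
        table = synth_noe_table(scen, n_contacts=9)
        assert len(table) == 9

    def test_determinism(self, bicyclic_cis):
        t1 = synth_noe_table(bicyclic_cis, n_contacts=12, noise=0.05, seed=4)
        t2 = synth_noe_table(bicyclic_cis, n_contacts=12, noise=0.05, seed=4)
        assert t1.equals(t2)

    def test_insufficient_contacts_rejected(self, bicyclic_cis):
        with pytest.raises(ValueError, match="cannot supply"):
            synth_noe_table(bicyclic_cis, n_contacts=10_000)

    def test_selection_includes_cross_fragment_contacts(self, bicyclic_cis):
        """Discriminating selection must never be purely local."""
        table = synth_noe_table(bicyclic_cis, n_contacts=12)
        groups = {gid: (m, c) for gid, m, c in _proton_group_table(bicyclic_cis.molecule)}
        import networkx as nx

        g = bicyclic_cis.molecule.graph()
        spl = dict(nx.all_pairs_shortest_path_length(g))
        seps = [spl[groups[r.group_i][1]][groups[r.group_j][1]] for r in table.itertuples()]
        assert max(seps) >= 3


class TestSynthRdc:
    def test_roundtrip_tensor_recovery(self, macrocycle, rng):
        tensor = random_tensor(rng, 1e-3)
        rdcs = synth_rdc_table(macrocycle, 28, tensor, noise=0.0)
        assert sum(len(r.pairs) for r in rdcs) == 28
        fitted, report = fit_tensor(macrocycle.truth_coords, rdcs, macrocycle.molecule.elements())
        np.testing.assert_allclose(
            fitted.matrix, tensor.matrix, atol=1e-8 * np.abs(tensor.matrix).max()
        )

    def test_methylene_rows_are_pair_sums(self, macrocycle, rng):
        from fcdg.rdc import backcalc_rdc

        tensor = random_tensor(rng, 1e-3)
        rdcs = synth_rdc_table(macrocycle, 28, tensor)
        elements = macrocycle.molecule.elements()
        summed = [r for r in rdcs if len(r.pairs) == 2]
        assert summed, "expected summed methylene rows"
        for r in summed:
            d1 = backcalc_rdc(macrocycle.truth_coords, tensor, r.pairs[0], elements)
            d2 = backcalc_rdc(macrocycle.truth_coords, tensor, r.pairs[1], elements)
            assert r.observed == pytest.approx(d1 + d2, rel=1e-12)

    def test_insufficient_vectors_rejected(self, macrocycle, rng):
        with pytest.raises(ValueError, match="vectors"):
            synth_rdc_table(macrocycle, 999, random_tensor(rng))


def test_truth_zero_energy_against_own_restraints(bicyclic_cis):
    """Every scenario's truth coordinates satisfy their own noise-free windows."""
    scen = bicyclic_cis
    mol = scen.molecule
    table = synth_noe_table(scen, n_contacts=12, noise=0.0)
    groups = {gid: m for gid, m, _ in _proton_group_table(mol)}
    restraints = build_restraints(table, margin=0.10, groups=groups)
    sm = smooth_bounds(build_bounds(mol))
    e = pseudo_energy(scen.truth_coords, mol, sm, restraints)
    assert e.e_dist == pytest.approx(0.0, abs=1e-10)


def test_recovery_experiment_smoke(bicyclic_cis):
    """A small-scale end-to-end recovery run returns a coherent summary."""
    params = DDDParams(hot_steps=60, cool_steps=120, dt=30.0, quench_max_iter=200)
    out = recovery_experiment(bicyclic_cis, n_structures=12, n_seeds=2, params=params)
    assert set(out) >= {"success_rate", "median_delta_e", "reports", "truth"}
    assert len(out["reports"]) == 2
    assert 0.0 <= out["success_rate"] <= 1.0


def test_write_scenario_emits_text_artifacts(bicyclic_cis, tmp_path):
    paths = write_scenario(bicyclic_cis, tmp_path / "scen")
    assert paths["sdf"].exists() and paths["groups"].exists() and paths["restraints"].exists()
    assert "V2000" in paths["sdf"].read_text()
    assert paths["groups"].read_text().startswith("group_id")


def test_default_budgets_mirror_sparse_regimes():
    assert DEFAULT_BUDGETS == {"bicyclic": 12, "chain": 25, "macrocycle": 9}
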