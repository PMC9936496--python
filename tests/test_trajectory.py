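"""Tests for trajectory distance statistics, heptad register and RMSD."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from azocoil import synthetic, trajectory as tj

E3 = synthetic.E3_SEQUENCE


def _toy_ensemble(coords_per_frame, topology, state="trans"):
    return tj.TrajectoryEnsemble(replicas=[np.asarray(coords_per_frame)],
                                 topology=topology, state_label=state)


def _simple_topology(n_atoms):
    return pd.DataFrame({
        "chain": ["E"] * n_atoms,
        "residue_index": np.arange(1, n_atoms + 1),
        "residue_name": ["ALA"] * n_atoms,
        "atom_name": ["CB"] * n_atoms,
        "element": ["C"] * n_atoms,
        "is_heavy": [True] * n_atoms,
        "is_sidechain": [True] * n_atoms,
    })


class TestHeptadRegister:
    def test_e3_with_g_offset_places_hydrophobic_core(self):
        reg = tj.assign_heptad_register(E3, "g")
        # Ile9 at 'a'; Leu5 and Leu12 at 'd'; Ala4 'c'; Glu8 'g'
        assert reg[8] == "a"
        assert reg[4] == "d" and reg[11] == "d"
        assert reg[3] == "c" and reg[7] == "g"

    def test_offset_a_starts_at_a(self):
        assert tj.assign_heptad_register("LEQK", "a")[0] == "a"

    def test_cyclic_with_period_seven(self):
        reg = tj.assign_heptad_register("A" * 21, "c")
        assert reg[:7] == reg[7:14] == reg[14:]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            tj.assign_heptad_register("", "a")


class TestMoietyDistances:
    def test_three_four_five_triangle(self):
        topo = _simple_topology(2)
        frame = np.array([[[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]])
        ens = _toy_ensemble(frame, topo)
        series = tj.moiety_distance_series(ens, [0], [1])
        assert series[0][0] == pytest.approx(5.0)

    def test_coincident_atoms_give_zero_min_distance(self):
        topo = _simple_topology(3)
        frame = np.array([[[0.0, 0.0, 0.0], [1.0, 1.0, 1.0],
                           [0.0, 0.0, 0.0]]])
        ens = _toy_ensemble(frame, topo)
        assert tj.moiety_distance_series(ens, [0, 1], [2])[0][0] == 0.0

    def test_min_metric_matches_bruteforce_pairs(self, rng):
        n_a, n_b = 5, 6
        topo = _simple_topology(n_a + n_b)
        frames = rng.normal(size=(4, n_a + n_b, 3)) * 10.0
        ens = _toy_ensemble(frames, topo)
        series = tj.moiety_distance_series(ens, range(n_a),
                                           range(n_a, n_a + n_b))
        for fi, frame in enumerate(frames):
            brute = min(np.linalg.norm(frame[i] - frame[j])
                        for i in range(n_a)
                        for j in range(n_a, n_a + n_b))
            assert series[0][fi] == pytest.approx(brute, rel=1e-12)

    def test_symmetric_and_rigid_motion_invariant(self, rng):
        topo = _simple_topology(8)
        frame = rng.normal(size=(1, 8, 3)) * 5.0
        ens = _toy_ensemble(frame, topo)
        a, b = [0, 1, 2], [5, 6, 7]
        d_ab = tj.moiety_distance_series(ens, a, b)[0][0]
        d_ba = tj.moiety_distance_series(ens, b, a)[0][0]
        assert d_ab == pytest.approx(d_ba)
        R = Rotation.random(random_state=3).as_matrix()
        moved = frame @ R.T + np.array([10.0, -4.0, 2.0])
        ens2 = _toy_ensemble(moved, topo)
        assert tj.moiety_distance_series(ens2, a, b)[0][0] == pytest.approx(
            d_ab, rel=1e-9)

    def test_empty_selection_rejected(self):
        ens = _toy_ensemble(np.zeros((1, 2, 3)), _simple_topology(2))
        with pytest.raises(ValueError, match="empty"):
            tj.moiety_distance_series(ens, [], [1])


class TestEnsembleAveraging:
    def test_replica_means_average_with_sample_sd(self):
        series = [np.full(10, 4.0), np.full(10, 5.0), np.full(10, 6.0)]
        mean, sd = tj.ensemble_mean_distance(series)
        assert mean == pytest.approx(5.0)
        assert sd == pytest.approx(1.0)

    def test_identical_replicas_zero_spread(self):
        series = [np.array([1.0, 3.0])] * 3
        mean, sd = tj.ensemble_mean_distance(series)
        assert mean == pytest.approx(2.0)
        assert sd == 0.0

    def test_single_replica_passthrough_with_warning(self):
        with pytest.warns(UserWarning, match="single replica"):
            mean, sd = tj.ensemble_mean_distance([np.array([2.0, 4.0])])
        assert (mean, sd) == (3.0, 0.0)

    def test_permutation_invariant_in_replica_order(self, rng):
        series = [rng.normal(5, 1, 20) for _ in range(3)]
        m1 = tj.ensemble_mean_distance(series)
        m2 = tj.ensemble_mean_distance(series[::-1])
        assert m1[0] == pytest.approx(m2[0])
        assert m1[1] == pytest.approx(m2[1])


class TestNormalizedDistanceChange:
    @staticmethod
    def _table(means):
        return pd.DataFrame([
            {"residue_index": r, "residue_name": "ALA", "moiety": m,
             "mean": v, "sd": 0.0}
            for (r, m), v in means.items()])

    def test_identical_states_give_zero_change(self):
        t = self._table({(1, "diazene"): 5.0, (2, "ring2"): 7.0})
        out = tj.normalized_distance_change(t, t.copy())
        assert np.allclose(out["delta_norm"], 0.0)
        assert not out["significant"].any()

    def test_signed_changes_against_cutoff(self):
        t = self._table({(1, "diazene"): 5.0, (2, "diazene"): 5.0})
        c = self._table({(1, "diazene"): 6.5, (2, "diazene"): 4.5})
        out = tj.normalized_distance_change(t, c, cutoff=0.2)
        row1 = out[out.residue_index == 1].iloc[0]
        row2 = out[out.residue_index == 2].iloc[0]
        assert row1["delta_norm"] == pytest.approx(0.30)
        assert bool(row1["significant"])
        assert row2["delta_norm"] == pytest.approx(-0.10)
        assert not row2["significant"]

    def test_scale_invariance_of_delta_norm(self):
        t = self._table({(1, "ring1"): 4.0})
        c = self._table({(1, "ring1"): 5.0})
        out1 = tj.normalized_distance_change(t, c)
        t2, c2 = t.copy(), c.copy()
        t2["mean"] *= 7.0
        c2["mean"] *= 7.0
        out2 = tj.normalized_distance_change(t2, c2)
        assert out1["delta_norm"].iloc[0] == pytest.approx(
            out2["delta_norm"].iloc[0])

    def test_mismatched_keys_rejected(self):
        t = self._table({(1, "diazene"): 5.0})
        c = self._table({(2, "diazene"): 5.0})
        with pytest.raises(ValueError, match="mismatched"):
            tj.normalized_distance_change(t, c)


class TestContactShell:
    def test_closed_boundary_at_radius(self):
        topo = _simple_topology(3)
        for d, included in ((4.9, True), (5.1, False)):
            frame = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0],
                              [50.0, 0.0, 0.0]])
            hits = tj.contact_shell(frame, [0], topo, chain="E")
            assert (2 in hits) is included

    def test_matches_bruteforce_on_random_frame(self, rng):
        n = 30
        topo = _simple_topology(n)
        frame = rng.normal(size=(n, 3)) * 6.0
        probes = [0, 1]
        hits = tj.contact_shell(frame, probes, topo, chain="E", radius=5.0)
        brute = [int(topo.loc[i, "residue_index"]) for i in range(n)
                 if cdist(frame[[i]], frame[probes]).min() <= 5.0]
        assert hits == sorted(brute)

    def test_empty_probe_warns_and_returns_empty(self):
        topo = _simple_topology(2)
        with pytest.warns(UserWarning, match="empty probe"):
            assert tj.contact_shell(np.zeros((2, 3)), [], topo, "E") == []


class TestHelixRmsd:
    def test_identity_and_rigid_motion_give_zero(self):
        helix = tj.ideal_helix(12)
        assert tj.helix_rmsd(helix, helix) == pytest.approx(0.0, abs=1e-9)
        R = Rotation.from_euler("xyz", [0.3, -1.1, 0.7]).as_matrix()
        moved = helix @ R.T + np.array([3.0, -2.0, 8.0])
        assert tj.helix_rmsd(moved, helix) == pytest.approx(0.0, abs=1e-9)

    def test_default_reference_is_matching_ideal_helix(self):
        helix = tj.ideal_helix(15)
        assert tj.helix_rmsd(helix) == pytest.approx(0.0, abs=1e-9)

    def test_single_displaced_atom_matches_numeric_oracle(self):
        # Oracle: direct numeric minimization over rigid motions.
        from scipy.optimize import minimize
        ref = tj.ideal_helix(10)
        moved = ref.copy()
        moved[4] += np.array([0.0, 0.0, 2.0])

        def rmsd_of(x):
            R = Rotation.from_rotvec(x[:3]).as_matrix()
            shifted = moved @ R.T + x[3:]
            return np.sqrt(np.mean(np.sum((shifted - ref) ** 2, axis=1)))

        best = min(minimize(rmsd_of, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12,
                                     "maxiter": 20000}).fun
                   for x0 in (np.zeros(6), np.array([0.1, 0, 0, 0, 0, 0])))
        val = tj.helix_rmsd(moved, ref)
        assert val == pytest.approx(best, abs=1e-6)
        # and bounded by the translation-only closed form d*sqrt((N-1))/N
        assert val <= 2.0 * np.sqrt(9) / 10 + 1e-12

    def test_too_few_atoms_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            tj.helix_rmsd(np.zeros((2, 3)))


class TestToyTrajectoryRecovery:
    def test_measured_table_matches_analytic_truth(self,
                                                   default_toy_trajectory):
        trans, cis, mm, truth = default_toy_trajectory
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t_tbl = tj.chain_moiety_distances(trans, "E", mm)
            c_tbl = tj.chain_moiety_distances(cis, "E", mm)
        measured = tj.normalized_distance_change(t_tbl, c_tbl,
                                                 cutoff=truth["cutoff"])
        truth_tbl = pd.DataFrame(truth["table"])
        keys = ["residue_index", "moiety"]
        m = measured.set_index(keys).sort_index()
        t = truth_tbl.set_index(keys).sort_index()
        assert m.index.equals(t.index)
        assert (m["significant"] == t["significant"]).all()
        sig = t["significant"]
        assert (np.sign(m.loc[sig, "delta_norm"])
                == np.sign(t.loc[sig, "delta_norm"])).all()

    def test_diazene_moves_away_from_opposing_d_positions(
            self, default_toy_trajectory):
        # The d-position Leu residues facing the switch must see a
        # positive (farther-in-cis) diazene change; sign is stable
        # across generator seeds.
        for seed in (1, 2):
            _, _, _, truth = (default_toy_trajectory if seed == 1 else
                              synthetic.gen_toy_trajectory(
                                  synthetic.TrajectorySpec(seed=seed,
                                                           n_frames=20)))
            tbl = pd.DataFrame(truth["table"])
            reg = tj.assign_heptad_register(E3,
                                            synthetic.E3_REGISTER_OFFSET)
            d_positions = [i + 1 for i, r in enumerate(reg) if r == "d"]
            rows = tbl[(tbl.moiety == "diazene")
                       & tbl.residue_index.isin(d_positions)]
            assert (rows["delta_norm"] > 0).all()

    def test_jitter_free_frames_are_identical(self):
        spec = synthetic.TrajectorySpec(jitter_sigma=0.0, n_frames=3,
                                        n_replicas=2)
        trans, _, _, _ = synthetic.gen_toy_trajectory(spec)
        for rep in trans.replicas:
            assert np.allclose(rep[0], rep[1])
            assert np.allclose(rep[0], rep[2])
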