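"""MSM stack: featurization, VAMP-2, TICA, clustering, estimation, PCCA++."""

import itertools

import numpy as np
import pytest

from mdresidence.core import Trajectory
from mdresidence import msm
from mdresidence.msm import (MSMModel, cluster_microstates, estimate_msm,
                             featurize_backbone_torsions, fit_tica,
                             implied_timescales, its_over_lags,
                             pcca_coarse_grain, select_representatives,
                             transition_matrix_from_counts, vamp2_score)
from mdresidence.synthetic import (KineticEmissionSpec, build_peptide,
                                   gen_metastable_trajectory,
                                   sample_markov_chain)


class TestFeaturization:
    def test_feature_count_five_residues(self):
        pep = build_peptide([(-60.0, -45.0)] * 5)
        traj = Trajectory(pep, pep.coords[None])
        fm = featurize_backbone_torsions(traj)
        # 4 phi + 4 psi torsions, each as (cos, sin)
        assert fm.data.shape == (1, 16)

    def test_sincos_identity(self):
        pep = build_peptide([(-60.0, -45.0), (-120.0, 130.0), (60.0, 40.0)])
        traj = Trajectory(pep, pep.coords[None])
        fm = featurize_backbone_torsions(traj)
        pairs = fm.data[0].reshape(-1, 2)
        np.testing.assert_allclose((pairs ** 2).sum(axis=1), 1.0, atol=1e-9)

    def test_recovers_requested_torsions(self):
        """The featurizer reads back the phi/psi the builder planted."""
        angles = [(-57.0, -47.0), (-120.0, 130.0), (-75.0, 150.0),
                  (60.0, 40.0)]
        pep = build_peptide(angles)
        traj = Trajectory(pep, pep.coords[None])
        fm = featurize_backbone_torsions(traj)
        got = {}
        for j, lab in enumerate(fm.labels):
            chain, resnum, name, comp = lab
            got.setdefault((resnum, name), {})[comp] = fm.data[0, j]
        for resnum, phi_psi in enumerate(angles, start=1):
            for name, expect in zip(("phi", "psi"), phi_psi):
                if (resnum, name) not in got:
                    continue  # undefined at the termini
                rec = np.degrees(np.arctan2(got[(resnum, name)]["sin"],
                                            got[(resnum, name)]["cos"]))
                assert rec == pytest.approx(expect, abs=1e-5)

    def test_periodicity_metric(self):
        """179 deg and -179 deg are closer in feature space than 179 and
        170 deg."""
        def feat(a):
            return np.array([np.cos(np.radians(a)), np.sin(np.radians(a))])
        assert np.linalg.norm(feat(179) - feat(-179)) < \
            np.linalg.norm(feat(179) - feat(170))

    def test_constant_helix_zero_variance(self):
        pep = build_peptide([(-57.0, -47.0)] * 6)
        xyz = np.repeat(pep.coords[None], 5, axis=0)
        fm = featurize_backbone_torsions(Trajectory(pep, xyz))
        assert np.allclose(fm.data.var(axis=0), 0.0, atol=1e-18)

    def test_exclusions_respected(self):
        pep = build_peptide([(-60.0, -45.0)] * 5)
        traj = Trajectory(pep, pep.coords[None])
        fm = featurize_backbone_torsions(traj, residue_exclusions=[("A", 3)])
        assert fm.data.shape[1] == 12  # phi3 and psi3 dropped


class TestVAMP2:
    def test_iid_noise_approaches_one(self):
        rng = np.random.default_rng(0)
        scores = [vamp2_score(rng.normal(size=(20000, 3)), lag=5,
                              n_components=3) for _ in range(3)]
        assert np.mean(scores) == pytest.approx(1.0, abs=0.02)

    def test_two_state_indicator_closed_form(self):
        """For exact two-state indicator features the VAMP-2 score is
        1 + lambda_2^2."""
        t = np.array([[0.9, 0.1], [0.2, 0.8]])
        lam2 = 0.7
        states = sample_markov_chain(t, 200000, seed=3)
        x = np.column_stack([(states == 0).astype(float),
                             (states == 1).astype(float)])
        score = vamp2_score(x, lag=1, n_components=2)
        assert score == pytest.approx(1.0 + lam2 ** 2, abs=0.02)

    def test_single_component_is_constant(self):
        rng = np.random.default_rng(1)
        assert vamp2_score(rng.normal(size=(500, 4)), 2, n_components=1) == 1.0


class TestTICA:
    @staticmethod
    def _slow_fast(n=50000, seed=0):
        """AR(1) pair: slow coordinate (corr time ~100) and fast (~2)."""
        rng = np.random.default_rng(seed)
        a_slow, a_fast = np.exp(-1 / 100), np.exp(-1 / 2)
        x = np.zeros((n, 2))
        for i in range(1, n):
            x[i, 0] = a_slow * x[i - 1, 0] + rng.normal()
            x[i, 1] = a_fast * x[i - 1, 1] + rng.normal()
        return x

    def test_ic1_aligns_with_slow_axis(self):
        x = self._slow_fast()
        model, _ = fit_tica(x, lag=10, n_dims=2)
        ic1 = model.loadings[:, 0] / np.linalg.norm(model.loadings[:, 0])
        assert abs(ic1[0]) > 0.99

    def test_white_noise_eigenvalues_near_zero(self):
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(5):
            model, _ = fit_tica(rng.normal(size=(20000, 3)), lag=5)
            vals.append(np.abs(model.eigenvalues).max())
        assert np.max(vals) < 0.05

    def test_affine_rescaling_invariance(self):
        """Projections agree up to sign under feature rescaling/shift."""
        x = self._slow_fast(n=20000, seed=2)
        _, p1 = fit_tica(x, lag=10, n_dims=2)
        x2 = x * np.array([3.0, 0.2]) + np.array([5.0, -1.0])
        _, p2 = fit_tica(x2, lag=10, n_dims=2)
        for k in range(2):
            agree = min(np.max(np.abs(p1[:, k] - p2[:, k])),
                        np.max(np.abs(p1[:, k] + p2[:, k])))
            assert agree < 1e-6

    def test_lag_validation(self):
        with pytest.raises(ValueError, match="exceed"):
            fit_tica(np.zeros((5, 2)), lag=10)


class TestClustering:
    def test_sqrt_n_default(self):
        rng = np.random.default_rng(0)
        centers, labels = cluster_microstates(rng.normal(size=(400, 2)))
        assert centers.shape[0] == 20

    def test_degenerate_single_point(self):
        centers, labels = cluster_microstates(np.zeros((50, 2)), k_override=5)
        assert centers.shape[0] == 1
        assert np.all(labels == 0)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            cluster_microstates(np.zeros((3, 2)), k_override=10)

    def test_near_optimal_vs_exhaustive_bipartition(self):
        """k-means objective within 5% of the exhaustive 2-partition
        optimum on 20 points."""
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 1, (10, 2)),
                         rng.normal(6, 1, (10, 2))])
        best = np.inf
        n = len(pts)
        masks = (np.arange(2 ** (n - 1))[:, None] >>
                 np.arange(n)[None, :]) & 1  # point 0 fixed in group A
        masks = masks.astype(bool)
        sq = (pts ** 2).sum()
        for mask in masks:
            a, b = pts[~mask], pts[mask]
            if len(b) == 0:
                continue
            cost = sq - (a.sum(0) ** 2).sum() / len(a) - \
                (b.sum(0) ** 2).sum() / len(b)
            best = min(best, cost)
        km_best = np.inf
        for seed in range(10):
            centers, labels = cluster_microstates(pts, k_override=2, seed=seed)
            cost = sum(((pts[labels == c] - centers[c]) ** 2).sum()
                       for c in range(len(centers)))
            km_best = min(km_best, cost)
        assert km_best <= best * 1.05


class TestEstimation:
    def test_symmetric_counts_exact(self):
        t, mu = transition_matrix_from_counts(np.array([[9.0, 1.0],
                                                        [1.0, 9.0]]))
        np.testing.assert_allclose(t, [[0.9, 0.1], [0.1, 0.9]], atol=1e-10)
        np.testing.assert_allclose(mu, [0.5, 0.5], atol=1e-10)

    def test_nonreversible_stationary(self):
        t, mu = transition_matrix_from_counts(
            np.array([[90.0, 10.0], [30.0, 70.0]]), mode="nonreversible")
        np.testing.assert_allclose(t, [[0.9, 0.1], [0.3, 0.7]], atol=1e-12)
        np.testing.assert_allclose(mu, [0.75, 0.25], atol=1e-10)

    def test_reversible_contracts(self):
        rng = np.random.default_rng(11)
        c = rng.integers(1, 50, size=(5, 5)).astype(float)
        t, mu = transition_matrix_from_counts(c)
        np.testing.assert_allclose(t.sum(axis=1), 1.0, atol=1e-10)
        np.testing.assert_allclose(mu @ t, mu, atol=1e-10)
        detailed = mu[:, None] * t - (mu[:, None] * t).T
        assert np.max(np.abs(detailed)) < 1e-8

    def test_disconnected_restricted_with_warning(self):
        # state 2 is entered but never left back: not strongly connected
        traj = np.array([0, 1, 0, 1, 0, 1, 0, 2, 2, 2])
        with pytest.warns(UserWarning, match="connected"):
            model = estimate_msm(traj, 1)
        assert model.n_states == 2
        assert set(model.active_set) == {0, 1}

    def test_bayesian_pi_spread(self):
        t = np.array([[0.95, 0.05], [0.05, 0.95]])
        traj = sample_markov_chain(t, 5000, seed=1)
        model = estimate_msm(traj, 1, mode="bayesian", n_samples=50, seed=2)
        assert model.pi_samples is not None
        assert model.pi_std() is not None
        assert np.abs(model.pi_samples.mean(axis=0) -
                      model.stationary).max() < 0.05


class TestTimescales:
    def test_closed_form(self):
        t = np.array([[0.95, 0.05], [0.045, 0.955]])
        model = MSMModel(counts=np.ones((2, 2)), transition_matrix=t,
                         stationary=np.array([0.5, 0.5]), lag_frames=40,
                         active_set=np.arange(2))
        table = implied_timescales([model], n_timescales=1, frame_ns=1.0)
        lam2 = np.sort(np.linalg.eigvals(t))[0]
        assert table["timescale"].iloc[0] == pytest.approx(-40 / np.log(lam2))
        # the specific case lambda2 = 0.9 at tau = 40 ns
        t9 = np.array([[0.95, 0.05], [0.05, 0.95]])
        m9 = MSMModel(counts=np.ones((2, 2)), transition_matrix=t9,
                      stationary=np.array([0.5, 0.5]), lag_frames=40,
                      active_set=np.arange(2))
        got = implied_timescales([m9], 1)["timescale"].iloc[0]
        assert got == pytest.approx(-40 / np.log(0.9), rel=1e-12)
        assert got == pytest.approx(379.6489, abs=0.001)

    def test_nondecaying_eigenvalue_flagged_absent(self):
        t = np.eye(2)
        model = MSMModel(counts=np.ones((2, 2)), transition_matrix=t,
                         stationary=np.array([0.5, 0.5]), lag_frames=10,
                         active_set=np.arange(2))
        table = implied_timescales([model], 1)
        assert np.isnan(table["timescale"].iloc[0])

    def test_markov_chain_constant_over_lags(self):
        t = np.array([[0.97, 0.03], [0.02, 0.98]])
        traj = sample_markov_chain(t, 200000, seed=4)
        table, converged = its_over_lags(traj, [1, 2, 4, 8], n_timescales=1)
        slow = table[table["index"] == 2]["timescale"]
        assert converged
        assert slow.max() / slow.min() < 1.15


def _block_matrix():
    t = np.zeros((6, 6))
    for b in range(3):
        i, j = 2 * b, 2 * b + 1
        t[i, i] = t[j, j] = 0.45
        t[i, j] = t[j, i] = 0.45
        for k in range(6):
            if k not in (i, j):
                t[i, k] += 0.1 / 4
                t[j, k] += 0.1 / 4
    return t


class TestPCCA:
    def test_two_state_identity_partition(self):
        t = np.array([[0.9, 0.1], [0.1, 0.9]])
        model = MSMModel(counts=np.ones((2, 2)), transition_matrix=t,
                         stationary=np.array([0.5, 0.5]), lag_frames=1,
                         active_set=np.arange(2))
        part = pcca_coarse_grain(model, 2)
        assert sorted(part.assignments.tolist()) == [0, 1]
        np.testing.assert_allclose(np.sort(part.pi), [0.5, 0.5], atol=1e-12)

    def test_planted_blocks_recovered_exactly(self):
        """Crisp PCCA++ partition equals the planted 3 blocks, checked
        against every possible 3-partition."""
        t = _block_matrix()
        mu = np.full(6, 1 / 6)
        model = MSMModel(counts=t * 600, transition_matrix=t, stationary=mu,
                         lag_frames=1, active_set=np.arange(6))
        part = pcca_coarse_grain(model, 3)
        planted = [frozenset({0, 1}), frozenset({2, 3}), frozenset({4, 5})]
        got = [frozenset(np.where(part.assignments == s)[0].tolist())
               for s in range(3)]
        assert sorted(got, key=min) == planted
        # and the planted partition is the unique best metastable one
        best = None
        for labels in itertools.product(range(3), repeat=6):
            if len(set(labels)) != 3:
                continue
            sets = [np.where(np.array(labels) == s)[0] for s in range(3)]
            trace = sum(
                mu[s] @ t[np.ix_(s, s)].sum(axis=1) / mu[s].sum()
                for s in sets)
            if best is None or trace > best[0]:
                best = (trace, labels)
        best_sets = sorted((frozenset(np.where(np.array(best[1]) == s)[0]
                                      .tolist()) for s in range(3)), key=min)
        assert best_sets == planted

    def test_pi_sums_to_one(self):
        rng = np.random.default_rng(13)
        c = rng.integers(1, 100, size=(8, 8)).astype(float)
        t, mu = transition_matrix_from_counts(c)
        model = MSMModel(counts=c, transition_matrix=t, stationary=mu,
                         lag_frames=1, active_set=np.arange(8))
        part = pcca_coarse_grain(model, 3)
        assert abs(part.pi.sum() - 1.0) < 1e-10
        assert np.all(part.memberships >= 0)
        np.testing.assert_allclose(part.memberships.sum(axis=1), 1.0,
                                   atol=1e-10)


class TestCKTest:
    def test_markov_fixture_passes(self):
        traj = sample_markov_chain(_block_matrix(), 50000, seed=1)
        model = estimate_msm(traj, 1)
        ck = msm.ck_test(model, traj, 3, factors=(2, 3, 4, 5), seed=0)
        assert ck.passed
        assert ck.max_deviation < 0.02

    def test_hidden_state_fixture_fails(self):
        """Lumping two hidden states with very different exit rates breaks
        the Markov property at the observation lag."""
        th = np.zeros((4, 4))
        th[0, 0], th[0, 1] = 0.997, 0.003
        th[1, 0], th[1, 1], th[1, 2], th[1, 3] = 0.003, 0.747, 0.15, 0.10
        th[2, 1], th[2, 2], th[2, 3] = 0.20, 0.75, 0.05
        th[3, 1], th[3, 2], th[3, 3] = 0.15, 0.05, 0.80
        hidden = sample_markov_chain(th, 50000, seed=2)
        obs = np.where(hidden <= 1, 0, hidden - 1)
        model = estimate_msm(obs, 1)
        ck = msm.ck_test(model, obs, 3, factors=(2, 3, 4, 5), seed=0)
        assert not ck.passed
        assert ck.max_deviation > 0.03

    def test_factor_validation(self):
        model = MSMModel(counts=np.ones((2, 2)),
                         transition_matrix=np.full((2, 2), 0.5),
                         stationary=np.array([0.5, 0.5]), lag_frames=1,
                         active_set=np.arange(2))
        with pytest.raises(ValueError, match="factors"):
            msm.ck_test(model, np.zeros(10, dtype=int), 2, factors=(1, 2))


class TestRepresentatives:
    def test_single_frame_state(self):
        t = np.array([[0.9, 0.1], [0.1, 0.9]])
        model = MSMModel(counts=np.ones((2, 2)), transition_matrix=t,
                         stationary=np.array([0.99, 0.01]), lag_frames=1,
                         active_set=np.arange(2))
        part = pcca_coarse_grain(model, 2)
        proj = np.array([[0.0], [0.1], [5.0]])
        assign = np.array([0, 0, 1])
        with pytest.warns(UserWarning, match="microstates"):
            reps = select_representatives(part, proj, assign, n_per_state=3)
        one_frame_state = [r for r in reps if len(r) == 1]
        assert [2] in one_frame_state

    def test_frame_reordering_same_coordinates(self):
        """Permuting the frames (with assignments permuted consistently)
        selects representatives at the same projected coordinates."""
        spec = KineticEmissionSpec(n_frames=3000, seed=5)
        out = gen_metastable_trajectory(spec)
        res = msm.msm_pipeline(out["features"], 5, 5, seed=1)
        proj, assign = res["projected"], res["assignments"]
        part = res["partition"]
        active_map = {orig: i for i, orig in
                      enumerate(res["model"].active_set)}
        mask = np.isin(assign, res["model"].active_set)
        local = np.array([active_map[a] for a in assign[mask]])
        proj_a = proj[mask]
        reps1 = select_representatives(part, proj_a, local)
        coords1 = sorted(tuple(np.round(proj_a[f], 9))
                         for state in reps1 for f in state)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(proj_a))
        reps2 = select_representatives(part, proj_a[perm], local[perm])
        coords2 = sorted(tuple(np.round(proj_a[perm][f], 9))
                         for state in reps2 for f in state)
        assert coords1 == coords2


def test_full_stack_reproducible_bit_for_bit():
    spec = KineticEmissionSpec(n_frames=5000, seed=9)
    out = gen_metastable_trajectory(spec)
    r1 = msm.msm_pipeline(out["features"], 5, 10, seed=7)
    r2 = msm.msm_pipeline(out["features"], 5, 10, seed=7)
    np.testing.assert_array_equal(r1["assignments"], r2["assignments"])
    np.testing.assert_array_equal(r1["model"].transition_matrix,
                                  r2["model"].transition_matrix)
    np.testing.assert_array_equal(r1["partition"].pi, r2["partition"].pi)
    assert r1["representatives"] == r2["representatives"]
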