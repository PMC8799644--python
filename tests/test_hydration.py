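"""Hydration-site clustering, displaced-water scores, weighted averages."""

import numpy as np
import pytest

from mdresidence.hydration import (HydrationSite, cluster_hydration_sites,
                                   estimate_site_energy,
                                   ligand_displacement_score, overlap_factor,
                                   read_site_table, weighted_state_score,
                                   write_site_table)
from mdresidence.synthetic import gen_water_ensemble


def _site(center, members, delta_g=None, n_frames=100):
    members = np.atleast_2d(np.asarray(members, dtype=float))
    return HydrationSite(center=np.asarray(center, dtype=float),
                         occupancy=len(members), n_frames=n_frames,
                         delta_g=delta_g, member_positions=members)


class TestClustering:
    def test_point_mass_single_site(self):
        frames = [np.array([[1.0, 2.0, 3.0]])] * 100
        sites = cluster_hydration_sites(frames)
        assert len(sites) == 1
        assert sites.sites[0].occupancy == 100
        np.testing.assert_allclose(sites.sites[0].center, [1, 2, 3])

    def test_two_separated_groups(self):
        frames = [np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0]])] * 30
        sites = cluster_hydration_sites(frames)
        assert len(sites) == 2

    def test_matches_bruteforce_greedy_oracle(self):
        """On a scatter of <= 20 points the KD-tree implementation matches a
        naive O(n^3) greedy clustering recomputed from the full distance
        matrix each round."""
        rng = np.random.default_rng(12)
        pts = rng.uniform(0, 5, size=(20, 3))
        got = cluster_hydration_sites([pts], radius=1.0, min_occupancy=2)

        remaining = pts.copy()
        expect = []
        while len(remaining):
            d = np.linalg.norm(remaining[:, None] - remaining[None], axis=2)
            counts = (d <= 1.0 + 1e-12).sum(axis=1)
            best = int(np.argmax(counts))
            if counts[best] < 2:
                break
            members = np.where(d[best] <= 1.0 + 1e-12)[0]
            expect.append((len(members), remaining[members].mean(axis=0)))
            remaining = np.delete(remaining, members, axis=0)
        assert len(got) == len(expect)
        for site, (occ, center) in zip(got.sites, expect):
            assert site.occupancy == occ
            np.testing.assert_allclose(site.center, center, atol=1e-12)

    def test_frame_order_invariance_and_occupancy_conservation(self):
        ens = gen_water_ensemble(
            [{"center": (0, 0, 0), "occupancy": 50},
             {"center": (4, 0, 0), "occupancy": 40}],
            n_frames=50, bulk_noise_per_frame=0, seed=3)
        frames = ens["positions_by_frame"]
        s1 = cluster_hydration_sites(frames, min_occupancy=5)
        s2 = cluster_hydration_sites(frames[::-1], min_occupancy=5)
        assert sorted(s.occupancy for s in s1) == \
            sorted(s.occupancy for s in s2)
        assert sum(s.occupancy for s in s1) == 90

    def test_shell_filtering(self):
        frames = [np.array([[0.0, 0.0, 0.0], [30.0, 0.0, 0.0]])] * 20
        sites = cluster_hydration_sites(frames, shell_center=np.zeros(3),
                                        shell=10.0)
        assert len(sites) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="frame"):
            cluster_hydration_sites([])


class TestSiteEnergy:
    def test_bulk_density_zero_energy(self):
        volume = 4 / 3 * np.pi
        bulk = 0.0334
        occ = bulk * volume * 1000
        s = HydrationSite(center=np.zeros(3), occupancy=occ, n_frames=1000)
        assert estimate_site_energy(s) == pytest.approx(0.0, abs=1e-12)
        assert s.source == "estimated"

    def test_e_fold_density(self):
        volume = 4 / 3 * np.pi
        occ = np.e * 0.0334 * volume * 1000
        s = HydrationSite(center=np.zeros(3), occupancy=occ, n_frames=1000)
        assert estimate_site_energy(s) == pytest.approx(-0.616, abs=1e-12)

    def test_zero_occupancy_undefined(self):
        s = HydrationSite(center=np.zeros(3), occupancy=0, n_frames=10)
        with pytest.raises(ValueError):
            estimate_site_energy(s)

    def test_planted_double_density_recovered(self):
        """A site planted at twice bulk density reads back -kT ln 2 within
        0.1 kcal/mol."""
        volume = 4 / 3 * np.pi * 1.0 ** 3
        n_frames = 4000
        occ = int(round(2.0 * 0.0334 * volume * n_frames))
        ens = gen_water_ensemble([{"center": (0, 0, 0), "occupancy": occ}],
                                 n_frames=n_frames, site_sigma=0.25, seed=4)
        sites = cluster_hydration_sites(ens["positions_by_frame"],
                                        min_occupancy=20)
        assert len(sites) == 1
        dg = estimate_site_energy(sites.sites[0])
        assert dg == pytest.approx(-0.616 * np.log(2.0), abs=0.1)


class TestOverlap:
    def test_members_at_ligand_center(self):
        s = _site([0, 0, 0], [[0, 0, 0]] * 5)
        assert overlap_factor(s, np.zeros((1, 3)), np.array([1.7])) == 1.0

    def test_far_site(self):
        s = _site([10, 0, 0], [[10, 0, 0]] * 5)
        assert overlap_factor(s, np.zeros((1, 3)), np.array([1.7])) == 0.0

    def test_exact_half_not_displaced(self):
        """Overlap of exactly 0.5 does not count as displaced (strict >)."""
        members = [[0.0, 0.0, 0.0]] * 2 + [[9.0, 0.0, 0.0]] * 2
        s = _site([4.5, 0, 0], members, delta_g=2.0)
        res = ligand_displacement_score([s], np.zeros((1, 3)),
                                        np.array([1.7]))
        assert res.overlap_factors[0] == 0.5
        assert not res.displaced[0]
        assert res.score == 0.0


class TestScore:
    def test_sign_convention(self):
        """Displacing unstable (positive dG) waters scores favorably
        (negative): sites at +3 and +2 kcal/mol give -5."""
        lig = np.zeros((1, 3))
        s1 = _site([0, 0, 0], [[0, 0, 0]] * 4, delta_g=3.0)
        s2 = _site([1.5, 0, 0], [[1.5, 0, 0]] * 4, delta_g=2.0)
        res = ligand_displacement_score([s1, s2], lig, np.array([1.7]))
        assert res.score == pytest.approx(-5.0)

    def test_no_displaced_sites(self):
        s = _site([20, 0, 0], [[20, 0, 0]] * 3, delta_g=3.0)
        res = ligand_displacement_score([s], np.zeros((1, 3)),
                                        np.array([1.7]))
        assert res.score == 0.0

    def test_nondisplaced_site_leaves_score(self):
        lig = np.zeros((1, 3))
        displaced = _site([0, 0, 0], [[0, 0, 0]] * 4, delta_g=3.0)
        res1 = ligand_displacement_score([displaced], lig, np.array([1.7]))
        far = _site([8.0, 0, 0], [[8.0, 0, 0]] * 4, delta_g=-2.0)
        res2 = ligand_displacement_score([displaced, far], lig,
                                         np.array([1.7]))
        assert res1.score == res2.score

    def test_additivity_over_disjoint_sets(self):
        lig = np.zeros((1, 3))
        a = _site([0, 0, 0], [[0, 0, 0]] * 3, delta_g=1.5)
        b = _site([1.2, 0, 0], [[1.2, 0, 0]] * 3, delta_g=-0.5)
        sep = ligand_displacement_score([a], lig, np.array([1.7])).score + \
            ligand_displacement_score([b], lig, np.array([1.7])).score
        joint = ligand_displacement_score([a, b], lig, np.array([1.7])).score
        assert joint == pytest.approx(sep)

    def test_missing_energy_reported(self):
        s = _site([0, 0, 0], [[0, 0, 0]], delta_g=None)
        with pytest.raises(ValueError, match="delta_g"):
            ligand_displacement_score([s], np.zeros((1, 3)), np.array([1.7]))


class TestWeightedScore:
    def test_equilibrium_weighted_average(self):
        """Hand arithmetic: scores (-50, -45.2, -60) with weights
        (0.08, 0.07, 0.85) average to -58.164."""
        ws = weighted_state_score([-50.0, -45.2, -60.0], [0.08, 0.07, 0.85])
        assert ws.weighted_average == pytest.approx(-58.164, abs=1e-9)
        assert ws.plain_average == pytest.approx(np.mean([-50, -45.2, -60.0]))

    def test_equal_weights_match_plain(self):
        ws = weighted_state_score([-10.0, -20.0, -30.0], [1, 1, 1])
        assert ws.weighted_average == pytest.approx(ws.plain_average)

    def test_one_hot_weight(self):
        ws = weighted_state_score([-10.0, -20.0, -30.0], [0, 1, 0])
        assert ws.weighted_average == -20.0

    def test_within_state_averaging_first(self):
        ws = weighted_state_score([[-10.0, -14.0], [-20.0, -22.0]],
                                  [0.5, 0.5])
        np.testing.assert_allclose(ws.state_scores, [-12.0, -21.0])
        assert ws.weighted_average == pytest.approx(-16.5)

    def test_bounds_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = rng.normal(size=4) * 30
            w = rng.random(4)
            ws = weighted_state_score(s, w)
            assert s.min() - 1e-12 <= ws.weighted_average <= s.max() + 1e-12

    def test_validation(self):
        with pytest.raises(ValueError, match="length"):
            weighted_state_score([1.0, 2.0], [0.5])
        with pytest.raises(ValueError, match="weights"):
            weighted_state_score([1.0], [0.0])


def test_planted_ensemble_recall_and_exact_score():
    """All planted sites are recovered and the displaced-site score equals
    the generator's ground-truth sum exactly."""
    planted = [
        {"center": (0.0, 0.0, 0.0), "occupancy": 80, "delta_g": 2.5},
        {"center": (2.5, 0.0, 0.0), "occupancy": 60, "delta_g": 1.0},
        {"center": (0.0, 8.0, 0.0), "occupancy": 70, "delta_g": -1.2},
    ]
    ens = gen_water_ensemble(planted, n_frames=100, seed=6)
    sites = cluster_hydration_sites(ens["positions_by_frame"],
                                    min_occupancy=20)
    # recall: every planted center has a recovered site within 0.5 A
    centers = np.array([s.center for s in sites])
    for truth in planted:
        d = np.linalg.norm(centers - np.asarray(truth["center"]), axis=1)
        sites.sites[int(np.argmin(d))].delta_g = truth["delta_g"]
        assert d.min() < 0.5
    lig = np.array([[0.0, 0.0, 0.0], [2.5, 0.0, 0.0]])
    res = ligand_displacement_score(sites, lig, np.full(2, 1.7))
    assert res.score == pytest.approx(-(2.5 + 1.0))


def test_site_table_roundtrip(tmp_path):
    s = cluster_hydration_sites([np.array([[0.0, 0.0, 0.0]])] * 10)
    estimate_site_energy(s.sites[0])
    p = tmp_path / "sites.tsv"
    write_site_table(s, p)
    back = read_site_table(p, n_frames=10)
    assert len(back) == 1
    assert back.sites[0].delta_g == pytest.approx(s.sites[0].delta_g)
    assert back.sites[0].source == "estimated"
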