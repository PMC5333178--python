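"""Per-step attribute derivation: stuckness, distances, free space,
lining residues, profiles, speed, classification, smoothing, aggregation."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import PHASE_TO_CATEGORY, random_rotation
from ligandpath.attributes import (
    active_site_position,
    aggregate_bars,
    charge_profile,
    classify_position,
    direction_series,
    distance_series,
    free_space_from_tunnel,
    hydrophobicity_profile,
    lining_residues,
    residue_turnover,
    sliding_window,
    speed_series,
    straightness,
    stuckness_series,
    temporal_tunnel,
)
from ligandpath.model import (
    ActiveSiteSpec,
    FrameSet,
    LigandTrajectory,
    StucknessParams,
    TunnelProfile,
    ValidationError,
)


def brute_force_straightness(pts: np.ndarray, x: int, n: int) -> float:
    """Oracle: explicit double loop over the clipped window."""
    lo, hi = max(0, x - n), min(len(pts) - 1, x + n)
    window = pts[lo : hi + 1]
    max_pair = max(
        np.linalg.norm(a - b) for a, b in itertools.combinations(window, 2)
    )
    path = sum(
        np.linalg.norm(window[i + 1] - window[i]) for i in range(len(window) - 1)
    )
    return max_pair / path


def make_frames(coords_one_frame, n_frames=1, **kwargs):
    coords = np.repeat(np.asarray(coords_one_frame, float)[None], n_frames, axis=0)
    n = coords.shape[1]
    defaults = dict(
        elements=np.array(["C"] * n),
        atom_names=np.array(["C1"] * n),
        res_names=np.array(["ALA"] * n),
        res_ids=np.arange(1, n + 1),
        chain_ids=np.array(["A"] * n),
    )
    defaults.update(kwargs)
    return FrameSet(coords=coords, **defaults)


class TestStuckness:
    def test_straight_motion_is_one(self):
        pts = np.column_stack([np.arange(20.0), np.zeros(20), np.zeros(20)])
        for x in (0, 5, 10, 19):
            assert straightness(pts, x) == pytest.approx(1.0, abs=1e-12)

    def test_alternating_positions_give_eighth(self):
        # 0,1,0,1,... with n=4: 9-point window, max pair 1, path 8
        pts = np.column_stack([np.arange(20) % 2.0, np.zeros(20), np.zeros(20)])
        assert straightness(pts, 10, StucknessParams(n=4)) == pytest.approx(0.125)

    def test_edge_window_shrinks(self):
        pts = np.column_stack([np.arange(20.0), np.zeros(20), np.zeros(20)])
        assert straightness(pts, 0, StucknessParams(n=4)) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_windows(self):
        rng = np.random.default_rng(99)
        pts = np.cumsum(rng.normal(size=(300, 3)), axis=0)
        for _ in range(200):
            x = int(rng.integers(0, 300))
            n = int(rng.integers(1, 8))
            assert straightness(pts, x, StucknessParams(n=n)) == pytest.approx(
                brute_force_straightness(pts, x, n), abs=1e-12
            )

    def test_invariant_under_rigid_motion_and_scaling(self):
        rng = np.random.default_rng(4)
        pts = np.cumsum(rng.normal(size=(50, 3)), axis=0)
        base = [straightness(pts, x) for x in range(50)]
        rot = random_rotation(rng)
        moved = 3.7 * (pts @ rot.T) + np.array([5.0, -2.0, 1.0])
        for x in (0, 10, 25, 49):
            assert straightness(moved, x) == pytest.approx(base[x], abs=1e-9)

    def test_returning_path_strictly_below_one(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.5, 0, 0], [1.5, 0, 0]])
        assert straightness(pts, 1, StucknessParams(n=2)) < 1.0

    def test_frozen_ligand_flagged(self):
        pts = np.zeros((10, 3))
        series = stuckness_series(pts)
        assert series["frozen"].all()
        assert (series["stuckness"] == 1.0).all()
        assert series["straightness"].isna().all()

    def test_display_is_complement(self):
        rng = np.random.default_rng(6)
        pts = np.cumsum(rng.normal(size=(30, 3)), axis=0)
        series = stuckness_series(pts)
        np.testing.assert_allclose(
            series["stuckness"], 1.0 - series["straightness"]
        )
        assert ((series["straightness"] > 0) & (series["straightness"] <= 1)).all()


class TestActiveSite:
    def test_single_atom_residue(self):
        frames = make_frames([[1.0, 2.0, 3.0]])
        spec = ActiveSiteSpec(residues=[("A", 1)])
        np.testing.assert_allclose(
            active_site_position(frames, spec, 0), [1.0, 2.0, 3.0]
        )

    def test_equal_masses_average(self):
        frames = make_frames([[0.0, 0, 0], [2.0, 0, 0]], res_ids=np.array([1, 1]))
        spec = ActiveSiteSpec(residues=[("A", 1)])
        np.testing.assert_allclose(active_site_position(frames, spec, 0), [1, 0, 0])

    def test_mass_weighting_matches_direct_sum(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(24, 3)) * 3
        elements = np.array((["C", "N", "O"] * 8))
        res_ids = np.repeat([1, 2, 3], 8)
        frames = make_frames(
            coords, elements=elements, res_ids=res_ids,
            res_names=np.repeat(["ALA", "GLY", "SER"], 8),
            atom_names=np.array(["X"] * 24),
        )
        spec = ActiveSiteSpec(residues=[("A", 1), ("A", 2), ("A", 3)])
        from ligandpath.scales import atomic_mass

        masses = np.array([atomic_mass(e) for e in elements])
        expected = (coords * masses[:, None]).sum(0) / masses.sum()
        np.testing.assert_allclose(
            active_site_position(frames, spec, 0), expected, atol=1e-12
        )

    def test_missing_residue_raises(self):
        frames = make_frames([[0.0, 0, 0]])
        spec = ActiveSiteSpec(residues=[("B", 9)])
        with pytest.raises(Exception):
            active_site_position(frames, spec, 0)


class TestDistanceAndDirection:
    def test_ligand_at_site_distance_zero_and_345(self):
        frames = make_frames([[0.0, 0, 0]], n_frames=2)
        spec = ActiveSiteSpec(residues=[("A", 1)])
        traj = LigandTrajectory(positions=np.array([[0.0, 0, 0], [3.0, 4.0, 0]]))
        d = distance_series(traj, frames, spec)
        np.testing.assert_allclose(d, [0.0, 5.0])

    def test_monotone_approach_smoothed_is_decreasing(self, small_scenario):
        # designed approach: ligand walks straight toward the site
        frames = make_frames([[0.0, 0, 0]], n_frames=50)
        spec = ActiveSiteSpec(residues=[("A", 1)])
        rng = np.random.default_rng(20)
        z = np.linspace(30, 2, 50) + rng.normal(scale=0.2, size=50)
        traj = LigandTrajectory(
            positions=np.column_stack([np.zeros(50), np.zeros(50), z])
        )
        smoothed = sliding_window(distance_series(traj, frames, spec), 9)
        assert (np.diff(smoothed) < 0).all()

    def test_direction_labels(self):
        assert (direction_series(np.arange(10.0, 0, -1)) == "toward").all()
        assert (direction_series(np.arange(10.0)) == "away").all()

    def test_plateau_inherits_previous_label(self):
        d = np.array([5.0, 4.0, 4.0, 4.0, 6.0])
        labels = direction_series(d)
        assert list(labels[:3]) == ["toward", "toward", "toward"]
        assert labels[3] == "away"

    def test_first_step_defaults_away_on_tie(self):
        labels = direction_series(np.array([1.0, 1.0, 0.5]))
        assert labels[0] == "away"


class TestFreeSpace:
    def test_containing_sphere_radius_returned(self):
        tunnel = TunnelProfile(spheres={0: [[0, 0, 0, 2.0]]})
        traj = LigandTrajectory(positions=np.array([[0.5, 0, 0]]))
        r, outside = free_space_from_tunnel(tunnel, traj, 0)
        assert r == 2.0 and not outside

    def test_nearest_center_wins_among_containing(self):
        tunnel = TunnelProfile(
            spheres={0: [[0.3, 0, 0, 1.5], [0.9, 0, 0, 3.0]]}
        )
        traj = LigandTrajectory(positions=np.array([[0.0, 0, 0]]))
        r, outside = free_space_from_tunnel(tunnel, traj, 0)
        assert r == 1.5 and not outside

    def test_outside_tunnel_falls_back_to_nearest(self):
        tunnel = TunnelProfile(spheres={0: [[5.0, 0, 0, 1.0]]})
        traj = LigandTrajectory(positions=np.array([[0.0, 0, 0]]))
        r, outside = free_space_from_tunnel(tunnel, traj, 0)
        assert r == 1.0 and outside


class TestTemporalTunnel:
    def test_symmetric_shell_centers_on_ligand(self):
        # 5 antipodal pairs on a radius-3 sphere: mean is exactly the center
        rng = np.random.default_rng(8)
        dirs = rng.normal(size=(5, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        atoms = np.concatenate([3 * dirs, -3 * dirs])
        frames = make_frames(atoms)
        traj = LigandTrajectory(positions=np.zeros((1, 3)))
        tunnel = temporal_tunnel(frames, traj)
        sphere = tunnel.spheres[0][0]
        np.testing.assert_allclose(sphere[:3], 0.0, atol=1e-12)
        assert sphere[3] == pytest.approx(3.0)

    def test_extra_atom_shifts_center_brute_force(self):
        rng = np.random.default_rng(8)
        dirs = rng.normal(size=(5, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        atoms = np.concatenate([3 * dirs, -3 * dirs, [[1.0, 0, 0]]])
        frames = make_frames(atoms)
        traj = LigandTrajectory(positions=np.zeros((1, 3)))
        sphere = temporal_tunnel(frames, traj).spheres[0][0]
        d = np.linalg.norm(atoms - traj.positions[0], axis=1)
        ten = atoms[np.argsort(d, kind="stable")[:10]]
        center = ten.mean(axis=0)
        radius = np.linalg.norm(atoms - center, axis=1).min()
        np.testing.assert_allclose(sphere[:3], center, atol=1e-9)
        assert sphere[3] == pytest.approx(radius, abs=1e-9)

    def test_random_shell_radius_is_exhaustive_minimum(self):
        rng = np.random.default_rng(5)
        atoms = rng.normal(size=(1000, 3)) * 8
        coords = np.repeat(atoms[None], 3, axis=0) + rng.normal(
            scale=0.1, size=(3, 1000, 3)
        )
        frames = make_frames(
            atoms, n_frames=3,
            res_ids=np.repeat(np.arange(1, 501), 2),
            res_names=np.array(["ALA"] * 1000),
        )
        frames.coords = coords
        traj = LigandTrajectory(positions=rng.normal(size=(3, 3)))
        tunnel = temporal_tunnel(frames, traj)
        for x in range(3):
            center = tunnel.spheres[x][0][:3]
            radius = tunnel.spheres[x][0][3]
            brute = min(
                float(np.linalg.norm(coords[x, i] - center)) for i in range(1000)
            )
            assert radius == pytest.approx(brute, abs=1e-9)
            # radius never exceeds distance to any atom
            assert (np.linalg.norm(coords[x] - center, axis=1) >= radius - 1e-12).all()

    def test_too_few_atoms_rejected(self):
        frames = make_frames(np.zeros((4, 3)))
        traj = LigandTrajectory(positions=np.zeros((1, 3)))
        with pytest.raises(ValidationError):
            temporal_tunnel(frames, traj)


class TestLiningResidues:
    def test_surface_distance_arithmetic(self):
        # centre distance 3.0, radii 1.7 (C) + 1.2 (H) => 0.1
        frames = make_frames([[3.0, 0, 0]])
        lig = np.array([[0.0, 0, 0]])
        pairs = lining_residues(
            frames, lig, 0, k=3, ligand_elements=np.array(["H"])
        )
        assert pairs[0][0] == "A:1"
        assert pairs[0][1] == pytest.approx(0.1)

    def test_fewer_residues_than_k(self):
        frames = make_frames([[1.0, 0, 0], [2.0, 0, 0]], res_ids=np.array([1, 2]))
        pairs = lining_residues(frames, np.zeros((1, 3)), 0, k=3)
        assert len(pairs) == 2

    def test_matches_exhaustive_scan(self, small_scenario):
        frames = small_scenario["frames"]
        traj = small_scenario["traj"]
        labels = frames.residue_labels()
        radii = frames.vdw_radii
        for x in (0, 40, 80, 119):
            lig = traj.ligand_atoms(x)
            got = lining_residues(
                frames, lig, x, k=3, ligand_elements=traj.atom_elements
            )
            per_res = {}
            for i in range(frames.n_atoms):
                for j in range(len(lig)):
                    d = np.linalg.norm(frames.coords[x, i] - lig[j])
                    sd = max(0.0, d - radii[i] - 1.7)  # ligand C radius
                    lab = labels[i]
                    per_res[lab] = min(per_res.get(lab, np.inf), sd)
            expected = sorted(per_res.items(), key=lambda kv: (kv[1], kv[0]))[:3]
            assert [g[0] for g in got] == [e[0] for e in expected]
            np.testing.assert_allclose(
                [g[1] for g in got], [e[1] for e in expected], atol=1e-9
            )


class TestProfiles:
    def test_single_ile_gives_kd_value(self):
        frames = make_frames([[2.0, 0, 0]], res_names=np.array(["ILE"]))
        val = hydrophobicity_profile(frames, np.zeros((1, 3)), 0, cutoff=2.0)
        assert val == pytest.approx(4.5)

    def test_empty_lining_set_is_missing(self):
        frames = make_frames([[50.0, 0, 0]])
        val = hydrophobicity_profile(frames, np.zeros((1, 3)), 0, cutoff=2.0)
        assert np.isnan(val)

    def test_mean_of_two_residues(self):
        frames = make_frames(
            [[2.0, 0, 0], [-2.0, 0, 0]],
            res_names=np.array(["ILE", "ARG"]),
            res_ids=np.array([1, 2]),
        )
        val = hydrophobicity_profile(frames, np.zeros((1, 3)), 0, cutoff=2.0)
        assert val == pytest.approx((4.5 - 4.5) / 2)

    def test_charge_symmetry_cancels(self):
        frames = make_frames(
            [[2.0, 0, 0], [-2.0, 0, 0]],
            res_ids=np.array([1, 2]),
            charges=np.array([0.5, -0.5]),
        )
        assert charge_profile(frames, np.zeros((1, 3)), 0) == pytest.approx(0.0)

    def test_charge_out_of_range_is_missing(self):
        frames = make_frames([[50.0, 0, 0]], charges=np.array([0.5]))
        assert np.isnan(charge_profile(frames, np.zeros((1, 3)), 0))

    def test_charge_requires_charges(self):
        frames = make_frames([[2.0, 0, 0]])
        with pytest.raises(ValidationError):
            charge_profile(frames, np.zeros((1, 3)), 0)

    def test_charge_matches_exhaustive_scan(self, small_scenario):
        frames = small_scenario["frames"]
        traj = small_scenario["traj"]
        radii = frames.vdw_radii
        for x in (60, 90, 110):
            lig = traj.ligand_atoms(x)
            sel = []
            for i in range(frames.n_atoms):
                d = min(
                    np.linalg.norm(frames.coords[x, i] - lig[j])
                    for j in range(len(lig))
                )
                if d - radii[i] - 1.7 <= 2.0:
                    sel.append(frames.charges[i])
            got = charge_profile(
                frames, lig, x, cutoff=2.0, ligand_elements=traj.atom_elements
            )
            if sel:
                assert got == pytest.approx(float(np.mean(sel)), abs=1e-12)
            else:
                assert np.isnan(got)


class TestSpeedAndTurnover:
    def test_stationary_and_unit_step(self):
        still = LigandTrajectory(positions=np.zeros((5, 3)))
        np.testing.assert_allclose(speed_series(still, 2.0), 0.0)
        moving = LigandTrajectory(
            positions=np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        )
        np.testing.assert_allclose(speed_series(moving, 2.0), 0.5)

    def test_path_length_conservation(self):
        rng = np.random.default_rng(21)
        traj = LigandTrajectory(positions=np.cumsum(rng.normal(size=(100, 3)), axis=0))
        dt = 2.0
        speeds = speed_series(traj, dt)
        path = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1).sum()
        assert speeds[:-1].sum() * dt == pytest.approx(path, abs=1e-9)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"A", "B", "C"}, {"A", "B", "C"}, 0),
            ({"A", "B", "C"}, {"A", "B", "D"}, 2),
            ({"A", "B", "C"}, {"D", "E", "F"}, 6),
        ],
    )
    def test_turnover_symmetric_difference(self, a, b, expected):
        assert residue_turnover(a, b) == expected

    def test_turnover_accepts_distance_pairs(self):
        assert residue_turnover([("A:1", 0.2)], [("A:2", 0.1)]) == 2


class TestClassification:
    def test_ligand_at_site_is_active_site(self):
        frames = make_frames([[0.0, 0, 0]], n_frames=1)
        spec = ActiveSiteSpec(residues=[("A", 1)])
        traj = LigandTrajectory(positions=np.array([[0.5, 0, 0]]))
        assert classify_position(frames, traj, spec, x=0) == "active-site"

    def test_far_ligand_is_outside(self):
        frames = make_frames([[0.0, 0, 0]], n_frames=1)
        spec = ActiveSiteSpec(residues=[("A", 1)])
        traj = LigandTrajectory(positions=np.array([[100.0, 0, 0]]))
        assert classify_position(frames, traj, spec, x=0) == "outside"

    def test_phase_recovery_on_default_scenario(self, default_scenario):
        truth = default_scenario["truth"]
        cats = classify_position(
            default_scenario["frames"],
            default_scenario["traj"],
            default_scenario["site"],
        )
        expected = np.array([PHASE_TO_CATEGORY[l] for l in truth.labels], dtype=object)
        assert (cats == expected).mean() >= 0.90


class TestSlidingWindowAndBars:
    def test_window_one_is_identity(self):
        s = np.array([1.0, 5.0, 2.0])
        np.testing.assert_array_equal(sliding_window(s, 1), s)

    def test_constant_series_unchanged(self):
        np.testing.assert_allclose(sliding_window(np.full(10, 3.0), 5), 3.0)

    def test_ramp_interior_unchanged_ends_clipped(self):
        s = np.arange(11.0)
        out = sliding_window(s, 3)
        np.testing.assert_allclose(out[1:-1], s[1:-1])
        assert out[0] == pytest.approx(0.5)
        assert out[-1] == pytest.approx(9.5)

    def test_missing_values_excluded(self):
        s = np.array([1.0, np.nan, 3.0])
        out = sliding_window(s, 3)
        assert out[1] == pytest.approx(2.0)
        assert np.isnan(sliding_window(np.full(5, np.nan), 3)).all()

    def test_bars_identity_when_bins_equal_steps(self):
        s = np.arange(10.0)
        bars = aggregate_bars(s, 10)
        np.testing.assert_allclose(bars["mean"], s)

    def test_bars_two_blocks(self):
        s = np.concatenate([np.full(10, 1.0), np.full(10, 3.0)])
        bars = aggregate_bars(s, 2)
        np.testing.assert_allclose(bars["mean"], [1.0, 3.0])

    def test_remainder_spread_over_leading_bins(self):
        bars = aggregate_bars(np.arange(7.0), 2)
        sizes = (bars["end"] - bars["start"]).tolist()
        assert sizes == [4, 3]

    def test_more_bins_than_steps(self):
        bars = aggregate_bars(np.arange(3.0), 5)
        assert len(bars) == 3

    def test_modal_category_priority_tie_break(self):
        s = np.zeros(4)
        cats = ["surface", "surface", "active-site", "active-site"]
        bars = aggregate_bars(s, 1, categories=cats)
        assert bars["category"][0] == "active-site"
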