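"""Landscape, oracle, dynamics, steering, seeding and embedding checks."""

import numpy as np
import pytest

from allostate import toydyn as td
from allostate import (boltzmann_macrostate_probs, builtin_presets,
                       default_macrostate_centres, extract_seeds,
                       generate_seeded_pool, potential_energy,
                       simulate_feature_trajectory, simulate_steering)
from allostate.toydyn import (FeatureScaling, FeatureTrajectory,
                              GeneratorPreset, StateCentres, SteeringSpec)

from conftest import batch_means_se


def _isolated_well_preset(depth=3.0):
    return GeneratorPreset(
        name="iso", well_centres=[[0.0, 0.0]], well_depths=[depth],
        well_widths=[[1.0, 1.0]], box_centre=[0.0, 0.0],
        box_half_widths=[10.0, 10.0], wall_stiffness=[5.0, 5.0],
        diffusion=[0.01, 0.01])


class TestPotential:
    def test_energy_at_well_centre_is_minus_depth(self):
        p = _isolated_well_preset(depth=3.0)
        assert potential_energy([0.0, 0.0], p) == pytest.approx(-3.0, abs=1e-12)

    def test_zero_depths_give_zero_inside_box(self):
        p = GeneratorPreset(name="flat", well_centres=[[0.0]],
                            well_depths=[0.0], well_widths=[[1.0]],
                            box_centre=[0.0], box_half_widths=[5.0],
                            wall_stiffness=[1.0], diffusion=[0.01])
        assert potential_energy([3.0], p) == 0.0

    def test_wall_grows_quadratically_outside_box(self):
        p = _isolated_well_preset(depth=0.0)
        u1 = potential_energy([11.0, 0.0], p)   # 1 unit outside
        u2 = potential_energy([12.0, 0.0], p)   # 2 units outside
        assert u1 == pytest.approx(0.5 * 5.0 * 1.0)
        assert u2 == pytest.approx(0.5 * 5.0 * 4.0)

    def test_matches_term_by_term_reimplementation(self):
        rng = np.random.default_rng(3)
        p = builtin_presets()["apo"]
        for _ in range(20):
            x = rng.uniform(p.box_centre - 1.5 * p.box_half_widths,
                            p.box_centre + 1.5 * p.box_half_widths)
            u = 0.0
            for m in range(p.n_wells):
                s = sum((x[d] - p.well_centres[m, d]) ** 2
                        / (2 * p.well_widths[m, d] ** 2)
                        for d in range(p.dim))
                u -= p.well_depths[m] * np.exp(-s)
            for d in range(p.dim):
                exc = abs(x[d] - p.box_centre[d]) - p.box_half_widths[d]
                if exc > 0:
                    u += 0.5 * p.wall_stiffness[d] * exc ** 2
            assert potential_energy(x, p) == pytest.approx(u, rel=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            potential_energy([1.0], _isolated_well_preset())

    def test_gradient_matches_finite_differences(self):
        p = builtin_presets()["agonist"]
        rng = np.random.default_rng(5)
        x = rng.uniform(p.box_centre - p.box_half_widths,
                        p.box_centre + p.box_half_widths, size=(4, 3))
        g = td._gradient_batch(x, p)
        eps = 1e-6
        for i in range(4):
            for d in range(3):
                xp, xm = x[i].copy(), x[i].copy()
                xp[d] += eps
                xm[d] -= eps
                fd = (potential_energy(xp, p) - potential_energy(xm, p)) / (2 * eps)
                assert g[i, d] == pytest.approx(fd, rel=1e-5, abs=1e-7)


class TestBoltzmannOracle:
    def test_mirror_symmetric_wells_split_evenly(self, shallow_double_well):
        part = StateCentres(names=("left", "right"),
                            centres=[[-1.0], [1.0]],
                            scaling=FeatureScaling([0.0], [1.0]))
        probs = boltzmann_macrostate_probs(shallow_double_well, part,
                                           grid_resolution=200)
        assert probs["left"] == pytest.approx(0.5, abs=1e-9)
        assert probs["right"] == pytest.approx(0.5, abs=1e-9)

    def test_single_deep_well_dominates(self):
        p = GeneratorPreset(
            name="deep", well_centres=[[-1.0], [1.0]],
            well_depths=[10.0, 0.0], well_widths=[[0.3], [0.3]],
            box_centre=[0.0], box_half_widths=[2.0],
            wall_stiffness=[25.0], diffusion=[0.01])
        part = StateCentres(names=("deep", "empty"), centres=[[-1.0], [1.0]],
                            scaling=FeatureScaling([0.0], [1.0]))
        p1 = boltzmann_macrostate_probs(p, part, grid_resolution=100)
        p2 = boltzmann_macrostate_probs(p, part, grid_resolution=200)
        assert p1["deep"] > 0.99
        assert abs(p1["deep"] - p2["deep"]) < 1e-3

    def test_two_kt_depth_difference_gives_exp2_ratio(self):
        p = GeneratorPreset(
            name="asym", well_centres=[[-1.0], [1.0]],
            well_depths=[12.0, 10.0], well_widths=[[0.15], [0.15]],
            box_centre=[0.0], box_half_widths=[1.6],
            wall_stiffness=[400.0], diffusion=[0.01])
        part = StateCentres(names=("a", "b"), centres=[[-1.0], [1.0]],
                            scaling=FeatureScaling([0.0], [1.0]))
        probs = boltzmann_macrostate_probs(p, part, grid_resolution=400)
        # independent 1-D quadrature oracle
        x = np.linspace(-2.0, 2.0, 40001)
        u = (-12.0 * np.exp(-(x + 1) ** 2 / (2 * 0.15 ** 2))
             - 10.0 * np.exp(-(x - 1) ** 2 / (2 * 0.15 ** 2))
             + 0.5 * 400.0 * np.maximum(np.abs(x) - 1.6, 0.0) ** 2)
        w = np.exp(-u)
        ratio_oracle = w[x < 0].sum() / w[x >= 0].sum()
        assert probs["a"] / probs["b"] == pytest.approx(ratio_oracle, rel=2e-3)
        # deep equal-width wells: ratio ≈ exp(ΔU) = e² up to the Laplace
        # √(A_b/A_a) width factor (≈ 0.91 here)
        assert probs["a"] / probs["b"] == pytest.approx(np.exp(2.0), rel=0.12)

    def test_grid_refinement_converges_for_shipped_presets(self):
        for name, p in builtin_presets().items():
            part = default_macrostate_centres(p)
            a = boltzmann_macrostate_probs(p, part, grid_resolution=100)
            b = boltzmann_macrostate_probs(p, part, grid_resolution=200)
            for k in a:
                assert abs(a[k] - b[k]) < 1e-3, name
            assert sum(b.values()) == pytest.approx(1.0, abs=1e-9)

    def test_centre_outside_box_raises(self, shallow_double_well):
        part = StateCentres(names=("a", "b"), centres=[[-5.0], [1.0]],
                            scaling=FeatureScaling([0.0], [1.0]))
        with pytest.raises(ValueError):
            boltzmann_macrostate_probs(shallow_double_well, part)

    def test_active_state_ordering_of_shipped_presets(self):
        active = {}
        for name, p in builtin_presets().items():
            probs = boltzmann_macrostate_probs(
                p, default_macrostate_centres(p), grid_resolution=120)
            active[name] = probs["active"]
        assert active["apo"] < active["partial"] < active["agonist"] \
            <= active["partial-restrained"]


class TestDynamics:
    def test_zero_diffusion_keeps_start(self):
        p = _isolated_well_preset()
        p = td.GeneratorPreset(
            name="frozen", well_centres=p.well_centres,
            well_depths=p.well_depths, well_widths=p.well_widths,
            box_centre=p.box_centre, box_half_widths=p.box_half_widths,
            wall_stiffness=p.wall_stiffness, diffusion=[0.0, 0.0])
        t = simulate_feature_trajectory(p, [0.0, 0.0], n_steps=50,
                                        save_stride=5, seed=1)
        assert t.n_frames == 10
        assert np.all(t.frames == 0.0)

    def test_same_seed_bitwise_identical(self, shallow_double_well):
        a = simulate_feature_trajectory(shallow_double_well, [-1.0], 500,
                                        save_stride=2, seed=42)
        b = simulate_feature_trajectory(shallow_double_well, [-1.0], 500,
                                        save_stride=2, seed=42)
        c = simulate_feature_trajectory(shallow_double_well, [-1.0], 500,
                                        save_stride=2, seed=43)
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_start_outside_box_rejected(self, shallow_double_well):
        with pytest.raises(ValueError):
            simulate_feature_trajectory(shallow_double_well, [5.0], 10)

    def test_occupancy_matches_oracle_within_three_se(self, shallow_double_well):
        """Detailed balance of the integrator: long-run occupancy of a
        double well agrees with exact quadrature within 3 batch-means SE."""
        p = shallow_double_well
        part = StateCentres(names=("left", "right"), centres=[[-1.0], [1.0]],
                            scaling=FeatureScaling([0.0], [1.0]))
        oracle = boltzmann_macrostate_probs(p, part, grid_resolution=300)
        t = simulate_feature_trajectory(p, [-1.0], n_steps=400_000,
                                        save_stride=4, seed=11)
        ind = (t.frames[:, 0] < 0).astype(float)
        se = batch_means_se(ind)
        assert abs(ind.mean() - oracle["left"]) < 3 * max(se, 1e-4)

    def test_pool_matches_single_trajectory_streams(self, shallow_double_well):
        """Batch integration reproduces per-trajectory streams bit-for-bit,
        so pools are order-independent."""
        seeds = [(0, np.array([-1.0])), (1, np.array([1.0])),
                 (2, np.array([0.0]))]
        pool = generate_seeded_pool(shallow_double_well, seeds, traj_len=200,
                                    save_stride=2, seed=5)
        # trajectory 1 re-simulated alone from its own derived stream
        solo = td._integrate_batch(shallow_double_well,
                                   np.array([[1.0]]), [td._rng_for(5, 1)],
                                   200, 2)[0]
        assert np.array_equal(pool[1].frames, solo)


class TestSteering:
    def test_stiff_restraint_tracks_centre(self):
        p = builtin_presets()["apo"]
        scaling = FeatureScaling.from_preset(p)
        errs = []
        for k in (100.0, 1000.0, 10_000.0):
            spec = SteeringSpec(waypoints=p.well_centres,
                                restraint_constant=k, steps_per_leg=1000)
            traj = simulate_steering(p, spec, seed=2)
            wps = scaling.scale(p.well_centres)
            n = traj.n_frames
            dev = []
            for i, x in enumerate(traj.frames):
                prog = (i + 1) / 1000
                leg = min(int(prog), len(wps) - 2)
                frac = prog - leg
                centre = wps[leg] + frac * (wps[leg + 1] - wps[leg])
                dev.append(np.linalg.norm(scaling.scale(x) - centre))
            errs.append(max(dev))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 0.05

    @pytest.mark.parametrize("reverse", [False, True])
    def test_endpoint_reaches_target_state(self, reverse):
        p = builtin_presets()["apo"]
        wps = p.well_centres[::-1] if reverse else p.well_centres
        spec = SteeringSpec(waypoints=wps, steps_per_leg=1500)
        traj = simulate_steering(p, spec, seed=3)
        assert traj.provenance == "steered"
        part = default_macrostate_centres(p)
        label = part.assign(traj.frames[-1][None])[0]
        assert part.names[label] == ("inactive" if reverse else "active")


class TestSeeds:
    def _steered(self, steps=1500):
        p = builtin_presets()["apo"]
        spec = SteeringSpec(waypoints=p.well_centres, steps_per_leg=steps)
        return p, simulate_steering(p, spec, seed=4)

    def test_hundred_seeds_extracted(self):
        p, traj = self._steered()
        seeds = extract_seeds(traj, 100, FeatureScaling.from_preset(p))
        idx = [i for i, _ in seeds]
        assert len(seeds) == 100
        assert idx[0] == 0 and idx[-1] == traj.n_frames - 1
        assert all(b > a for a, b in zip(idx, idx[1:]))

    def test_constant_speed_path_gives_uniform_spacing(self):
        frames = np.linspace([0.0, 0.0], [10.0, 0.0], 101)
        traj = FeatureTrajectory(frames, feature_names=("a", "b"),
                                 units=("u", "u"))
        seeds = extract_seeds(traj, 11, FeatureScaling.identity(2))
        assert [i for i, _ in seeds] == list(range(0, 101, 10))

    def test_fast_slow_path_matches_bisection_oracle(self):
        import bisect

        # fast leg (step 1.0) then slow leg (step 0.1)
        xs = np.concatenate([np.arange(0, 50, 1.0),
                             np.arange(50, 55, 0.1)])
        traj = FeatureTrajectory(xs[:, None], feature_names=("x",),
                                 units=("u",))
        scaling = FeatureScaling.identity(1)
        seeds = extract_seeds(traj, 12, scaling)
        arc = np.concatenate([[0], np.cumsum(np.abs(np.diff(xs)))])
        for j, (i, _) in enumerate(seeds):
            target = arc[-1] * j / 11
            k = bisect.bisect_left(arc, target)
            cand = [c for c in (k - 1, k, k + 1) if 0 <= c < len(arc)]
            best = min(cand, key=lambda c: abs(arc[c] - target))
            assert abs(arc[i] - arc[best]) <= 1e-12 or abs(i - best) <= 1

    def test_degenerate_path_falls_back_uniform(self):
        traj = FeatureTrajectory(np.zeros((50, 2)), feature_names=("a", "b"),
                                 units=("u", "u"))
        with pytest.warns(UserWarning, match="degenerate"):
            seeds = extract_seeds(traj, 5, FeatureScaling.identity(2))
        assert [i for i, _ in seeds] == [0, 12, 24, 37, 49]


class TestSeededPool:
    def test_pool_size_and_frame_contract(self, shallow_double_well):
        seeds = [np.array([x]) for x in np.linspace(-1, 1, 20)]
        pool = generate_seeded_pool(shallow_double_well, seeds, traj_len=250,
                                    save_stride=5, seed=9)
        assert len(pool) == 20
        assert all(t.n_frames == 50 for t in pool)
        assert all(t.provenance == "seeded" for t in pool)
        assert [t.seed_index for t in pool] == list(range(20))

    def test_deep_single_well_concentrates_occupancy(self):
        p = GeneratorPreset(
            name="deep1", well_centres=[[-1.0], [1.0]],
            well_depths=[8.0, 0.0], well_widths=[[0.35], [0.35]],
            box_centre=[0.0], box_half_widths=[2.0],
            wall_stiffness=[25.0], diffusion=[0.01])
        seeds = [np.array([x]) for x in np.linspace(-1.8, 1.8, 30)]
        pool = generate_seeded_pool(p, seeds, traj_len=4000, save_stride=4,
                                    seed=13)
        kept = np.concatenate([t.frames[t.n_frames // 10:, 0] for t in pool])
        assert (kept < 0).mean() > 0.95


class TestEmbedding:
    def test_round_trip_of_reference_feature_point(self, toy_setup):
        from allostate.featurize import featurize_frame
        from allostate.toydyn import embed_structure

        toy, regions, refs = toy_setup
        got = featurize_frame(embed_structure((60.0, 2.0, 2.5), toy),
                              regions, refs)
        assert np.allclose(got, [60.0, 2.0, 2.5], atol=1e-6)

    def test_zero_displacement_matches_reference(self, toy_setup):
        from allostate.featurize import featurize_frame
        from allostate.toydyn import embed_structure

        toy, regions, refs = toy_setup
        frame = embed_structure((30.0, 0.0, 0.0), toy)
        assert np.allclose(frame.coords, refs.inactive.coords)
        got = featurize_frame(frame, regions, refs)
        assert got[1] == pytest.approx(0.0, abs=1e-12)
        assert got[2] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_angles_rejected(self, toy_setup):
        from allostate.toydyn import embed_structure

        toy, _, _ = toy_setup
        for bad in ((0.0, 1.0, 1.0), (180.0, 1.0, 1.0), (30.0, -0.1, 0.0)):
            with pytest.raises(ValueError):
                embed_structure(bad, toy)


class TestTsvRoundTrip:
    def test_feature_tsv_round_trip(self, tmp_path, shallow_double_well):
        t = simulate_feature_trajectory(shallow_double_well, [-1.0], 100,
                                        save_stride=2, seed=1)
        path = tmp_path / "t.tsv"
        t.to_tsv(path)
        back = FeatureTrajectory.from_tsv(path)
        assert back.feature_names == t.feature_names
        assert back.provenance == t.provenance
        assert back.frame_spacing == t.frame_spacing
        assert np.allclose(back.frames, t.frames, atol=1e-9)

    def test_preset_toml_loading(self, tmp_path):
        cfg = tmp_path / "p.toml"
        cfg.write_text(
            "[preset]\nname = \"custom\"\nwell_depths = [1.0, 2.0, 3.0]\n"
            "timestep = 0.5\n")
        p = td.load_preset(cfg)
        assert p.name == "custom"
        assert np.allclose(p.well_depths, [1, 2, 3])
        assert p.timestep == 0.5
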