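import numpy as np
import pytest
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from furrowsim.force_schedule import (
    Keyframes,
    ScheduleParams,
    build_schedule,
)
from furrowsim.geometry import shoelace_batch
from furrowsim.solver import (
    Simulator,
    SolverConfig,
    SolverError,
    damping_matrix,
    enforce_incompressibility,
    vitelline_contact,
    yolk_pressure,
)

TRI = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])


def zero_schedule(duration=5.0):
    z = Keyframes(times=(0.0, duration), values=(0.0, 0.0))
    return build_schedule(
        "wildtype",
        ScheduleParams(duration=duration, apical=z, lateral=z, basal=z),
    )


class TestViscousOperator:
    def test_free_triangle_follows_overdamped_closed_form(self):
        """A rigidly translating triangle under constant force moves at
        x(t) = x0 + (f/mu) t when each node carries drag mu."""
        mu, f, dt, steps = 2.0, np.array([0.3, -0.1]), 0.05, 40
        x = TRI.copy()
        tris = np.array([[0, 1, 2]])
        for _ in range(steps):
            C = damping_matrix(x, tris, mu) + mu * sp.identity(6)
            rhs = np.concatenate([np.full(3, f[0]), np.full(3, f[1])])
            v = spla.spsolve(C.tocsc(), rhs)
            x = x + dt * np.stack([v[:3], v[3:]], axis=1)
        expected = TRI + (f / mu) * (dt * steps)
        np.testing.assert_allclose(x, expected, rtol=1e-9, atol=1e-12)

    def test_rigid_translation_undamped_by_strain_rate_operator(self):
        C = damping_matrix(TRI, np.array([[0, 1, 2]]), 1.0)
        v_rigid = np.concatenate([np.ones(3), np.zeros(3)])
        assert np.abs(C @ v_rigid).max() < 1e-12

    def test_inverted_element_raises_without_floor(self):
        bad = TRI[::-1]  # clockwise = negative area
        with pytest.raises(SolverError, match="inverted"):
            damping_matrix(bad, np.array([[0, 1, 2]]), 1.0)


class TestYolkPressure:
    cfg = SolverConfig()

    def test_reference_state(self):
        assert yolk_pressure(100.0, 100.0, self.cfg, 0.4) == pytest.approx(0.4)

    def test_cap_at_ten_percent(self):
        # far below reference: exactly the +10% cap
        assert yolk_pressure(1.0, 100.0, self.cfg, 0.4) == pytest.approx(
            0.4 * 1.10, rel=1e-12
        )
        assert yolk_pressure(1e4, 100.0, self.cfg, 0.4) == pytest.approx(
            0.4 * 0.90, rel=1e-12
        )

    def test_linear_region_closed_form(self):
        A0, A = 100.0, 99.0
        k = self.cfg.pressure_gain
        expected = 0.4 * (1.0 + k * (A0 - A) / A0)
        assert yolk_pressure(A, A0, self.cfg, 0.4) == pytest.approx(
            expected, rel=1e-15
        )

    def test_monotone_non_increasing_in_area(self):
        areas = np.linspace(80, 120, 41)
        p = [yolk_pressure(a, 100.0, self.cfg, 0.4) for a in areas]
        assert np.all(np.diff(p) <= 0)


class TestVitellineContact:
    def test_interior_nodes_unchanged(self, rng):
        x = rng.uniform(-0.5, 0.5, (50, 2))
        np.testing.assert_array_equal(vitelline_contact(x, 1.0), x)

    def test_radial_projection_preserves_angle(self):
        x = np.array([[1.05 * np.cos(0.7), 1.05 * np.sin(0.7)]])
        out = vitelline_contact(x, 1.0)
        assert np.linalg.norm(out[0]) == pytest.approx(1.0, rel=1e-14)
        assert np.arctan2(out[0, 1], out[0, 0]) == pytest.approx(0.7)

    def test_tangential_slide_matches_first_order_arc(self, small_mesh,
                                                      small_labels):
        """A contacting node pushed tangentially slides along the circle;
        the arc length agrees with the unconstrained displacement to first
        order in dt."""
        sim = Simulator(small_mesh, small_labels, zero_schedule(),
                        SolverConfig(pressure_p0=0.0))
        x = small_mesh.nodes
        i = int(small_mesh.ray_ids[0, -1])  # apical node on the circle
        r0 = np.linalg.norm(x[i])
        u_t = np.array([-x[i, 1], x[i, 0]]) / r0
        F = np.zeros_like(x)
        F[i] = 0.5 * u_t
        v = sim.velocities(x, F)
        for dt in (1e-2, 1e-3):
            moved = vitelline_contact(x + dt * v, small_mesh.vitelline_radius)
            arc = r0 * abs(
                np.arctan2(moved[i, 1], moved[i, 0])
                - np.arctan2(x[i, 1], x[i, 0])
            )
            free = dt * abs(v[i] @ u_t)
            assert arc == pytest.approx(free, rel=5e-3 + dt)


class TestIncompressibility:
    def test_satisfied_state_is_fixed_point(self, small_mesh):
        ref = small_mesh.cell_areas()
        out = enforce_incompressibility(small_mesh, small_mesh.nodes, ref)
        np.testing.assert_array_equal(out, small_mesh.nodes)

    def test_uniform_scaling_restored(self, small_mesh):
        ref = small_mesh.cell_areas()
        scaled = small_mesh.nodes * np.sqrt(1.1)  # areas x1.1
        out = enforce_incompressibility(small_mesh, scaled, ref, tol=1e-8)
        areas = shoelace_batch(out[small_mesh.loops])
        np.testing.assert_allclose(areas, ref, rtol=1e-7)

    def test_random_perturbation_restored_against_shoelace_oracle(
        self, small_mesh, rng
    ):
        ref = small_mesh.cell_areas()
        x = small_mesh.nodes + rng.normal(0, 0.01, small_mesh.nodes.shape)
        out = enforce_incompressibility(small_mesh, x, ref, tol=1e-8)
        # independent shoelace recomputation, vertex by vertex
        for k in range(0, small_mesh.n_cells, 7):
            poly = out[small_mesh.loops[k]]
            s = 0.0
            for i in range(len(poly)):
                x0, y0 = poly[i]
                x1, y1 = poly[(i + 1) % len(poly)]
                s += x0 * y1 - x1 * y0
            assert 0.5 * s == pytest.approx(ref[k], rel=1e-6)


class TestStep:
    def test_zero_forces_zero_pressure_is_stationary(self, small_mesh,
                                                     small_labels):
        sim = Simulator(small_mesh, small_labels, zero_schedule(),
                        SolverConfig(pressure_p0=0.0))
        state = sim.initial_state()
        out = sim.step(state)
        assert np.abs(out.positions - state.positions).max() < 1e-12

    def test_balanced_pressurized_start_barely_moves(self, small_mesh,
                                                     small_labels):
        # with the wall carrying the pressure surplus, the initial state is
        # quasi-static: one step moves nodes far less than a force-free scale
        sim = Simulator(small_mesh, small_labels, build_schedule("wildtype"),
                        SolverConfig())
        out = sim.step(sim.initial_state())
        assert np.abs(out.positions - small_mesh.nodes).max() < 5e-3

    def test_mirror_symmetry_preserved(self, small_mesh, small_labels):
        sim = Simulator(small_mesh, small_labels, build_schedule("wildtype"),
                        SolverConfig())
        tree = cKDTree(small_mesh.nodes)
        _, mirror = tree.query(small_mesh.nodes * [-1, 1], k=1)
        state = sim.initial_state()
        for _ in range(100):
            state = sim.step(state)
        x = state.positions
        assert np.abs(x * [-1, 1] - x[mirror]).max() < 1e-6


class TestRun:
    def test_deterministic(self, small_mesh, small_labels):
        cfg = SolverConfig(dt=0.02)
        sched = build_schedule("wildtype")
        a = Simulator(small_mesh, small_labels, sched, cfg).run(duration=2.0)
        b = Simulator(small_mesh, small_labels, sched, cfg).run(duration=2.0)
        np.testing.assert_array_equal(
            a.states[-1].positions, b.states[-1].positions
        )

    def test_area_conservation_throughout(self, small_mesh, small_labels):
        sim = Simulator(small_mesh, small_labels, build_schedule("wildtype"),
                        SolverConfig())
        traj = sim.run(duration=6.0)
        ref = sim.reference_areas
        worst = max(
            np.max(np.abs(s.cell_areas - ref) / ref) for s in traj.states
        )
        assert worst <= 1e-4

    def test_no_vitelline_penetration(self, small_mesh, small_labels):
        sim = Simulator(small_mesh, small_labels, build_schedule("wildtype"),
                        SolverConfig())
        traj = sim.run(duration=6.0)
        R = small_mesh.vitelline_radius
        for s in traj.states:
            assert np.linalg.norm(s.positions, axis=1).max() <= R + 1e-7

    def test_first_state_is_initial_mesh_and_times_increase(
        self, small_mesh, small_labels
    ):
        sim = Simulator(small_mesh, small_labels, build_schedule("wildtype"),
                        SolverConfig())
        traj = sim.run(duration=3.0)
        np.testing.assert_array_equal(traj.states[0].positions,
                                      small_mesh.nodes)
        assert np.all(np.diff(traj.times) > 0)

    def test_dt_refinement_first_order_consistency(self, small_mesh,
                                                   small_labels):
        sched = build_schedule("wildtype")
        final = {}
        for dt in (0.02, 0.01):
            cfg = SolverConfig(dt=dt)
            traj = Simulator(small_mesh, small_labels, sched, cfg).run(
                duration=6.0
            )
            final[dt] = traj.states[-1].positions
        rms = np.sqrt(np.mean((final[0.02] - final[0.01]) ** 2))
        assert rms / small_mesh.vitelline_radius < 0.01

    def test_monotone_response_to_apical_amplitude(self, small_mesh,
                                                   small_labels):
        """Scaling the apical drive up never shallows the final furrow."""
        from furrowsim.observables import invagination_depth

        depths = []
        for s in (0.5, 0.75, 1.0):
            p = ScheduleParams(
                apical=Keyframes(times=(0.0, 12.0, 21.0),
                                 values=(0.05 * s, s, s)),
            )
            sim = Simulator(small_mesh, small_labels,
                            build_schedule("wildtype", p),
                            SolverConfig(dt=0.02))
            traj = sim.run(duration=14.0)
            depths.append(invagination_depth(traj)["depth"].iloc[-1])
        assert depths[0] <= depths[1] + 1e-6 <= depths[2] + 2e-6
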