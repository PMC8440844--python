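"""Body-cover dynamics: parameter rules, stepping, collision, energy."""

import numpy as np
import pytest
from dataclasses import replace

from voxphys.posture import MuscleActivation, PostureState, posture_from_activations
from voxphys.tbcm import (
    TBCMState,
    linearized_frequencies,
    mechanical_energy,
    rules_update,
    step,
    zipper_collision,
)


class TestRulesUpdate:
    def test_identity_at_rest(self, params):
        """Zero strain + zero activation reproduces the reference parameters."""
        bc = params["body_cover"]
        post = PostureState(strain=0.0, length=bc["L0"], xi02=1e-3, gap_area=0.0)
        cfg = rules_update(post, params, a_TA=0.0)
        rho, L0, T0 = bc["rho_tissue"], bc["L0"], bc["T0"]
        m_cov = rho * L0 * T0 * bc["Dc0"]
        assert cfg.m_l == pytest.approx(bc["nodal"] * m_cov, rel=1e-12)
        assert cfg.m_b == pytest.approx(rho * L0 * T0 * bc["Db0"], rel=1e-12)
        # zero tissue stress at rest -> shear-only stiffness
        assert cfg.k_l == pytest.approx(
            2 * bc["mu_cover"] * L0 * bc["nodal"] * T0 / bc["Dc0"], rel=1e-12
        )

    def test_body_stiffness_nondecreasing_in_ta(self, params, mid_posture):
        ks = [rules_update(mid_posture, params, a_TA=a).k_b for a in np.linspace(0, 1, 11)]
        assert np.all(np.diff(ks) >= -1e-12)
        assert ks[-1] > ks[0]

    def test_cover_stiffness_grows_with_strain(self, params):
        posts = [
            posture_from_activations(MuscleActivation(0.5, 0.5, 0.0, a, 0.0), params)
            for a in (0.0, 0.5, 1.0)
        ]
        ks = [rules_update(p, params).k_l for p in posts]
        assert ks[2] > ks[0]

    def test_deterministic(self, params, mid_posture):
        c1 = rules_update(mid_posture, params, a_TA=0.5)
        c2 = rules_update(mid_posture, params, a_TA=0.5)
        assert c1 == c2

    def test_nonphysical_posture_rejected(self, params):
        bad = PostureState(strain=-0.3, length=-1e-3, xi02=0.0, gap_area=0.0)
        with pytest.raises(ValueError):
            rules_update(replace(bad, length=-1e-3), params)


class TestStep:
    def test_rest_equilibrium_persists(self, mid_config, mid_posture):
        """No driving, state at rest: unchanged over 1,000 steps."""
        state = TBCMState()
        dt = 1.0 / 44100.0
        for i in range(1000):
            state = step(state, mid_config, (0.0, 0.0), dt, posture=mid_posture, time_index=i)
        assert np.max(np.abs(state.x)) < 1e-12
        assert np.max(np.abs(state.v)) < 1e-12

    def test_free_oscillation_matches_linearized_eigenfrequency(self, params):
        """Small free decay oscillates at the lowest eigenfrequency (1% tol).

        Damping is disabled so the oracle is the undamped eigen-decomposition
        of the stiffness/mass matrices; amplitude is kept small so the cubic
        spring terms stay negligible.
        """
        from voxphys.params import merge_overrides

        p0 = merge_overrides(params, {"body_cover": {"zeta_l": 0.0, "zeta_u": 0.0, "zeta_b": 0.0}})
        post = posture_from_activations(MuscleActivation(0.5, 0.5, 0.0, 0.5, 0.5), p0)
        cfg = rules_update(post, p0, a_TA=0.5)
        open_posture = replace(post, xi02=5e-3)  # keep clear of collision
        fs = 44100.0
        # oracle: eigen-decomposition of the linearized stiffness/mass matrices
        K = np.array([
            [cfg.k_l + cfg.k_c, -cfg.k_c, -cfg.k_l],
            [-cfg.k_c, cfg.k_u + cfg.k_c, -cfg.k_u],
            [-cfg.k_l, -cfg.k_u, cfg.k_l + cfg.k_u + cfg.k_b],
        ])
        M = np.diag([cfg.m_l, cfg.m_u, cfg.m_b])
        w2, vecs = np.linalg.eig(np.linalg.solve(M, K))
        lowest = int(np.argmin(w2.real))
        f_oracle = float(np.sqrt(w2.real[lowest]) / (2 * np.pi))
        x0 = np.real(vecs[:, lowest])
        x0 = 1e-6 * x0 / np.max(np.abs(x0))
        state = TBCMState(x=x0, v=np.zeros(3))
        xs = []
        for i in range(int(0.25 * fs)):
            state = step(state, cfg, (0.0, 0.0), 1.0 / fs, posture=open_posture, time_index=i)
            xs.append(state.x[0])
        xs = np.asarray(xs)
        # dominant frequency from zero crossings of the in-phase mode
        sign_changes = np.flatnonzero(np.diff(np.sign(xs)) != 0)
        f_measured = fs / (2.0 * np.mean(np.diff(sign_changes)))
        assert f_measured == pytest.approx(f_oracle, rel=0.01)
        # and the helper agrees with the oracle decomposition
        assert np.min(np.abs(linearized_frequencies(cfg) - f_oracle)) < 1e-6 * f_oracle

    def test_collision_force_is_repulsive(self, mid_config, mid_posture):
        """A mass driven past the midline is pushed back outward."""
        deep = TBCMState(x=np.array([-2e-3, -2e-3, 0.0]), v=np.zeros(3))
        after = step(deep, mid_config, (0.0, 0.0), 1.0 / 44100.0, posture=mid_posture)
        assert after.v[0] > deep.v[0]  # outward (positive) acceleration
        assert after.contact

    def test_blowup_raises_with_index(self, mid_config, mid_posture):
        from voxphys.tbcm import NumericalBlowupError

        bad = TBCMState(x=np.array([np.nan, 0.0, 0.0]), v=np.zeros(3))
        with pytest.raises(NumericalBlowupError) as err:
            step(bad, mid_config, (0.0, 0.0), 1.0 / 44100.0, posture=mid_posture, time_index=17)
        assert err.value.index == 17

    def test_energy_nonincreasing_with_damping_no_driving(self, mid_config, mid_posture):
        state = TBCMState(x=np.array([2e-4, -1e-4, 5e-5]), v=np.zeros(3))
        open_posture = replace(mid_posture, xi02=5e-3)
        energies = [mechanical_energy(state, mid_config)]
        for i in range(2000):
            state = step(state, mid_config, (0.0, 0.0), 1.0 / 44100.0, posture=open_posture)
            energies.append(mechanical_energy(state, mid_config))
        energies = np.asarray(energies)
        diffs = np.diff(energies)
        # non-increasing at every step up to the explicit integrator's O(dt^2)
        # discretization error, and decaying overall
        assert np.all(diffs <= 1e-4 * energies[:-1])
        assert energies[-1] < 0.5 * energies[0]


class TestZipperCollision:
    def test_no_contact_when_clear_of_midline(self, mid_config, mid_posture):
        state = TBCMState(x=np.array([1e-3, 1e-3, 0.0]), v=np.zeros(3))
        open_posture = replace(mid_posture, xi02=1e-3)
        samp = zipper_collision(state, mid_config, open_posture)
        assert samp.pc == 0.0 and samp.contact_length == 0.0 and samp.contact_area == 0.0

    def test_tangency_boundary_case(self, mid_config, mid_posture):
        """Anterior point exactly at the midline with open posterior: no contact."""
        post = replace(mid_posture, xi02=1e-3)
        state = TBCMState(
            x=np.array([-mid_config.x_l0_offset, -mid_config.x_u0_offset, 0.0]),
            v=np.zeros(3),
        )
        samp = zipper_collision(state, mid_config, post)
        assert samp.pc == pytest.approx(0.0, abs=1e-9)

    def test_matches_closed_form_integration(self, mid_config, rng):
        """Contact length and Pc agree with quadrature on the linear profile."""
        L = mid_config.length
        for _ in range(50):
            x_l = rng.uniform(-1.5e-3, 0.5e-3)
            x_u = rng.uniform(-1.5e-3, 0.5e-3)
            xi02 = rng.uniform(0.2e-3, 2e-3)
            post = PostureState(strain=0.0, length=L, xi02=xi02, gap_area=0.0)
            state = TBCMState(x=np.array([x_l, x_u, 0.0]), v=np.zeros(3))
            samp = zipper_collision(state, mid_config, post)

            y = np.linspace(0.0, L, 20001)
            h_l = x_l + mid_config.x_l0_offset + y / L * xi02
            h_u = x_u + mid_config.x_u0_offset + y / L * xi02
            pen_l = np.trapezoid(np.maximum(-h_l, 0.0), y)
            pen_u = np.trapezoid(np.maximum(-h_u, 0.0), y)
            ell_l = np.sum(h_l < 0) / y.size * L
            ell_u = np.sum(h_u < 0) / y.size * L
            area = ell_l * mid_config.T_l + ell_u * mid_config.T_u
            force = mid_config.k_col_l * pen_l + mid_config.k_col_u * pen_u
            pc_ref = force / area if area > 0 else 0.0
            assert samp.pc == pytest.approx(pc_ref, rel=1e-3, abs=1e-6)

    def test_contact_complementarity_in_simulation(self, mid_sim):
        """Pc > 0 exactly when the folds are in contact, at every sample."""
        pc = mid_sim.pc
        assert np.all(pc >= 0.0)
        assert pc.max() > 0.0  # this grid point does collide
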