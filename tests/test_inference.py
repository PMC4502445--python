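"""The generalized filter: errors, free energy, gradients, action, learning."""

import numpy as np
import pytest
from scipy.linalg import expm

from syrinx.inference import (
    ActionState,
    GeneralizedFilter,
    ParameterAccumulator,
    ParameterBelief,
    birdsong_functions,
    linear_functions,
    theta_error_derivative,
    update_parameter_belief,
)
from syrinx.songmodel import default_model, generate_song

DT = 1.0 / 64.0


def make_filter(theta=0.8, order=6):
    model = default_model(theta)
    filt = GeneralizedFilter(
        birdsong_functions(model), order=order, theta=theta, dt=DT
    )
    return model, filt


def random_posterior(filt, rng, scale=1.0):
    post = filt.init_posterior(rng)
    for arr in (post.mu_x1, post.mu_x2, post.mu_v):
        arr[:] = scale * rng.standard_normal(arr.shape)
    return post


class TestPredictionErrors:
    def test_self_consistent_point_has_no_errors(self, rng):
        model, filt = make_filter(theta=0.8)
        post = filt.consistent_posterior([1.0, 2.0, 15.0], [3.0, -2.0, 25.0])
        sens = filt.predicted_output_jet(post)
        e = filt.prediction_errors(post, sens, model.log_precisions)
        assert np.allclose(e.eps["s"], 0.0, atol=1e-10)
        assert np.allclose(e.eps["v"], 0.0, atol=1e-10)
        # dynamical errors vanish at every order except the truncation tail
        assert np.allclose(e.eps["x1"][:-1], 0.0, atol=1e-9)
        assert np.allclose(e.eps["x2"][:-1], 0.0, atol=1e-9)

    def test_precision_scaling_of_weighted_errors(self, rng):
        model, filt = make_filter()
        post = random_posterior(filt, rng)
        sens = rng.standard_normal((7, 4))
        lp = dict(model.log_precisions)
        e1 = filt.prediction_errors(post, sens, lp)
        lp2 = dict(lp)
        lp2["aud"] += np.log(2.0)
        filt._prec_cache.clear()
        e2 = filt.prediction_errors(post, sens, lp2)
        aud1 = e1.weighted["s"].reshape(7, 4)[:, :2]
        aud2 = e2.weighted["s"].reshape(7, 4)[:, :2]
        assert np.allclose(aud2, 2.0 * aud1)
        prop1 = e1.weighted["s"].reshape(7, 4)[:, 2:]
        prop2 = e2.weighted["s"].reshape(7, 4)[:, 2:]
        assert np.allclose(prop2, prop1)

    def test_matches_straight_line_reevaluation(self, rng):
        # independent oracle: re-evaluate g, f and the shift by hand
        from syrinx import songmodel as sm

        model, filt = make_filter(theta=0.8)
        post = random_posterior(filt, rng)
        sens = rng.standard_normal((7, 4))
        e = filt.prediction_errors(post, sens, model.log_precisions)
        fi, ai = model.syrinx.freq_state_index, model.syrinx.amp_state_index
        for k in range(7):
            pred = post.mu_x1[k][[fi, ai, fi, ai]]
            assert np.allclose(e.eps["s"][k], sens[k] - pred)
        x0, v0 = post.mu_x1[0], post.mu_v[0]
        rho = sm.rayleigh_control(float(v0[0]), 0.8, model.level1)
        f0 = DT * sm.lorenz_flow(x0, model.level1, rho)
        assert np.allclose(e.eps["x1"][0], post.mu_x1[1] - f0)
        Jx = DT * sm.lorenz_jacobian(x0, model.level1, rho)
        Jv = np.zeros((3, 1))
        Jv[1, 0] = DT * 0.8 * x0[0] * sm.sat_control_d1(float(v0[0])) / model.level1.tau
        for k in range(1, 7):
            fk = Jx @ post.mu_x1[k]
            if k <= 2:
                fk = fk + (Jv @ post.mu_v[k])
            target = post.mu_x1[k + 1] if k < 6 else np.zeros(3)
            assert np.allclose(e.eps["x1"][k], target - fk)
        for k in range(3):
            pred_v = model.level2_gain * post.mu_x2[k, 0] + (
                model.level2_offset if k == 0 else 0.0
            )
            assert np.allclose(e.eps["v"][k], post.mu_v[k] - pred_v)

    def test_shape_mismatch_rejected(self, rng):
        model, filt = make_filter()
        post = random_posterior(filt, rng)
        with pytest.raises(ValueError):
            filt.prediction_errors(post, np.zeros((5, 4)), model.log_precisions)


class TestFreeEnergy:
    def test_zero_errors_leave_logdet_only(self):
        model, filt = make_filter()
        post = filt.init_posterior()
        # at the origin every flow vanishes; the cause prediction is the
        # level-2 offset, so the expectation must sit there for zero error
        post.mu_v[0, 0] = model.level2_offset
        sens = np.zeros((7, 4))
        e = filt.prediction_errors(post, sens, model.log_precisions)
        F = filt.free_energy(e, model.log_precisions)
        assert F == pytest.approx(
            -0.5 * filt.precisions(model.log_precisions)["logdet"]
        )

    def test_monotone_in_error_magnitude(self, rng):
        model, filt = make_filter()
        post = filt.init_posterior()
        base = np.zeros((7, 4))
        lp = model.log_precisions
        f_prev = filt.free_energy(filt.prediction_errors(post, base, lp), lp)
        for scale in (0.5, 1.0, 2.0, 4.0):
            s = base.copy()
            s[0, 0] = scale
            f = filt.free_energy(filt.prediction_errors(post, s, lp), lp)
            assert f > f_prev
            f_prev = f

    def test_matches_dense_quadratic_oracle(self, rng):
        # brute-force 1/2 eps' Pi eps with explicitly assembled matrices
        model, filt = make_filter()
        post = random_posterior(filt, rng)
        sens = rng.standard_normal((7, 4))
        lp = model.log_precisions
        e = filt.prediction_errors(post, sens, lp)
        Pi = filt.precisions(lp)["Pi"]
        quad = sum(
            float(e.eps[b].ravel() @ Pi[b] @ e.eps[b].ravel()) for b in e.eps
        )
        expected = 0.5 * (quad - filt.precisions(lp)["logdet"])
        assert filt.free_energy(e, lp) == pytest.approx(expected)


class TestGradients:
    """Analytic derivatives vs central finite differences (< 1e-4 relative)."""

    def test_state_gradient(self, rng):
        model, filt = make_filter(theta=0.8)
        lp = model.log_precisions
        post = random_posterior(filt, rng, scale=0.7)
        sens = rng.standard_normal((7, 4))
        mu = filt.flatten(post)
        e = filt.prediction_errors(post, sens, lp)
        g = filt.free_energy_gradient(post, e, lp)

        def F(m):
            p = filt.unflatten(m)
            return filt.free_energy(filt.prediction_errors(p, sens, lp), lp)

        h = 1e-5
        eye = np.eye(mu.size)
        gfd = np.array([(F(mu + h * eye[i]) - F(mu - h * eye[i])) / (2 * h)
                        for i in range(mu.size)])
        assert np.linalg.norm(g - gfd) / np.linalg.norm(gfd) < 1e-4

    def test_theta_gradient(self, rng):
        model, filt = make_filter(theta=0.8)
        lp = model.log_precisions
        post = random_posterior(filt, rng, scale=0.7)
        sens = rng.standard_normal((7, 4))
        e = filt.prediction_errors(post, sens, lp)
        d = theta_error_derivative(filt, post).ravel()
        g = float(d @ e.weighted["x1"])

        def F(theta):
            f2 = GeneralizedFilter(filt.funcs, theta=theta, dt=DT)
            return f2.free_energy(f2.prediction_errors(post, sens, lp), lp)

        h = 1e-5
        gfd = (F(0.8 + h) - F(0.8 - h)) / (2 * h)
        assert abs(g - gfd) / abs(gfd) < 1e-4

    def test_action_gradient(self, rng):
        # dF/da through the proprioceptive channels at order 0
        model, filt = make_filter()
        lp = model.log_precisions
        post = random_posterior(filt, rng, scale=0.7)
        a = rng.standard_normal(2)

        def F(a_):
            s = rng2_sens.copy()
            s[0, 2:] = a_
            return filt.free_energy(filt.prediction_errors(post, s, lp), lp)

        rng2_sens = rng.standard_normal((7, 4))
        Pi_s = filt.precisions(lp)["Pi"]["s"]
        M = np.zeros((7 * 4, 2))
        M[2, 0] = M[3, 1] = 1.0
        s = rng2_sens.copy()
        s[0, 2:] = a
        e = filt.prediction_errors(post, s, lp)
        g = M.T @ e.weighted["s"]
        h = 1e-6
        for i in range(2):
            step = np.eye(2)[i] * h
            gfd = (F(a + step) - F(a - step)) / (2 * h)
            assert abs(g[i] - gfd) / (abs(gfd) + 1e-12) < 1e-4


class TestFilterStep:
    def test_zero_error_state_is_pure_prediction(self):
        # a linear model with the posterior in the flow's null direction has
        # exactly zero errors everywhere: the update must be the exact
        # temporal translation (= identity, all derivatives zero)
        A = np.array([[0.0, 0.0], [1.0, -1.0]])  # null vector (1, 1)
        filt = GeneralizedFilter(linear_functions(A, np.eye(2)), order=4,
                                 cause_order=0, dt=1.0)
        post = filt.init_posterior()
        post.mu_x1[0] = [1.0, 1.0]
        sens = np.zeros((5, 2))
        sens[0] = [1.0, 1.0]
        lp = {"y": 2.0, "x1": 2.0}
        new = filt.filter_step(post, sens, lp)
        assert np.allclose(filt.flatten(new), filt.flatten(post), atol=1e-9)

    def test_translation_on_self_consistent_chaotic_state(self):
        model, filt = make_filter(theta=0.8)
        post = filt.consistent_posterior([1.0, 2.0, 15.0], [3.0, -2.0, 25.0])
        sens = filt.predicted_output_jet(post)
        new = filt.filter_step(post, sens, model.log_precisions)
        ref = expm(filt._D) @ filt.flatten(post)
        # small deviation from pure Taylor translation: only the truncation
        # tail (order n) carries errors
        assert np.linalg.norm(filt.flatten(new) - ref) < 0.1 * np.linalg.norm(ref)

    def test_free_energy_descends_on_static_sensation(self, rng):
        model, filt = make_filter(theta=0.5)
        lp = model.log_precisions
        post = random_posterior(filt, rng, scale=0.5)
        sens = np.zeros((7, 4))
        sens[0] = [5.0, 2.0, 5.0, 2.0]
        F = []
        for _ in range(40):
            post = filt.filter_step(post, sens, lp)
            F.append(post.free_energy)
        # after burn-in the free energy has fallen a long way and settled
        burn = 10
        assert F[-1] <= F[burn]
        assert F[-1] < 0.05 * F[0]
        plateau = np.abs(np.diff(F[-10:]))
        assert plateau.max() < 0.01 * abs(F[0] - F[-1])

    def test_kalman_bucy_equivalence(self):
        """Linear model: generalized filter tracks a Kalman-Bucy oracle.

        High-SNR rotation observed directly; relative RMS between the two
        filtered mean trajectories after burn-in must be below 1%, for
        embedding orders 2-6.
        """
        from syrinx.cli_io import make_fixture

        fx = make_fixture("kalman", 0)
        A, C = fx.data["A"], fx.data["C"]
        dt, Y, sigma = fx.data["dt"], fx.data["obs"], fx.data["sigma"]
        lp = {"y": float(np.log(1.0 / sigma**2)), "x1": 4.0}
        Ad = expm(A * dt)
        # discrete Kalman oracle with matched assumptions
        Qd = np.exp(-lp["x1"]) * dt * np.eye(2)
        R = sigma**2 * np.eye(2)
        for order in (2, 4, 6):
            funcs = linear_functions(A, C)
            filt = GeneralizedFilter(funcs, order=order, cause_order=0, dt=dt)
            post = filt.init_posterior()
            M = np.empty_like(Y)
            for i in range(len(Y)):
                s = np.zeros((order + 1, 2))
                s[0] = Y[i]
                for k in range(1, order + 1):
                    s[k] = np.linalg.matrix_power(A * dt, k) @ Y[i]
                M[i] = post.mu_x1[0]
                post = filt.filter_step(post, s, lp)
            xk = np.zeros(2)
            P = np.eye(2) * 10.0
            K = np.empty_like(Y)
            for i in range(len(Y)):
                S = C @ P @ C.T + R
                G = P @ C.T @ np.linalg.inv(S)
                xk = xk + G @ (Y[i] - C @ xk)
                P = (np.eye(2) - G @ C) @ P
                K[i] = xk
                xk = Ad @ xk
                P = Ad @ P @ Ad.T + Qd
            burn = len(Y) // 4
            rel = np.sqrt(np.mean((M[burn:] - K[burn:]) ** 2)) / np.sqrt(
                np.mean(K[burn:] ** 2)
            )
            assert rel < 0.01, f"order {order}: {rel:.4f}"

    def test_precision_raises_influence_of_a_channel(self, rng):
        # raising a channel's log-precision strictly increases the norm of
        # the update it induces
        model, filt = make_filter()
        post = random_posterior(filt, rng, scale=0.5)
        sens = np.zeros((7, 4))
        sens[0, :2] = [4.0, 4.0]
        base = filt.flatten(filt.filter_step(post, sens, dict(model.log_precisions, aud=-2.0)))
        mid = filt.flatten(filt.filter_step(post, sens, dict(model.log_precisions, aud=0.0)))
        high = filt.flatten(filt.filter_step(post, sens, dict(model.log_precisions, aud=2.0)))
        ref = filt.flatten(filt.filter_step(post, np.zeros((7, 4)), dict(model.log_precisions, aud=-20.0)))
        d = [np.linalg.norm(x - ref) for x in (base, mid, high)]
        assert d[0] < d[1] < d[2]

    def test_rejects_nonpositive_dt(self, rng):
        model, filt = make_filter()
        with pytest.raises(ValueError):
            filt.filter_step(filt.init_posterior(), np.zeros((7, 4)),
                             model.log_precisions, dt=0.0)


class TestAction:
    def test_zero_proprioceptive_error_leaves_action_unchanged(self):
        model, filt = make_filter()
        post = filt.init_posterior()
        sens = np.zeros((7, 4))
        e = filt.prediction_errors(post, sens, model.log_precisions)
        act = ActionState(a=np.array([1.0, -2.0]))
        # prediction is zero and proprio input zero -> no error, no update
        new = filt.action_step(post, e, act, model.log_precisions, dt=1.0)
        assert np.allclose(new.a, act.a)

    def test_listening_attenuates_reflex_by_exp_minus_8(self):
        model, filt = make_filter()
        post = filt.init_posterior()
        post.mu_x1[0] = [0.0, 2.0, 3.0]  # predicted output (3, 2)
        act = ActionState(a=np.zeros(2))
        sens = np.zeros((7, 4))
        rates = {}
        for name, prop in (("sing", 0.0), ("listen", -8.0)):
            lp = dict(model.log_precisions, prop=prop)
            e = filt.prediction_errors(post, sens, lp)
            new = filt.action_step(post, e, act, lp, dt=1.0)
            rates[name] = np.linalg.norm(new.da_dt)
        assert rates["sing"] / rates["listen"] == pytest.approx(np.exp(8.0), rel=1e-6)

    def test_scalar_reflex_converges_exponentially(self):
        # closed form: with constant prediction g and precision rate k,
        # a(t) = g + (a0 - g) exp(-k t)
        model, filt = make_filter()
        post = filt.init_posterior()
        post.mu_x1[0] = [0.0, 4.0, 6.0]
        lp = dict(model.log_precisions, prop=0.0, aud=-20.0)
        target = np.array([6.0, 4.0])
        act = ActionState(a=np.zeros(2))
        gaps = []
        for _ in range(60):
            sens = np.zeros((7, 4))
            sens[0, 2:] = act.a
            e = filt.prediction_errors(post, sens, lp)
            act = filt.action_step(post, e, act, lp, dt=1.0, gain=0.25)
            gaps.append(np.linalg.norm(act.a - target))
        gaps = np.array(gaps)
        # constant contraction factor per step = exponential convergence
        # (checked while the gap is far above the floating-point floor)
        ratios = gaps[1:12] / gaps[:11]
        assert np.std(ratios) < 1e-3 * ratios.mean()
        assert 0.0 < ratios[0] < 1.0
        assert gaps[-1] < 1e-3 * gaps[0]


class TestParameterLearning:
    def test_empty_epoch_rejected(self):
        acc = ParameterAccumulator()
        with pytest.raises(ValueError):
            acc.finalize()

    def test_zero_gradient_leaves_mean_unchanged(self):
        b = update_parameter_belief(ParameterBelief(0.7, 64.0), 0.0, 10.0)
        assert b.mean == 0.7
        assert b.precision == 74.0

    def test_prior_precision_retained_across_epochs(self):
        belief = ParameterBelief(0.5, 64.0)
        for _ in range(3):
            prior = ParameterBelief(belief.mean, 64.0)
            belief = update_parameter_belief(prior, 1.0, 5.0, prior_precision=64.0)
            assert belief.precision == pytest.approx(69.0)

    def test_nonpositive_posterior_precision_rejected(self):
        with pytest.raises(FloatingPointError):
            update_parameter_belief(ParameterBelief(0.5, 64.0), 0.0, -100.0)

    def test_epoch_gradient_matches_finite_differences(self, rng):
        model, filt = make_filter(theta=0.8)
        lp = model.log_precisions
        posts, senses = [], []
        for _ in range(5):
            posts.append(random_posterior(filt, rng, scale=0.7))
            senses.append(rng.standard_normal((7, 4)))

        def epoch_F(theta):
            f2 = GeneralizedFilter(filt.funcs, theta=theta, dt=DT)
            return sum(
                f2.free_energy(f2.prediction_errors(p, s, lp), lp)
                for p, s in zip(posts, senses)
            )

        acc = ParameterAccumulator()
        for p, s in zip(posts, senses):
            e = filt.prediction_errors(p, s, lp)
            acc.add(filt, p, e, lp, mean_field=False)
        g, _ = acc.finalize()
        h = 1e-5
        gfd = (epoch_F(0.8 + h) - epoch_F(0.8 - h)) / (2 * h)
        assert abs(g - gfd) / abs(gfd) < 1e-4

    def test_evidence_weighting_scales_with_auditory_precision(self, rng):
        model, filt = make_filter()
        lp = model.log_precisions
        post = random_posterior(filt, rng)
        sens = rng.standard_normal((7, 4))
        e = filt.prediction_errors(post, sens, lp)
        a1, a2 = ParameterAccumulator(), ParameterAccumulator()
        a1.add(filt, post, e, lp, weight=1.0, mean_field=False)
        a2.add(filt, post, e, lp, weight=np.exp(-4.0), mean_field=False)
        assert a2.gradient == pytest.approx(np.exp(-4.0) * a1.gradient)
        assert a2.curvature == pytest.approx(np.exp(-4.0) * a1.curvature)

    def test_teacher_student_recovery_with_clamped_states(self):
        """Student's theta converges to the teacher's within 0.05."""
        m_true = default_model(1.0)
        funcs = birdsong_functions(m_true)
        lp = m_true.log_precisions
        teacher = GeneralizedFilter(funcs, theta=1.0, dt=DT)
        belief = ParameterBelief(0.5, 64.0)
        for epoch in range(32):
            tr, _ = generate_song(m_true, duration=1.0, seed=50 + epoch,
                                  noise_std=(0.05, 0.05))
            student = GeneralizedFilter(funcs, theta=belief.mean, dt=DT)
            acc = ParameterAccumulator()
            for i in range(0, len(tr["t"]), 2):
                post = teacher.consistent_posterior(tr["x1"][i], tr["x2"][i])
                sens = teacher.predicted_output_jet(post)
                e = student.prediction_errors(post, sens, lp)
                acc.add(student, post, e, lp, mean_field=False)
            g, c = acc.finalize()
            belief = update_parameter_belief(ParameterBelief(belief.mean, 64.0), g, c)
            if abs(belief.mean - 1.0) < 0.05:
                break
        assert abs(belief.mean - 1.0) < 0.05

    def test_theta_estimator_bias_shrinks_with_epochs(self):
        # consistency: more accumulated evidence pulls the posterior mean
        # closer to the truth
        m_true = default_model(1.0)
        funcs = birdsong_functions(m_true)
        lp = m_true.log_precisions
        teacher = GeneralizedFilter(funcs, theta=1.0, dt=DT)
        student = GeneralizedFilter(funcs, theta=0.6, dt=DT)
        acc = ParameterAccumulator()
        biases = []
        tr, _ = generate_song(m_true, duration=2.0, seed=9, noise_std=(0.05, 0.05))
        for i in range(len(tr["t"])):
            post = teacher.consistent_posterior(tr["x1"][i], tr["x2"][i])
            sens = teacher.predicted_output_jet(post)
            e = student.prediction_errors(post, sens, lp)
            acc.add(student, post, e, lp, mean_field=False)
            if (i + 1) % 32 == 0:
                g, c = acc.finalize()
                b = update_parameter_belief(ParameterBelief(0.6, 64.0), g, c)
                biases.append(abs(b.mean - 1.0))
        assert biases[-1] < biases[0]
        assert biases[-1] < 0.02
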