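import numpy as np
import pytest

from forcekit.force_training import (
    EarlyStopping,
    TrainingConfig,
    _family_rls_step,
    bio_force_fit,
    compute_error,
    force_fit,
    full_force_fit,
    init_P,
    init_recurrent_rls,
    predict,
    rescale_traces,
    rls_update_P,
    spiking_fit,
    state_from_traces,
    update_output_weights,
    update_recurrent_weights,
)
from forcekit.rate_layers import init_rate_network, run_network, step_rate
from forcekit.spiking_layers import init_spiking_network, run_spiking_network
from forcekit.synthetic_tasks import (
    TaskData,
    gen_sum_of_sines,
    gen_synthetic_recording,
)


class TestRLSPrimitives:
    def test_init_P(self):
        assert np.array_equal(init_P(2.0, 3), 0.5 * np.eye(3))
        assert np.array_equal(init_P(1.0, 1), [[1.0]])
        with pytest.raises(ValueError):
            init_P(0.0, 3)

    def test_update_with_zero_rate_is_identity(self):
        P = init_P(1.0, 4)
        assert np.array_equal(rls_update_P(P, np.zeros(4)), P)

    def test_rank_one_update_matches_direct_inverse(self):
        P = rls_update_P(np.eye(2), np.array([1.0, 0.0]))
        assert np.allclose(P, [[0.5, 0.0], [0.0, 1.0]])
        P = rls_update_P(P, np.array([0.0, 1.0]))
        assert np.allclose(P, np.diag([0.5, 0.5]))

    def test_P_tracks_inverse_regularized_correlation(self, rng):
        # P after T updates must equal inv(alpha I + sum r r^T)
        alpha, n, t_steps = 0.7, 20, 150
        rs = rng.normal(size=(t_steps, n))
        P = init_P(alpha, n)
        for r in rs:
            P = rls_update_P(P, r)
        direct = np.linalg.inv(alpha * np.eye(n) + rs.T @ rs)
        rel = np.linalg.norm(P - direct) / np.linalg.norm(direct)
        assert rel < 1e-10
        assert np.max(np.abs(P - P.T)) < 1e-10

    def test_compute_error(self):
        assert compute_error(np.array([0.7]), np.array([0.5]))[0] == pytest.approx(0.2)
        assert np.array_equal(
            compute_error(np.array([1.0, 2.0]), np.array([1.0, 2.0])),
            np.zeros(2),
        )
        e = compute_error(np.array([1.0, 0.0]), np.array([0.5, 1.0]))
        assert np.allclose(e, [0.5, -1.0])
        with pytest.raises(ValueError):
            compute_error(np.zeros(2), np.zeros(3))

    def test_output_update_scalar_case(self):
        w = update_output_weights(
            np.array([[0.3]]), np.array([0.2]), np.array([[0.5]]), np.array([1.0])
        )
        assert w[0, 0] == pytest.approx(0.2)

    def test_output_update_zero_error_fixed_point(self, rng):
        w = rng.normal(size=(5, 2))
        P = init_P(1.0, 5)
        w2 = update_output_weights(w, np.zeros(2), P, rng.normal(size=5))
        assert np.array_equal(w, w2)


class TestRecurrentRLS:
    def test_full_connectivity_reduces_to_shared_P(self, rng):
        # every A^i with B(i) = all neurons must equal the shared P exactly
        n = 10
        mask = np.ones((n, n), dtype=bool)
        family = init_recurrent_rls(mask, 1.0)
        P = init_P(1.0, n)
        for _ in range(50):
            r = rng.normal(size=n)
            P = rls_update_P(P, r)
            _family_rls_step(family, r)
            for A in family.A:
                assert np.allclose(A, P, atol=1e-12)

    def test_single_presynaptic_neuron_scalar_recursion(self):
        # B(1) = {0}: the A^1 recursion is scalar Sherman-Morrison
        mask = np.array([[False, True], [False, False]])
        family = init_recurrent_rls(mask, 2.0)
        w = np.zeros((2, 2))
        a_scalar = 1.0 / 2.0
        rates = [0.5, -1.0, 2.0, 0.3]
        for rv in rates:
            r = np.array([rv, 0.7])
            w, family = update_recurrent_weights(w, family, 0.0, r, mask)
            a_scalar = a_scalar - a_scalar**2 * rv**2 / (1 + rv**2 * a_scalar)
            assert family.A[1][0, 0] == pytest.approx(a_scalar, rel=1e-12)
        assert family.A[0].shape == (0, 0)

    def test_zero_error_updates_A_but_not_weights(self, rng):
        n = 6
        mask = np.ones((n, n), dtype=bool)
        family = init_recurrent_rls(mask, 1.0)
        w = rng.normal(size=(n, n))
        a_before = family.A[0].copy()
        w2, family = update_recurrent_weights(
            w, family, 0.0, rng.normal(size=n), mask
        )
        assert np.array_equal(w, w2)
        assert not np.array_equal(family.A[0], a_before)

    def test_vector_error_rejected(self):
        mask = np.ones((3, 3), dtype=bool)
        family = init_recurrent_rls(mask, 1.0)
        with pytest.raises(ValueError, match="scalar"):
            update_recurrent_weights(
                np.zeros((3, 3)), family, np.array([1.0, 2.0]), np.ones(3), mask
            )


class TestForceFit:
    def test_zero_target_zero_weights_stay_zero(self):
        params, _ = init_rate_network(
            15, "nofeedback_esn", dims=(1, 1), seed=0, w_out_init="zeros"
        )
        task = TaskData(
            f_in=np.ones((50, 1)), f_out=np.zeros((50, 1)), dt=1.0
        )
        trained, _ = force_fit(params, task, TrainingConfig(epochs=2))
        assert np.all(trained.w_out == 0)

    def test_one_epoch_equals_ridge_solution(self, small_reservoir):
        # frozen feedback-independent rates: FORCE output training is RLS,
        # whose fixed point after one pass is the ridge regression solution
        params, state = small_reservoir
        task = gen_sum_of_sines(n_steps=300)
        traj, _ = run_network(
            params, state.copy(), np.hstack([task.f_in, task.hint])
        )
        alpha = 1.0
        ridge = np.linalg.solve(
            alpha * np.eye(30) + traj.r.T @ traj.r, traj.r.T @ task.f_out
        )
        trained, _ = force_fit(params, task, TrainingConfig(alpha=alpha))
        rel = np.linalg.norm(trained.w_out - ridge) / np.linalg.norm(ridge)
        assert rel < 1e-6

    def test_update_count_with_interval(self):
        params, _ = init_rate_network(10, "nofeedback_esn", dims=(2, 1), seed=1)
        task = gen_sum_of_sines(n_steps=373)
        cfg = TrainingConfig(epochs=1, update_interval=50, warmup_steps=20)
        _, history = force_fit(params, task, cfg)
        assert history.n_updates == [(373 - 20) // 50]

    def test_update_gating_schedule(self):
        # weights change only at steps == 0 mod k after the warmup
        params, _ = init_rate_network(10, "nofeedback_esn", dims=(2, 1), seed=1)
        task = gen_sum_of_sines(n_steps=200)
        k, warmup = 25, 30
        snapshots = {}

        def callback(epoch, step_no, p):
            snapshots[step_no] = p.w_out.copy()

        force_fit(
            params,
            task,
            TrainingConfig(epochs=1, update_interval=k, warmup_steps=warmup),
            step_callback=callback,
        )
        prev = None
        for step_no in sorted(snapshots):
            if prev is not None:
                changed = not np.array_equal(snapshots[step_no], prev)
                scheduled = step_no > warmup and (step_no - warmup) % k == 0
                assert changed == scheduled, f"step {step_no}"
            prev = snapshots[step_no]

    def test_history_is_deterministic(self):
        task = gen_sum_of_sines(n_steps=200)
        runs = []
        for _ in range(2):
            params, _ = init_rate_network(
                30, "feedback_esn", dims=(2, 1), seed=4
            )
            _, h = force_fit(params, task, TrainingConfig(epochs=3))
            runs.append((h.train_mae, h.val_mae, h.n_updates))
        assert runs[0] == runs[1]

    def test_rejects_constrained_layer(self):
        params, _ = init_rate_network(5, "constrained_esn", seed=0)
        task = gen_sum_of_sines(n_steps=50)
        with pytest.raises(ValueError, match="rate layer"):
            force_fit(params, task, TrainingConfig())


class TestFullForce:
    def test_hint_zeros_accepted(self):
        params, _ = init_rate_network(20, "nofeedback_esn", dims=(1, 1), seed=0)
        task = gen_sum_of_sines(n_steps=100)
        assert np.all(task.hint == 0)
        trained, history = full_force_fit(params, task, TrainingConfig(epochs=1))
        assert history.epochs_completed == 1

    def test_zero_target_same_seed_no_recurrent_change(self):
        # target net == task net and f_out == 0: currents already match
        params, _ = init_rate_network(
            12, "nofeedback_esn", dims=(1, 1), seed=3, w_out_init="zeros"
        )
        task = TaskData(
            f_in=np.random.default_rng(0).normal(size=(60, 1)),
            f_out=np.zeros((60, 1)),
            dt=1.0,
        )
        trained, _ = full_force_fit(
            params, task, TrainingConfig(epochs=1), target_seed=3
        )
        assert np.allclose(trained.w_R, params.w_R, atol=1e-12)
        assert np.all(trained.w_out == 0)

    def test_requires_nofeedback_layer(self):
        params, _ = init_rate_network(5, "feedback_esn", seed=0)
        task = gen_sum_of_sines(n_steps=50)
        with pytest.raises(ValueError, match="nofeedback"):
            full_force_fit(params, task, TrainingConfig())

    def test_learns_periodic_target_closed_loop(self):
        # small version of the autonomous-generation experiment
        params, _ = init_rate_network(100, "nofeedback_esn", dims=(1, 1), seed=0)
        task = gen_sum_of_sines(n_steps=401)
        trained, history = full_force_fit(
            params, task, TrainingConfig(epochs=5, seed=0)
        )
        assert history.val_mae[-1] < history.val_mae[0]
        assert history.val_mae[-1] < 0.1


class TestSpikingFit:
    def _tiny_task(self, n_steps=400):
        t = np.arange(n_steps) * 1e-4
        f = np.sin(2 * np.pi * 20 * t)[:, None]
        return TaskData(f_in=np.zeros((n_steps, 0)), f_out=f, dt=1e-4)

    def test_warmup_covering_run_freezes_decoders(self):
        params, state = init_spiking_network(
            20, "lif", dims=(0, 1), seed=0, i_bias=35.0
        )
        task = self._tiny_task()
        trained, history = spiking_fit(
            params, state, task, TrainingConfig(warmup_steps=400)
        )
        assert np.all(trained.phi == 0)
        assert history.n_updates == [0]

    def test_update_counting(self):
        params, state = init_spiking_network(
            20, "lif", dims=(0, 1), seed=0, i_bias=35.0
        )
        task = self._tiny_task(n_steps=350)
        _, history = spiking_fit(
            params,
            state,
            task,
            TrainingConfig(update_interval=50, warmup_steps=100),
        )
        assert history.n_updates == [(350 - 100) // 50]

    def test_lorenz_closed_loop_output_stays_bounded(self):
        # scaled-down autonomous-dynamics experiment: after FORCE training
        # the decoded output must not blow up when the target is removed
        from forcekit.synthetic_tasks import gen_lorenz

        lorenz = gen_lorenz(duration_s=3.0, dt=1e-4, seed=0)
        train = TaskData(
            f_in=np.zeros((20000, 0)), f_out=lorenz.f_out[:20000], dt=1e-4
        )
        test = TaskData(
            f_in=np.zeros((10000, 0)), f_out=lorenz.f_out[20000:], dt=1e-4
        )
        params, state = init_spiking_network(
            200, "theta", dims=(0, 3), sparsity=0.1, gain=25.0,
            feedback_scale=15.0, seed=0, dt=1e-4,
        )
        _, warm = run_spiking_network(params, state, 5000, record=False)
        trained, _ = spiking_fit(
            params, warm, train,
            TrainingConfig(update_interval=50, warmup_steps=5000),
        )
        outputs, _ = predict(trained, test, state0=warm)
        amplitude = np.abs(lorenz.f_out).max()
        assert np.all(np.isfinite(outputs))
        assert np.abs(outputs).max() < 3.0 * amplitude

    def test_decoders_reduce_error(self):
        params, state = init_spiking_network(
            100, "lif", dims=(0, 1), gain=10.0, seed=1, i_bias=35.0
        )
        task = self._tiny_task(2000)
        _, warm = run_spiking_network(params, state, 500, record=False)
        trained, history = spiking_fit(
            params, warm, task, TrainingConfig(epochs=1)
        )
        untrained_mae = predict(params, task, state0=warm)[1]
        assert history.train_mae[0] < untrained_mae


class TestBioForce:
    def test_zero_traces_zero_weights_unchanged(self):
        mask = ~np.eye(8, dtype=bool)
        params, _ = init_rate_network(
            8, "constrained_esn", gain=0.0, dims=(1, 1), seed=0, mask=mask,
            w_out_init="zeros",
        )
        res = bio_force_fit(
            params, np.zeros((40, 8)), TrainingConfig(epochs=2)
        )
        assert np.all(res.effective_weights == 0)

    def test_early_stopping_halts(self):
        task, _, mask = gen_synthetic_recording(
            n_neurons=20, n_steps=120, seed=1
        )
        params, _ = init_rate_network(
            20, "constrained_esn", gain=0.0, dims=(3, 1), seed=5,
            tau=0.5, dt=0.25, mask=mask,
        )
        # a large min_delta makes every epoch count as "no improvement"
        cfg = TrainingConfig(
            epochs=30,
            early_stopping=EarlyStopping(patience=2, min_delta=1.0),
        )
        res = bio_force_fit(params, task.f_out, cfg, f_in=task.f_in)
        assert res.history.epochs_completed == 3

    def test_isolated_neuron_warned_and_untrained(self):
        mask = ~np.eye(6, dtype=bool)
        mask[:, 2] = False  # neuron 2 receives nothing
        params, _ = init_rate_network(
            6, "constrained_esn", gain=0.0, dims=(1, 1), seed=0, mask=mask,
        )
        traces = np.random.default_rng(0).uniform(-0.5, 0.5, (30, 6))
        with pytest.warns(UserWarning, match=r"\[2\]"):
            res = bio_force_fit(params, traces, TrainingConfig(epochs=1))
        assert np.all(res.effective_weights[:, 2] == 0)
        # untrained = left at its initial value
        assert np.array_equal(res.params.w_in[:, 2], params.w_in[:, 2])
        assert not np.array_equal(
            res.params.w_R[:, 0], params.w_R[:, 0]
        )  # connected neurons did train

    def test_trace_shape_checked(self):
        params, _ = init_rate_network(5, "constrained_esn", seed=0)
        with pytest.raises(ValueError, match="T x N"):
            bio_force_fit(params, np.zeros((10, 4)), TrainingConfig())

    def test_teacher_student_short_recovery(self):
        # small sanity version of the connectivity-fitting experiment
        task, truth, mask = gen_synthetic_recording(
            n_neurons=30, n_steps=300, seed=3
        )
        params, _ = init_rate_network(
            30, "constrained_esn", gain=0.0, dims=(3, 1), seed=9,
            tau=0.5, dt=0.25, mask=mask,
        )
        res = bio_force_fit(
            params,
            task.f_out[:240],
            TrainingConfig(epochs=5),
            f_in=task.f_in[:240],
        )
        y = rescale_traces(task.f_out)
        state = state_from_traces(res.params, y[239])
        preds = []
        for t in range(240, 300):
            state = step_rate(res.params, state, task.f_in[t])
            preds.append(state.r)
        preds = np.array(preds)
        corr = np.nanmean(
            [np.corrcoef(preds[:, i], y[240:, i])[0, 1] for i in range(30)]
        )
        assert corr > 0.6

    def test_rates_mode_moves_same_direction(self):
        task, _, mask = gen_synthetic_recording(
            n_neurons=15, n_steps=150, seed=2
        )
        params, _ = init_rate_network(
            15, "constrained_esn", gain=0.0, dims=(3, 1), seed=4,
            tau=0.5, dt=0.25, mask=mask,
        )
        res = bio_force_fit(
            params, task.f_out, TrainingConfig(epochs=3),
            f_in=task.f_in, match="rates",
        )
        assert res.history.val_mae[-1] < res.history.val_mae[0]


class TestPredict:
    def test_perfect_and_offset_readouts(self):
        params, _ = init_rate_network(
            5, "nofeedback_esn", gain=0.0, dims=(1, 1), seed=0,
            w_out_init="zeros",
        )
        params.w_in[:] = 0
        task = TaskData(f_in=np.zeros((20, 1)), f_out=np.zeros((20, 1)), dt=1.0)
        _, mae = predict(params, task)
        assert mae == 0.0
        task_off = TaskData(
            f_in=np.zeros((20, 1)), f_out=0.5 * np.ones((20, 1)), dt=1.0
        )
        _, mae = predict(params, task_off)
        assert mae == pytest.approx(0.5)

    def test_mae_invariant_under_time_permutation(self, rng):
        z = rng.normal(size=(30, 2))
        f = rng.normal(size=(30, 2))
        perm = rng.permutation(30)
        assert np.mean(np.abs(z - f)) == pytest.approx(
            np.mean(np.abs(z[perm] - f[perm]))
        )
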