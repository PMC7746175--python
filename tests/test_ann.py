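import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cervinet.ann import (
    NetArchitecture,
    NetModel,
    TrainConfig,
    forward,
    init_model,
    jacobian,
    load_model,
    mse,
    save_model,
    train_lm,
)


def finite_difference_jacobian(model, x, eps=1e-6):
    theta = model.flatten()
    J = np.empty((x.shape[0], theta.size))
    for k in range(theta.size):
        plus, minus = theta.copy(), theta.copy()
        plus[k] += eps
        minus[k] -= eps
        J[:, k] = (
            forward(model.with_params(plus), x) - forward(model.with_params(minus), x)
        ) / (2 * eps)
    return J


class TestForward:
    def test_zero_parameters_give_zero_output(self):
        arch = NetArchitecture(n_inputs=4, hidden_layers=(3,))
        model = init_model(arch, seed=0).with_params(np.zeros(arch.n_params))
        x = np.random.default_rng(0).normal(size=(7, 4))
        np.testing.assert_allclose(forward(model, x), 0.0)

    def test_constant_network_outputs_its_bias(self):
        arch = NetArchitecture(n_inputs=4, hidden_layers=(3,))
        model = init_model(arch, seed=0).with_params(np.zeros(arch.n_params))
        theta = model.flatten()
        theta[-1] = 7.5  # output bias is the last parameter
        model = model.with_params(theta)
        x = np.random.default_rng(1).normal(size=(5, 4))
        np.testing.assert_allclose(forward(model, x), 7.5)

    def test_hand_computed_single_neuron_chain(self):
        arch = NetArchitecture(n_inputs=1, hidden_layers=(1,))
        model = NetModel(
            arch,
            weights=[np.array([[0.7]]), np.array([[1.3]])],
            biases=[np.array([-0.2]), np.array([0.4])],
        )
        x = 0.9
        expected = 1.3 * np.tanh(0.7 * x - 0.2) + 0.4
        assert forward(model, [x]) == pytest.approx(expected, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        model = init_model(NetArchitecture(n_inputs=3, hidden_layers=(2,)), seed=0)
        with pytest.raises(ValueError):
            forward(model, np.zeros(4))


class TestJacobian:
    @pytest.mark.parametrize(
        "hidden", [(1,), (5,), (2, 5), (5, 2), (2, 2)], ids=str
    )
    def test_matches_finite_differences(self, hidden):
        arch = NetArchitecture(n_inputs=3, hidden_layers=hidden)
        model = init_model(arch, seed=3)
        x = np.random.default_rng(7).normal(size=(6, 3))
        np.testing.assert_allclose(
            jacobian(model, x),
            finite_difference_jacobian(model, x),
            rtol=1e-6,
            atol=1e-8,
        )

    def test_duplicate_samples_duplicate_rows(self):
        model = init_model(NetArchitecture(n_inputs=2, hidden_layers=(3,)), seed=0)
        x = np.array([[0.5, -1.0], [0.5, -1.0]])
        J = jacobian(model, x)
        np.testing.assert_array_equal(J[0], J[1])

    def test_output_bias_column_is_one(self):
        model = init_model(NetArchitecture(n_inputs=2, hidden_layers=(3,)), seed=0)
        J = jacobian(model, np.zeros((1, 2)))
        assert J[0, -1] == pytest.approx(1.0)


class TestTrainLM:
    def test_gauss_newton_step_solves_linear_least_squares(self):
        # a purely linear model: one LM step with vanishing damping is the
        # normal-equations solution, here the exact interpolant w=2, b=0
        arch = NetArchitecture(n_inputs=1, hidden_layers=())
        model = NetModel(arch, [np.zeros((1, 1))], [np.zeros(1)])
        trained, _ = train_lm(
            model,
            np.array([[1.0], [2.0]]),
            np.array([2.0, 4.0]),
            TrainConfig(lambda_init=1e-12, max_epochs=1),
        )
        assert trained.weights[0][0, 0] == pytest.approx(2.0, abs=1e-8)
        assert trained.biases[0][0] == pytest.approx(0.0, abs=1e-8)

    def test_ols_equivalence_on_random_linear_problems(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            n, p = 30, 4
            x = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            beta = np.linalg.lstsq(np.column_stack([x, np.ones(n)]), y, rcond=None)[0]
            arch = NetArchitecture(n_inputs=p, hidden_layers=())
            model = NetModel(arch, [np.zeros((1, p))], [np.zeros(1)])
            trained, _ = train_lm(
                model, x, y, TrainConfig(lambda_init=1e-12, max_epochs=1)
            )
            np.testing.assert_allclose(trained.weights[0][0], beta[:p], atol=1e-7)
            np.testing.assert_allclose(trained.biases[0][0], beta[p], atol=1e-7)

    def test_exact_initial_fit_leaves_model_unchanged(self):
        arch = NetArchitecture(n_inputs=1, hidden_layers=())
        model = NetModel(arch, [np.array([[3.0]])], [np.array([1.0])])
        x = np.array([[0.0], [1.0], [2.0]])
        y = 3.0 * x[:, 0] + 1.0
        trained, history = train_lm(model, x, y, TrainConfig(max_epochs=50))
        assert history == [0.0]
        np.testing.assert_array_equal(trained.weights[0], model.weights[0])

    def test_learns_sine(self):
        x = np.linspace(-3, 3, 50)[:, None]
        y = np.sin(x[:, 0])
        model = init_model(NetArchitecture(n_inputs=1, hidden_layers=(8,)), seed=0)
        _, history = train_lm(model, x, y, TrainConfig(max_epochs=200))
        assert history[-1] < 1e-3

    def test_history_non_increasing(self):
        x = np.linspace(-2, 2, 30)[:, None]
        y = x[:, 0] ** 2
        model = init_model(NetArchitecture(n_inputs=1, hidden_layers=(4,)), seed=1)
        _, history = train_lm(model, x, y, TrainConfig(max_epochs=60))
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_bit_reproducible(self):
        x = np.random.default_rng(5).normal(size=(40, 3))
        y = x @ np.array([1.0, -2.0, 0.5]) + 0.3 * np.sin(x[:, 0])
        runs = []
        for _ in range(2):
            model = init_model(NetArchitecture(n_inputs=3, hidden_layers=(4,)), seed=9)
            trained, hist = train_lm(model, x, y, TrainConfig(max_epochs=30))
            runs.append((trained.flatten(), hist))
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        assert runs[0][1] == runs[1][1]


class TestMse:
    def test_identity_zero(self):
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_known_value(self):
        assert mse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(12.5)

    def test_translation_invariance(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([0.5, 2.5, 2.0])
        assert mse(a + 7, b + 7) == pytest.approx(mse(a, b))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse([1.0], [1.0, 2.0])


def test_model_json_round_trip(tmp_path):
    model = init_model(NetArchitecture(n_inputs=18, hidden_layers=(10,)), seed=4)
    path = tmp_path / "model.json"
    save_model(model, path, train_config=TrainConfig(), zscore_params={"mean": [0.0]})
    back = load_model(path)
    x = np.random.default_rng(2).normal(size=(3, 18))
    np.testing.assert_array_equal(forward(back, x), forward(model, x))


@settings(deadline=None, max_examples=25)
@given(
    widths=st.lists(st.integers(min_value=1, max_value=5), min_size=1, max_size=2),
    seed=st.integers(min_value=0, max_value=1000),
)
def test_jacobian_property_random_architectures(widths, seed):
    arch = NetArchitecture(n_inputs=2, hidden_layers=tuple(widths))
    model = init_model(arch, seed=seed)
    x = np.random.default_rng(seed).normal(size=(4, 2))
    np.testing.assert_allclose(
        jacobian(model, x),
        finite_difference_jacobian(model, x),
        rtol=2e-6,
        atol=1e-7,
    )
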