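import numpy as np
import pytest
from scipy.stats import multinomial

from cleavenet.models import (ArchitectureConfig, BiasFactorizedModel,
                              ProfileCountModel, ProfilePrediction, combine,
                              combined_loss, default_lambda, estimate_gamma,
                              mnll_loss, mse_log_counts, receptive_field)
from cleavenet.nn import SeqCNN, one_hot, softmax


# ---------------------------------------------------------------------------
# receptive field
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("layers,expected", [(8, 1041), (4, 81), (0, 21)])
def test_receptive_field_printed_architectures(layers, expected):
    cfg = ArchitectureConfig(first_conv_width=21, n_dilated_layers=layers,
                             dilated_width=3, dilation_base=2,
                             input_len=2114, output_len=1000)
    assert receptive_field(cfg) == expected


def test_receptive_field_degenerate():
    cfg = ArchitectureConfig(first_conv_width=1, n_dilated_layers=0,
                             input_len=100, output_len=50)
    assert receptive_field(cfg) == 1


def test_receptive_field_matches_gradient_support():
    """The calculator agrees with the empirically measured span of nonzero
    input gradient around an output position, for a small random net."""
    cfg = ArchitectureConfig(n_filters=4, first_conv_width=7,
                             n_dilated_layers=2, dilated_width=3,
                             dilation_base=2, profile_head_width=1,
                             input_len=201, output_len=201)
    net = SeqCNN(cfg, np.random.default_rng(0), dtype=np.float64)
    # absolute-valued weights + positive input keep every ReLU active, so
    # the gradient support is exactly the architectural connectivity
    for k, v in net.params.items():
        net.params[k] = np.abs(v) + 1e-3
    x = np.full((1, cfg.input_len, 4), 0.5)
    _, _, cache = net.forward(x, want_cache=True)
    dlogits = np.zeros((1, cfg.output_len))
    dlogits[0, cfg.output_len // 2] = 1.0
    _, dx = net.backward(cache, dlogits, np.zeros(1), need_dx=True)
    support = np.flatnonzero(np.abs(dx[0]).sum(axis=1) > 0)
    measured = support[-1] - support[0] + 1
    assert measured == receptive_field(cfg)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def test_mnll_trivial_cases():
    assert mnll_loss([1, 1], [0.5, 0.5]) == pytest.approx(-np.log(0.5))
    assert mnll_loss([5, 0], [1.0, 0.0]) == pytest.approx(0.0)


def test_mnll_matches_independent_pmf_oracle():
    rng = np.random.default_rng(0)
    for _ in range(100):
        L = 20
        p = rng.dirichlet(np.ones(L))
        k = rng.multinomial(int(rng.integers(1, 200)), p)
        oracle = -multinomial.logpmf(k, n=k.sum(), p=p)
        assert mnll_loss(k, p) == pytest.approx(oracle, abs=1e-9)


def test_mnll_minimized_by_empirical_distribution():
    rng = np.random.default_rng(1)
    for _ in range(20):
        k = rng.integers(0, 30, size=12).astype(float)
        if k.sum() == 0:
            continue
        best = mnll_loss(k, k / k.sum())
        q = rng.dirichlet(np.ones(12))
        assert mnll_loss(k, q) >= best - 1e-12


def test_mse_log_counts():
    assert mse_log_counts(10, 10) == 0.0
    assert mse_log_counts(np.e - 1, 0) == pytest.approx(1.0)
    rng = np.random.default_rng(2)
    a, b = rng.uniform(0, 1000, 2)
    assert mse_log_counts(a, b) == pytest.approx(
        (np.log(1 + a) - np.log(1 + b)) ** 2)


def test_combined_loss_arithmetic_and_lambda_rule():
    k = np.array([3.0, 1.0, 0.0, 2.0])
    logits = np.array([0.1, -0.2, 0.3, 0.0])
    pred = ProfilePrediction(logits=logits, log_total=np.log1p(6.0))
    # lambda = 0 reduces to the MNLL alone
    assert combined_loss(k, pred, 0.0) == pytest.approx(
        mnll_loss(k, softmax(logits)))
    # mnll + lambda * mse by hand
    pred2 = ProfilePrediction(logits=logits, log_total=np.log1p(12.0))
    lam = 0.5
    expected = mnll_loss(k, softmax(logits)) + lam * mse_log_counts(6.0, 12.0)
    assert combined_loss(k, pred2, lam) == pytest.approx(expected)
    # the lambda default: median validation totals / 10
    assert default_lambda([50, 100, 200]) == pytest.approx(10.0)


def test_estimate_gamma():
    obs = np.array([10.0, 20.0, 40.0])
    assert estimate_gamma(np.log1p(obs), obs) == pytest.approx(1.0)
    assert estimate_gamma(np.log1p(obs) - 1.0, obs) == pytest.approx(
        np.exp(-1.0))
    rng = np.random.default_rng(3)
    b = rng.uniform(1, 5, 10)
    o = rng.uniform(1, 500, 10)
    assert estimate_gamma(b, o) == pytest.approx(
        np.exp(np.mean(b - np.log1p(o))))


# ---------------------------------------------------------------------------
# factorized combination
# ---------------------------------------------------------------------------

def test_softmax_of_sum_is_normalized_product_of_softmaxes():
    rng = np.random.default_rng(4)
    a = rng.normal(size=500)
    b = rng.normal(size=500)
    lhs = softmax(a + b)
    prod = softmax(a) * softmax(b)
    rhs = prod / prod.sum()
    assert np.abs(lhs - rhs).max() < 1e-9


def test_combine_uniform_bias_and_zero_gamma():
    rng = np.random.default_rng(5)
    tf = ProfilePrediction(logits=rng.normal(size=50), log_total=np.array(4.0))
    flat = ProfilePrediction(logits=np.zeros(50), log_total=np.array(2.0))
    fp = combine(tf, flat, gamma=0.0)
    assert np.allclose(fp.combined.probabilities, tf.probabilities)
    assert fp.combined.log_total == pytest.approx(float(tf.log_total))
    assert fp.combined.probabilities.sum() == pytest.approx(1.0, abs=1e-6)


def test_combine_count_rules():
    tf = ProfilePrediction(logits=np.zeros(4), log_total=np.array(3.0))
    bias = ProfilePrediction(logits=np.zeros(4), log_total=np.array(1.0))
    add = combine(tf, bias, gamma=0.5, count_combine="add")
    assert add.combined.log_total == pytest.approx(3.5)
    lse = combine(tf, bias, gamma=0.5, count_combine="logsumexp")
    assert lse.combined.log_total == pytest.approx(
        np.log(np.exp(3.0) + 0.5 * np.exp(1.0)))


# ---------------------------------------------------------------------------
# estimator behaviour
# ---------------------------------------------------------------------------

def _toy_data(n=24, input_len=150, output_len=60, seed=0):
    rng = np.random.default_rng(seed)
    X = np.zeros((n, input_len, 4), dtype=np.float32)
    idx = rng.integers(0, 4, size=(n, input_len))
    X[np.arange(n)[:, None], np.arange(input_len)[None, :], idx] = 1.0
    y = rng.poisson(3.0, size=(n, output_len)).astype(np.float64)
    return X, y


def _tiny_params(**kw):
    p = dict(n_filters=4, first_conv_width=5, n_dilated_layers=1,
             profile_head_width=5, input_len=150, output_len=60,
             max_epochs=2, batch_size=8, random_state=0)
    p.update(kw)
    return p


def test_fit_is_deterministic_given_seed():
    X, y = _toy_data()
    a = ProfileCountModel(**_tiny_params()).fit(X, y)
    b = ProfileCountModel(**_tiny_params()).fit(X, y)
    assert a.best_val_loss_ == b.best_val_loss_
    for k in a.net_.params:
        assert np.array_equal(a.net_.params[k], b.net_.params[k])
    assert np.array_equal(a.predict(X), b.predict(X))


def test_forward_rejects_wrong_length():
    X, y = _toy_data()
    m = ProfileCountModel(**_tiny_params()).fit(X, y)
    with pytest.raises(ValueError, match="shorter"):
        m.predict(X[:, :100, :])


def test_bias_weights_frozen_during_residual_training():
    X, y = _toy_data(n=30)
    bias = ProfileCountModel(**_tiny_params()).fit(X, y)
    before = {k: v.copy() for k, v in bias.net_.params.items()}
    fact = BiasFactorizedModel(bias_model=bias, **_tiny_params(max_epochs=3))
    fact.fit(X, y)
    for k, v in before.items():
        assert np.array_equal(v, bias.net_.params[k]), \
            f"bias parameter {k} changed during residual training"
    assert fact._bias_checksum_before_ == fact._bias_checksum_after_


def test_corrected_prediction_ignores_bias_submodel():
    X, y = _toy_data(n=30)
    bias = ProfileCountModel(**_tiny_params()).fit(X, y)
    fact = BiasFactorizedModel(bias_model=bias, **_tiny_params(max_epochs=2))
    fact.fit(X, y)
    corrected = fact.predict_logits(X, corrected=True)
    # corrupting the bias weights must not change the corrected output
    bias.net_.params["conv0_W"] += 1.0
    assert np.array_equal(corrected, fact.predict_logits(X, corrected=True))
    assert not np.array_equal(corrected, fact.predict_logits(X))
    bias.net_.params["conv0_W"] -= 1.0


def test_combined_probabilities_normalized():
    X, y = _toy_data(n=20)
    bias = ProfileCountModel(**_tiny_params()).fit(X, y)
    fact = BiasFactorizedModel(bias_model=bias, **_tiny_params()).fit(X, y)
    probs = fact.predict_profile(X[:5])
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


def test_early_stopping_restores_best_checkpoint():
    X, y = _toy_data(n=40)
    m = ProfileCountModel(**_tiny_params(max_epochs=12, patience=3))
    m.fit(X, y)
    assert m.best_val_loss_ == pytest.approx(m.history_["val_loss"].min())
    assert m.best_epoch_ == int(m.history_["val_loss"].idxmin())


def test_checkpoint_roundtrip(tmp_path):
    X, y = _toy_data()
    m = ProfileCountModel(**_tiny_params()).fit(X, y)
    m.save(str(tmp_path / "m"))
    back = ProfileCountModel.load(str(tmp_path / "m"))
    assert np.array_equal(m.predict(X), back.predict(X))


def test_sklearn_params_roundtrip():
    m = ProfileCountModel(n_filters=12)
    params = m.get_params()
    assert params["n_filters"] == 12
    m.set_params(n_filters=6)
    assert m.get_params()["n_filters"] == 6
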