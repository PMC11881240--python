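"""GNN primitives, training behavior, metrics and cross-validation."""

import numpy as np
import pytest

from herbnet import (
    ModelConfig,
    cross_validate,
    forward,
    mse_loss,
    r_squared,
    sage_layer,
    train,
)
from herbnet.errors import DivergenceError, HerbnetError
from herbnet.model import (
    R2_UNDEFINED,
    CVResult,
    _stratified_folds,
    cv_results_frame,
    default_grid,
    init_params,
    loss_and_grads,
    save_model,
    load_model,
)
from herbnet.synth import block_assignment
from conftest import SMALL_CFG


# ---------------------------------------------------------------------------
# sage_layer
# ---------------------------------------------------------------------------


def test_sage_layer_zero_weights_give_zero_output(rng):
    x = rng.normal(size=(5, 3))
    out = sage_layer(x, [[1], [0, 2], [1], [4], [3]], np.zeros((4, 6)))
    assert out.shape == (5, 4)
    assert np.all(out == 0.0)


def test_sage_layer_two_node_path_by_hand():
    x = np.array([[1.0, 2.0], [3.0, 4.0]])
    w = np.array([[1.0, 0, 0, 0], [0, 0, 1.0, 0]])  # picks (self[0], neighbor[0])
    out = sage_layer(x, [[1], [0]], w)
    np.testing.assert_allclose(out, [[1.0, 3.0], [3.0, 1.0]])


def test_sage_layer_matches_per_node_loop(rng):
    """Vectorized layer equals a naive per-node loop on random graphs."""
    for _ in range(5):
        n, d_in, d_out = int(rng.integers(3, 50)), 4, 6
        x = rng.normal(size=(n, d_in))
        nbrs = [
            list(rng.choice(n, size=rng.integers(0, n), replace=False))
            for _ in range(n)
        ]
        w = rng.normal(size=(d_out, 2 * d_in))
        b = rng.normal(size=d_out)
        got = sage_layer(x, nbrs, w, b)
        for v in range(n):
            agg = x[nbrs[v]].mean(axis=0) if nbrs[v] else np.zeros(d_in)
            expect = np.maximum(w @ np.concatenate([x[v], agg]) + b, 0.0)
            np.testing.assert_allclose(got[v], expect, atol=1e-6)


def test_sage_layer_dimension_mismatch():
    with pytest.raises(ValueError, match="dim"):
        sage_layer(np.ones((3, 2)), [[1], [0], [0]], np.ones((2, 6)))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def test_mse_closed_forms(rng):
    assert mse_loss([1.0, 2.0], [1.0, 2.0]) == 0.0
    assert mse_loss((1, 2), (0, 0)) == pytest.approx(2.5)
    y, yh = rng.normal(size=20), rng.normal(size=20)
    loop = sum((a - b) ** 2 for a, b in zip(y, yh)) / 20
    assert mse_loss(y, yh) == pytest.approx(loop)
    with pytest.raises(ValueError):
        mse_loss([], [])
    with pytest.raises(ValueError):
        mse_loss([1.0], [1.0, 2.0])


def test_r_squared_closed_forms(rng):
    y = np.array([1.0, 2.0, 3.0, 4.0])
    assert r_squared(y, y) == pytest.approx(1.0)
    assert r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)
    assert r_squared(np.ones(4), np.zeros(4)) is R2_UNDEFINED  # SS_tot = 0
    yh = rng.normal(size=10)
    yy = rng.normal(size=10)
    direct = 1 - np.sum((yy - yh) ** 2) / np.sum((yy - yy.mean()) ** 2)
    assert r_squared(yy, yh) == pytest.approx(direct)


def test_r_squared_never_exceeds_one(rng):
    for _ in range(20):
        y = rng.normal(size=8)
        yh = rng.normal(size=8)
        r2 = r_squared(y, yh)
        assert r2 is R2_UNDEFINED or r2 <= 1.0


# ---------------------------------------------------------------------------
# forward / gradients
# ---------------------------------------------------------------------------


def test_forward_is_deterministic_and_symmetric(small_model, small_graph):
    a, b = small_graph.herb_ids[0], small_graph.herb_ids[3]
    y1 = forward(small_model, small_graph, (a, b))
    y2 = forward(small_model, small_graph, (a, b))
    assert y1 == y2
    assert forward(small_model, small_graph, (b, a)) == pytest.approx(y1)
    assert y1 >= 0.0


def test_forward_unknown_herb_raises(small_model, small_graph):
    with pytest.raises(LookupError, match="nope"):
        forward(small_model, small_graph, ("nope", small_graph.herb_ids[0]))


def test_zeroed_output_layer_predicts_constant(small_model, small_graph):
    """With the MLP output layer zeroed, the softplus head pins every pair to
    the same constant softplus(0) = ln 2, independent of the pair."""
    import copy

    m = copy.deepcopy(small_model)
    m.params["mlp_W2"][:] = 0.0
    m.params["mlp_b2"][:] = 0.0
    pairs = np.array([[0, 1], [2, 5], [1, 7]])
    np.testing.assert_allclose(m.predict_pairs(small_graph, pairs), np.log(2.0))


def test_analytic_gradients_match_finite_differences(small_graph, small_labels):
    cfg = ModelConfig(hidden_channels=6, epochs=1, seed=4, mlp_hidden=5)
    p = init_params(small_graph, cfg, np.random.default_rng(0))
    from herbnet.model import _pairs_to_indices

    pairs, y = _pairs_to_indices(small_graph, small_labels[:15])
    _, grads, _ = loss_and_grads(p, small_graph, pairs, y, n_layers=2)
    rng = np.random.default_rng(1)
    eps = 1e-6
    for key in ("mlp_W1", "W_self_0_hh", "W_nbr_1_mh", "emb_herb", "proj_fp"):
        arr = p[key]
        idx = tuple(int(rng.integers(s)) for s in arr.shape)
        orig = arr[idx]
        arr[idx] = orig + eps
        lp, _, _ = loss_and_grads(p, small_graph, pairs, y, n_layers=2)
        arr[idx] = orig - eps
        lm, _, _ = loss_and_grads(p, small_graph, pairs, y, n_layers=2)
        arr[idx] = orig
        assert grads[key][idx] == pytest.approx((lp - lm) / (2 * eps), abs=1e-5, rel=1e-4)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def test_training_reduces_loss_and_is_seed_reproducible(small_graph, small_labels):
    cfg = ModelConfig(hidden_channels=16, epochs=25, seed=5)
    m1 = train(small_graph, small_labels, cfg)
    m2 = train(small_graph, small_labels, cfg)
    assert m1.training_log == m2.training_log
    assert m1.training_log[-1] < m1.training_log[0]
    # epoch-averaged loss over the last 10 epochs below the first 10
    assert np.mean(m1.training_log[-10:]) < np.mean(m1.training_log[:10])
    for k in m1.params:
        np.testing.assert_array_equal(m1.params[k], m2.params[k])


def test_constant_labels_are_learned(small_graph, small_labels):
    from herbnet import PairLabel

    const = [PairLabel(l.pair, l.n_ij, 2.0) for l in small_labels]
    cfg = ModelConfig(hidden_channels=16, learning_rate=1e-2, epochs=60, seed=1,
                      negative_pair_ratio=0.0)
    m = train(small_graph, const, cfg)
    assert m.training_log[-1] < 0.1 * m.training_log[0]


def test_training_requires_enough_pairs(small_graph, small_labels):
    with pytest.raises(HerbnetError):
        train(small_graph, small_labels[:5], ModelConfig(epochs=1))


def test_non_finite_loss_raises_divergence_error(small_graph, small_labels, monkeypatch):
    import herbnet.model as mod

    def bad_init(g, cfg, rng):
        p = init_params(g, cfg, rng)
        p["emb_herb"][0, 0] = np.inf
        return p

    monkeypatch.setattr(mod, "init_params", bad_init)
    with pytest.raises(DivergenceError) as exc:
        train(small_graph, small_labels, ModelConfig(hidden_channels=8, epochs=3))
    assert exc.value.epoch == 0


def test_model_serialization_round_trip(tmp_path, small_model):
    path = tmp_path / "m.npz"
    save_model(small_model, path)
    back = load_model(path)
    assert back.config == small_model.config
    assert back.training_log == small_model.training_log
    for k in small_model.params:
        np.testing.assert_array_equal(back.params[k], small_model.params[k])


# ---------------------------------------------------------------------------
# parameter recovery on the planted blocks
# ---------------------------------------------------------------------------


def test_within_block_pairs_score_higher(small_model, small_graph):
    blocks = block_assignment(SMALL_CFG)
    from herbnet import predict_all_pairs

    preds = predict_all_pairs(small_model, small_graph)
    within = [p.y_hat for p in preds if blocks[p.pair[0]] == blocks[p.pair[1]]]
    between = [p.y_hat for p in preds if blocks[p.pair[0]] != blocks[p.pair[1]]]
    assert np.mean(within) > np.mean(between)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def test_cv_requires_at_least_two_folds(small_graph, small_labels):
    with pytest.raises(ValueError):
        cross_validate(small_graph, small_labels, [ModelConfig(epochs=1)], k=1)


def test_cv_single_config_smoke(small_graph, small_labels):
    cfg = ModelConfig(hidden_channels=16, epochs=10, seed=2)
    res = cross_validate(small_graph, small_labels, [cfg], k=5, seed=9)
    assert len(res) == 1
    assert np.isfinite(res[0].mse) and res[0].mse >= 0
    assert len(res[0].fold_mse) == 5


def test_fold_partition_is_seed_deterministic(rng):
    y = rng.normal(size=57)
    f1 = _stratified_folds(y, 5, np.random.default_rng(3))
    f2 = _stratified_folds(y, 5, np.random.default_rng(3))
    np.testing.assert_array_equal(f1, f2)
    # stratification: every fold non-empty, sizes near-balanced
    sizes = np.bincount(f1, minlength=5)
    assert sizes.min() >= 1 and sizes.max() - sizes.min() <= 1


def test_diverged_fit_reports_undefined_r2(small_graph, small_labels, monkeypatch):
    import herbnet.model as mod

    def always_diverge(*a, **kw):
        raise DivergenceError(0)

    monkeypatch.setattr(mod, "train", always_diverge)
    res = cross_validate(small_graph, small_labels, [ModelConfig(epochs=1)], k=3)
    assert res[0].diverged and res[0].r2 is R2_UNDEFINED


def test_cv_frame_renders_undefined_marker():
    rows = [
        CVResult(config=ModelConfig(hidden_channels=64, learning_rate=1e-2),
                 mse=1.25, r2=None, diverged=True),
        CVResult(config=ModelConfig(hidden_channels=64, learning_rate=1e-3),
                 mse=0.15, r2=0.83),
    ]
    df = cv_results_frame(rows)
    assert list(df.columns) == ["hidden_channels", "lr", "mse", "r2"]
    assert df.loc[0, "r2"] == "/"
    assert df.loc[1, "r2"] == pytest.approx(0.83)


def test_default_grid_shape():
    grid = default_grid(epochs=5)
    assert len(grid) == 12
    assert {c.hidden_channels for c in grid} == {64, 128, 256, 512}
    assert {c.learning_rate for c in grid} == {1e-4, 1e-3, 1e-2}
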