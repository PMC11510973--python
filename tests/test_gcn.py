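import numpy as np
import pytest

from neurofuse.gcn import (
    GCNConfig,
    ModelError,
    evaluate_cv,
    graph_conv,
    grid_search,
    make_model,
    normalize_adjacency,
    prepare_batch,
    topk_pool,
    train,
)
from neurofuse.graphs import GraphSample

FAST = GCNConfig(epochs=40)


def random_fused_sample(rng, y=None):
    names = tuple(f"E{i}" for i in range(14)) + tuple(f"Ch{i}" for i in range(1, 7))
    a = (rng.random((20, 20)) < 0.3).astype(int)
    a = np.triu(a, 1)
    a = a + a.T
    return GraphSample(rng.standard_normal((20, 13)), a, names,
                       int(rng.integers(2)) if y is None else y, "fused:beta")


# ---------------------------------------------------------------------------
# primitives

def test_graph_conv_isolated_node_identity():
    x = np.array([[1.0, 2.0, 3.0]])
    a = np.zeros((1, 1))
    out = graph_conv(x, a, np.eye(3))
    np.testing.assert_allclose(out, x)  # self-loop only, unit normalization


def test_graph_conv_permutation_equivariance():
    rng = np.random.default_rng(0)
    x = rng.standard_normal((6, 4))
    a = (rng.random((6, 6)) < 0.5).astype(float)
    a = np.triu(a, 1)
    a = a + a.T
    w = rng.standard_normal((4, 5))
    perm = rng.permutation(6)
    out = graph_conv(x, a, w)
    out_p = graph_conv(x[perm], a[np.ix_(perm, perm)], w)
    np.testing.assert_allclose(out_p, out[perm], atol=1e-12)


def test_graph_conv_matches_dense_oracle():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((5, 3))
    a = np.array([[0, 1, 0, 0, 1], [1, 0, 1, 0, 0], [0, 1, 0, 1, 0],
                  [0, 0, 1, 0, 1], [1, 0, 0, 1, 0]], dtype=float)
    w = rng.standard_normal((3, 2))
    at = a + np.eye(5)
    d = np.diag(1 / np.sqrt(at.sum(1)))
    expected = np.maximum(d @ at @ d @ x @ w, 0)
    np.testing.assert_allclose(graph_conv(x, a, w), expected, atol=1e-6)


def test_topk_pool_contracts():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((6, 4))
    a = (rng.random((6, 6)) < 0.5).astype(float)
    p = rng.standard_normal(4)

    x_all, a_all, idx_all = topk_pool(x, a, 6, p)
    np.testing.assert_array_equal(idx_all, np.arange(6))  # nodes unchanged
    s = x @ (p / np.linalg.norm(p))
    np.testing.assert_allclose(x_all, x * np.tanh(s)[:, None])

    x1, a1, idx1 = topk_pool(x, a, 1, p)
    assert idx1[0] == np.argmax(s)
    assert x1.shape == (1, 4) and a1.shape == (1, 1)

    _, _, idx3 = topk_pool(x, a, 3, p)
    np.testing.assert_array_equal(np.sort(idx3),
                                  np.sort(np.argsort(-s)[:3]))


# ---------------------------------------------------------------------------
# forward pass

def test_forward_trace_architecture():
    rng = np.random.default_rng(3)
    samples = [random_fused_sample(rng) for _ in range(3)]
    model = make_model(samples, seed=0)
    batch = prepare_batch(samples, model.split)
    trace = []
    logits, _ = model.forward(batch, trace=trace)
    assert trace == [(20, 30), (20, 60), (10, 60), (10, 90), (1, 90), (1, 2)]
    assert logits.shape == (3, 2)
    assert np.all(np.isfinite(logits))
    probs = np.exp(logits) / np.exp(logits).sum(1, keepdims=True)
    np.testing.assert_allclose(probs.sum(1), 1.0)


def test_forward_node_permutation_invariance():
    rng = np.random.default_rng(4)
    sample = random_fused_sample(rng)
    model = make_model([sample], seed=1)
    logits, _ = model.forward(prepare_batch([sample], model.split))

    # permute within each modality block (blocks must stay contiguous)
    perm = np.concatenate([rng.permutation(14), 14 + rng.permutation(6)])
    permuted = GraphSample(sample.node_features[perm],
                           sample.adjacency[np.ix_(perm, perm)],
                           tuple(sample.node_names[i] for i in perm),
                           sample.y, sample.modality)
    logits_p, _ = model.forward(prepare_batch([permuted], model.split))
    np.testing.assert_allclose(logits_p, logits, atol=1e-10)


def test_analytic_gradients_match_finite_differences():
    rng = np.random.default_rng(5)
    samples = [random_fused_sample(rng, y=i % 2) for i in range(4)]
    model = make_model(samples, seed=2)
    batch = prepare_batch(samples, model.split)
    wd = 5e-4
    _, grads = model.loss_and_grads(batch, weight_decay=wd)
    eps = 1e-5
    check_rng = np.random.default_rng(6)
    for key, w in model.params.items():
        flat = w.ravel()
        for _ in range(4):
            i = int(check_rng.integers(flat.size))
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = model.loss_and_grads(batch, weight_decay=wd)
            flat[i] = orig - eps
            lm, _ = model.loss_and_grads(batch, weight_decay=wd)
            flat[i] = orig
            fd = (lp - lm) / (2 * eps)
            an = grads[key].ravel()[i]
            assert an == pytest.approx(fd, rel=1e-4, abs=1e-8), key


# ---------------------------------------------------------------------------
# training and evaluation

def test_training_deterministic_and_learns(tiny_samples):
    fused = [s for s in tiny_samples if s.modality == "fused:beta"]
    # replicate the four segments to give the optimizer a few batches
    data = fused * 4
    m1, h1 = train(data, FAST)
    m2, h2 = train(data, FAST)
    assert h1[-1] == h2[-1]  # same seed, identical final loss
    assert h1[-1] < h1[0]
    assert np.mean(m1.predict(data) == [s.y for s in data]) >= 0.9


def test_single_class_dataset_rejected(tiny_samples):
    fused = [s for s in tiny_samples if s.modality == "fused:beta" and s.y == 1]
    with pytest.raises(ModelError):
        train(fused * 3, FAST)


def test_unimodal_pool_sizes(tiny_samples):
    eeg = [s for s in tiny_samples if s.modality == "beta"]
    fn = [s for s in tiny_samples if s.modality == "fNIRS"]
    m_eeg = make_model(eeg, seed=0)
    m_fn = make_model(fn, seed=0)
    assert (m_eeg.n_nodes, m_eeg.k1) == (14, 7)
    assert (m_fn.n_nodes, m_fn.k1) == (6, 3)
    trace = []
    m_fn.forward(prepare_batch(fn, m_fn.split), trace=trace)
    assert trace == [(6, 30), (6, 60), (3, 60), (3, 90), (1, 90), (1, 2)]


def test_cv_stratification_and_metric_arithmetic(tiny_samples):
    rng = np.random.default_rng(7)
    samples = [random_fused_sample(rng, y=y)
               for y in [0] * 9 + [1] * 11]
    from sklearn.model_selection import StratifiedKFold
    y = np.array([s.y for s in samples])
    skf = StratifiedKFold(n_splits=4, shuffle=True, random_state=0)
    global_frac = y.mean()
    for _, te in skf.split(np.zeros_like(y), y):
        # fold class proportions within one sample of the global proportions
        assert abs(y[te].sum() - global_frac * len(te)) <= 1.0

    # binary F1 equals 2PR/(P+R) computed from a confusion matrix by hand
    truth = np.array([0, 0, 1, 1, 1, 0, 1])
    pred = np.array([0, 1, 1, 0, 1, 0, 1])
    tp = int(((truth == 1) & (pred == 1)).sum())
    fp = int(((truth == 0) & (pred == 1)).sum())
    fn = int(((truth == 1) & (pred == 0)).sum())
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    from sklearn.metrics import f1_score
    assert f1_score(truth, pred) == pytest.approx(
        2 * precision * recall / (precision + recall))


def test_all_positive_predictor_arithmetic():
    # degenerate classifier on the 61/75 class split
    truth = np.array([0] * 61 + [1] * 75)
    pred = np.ones_like(truth)
    from sklearn.metrics import precision_score, recall_score
    assert recall_score(truth, pred) == 1.0
    assert precision_score(truth, pred) == pytest.approx(75 / 136)


def test_evaluate_cv_requires_enough_samples(tiny_samples):
    fused = [s for s in tiny_samples if s.modality == "fused:beta"]
    with pytest.raises(ModelError):
        evaluate_cv(fused, FAST, folds=10)


def test_grid_search_selects_dominant_config():
    rng = np.random.default_rng(8)
    # linearly separable labels via a planted feature
    samples = []
    for i in range(16):
        s = random_fused_sample(rng, y=i % 2)
        feats = s.node_features.copy()
        feats[:, 0] = 3.0 * s.y + 0.1 * rng.standard_normal(20)
        samples.append(GraphSample(feats, s.adjacency, s.node_names, s.y,
                                   s.modality))
    base = GCNConfig(epochs=30)
    best, table = grid_search(samples, [base], folds=2)
    assert best == base and len(table) == 1

    crippled = GCNConfig(epochs=30, lr=0.0)  # cannot learn at all
    best, table = grid_search(samples, [crippled, base], folds=2)
    assert best == base
    assert len(table) == 2  # every evaluated combination is reported

    best_map, table = grid_search(samples, {"lr": [1e-3], "epochs": [30]},
                                  folds=2)
    assert best_map.lr == 1e-3 and best_map.epochs == 30
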