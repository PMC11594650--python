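"""Metrics, the training loop and the cross-validation / ablation drivers."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from priddg import DualBranchNetwork, TrainSpec, compute_metrics
from priddg.training import (
    ABLATION_GRIDS,
    make_splits,
    run_ablation,
    run_cv,
    train_model,
)


def _brute_force_metrics(y_true, y_pred):
    """Independent loop-based oracle for PCC / RMSE / MAE."""
    n = len(y_true)
    se = sum((p - t) ** 2 for t, p in zip(y_true, y_pred))
    ae = sum(abs(p - t) for t, p in zip(y_true, y_pred))
    mt = sum(y_true) / n
    mp = sum(y_pred) / n
    vt = sum((t - mt) ** 2 for t in y_true) / n
    vp = sum((p - mp) ** 2 for p in y_pred) / n
    cov = sum((t - mt) * (p - mp) for t, p in zip(y_true, y_pred)) / n
    pcc = None if vt == 0 or vp == 0 else cov / math.sqrt(vt * vp)
    return pcc, math.sqrt(se / n), ae / n


# -- metrics -----------------------------------------------------------------

def test_metrics_identity_prediction():
    y = np.array([0.5, -1.0, 2.0])
    m = compute_metrics(y, y)
    assert (m.pcc, m.rmse, m.mae) == (pytest.approx(1.0), 0.0, 0.0)


def test_metrics_shift_invariance_of_pcc():
    y = np.array([0.0, 1.0, 3.0])
    m = compute_metrics(y, y + 1.0)
    assert m.pcc == pytest.approx(1.0)
    assert m.rmse == pytest.approx(1.0)
    assert m.mae == pytest.approx(1.0)


def test_metrics_hand_computed_pair():
    m = compute_metrics([0.0, 0.0], [1.0, 3.0])
    assert m.mae == pytest.approx(2.0)
    assert m.rmse == pytest.approx(math.sqrt(5.0))
    assert m.pcc is None  # constant y_true: correlation undefined, not 0


def test_metrics_input_validation():
    with pytest.raises(ValueError):
        compute_metrics([1.0], [1.0])
    with pytest.raises(ValueError):
        compute_metrics([1.0, 2.0], [1.0, 2.0, 3.0])


@given(
    st.lists(st.floats(-100, 100, allow_nan=False, width=32), min_size=2, max_size=50),
    st.integers(0, 2**31 - 1),
)
def test_metrics_agree_with_brute_force_oracle(y_true, seed):
    rng = np.random.default_rng(seed)
    y_pred = [float(v) for v in rng.normal(size=len(y_true))]
    y_true = [float(v) for v in y_true]
    m = compute_metrics(y_true, y_pred)
    pcc, rmse, mae = _brute_force_metrics(y_true, y_pred)
    assert m.rmse == pytest.approx(rmse, rel=1e-10)
    assert m.mae == pytest.approx(mae, rel=1e-10)
    if pcc is None:
        assert m.pcc is None
    else:
        assert m.pcc == pytest.approx(pcc, rel=1e-9, abs=1e-12)
    assert m.mae <= m.rmse + 1e-12  # Jensen


# -- training loop -----------------------------------------------------------

def test_zero_learning_rate_is_a_no_op(small_features, small_features_config):
    cfg = dataclasses.replace(small_features_config, lr=0.0)
    net = DualBranchNetwork(cfg, seed=0)
    before = [p.data.copy() for p in net.parameters()]
    train_model(net, small_features.subset(range(16)), None, cfg,
                TrainSpec(batch_size=8, max_epochs=3, patience=None, seed=0))
    for b, p in zip(before, net.parameters()):
        assert np.array_equal(b, p.data)


def test_training_is_seed_reproducible(small_features, small_features_config):
    cfg = small_features_config
    states = []
    for _ in range(2):
        net = DualBranchNetwork(cfg, seed=5)
        train_model(net, small_features.subset(range(24)),
                    small_features.subset(range(24, 32)), cfg,
                    TrainSpec(batch_size=8, max_epochs=3, patience=2, seed=5))
        states.append(net.copy_state())
    for a, b in zip(*states):
        assert np.array_equal(a, b)


def test_training_requires_validation_for_early_stopping(small_features,
                                                         small_features_config):
    net = DualBranchNetwork(small_features_config, seed=0)
    with pytest.raises(ValueError, match="requires a validation set"):
        train_model(net, small_features.subset(range(8)), None,
                    small_features_config,
                    TrainSpec(batch_size=4, max_epochs=3, patience=1, seed=0))


def test_trainspec_constraints():
    with pytest.raises(ValueError):
        TrainSpec(batch_size=0)
    with pytest.raises(ValueError):
        TrainSpec(max_epochs=10, patience=10)


# -- split construction ------------------------------------------------------

def _dummy_features(n):
    from priddg.features import FeatureArrays

    return FeatureArrays(E=None, P=None, local_index=np.zeros(n, dtype=int),
                         y=np.zeros(n), records=[None] * n,
                         pair_keys=[(i,) for i in range(n)])


def test_cv3_partitions_630_into_10x63():
    data = _dummy_features(630)
    splits = make_splits(data, "cv3", repeats=1, seed=0)
    assert len(splits) == 10
    tests = [set(te.tolist()) for _, _, te in splits]
    assert all(len(t) == 63 for t in tests)
    union = set().union(*tests)
    assert union == set(range(630))
    for i in range(10):
        for j in range(i + 1, 10):
            assert not tests[i] & tests[j]
    # train/val/test of each fold partition the data
    for tr, va, te in splits:
        assert len(tr) + len(va) + len(te) == 630
        assert not set(tr.tolist()) & set(te.tolist())
        assert not set(va.tolist()) & set(te.tolist())


def test_cv1_split_cardinalities_on_315():
    """90/10 with 10% of the training portion for validation (floor rule)."""
    splits = make_splits(_dummy_features(315), "cv1", repeats=1, seed=0)
    tr, va, te = splits[0]
    assert len(te) == 31
    assert len(va) == 28
    assert len(tr) == 256


def test_cv2_split_cardinalities_on_315():
    (tr, va, te), = make_splits(_dummy_features(315), "cv2", repeats=1, seed=0)
    assert len(te) == 63
    assert len(va) == 25
    assert len(tr) == 227


def test_splits_are_seed_stable():
    data = _dummy_features(100)
    for strategy in ("cv1", "cv2", "cv3"):
        a = make_splits(data, strategy, repeats=3, seed=11)
        b = make_splits(data, strategy, repeats=3, seed=11)
        for (t1, v1, s1), (t2, v2, s2) in zip(a, b):
            assert np.array_equal(t1, t2) and np.array_equal(v1, v2)
            assert np.array_equal(s1, s2)
        c = make_splits(data, strategy, repeats=3, seed=12)
        assert any(not np.array_equal(s1, s2)
                   for (_, _, s1), (_, _, s2) in zip(a, c))


def test_pair_grouped_splits_keep_partners(small_features):
    splits = make_splits(small_features, "cv3", repeats=1, seed=2,
                         pair_grouping=True)
    for tr, va, te in splits:
        zones = {}
        for zone, idx in (("tr", tr), ("va", va), ("te", te)):
            for i in idx:
                key = small_features.pair_keys[i]
                assert zones.setdefault(key, zone) == zone


def test_unknown_strategy_rejected(small_features):
    with pytest.raises(ValueError, match="unknown CV strategy"):
        make_splits(small_features, "cv9", repeats=1, seed=0)


# -- cross-validation and ablation drivers -----------------------------------

FAST = TrainSpec(batch_size=16, max_epochs=2, patience=1, seed=0)


def test_run_cv_is_reproducible(small_features, small_features_config):
    a = run_cv(small_features, "cv2", small_features_config, FAST, seed=3, repeats=2)
    b = run_cv(small_features, "cv2", small_features_config, FAST, seed=3, repeats=2)
    assert a.to_dict() == b.to_dict()
    assert len(a.per_fold) == 2
    assert a.seeds == [3, 4]


def test_run_cv_reports_aggregates(small_features, small_features_config):
    rep = run_cv(small_features, "cv2", small_features_config, FAST, seed=1,
                 repeats=2)
    s = rep.summary()
    assert s["n_folds"] == 2
    assert s["rmse"] >= s["mae"] >= 0
    assert -1 <= s["pcc"] <= 1


def test_run_ablation_shares_splits_and_modes(small_features, small_features_config):
    grid = [("p", "p"), ("Ep", "m")]
    results = run_ablation(small_features, grid, small_features_config, FAST,
                           seed=2, strategy="cv2", repeats=1)
    assert set(results) == set(grid)
    # identical fold assignment: every configuration evaluated the same
    # number of samples per fold
    ns = {k: [m.n for m in rep.per_fold] for k, rep in results.items()}
    assert ns[("p", "p")] == ns[("Ep", "m")]


def test_run_ablation_full_model_matches_run_cv(small_features,
                                                small_features_config):
    """(Ep, m) is the default full model: identical report to plain CV."""
    results = run_ablation(small_features, [("Ep", "m")], small_features_config,
                           FAST, seed=4, strategy="cv2", repeats=1)
    direct = run_cv(small_features, "cv2", small_features_config, FAST, seed=4,
                    repeats=1)
    assert results[("Ep", "m")].to_dict() == direct.to_dict()


def test_run_ablation_rejects_unknown_mode(small_features, small_features_config):
    with pytest.raises(ValueError, match="unknown branch mode"):
        run_ablation(small_features, [("zz", "m")], small_features_config, FAST,
                     seed=0, repeats=1)
    with pytest.raises(ValueError, match="empty ablation grid"):
        run_ablation(small_features, [], small_features_config, FAST, seed=0,
                     repeats=1)


def test_ablation_grids_match_published_tables():
    assert ABLATION_GRIDS["encoder"] == [("p", "p"), ("Ep", "p"), ("p", "Ep"),
                                         ("Ep", "Ep")]
    assert ABLATION_GRIDS["conv"] == [("m", "p"), ("p", "m"), ("m", "m")]
    assert ABLATION_GRIDS["combined"][-1] == ("Ep", "m")
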