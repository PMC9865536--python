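import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from doaeeg.drsn import ModelConfig, TrainConfig
from doaeeg.evaluate import (
    STATES,
    Dataset,
    compute_metrics,
    kfold_by_subject,
    kfold_random,
    psi_to_state,
    run_experiment,
    standardize,
)

# --- state binning ---------------------------------------------------------


def test_state_bin_edges():
    assert psi_to_state(100) == "AW"
    assert psi_to_state(81) == "AW"
    assert psi_to_state(80) == "LA"
    assert psi_to_state(51) == "LA"
    assert psi_to_state(50) == "NA"
    assert psi_to_state(26) == "NA"
    assert psi_to_state(25) == "DA"
    assert psi_to_state(0) == "DA"


def test_state_invalid_input():
    for bad in (-1.0, 100.5, float("nan"), float("inf")):
        with pytest.raises(ValueError):
            psi_to_state(bad)


@settings(max_examples=50, deadline=None)
@given(st.floats(0.0, 100.0))
def test_state_total(psi):
    assert psi_to_state(psi) in STATES


# --- standardization -------------------------------------------------------


def test_standardize_stats():
    rng = np.random.default_rng(0)
    tr = rng.normal(3.0, 2.0, size=(50, 4))
    te = rng.normal(3.0, 2.0, size=(20, 4))
    tr_s, te_s, mean, std = standardize(tr, te)
    assert np.allclose(tr_s.mean(axis=0), 0, atol=1e-12)
    assert np.allclose(tr_s.std(axis=0), 1, atol=1e-12)
    # the test set uses the train statistics, not its own
    assert np.allclose(te_s, (te - mean) / std)


def test_standardize_constant_column():
    tr = np.column_stack([np.ones(10), np.arange(10.0)])
    tr_s, _, _, _ = standardize(tr)
    assert np.all(tr_s[:, 0] == 0)


def test_standardize_validation():
    with pytest.raises(ValueError):
        standardize(np.empty((0, 3)))
    with pytest.raises(ValueError):
        standardize(np.zeros(5))


# --- metrics ---------------------------------------------------------------


def test_metrics_perfect():
    y = np.array([90.0, 60.0, 40.0, 10.0, 95.0])
    r = compute_metrics(y, y)
    assert r.mse == 0
    assert r.macro_acc == 1 and r.macro_f1 == 1 and r.multiclass_acc == 1
    assert np.isclose(r.spearman, 1.0)


def test_metrics_hand_case():
    # pred states: AW, LA, LA, DA ; true: AW, AW, LA, NA
    pred = np.array([90.0, 70.0, 60.0, 10.0])
    truth = np.array([85.0, 90.0, 55.0, 30.0])
    with pytest.warns(UserWarning):
        r = compute_metrics(pred, truth)
    assert np.isclose(r.mse, np.mean((pred - truth) ** 2))
    assert np.isclose(r.multiclass_acc, 0.5)
    # AW: tp=1 fp=0 fn=1 tn=2 -> acc .75, se .5, pr 1
    aw = r.per_state["AW"]
    assert np.isclose(aw["acc"], 0.75) and np.isclose(aw["se"], 0.5) and aw["pr"] == 1.0
    # DA predicted once but never true -> pr 0 (warned), se 0 denominator-free
    assert r.per_state["DA"]["pr"] == 0.0


def test_metrics_validation():
    with pytest.raises(ValueError):
        compute_metrics(np.array([1.0]), np.array([1.0, 2.0]))
    with pytest.raises(ValueError):
        compute_metrics(np.empty(0), np.empty(0))


# --- folds -----------------------------------------------------------------


@settings(max_examples=25, deadline=None)
@given(st.integers(5, 60), st.integers(2, 5), st.integers(0, 1000))
def test_kfold_random_partition(n, k, seed):
    folds = kfold_random(n, k=k, seed=seed)
    assert len(folds) == k
    all_test = np.concatenate([te for _, te in folds])
    assert np.array_equal(np.sort(all_test), np.arange(n))
    sizes = [len(te) for _, te in folds]
    assert max(sizes) - min(sizes) <= 1
    for tr, te in folds:
        assert np.intersect1d(tr, te).size == 0
        assert np.array_equal(np.sort(np.concatenate([tr, te])), np.arange(n))


def test_kfold_random_validation():
    with pytest.raises(ValueError):
        kfold_random(3, k=5)


def test_kfold_by_subject_grouping():
    sids = np.repeat([f"S{i}" for i in range(7)], 10)
    folds = kfold_by_subject(sids, k=3, seed=1)
    assert len(folds) == 3
    for tr, te in folds:
        assert set(sids[tr]).isdisjoint(set(sids[te]))
    covered = sorted(set(np.concatenate([sids[te] for _, te in folds])))
    assert covered == sorted(set(sids))


def test_kfold_by_subject_explicit_groups():
    sids = np.repeat(["A", "B", "C"], 4)
    folds = kfold_by_subject(sids, groups=[["A"], ["B", "C"]])
    assert len(folds) == 2
    with pytest.raises(ValueError):
        kfold_by_subject(sids, groups=[["A"], ["A", "B", "C"]])
    with pytest.raises(ValueError):
        kfold_by_subject(sids, groups=[["A"], ["B"]])  # C missing


# --- experiment driver -----------------------------------------------------


def test_run_experiment_smoke():
    rng = np.random.default_rng(5)
    n = 40
    x = rng.standard_normal((n, 4, 64)).astype(np.float32)
    psi = rng.uniform(0, 100, size=n)
    feats = rng.standard_normal((n, 14))
    sids = np.repeat([f"S{i}" for i in range(5)], n // 5)
    ds = Dataset(x=x, psi=psi, subject_ids=sids, features=feats)
    cfg = ModelConfig(training=TrainConfig(max_epochs=2, seed=0))
    res = run_experiment(
        ds, models=("rf", "drsn"), cv="subject", k=3, seed=0,
        drsn_config=cfg, ablate=True,
    )
    for name in ("rf", "drsn", "drsn_ablated"):
        assert len(res[name]["folds"]) == 3
        assert "mse" in res[name]["mean"]
        assert res[name]["mean"]["mse"] >= 0


def test_run_experiment_requires_features():
    ds = Dataset(
        x=np.zeros((10, 4, 32)), psi=np.linspace(0, 100, 10),
        subject_ids=np.zeros(10), features=None,
    )
    with pytest.raises(ValueError):
        run_experiment(ds, models=("svr",), cv="random", k=2)
    with pytest.raises(ValueError):
        run_experiment(ds, models=(), cv="nope")
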