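"""Standardization, state binning, the macro-averaged metric suite, and
cross-validation drivers (random and subject-grouped five-fold), including
the soft-thresholding ablation experiment.

PSI maps onto four anesthetized states: awake AW (80, 100], light LA
(50, 80], normal NA (25, 50] and deep DA [0, 25].  Classification metrics
are one-vs-rest per state and macro-averaged (unweighted mean over the four
states); regression quality is the mean squared PSI error plus Spearman's
rank correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import spearmanr

from .baselines import BaselineSpec, fit_baseline, predict_baseline
from .drsn import DRSNRegressor, ModelConfig, train as train_drsn

STATES = ("AW", "LA", "NA", "DA")
#: half-open lower bound of each state bin (psi > lo and psi <= hi), DA closed at 0.
_BINS = {"AW": (80.0, 100.0), "LA": (50.0, 80.0), "NA": (25.0, 50.0), "DA": (0.0, 25.0)}


def psi_to_state(psi: float) -> str:
    """Map a PSI value (integer or continuous) to its anesthetized state."""
    if not np.isfinite(psi) or psi < 0.0 or psi > 100.0:
        raise ValueError(f"PSI must lie in [0, 100], got {psi}")
    if psi > 80.0:
        return "AW"
    if psi > 50.0:
        return "LA"
    if psi > 25.0:
        return "NA"
    return "DA"


def standardize(train: np.ndarray, test: np.ndarray | None = None):
    """Column-wise z-scoring with statistics from the training set only.

    Works on any (n, d) layout — flattened 4x712 windows (d = 2848) and
    14-feature tables alike.  Columns with (near-)zero spread map to 0.
    Returns (train_std, test_std, mean, std).
    """
    train = np.asarray(train, dtype=float)
    if train.ndim != 2 or train.shape[0] == 0:
        raise ValueError("train must be a non-empty (n, d) array")
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    safe = np.where(std < 1e-8, 1.0, std)
    zero = std < 1e-8
    tr = (train - mean) / safe
    tr[:, zero] = 0.0
    te = None
    if test is not None:
        te = (np.asarray(test, dtype=float) - mean) / safe
        te[:, zero] = 0.0
    return tr, te, mean, std


@dataclass
class EvalReport:
    mse: float
    per_state: dict = field(default_factory=dict)  # state -> {acc, se, pr, f1, support}
    macro_acc: float = 0.0
    macro_se: float = 0.0
    macro_pr: float = 0.0
    macro_f1: float = 0.0
    multiclass_acc: float = 0.0
    spearman: float = 0.0

    def summary(self) -> dict:
        return {
            "mse": self.mse,
            "macro_acc": self.macro_acc,
            "macro_se": self.macro_se,
            "macro_f1": self.macro_f1,
            "multiclass_acc": self.multiclass_acc,
            "spearman": self.spearman,
        }


def compute_metrics(predictions: np.ndarray, truth: np.ndarray) -> EvalReport:
    """Regression + one-vs-rest classification metrics of predicted PSI.

    Zero-denominator cells (e.g. precision with no positive predictions)
    are defined as 0 and flagged with a warning.
    """
    predictions = np.asarray(predictions, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if predictions.shape != truth.shape or predictions.size == 0:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    mse = float(np.mean((predictions - truth) ** 2))
    pred_states = np.array([psi_to_state(p) for p in predictions])
    true_states = np.array([psi_to_state(t) for t in truth])
    n = truth.size
    report = EvalReport(mse=mse)
    accs, ses, prs, f1s = [], [], [], []
    for s in STATES:
        tp = int(np.sum((pred_states == s) & (true_states == s)))
        fp = int(np.sum((pred_states == s) & (true_states != s)))
        fn = int(np.sum((pred_states != s) & (true_states == s)))
        tn = n - tp - fp - fn
        acc = (tp + tn) / n
        se = _safe_div(tp, tp + fn, f"state {s}: no true samples")
        pr = _safe_div(tp, tp + fp, f"state {s}: no predicted samples")
        f1 = _safe_div(2 * se * pr, se + pr, f"state {s}: SE + PR = 0")
        report.per_state[s] = {
            "acc": acc, "se": se, "pr": pr, "f1": f1, "support": tp + fn,
        }
        accs.append(acc); ses.append(se); prs.append(pr); f1s.append(f1)
    report.macro_acc = float(np.mean(accs))
    report.macro_se = float(np.mean(ses))
    report.macro_pr = float(np.mean(prs))
    report.macro_f1 = float(np.mean(f1s))
    report.multiclass_acc = float(np.mean(pred_states == true_states))
    if np.unique(truth).size < 2 or np.unique(predictions).size < 2:
        report.spearman = 1.0 if np.array_equal(predictions, truth) else 0.0
    else:
        report.spearman = float(spearmanr(predictions, truth).statistic)
    return report


def _safe_div(num: float, den: float, context: str) -> float:
    if den == 0:
        warnings.warn(f"metric denominator is zero ({context}); defining value as 0")
        return 0.0
    return num / den


# --- fold construction -----------------------------------------------------


def kfold_random(n: int, k: int = 5, seed: int = 0):
    """Disjoint, exhaustive random folds with sizes differing by at most 1.

    Returns a list of (train_idx, test_idx) pairs; deterministic given seed.
    """
    if k > n:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    out = []
    for i in range(k):
        test = np.sort(folds[i])
        train = np.sort(np.concatenate([folds[j] for j in range(k) if j != i]))
        out.append((train, test))
    return out


def kfold_by_subject(subject_ids, groups=None, k: int = 5, seed: int = 0):
    """Subject-grouped folds: each fold's test set holds all samples of its
    subjects and none of any other fold's subjects.

    ``groups`` may list subject groups explicitly (they must partition the
    subjects); otherwise subjects are shuffled and split into k near-equal
    groups (e.g. 18 subjects -> 4/4/4/3/3).
    """
    subject_ids = np.asarray(subject_ids)
    subjects = sorted(set(subject_ids.tolist()))
    if groups is None:
        rng = np.random.default_rng(seed)
        order = list(np.array(subjects)[rng.permutation(len(subjects))])
        groups = [list(g) for g in np.array_split(np.array(order), k)]
    seen: set = set()
    for g in groups:
        for s in g:
            if s in seen:
                raise ValueError(f"subject {s} appears in more than one group")
            seen.add(s)
    if seen != set(subjects):
        raise ValueError("groups do not cover every subject in the data")
    out = []
    for g in groups:
        test_mask = np.isin(subject_ids, list(g))
        train = np.where(~test_mask)[0]
        test = np.where(test_mask)[0]
        if train.size == 0:
            raise ValueError("a fold's training set is empty (too few subjects)")
        out.append((train, test))
    return out


# --- experiment driver -----------------------------------------------------


@dataclass
class Dataset:
    """Preprocessed windows ready for model fitting."""

    x: np.ndarray            # (n, 4, 712) cleaned EEG
    psi: np.ndarray          # (n,)
    subject_ids: np.ndarray  # (n,)
    features: np.ndarray | None = None  # (n, 14), for the baselines


def _aggregate(reports: list[EvalReport]) -> dict:
    keys = reports[0].summary().keys()
    vals = {k: np.array([r.summary()[k] for r in reports]) for k in keys}
    return {
        "mean": {k: float(v.mean()) for k, v in vals.items()},
        "std": {k: float(v.std()) for k, v in vals.items()},
    }


def run_experiment(
    dataset: Dataset,
    models: tuple[str, ...] = ("svr", "rf", "ann", "drsn"),
    cv: str = "random",
    k: int = 5,
    seed: int = 0,
    drsn_config: ModelConfig | None = None,
    ablate: bool = False,
    collect_predictions: bool = False,
) -> dict:
    """Cross-validated comparison of the DRSN against the feature baselines.

    Per fold: standardize on the training portion only (flattened 2848-column
    windows for the DRSN, feature columns for the baselines), fit every
    requested model, and score it on the held-out portion.  ``ablate`` adds a
    soft-threshold-free DRSN trained on identical folds with the same seed.
    """
    n = len(dataset.x)
    if cv == "random":
        folds = kfold_random(n, k=k, seed=seed)
    elif cv == "subject":
        folds = kfold_by_subject(dataset.subject_ids, k=k, seed=seed)
    else:
        raise ValueError("cv must be 'random' or 'subject'")
    needs_features = any(m in ("svr", "rf", "ann") for m in models)
    if needs_features and dataset.features is None:
        raise ValueError("dataset.features required for the feature baselines")
    drsn_variants = [("drsn", False)] if "drsn" in models else []
    if ablate:
        drsn_variants.append(("drsn_ablated", True))
    results: dict = {m: {"folds": []} for m in models}
    for name, _ in drsn_variants:
        results.setdefault(name, {"folds": []})
    preds_store: dict = {}
    for fold_i, (tr, te) in enumerate(folds):
        y_tr, y_te = dataset.psi[tr], dataset.psi[te]
        if needs_features:
            f_tr, f_te, _, _ = standardize(dataset.features[tr], dataset.features[te])
            for m in models:
                if m not in ("svr", "rf", "ann"):
                    continue
                try:
                    fitted = fit_baseline(BaselineSpec(kind=m, seed=seed), f_tr, y_tr)
                    pred = predict_baseline(fitted, f_te)
                except Exception as exc:
                    raise RuntimeError(f"fold {fold_i}, model {m}: {exc}") from exc
                results[m]["folds"].append(compute_metrics(pred, y_te))
                if collect_predictions:
                    preds_store.setdefault(m, []).append((te, pred))
        if drsn_variants:
            flat_tr = dataset.x[tr].reshape(len(tr), -1)
            flat_te = dataset.x[te].reshape(len(te), -1)
            s_tr, s_te, _, _ = standardize(flat_tr, flat_te)
            x_tr = s_tr.reshape(len(tr), *dataset.x.shape[1:])
            x_te = s_te.reshape(len(te), *dataset.x.shape[1:])
            for name, ab in drsn_variants:
                cfg = drsn_config or ModelConfig()
                cfg.training.seed = seed
                model = DRSNRegressor(cfg, ablate_soft_threshold=ab)
                train_drsn(model, x_tr, y_tr, cfg.training)
                pred = model.predict(x_te)
                results[name]["folds"].append(compute_metrics(pred, y_te))
                if collect_predictions:
                    preds_store.setdefault(name, []).append((te, pred))
    for m, res in results.items():
        if res["folds"]:
            res.update(_aggregate(res["folds"]))
    if collect_predictions:
        results["_predictions"] = preds_store
    return results
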