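"""Logistic-regression and gradient-boosted-tree comparators.

Both are trained on the same 33 standardized features as the network, in
two flavours each: on the full labeled variant set and on the identical
under-sampled subset the network consumed ("_subset"). The boosted-tree
comparator is a thin adapter over xgboost with the pinned settings
(50 boosting rounds, scale_pos_weight for the class imbalance, RMSLE as
the monitoring metric); logistic regression is fit by maximum likelihood
with a tiny ridge (1e-6) fallback under perfect separation so comparisons
always complete.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

logger = logging.getLogger(__name__)

GBT_ROUNDS_DEFAULT = 50
RIDGE_LAMBDA = 1e-6

METHODS = ("dnn", "logistic", "logistic_subset", "gbt", "gbt_subset")


@dataclass
class LogisticModel:
    intercept: float
    coef: np.ndarray
    se_intercept: float | None = None
    se: np.ndarray | None = None
    converged: bool = True
    ridge_used: bool = False


def _ridge_newton(Xd: np.ndarray, y: np.ndarray, lam: float, max_iter: int, tol: float):
    """Ridge-stabilised Newton-Raphson for the logistic log-likelihood."""
    beta = np.zeros(Xd.shape[1])
    prev = np.inf
    for _ in range(max_iter):
        p = expit(Xd @ beta)
        g = Xd.T @ (y - p) - lam * beta
        w = np.clip(p * (1 - p), 1e-10, None)
        H = (Xd * w[:, None]).T @ Xd + lam * np.eye(Xd.shape[1])
        beta = beta + np.linalg.solve(H, g)
        ll = float(np.sum(y * np.log(np.clip(p, 1e-12, 1)) +
                          (1 - y) * np.log(np.clip(1 - p, 1e-12, 1))))
        if abs(ll - prev) < tol:
            break
        prev = ll
    se = np.sqrt(np.diag(np.linalg.inv(H)))
    return beta, se


def fit_logistic(
    X: pd.DataFrame | np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticModel:
    """Maximum-likelihood logistic regression (statsmodels Newton).

    Perfect separation or a singular Hessian falls back to a finite
    ridge-stabilised fit (lambda = 1e-6) with a warning, so the comparison
    harness never dies on a degenerate training set.
    """
    arr = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("logistic fit requires both classes present")
    Xd = sm.add_constant(arr, has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=max_iter, tol=tol)
        if not res.mle_retvals.get("converged", False):
            raise RuntimeError("did not converge")
        beta, se = np.asarray(res.params), np.asarray(res.bse)
        ridge = False
    except Exception as exc:  # separation, singular Hessian, non-convergence
        logger.warning("logistic MLE failed (%s); refitting with ridge %.0e",
                       exc, RIDGE_LAMBDA)
        beta, se = _ridge_newton(Xd, y, RIDGE_LAMBDA, max_iter, tol)
        ridge = True
    return LogisticModel(
        intercept=float(beta[0]),
        coef=beta[1:],
        se_intercept=float(se[0]),
        se=se[1:],
        converged=not ridge,
        ridge_used=ridge,
    )


def predict_logistic(model: LogisticModel, X) -> np.ndarray:
    arr = np.asarray(X, dtype=float)
    if arr.shape[1] != len(model.coef):
        raise ValueError(f"schema mismatch: {arr.shape[1]} features vs {len(model.coef)}")
    return expit(model.intercept + arr @ model.coef)


def fit_gbt(
    X,
    y: np.ndarray,
    rounds: int = GBT_ROUNDS_DEFAULT,
    imbalance_weight: float | None = None,
    seed: int = 0,
):
    """Gradient-boosted trees (xgboost) with the pinned comparator settings."""
    from xgboost import XGBClassifier

    y = np.asarray(y).astype(int)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("GBT fit requires both classes present")
    if imbalance_weight is None:
        imbalance_weight = n_neg / n_pos
    model = XGBClassifier(
        n_estimators=rounds,
        objective="binary:logistic",
        eval_metric="rmsle",
        scale_pos_weight=imbalance_weight,
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
    )
    model.fit(np.asarray(X, dtype=float), y)
    return model


def predict_gbt(model, X) -> np.ndarray:
    return model.predict_proba(np.asarray(X, dtype=float))[:, 1]


def mask_hash(mask: np.ndarray) -> str:
    """Stable fingerprint of an under-sampling mask for shared-mask checks."""
    return hashlib.sha256(np.asarray(mask, dtype=np.int64).tobytes()).hexdigest()


def run_comparison(
    X_features: pd.DataFrame,
    y_labels: np.ndarray,
    X_apply: pd.DataFrame,
    truth: np.ndarray,
    apply_stats: pd.DataFrame,
    truth_stats: pd.DataFrame,
    mask: np.ndarray,
    methods: tuple[str, ...] = METHODS,
    threshold: float = 0.5,
    alpha: float = 5e-8,
    merge_bp: int = 250_000,
    seed: int = 0,
    dnn_model=None,
    dnn_predictions: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Train every comparator on the same features and score them.

    Training pairs X_features (the smaller study) with y_labels (the larger
    study); every method predicts on ``X_apply`` and is scored against
    ``truth`` (variant level) and against loci called from ``truth_stats``
    (locus level). Full-sample and "_subset" variants share the identical
    under-sampling ``mask``. A failing method is recorded and skipped.

    Returns (metric table, per-method prediction vectors).
    """
    from deepgwas.evaluation import call_loci, locus_metrics, variant_metrics
    from deepgwas.nn import NetworkConfig, TrainingHyper, init_model
    from deepgwas.nn import train as nn_train
    from deepgwas.training import LabeledSet, Scaler

    scaler = Scaler.fit(X_features.iloc[mask])
    Xs = scaler.transform(X_features).to_numpy()
    Xs_apply = scaler.transform(X_apply).to_numpy()
    y = np.asarray(y_labels).astype(int)
    shared_hash = mask_hash(mask)

    preds: dict[str, np.ndarray] = {}
    rows = []
    for method in methods:
        try:
            if method == "dnn":
                if dnn_predictions is not None:
                    p = np.asarray(dnn_predictions, dtype=float)
                else:
                    model = dnn_model or init_model(
                        NetworkConfig(input_width=Xs.shape[1]), seed=seed,
                        feature_names=list(X_features.columns),
                    )
                    model, _ = nn_train(model, Xs[mask], y[mask],
                                        TrainingHyper(seed=seed))
                    p = _predict(model, Xs_apply)
            elif method == "logistic":
                p = predict_logistic(fit_logistic(Xs, y), Xs_apply)
            elif method == "logistic_subset":
                p = predict_logistic(fit_logistic(Xs[mask], y[mask]), Xs_apply)
            elif method == "gbt":
                p = predict_gbt(fit_gbt(Xs, y, seed=seed), Xs_apply)
            elif method == "gbt_subset":
                p = predict_gbt(fit_gbt(Xs[mask], y[mask], seed=seed), Xs_apply)
            else:
                raise ValueError(f"unknown method {method!r}")
        except Exception as exc:
            logger.warning("method %s failed: %s", method, exc)
            rows.append({"method": method, "error": str(exc)})
            continue
        preds[method] = p
        vm = variant_metrics(p, truth, threshold=threshold)
        pred_sig = apply_stats.assign(score=p).loc[lambda d: d["score"] >= threshold]
        truth_sig = truth_stats.loc[truth_stats["p_value"] < alpha].assign(
            score=lambda d: -np.log10(d["p_value"])
        )
        pred_loci = call_loci(pred_sig, merge_bp=merge_bp)
        truth_loci = call_loci(truth_sig, merge_bp=merge_bp)
        lm = locus_metrics(pred_loci, truth_loci, slack_bp=merge_bp)
        rows.append(
            {
                "method": method,
                "variant_tpr": vm["tpr"],
                "variant_f1": vm["f1"],
                "variant_auroc": vm["auroc"],
                "variant_auprc": vm["auprc"],
                "locus_tpr": lm["tpr"],
                "locus_f1": lm["f1"],
                "mask_hash": shared_hash if method.endswith("_subset") or method == "dnn"
                else None,
                "error": None,
            }
        )
    return pd.DataFrame(rows), preds


def _predict(model, Xs_apply: np.ndarray) -> np.ndarray:
    from deepgwas.nn import forward

    return forward(model, Xs_apply)
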