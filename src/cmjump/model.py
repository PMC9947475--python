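"""Height-regression stage: split, z-score, Lasso reduction, MLP grid search.

The pipeline mirrors common supervised-learning practice for small tabular
biomechanics datasets:

1. random 75/25 train/test split;
2. per-feature z-score normalization with statistics from the training split
   only (stored for later application to test/production rows);
3. Lasso (L1) linear regression at α = 0.1 under the (1/(2n))·RSS + α·‖w‖₁
   convention to drop collinear/uninformative features — survivors with
   |coefficient| > 1e-10 are kept in canonical order;
4. a single-hidden-layer MLP tuned by exhaustive grid search over
   4 activations × 3 solvers × 1–16 hidden units (192 combinations) with
   5-fold cross-validation scored by negative mean absolute error;
5. the best combination is refit on the whole training split.

Heights are handled in metres at the API surface; the regression itself is
carried out in centimetres, the scale on which the Lasso α and the reported
MAE are meaningful.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, LinearRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neural_network import MLPRegressor

from .errors import DegenerateFeatureError, EmptySelectionError, SchemaError
from .features import FEATURE_NAMES

logger = logging.getLogger(__name__)

M_TO_CM = 100.0

#: the full hyperparameter grid: 4 x 3 x 16 = 192 combinations
def default_grid() -> dict[str, list]:
    return {
        "activation": ["identity", "logistic", "tanh", "relu"],
        "solver": ["lbfgs", "sgd", "adam"],
        "hidden_layer_sizes": [(k,) for k in range(1, 17)],
    }


def grid_size(grid: dict[str, list] | None = None) -> int:
    g = grid or default_grid()
    n = 1
    for v in g.values():
        n *= len(v)
    return n


def split_dataset(n: int, frac: float = 0.75, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random disjoint train/test split; train size = floor(frac·n)."""
    if not 0.0 < frac < 1.0:
        raise ValueError(f"frac must lie in (0, 1), got {frac}")
    if n < 8:
        raise ValueError("at least 8 jumps are needed for a split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(frac * n))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class ScalerStats:
    """Per-feature mean and sample standard deviation from the training split."""

    names: list[str]
    mean: np.ndarray
    sd: np.ndarray


def fit_scaler(x: pd.DataFrame) -> ScalerStats:
    mean = x.mean(axis=0).to_numpy()
    sd = x.std(axis=0, ddof=1).to_numpy()
    if np.any(sd <= 0) or np.any(~np.isfinite(sd)):
        bad = x.columns[np.flatnonzero((sd <= 0) | ~np.isfinite(sd))[0]]
        raise DegenerateFeatureError(f"feature {bad!r} is constant on the training split")
    return ScalerStats(names=list(x.columns), mean=mean, sd=sd)


def apply_scaler(x: pd.DataFrame, stats: ScalerStats) -> pd.DataFrame:
    missing = [c for c in stats.names if c not in x.columns]
    if missing:
        raise SchemaError(f"missing feature column(s): {missing}")
    x = x[stats.names]
    return (x - stats.mean) / stats.sd


def lasso_select(
    xz: pd.DataFrame, y_cm: np.ndarray, alpha: float = 0.1
) -> list[str]:
    """Feature names surviving L1 shrinkage, in canonical column order.

    ``xz`` must already be z-scored; ``y_cm`` is the reference height in cm.
    """
    if alpha == 0.0:
        coef = LinearRegression().fit(xz.to_numpy(), y_cm).coef_
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            coef = Lasso(alpha=alpha, max_iter=100_000).fit(xz.to_numpy(), y_cm).coef_
    keep = [name for name, c in zip(xz.columns, coef) if abs(c) > 1e-10]
    if not keep:
        raise EmptySelectionError(
            f"alpha={alpha} shrank every coefficient to zero"
        )
    return keep


@dataclass
class ModelBundle:
    """Everything needed to reproduce a trained height predictor."""

    scaler: ScalerStats
    selected: list[str]
    hyperparams: dict
    mlp: MLPRegressor
    cv_score_cm: float  # mean negative MAE over the folds, cm
    fold_scores_cm: list[float]
    seed: int
    version: str = "1"


def grid_search_mlp(
    xz: pd.DataFrame,
    y_cm: np.ndarray,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
    max_iter: int = 2000,
) -> tuple[MLPRegressor, dict, float, list[float], pd.DataFrame]:
    """Exhaustive hyperparameter search with shuffled k-fold CV.

    Returns the refit best estimator, its parameters, its mean CV score
    (negative MAE, cm), the per-fold scores, and the full per-combination
    score table.  Non-convergent fits are scored as-is, with a logged
    warning, matching permissive scikit-learn practice.
    """
    grid = grid or default_grid()
    if len(y_cm) < folds:
        raise ValueError(f"need at least {folds} training rows for {folds}-fold CV")
    base = MLPRegressor(
        max_iter=max_iter,
        random_state=seed,
        learning_rate_init=1e-3,
        alpha=1e-4,
    )
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        base,
        grid,
        scoring="neg_mean_absolute_error",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        search.fit(xz.to_numpy(), y_cm)
    n_nc = sum(issubclass(w.category, ConvergenceWarning) for w in caught)
    if n_nc:
        logger.warning("%d non-convergent MLP fits during grid search (scored as-is)", n_nc)
    res = search.cv_results_
    best = int(search.best_index_)
    fold_scores = [float(res[f"split{i}_test_score"][best]) for i in range(folds)]
    table = pd.DataFrame(
        {
            "activation": [p["activation"] for p in res["params"]],
            "solver": [p["solver"] for p in res["params"]],
            "hidden_units": [p["hidden_layer_sizes"][0] for p in res["params"]],
            "mean_neg_mae_cm": res["mean_test_score"],
        }
    )
    for _, row in table.iterrows():
        logger.info(
            "grid: %s/%s/%d -> neg MAE %.3f cm",
            row["activation"], row["solver"], row["hidden_units"], row["mean_neg_mae_cm"],
        )
    params = dict(search.best_params_)
    return search.best_estimator_, params, float(search.best_score_), fold_scores, table


def train_height_model(
    features: pd.DataFrame,
    h_fp_m: np.ndarray,
    alpha: float = 0.1,
    grid: dict | None = None,
    folds: int = 5,
    seed: int = 0,
    max_iter: int = 2000,
) -> ModelBundle:
    """Scaler + Lasso + grid-searched MLP on a (training) feature table.

    ``features`` holds the 26 canonical columns (extra columns ignored);
    ``h_fp_m`` is the reference force-platform height in metres.
    """
    x = features[list(FEATURE_NAMES)] if set(FEATURE_NAMES) <= set(features.columns) else features
    y_cm = np.asarray(h_fp_m, dtype=float) * M_TO_CM
    scaler = fit_scaler(x)
    xz = apply_scaler(x, scaler)
    selected = lasso_select(xz, y_cm, alpha=alpha)
    logger.info("Lasso kept %d/%d features: %s", len(selected), x.shape[1], selected)
    mlp, params, score, fold_scores, _ = grid_search_mlp(
        xz[selected], y_cm, grid=grid, folds=folds, seed=seed, max_iter=max_iter
    )
    logger.info("best combination %s, CV neg MAE %.2f cm", params, score)
    return ModelBundle(
        scaler=scaler,
        selected=selected,
        hyperparams=params,
        mlp=mlp,
        cv_score_cm=score,
        fold_scores_cm=fold_scores,
        seed=seed,
    )


def predict_height(bundle: ModelBundle, features: pd.DataFrame) -> np.ndarray:
    """Predicted jump heights in metres for rows of the 26-column table."""
    missing = [c for c in bundle.scaler.names if c not in features.columns]
    if missing:
        raise SchemaError(f"missing feature column(s): {missing}")
    xz = apply_scaler(features, bundle.scaler)
    pred_cm = bundle.mlp.predict(xz[bundle.selected].to_numpy())
    return pred_cm / M_TO_CM


# ---------------------------------------------------------------------------
# serialization: versioned JSON with weights as nested lists


def save_bundle(bundle: ModelBundle, path) -> None:
    mlp = bundle.mlp
    payload = {
        "format": "cmjump-model-bundle",
        "version": bundle.version,
        "seed": bundle.seed,
        "scaler": {
            "names": bundle.scaler.names,
            "mean": bundle.scaler.mean.tolist(),
            "sd": bundle.scaler.sd.tolist(),
        },
        "selected": bundle.selected,
        "hyperparams": {
            **bundle.hyperparams,
            "hidden_layer_sizes": list(bundle.hyperparams["hidden_layer_sizes"]),
        },
        "cv_score_cm": bundle.cv_score_cm,
        "fold_scores_cm": bundle.fold_scores_cm,
        "weights": {
            "coefs": [w.tolist() for w in mlp.coefs_],
            "intercepts": [b.tolist() for b in mlp.intercepts_],
            "out_activation": mlp.out_activation_,
        },
    }
    Path(path).write_text(json.dumps(payload))


def load_bundle(path) -> ModelBundle:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "cmjump-model-bundle":
        raise SchemaError(f"{path} is not a model bundle")
    hp = dict(payload["hyperparams"])
    hp["hidden_layer_sizes"] = tuple(hp["hidden_layer_sizes"])
    mlp = MLPRegressor(
        activation=hp["activation"],
        solver=hp["solver"],
        hidden_layer_sizes=hp["hidden_layer_sizes"],
    )
    w = payload["weights"]
    mlp.coefs_ = [np.asarray(c) for c in w["coefs"]]
    mlp.intercepts_ = [np.asarray(b) for b in w["intercepts"]]
    mlp.n_layers_ = len(mlp.coefs_) + 1
    mlp.n_outputs_ = 1
    mlp.out_activation_ = w["out_activation"]
    mlp.n_features_in_ = len(payload["selected"])
    scaler = ScalerStats(
        names=payload["scaler"]["names"],
        mean=np.asarray(payload["scaler"]["mean"]),
        sd=np.asarray(payload["scaler"]["sd"]),
    )
    return ModelBundle(
        scaler=scaler,
        selected=payload["selected"],
        hyperparams=hp,
        mlp=mlp,
        cv_score_cm=payload["cv_score_cm"],
        fold_scores_cm=payload["fold_scores_cm"],
        seed=payload["seed"],
        version=payload["version"],
    )
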