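"""Two-level stacked ensemble for SBP/DBP regression.

The fitted pipeline is: median imputation of missing demographics ->
engineered ratio/polynomial terms -> robust (median/IQR) scaling ->
mutual-information feature selection -> a tabular-transformer embedder
over the categorical channel -> three gradient-boosted tree base
regressors per target (XGBoost, LightGBM and a classical GBM), each
tuned by seeded random search over the printed ranges with inner 3-fold
MAE -> a gradient-boosting meta-regressor trained on out-of-fold base
predictions concatenated with the embedder representation and the
engineered features.  Out-of-fold meta-features are mandatory: the
meta-learner never sees a base prediction made by a model trained on
that row.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.model_selection import KFold
from xgboost import XGBRegressor

from .embedder import EmbedderConfig, TabTransformerEmbedder
from .evaluation import ErrorStats, regression_metrics
from .features import (
    BASE_COLUMNS,
    CONTINUOUS_BASE,
    ENGINEERED_COLUMNS,
    engineer_features,
)

logger = logging.getLogger(__name__)

# lightgbm's sklearn wrapper invents "Column_N" feature names for ndarray
# input and then warns on every ndarray predict; the pipeline is ndarray-only
warnings.filterwarnings(
    "ignore", message="X does not have valid feature names"
)

__all__ = [
    "ScalerParams",
    "BaseSearchSpace",
    "MetaConfig",
    "CVConfig",
    "PipelineConfig",
    "StackedEnsemble",
    "CVResult",
    "ContractError",
    "StackingDegradationError",
    "robust_scale",
    "mi_select",
    "tune_fit_base",
    "fit_stacked_ensemble",
    "cross_validate",
    "predict_bp",
    "TARGETS",
    "VARIANTS",
]

TARGETS = ("sbp", "dbp")
VARIANTS = ("xgboost", "lightgbm", "gbdt")
CATEGORICAL = ("gender",)


class ContractError(ValueError):
    """Feature columns differ from the training contract."""


class StackingDegradationError(RuntimeError):
    """Meta-model pooled MAE > 1.25x the best base model's."""


# ---------------------------------------------------------------------------
# robust scaling


@dataclass(eq=False)
class ScalerParams:
    columns: list[str]
    median: np.ndarray
    iqr: np.ndarray


def robust_scale(
    matrix: pd.DataFrame,
    params: ScalerParams | None = None,
    categorical: Sequence[str] = CATEGORICAL,
) -> tuple[pd.DataFrame, ScalerParams]:
    """(x - median) / IQR per continuous column; categorical untouched.

    Quartiles use linear interpolation of order statistics (type 7).
    Zero-IQR columns are centred only.  Pass fitted ``params`` for a
    transform-only application on new data.
    """
    if matrix.empty:
        raise ValueError("empty matrix")
    cont = [c for c in matrix.columns if c not in categorical]
    if params is None:
        values = matrix[cont].to_numpy(dtype=float)
        med = np.nanmedian(values, axis=0)
        q1, q3 = np.nanquantile(values, [0.25, 0.75], axis=0)
        params = ScalerParams(columns=cont, median=med, iqr=q3 - q1)
    elif params.columns != cont:
        raise ContractError("scaler columns differ from fitted params")
    out = matrix.copy()
    denom = np.where(params.iqr > 0, params.iqr, 1.0)
    out[cont] = (matrix[cont].to_numpy(dtype=float) - params.median) / denom
    return out, params


# ---------------------------------------------------------------------------
# mutual-information selection


def _binned_mi(x: np.ndarray, y: np.ndarray, bins: int = 8) -> float:
    """MI(x; y) in nats from a quantile-binned contingency table."""
    def _digitize(v: np.ndarray) -> np.ndarray | None:
        edges = np.unique(np.quantile(v, np.linspace(0, 1, bins + 1)[1:-1]))
        if edges.size == 0:
            return None  # constant variable
        return np.searchsorted(edges, v, side="right")

    xb = _digitize(np.asarray(x, dtype=float))
    yb = _digitize(np.asarray(y, dtype=float))
    if xb is None or yb is None:
        return 0.0
    nx, ny = xb.max() + 1, yb.max() + 1
    joint = np.zeros((nx, ny))
    np.add.at(joint, (xb, yb), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float(np.sum(joint[mask] * np.log(joint[mask] / (px @ py)[mask])))


def mi_select(
    matrix: pd.DataFrame,
    targets: np.ndarray,
    k_keep: int,
    bins: int = 8,
) -> list[str]:
    """Top ``k_keep`` continuous columns by mean MI against SBP and DBP.

    Deterministic: histogram MI on quantile bins, ties broken by original
    column order.
    """
    targets = np.asarray(targets, dtype=float).reshape(len(matrix), -1)
    if not 1 <= k_keep <= matrix.shape[1]:
        raise ValueError(f"k_keep must be in [1, {matrix.shape[1]}]")
    scores = []
    for c in matrix.columns:
        x = matrix[c].to_numpy(dtype=float)
        scores.append(
            float(np.mean([_binned_mi(x, targets[:, j], bins) for j in
                           range(targets.shape[1])]))
        )
    order = sorted(range(len(scores)), key=lambda j: (-scores[j], j))
    keep = sorted(order[:k_keep])
    return [matrix.columns[j] for j in keep]


# ---------------------------------------------------------------------------
# base and meta regressors


@dataclass(frozen=True)
class BaseSearchSpace:
    n_estimators: tuple[int, int] = (300, 1000)
    learn_rate: tuple[float, float] = (0.01, 0.1)
    max_depth: tuple[int, int] = (3, 10)
    subsample: tuple[float, float] = (0.5, 1.0)  # XGBoost variant only
    colsample: tuple[float, float] = (0.5, 1.0)  # XGBoost variant only
    n_trials: int = 25

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


@dataclass(frozen=True)
class MetaConfig:
    n_estimators: int = 200
    learn_rate: float = 0.05
    max_depth: int = 4


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    shuffle: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass(frozen=True)
class PipelineConfig:
    k_keep: int = 20
    variants: tuple[str, ...] = VARIANTS
    embedder: EmbedderConfig = field(default_factory=EmbedderConfig)
    base_space: BaseSearchSpace = field(default_factory=BaseSearchSpace)
    meta: MetaConfig = field(default_factory=MetaConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    min_pulses: int = 3
    seed: int = 0


def _make_base(variant: str, params: dict, seed: int):
    if variant == "xgboost":
        return XGBRegressor(
            n_estimators=params["n_estimators"],
            learning_rate=params["learn_rate"],
            max_depth=params["max_depth"],
            subsample=params.get("subsample", 1.0),
            colsample_bytree=params.get("colsample", 1.0),
            tree_method="hist",
            random_state=seed,
            n_jobs=1,
            verbosity=0,
        )
    if variant == "lightgbm":
        return LGBMRegressor(
            n_estimators=params["n_estimators"],
            learning_rate=params["learn_rate"],
            max_depth=params["max_depth"],
            num_leaves=min(2 ** params["max_depth"], 63),
            random_state=seed,
            n_jobs=1,
            verbose=-1,
            deterministic=True,
            force_row_wise=True,
        )
    if variant == "gbdt":
        return GradientBoostingRegressor(
            n_estimators=params["n_estimators"],
            learning_rate=params["learn_rate"],
            max_depth=params["max_depth"],
            random_state=seed,
        )
    raise ValueError(f"unknown base variant: {variant}")


def _sample_params(
    space: BaseSearchSpace, variant: str, rng: np.random.Generator
) -> dict:
    params = {
        "n_estimators": int(rng.integers(space.n_estimators[0],
                                         space.n_estimators[1] + 1)),
        "learn_rate": float(np.exp(rng.uniform(np.log(space.learn_rate[0]),
                                               np.log(space.learn_rate[1])))),
        "max_depth": int(rng.integers(space.max_depth[0], space.max_depth[1] + 1)),
    }
    if variant == "xgboost":
        params["subsample"] = float(rng.uniform(*space.subsample))
        params["colsample"] = float(rng.uniform(*space.colsample))
    return params


def tune_fit_base(
    features: np.ndarray,
    target: np.ndarray,
    space: BaseSearchSpace,
    variant: str,
    seed: int = 0,
):
    """Seeded random search over the stated ranges, scored by 3-fold MAE.

    Returns ``(fitted_model, chosen_params, best_mae)``; the best
    configuration is refit on the full training partition.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(target, dtype=float).ravel()
    if len(X) < 6:
        raise ValueError("too few rows for inner 3-fold model selection")
    rng = np.random.default_rng(seed)
    inner = KFold(n_splits=3, shuffle=True, random_state=seed % (2**31))
    best_mae, best_params = np.inf, None
    for _trial in range(space.n_trials):
        params = _sample_params(space, variant, rng)
        maes = []
        for tr, va in inner.split(X):
            model = _make_base(variant, params, seed)
            model.fit(X[tr], y[tr])
            maes.append(np.mean(np.abs(model.predict(X[va]) - y[va])))
        mae = float(np.mean(maes))
        if mae < best_mae:
            best_mae, best_params = mae, params
    model = _make_base(variant, best_params, seed)
    model.fit(X, y)
    return model, best_params, best_mae


# ---------------------------------------------------------------------------
# stacked ensemble


class StackedEnsemble:
    """Scaler + selector + embedder + per-target bases and meta-regressor."""

    def __init__(self, config: PipelineConfig | None = None) -> None:
        self.config = config or PipelineConfig()
        self.fitted = False

    # -- fitting -----------------------------------------------------------

    def _prepare(self, X: pd.DataFrame, fit: bool) -> pd.DataFrame:
        if list(X.columns) != BASE_COLUMNS:
            raise ContractError(
                "feature columns differ from the training contract; expected "
                f"{BASE_COLUMNS}"
            )
        X = X.copy()
        if fit:
            self.impute_medians_ = {
                c: float(np.nanmedian(X[c].to_numpy(dtype=float)))
                for c in CONTINUOUS_BASE
            }
        for c in CONTINUOUS_BASE:
            X[c] = X[c].fillna(self.impute_medians_[c])
        return engineer_features(X)

    def fit(self, X: pd.DataFrame, y: pd.DataFrame) -> "StackedEnsemble":
        cfg = self.config
        if list(y.columns) != list(TARGETS):
            raise ContractError(f"targets must have columns {TARGETS}")
        Xe = self._prepare(X, fit=True)
        scaled, self.scaler_ = robust_scale(Xe, None)
        cont_cols = [c for c in Xe.columns if c not in CATEGORICAL]
        self.selected_ = mi_select(
            scaled[cont_cols], y.to_numpy(), min(cfg.k_keep, len(cont_cols))
        )

        x_cat = scaled["gender"].to_numpy(dtype=int).reshape(-1, 1)
        x_cont = scaled[self.selected_].to_numpy(dtype=float)
        self.embedder_ = TabTransformerEmbedder(
            EmbedderConfig(**{**asdict(cfg.embedder), "seed": cfg.seed})
        )
        self.embedder_.fit(x_cat, [2], x_cont, y.to_numpy())
        E = self.embedder_.transform(x_cat, x_cont)
        G = scaled[ENGINEERED_COLUMNS].to_numpy(dtype=float)
        X_base = np.column_stack([x_cont, x_cat.astype(float)])

        kf = KFold(n_splits=cfg.cv.k, shuffle=cfg.cv.shuffle,
                   random_state=cfg.cv.seed)
        splits = list(kf.split(X_base))
        self.bases_: dict[str, dict[str, object]] = {}
        self.base_params_: dict[str, dict[str, dict]] = {}
        self.metas_: dict[str, GradientBoostingRegressor] = {}
        self.oof_mae_: dict[str, dict[str, float]] = {}
        for t_idx, target in enumerate(TARGETS):
            yt = y[target].to_numpy(dtype=float)
            oof = np.full((len(X_base), len(cfg.variants)), np.nan)
            self.bases_[target] = {}
            self.base_params_[target] = {}
            self.oof_mae_[target] = {}
            for v_idx, variant in enumerate(cfg.variants):
                seed_v = (cfg.seed + 101 * t_idx + 17 * v_idx + 1) % (2**31)
                model, params, _ = tune_fit_base(
                    X_base, yt, cfg.base_space, variant, seed=seed_v
                )
                for tr, va in splits:
                    fold_model = _make_base(variant, params, seed_v)
                    fold_model.fit(X_base[tr], yt[tr])
                    oof[va, v_idx] = fold_model.predict(X_base[va])
                self.bases_[target][variant] = model  # refit on all rows
                self.base_params_[target][variant] = params
                self.oof_mae_[target][variant] = float(
                    np.mean(np.abs(oof[:, v_idx] - yt))
                )
            if np.isnan(oof).any():
                raise RuntimeError("stacking integrity: rows without OOF predictions")
            meta_X = np.column_stack([oof, E, G])
            meta = GradientBoostingRegressor(
                n_estimators=cfg.meta.n_estimators,
                learning_rate=cfg.meta.learn_rate,
                max_depth=cfg.meta.max_depth,
                random_state=cfg.seed % (2**31),
            )
            meta.fit(meta_X, yt)
            self.metas_[target] = meta
        self.columns_ = list(BASE_COLUMNS)
        self.fitted = True
        return self

    # -- prediction --------------------------------------------------------

    def _transform_stack(self, X: pd.DataFrame):
        Xe = self._prepare(X, fit=False)
        scaled, _ = robust_scale(Xe, self.scaler_)
        x_cat = scaled["gender"].to_numpy(dtype=int).reshape(-1, 1)
        x_cont = scaled[self.selected_].to_numpy(dtype=float)
        G = scaled[ENGINEERED_COLUMNS].to_numpy(dtype=float)
        finite = (
            np.all(np.isfinite(x_cont), axis=1) & np.all(np.isfinite(G), axis=1)
        )
        # rejected rows get placeholder zeros so the embedder stays numeric
        x_cont = np.where(finite[:, None], x_cont, 0.0)
        G = np.where(finite[:, None], G, 0.0)
        E = self.embedder_.transform(x_cat, x_cont)
        X_base = np.column_stack([x_cont, x_cat.astype(float)])
        return X_base, E, G, finite

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Per-row (SBP, DBP) in mmHg; non-finite rows yield NaN with a warning."""
        if not self.fitted:
            raise RuntimeError("ensemble not fitted")
        X_base, E, G, finite = self._transform_stack(X)
        if not finite.all():
            bad = np.flatnonzero(~finite)
            warnings.warn(
                f"{bad.size} rows with non-finite features rejected "
                f"(row indices {bad[:10].tolist()}...)",
                stacklevel=2,
            )
        out = pd.DataFrame(
            np.nan, index=X.index, columns=list(TARGETS), dtype=float
        )
        if finite.any():
            rows = np.flatnonzero(finite)
            for target in TARGETS:
                base_preds = np.column_stack(
                    [
                        self.bases_[target][v].predict(X_base[finite])
                        for v in self.config.variants
                    ]
                )
                meta_X = np.column_stack([base_preds, E[finite], G[finite]])
                col = out.columns.get_loc(target)
                out.iloc[rows, col] = self.metas_[target].predict(meta_X)
        return out

    def predict_bases(self, X: pd.DataFrame) -> dict[str, pd.DataFrame]:
        """Deployment base-model predictions per variant (diagnostics)."""
        X_base, _, _, _ = self._transform_stack(X)
        return {
            v: pd.DataFrame(
                {t: self.bases_[t][v].predict(X_base) for t in TARGETS},
                index=X.index,
            )
            for v in self.config.variants
        }

    # -- reporting ---------------------------------------------------------

    def manifest(self) -> dict:
        """Exact configuration of every fitted component, for reproduction."""
        cfg = self.config
        return {
            "package": "pulsebp",
            "column_order": self.columns_,
            "selected_features": self.selected_,
            "embedder": {
                "embed_dim": cfg.embedder.embed_dim,
                "depth": cfg.embedder.depth,
                "heads": cfg.embedder.heads,
                "dropout": cfg.embedder.dropout,
                "mlp_hidden_mults": list(cfg.embedder.mlp_hidden_mults),
                "epochs": cfg.embedder.epochs,
                "batch": cfg.embedder.batch,
                "learn_rate": cfg.embedder.learn_rate,
            },
            "base_search_space": {
                "n_estimators": list(cfg.base_space.n_estimators),
                "learn_rate": list(cfg.base_space.learn_rate),
                "max_depth": list(cfg.base_space.max_depth),
                "subsample": list(cfg.base_space.subsample),
                "colsample": list(cfg.base_space.colsample),
                "n_trials": cfg.base_space.n_trials,
            },
            "meta": {
                "n_estimators": cfg.meta.n_estimators,
                "learn_rate": cfg.meta.learn_rate,
                "max_depth": cfg.meta.max_depth,
            },
            "cv": {"k": cfg.cv.k, "shuffle": cfg.cv.shuffle, "seed": cfg.cv.seed},
            "variants": list(cfg.variants),
            "chosen_base_params": self.base_params_,
            "seed": cfg.seed,
        }


def fit_stacked_ensemble(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> StackedEnsemble:
    return StackedEnsemble(config).fit(features, targets)


def predict_bp(model: StackedEnsemble, features: pd.DataFrame) -> pd.DataFrame:
    return model.predict(features)


# ---------------------------------------------------------------------------
# outer cross-validation


@dataclass
class CVResult:
    fold_reports: list[dict[str, ErrorStats]]
    pooled: dict[str, ErrorStats]
    predictions: pd.DataFrame  # subject_id index; {t}_true, {t}_pred, fold
    stacking_ratio: dict[str, float]  # meta MAE / best base MAE per target


def cross_validate(
    features: pd.DataFrame,
    targets: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> CVResult:
    """Subject-level k-fold evaluation of the full pipeline.

    Every fitted component (imputer, scaler, selector, embedder, bases,
    meta) is learned inside each training fold only; validation-fold
    predictions are pooled for the headline metrics.  The meta-model's
    pooled MAE is monitored against the best single base model: a ratio
    above 1.1 logs a warning and above 1.25 raises.
    """
    config = config or PipelineConfig()
    cv = config.cv
    n = len(features)
    if n < cv.k:
        raise ValueError("fewer subjects than folds")
    if features.index.has_duplicates:
        raise ValueError("duplicate subject in dataset: splits are by subject")
    kf = KFold(n_splits=cv.k, shuffle=cv.shuffle, random_state=cv.seed)

    pred_frames = []
    base_frames: dict[str, list[pd.DataFrame]] = {v: [] for v in config.variants}
    fold_reports = []
    for fold, (tr, va) in enumerate(kf.split(features)):
        X_tr, X_va = features.iloc[tr], features.iloc[va]
        y_tr, y_va = targets.iloc[tr], targets.iloc[va]
        ens = StackedEnsemble(config).fit(X_tr, y_tr)
        pred = ens.predict(X_va)
        frame = pd.DataFrame(index=X_va.index)
        for t in TARGETS:
            frame[f"{t}_true"] = y_va[t]
            frame[f"{t}_pred"] = pred[t]
        frame["fold"] = fold
        pred_frames.append(frame)
        for v, bp in ens.predict_bases(X_va).items():
            base_frames[v].append(
                pd.concat(
                    [bp.add_suffix("_pred"), y_va.add_suffix("_true")], axis=1
                )
            )
        if len(X_va) >= 2:
            fold_reports.append(
                {t: regression_metrics(y_va[t], pred[t]) for t in TARGETS}
            )
        else:
            logger.warning("fold %d has %d subjects; per-fold metrics skipped",
                           fold, len(X_va))

    predictions = pd.concat(pred_frames).loc[features.index]
    pooled = {
        t: regression_metrics(predictions[f"{t}_true"], predictions[f"{t}_pred"])
        for t in TARGETS
    }

    stacking_ratio = {}
    for t in TARGETS:
        meta_mae = pooled[t].mae
        base_maes = []
        for v in config.variants:
            bf = pd.concat(base_frames[v])
            base_maes.append(
                float(np.mean(np.abs(bf[f"{t}_pred"] - bf[f"{t}_true"])))
            )
        ratio = meta_mae / min(base_maes)
        stacking_ratio[t] = ratio
        # below ~30 pooled predictions an MAE ratio is sampling noise, so the
        # degradation check only warns
        if ratio > 1.25 and n >= 30:
            raise StackingDegradationError(
                f"{t}: meta MAE {meta_mae:.3f} exceeds 1.25x best base "
                f"({min(base_maes):.3f})"
            )
        if ratio > 1.1:
            logger.warning(
                "%s: meta MAE %.3f above 1.1x best base %.3f",
                t, meta_mae, min(base_maes),
            )
    return CVResult(fold_reports, pooled, predictions, stacking_ratio)
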