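"""Energy-expenditure regression models.

Two regressor families, each usable either directly (one model for all
windows) or class-conditionally (one model per activity class, routed by the
true label or by the kNN classifier):

* Multiple linear regression fit by minimizing the sum of squared *relative*
  errors, Σ_j ((β0 + Σ_i βi F_ij − y_j) / y_j)². Dividing each row of the
  design and target by y_j turns this into an ordinary least-squares problem
  with target 1, so the fit is closed-form (weighted least squares with
  weights 1/y_j²) and unique whenever the design has full column rank.

* An ensemble of small single-hidden-layer sigmoid networks trained by
  Levenberg-Marquardt on standardized inputs/targets with Nguyen-Widrow
  initialization, a random 70/30 train/validation split per net, and three
  stopping rules (epoch cap, gradient tolerance, validation-failure streak).
  The ensemble prediction is the mean over nets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import ClassifierConfig, FittedKnn, classify, fit_knn
from .constants import ACTIVITY_CLASSES
from .presets import ANN_HIDDEN_UNITS, preset_features


# ---------------------------------------------------------------------------
# Relative-error multiple linear regression
# ---------------------------------------------------------------------------

@dataclass
class MlrModel:
    intercept: float
    coefficients: dict  # feature name -> beta
    meta: dict = field(default_factory=dict)

    @property
    def features(self) -> list:
        return list(self.coefficients.keys())

    def to_dict(self) -> dict:
        return {"kind": "mlr", "intercept": self.intercept,
                "coefficients": dict(self.coefficients), "meta": dict(self.meta)}

    @classmethod
    def from_dict(cls, d: dict) -> "MlrModel":
        return cls(intercept=d["intercept"], coefficients=dict(d["coefficients"]),
                   meta=d.get("meta", {}))


def _design(table: pd.DataFrame, features: Sequence[str]) -> np.ndarray:
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise KeyError(f"features not in table: {missing}")
    X = table[list(features)].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("missing values in selected features; rows must be gated first")
    return X


def fit_relative_mlr(table: pd.DataFrame, y: np.ndarray,
                     features: Sequence[str], meta: dict | None = None) -> MlrModel:
    """Fit EE = β0 + Σ βi·Fi by minimizing summed squared relative errors."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("all target EE values must be positive")
    X = _design(table, features)
    n, p = X.shape
    if n < p + 1:
        raise ValueError(f"need at least {p + 1} rows for {p} features, got {n}")
    A = np.column_stack([np.ones(n), X]) / y[:, None]
    b = np.ones(n)
    beta, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < p + 1:
        raise ValueError(
            f"rank-deficient design (rank {rank} < {p + 1}); "
            f"collinear features among {list(features)}")
    return MlrModel(intercept=float(beta[0]),
                    coefficients={f: float(b_) for f, b_ in zip(features, beta[1:])},
                    meta=meta or {})


def predict_mlr(model: MlrModel, table: pd.DataFrame) -> np.ndarray:
    """Affine evaluation; negative predictions are returned as-is."""
    X = _design(table, model.features)
    beta = np.array([model.coefficients[f] for f in model.features])
    return model.intercept + X @ beta


def relative_sse(model: MlrModel, table: pd.DataFrame, y: np.ndarray) -> float:
    """The fitted objective: Σ ((pred - y)/y)^2."""
    pred = predict_mlr(model, table)
    y = np.asarray(y, dtype=float)
    return float(np.sum(((pred - y) / y) ** 2))


# ---------------------------------------------------------------------------
# Levenberg-Marquardt ANN ensemble
# ---------------------------------------------------------------------------

@dataclass
class AnnTrainConfig:
    hidden_units: int = 3
    ensemble_size: int = 100
    max_epochs: int = 500
    gradient_tol: float = 1e-6
    val_fail_limit: int = 6
    train_frac: float = 0.7
    mu0: float = 1e-3
    mu_max: float = 1e10


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # clipped to keep exp finite; saturation beyond ±500 is exact in float64
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))


def _nguyen_widrow_init(p: int, h: int, rng: np.random.Generator):
    """Nguyen-Widrow hidden-layer initialization for inputs scaled to [-1, 1]."""
    w = rng.uniform(-1.0, 1.0, size=(h, p))
    norms = np.linalg.norm(w, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    beta = 0.7 * h ** (1.0 / p)
    w = beta * w / norms
    if h > 1:
        b = beta * np.linspace(-1, 1, h) * np.sign(w[:, 0])
    else:
        b = np.zeros(1)
    return w, b


@dataclass
class _Net:
    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float

    def forward(self, X: np.ndarray) -> np.ndarray:
        a = _sigmoid(X @ self.W1.T + self.b1)
        return a @ self.w2 + self.b2

    def pack(self) -> np.ndarray:
        return np.concatenate([self.W1.ravel(), self.b1, self.w2, [self.b2]])

    @classmethod
    def unpack(cls, theta: np.ndarray, p: int, h: int) -> "_Net":
        i = 0
        W1 = theta[i:i + h * p].reshape(h, p); i += h * p
        b1 = theta[i:i + h]; i += h
        w2 = theta[i:i + h]; i += h
        return cls(W1=W1, b1=b1, w2=w2, b2=float(theta[i]))


def _jacobian(net: _Net, X: np.ndarray) -> np.ndarray:
    """d(prediction)/d(theta) for every training row. Shape (n, m)."""
    z = X @ net.W1.T + net.b1
    a = _sigmoid(z)
    da = a * (1 - a)                       # (n, h)
    g = net.w2 * da                        # (n, h): dy/dz_j
    n, h = a.shape
    p = X.shape[1]
    J = np.empty((n, h * p + h + h + 1))
    J[:, :h * p] = (g[:, :, None] * X[:, None, :]).reshape(n, h * p)
    J[:, h * p:h * p + h] = g
    J[:, h * p + h:h * p + 2 * h] = a
    J[:, -1] = 1.0
    return J


def _train_net(X: np.ndarray, y: np.ndarray, cfg: AnnTrainConfig,
               rng: np.random.Generator) -> _Net:
    """Train one net with LM on a random 70/30 split; early-stopping weights."""
    n, p = X.shape
    idx = rng.permutation(n)
    n_train = max(2, int(round(cfg.train_frac * n)))
    tr, va = idx[:n_train], idx[n_train:]
    Xt, yt = X[tr], y[tr]
    Xv, yv = (X[va], y[va]) if len(va) else (Xt, yt)

    W1, b1 = _nguyen_widrow_init(p, cfg.hidden_units, rng)
    w2 = rng.uniform(-0.5, 0.5, size=cfg.hidden_units)
    net = _Net(W1=W1, b1=b1, w2=w2, b2=0.0)

    theta = net.pack()
    mu = cfg.mu0
    best_val = np.inf
    best_theta = theta.copy()
    val_fails = 0
    h = cfg.hidden_units

    def sse(th, Xs, ys):
        return float(np.sum((_Net.unpack(th, p, h).forward(Xs) - ys) ** 2))

    err = sse(theta, Xt, yt)
    for _ in range(cfg.max_epochs):
        net = _Net.unpack(theta, p, h)
        r = net.forward(Xt) - yt
        J = _jacobian(net, Xt)
        grad = J.T @ r
        if np.max(np.abs(grad)) < cfg.gradient_tol:
            break
        JTJ = J.T @ J
        accepted = False
        while mu <= cfg.mu_max:
            try:
                delta = np.linalg.solve(JTJ + mu * np.eye(JTJ.shape[0]), -grad)
            except np.linalg.LinAlgError:
                mu *= 10
                continue
            new_theta = theta + delta
            new_err = sse(new_theta, Xt, yt)
            if new_err < err:
                theta, err = new_theta, new_err
                mu = max(mu / 10, 1e-12)
                accepted = True
                break
            mu *= 10
        if not accepted:
            break
        val_err = sse(theta, Xv, yv)
        if val_err < best_val:
            best_val = val_err
            best_theta = theta.copy()
            val_fails = 0
        else:
            val_fails += 1
            if val_fails >= cfg.val_fail_limit:
                break
    return _Net.unpack(best_theta, p, h)


@dataclass
class AnnEnsemble:
    features: list
    config: AnnTrainConfig
    nets: list
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    y_scale: float
    meta: dict = field(default_factory=dict)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = _design(table, self.features)
        Xs = (X - self.x_mean) / self.x_scale
        preds = np.mean([net.forward(Xs) for net in self.nets], axis=0)
        return preds * self.y_scale + self.y_mean


def fit_ann_ensemble(table: pd.DataFrame, y: np.ndarray, features: Sequence[str],
                     config: AnnTrainConfig | None = None, seed: int = 0,
                     meta: dict | None = None) -> AnnEnsemble:
    """Train an ensemble of LM-trained sigmoid networks; reproducible per seed."""
    config = config or AnnTrainConfig()
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("all target EE values must be positive")
    X = _design(table, features)
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=0)
    x_scale[x_scale == 0] = 1.0
    y_mean = float(y.mean())
    y_scale = float(y.std(ddof=0)) or 1.0
    Xs = (X - x_mean) / x_scale
    ys = (y - y_mean) / y_scale
    ss = np.random.SeedSequence(seed)
    nets = [_train_net(Xs, ys, config, np.random.default_rng(child))
            for child in ss.spawn(config.ensemble_size)]
    return AnnEnsemble(features=list(features), config=config, nets=nets,
                       x_mean=x_mean, x_scale=x_scale, y_mean=y_mean,
                       y_scale=y_scale, meta=meta or {})


# ---------------------------------------------------------------------------
# Model bundles (direct / class-conditional)
# ---------------------------------------------------------------------------

@dataclass
class EEModelBundle:
    architecture: str                      # "direct" | "class_conditional"
    regressor: str                         # "mlr" | "ann"
    models: Mapping[str, object]           # {"direct": model} or {class: model}
    classifier: FittedKnn | None = None

    def model_for(self, activity_class: str):
        if self.architecture == "direct":
            return self.models["direct"]
        return self.models[activity_class]


def fit_bundle(table: pd.DataFrame, architecture: str = "class_conditional",
               regressor: str = "mlr", feature_sets=None,
               ann_config: AnnTrainConfig | None = None, seed: int = 0,
               classifier_config: ClassifierConfig | None = None,
               fit_classifier: bool = True) -> EEModelBundle:
    """Fit an EE model bundle on a gated feature table.

    ``table`` needs ``activity_class`` and ``ee_meas`` columns plus every
    selected feature. Class-conditional bundles train each class model only
    on windows of its true class. When ``fit_classifier``, a kNN gate is
    fitted on the same table for routing at prediction time.
    """
    if architecture not in ("direct", "class_conditional"):
        raise ValueError(f"unknown architecture {architecture!r}")
    if regressor not in ("mlr", "ann"):
        raise ValueError(f"unknown regressor {regressor!r}")
    if feature_sets is None:
        feature_sets = preset_features(architecture, regressor)
    y_all = table["ee_meas"].to_numpy(dtype=float)
    if np.isnan(y_all).any():
        raise ValueError("every training window needs a measured EE")

    def _fit(sub: pd.DataFrame, feats, tag: str):
        y = sub["ee_meas"].to_numpy(dtype=float)
        if regressor == "mlr":
            return fit_relative_mlr(sub, y, feats, meta={"segment": tag})
        cfg = ann_config or AnnTrainConfig(hidden_units=ANN_HIDDEN_UNITS.get(tag, 3))
        return fit_ann_ensemble(sub, y, feats, cfg, seed=seed, meta={"segment": tag})

    models = {}
    if architecture == "direct":
        if not isinstance(feature_sets, (list, tuple)):
            raise ValueError("direct architecture expects a flat feature list")
        models["direct"] = _fit(table, list(feature_sets), "direct")
    else:
        if not isinstance(feature_sets, Mapping):
            raise ValueError("class_conditional architecture expects a per-class mapping")
        for cls in ACTIVITY_CLASSES:
            sub = table[table["activity_class"] == cls]
            feats = list(feature_sets[cls])
            if len(sub) < len(feats) + 1:
                raise ValueError(
                    f"class {cls!r} has {len(sub)} windows for {len(feats)} features")
            models[cls] = _fit(sub, feats, cls)

    clf = None
    if fit_classifier and architecture == "class_conditional":
        clf = fit_knn(table, table["activity_class"].to_numpy(),
                      classifier_config or ClassifierConfig())
    return EEModelBundle(architecture=architecture, regressor=regressor,
                         models=models, classifier=clf)


def _predict_one(model, table: pd.DataFrame) -> np.ndarray:
    if isinstance(model, MlrModel):
        return predict_mlr(model, table)
    return model.predict(table)


def predict_bundle(bundle: EEModelBundle, table: pd.DataFrame,
                   class_source: str = "true_label") -> np.ndarray:
    """Per-window EE estimates, routing windows to their class model.

    ``class_source``: 'true_label' uses the table's ``activity_class`` column
    (the perfect-classification scenario); 'classifier' routes by the
    bundle's fitted kNN gate.
    """
    if bundle.architecture == "direct":
        return _predict_one(bundle.models["direct"], table)
    if class_source == "true_label":
        routed = table["activity_class"].to_numpy()
    elif class_source == "classifier":
        if bundle.classifier is None:
            raise ValueError("bundle has no fitted classifier for routing")
        routed = classify(bundle.classifier, table)
    else:
        raise ValueError(f"unknown class source {class_source!r}")
    pred = np.full(len(table), np.nan)
    for cls in ACTIVITY_CLASSES:
        mask = routed == cls
        if mask.any():
            pred[mask] = _predict_one(bundle.models[cls], table.loc[mask])
    return pred


def loso_predictions(table: pd.DataFrame, architecture: str = "class_conditional",
                     regressor: str = "mlr", class_source: str = "true_label",
                     feature_sets=None, ann_config: AnnTrainConfig | None = None,
                     seed: int = 0) -> pd.DataFrame:
    """Leave-one-subject-out EE predictions for every window.

    For each subject fold, the bundle (and its routing classifier) is trained
    on the remaining subjects only. Returns the table's metadata columns plus
    an ``ee_pred`` column.
    """
    out = []
    for sid in table["subject_id"].unique():
        train = table[table["subject_id"] != sid]
        test = table[table["subject_id"] == sid]
        bundle = fit_bundle(train, architecture, regressor, feature_sets,
                            ann_config, seed,
                            fit_classifier=(class_source == "classifier"))
        pred = predict_bundle(bundle, test, class_source=class_source)
        fold = test[["subject_id", "activity_name", "activity_class", "ee_meas"]].copy()
        fold["ee_pred"] = pred
        out.append(fold)
    return pd.concat(out, ignore_index=True)


# ---------------------------------------------------------------------------
# JSON serialization of fitted bundles
# ---------------------------------------------------------------------------

def _ann_to_dict(m: AnnEnsemble) -> dict:
    return {
        "kind": "ann",
        "features": m.features,
        "config": vars(m.config),
        "nets": [{"W1": n.W1.tolist(), "b1": n.b1.tolist(),
                  "w2": n.w2.tolist(), "b2": n.b2} for n in m.nets],
        "x_mean": m.x_mean.tolist(), "x_scale": m.x_scale.tolist(),
        "y_mean": m.y_mean, "y_scale": m.y_scale, "meta": dict(m.meta),
    }


def _ann_from_dict(d: dict) -> AnnEnsemble:
    nets = [_Net(W1=np.array(n["W1"]), b1=np.array(n["b1"]),
                 w2=np.array(n["w2"]), b2=float(n["b2"])) for n in d["nets"]]
    return AnnEnsemble(features=list(d["features"]),
                       config=AnnTrainConfig(**d["config"]), nets=nets,
                       x_mean=np.array(d["x_mean"]), x_scale=np.array(d["x_scale"]),
                       y_mean=float(d["y_mean"]), y_scale=float(d["y_scale"]),
                       meta=d.get("meta", {}))


def bundle_to_dict(bundle: EEModelBundle) -> dict:
    models = {}
    for key, m in bundle.models.items():
        models[key] = m.to_dict() if isinstance(m, MlrModel) else _ann_to_dict(m)
    clf = None
    if bundle.classifier is not None:
        c = bundle.classifier
        clf = {"k": c.config.k, "features": list(c.config.features),
               "standardize": c.config.standardize,
               "X": c.X.tolist(), "labels": c.labels.tolist(),
               "mean": c.mean.tolist(), "scale": c.scale.tolist()}
    return {"architecture": bundle.architecture, "regressor": bundle.regressor,
            "models": models, "classifier": clf}


def bundle_from_dict(d: dict) -> EEModelBundle:
    models = {}
    for key, md in d["models"].items():
        models[key] = (MlrModel.from_dict(md) if md["kind"] == "mlr"
                       else _ann_from_dict(md))
    clf = None
    if d.get("classifier"):
        c = d["classifier"]
        clf = FittedKnn(config=ClassifierConfig(k=c["k"], features=tuple(c["features"]),
                                                standardize=c["standardize"]),
                        X=np.array(c["X"]), labels=np.array(c["labels"]),
                        mean=np.array(c["mean"]), scale=np.array(c["scale"]))
    return EEModelBundle(architecture=d["architecture"], regressor=d["regressor"],
                         models=models, classifier=clf)


def greedy_forward_selection(table: pd.DataFrame, y: np.ndarray,
                             candidates: Sequence[str], max_features: int = 6,
                             n_folds: int = 5, seed: int = 0) -> list:
    """Exploratory greedy forward feature selection for the relative-error MLR.

    Utility only — the shipped presets are fixed published sets and are *not*
    produced by this search.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    n = len(y)
    fold_id = rng.integers(0, n_folds, size=n)
    selected: list = []
    remaining = list(candidates)
    best_score = np.inf
    while remaining and len(selected) < max_features:
        scores = {}
        for cand in remaining:
            feats = selected + [cand]
            errs = []
            for f in range(n_folds):
                tr, te = fold_id != f, fold_id == f
                if tr.sum() < len(feats) + 1 or te.sum() == 0:
                    continue
                try:
                    m = fit_relative_mlr(table.loc[tr], y[tr], feats)
                except ValueError:
                    continue
                pred = predict_mlr(m, table.loc[te])
                errs.append(np.mean(np.abs((pred - y[te]) / y[te])))
            if errs:
                scores[cand] = float(np.mean(errs))
        if not scores:
            break
        cand, score = min(scores.items(), key=lambda kv: kv[1])
        if score >= best_score:
            break
        selected.append(cand)
        remaining.remove(cand)
        best_score = score
    return selected
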