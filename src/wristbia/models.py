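"""Feature construction and the regression models for H^2/R50 and percent body fat.

Two quantities are estimated, each by both an ordinary linear regression and a
small feed-forward network:

* the cylinder-model impedance index H^2/R50 (height squared over whole-body
  50 kHz impedance, cm^2/ohm), predicted from upper-body inputs only
  ("Network 1": 3 hidden layers x 128 ReLU nodes);
* percent body fat, predicted from anthropometrics plus the H^2/R50 estimate
  ("Network 2": 3 hidden layers x 256 ReLU nodes).

Both networks train with Adam (beta1=0.9, beta2=0.999, eps=1e-8) on a
mean-squared-error loss for at most 2000 epochs with early stopping on a
held-out validation split, restoring the best-validation weights.  Gradients
are minibatch with seeded shuffling, inputs and targets are standardized by
training-set moments,
and every source of randomness flows from the spec seed, so training is
bit-reproducible.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import statsmodels.api as sm

from .errors import (
    ConfigError,
    DivergenceError,
    SchemaError,
    SingularDesignError,
    WristBiaError,
)
from .simulate import SubjectRecord

__all__ = [
    "FeatureSet",
    "FEATURE_SETS",
    "LinearModel",
    "MLPSpec",
    "TrainedModel",
    "H2RVariant",
    "PBFRegime",
    "build_features",
    "build_feature_matrix",
    "fit_ols",
    "predict_linear",
    "train_mlp",
    "train_mlp_cv_ensemble",
    "predict_mlp",
    "predict_mlp_ensemble",
    "network1_spec",
    "network2_spec",
    "fit_h2r_model",
    "estimate_h2r",
    "fit_pbf_model",
    "estimate_pbf",
    "H2RModel",
    "PBFModel",
]

PBF_CLIP = (0.0, 60.0)  # physiologic guard on percent-body-fat predictions


@dataclass(frozen=True)
class FeatureSet:
    """Named, ordered collection of feature identifiers."""

    name: str
    features: tuple[str, ...]


# feature identifiers:
#   height_cm, age_yr, gender (female=1), weight_kg         anthropometrics
#   r50_prop           calibrated settled upper-body impedance (ohms)
#   h2_over_imp        height^2 / r50_prop (cm^2/ohm)
#   h2_over_r50        H^2/R50 index (reference or model estimate, cm^2/ohm)
#   hip_cm, waist_cm, waist_hip_ratio                       lower-body shape
_BASE = ("height_cm", "age_yr", "gender", "weight_kg")
FEATURE_SETS: dict[str, FeatureSet] = {
    fs.name: fs
    for fs in (
        FeatureSet("CONV5", _BASE + ("h2_over_r50",)),
        FeatureSet("PROP8", _BASE + ("h2_over_r50", "hip_cm", "waist_cm", "waist_hip_ratio")),
        FeatureSet("NET1_M1", _BASE + ("r50_prop",)),
        FeatureSet("NET1_M2", _BASE + ("r50_prop", "h2_over_imp")),
        FeatureSet("NET1_M3", _BASE + ("r50_prop", "h2_over_imp", "waist_hip_ratio")),
        FeatureSet("NET2_CONV", _BASE + ("h2_over_r50",)),
        FeatureSet("NET2_PROP", _BASE + ("h2_over_r50", "hip_cm", "waist_cm", "waist_hip_ratio")),
    )
}


class H2RVariant(enum.Enum):
    """How H^2/R50 is estimated from upper-body inputs."""

    REGRESSION = "REGRESSION"  # OLS on the 5 NET1_M1 features
    MODEL_I = "NET1_M1"
    MODEL_II = "NET1_M2"
    MODEL_III = "NET1_M3"


class PBFRegime(enum.Enum):
    """The four percent-body-fat estimation regimes."""

    L_CONV = "L_CONV"
    L_PROP = "L_PROP"
    DNN_CONV = "DNN_CONV"
    DNN_PROP = "DNN_PROP"


def build_features(
    subject: SubjectRecord,
    settled_ohms: float | None,
    feature_set: FeatureSet | str,
    h2r: float | None = None,
) -> np.ndarray:
    """Assemble one subject's feature vector in the set's declared order.

    ``settled_ohms`` is the calibrated upper-body impedance (needed by the
    ``r50_prop`` and ``h2_over_imp`` features); ``h2r`` is the H^2/R50 value
    consumed by the ``h2_over_r50`` feature (a reference value or an upstream
    model estimate).  A feature whose inputs are missing raises
    :class:`SchemaError` naming the field.
    """
    if isinstance(feature_set, str):
        feature_set = FEATURE_SETS[feature_set]
    out = np.empty(len(feature_set.features))
    for j, name in enumerate(feature_set.features):
        if name == "height_cm":
            v = subject.height_cm
        elif name == "age_yr":
            v = subject.age_yr
        elif name == "gender":
            v = float(subject.gender)
        elif name == "weight_kg":
            v = subject.weight_kg
        elif name == "hip_cm":
            v = subject.hip_cm
        elif name == "waist_cm":
            v = subject.waist_cm
        elif name == "waist_hip_ratio":
            v = subject.waist_cm / subject.hip_cm
        elif name == "r50_prop":
            if settled_ohms is None or settled_ohms <= 0:
                raise SchemaError("r50_prop requires settled_ohms > 0")
            v = settled_ohms
        elif name == "h2_over_imp":
            if settled_ohms is None or settled_ohms <= 0:
                raise SchemaError("h2_over_imp requires settled_ohms > 0")
            v = subject.height_cm**2 / settled_ohms
        elif name == "h2_over_r50":
            if h2r is None:
                raise SchemaError("h2_over_r50 requires an h2r value")
            v = h2r
        else:  # pragma: no cover - registry and branches kept in sync
            raise SchemaError(f"unknown feature {name}")
        if not math.isfinite(v):
            raise SchemaError(f"non-finite value for feature {name}")
        out[j] = v
    return out


def build_feature_matrix(
    subjects: list[SubjectRecord],
    settled: dict[str, float] | None,
    feature_set: FeatureSet | str,
    h2r: dict[str, float] | None = None,
) -> np.ndarray:
    """Stack per-subject feature vectors into an (n, p) design matrix."""
    rows = []
    for s in subjects:
        rows.append(
            build_features(
                s,
                None if settled is None else settled[s.id],
                feature_set,
                None if h2r is None else h2r[s.id],
            )
        )
    return np.asarray(rows)


@dataclass(frozen=True)
class LinearModel:
    """Fitted affine model with classical OLS inference."""

    feature_names: tuple[str, ...]
    intercept: float
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    intercept_std_error: float
    intercept_p_value: float
    n_fit: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": list(self.feature_names),
                "intercept": self.intercept,
                "coefficients": list(map(float, self.coefficients)),
                "std_errors": list(map(float, self.std_errors)),
                "p_values": list(map(float, self.p_values)),
                "intercept_std_error": self.intercept_std_error,
                "intercept_p_value": self.intercept_p_value,
                "n_fit": self.n_fit,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "LinearModel":
        d = json.loads(text)
        return cls(
            feature_names=tuple(d["feature_names"]),
            intercept=d["intercept"],
            coefficients=np.asarray(d["coefficients"]),
            std_errors=np.asarray(d["std_errors"]),
            p_values=np.asarray(d["p_values"]),
            intercept_std_error=d["intercept_std_error"],
            intercept_p_value=d["intercept_p_value"],
            n_fit=d["n_fit"],
        )


def fit_ols(
    features: np.ndarray,
    targets: np.ndarray,
    feature_names: tuple[str, ...] | None = None,
) -> LinearModel:
    """Ordinary least squares with two-sided coefficient t-tests.

    p-values come from t-tests of coefficient/SE with n - p - 1 residual
    degrees of freedom, the classical inference printed in regression tables.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if X.ndim != 2:
        raise SchemaError("features must be 2-d")
    n, p = X.shape
    if n <= p + 1:
        raise SchemaError(f"need more rows ({n}) than features + 1 ({p + 1})")
    design = sm.add_constant(X, has_constant="add")
    # reject only genuine rank deficiency; near-collinear anthropometric
    # designs (e.g. waist, hip and their ratio) are legitimate inputs
    sv = np.linalg.svd(design, compute_uv=False)
    if sv[-1] <= sv[0] * 1e-12:
        raise SingularDesignError("design matrix is rank deficient")
    res = sm.OLS(y, design).fit()
    names = feature_names or tuple(f"x{j}" for j in range(p))
    if len(names) != p:
        raise SchemaError("feature_names length mismatch")
    return LinearModel(
        feature_names=tuple(names),
        intercept=float(res.params[0]),
        coefficients=np.asarray(res.params[1:]),
        std_errors=np.asarray(res.bse[1:]),
        p_values=np.asarray(res.pvalues[1:]),
        intercept_std_error=float(res.bse[0]),
        intercept_p_value=float(res.pvalues[0]),
        n_fit=n,
    )


def predict_linear(model: LinearModel, features: np.ndarray) -> np.ndarray | float:
    """Affine prediction; accepts one vector or an (n, p) matrix."""
    X = np.asarray(features, dtype=float)
    if X.shape[-1] != len(model.coefficients):
        raise SchemaError(
            f"expected {len(model.coefficients)} features, got {X.shape[-1]}"
        )
    out = model.intercept + X @ model.coefficients
    return float(out) if X.ndim == 1 else out


@dataclass(frozen=True)
class MLPSpec:
    """Architecture and optimizer settings of one feed-forward network.

    ``batch_size`` and ``patience`` govern the minibatch Adam loop: one epoch
    is a full seeded shuffle of the training rows, and training stops when the
    validation MSE has not improved for ``patience`` consecutive epochs (the
    best-validation weights are restored).
    """

    input_dim: int
    hidden_nodes: int
    hidden_layers: int = 3
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    max_epochs: int = 2000
    batch_size: int = 8
    patience: int = 100
    validation_fraction: float = 0.1
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_dim < 1 or self.hidden_nodes < 1 or self.hidden_layers < 1:
            raise ConfigError("dims must be positive")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be positive")
        if not self.patience < self.max_epochs:
            raise ConfigError("patience must be < max_epochs")
        if not 0 < self.validation_fraction < 1:
            raise ConfigError("validation_fraction must be in (0, 1)")


def network1_spec(input_dim: int = 7, seed: int = 0, **overrides) -> MLPSpec:
    """H^2/R50 network: 3 hidden layers of 128 nodes."""
    return MLPSpec(input_dim=input_dim, hidden_nodes=overrides.pop("hidden_nodes", 128),
                   seed=seed, **overrides)


def network2_spec(input_dim: int = 8, seed: int = 0, **overrides) -> MLPSpec:
    """Percent-body-fat network: 3 hidden layers of 256 nodes."""
    return MLPSpec(input_dim=input_dim, hidden_nodes=overrides.pop("hidden_nodes", 256),
                   seed=seed, **overrides)


@dataclass
class TrainedModel:
    """Weights and normalization constants of a trained network."""

    spec: MLPSpec
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    history: list[tuple[int, float, float]]  # (epoch, train mse, val mse)
    stopped_epoch: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "spec": self.spec.__dict__,
                "weights": [w.tolist() for w in self.weights],
                "biases": [b.tolist() for b in self.biases],
                "x_mean": self.x_mean.tolist(),
                "x_sd": self.x_sd.tolist(),
                "y_mean": self.y_mean,
                "y_sd": self.y_sd,
                "history": self.history,
                "stopped_epoch": self.stopped_epoch,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        d = json.loads(text)
        return cls(
            spec=MLPSpec(**d["spec"]),
            weights=[np.asarray(w) for w in d["weights"]],
            biases=[np.asarray(b) for b in d["biases"]],
            x_mean=np.asarray(d["x_mean"]),
            x_sd=np.asarray(d["x_sd"]),
            y_mean=d["y_mean"],
            y_sd=d["y_sd"],
            history=[tuple(h) for h in d["history"]],
            stopped_epoch=d["stopped_epoch"],
        )


def _init_params(spec: MLPSpec, rng: np.random.Generator):
    dims = [spec.input_dim] + [spec.hidden_nodes] * spec.hidden_layers + [1]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        # He initialization, the standard choice for ReLU stacks
        weights.append(rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def _forward(X, weights, biases):
    """Forward pass returning layer activations for backprop."""
    acts = [X]
    h = X
    n_layers = len(weights)
    for i, (W, b) in enumerate(zip(weights, biases)):
        z = h @ W + b
        h = z if i == n_layers - 1 else np.maximum(z, 0.0)
        acts.append(h)
    return acts


def _fit_network(
    spec: MLPSpec,
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xva: np.ndarray,
    yva: np.ndarray,
    rng: np.random.Generator,
) -> TrainedModel:
    """Minibatch-Adam training of one network on an explicit train/val split."""
    if spec.standardize:
        x_mean, x_sd = Xtr.mean(axis=0), Xtr.std(axis=0)
        x_sd = np.where(x_sd == 0, 1.0, x_sd)
        y_mean, y_sd = float(ytr.mean()), float(ytr.std()) or 1.0
    else:
        x_mean, x_sd = np.zeros(Xtr.shape[1]), np.ones(Xtr.shape[1])
        y_mean, y_sd = 0.0, 1.0
    Xtr_s, Xva_s = (Xtr - x_mean) / x_sd, (Xva - x_mean) / x_sd
    ytr_s, yva_s = (ytr - y_mean) / y_sd, (yva - y_mean) / y_sd

    weights, biases = _init_params(spec, rng)
    m_w = [np.zeros_like(w) for w in weights]
    v_w = [np.zeros_like(w) for w in weights]
    m_b = [np.zeros_like(b) for b in biases]
    v_b = [np.zeros_like(b) for b in biases]

    best_val = math.inf
    best = ([w.copy() for w in weights], [b.copy() for b in biases])
    since_best = 0
    history: list[tuple[int, float, float]] = []
    stopped = 0
    n_tr = len(Xtr)
    step = 0

    for epoch in range(1, spec.max_epochs + 1):
        perm = rng.permutation(n_tr)
        epoch_sse = 0.0
        for k in range(0, n_tr, spec.batch_size):
            idx = perm[k : k + spec.batch_size]
            acts = _forward(Xtr_s[idx], weights, biases)
            resid = acts[-1].ravel() - ytr_s[idx]
            epoch_sse += float(resid @ resid)

            grad = (2.0 / len(idx)) * resid[:, None]
            g_w, g_b = [None] * len(weights), [None] * len(biases)
            for i in range(len(weights) - 1, -1, -1):
                g_w[i] = acts[i].T @ grad
                g_b[i] = grad.sum(axis=0)
                if i > 0:
                    grad = (grad @ weights[i].T) * (acts[i] > 0)

            step += 1
            lr_t = (
                spec.learning_rate
                * math.sqrt(1 - spec.beta2**step)
                / (1 - spec.beta1**step)
            )
            for i in range(len(weights)):
                m_w[i] = spec.beta1 * m_w[i] + (1 - spec.beta1) * g_w[i]
                v_w[i] = spec.beta2 * v_w[i] + (1 - spec.beta2) * g_w[i] ** 2
                weights[i] -= lr_t * m_w[i] / (np.sqrt(v_w[i]) + spec.epsilon)
                m_b[i] = spec.beta1 * m_b[i] + (1 - spec.beta1) * g_b[i]
                v_b[i] = spec.beta2 * v_b[i] + (1 - spec.beta2) * g_b[i] ** 2
                biases[i] -= lr_t * m_b[i] / (np.sqrt(v_b[i]) + spec.epsilon)

        train_loss = epoch_sse / n_tr
        if not math.isfinite(train_loss):
            raise DivergenceError(epoch)
        val_pred = _forward(Xva_s, weights, biases)[-1].ravel()
        val_loss = float(np.mean((val_pred - yva_s) ** 2))
        if not math.isfinite(val_loss):
            raise DivergenceError(epoch)
        history.append((epoch, train_loss, val_loss))
        stopped = epoch

        if val_loss < best_val:
            best_val = val_loss
            best = ([w.copy() for w in weights], [b.copy() for b in biases])
            since_best = 0
        else:
            since_best += 1
            if since_best >= spec.patience:
                break

    return TrainedModel(
        spec=spec,
        weights=best[0],
        biases=best[1],
        x_mean=x_mean,
        x_sd=x_sd,
        y_mean=y_mean,
        y_sd=y_sd,
        history=history,
        stopped_epoch=stopped,
    )


def train_mlp(
    spec: MLPSpec, train_features: np.ndarray, train_targets: np.ndarray
) -> TrainedModel:
    """Train a ReLU MLP with minibatch Adam, MSE loss and early stopping.

    A ``validation_fraction`` share of the rows (seeded shuffle) is held out;
    training stops once the validation MSE has not improved for ``patience``
    consecutive epochs, and the best-validation weights are restored.  A fixed
    seed yields identical weights and predictions.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_targets, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise SchemaError(f"features must be (n, {spec.input_dim})")
    if len(X) < 20:
        raise SchemaError("need at least 20 training rows")

    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(X))
    n_val = max(1, int(round(spec.validation_fraction * len(X))))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    return _fit_network(spec, X[tr_idx], y[tr_idx], X[val_idx], y[val_idx], rng)


def train_mlp_cv_ensemble(
    spec: MLPSpec,
    train_features: np.ndarray,
    train_targets: np.ndarray,
    n_folds: int = 5,
) -> list[TrainedModel]:
    """Train a k-fold cross-validation ensemble of networks.

    The rows are split into ``n_folds`` seeded folds; each member trains on
    the other folds and early-stops on its own fold, so every row contributes
    to training and no single tiny validation split decides when to stop.
    Ensemble predictions (:func:`predict_mlp_ensemble`) average the members —
    the variance control that makes a wide network competitive at cohort-scale
    sample sizes.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_targets, dtype=float).ravel()
    if X.ndim != 2 or X.shape[1] != spec.input_dim:
        raise SchemaError(f"features must be (n, {spec.input_dim})")
    if len(X) < 4 * n_folds:
        raise SchemaError("too few rows for the requested fold count")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(X))
    folds = np.array_split(order, n_folds)
    member_seeds = rng.integers(0, 2**31 - 1, n_folds)
    members = []
    for i in range(n_folds):
        val_idx = folds[i]
        tr_idx = np.concatenate([folds[j] for j in range(n_folds) if j != i])
        member_spec = replace(spec, seed=int(member_seeds[i]))
        members.append(
            _fit_network(
                member_spec,
                X[tr_idx],
                y[tr_idx],
                X[val_idx],
                y[val_idx],
                np.random.default_rng(member_spec.seed),
            )
        )
    return members


def predict_mlp_ensemble(members: list[TrainedModel], features: np.ndarray) -> np.ndarray:
    """Mean prediction over ensemble members."""
    return np.mean([predict_mlp(m, features) for m in members], axis=0)


def predict_mlp(model: TrainedModel, features: np.ndarray) -> np.ndarray | float:
    """Deterministic forward pass applying the stored standardization."""
    X = np.asarray(features, dtype=float)
    single = X.ndim == 1
    if single:
        X = X[None, :]
    if X.shape[1] != model.spec.input_dim:
        raise SchemaError(f"expected {model.spec.input_dim} features, got {X.shape[1]}")
    Xs = (X - model.x_mean) / model.x_sd
    out = _forward(Xs, model.weights, model.biases)[-1].ravel()
    out = out * model.y_sd + model.y_mean
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# Stage wrappers: H^2/R50 estimation and percent-body-fat estimation
# ---------------------------------------------------------------------------


@dataclass
class H2RModel:
    """A fitted H^2/R50 estimator (regression or Network-1 variant).

    Network variants hold a cross-validation ensemble of trained networks;
    predictions average the members.
    """

    variant: H2RVariant
    feature_set: FeatureSet
    linear: LinearModel | None = None
    mlps: list[TrainedModel] | None = None


@dataclass
class PBFModel:
    """A fitted percent-body-fat estimator for one regime."""

    regime: PBFRegime
    feature_set: FeatureSet
    linear: LinearModel | None = None
    mlps: list[TrainedModel] | None = None


def _h2r_feature_set(variant: H2RVariant) -> FeatureSet:
    if variant is H2RVariant.REGRESSION:
        return FEATURE_SETS["NET1_M1"]
    return FEATURE_SETS[variant.value]


def fit_h2r_model(
    subjects: list[SubjectRecord],
    settled: dict[str, float],
    variant: H2RVariant,
    seed: int = 0,
    hidden_nodes: int = 128,
) -> H2RModel:
    """Fit an H^2/R50 estimator on training subjects with known reference values."""
    fset = _h2r_feature_set(variant)
    X = build_feature_matrix(subjects, settled, fset)
    y = np.array([s.ref_h2r for s in subjects])
    if variant is H2RVariant.REGRESSION:
        return H2RModel(variant, fset, linear=fit_ols(X, y, fset.features))
    spec = network1_spec(input_dim=len(fset.features), seed=seed, hidden_nodes=hidden_nodes)
    return H2RModel(variant, fset, mlps=train_mlp_cv_ensemble(spec, X, y))


def estimate_h2r(
    subjects: list[SubjectRecord],
    settled: dict[str, float],
    model: H2RModel,
) -> np.ndarray:
    """Per-subject H^2/R50 estimates from upper-body inputs only."""
    if model.linear is None and model.mlps is None:
        raise WristBiaError("h2r model is not fitted")
    X = build_feature_matrix(subjects, settled, model.feature_set)
    if model.linear is not None:
        return np.asarray(predict_linear(model.linear, X))
    return predict_mlp_ensemble(model.mlps, X)


def _pbf_feature_set(regime: PBFRegime) -> FeatureSet:
    if regime in (PBFRegime.L_CONV, PBFRegime.DNN_CONV):
        return FEATURE_SETS["CONV5"]
    return FEATURE_SETS["PROP8"]


def fit_pbf_model(
    subjects: list[SubjectRecord],
    h2r_estimates: dict[str, float],
    regime: PBFRegime,
    seed: int = 0,
    hidden_nodes: int = 256,
) -> PBFModel:
    """Fit a percent-body-fat estimator on training subjects."""
    fset = _pbf_feature_set(regime)
    X = build_feature_matrix(subjects, None, fset, h2r_estimates)
    y = np.array([s.true_pbf_pct for s in subjects])
    if regime in (PBFRegime.L_CONV, PBFRegime.L_PROP):
        return PBFModel(regime, fset, linear=fit_ols(X, y, fset.features))
    spec = network2_spec(input_dim=len(fset.features), seed=seed, hidden_nodes=hidden_nodes)
    return PBFModel(regime, fset, mlps=train_mlp_cv_ensemble(spec, X, y))


def estimate_pbf(
    subjects: list[SubjectRecord],
    h2r_estimates: dict[str, float],
    model: PBFModel,
) -> np.ndarray:
    """Per-subject percent-body-fat predictions, clipped to [0, 60]%."""
    if model.linear is None and model.mlps is None:
        raise WristBiaError("pbf model is not fitted")
    X = build_feature_matrix(subjects, None, model.feature_set, h2r_estimates)
    if model.linear is not None:
        pred = np.asarray(predict_linear(model.linear, X))
    else:
        pred = predict_mlp_ensemble(model.mlps, X)
    return np.clip(pred, *PBF_CLIP)
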