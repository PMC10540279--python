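"""Small-data feed-forward network with leave-one-out cross-validation.

The regression problem is n ~ 17 ligands with <= 15 features on [0, 1] and a
scalar selectivity target, so the network is deliberately tiny: two hidden
layers of 15 nodes by default, a selectable activation, a linear output, and
full-batch Adam on mean-squared error.  Everything is plain numpy with an
explicit seed, so identical inputs give bit-identical models — a property the
validation battery (shuffling/randomisation) depends on.

Model evaluation follows the small-data convention: leave-one-out (LOO)
cross-validation, with min-max normalisation re-fitted on each training fold
so the held-out ligand never leaks into the scaling.  Quality is summarised by
RMSE, the squared Pearson correlation of predicted vs observed (the
scatter-plot R^2), and the slope of the least-squares fit of predicted on
observed (ideal m = 1).
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .features import FeatureTable, NormalizationParams, minmax_apply, minmax_fit
from .selectivity import MajorLabel, Metric, format_er, from_metric

__all__ = [
    "Activation",
    "NNConfig",
    "NNParameters",
    "CVResult",
    "activation",
    "activation_grad",
    "initialize",
    "forward",
    "loss_and_grads",
    "train",
    "train_table",
    "loo_cross_validate",
    "evaluate",
    "regression_metrics",
    "clamp_metric_value",
]


class Activation(str, enum.Enum):
    relu = "relu"
    leaky_relu = "leaky_relu"
    softplus = "softplus"
    sigmoid = "sigmoid"
    tanh = "tanh"
    linear = "linear"


@dataclass(frozen=True)
class NNConfig:
    """Architecture and training hyperparameters."""

    input_dim: int
    hidden_layers: tuple[int, ...] = (15, 15)
    activation: Activation = Activation.relu
    leaky_slope: float = 0.01
    learning_rate: float = 1e-2
    max_epochs: int = 2000
    seed: int = 0
    target_metric: Metric = Metric.s_select
    l2: float = 0.0
    loss_rel_tol: float = 1e-10

    def __post_init__(self) -> None:
        if any(w < 1 for w in self.hidden_layers):
            raise ValueError("hidden layer widths must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        object.__setattr__(self, "activation", Activation(self.activation))
        object.__setattr__(self, "target_metric", Metric(self.target_metric))
        object.__setattr__(self, "hidden_layers", tuple(self.hidden_layers))


@dataclass
class NNParameters:
    """Trained weights/biases plus the normalisation they expect."""

    weights: list[np.ndarray]           # layer l: (fan_in, fan_out)
    biases: list[np.ndarray]            # layer l: (fan_out,)
    config: NNConfig
    normalization: NormalizationParams | None = None
    feature_names: list[str] | None = None

    def __post_init__(self) -> None:
        dims = [self.config.input_dim, *self.config.hidden_layers, 1]
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (dims[l], dims[l + 1]) or b.shape != (dims[l + 1],):
                raise ValueError(f"layer {l}: shape {w.shape} breaks the chain {dims}")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise ValueError(f"layer {l}: non-finite parameters")

    def to_json(self) -> str:
        doc = {
            "config": {
                "input_dim": self.config.input_dim,
                "hidden_layers": list(self.config.hidden_layers),
                "activation": self.config.activation.value,
                "leaky_slope": self.config.leaky_slope,
                "learning_rate": self.config.learning_rate,
                "max_epochs": self.config.max_epochs,
                "seed": self.config.seed,
                "target_metric": self.config.target_metric.value,
                "l2": self.config.l2,
            },
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_names": self.feature_names,
            "normalization": None,
        }
        if self.normalization is not None:
            doc["normalization"] = {
                "feature_names": list(self.normalization.feature_names),
                "mins": self.normalization.mins.tolist(),
                "maxs": self.normalization.maxs.tolist(),
                "excluded": list(self.normalization.excluded),
            }
        return json.dumps(doc, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NNParameters":
        doc = json.loads(text)
        cfg = NNConfig(**doc["config"])
        norm = None
        if doc.get("normalization"):
            nd = doc["normalization"]
            norm = NormalizationParams(
                tuple(nd["feature_names"]),
                np.asarray(nd["mins"], dtype=float),
                np.asarray(nd["maxs"], dtype=float),
                tuple(nd["excluded"]),
            )
        return cls(
            [np.asarray(w, dtype=float) for w in doc["weights"]],
            [np.asarray(b, dtype=float) for b in doc["biases"]],
            cfg,
            norm,
            doc.get("feature_names"),
        )


@dataclass
class CVResult:
    """Predicted-vs-observed pairs on the model's target metric plus summary fit
    diagnostics.  ``degenerate`` flags cases (constant observed or predicted
    values) where R^2 and the slope are undefined and reported as NaN."""

    ligand_ids: list[str]
    observed: np.ndarray
    predicted: np.ndarray
    rmse: float
    r_squared: float
    slope: float
    metric: Metric
    degenerate: bool = False
    r_squared_cod: float = float("nan")  # 1 - SS_res/SS_tot, logged alongside

    def to_dict(self) -> dict:
        return {
            "ligand_ids": self.ligand_ids,
            "observed": self.observed.tolist(),
            "predicted": self.predicted.tolist(),
            "rmse": self.rmse,
            "r_squared": self.r_squared,
            "slope": self.slope,
            "metric": self.metric.value,
            "degenerate": self.degenerate,
            "r_squared_cod": self.r_squared_cod,
        }


# ---------------------------------------------------------------------------
# Activations
# ---------------------------------------------------------------------------

def activation(kind: Activation | str, x, leaky_slope: float = 0.01):
    """Elementwise activation; array- and scalar-safe, overflow-safe softplus."""
    kind = Activation(kind)
    x = np.asarray(x, dtype=float)
    if kind is Activation.relu:
        return np.maximum(0.0, x)
    if kind is Activation.leaky_relu:
        return np.where(x > 0, x, leaky_slope * x)
    if kind is Activation.softplus:
        return np.logaddexp(0.0, x)
    if kind is Activation.sigmoid:
        return expit(x)
    if kind is Activation.tanh:
        return np.tanh(x)
    if kind is Activation.linear:
        return x
    raise AssertionError(kind)


def activation_grad(kind: Activation | str, x, leaky_slope: float = 0.01):
    """Derivative of :func:`activation` at pre-activation ``x`` (relu uses the
    0 subgradient at the kink)."""
    kind = Activation(kind)
    x = np.asarray(x, dtype=float)
    if kind is Activation.relu:
        return (x > 0).astype(float)
    if kind is Activation.leaky_relu:
        return np.where(x > 0, 1.0, leaky_slope)
    if kind is Activation.softplus:
        return expit(x)
    if kind is Activation.sigmoid:
        s = expit(x)
        return s * (1.0 - s)
    if kind is Activation.tanh:
        return 1.0 - np.tanh(x) ** 2
    if kind is Activation.linear:
        return np.ones_like(x)
    raise AssertionError(kind)


# ---------------------------------------------------------------------------
# Initialisation / forward / gradients
# ---------------------------------------------------------------------------

def initialize(cfg: NNConfig) -> NNParameters:
    """He-scaled Gaussian weights (sd = sqrt(2/fan_in)), zero biases, seeded."""
    rng = np.random.default_rng(cfg.seed)
    dims = [cfg.input_dim, *cfg.hidden_layers, 1]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NNParameters(weights, biases, cfg)


def forward(p: NNParameters, x: np.ndarray) -> np.ndarray | float:
    """Network output: affine -> activation per hidden layer, final affine.

    Accepts a single feature vector (returns a float) or an (n, d) batch
    (returns an (n,) array).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    a = x[None, :] if single else x
    if a.shape[1] != p.config.input_dim:
        raise ValueError(
            f"expected {p.config.input_dim} features, got {a.shape[1]}"
        )
    n_layers = len(p.weights)
    for l in range(n_layers - 1):
        a = activation(p.config.activation, a @ p.weights[l] + p.biases[l],
                       p.config.leaky_slope)
    out = (a @ p.weights[-1] + p.biases[-1]).ravel()
    return float(out[0]) if single else out


def loss_and_grads(p: NNParameters, x: np.ndarray, y: np.ndarray):
    """Mean-squared-error loss and its analytic gradients by backpropagation.

    Returns (loss, dW list, db list); the gradients are exact for the smooth
    activations and use the standard subgradient convention at relu kinks.
    """
    cfg = p.config
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = len(x)
    n_layers = len(p.weights)
    acts = [x]
    zs = []
    a = x
    for l in range(n_layers - 1):
        z = a @ p.weights[l] + p.biases[l]
        zs.append(z)
        a = activation(cfg.activation, z, cfg.leaky_slope)
        acts.append(a)
    pred = (a @ p.weights[-1] + p.biases[-1]).ravel()
    resid = pred - y
    loss = float(np.mean(resid ** 2))
    if cfg.l2 > 0:
        loss += cfg.l2 * sum(float(np.sum(w ** 2)) for w in p.weights)

    dw = [np.zeros_like(w) for w in p.weights]
    db = [np.zeros_like(b) for b in p.biases]
    delta = (2.0 / n) * resid[:, None]            # (n, 1)
    dw[-1] = acts[-1].T @ delta
    db[-1] = delta.sum(axis=0)
    for l in range(n_layers - 2, -1, -1):
        delta = (delta @ p.weights[l + 1].T) * activation_grad(
            cfg.activation, zs[l], cfg.leaky_slope
        )
        dw[l] = acts[l].T @ delta
        db[l] = delta.sum(axis=0)
    if cfg.l2 > 0:
        for l in range(n_layers):
            dw[l] = dw[l] + 2.0 * cfg.l2 * p.weights[l]
    return loss, dw, db


def train(x: np.ndarray, y: np.ndarray, cfg: NNConfig) -> NNParameters:
    """Full-batch Adam on MSE until ``max_epochs`` or the relative loss change
    drops below ``loss_rel_tol``.  Deterministic for a fixed (data, cfg)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if len(x) < 2:
        raise ValueError("training needs at least 2 rows")
    if len(x) != len(y):
        raise ValueError("feature matrix and labels disagree in length")
    if x.shape[1] != cfg.input_dim:
        cfg = replace(cfg, input_dim=x.shape[1])
    p = initialize(cfg)
    # warm-start the output bias at the label mean: Adam moves each parameter
    # by at most ~lr per step, so starting the only offset parameter at 0 for
    # targets on a 0-100 scale would waste most of the epoch budget
    p.biases[-1][:] = y.mean()
    m = [np.zeros_like(w) for w in p.weights] + [np.zeros_like(b) for b in p.biases]
    v = [np.zeros_like(g) for g in m]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    prev_loss = None
    for epoch in range(1, cfg.max_epochs + 1):
        loss, dw, db = loss_and_grads(p, x, y)
        if not math.isfinite(loss):
            raise FloatingPointError(f"non-finite loss at epoch {epoch}")
        grads = dw + db
        params = p.weights + p.biases
        for i, g in enumerate(grads):
            m[i] = beta1 * m[i] + (1 - beta1) * g
            v[i] = beta2 * v[i] + (1 - beta2) * g ** 2
            mhat = m[i] / (1 - beta1 ** epoch)
            vhat = v[i] / (1 - beta2 ** epoch)
            params[i] -= cfg.learning_rate * mhat / (np.sqrt(vhat) + eps)
        if prev_loss is not None and prev_loss > 0:
            if abs(prev_loss - loss) / prev_loss < cfg.loss_rel_tol:
                break
        prev_loss = loss
    return p


def train_table(t: FeatureTable, cfg: NNConfig, *, normalize: bool = True) -> NNParameters:
    """Train on a labelled table: fit min-max on its rows, scale, train on the
    target metric, and attach the normalisation for later prediction."""
    if t.labels is None:
        raise ValueError("training requires labels")
    norm = minmax_fit(t) if normalize else None
    scaled = minmax_apply(t, norm) if normalize else t
    y = t.label_vector(cfg.target_metric)
    cfg = replace(cfg, input_dim=len(scaled.feature_names))
    p = train(scaled.values, y, cfg)
    p.normalization = norm
    p.feature_names = scaled.feature_names
    return p


# ---------------------------------------------------------------------------
# Metrics / LOO / evaluation
# ---------------------------------------------------------------------------

def regression_metrics(observed: np.ndarray, predicted: np.ndarray):
    """(rmse, r_squared, slope, degenerate, r2_cod) of predicted vs observed.

    r_squared is the squared Pearson correlation; slope is the least-squares
    slope of predicted regressed on observed; r2_cod is the coefficient of
    determination 1 - SS_res/SS_tot.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    rmse = float(np.sqrt(np.mean((pred - obs) ** 2)))
    so = obs.std()
    sp = pred.std()
    if so == 0.0 or sp == 0.0:
        return rmse, float("nan"), float("nan"), True, float("nan")
    r = float(np.corrcoef(obs, pred)[0, 1])
    slope = float(np.cov(obs, pred, ddof=0)[0, 1] / obs.var())
    cod = 1.0 - float(np.sum((pred - obs) ** 2) / np.sum((obs - obs.mean()) ** 2))
    return rmse, r * r, slope, False, cod


def loo_cross_validate(t: FeatureTable, cfg: NNConfig) -> CVResult:
    """Leave-one-out cross-validation.

    Rows are processed in ligand-id order so the result is independent of the
    input row order.  Each fold re-fits min-max normalisation on its n-1
    training rows only, trains with a fold-derived seed (cfg.seed + fold
    index), and predicts the held-out ligand on the target metric's natural
    scale.
    """
    if t.labels is None:
        raise ValueError("LOO cross-validation requires labels")
    t = t.sorted_by_id()
    ids = t.ligand_ids
    if len(ids) < 3:
        raise ValueError("LOO needs at least 3 ligands")
    observed = t.label_vector(cfg.target_metric)
    predicted = np.empty(len(ids))
    for fold, held in enumerate(ids):
        train_ids = [i for i in ids if i != held]
        fold_cfg = replace(cfg, seed=cfg.seed + fold)
        try:
            norm = minmax_fit(t, train_ids)
            scaled = minmax_apply(t, norm)
            sub = scaled.subset_rows(train_ids)
            y = sub.label_vector(cfg.target_metric)
            fold_cfg = replace(fold_cfg, input_dim=len(sub.feature_names))
            p = train(sub.values, y, fold_cfg)
            predicted[fold] = forward(p, scaled.df.loc[held].to_numpy(dtype=float))
        except Exception as exc:
            raise type(exc)(f"fold holding out ligand {held!r}: {exc}") from exc
    rmse, r2, slope, degenerate, cod = regression_metrics(observed, predicted)
    return CVResult(ids, observed, predicted, rmse, r2, slope,
                    cfg.target_metric, degenerate, cod)


def clamp_metric_value(value: float, metric: Metric | str) -> tuple[float, bool]:
    """Clamp an out-of-domain metric prediction to the nearest valid value.

    Returns (clamped_value, was_clamped).  Bounds keep every downstream
    conversion finite: percentages in [0.05, 99.95], ee in [0, 99.9],
    er_ratio in [1/1999, 1999] (i.e. er between 0.05:99.95 and 99.95:0.05).
    """
    metric = Metric(metric)
    lo, hi = {
        Metric.ee: (0.0, 99.9),
        Metric.er_ratio: (1.0 / 1999.0, 1999.0),
        Metric.ln_er: (-math.log(1999.0), math.log(1999.0)),
        Metric.s_select: (0.05, 99.95),
        Metric.r_select: (0.05, 99.95),
    }[metric]
    clamped = min(hi, max(lo, value))
    return clamped, clamped != value


def evaluate(p: NNParameters, t: FeatureTable) -> dict:
    """Apply a trained model to a labelled table.

    Returns a CVResult-shaped report on the model's target metric plus the
    predictions rendered as er "X:Y" strings (out-of-domain predictions are
    clamped and counted).
    """
    if t.labels is None:
        raise ValueError("evaluation requires labels")
    if p.feature_names is not None:
        missing = sorted(set(p.feature_names) - set(t.feature_names))
        extra = sorted(set(t.feature_names) - set(p.feature_names))
        if missing:
            raise ValueError(f"table lacks features {missing} (extra: {extra})")
    t = t.sorted_by_id()
    scaled = minmax_apply(t, p.normalization) if p.normalization is not None else t
    if p.feature_names is not None:
        scaled = scaled.restrict(p.feature_names)
    observed = t.label_vector(p.config.target_metric)
    predicted = np.asarray(forward(p, scaled.values), dtype=float)
    rmse, r2, slope, degenerate, cod = regression_metrics(observed, predicted)
    er_strings = []
    n_clamped = 0
    for v in predicted:
        cv, was = clamp_metric_value(float(v), p.config.target_metric)
        n_clamped += was
        rec = from_metric(cv, p.config.target_metric, MajorLabel.S)
        er_strings.append(format_er(rec))
    result = CVResult(t.ligand_ids, observed, predicted, rmse, r2, slope,
                      p.config.target_metric, degenerate, cod)
    return {"result": result, "er_strings": er_strings, "n_clamped": n_clamped}
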