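"""Maximum-entropy presence-background model with hinge features.

The model estimates a Gibbs distribution ``q(x) = exp(eta(x)) / Z`` over
the background cells, with ``eta(x) = sum_j lambda_j f_j(x)`` a linear
combination of hinge features, chosen to match the presence feature
means subject to an L1 penalty.  Fitting minimizes the penalized
log-loss

    L(lambda) = -(1/m) sum_presence eta(x_i)
                + log sum_background exp(eta(x)) - log N
                + sum_j r_j |lambda_j|,

with per-feature penalties ``r_j = beta * sqrt(s2_j / m)`` where ``s2_j``
is the feature variance over the m presences and ``beta`` the global
regularization multiplier.  This is convex; the solver is cyclic
coordinate descent with a Newton step per coordinate and
soft-thresholding on the penalty, converging on the relative change of
the full objective.

Only hinge features are used: for each variable, forward hinges
``max(0, x - t) / (max - t)`` and reverse hinges ``max(0, t - x) /
(t - min)`` at knots placed on evenly spaced quantiles of the pooled
presence + background values, all scaled into [0, 1] (and clamped there
when predicting outside the training range).  Hinge-only models yield
additive piecewise-linear responses on the link scale — flexible enough
for saturating and unimodal shapes while remaining smooth.

The raw output ``q`` is a relative occurrence rate; the logistic output

    p(x) = tau * exp(H) * q(x) / (1 - tau + tau * exp(H) * q(x)),

with ``H`` the entropy of ``q`` over the training background and ``tau``
the assumed prevalence at an average site, maps it to an interpretable
(0, 1) suitability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .raster import Grid, GridStack

__all__ = [
    "MaxentConfig",
    "HingeFeature",
    "FeatureSet",
    "MaxentModel",
    "build_features",
    "fit",
    "train",
    "predict_raw",
    "predict_logistic",
    "response_curve",
    "limiting_factor",
]


@dataclass
class MaxentConfig:
    """Model hyperparameters.

    beta_multiplier
        Global scale on the per-feature L1 penalties; larger values give
        smoother, sparser models.  Default 2.5.
    prevalence_tau
        Assumed probability of presence at an average site; affects only
        the logistic output transform, never the fit.  Default 0.3.
    knots_per_variable
        Number of quantile knots per variable for hinge expansion.
    convergence_tol
        Relative objective change per sweep at which fitting stops.
    """

    beta_multiplier: float = 2.5
    prevalence_tau: float = 0.3
    knots_per_variable: int = 30
    convergence_tol: float = 1e-7
    max_iterations: int = 2000

    def __post_init__(self) -> None:
        if self.beta_multiplier <= 0:
            raise ValueError("beta_multiplier must be positive")
        if not (0 < self.prevalence_tau < 1):
            raise ValueError("prevalence_tau must lie in (0, 1)")
        if self.knots_per_variable < 1 or self.max_iterations < 1:
            raise ValueError("knots_per_variable and max_iterations must be >= 1")
        if self.convergence_tol <= 0:
            raise ValueError("convergence_tol must be positive")


@dataclass(frozen=True)
class HingeFeature:
    """One hinge basis function on a named variable.

    Forward: ``clip((x - knot) / (vmax - knot), 0, 1)``;
    reverse: ``clip((knot - x) / (knot - vmin), 0, 1)``.
    Values are clamped into [0, 1] also outside the training range.
    """

    variable: str
    direction: str  # "forward" | "reverse"
    knot: float
    vmin: float
    vmax: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.direction == "forward":
            return np.clip((x - self.knot) / (self.vmax - self.knot), 0.0, 1.0)
        return np.clip((self.knot - x) / (self.knot - self.vmin), 0.0, 1.0)


@dataclass
class FeatureSet:
    features: list[HingeFeature]
    variables: list[str]
    ranges: dict[str, tuple[float, float]]

    def __len__(self) -> int:
        return len(self.features)

    def transform(self, table: pd.DataFrame) -> np.ndarray:
        """Map a table of raw predictor values to the (n, J) feature matrix."""
        n = len(table)
        out = np.empty((n, len(self.features)))
        for j, f in enumerate(self.features):
            out[:, j] = f(table[f.variable].to_numpy())
        return out


def build_features(
    presence_values: pd.DataFrame,
    background_values: pd.DataFrame,
    config: MaxentConfig,
) -> FeatureSet:
    """Hinge expansion with knots at quantiles of the pooled values.

    Per variable: knots at ``knots_per_variable`` evenly spaced interior
    quantiles of pooled presence + background values, one forward and
    one reverse hinge per knot; duplicate and degenerate knots (at the
    variable's min or max) are dropped.  Constant variables contribute
    no features.
    """
    if presence_values.empty or background_values.empty:
        raise ValueError("presence and background tables must be non-empty")
    if list(presence_values.columns) != list(background_values.columns):
        raise ValueError("presence and background tables must share columns")
    variables = list(presence_values.columns)
    features: list[HingeFeature] = []
    ranges: dict[str, tuple[float, float]] = {}
    probs = np.linspace(0.0, 1.0, config.knots_per_variable + 2)[1:-1]
    for var in variables:
        pooled = np.concatenate(
            [presence_values[var].to_numpy(float), background_values[var].to_numpy(float)]
        )
        vmin, vmax = float(pooled.min()), float(pooled.max())
        ranges[var] = (vmin, vmax)
        if vmin == vmax:
            continue
        # knots sit on observed values so ties collapse on coarse variables
        knots = np.unique(np.quantile(pooled, probs, method="closest_observation"))
        knots = knots[(knots > vmin) & (knots < vmax)]
        for t in knots:
            features.append(HingeFeature(var, "forward", float(t), vmin, vmax))
            features.append(HingeFeature(var, "reverse", float(t), vmin, vmax))
    return FeatureSet(features, variables, ranges)


@dataclass
class MaxentModel:
    """A fitted maximum-entropy model.

    Stores everything needed to predict anywhere: the hinge features and
    their coefficients, the log-normalizer ``log_z`` and entropy ``H``
    of the raw distribution over the *training* background, the
    prevalence ``tau`` of the logistic transform, and the presence means
    of the raw predictors (the reference point for response curves and
    limiting-factor maps).
    """

    features: FeatureSet
    coefficients: np.ndarray
    log_z: float
    entropy: float
    tau: float
    presence_means: dict[str, float] = field(default_factory=dict)
    n_background: int = 0

    @property
    def variables(self) -> list[str]:
        return self.features.variables

    def eta(self, feature_matrix: np.ndarray) -> np.ndarray:
        if len(self.features) == 0:
            return np.zeros(feature_matrix.shape[0])
        return feature_matrix @ self.coefficients

    # -- serialization ----------------------------------------------------

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variables": self.features.variables,
            "ranges": {k: list(v) for k, v in self.features.ranges.items()},
            "features": [
                {"variable": f.variable, "direction": f.direction, "knot": f.knot,
                 "vmin": f.vmin, "vmax": f.vmax}
                for f in self.features.features
            ],
            "coefficients": self.coefficients.tolist(),
            "log_z": self.log_z,
            "entropy": self.entropy,
            "tau": self.tau,
            "presence_means": self.presence_means,
            "n_background": self.n_background,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MaxentModel":
        d = json.loads(Path(path).read_text())
        fs = FeatureSet(
            [HingeFeature(**f) for f in d["features"]],
            d["variables"],
            {k: tuple(v) for k, v in d["ranges"].items()},
        )
        return cls(fs, np.asarray(d["coefficients"], dtype=float), d["log_z"], d["entropy"],
                   d["tau"], d["presence_means"], d["n_background"])


_MIN_FEATURE_SD = 0.05  # floor on the presence sd of a [0,1] feature


def penalties(presence_features: np.ndarray, config: MaxentConfig) -> np.ndarray:
    """Per-feature L1 penalties r_j = beta * sqrt(s2_j / m).

    The presence standard deviation is floored at a small fraction of
    the unit feature range: a hinge that happens to be constant over
    the presences would otherwise carry zero penalty and its
    coefficient would be free to run away.
    """
    m = presence_features.shape[0]
    s2 = presence_features.var(axis=0, ddof=1) if m > 1 else np.zeros(presence_features.shape[1])
    s2 = np.maximum(s2, _MIN_FEATURE_SD**2)
    return config.beta_multiplier * np.sqrt(s2 / m)


def objective(
    lam: np.ndarray,
    presence_features: np.ndarray,
    background_features: np.ndarray,
    r: np.ndarray,
) -> float:
    """The penalized log-loss L(lambda); the quantity fitting minimizes."""
    n = background_features.shape[0]
    eta_p = presence_features @ lam
    eta_b = background_features @ lam
    return float(
        -eta_p.mean() + logsumexp(eta_b) - np.log(n) + np.abs(lam) @ r
    )


def fit(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    config: MaxentConfig,
    feature_set: FeatureSet | None = None,
    presence_means: dict[str, float] | None = None,
) -> MaxentModel:
    """Fit coefficients by cyclic coordinate descent with soft-thresholding.

    Deterministic given inputs.  Raises if the relative objective change
    has not fallen below ``convergence_tol`` within ``max_iterations``
    sweeps; the error message carries the last objective value.
    """
    F_p = np.asarray(presence_features, dtype=float)
    F_b = np.asarray(background_features, dtype=float)
    m, J = F_p.shape
    n = F_b.shape[0]
    if m < 2:
        raise ValueError("need at least 2 presence points")
    if n < 1:
        raise ValueError("background must be non-empty")
    if feature_set is None:
        feature_set = FeatureSet([], [], {})

    lam = np.zeros(J)
    if J == 0:
        return _finalize(lam, F_b, feature_set, config, presence_means)

    r = penalties(F_p, config)
    fbar_p = F_p.mean(axis=0)
    eta_b = np.zeros(n)
    w = np.full(n, 1.0 / n)  # q over background, kept in sync with lam
    obj = objective(lam, F_p, F_b, r)
    step_cap = 2.0

    for sweep in range(config.max_iterations):
        for j in range(J):
            fj = F_b[:, j]
            mean_q = w @ fj
            grad = mean_q - fbar_p[j]
            if lam[j] == 0.0 and abs(grad) <= r[j]:
                continue  # KKT-inactive coordinate
            curv = max(w @ (fj * fj) - mean_q * mean_q, 1e-10)
            z = curv * lam[j] - grad
            new = np.sign(z) * max(abs(z) - r[j], 0.0) / curv
            delta = np.clip(new - lam[j], -step_cap, step_cap)
            if delta == 0.0:
                continue
            lam[j] += delta
            eta_b += delta * fj
            ez = np.exp(eta_b - eta_b.max())
            w = ez / ez.sum()
        new_obj = objective(lam, F_p, F_b, r)
        if new_obj > obj + 1e-12:
            step_cap = max(step_cap / 2, 1e-3)  # safeguard: Newton overshoot
        if abs(new_obj - obj) <= config.convergence_tol * max(abs(obj), 1.0):
            obj = new_obj
            break
        obj = new_obj
        # refresh eta to kill accumulated drift
        eta_b = F_b @ lam
        ez = np.exp(eta_b - eta_b.max())
        w = ez / ez.sum()
    else:
        raise RuntimeError(
            f"maxent fit did not converge in {config.max_iterations} sweeps; "
            f"last objective {obj:.10g}"
        )
    return _finalize(lam, F_b, feature_set, config, presence_means)


def _finalize(
    lam: np.ndarray,
    F_b: np.ndarray,
    feature_set: FeatureSet,
    config: MaxentConfig,
    presence_means: dict[str, float] | None,
) -> MaxentModel:
    n = F_b.shape[0]
    eta_b = F_b @ lam if lam.size else np.zeros(n)
    log_z = float(logsumexp(eta_b))
    log_q = eta_b - log_z
    entropy = float(-(np.exp(log_q) @ log_q))
    return MaxentModel(
        feature_set, lam, log_z, max(entropy, 0.0), config.prevalence_tau,
        presence_means or {}, n,
    )


def train(
    presence_values: pd.DataFrame,
    background_values: pd.DataFrame,
    config: MaxentConfig,
    add_samples_to_background: bool = True,
) -> MaxentModel:
    """Convenience wrapper: hinge expansion + fit from raw predictor tables.

    By default the presence samples are added to the background before
    fitting (the convention of the reference Maxent implementation).
    This keeps the objective bounded even when a feature separates the
    presences perfectly from the sampled background — otherwise its
    coefficient would diverge.
    """
    fs = build_features(presence_values, background_values, config)
    F_p = fs.transform(presence_values)
    F_b = fs.transform(background_values)
    if add_samples_to_background:
        F_b = np.vstack([F_b, F_p])
    means = {v: float(presence_values[v].mean()) for v in fs.variables}
    return fit(F_p, F_b, config, feature_set=fs, presence_means=means)


def predict_raw(model: MaxentModel, feature_matrix: np.ndarray, renormalize: bool = False) -> np.ndarray:
    """Raw (relative occurrence rate) output e^eta / Z.

    With ``renormalize=True`` the output is renormalized to sum to 1
    over the given points instead of using the training normalizer.
    """
    eta = model.eta(np.asarray(feature_matrix, dtype=float))
    if renormalize:
        return np.exp(eta - logsumexp(eta))
    return np.exp(eta - model.log_z)


def predict_logistic(model: MaxentModel, feature_matrix: np.ndarray) -> np.ndarray:
    """Logistic suitability p = tau*e^H*q / (1 - tau + tau*e^H*q), in (0, 1)."""
    eta = model.eta(np.asarray(feature_matrix, dtype=float))
    # e^H * q on the log scale for stability
    a = model.tau * np.exp(model.entropy + eta - model.log_z)
    return a / (1.0 - model.tau + a)


def predict_table(model: MaxentModel, table: pd.DataFrame) -> np.ndarray:
    """Logistic prediction from a raw predictor table."""
    return predict_logistic(model, model.features.transform(table))


def response_curve(
    model: MaxentModel,
    variable: str,
    n_steps: int = 100,
    reference: str = "presence-mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Marginal response: sweep one variable, others at presence means.

    Returns (x values over the variable's observed range, logistic
    predictions).
    """
    if variable not in model.variables:
        raise KeyError(f"unknown variable {variable!r}")
    if reference != "presence-mean":
        raise ValueError(f"unsupported reference {reference!r}")
    vmin, vmax = model.features.ranges[variable]
    xs = np.linspace(vmin, vmax, n_steps)
    table = pd.DataFrame({
        v: (xs if v == variable else np.full(n_steps, model.presence_means[v]))
        for v in model.variables
    })
    return xs, predict_table(model, table)


def limiting_factor(model: MaxentModel, stack: GridStack) -> Grid:
    """Map of the predictor most limiting suitability at each cell.

    For each variable, the cell's value is replaced by the variable's
    presence mean and the logistic prediction recomputed; the limiting
    variable maximizes (replaced - actual).  Ties, and cells where no
    replacement helps, resolve to the earliest variable in the model's
    canonical order.  Output values are indices into ``model.variables``.
    """
    for v in model.variables:
        if v not in stack:
            raise KeyError(f"stack is missing model variable {v!r}")
    rows, cols, values = stack.table(model.variables)
    table = pd.DataFrame(values, columns=model.variables)
    actual = predict_table(model, table)
    deltas = np.empty((len(table), len(model.variables)))
    for i, v in enumerate(model.variables):
        replaced = table.copy()
        replaced[v] = model.presence_means[v]
        deltas[:, i] = predict_table(model, replaced) - actual
    # argmax takes the first maximum -> canonical-order tie-break
    idx = np.argmax(deltas, axis=1)
    template = stack.template
    out = np.zeros(template.shape)
    mask = np.ones(template.shape, dtype=bool)
    out[rows, cols] = idx
    mask[rows, cols] = False
    return template.like(out, mask)


def predict_stack(model: MaxentModel, stack: GridStack) -> Grid:
    """Logistic suitability map over a predictor stack."""
    rows, cols, values = stack.table(model.variables)
    p = predict_table(model, pd.DataFrame(values, columns=model.variables))
    template = stack.template
    out = np.zeros(template.shape)
    mask = np.ones(template.shape, dtype=bool)
    out[rows, cols] = p
    mask[rows, cols] = False
    return template.like(out, mask)
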