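"""Tabular local-surrogate (LIME-style) explanations for the classifiers.

For one instance x and a trained black-box classifier f, the explainer

1. draws perturbations feature-wise from a normal law centered on x with the
   training-set spread of each feature (continuous features, no
   discretization);
2. weights each perturbation z by the proximity kernel
   ``exp(-D(x, z)^2 / w^2)`` with D the Euclidean distance in standardized
   units and w the kernel width (default ``0.75 * sqrt(d)``);
3. fits a proximity-weighted ridge regression of the black-box class
   probability on the standardized features, keeps the K largest
   coefficients in absolute value (hard sparsity), and refits the ridge on
   the kept set.

The refit coefficients are the signed feature contributions; the weighted
coefficient of determination of the surrogate on the perturbation sample is
reported as local fidelity. Contributions are rendered with the instance's
position relative to the training quartiles (e.g. ``RP_Gamma_C <= 0.12``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .selection import TrainedModel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LimeConfig:
    n_samples: int = 5000
    kernel_width: float | None = None  # default 0.75 * sqrt(d)
    num_features: int = 10
    ridge_penalty: float = 1.0
    seed: int = 0

    def validate(self, d: int) -> None:
        if self.n_samples < 10:
            raise ValueError("n_samples must be >= 10")
        if self.kernel_width is not None and self.kernel_width <= 0:
            raise ValueError("kernel_width must be positive")
        if not 1 <= self.num_features <= d:
            raise ValueError(f"num_features must lie in [1, {d}]")
        if self.ridge_penalty < 0:
            raise ValueError("ridge_penalty must be nonnegative")

    def width(self, d: int) -> float:
        return self.kernel_width if self.kernel_width is not None else 0.75 * np.sqrt(d)


@dataclass
class TrainStats:
    """Per-feature statistics of the training partition used for sampling,
    standardization and quartile display."""

    feature_names: list[str]
    mean: np.ndarray
    std: np.ndarray
    quartiles: np.ndarray  # (3, d): q1, median, q3

    @classmethod
    def from_table(cls, table: pd.DataFrame, feature_names: list[str]) -> "TrainStats":
        X = table[feature_names].to_numpy(dtype=float)
        std = X.std(axis=0, ddof=1)
        if (std < 0).any():
            raise ValueError("negative spread")
        return cls(
            feature_names=list(feature_names),
            mean=X.mean(axis=0),
            std=std,
            quartiles=np.quantile(X, [0.25, 0.5, 0.75], axis=0),
        )


@dataclass
class Explanation:
    instance_id: str
    predicted_class: str
    class_probabilities: dict[str, float]
    contributions: list[tuple[str, float, str]]  # (feature, signed weight, condition)
    intercept: float
    local_fidelity_r2: float

    def to_dict(self) -> dict:
        return {
            "instance_id": self.instance_id,
            "predicted_class": self.predicted_class,
            "class_probabilities": self.class_probabilities,
            "contributions": [
                {"feature": f, "weight": w, "condition": c}
                for f, w, c in self.contributions
            ],
            "intercept": self.intercept,
            "local_fidelity_r2": self.local_fidelity_r2,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)

    def contribution_percentages(self) -> dict[str, float]:
        """Optional sum-normalized view: |weight| as a percentage of the
        total absolute contribution."""
        total = sum(abs(w) for _, w, _ in self.contributions)
        if total == 0:
            return {f: 0.0 for f, _, _ in self.contributions}
        return {f: 100 * abs(w) / total for f, w, _ in self.contributions}


def sample_perturbations(
    instance: np.ndarray,
    stats: TrainStats,
    config: LimeConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Perturbation sample around ``instance`` and proximity weights.

    Row 0 is the unperturbed instance (weight exactly 1). Features with zero
    training spread stay fixed.
    """
    d = len(stats.feature_names)
    config.validate(d)
    rng = rng or np.random.default_rng(config.seed)
    x = np.asarray(instance, dtype=float)
    if x.shape != (d,):
        raise ValueError(f"instance must have {d} features")
    samples = x + rng.standard_normal((config.n_samples, d)) * stats.std
    samples[0] = x
    safe = np.where(stats.std > 0, stats.std, 1.0)
    z = (samples - x) / safe
    dist2 = (z**2).sum(axis=1)
    weights = np.exp(-dist2 / config.width(d) ** 2)
    return samples, weights


def _weighted_ridge(
    Z: np.ndarray, y: np.ndarray, w: np.ndarray, alpha: float
) -> tuple[float, np.ndarray]:
    """Closed-form proximity-weighted ridge with unpenalized intercept."""
    wsum = w.sum()
    zbar = (w[:, None] * Z).sum(axis=0) / wsum
    ybar = float((w * y).sum() / wsum)
    Zc, yc = Z - zbar, y - ybar
    A = (Zc * w[:, None]).T @ Zc + alpha * np.eye(Z.shape[1])
    b = (Zc * w[:, None]).T @ yc
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        alpha2 = max(10 * alpha, 1e-6)
        logger.warning("singular surrogate system; retrying with ridge_penalty=%g", alpha2)
        beta = np.linalg.solve(A + (alpha2 - alpha) * np.eye(Z.shape[1]), b)
    intercept = ybar - float(beta @ zbar)
    return intercept, beta


def fit_local_surrogate(
    samples: np.ndarray,
    weights: np.ndarray,
    target: np.ndarray,
    stats: TrainStats,
    config: LimeConfig,
) -> tuple[float, dict[str, float], float]:
    """Sparse weighted linear surrogate of the black-box probabilities.

    Returns (intercept, coefficients in standardized units keyed by feature
    name, weighted R^2). A constant target gives all-zero coefficients and
    R^2 = NaN (flagged undefined).
    """
    d = len(stats.feature_names)
    y = np.asarray(target, dtype=float)
    safe = np.where(stats.std > 0, stats.std, 1.0)
    Z = (samples - stats.mean) / safe
    wvar = _weighted_var(y, weights)
    if np.ptp(y) == 0 or wvar == 0:
        logger.info("constant black-box output; surrogate is the constant")
        return float(y[0]), {f: 0.0 for f in stats.feature_names}, float("nan")
    _, beta_full = _weighted_ridge(Z, y, weights, config.ridge_penalty)
    # hard sparsity: keep the K largest standardized coefficients, refit
    keep = np.argsort(-np.abs(beta_full), kind="stable")[: config.num_features]
    keep = np.sort(keep)
    intercept, beta_k = _weighted_ridge(Z[:, keep], y, weights, config.ridge_penalty)
    pred = intercept + Z[:, keep] @ beta_k
    r2 = 1.0 - _weighted_var(y - pred, weights, center=False) / wvar
    coefs = {stats.feature_names[j]: float(b) for j, b in zip(keep, beta_k)}
    return float(intercept), coefs, float(r2)


def _weighted_var(y: np.ndarray, w: np.ndarray, center: bool = True) -> float:
    mu = (w * y).sum() / w.sum() if center else 0.0
    return float((w * (y - mu) ** 2).sum() / w.sum())


def _condition_text(name: str, value: float, q: np.ndarray) -> str:
    q1, q2, q3 = q
    if value <= q1:
        return f"{name} <= {q1:.3g}"
    if value <= q2:
        return f"{q1:.3g} < {name} <= {q2:.3g}"
    if value <= q3:
        return f"{q2:.3g} < {name} <= {q3:.3g}"
    return f"{name} > {q3:.3g}"


def explain_instance(
    model: TrainedModel,
    instance: pd.Series | dict,
    train_table: pd.DataFrame,
    config: LimeConfig = LimeConfig(),
    target_class: str | None = None,
    instance_id: str = "",
) -> Explanation:
    """Explanation of the model's prediction for one instance.

    The surrogate regresses the black-box probability of ``target_class``
    (default: the predicted class) on the perturbation sample.
    """
    if isinstance(instance, dict):
        instance = pd.Series(instance)
    have = set(instance.index) & set(model.feature_names)
    if have != set(model.feature_names):
        diff = set(model.feature_names) ^ set(instance.index)
        raise ValueError(f"feature-name mismatch; symmetric difference: {sorted(diff)}")
    stats = TrainStats.from_table(train_table, model.feature_names)
    x = instance[model.feature_names].to_numpy(dtype=float)

    row = pd.DataFrame([x], columns=model.feature_names)
    proba_x = model.predict_proba(row)[0]
    class_probs = {c: float(p) for c, p in zip(model.classes, proba_x)}
    predicted = model.classes[int(np.argmax(proba_x))]
    target = target_class or predicted

    samples, weights = sample_perturbations(x, stats, config)
    sample_table = pd.DataFrame(samples, columns=model.feature_names)
    proba = model.predict_proba(sample_table)[:, model.classes.index(target)]
    intercept, coefs, r2 = fit_local_surrogate(samples, weights, proba, stats, config)

    ranked = sorted(coefs.items(), key=lambda kv: -abs(kv[1]))
    contributions = [
        (
            name,
            weight,
            _condition_text(name, float(instance[name]),
                            stats.quartiles[:, stats.feature_names.index(name)]),
        )
        for name, weight in ranked
    ]
    return Explanation(
        instance_id=instance_id or "instance",
        predicted_class=predicted,
        class_probabilities=class_probs,
        contributions=contributions,
        intercept=intercept,
        local_fidelity_r2=r2,
    )


def plot_explanation(explanation: Explanation, path: str | None = None):
    """Horizontal-bar plot of signed contributions (largest on top)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = [f for f, _, _ in explanation.contributions][::-1]
    vals = [w for _, w, _ in explanation.contributions][::-1]
    fig, ax = plt.subplots(figsize=(6, 0.4 * len(names) + 1.5))
    colors = ["tab:green" if v >= 0 else "tab:red" for v in vals]
    ax.barh(names, vals, color=colors)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel("local contribution to class probability")
    ax.set_title(
        f"{explanation.predicted_class} "
        f"(p = {explanation.class_probabilities[explanation.predicted_class]:.2f})"
    )
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
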