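"""Competence prediction and its modulation of learning and exploration.

A logistic regressor maps a point of the 2-D internal space to the
predicted probability that the policy encoded there reproduces its
associated sensory effects (operationally: a high value of the radial
closeness measure xi during the episode).  Its mean over all policy-map
nodes is the *global* competence C_tot, which scales the epoch learning
rate down as the agent masters its world; the *local* competence of the
policy chosen for an episode scales both that episode's contribution to
the map update (by 1 - c_k) and the amplitude of exploration noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .stm import TopologicalMap

#: default exploration-noise scale in normalized policy-parameter units
DEFAULT_SIGMA_EXPLORE = 0.15


def _features(points: np.ndarray, extent: float) -> np.ndarray:
    """Quadratic feature expansion (x, y, x^2, y^2, xy, 1) of internal
    points, with coordinates rescaled to [0, 1] by the grid extent so the
    expansion stays well-conditioned for plain gradient steps."""
    pts = np.atleast_2d(np.asarray(points, dtype=float)) / max(extent, 1.0)
    x, y = pts[:, 0], pts[:, 1]
    return np.stack([x, y, x**2, y**2, x * y, np.ones_like(x)], axis=1)


@dataclass
class CompetencePredictor:
    """Logistic model over quadratic features of an internal point.

    ``extent`` is G - 1, the side of the internal space's bounding box.
    Zero weights predict 0.5 everywhere (the maximally uncertain prior).
    """

    extent: float
    fit_rate: float = 0.1
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = np.zeros(6)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (6,):
            raise ValueError("weights must have 6 components")
        if self.fit_rate <= 0:
            raise ValueError("fit_rate must be positive")


def predict(point: np.ndarray, predictor: CompetencePredictor) -> float:
    """Predicted success probability for one internal point, in (0, 1)."""
    z = _features(point, predictor.extent) @ predictor.weights
    return float(1.0 / (1.0 + np.exp(-z[0])))


def predict_batch(points: np.ndarray, predictor: CompetencePredictor) -> np.ndarray:
    z = _features(points, predictor.extent) @ predictor.weights
    return 1.0 / (1.0 + np.exp(-z))


def fit_update(
    predictor: CompetencePredictor,
    points: Sequence[np.ndarray],
    targets: np.ndarray,
) -> CompetencePredictor:
    """One cross-entropy gradient step on a batch of (point, target) pairs.

    Targets are soft labels in [0, 1] (the radial closeness reached in an
    episode).  An empty batch returns the predictor unchanged.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    t = np.asarray(targets, dtype=float).ravel()
    if pts.shape[0] == 0:
        return replace(predictor, weights=predictor.weights.copy())
    if t.shape[0] != pts.shape[0]:
        raise ValueError("points and targets length mismatch")
    if np.any(t < 0) or np.any(t > 1):
        raise ValueError("targets must lie in [0, 1]")
    phi = _features(pts, predictor.extent)
    pred = 1.0 / (1.0 + np.exp(-(phi @ predictor.weights)))
    grad = phi.T @ (t - pred) / pts.shape[0]
    w = predictor.weights + predictor.fit_rate * grad
    if not np.all(np.isfinite(w)):
        raise FloatingPointError("non-finite predictor weights")
    return replace(predictor, weights=w)


def global_competence(
    policy_map: TopologicalMap, predictor: CompetencePredictor
) -> float:
    """Mean predicted competence over all policy-map grid nodes (C_tot)."""
    return float(np.mean(predict_batch(policy_map.grid_positions, predictor)))


def modulated_eta(c_tot: float, eta_min: float, eta_max: float) -> float:
    """Global learning rate, linear between the endpoints: eta_max at zero
    competence, eta_min at full competence."""
    if not (0.0 <= c_tot <= 1.0):
        raise ValueError("C_tot must lie in [0, 1]")
    if eta_min > eta_max:
        raise ValueError("eta_min must not exceed eta_max")
    return eta_max - c_tot * (eta_max - eta_min)


def exploration_noise(
    policy: np.ndarray,
    c_k: float,
    sigma_explore: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian exploration noise scaled by incompetence.

    Adds i.i.d. noise of standard deviation ``sigma_explore * (1 - c_k)``
    per parameter; at full local competence the policy is returned
    unchanged (exploitation).
    """
    theta = np.asarray(policy, dtype=float)
    if sigma_explore <= 0:
        raise ValueError("sigma_explore must be positive")
    if c_k >= 1.0:
        return theta.copy()
    std = sigma_explore * (1.0 - c_k)
    return theta + rng.normal(0.0, std, size=theta.shape)
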