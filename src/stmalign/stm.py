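"""Self-organizing maps and their supervised (anchored) generalization.

A :class:`TopologicalMap` is a grid of prototype vectors in one modality
space (visual, touch, proprioceptive or policy).  The grid nodes live on a
fixed 2-D integer lattice — the *internal space* shared by every modality —
so that a pattern in any modality can be summarized as a continuous point
in the same 2-D space, and distances between modalities become meaningful.

The classic SOM minimizes a neighborhood-weighted sum of squared
pattern-to-prototype distances,

    L = 1/2 sum_i sum_j phi_ij ||x_i - c_j||^2 ,

with phi_ij a radial function of the grid distance between node j and the
winning node for pattern i.  The supervised variant (STM) multiplies phi by
a second radial factor centred on an externally supplied *anchor* position
t_i in the grid, which confines the representation of pattern i to a
controlled region of the internal space.  Training several maps with a
shared anchor per tuple of paired patterns aligns their manifolds.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple, Optional

import numpy as np

#: per-node normalization floor in the batched update
EPS_NORM = 1e-8
#: activations below this are treated as exactly zero in centroids
ACTIVATION_FLOOR = 1e-12

MODALITY_TAGS = ("visual", "touch", "proprio", "policy")


def make_grid(grid_size: int) -> np.ndarray:
    """Integer-lattice node positions {0..G-1}^2, row-major, shape (G^2, 2)."""
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    rows, cols = np.meshgrid(
        np.arange(grid_size), np.arange(grid_size), indexing="ij"
    )
    return np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)


@dataclass
class TopologicalMap:
    """A grid of K = G^2 prototypes in a D-dimensional modality space.

    Parameters
    ----------
    prototypes
        (K, D) prototype matrix; finite.
    grid_positions
        (K, 2) fixed internal-space node coordinates (integer lattice).
    sigma_r
        Neighborhood width in grid units (> 0).  Annealed during training.
    sigma_t
        Anchor width in grid units (> 0), used only for anchored updates.
    modality_tag
        One of ``visual | touch | proprio | policy``.
    """

    prototypes: np.ndarray
    grid_positions: np.ndarray
    sigma_r: float
    sigma_t: float
    modality_tag: str = "visual"

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=float)
        self.grid_positions = np.asarray(self.grid_positions, dtype=float)
        if self.prototypes.ndim != 2:
            raise ValueError("prototypes must be a (K, D) matrix")
        if self.grid_positions.shape != (self.prototypes.shape[0], 2):
            raise ValueError("grid_positions must be (K, 2)")
        if self.sigma_r <= 0 or self.sigma_t <= 0:
            raise ValueError("sigma_r and sigma_t must be positive")
        if not np.all(np.isfinite(self.prototypes)):
            raise ValueError("prototypes must be finite")
        if len(np.unique(self.grid_positions, axis=0)) != self.n_nodes:
            raise ValueError("grid positions must be pairwise distinct")
        if self.modality_tag not in MODALITY_TAGS:
            raise ValueError(f"unknown modality_tag {self.modality_tag!r}")

    @property
    def n_nodes(self) -> int:
        return self.prototypes.shape[0]

    @property
    def dim(self) -> int:
        return self.prototypes.shape[1]

    @property
    def grid_size(self) -> int:
        return int(round(np.sqrt(self.n_nodes)))

    def with_sigma_r(self, sigma_r: float) -> "TopologicalMap":
        return replace(self, prototypes=self.prototypes.copy(), sigma_r=sigma_r)

    def copy(self) -> "TopologicalMap":
        return replace(self, prototypes=self.prototypes.copy())


def new_map(
    grid_size: int,
    dim: int,
    rng: np.random.Generator,
    *,
    sigma_r: Optional[float] = None,
    sigma_t: float = 1.5,
    modality_tag: str = "visual",
) -> TopologicalMap:
    """A fresh map with prototypes i.i.d. uniform in [0, 1]^D.

    ``sigma_r`` defaults to ``grid_size / 2`` (the start of the annealing
    schedule used in training).
    """
    grid = make_grid(grid_size)
    protos = rng.uniform(0.0, 1.0, size=(grid.shape[0], dim))
    return TopologicalMap(
        prototypes=protos,
        grid_positions=grid,
        sigma_r=float(sigma_r) if sigma_r is not None else grid_size / 2.0,
        sigma_t=sigma_t,
        modality_tag=modality_tag,
    )


def _check_pattern(pattern: np.ndarray, tm: TopologicalMap) -> np.ndarray:
    pattern = np.asarray(pattern, dtype=float).ravel()
    if pattern.shape[0] != tm.dim:
        raise ValueError(
            f"pattern dimension {pattern.shape[0]} != map dimension {tm.dim}"
        )
    if not np.all(np.isfinite(pattern)):
        raise ValueError("pattern must be finite")
    return pattern


def find_winner(pattern: np.ndarray, tm: TopologicalMap) -> int:
    """Index of the prototype at minimal Euclidean distance from the pattern.

    Ties are broken toward the lowest node index (argmin convention).
    """
    pattern = _check_pattern(pattern, tm)
    d2 = np.sum((tm.prototypes - pattern) ** 2, axis=1)
    return int(np.argmin(d2))


def find_winners(patterns: np.ndarray, tm: TopologicalMap) -> np.ndarray:
    """Vectorized :func:`find_winner` over the rows of ``patterns``."""
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[1] != tm.dim:
        raise ValueError("pattern dimension mismatch")
    if not np.all(np.isfinite(patterns)):
        raise ValueError("patterns must be finite")
    # ||x - c||^2 = ||x||^2 - 2 x.c + ||c||^2 ; ||x||^2 constant per row
    cross = patterns @ tm.prototypes.T
    d2 = np.sum(tm.prototypes**2, axis=1)[None, :] - 2.0 * cross
    return np.argmin(d2, axis=1)


def neighborhood_weights(
    winner: int,
    anchor: Optional[np.ndarray],
    tm: TopologicalMap,
) -> np.ndarray:
    """Radial neighborhood factor phi_j for one pattern.

    Unanchored: ``exp(-||g_j - g_winner||^2 / (2 sigma_r^2))``.
    Anchored:   the same, times ``exp(-||g_j - t||^2 / (2 sigma_t^2))``
    with ``t`` the anchor position in the internal space.
    """
    if not (0 <= winner < tm.n_nodes):
        raise ValueError("winner index out of range")
    g = tm.grid_positions
    d2 = np.sum((g - g[winner]) ** 2, axis=1)
    phi = np.exp(-d2 / (2.0 * tm.sigma_r**2))
    if anchor is not None:
        t = np.asarray(anchor, dtype=float).ravel()
        if t.shape != (2,) or not np.all(np.isfinite(t)):
            raise ValueError("anchor must be a finite 2-vector")
        da2 = np.sum((g - t) ** 2, axis=1)
        phi = phi * np.exp(-da2 / (2.0 * tm.sigma_t**2))
    return phi


def _phi_matrix(
    patterns: np.ndarray,
    anchors: Optional[np.ndarray],
    tm: TopologicalMap,
) -> np.ndarray:
    """(N, K) matrix of neighborhood weights, vectorized over patterns."""
    winners = find_winners(patterns, tm)
    g = tm.grid_positions
    dw2 = np.sum((g[winners][:, None, :] - g[None, :, :]) ** 2, axis=2)
    phi = np.exp(-dw2 / (2.0 * tm.sigma_r**2))
    if anchors is not None:
        anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
        if anchors.shape != (patterns.shape[0] if patterns.ndim == 2 else 1, 2):
            raise ValueError("anchors must be (N, 2)")
        da2 = np.sum((anchors[:, None, :] - g[None, :, :]) ** 2, axis=2)
        phi = phi * np.exp(-da2 / (2.0 * tm.sigma_t**2))
    return phi


def stm_loss(
    patterns: np.ndarray,
    anchors: Optional[np.ndarray],
    tm: TopologicalMap,
) -> float:
    """Neighborhood-weighted quantization loss (halved double sum)."""
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[0] == 0:
        raise ValueError("empty pattern set")
    phi = _phi_matrix(patterns, anchors, tm)
    d2 = (
        np.sum(patterns**2, axis=1)[:, None]
        - 2.0 * patterns @ tm.prototypes.T
        + np.sum(tm.prototypes**2, axis=1)[None, :]
    )
    return float(0.5 * np.sum(phi * np.maximum(d2, 0.0)))


def update_map(
    tm: TopologicalMap,
    patterns: np.ndarray,
    anchors: Optional[np.ndarray],
    sample_weights: np.ndarray,
    eta: float,
) -> TopologicalMap:
    """One batched delta-rule step toward the weighted neighborhood means.

    Each prototype moves by
    ``eta * sum_i w_i phi_ij (x_i - c_j) / max(sum_i w_i phi_ij, EPS_NORM)``;
    zero-weight samples contribute nothing, and ``eta = 0`` is a no-op.
    Returns a new map; the input map is not mutated.
    """
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    w = np.asarray(sample_weights, dtype=float).ravel()
    if eta < 0:
        raise ValueError("eta must be non-negative")
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("sample_weights must lie in [0, 1]")
    if w.shape[0] != patterns.shape[0]:
        raise ValueError("sample_weights length mismatch")
    if eta == 0.0 or patterns.shape[0] == 0 or not np.any(w > 0):
        return tm.copy()
    phi = _phi_matrix(patterns, anchors, tm) * w[:, None]  # (N, K)
    denom = np.maximum(phi.sum(axis=0), EPS_NORM)  # (K,)
    target = (phi.T @ patterns) / denom[:, None]  # weighted mean per node
    # nodes with effectively no mass keep their prototype
    active = phi.sum(axis=0) > EPS_NORM
    new_protos = tm.prototypes.copy()
    new_protos[active] += eta * (target[active] - tm.prototypes[active])
    if not np.all(np.isfinite(new_protos)):
        raise FloatingPointError("non-finite prototypes after update")
    return replace(tm, prototypes=new_protos)


class ForwardResult(NamedTuple):
    """Internal-space summary of one pattern: point, activation, winner."""

    point: np.ndarray  # (2,) continuous internal coordinates
    activation: np.ndarray  # (K,) radial grid activation, max 1 at winner
    winner: int


def forward_map(pattern: np.ndarray, tm: TopologicalMap) -> ForwardResult:
    """Map a modality pattern to the internal space.

    The grid activation is the radial basis of grid distance to the winning
    node; the point summary is the activation-weighted centroid of the node
    positions (continuous, unlike the discrete winner).
    """
    winner = find_winner(pattern, tm)
    g = tm.grid_positions
    d2 = np.sum((g - g[winner]) ** 2, axis=1)
    act = np.exp(-d2 / (2.0 * tm.sigma_r**2))
    act_eff = np.where(act < ACTIVATION_FLOOR, 0.0, act)
    point = (act_eff @ g) / act_eff.sum()
    return ForwardResult(point=point, activation=act, winner=winner)


def forward_map_batch(
    patterns: np.ndarray, tm: TopologicalMap
) -> tuple[np.ndarray, np.ndarray]:
    """Points (N, 2) and winners (N,) for a batch of patterns."""
    winners = find_winners(patterns, tm)
    g = tm.grid_positions
    d2 = np.sum((g[winners][:, None, :] - g[None, :, :]) ** 2, axis=2)
    act = np.exp(-d2 / (2.0 * tm.sigma_r**2))
    act = np.where(act < ACTIVATION_FLOOR, 0.0, act)
    points = (act @ g) / act.sum(axis=1)[:, None]
    return points, winners


def inverse_map(
    point: np.ndarray,
    tm: TopologicalMap,
    *,
    return_flag: bool = False,
) -> np.ndarray | tuple[np.ndarray, bool]:
    """Re-enact a modality pattern from an internal-space point.

    The pattern is the radial-basis weighted average of the prototypes,
    with weights centred on ``point``.  This single primitive serves both
    policy generation (inverse policy mapping) and sensory prediction.
    If every weight underflows, the nearest node's prototype is returned
    and the degenerate flag is set.
    """
    p = np.asarray(point, dtype=float).ravel()
    if p.shape != (2,) or not np.all(np.isfinite(p)):
        raise ValueError("point must be a finite 2-vector")
    g = tm.grid_positions
    lo, hi = g.min(axis=0), g.max(axis=0)
    if np.any(p < lo - 1e-9) or np.any(p > hi + 1e-9):
        raise ValueError("point outside the internal-space bounding box")
    d2 = np.sum((g - p) ** 2, axis=1)
    a = np.exp(-d2 / (2.0 * tm.sigma_r**2))
    a = np.where(a < ACTIVATION_FLOOR, 0.0, a)
    total = a.sum()
    if total <= 0.0:
        pattern = tm.prototypes[int(np.argmin(d2))].copy()
        return (pattern, True) if return_flag else pattern
    pattern = (a @ tm.prototypes) / total
    return (pattern, False) if return_flag else pattern


def anneal_sigma_r(
    epoch: int, n_epochs: int, sigma_start: float, sigma_end: float
) -> float:
    """Exponential neighborhood-width schedule across epochs.

    Decays from ``sigma_start`` at epoch 0 to ``sigma_end`` at the final
    epoch; constant if only one epoch.
    """
    if n_epochs <= 1:
        return sigma_end
    frac = min(max(epoch / (n_epochs - 1), 0.0), 1.0)
    return float(sigma_start * (sigma_end / sigma_start) ** frac)


class RunningScaler:
    """Per-dimension running min-max normalizer to [0, 1].

    Modality patterns pass through this before mapping so that distances
    are commensurable across modalities of very different native scales.
    Dimensions that have shown no range so far map to 0.
    """

    def __init__(self, dim: int):
        self.lo = np.full(dim, np.inf)
        self.hi = np.full(dim, -np.inf)

    def update(self, batch: np.ndarray) -> None:
        batch = np.atleast_2d(np.asarray(batch, dtype=float))
        self.lo = np.minimum(self.lo, batch.min(axis=0))
        self.hi = np.maximum(self.hi, batch.max(axis=0))

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo = np.where(np.isfinite(self.lo), self.lo, 0.0)
        rng = np.where(
            np.isfinite(self.hi) & np.isfinite(self.lo), self.hi - self.lo, 0.0
        )
        return (x - lo) / np.maximum(rng, 1e-12)

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo = np.where(np.isfinite(self.lo), self.lo, 0.0)
        rng = np.where(
            np.isfinite(self.hi) & np.isfinite(self.lo), self.hi - self.lo, 0.0
        )
        return x * np.maximum(rng, 0.0) + lo


def save_map(tm: TopologicalMap, path, *, epoch: int = -1) -> None:
    """Persist a map checkpoint (npz: prototypes, grid, sigmas, tag, epoch)."""
    np.savez(
        path,
        prototypes=tm.prototypes,
        grid_positions=tm.grid_positions,
        sigma_r=tm.sigma_r,
        sigma_t=tm.sigma_t,
        modality_tag=tm.modality_tag,
        epoch=epoch,
    )


def load_map(path) -> TopologicalMap:
    with np.load(path, allow_pickle=False) as z:
        return TopologicalMap(
            prototypes=z["prototypes"],
            grid_positions=z["grid_positions"],
            sigma_r=float(z["sigma_r"]),
            sigma_t=float(z["sigma_t"]),
            modality_tag=str(z["modality_tag"]),
        )
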