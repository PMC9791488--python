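"""Post-training analyses: map stability, prototype visualization,
clustering, re-enactment and convergence traces."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from . import intrinsic as isg
from . import stm
from .control import MODALITIES, SENSORY_MODALITIES, EpisodeRecord


def map_change(map_a: stm.TopologicalMap, map_b: stm.TopologicalMap) -> float:
    """Frobenius distance between the prototype matrices of two maps."""
    if map_a.prototypes.shape != map_b.prototypes.shape:
        raise ValueError("maps have different shapes")
    return float(np.linalg.norm(map_a.prototypes - map_b.prototypes))


def pca_rgb(tm: stm.TopologicalMap) -> tuple[np.ndarray, bool]:
    """Project prototypes on their first three principal components and
    rescale each to [0, 1], giving one RGB color per grid node.

    Returns ``(colors, degenerate)``; a zero-variance map yields mid-gray
    with the degenerate flag set.
    """
    protos = tm.prototypes
    if protos.shape[0] < 4:
        raise ValueError("need at least 4 prototypes")
    if np.allclose(protos.std(axis=0), 0.0):
        return np.full((tm.n_nodes, 3), 0.5), True
    n_comp = min(3, protos.shape[1], protos.shape[0])
    proj = PCA(n_components=n_comp, svd_solver="full").fit_transform(protos)
    if n_comp < 3:
        proj = np.pad(proj, ((0, 0), (0, 3 - n_comp)))
    lo, hi = proj.min(axis=0), proj.max(axis=0)
    colors = (proj - lo) / np.maximum(hi - lo, 1e-12)
    return colors, False


def _kmeans(data: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(data)


class ClusterAssignment:
    """Per-map k-means labels plus the cross-modal composition.

    Cross-modal labels come from k-means over the concatenation of the
    four per-map one-hot cluster indicators of each node, so nodes that
    co-cluster across modalities end up in the same cross-modal category.
    """

    def __init__(self, labels: dict, cross_modal: np.ndarray, k: int):
        self.labels = labels
        self.cross_modal_labels = cross_modal
        self.k = k


def cluster_maps(
    maps: dict, k: int = 5, rng: Optional[np.random.Generator] = None
) -> ClusterAssignment:
    """k-means (k = 5 by default, 10 restarts, seeded) on each map's
    prototypes, then the cross-modal composition over all four maps."""
    seed = int(rng.integers(2**31 - 1)) if rng is not None else 0
    labels = {m: _kmeans(maps[m].prototypes, k, seed) for m in maps}
    onehot = np.concatenate(
        [np.eye(k)[labels[m]] for m in sorted(labels)], axis=1
    )
    cross = _kmeans(onehot, k, seed)
    return ClusterAssignment(labels=labels, cross_modal=cross, k=k)


def reenact(point: np.ndarray, maps: dict) -> dict:
    """Endogenous re-enactment: inverse-map one internal point through all
    four maps, regenerating the multimodal pattern and policy it encodes.

    The visual pattern is reshaped to the 10x10x3 retina layout.
    """
    out = {}
    for m, tm in maps.items():
        pattern = stm.inverse_map(point, tm)
        if m == "visual":
            pattern = pattern.reshape(10, 10, 3)
        out[m] = pattern
    return out


def convergence_trace(record: EpisodeRecord) -> pd.DataFrame:
    """Per-timestep table of internal points, their distances to the
    selected policy's point, and the intrinsic-signal columns — the raw
    material of an attractor-convergence plot."""
    anchor = record.selected.x_hat_pi
    rows = {}
    for m in SENSORY_MODALITIES:
        pts = record.points[m]
        rows[f"x_{m}"] = pts[:, 0]
        rows[f"y_{m}"] = pts[:, 1]
        rows[f"dist_{m}"] = np.linalg.norm(pts - anchor, axis=1)
    rows["dist_policy"] = np.full(
        len(record.trace), float(np.linalg.norm(record.x_pi - anchor))
    )
    df = pd.DataFrame(rows)
    df["xi_hat"] = record.trace.xi_hat_values
    df["xi"] = record.trace.xi_values
    df["delta"] = record.trace.delta_values
    df["psi"] = record.trace.psi_values
    df.insert(0, "timestep", np.arange(len(df)))
    return df


def category_purity(episode_log: list, maps: dict, k: int = 5) -> float:
    """Majority-category purity of the internal clusters visited during
    training episodes.

    Each episode is assigned the cross-modal cluster of the grid node
    nearest its selected policy's internal point; purity is the weighted
    fraction of episodes whose category matches their cluster's majority
    category.
    """
    assignment = cluster_maps(maps, k=k)
    grid = maps["policy"].grid_positions
    clusters, categories = [], []
    for entry in episode_log:
        node = int(
            np.argmin(np.sum((grid - entry["x_hat_pi"]) ** 2, axis=1))
        )
        clusters.append(assignment.cross_modal_labels[node])
        categories.append(entry["category"])
    df = pd.DataFrame({"cluster": clusters, "category": categories})
    matched = 0
    for _, grp in df.groupby("cluster"):
        matched += grp["category"].value_counts().iloc[0]
    return matched / len(df)


def reenactment_roundtrip_rate(maps: dict) -> float:
    """Fraction of grid nodes whose re-enacted visual pattern forward-maps
    back to the same node."""
    vm = maps["visual"]
    hits = 0
    for j in range(vm.n_nodes):
        pattern = stm.inverse_map(vm.grid_positions[j], vm)
        if stm.find_winner(pattern, vm) == j:
            hits += 1
    return hits / vm.n_nodes


def prototype_grid_image(tm: stm.TopologicalMap) -> np.ndarray:
    """(G, G, 3) RGB image of the PCA-colored prototype grid."""
    colors, _ = pca_rgb(tm)
    g = tm.grid_size
    img = np.zeros((g, g, 3))
    for j, pos in enumerate(tm.grid_positions.astype(int)):
        img[pos[0], pos[1]] = colors[j]
    return img


def stability_curves(history: pd.DataFrame) -> pd.DataFrame:
    """Competence and per-map change per epoch, ready for CSV export."""
    cols = ["epoch", "c_tot", "eta"] + [f"change_{m}" for m in MODALITIES]
    return history[cols].copy()
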