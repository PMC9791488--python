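"""Synthetic generators exercising the learning machinery without the
simulated world.

The central object is a paired multimodal dataset: samples of a known 2-D
latent variable observed through smooth injective embeddings into several
modality spaces, plus Gaussian noise.  Training one map per modality with
anchors derived from the shared latent should pull paired observations to
nearby internal points — the alignment property the whole architecture
rests on — and the ground-truth latent makes that measurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import stm


@dataclass
class LatentPairedDataset:
    """Row-aligned multimodal observations of a shared 2-D latent."""

    latent: np.ndarray  # (N, 2) ground truth, in [0, 1]^2
    modalities: list  # list of (N, D_m) observation matrices
    noise_sigma: float

    @property
    def n(self) -> int:
        return self.latent.shape[0]


def _smooth_embedding(
    latent: np.ndarray, dim: int, rng: np.random.Generator
) -> np.ndarray:
    """Affine map plus a bounded sinusoidal warp into ``dim`` dimensions.

    The warp amplitude is kept well below the affine gain so the embedding
    stays injective on the unit square.
    """
    a = rng.normal(0.0, 1.0, size=(2, dim))
    b = rng.uniform(-0.5, 0.5, size=dim)
    w = rng.uniform(0.5, 2.0, size=(2, dim))
    phase = rng.uniform(0, 2 * np.pi, size=dim)
    return latent @ a + b + 0.15 * np.sin(latent @ w + phase)


def make_paired_dataset(
    n: int,
    dims: Sequence[int],
    noise_sigma: float,
    rng: np.random.Generator,
    *,
    embedding: str = "warped",
) -> LatentPairedDataset:
    """Reproducible paired dataset with recorded ground truth.

    ``embedding="identity"`` requires every modality to be 2-D and returns
    the latent itself (plus noise), which is handy for exact checks.
    """
    if n < 10:
        raise ValueError("need at least 10 samples")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if any(d < 2 for d in dims):
        raise ValueError("modality dimensions must be >= 2")
    latent = rng.uniform(0.0, 1.0, size=(n, 2))
    modalities = []
    for d in dims:
        if embedding == "identity":
            if d != 2:
                raise ValueError("identity embedding requires 2-D modalities")
            obs = latent.copy()
        elif embedding == "warped":
            obs = _smooth_embedding(latent, d, rng)
        else:
            raise ValueError(f"unknown embedding {embedding!r}")
        obs = obs + rng.normal(0.0, noise_sigma, size=obs.shape)
        modalities.append(obs)
    return LatentPairedDataset(
        latent=latent, modalities=modalities, noise_sigma=noise_sigma
    )


def alignment_error(maps: Sequence[stm.TopologicalMap], dataset: LatentPairedDataset) -> float:
    """Mean internal-space distance between paired forward-mapped points,
    averaged over all modality pairs and samples."""
    points = [
        stm.forward_map_batch(obs, tm)[0]
        for tm, obs in zip(maps, dataset.modalities)
    ]
    total, count = 0.0, 0
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            total += float(
                np.mean(np.linalg.norm(points[i] - points[j], axis=1))
            )
            count += 1
    return total / max(count, 1)


def train_maps_on_dataset(
    dataset: LatentPairedDataset,
    grid_size: int,
    rng: np.random.Generator,
    *,
    anchored: bool = True,
    epochs: int = 30,
    eta: float = 0.5,
    sigma_r_end: float = 0.8,
    sigma_t: float = 1.5,
) -> list:
    """Train one map per modality on the paired dataset.

    With ``anchored=True`` the shared anchor of each sample is its latent
    coordinate scaled onto the grid (supervised alignment); otherwise each
    map trains as an independent unsupervised SOM on the same schedule.
    """
    anchors = dataset.latent * (grid_size - 1) if anchored else None
    maps = [
        stm.new_map(
            grid_size,
            obs.shape[1],
            rng,
            sigma_t=sigma_t,
            modality_tag="visual",
        )
        for obs in dataset.modalities
    ]
    weights = np.ones(dataset.n)
    for epoch in range(epochs):
        sig = stm.anneal_sigma_r(epoch, epochs, grid_size / 2.0, sigma_r_end)
        maps = [
            stm.update_map(
                tm.with_sigma_r(sig), obs, anchors, weights, eta
            )
            for tm, obs in zip(maps, dataset.modalities)
        ]
    return maps


def planted_cluster_map(
    grid_size: int,
    n_clusters: int,
    dim: int,
    rng: np.random.Generator,
    *,
    separation: float = 10.0,
    spread: float = 0.1,
) -> tuple[stm.TopologicalMap, np.ndarray]:
    """A map whose prototypes form well-separated blobs, with the planted
    labels — ground truth for clustering checks."""
    k = grid_size**2
    centers = rng.normal(0.0, separation, size=(n_clusters, dim))
    labels = np.sort(rng.integers(0, n_clusters, size=k))
    # guarantee every cluster non-empty
    labels[:n_clusters] = np.arange(n_clusters)
    protos = centers[labels] + rng.normal(0.0, spread, size=(k, dim))
    tm = stm.TopologicalMap(
        prototypes=protos,
        grid_positions=stm.make_grid(grid_size),
        sigma_r=1.0,
        sigma_t=1.5,
        modality_tag="visual",
    )
    return tm, labels


def scripted_convergence_points(
    n_approach: int = 10,
    n_hold: int = 5,
    start_distance: float = 3.0,
) -> tuple[list, np.ndarray, np.ndarray]:
    """A hand-computable trace: a single sensory point moves linearly from
    ``start_distance`` to 0 toward the policy point over ``n_approach``
    steps, then stays.  Returns (per-step sensory points, policy point,
    selected-policy point); the latter two coincide."""
    anchor = np.array([2.0, 2.0])
    steps = []
    for t in range(n_approach + n_hold):
        d = start_distance * max(1.0 - t / (n_approach - 1), 0.0)
        steps.append([anchor + np.array([d, 0.0])])
    return steps, anchor.copy(), anchor.copy()
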