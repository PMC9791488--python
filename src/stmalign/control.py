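"""Online controller, policy selection and the training loop.

A *policy* is the weight vector of a small closed-loop network mapping the
current proprioceptive and touch state to desired joint angles; executing
a policy for T timesteps produces one episode of interaction.  The
offline layer selects the policy exogenously at the start of each episode:
the initial retinal image is forward-mapped to a point of the internal
space, that point is inverse-mapped through the policy map, and
competence-scaled exploration noise is added.  After a batch of episodes
(an epoch) all four topological maps are updated with per-timestep sample
weights ``psi_t * (1 - c_k)`` and the selected policy's internal point as
the shared anchor, and the competence predictor is refreshed from the
episode outcomes.

The arm is only partially under network control: a hardwired reaching
controller servoes the arm toward the most salient point, and the network
contributes a bounded correction, while the gripper is driven entirely by
the network.  This separates learning to manipulate from learning to
reach.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from . import competence as cp
from . import intrinsic as isg
from . import stm
from .environment import ArmGripperWorld, EnvConfig, SensoryFrame

SENSORY_MODALITIES = ("visual", "touch", "proprio")
MODALITIES = SENSORY_MODALITIES + ("policy",)


# ---------------------------------------------------------------------------
# the online controller network

@dataclass
class ControllerSpec:
    """Architecture of the online policy network.

    Inputs are the 5 normalized joint angles and the 40 touch sensors;
    a tanh hidden layer feeds 5 outputs.  The two gripper outputs command
    the gripper joints over their full range; the three arm outputs are a
    correction, clipped to ``arm_delta`` radians, added to the hardwired
    reach target.  With the default hidden width the policy space has
    45*10 + 10 + 10*5 + 5 = 515 parameters.
    """

    n_hidden: int = 10
    arm_delta: float = 0.2
    weight_gain: float = 2.0  # raw weight = (pattern - 1/2) * gain

    @property
    def n_in(self) -> int:
        return 45

    @property
    def n_out(self) -> int:
        return 5

    @property
    def n_params(self) -> int:
        h = self.n_hidden
        return self.n_in * h + h + h * self.n_out + self.n_out

    def unpack(self, theta: np.ndarray):
        h, ni, no = self.n_hidden, self.n_in, self.n_out
        theta = np.asarray(theta, dtype=float).ravel()
        if theta.shape[0] != self.n_params:
            raise ValueError("policy parameter vector has the wrong length")
        i = 0
        w1 = theta[i : i + ni * h].reshape(ni, h); i += ni * h
        b1 = theta[i : i + h]; i += h
        w2 = theta[i : i + h * no].reshape(h, no); i += h * no
        b2 = theta[i : i + no]
        return w1, b1, w2, b2

    def pattern_to_weights(self, pattern: np.ndarray) -> np.ndarray:
        """Affine bridge from the unit-box policy space the map works in
        to raw network weights."""
        return (np.asarray(pattern, dtype=float) - 0.5) * self.weight_gain

    def weights_to_pattern(self, theta: np.ndarray) -> np.ndarray:
        return np.asarray(theta, dtype=float) / self.weight_gain + 0.5


def online_policy(
    theta: np.ndarray,
    frame: SensoryFrame,
    reach_target: np.ndarray,
    spec: ControllerSpec,
    env_cfg: EnvConfig,
) -> np.ndarray:
    """Desired joint angles (5,) from the current sensory frame.

    A zero parameter vector yields the hardwired reach target for the arm
    and a mid-range gripper posture.
    """
    x = np.concatenate([frame.proprio, frame.touch])
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite sensory input")
    w1, b1, w2, b2 = spec.unpack(theta)
    hidden = np.tanh(x @ w1 + b1)
    out = np.tanh(hidden @ w2 + b2)  # (-1, 1)^5
    lo, hi = env_cfg.joint_lo, env_cfg.joint_hi
    arm_cmd = np.asarray(reach_target, dtype=float) + spec.arm_delta * out[:3]
    grip_mid = 0.5 * (lo[3:] + hi[3:])
    grip_half = 0.5 * (hi[3:] - lo[3:])
    grip_cmd = grip_mid + grip_half * out[3:]
    return np.clip(np.concatenate([arm_cmd, grip_cmd]), lo, hi)


def hardwired_reach(
    salient_point: np.ndarray,
    env: ArmGripperWorld,
    current_arm: Optional[np.ndarray] = None,
    *,
    reach_offset: float = 0.04,
    max_iter: int = 40,
    damping: float = 0.1,
) -> np.ndarray:
    """Arm joint targets placing the gripper base near the salient point.

    Damped-least-squares inverse kinematics seeded at the current posture
    (rest posture when none is given); iteration stops as soon as the arm
    tip is within ``reach_offset`` of the point, so a posture already on
    target is a fixed point.  Unreachable points resolve to the maximal
    extension toward the point.
    """
    cfg = env.cfg
    target = np.asarray(salient_point, dtype=float).ravel()
    q = (
        np.array(cfg.rest_posture[:3], dtype=float)
        if current_arm is None
        else np.asarray(current_arm, dtype=float).copy()
    )
    lo = np.array(cfg.arm_limits_lo)
    hi = np.array(cfg.arm_limits_hi)
    lengths = np.array(cfg.link_lengths)
    for _ in range(max_iter):
        joints = env.fk_arm(q)
        err = target - joints[-1]
        if np.linalg.norm(err) <= reach_offset:
            break
        # analytic Jacobian of the planar chain tip wrt joint angles
        cum = np.cumsum(q)
        jac = np.zeros((2, 3))
        for j in range(3):
            for k in range(j, 3):
                jac[0, j] += -lengths[k] * np.sin(cum[k])
                jac[1, j] += lengths[k] * np.cos(cum[k])
        jjt = jac @ jac.T + damping**2 * np.eye(2)
        dq = jac.T @ np.linalg.solve(jjt, err)
        q = np.clip(q + np.clip(dq, -0.3, 0.3), lo, hi)
    return q


# ---------------------------------------------------------------------------
# policy selection and episode bookkeeping

class SelectedPolicy(NamedTuple):
    pi_hat: np.ndarray  # selected policy pattern (unit-box policy space)
    pi: np.ndarray  # executed pattern = pi_hat + exploration noise
    c_k: float  # local competence of the selected policy
    r_hat_pi: np.ndarray  # grid activation of the selected policy
    x_hat_pi: np.ndarray  # internal point of the selected policy


def select_policy(
    initial_retina: np.ndarray,
    visual_map: stm.TopologicalMap,
    policy_map: stm.TopologicalMap,
    predictor: cp.CompetencePredictor,
    rng: np.random.Generator,
    *,
    sigma_explore: float = cp.DEFAULT_SIGMA_EXPLORE,
) -> SelectedPolicy:
    """Exogenous (stimulus-tied) action selection.

    The internal point encoding the initial visual state is mapped
    backwards through the policy map; noise inversely proportional to the
    predicted competence of that policy is added for exploration.
    """
    fwd_v = stm.forward_map(np.asarray(initial_retina).ravel(), visual_map)
    pi_hat = stm.inverse_map(fwd_v.point, policy_map)
    c_k = cp.predict(fwd_v.point, predictor)
    pi = cp.exploration_noise(pi_hat, c_k, sigma_explore, rng)
    fwd_p = stm.forward_map(pi_hat, policy_map)
    return SelectedPolicy(
        pi_hat=pi_hat,
        pi=pi,
        c_k=c_k,
        r_hat_pi=fwd_p.activation,
        x_hat_pi=fwd_p.point,
    )


@dataclass
class EpisodeRecord:
    """Everything one episode contributes to the epoch update."""

    category: str
    selected: SelectedPolicy
    x_pi: np.ndarray  # internal point of the executed (noisy) policy
    patterns: dict  # modality -> (T, D) scaled sensory patterns
    points: dict  # modality -> (T, 2) internal points
    trace: isg.SignalTrace
    grasped: bool = False
    target_stat: str = "max_xi"

    @property
    def target(self) -> float:
        """Per-episode competence target: the amount of radial closeness
        experienced over the episode (see ``TrainConfig.target_stat``)."""
        if self.target_stat == "mean_xi":
            return float(np.mean(self.trace.xi_values))
        if self.target_stat == "max_xi":
            return float(np.max(self.trace.xi_values))
        if self.target_stat == "mean_psi":
            return float(np.mean(self.trace.psi_values))
        raise ValueError(f"unknown target_stat {self.target_stat!r}")


@dataclass
class EpochHistory:
    """Algorithm-level storage for one epoch (V, SS, P, Pi, c, Psi)."""

    episodes: list = field(default_factory=list)

    def append(self, rec: EpisodeRecord) -> None:
        self.episodes.append(rec)

    def stacked_patterns(self, modality: str) -> np.ndarray:
        return np.concatenate([e.patterns[modality] for e in self.episodes])

    def stacked_anchors(self) -> np.ndarray:
        return np.concatenate(
            [
                np.tile(e.selected.x_hat_pi, (len(e.trace), 1))
                for e in self.episodes
            ]
        )

    def stacked_psi(self) -> np.ndarray:
        return np.concatenate([e.trace.psi_values for e in self.episodes])

    def stacked_local_incompetence(self) -> np.ndarray:
        return np.concatenate(
            [
                np.full(len(e.trace), 1.0 - e.selected.c_k)
                for e in self.episodes
            ]
        )

    @property
    def policies(self) -> np.ndarray:
        return np.stack([e.selected.pi for e in self.episodes])

    @property
    def competences(self) -> np.ndarray:
        return np.array([e.selected.c_k for e in self.episodes])

    @property
    def targets(self) -> np.ndarray:
        return np.array([e.target for e in self.episodes])


# ---------------------------------------------------------------------------
# training configuration

@dataclass
class TrainConfig:
    """All training constants; the defaults are the full-scale profile."""

    grid_size: int = 10
    epochs: int = 300
    episodes_per_epoch: int = 24
    steps_per_episode: int = 50
    n_hidden: int = 10
    sigma_t: float = 1.5
    sigma_r_end: float = 0.8
    sigma_xi: float = isg.DEFAULT_SIGMA_XI
    th_delta: float = isg.DEFAULT_TH_DELTA
    eta_min: float = 0.02
    eta_max: float = 0.5
    # width used when *reading* the maps (forward/inverse mapping, anchors);
    # the annealed sigma_r only shapes the update neighborhood
    sigma_readout: float = 0.8
    # fraction of the run spent annealing sigma_r from G/2 down to
    # sigma_r_end; the remainder fine-tunes at sigma_r_end (Kohonen's
    # ordering-then-convergence schedule)
    anneal_fraction: float = 0.25
    fit_rate: float = 0.1
    predictor_steps: int = 30
    sigma_explore: float = cp.DEFAULT_SIGMA_EXPLORE
    arm_delta: float = 0.2
    # episode-level statistic the competence predictor is trained on
    target_stat: str = "max_xi"
    # initial bias of the competence predictor: a fresh agent predicts low
    # success probability (logistic(-2) ~ 0.12) until experience says more
    competence_prior_bias: float = -2.0
    seed: int = 0

    @property
    def sigma_r_start(self) -> float:
        return self.grid_size / 2.0

    def controller(self) -> ControllerSpec:
        return ControllerSpec(n_hidden=self.n_hidden, arm_delta=self.arm_delta)


def smoke_config(seed: int = 0) -> TrainConfig:
    """Scaled-down profile (6x6 grid, 40 epochs) used by the test suite."""
    return TrainConfig(grid_size=6, epochs=40, seed=seed)


def init_learner(
    config: TrainConfig, rng: np.random.Generator
) -> tuple[dict, cp.CompetencePredictor]:
    """Fresh topological maps for the four modalities plus the predictor."""
    ctrl = config.controller()
    dims = {
        "visual": 300,
        "touch": 40,
        "proprio": 5,
        "policy": ctrl.n_params,
    }
    maps = {
        tag: stm.new_map(
            config.grid_size,
            dim,
            rng,
            sigma_r=config.sigma_r_start,
            sigma_t=config.sigma_t,
            modality_tag=tag,
        )
        for tag, dim in dims.items()
    }
    w0 = np.zeros(6)
    w0[-1] = config.competence_prior_bias
    predictor = cp.CompetencePredictor(
        extent=config.grid_size - 1.0, fit_rate=config.fit_rate, weights=w0
    )
    return maps, predictor


def _frame_patterns(frame: SensoryFrame) -> dict:
    """Scaled modality patterns of one frame (all natively in [0, 1])."""
    return {
        "visual": frame.retina.ravel(),
        "touch": frame.touch.copy(),
        "proprio": frame.proprio.copy(),
    }


def run_episode(
    env: ArmGripperWorld,
    state,
    frame: SensoryFrame,
    maps: dict,
    selected: SelectedPolicy,
    config: TrainConfig,
    *,
    category: str,
) -> EpisodeRecord:
    """T closed-loop control steps with frozen maps; returns the record of
    sensory patterns, internal points and the intrinsic-signal trace."""
    T = config.steps_per_episode
    if T < 1:
        raise ValueError("steps_per_episode must be >= 1")
    ctrl = config.controller()
    theta = ctrl.pattern_to_weights(selected.pi)
    # the executed policy's internal point is constant within the episode
    # because maps are frozen until the epoch update
    x_pi = stm.forward_map(selected.pi, maps["policy"]).point
    trace = isg.SignalTrace(sigma_xi=config.sigma_xi, th_delta=config.th_delta)
    patterns = {m: [] for m in SENSORY_MODALITIES}
    points = {m: [] for m in SENSORY_MODALITIES}
    grasped = False
    for _ in range(T):
        reach = hardwired_reach(
            frame.salient_point, env, current_arm=state.joint_angles[:3]
        )
        command = online_policy(theta, frame, reach, ctrl, env.cfg)
        state, frame = env.step(state, command)
        grasped = grasped or state.grasped
        pats = _frame_patterns(frame)
        pts = {}
        for m in SENSORY_MODALITIES:
            fwd = stm.forward_map(pats[m], maps[m])
            patterns[m].append(pats[m])
            points[m].append(fwd.point)
            pts[m] = fwd.point
        trace.step(
            [pts[m] for m in SENSORY_MODALITIES], x_pi, selected.x_hat_pi
        )
    return EpisodeRecord(
        category=category,
        selected=selected,
        x_pi=x_pi,
        patterns={m: np.array(v) for m, v in patterns.items()},
        points={m: np.array(v) for m, v in points.items()},
        trace=trace,
        grasped=grasped,
        target_stat=config.target_stat,
    )


def run_epoch(
    env: ArmGripperWorld,
    maps: dict,
    predictor: cp.CompetencePredictor,
    config: TrainConfig,
    rng: np.random.Generator,
    *,
    epoch: int = 0,
) -> tuple[dict, cp.CompetencePredictor, dict, EpochHistory]:
    """One epoch: measure global competence, run the episodes with frozen
    maps, then apply the batched anchored update and refresh the predictor.

    Returns the updated maps and predictor, a stats row, and the full
    epoch history.
    """
    c_tot = cp.global_competence(maps["policy"], predictor)
    eta = cp.modulated_eta(c_tot, config.eta_min, config.eta_max)
    # frozen read-only views with the fixed representation width
    read_maps = {
        m: tm.with_sigma_r(config.sigma_readout) for m, tm in maps.items()
    }
    history = EpochHistory()
    for _ in range(config.episodes_per_epoch):
        state, frame = env.reset(rng)
        selected = select_policy(
            frame.retina.ravel(),
            read_maps["visual"],
            read_maps["policy"],
            predictor,
            rng,
            sigma_explore=config.sigma_explore,
        )
        rec = run_episode(
            env,
            state,
            frame,
            read_maps,
            selected,
            config,
            category=state.object.category if state.object else "none",
        )
        history.append(rec)

    new_maps = {}
    changes = {}
    anchors = history.stacked_anchors()
    weights = np.clip(
        history.stacked_psi() * history.stacked_local_incompetence(), 0.0, 1.0
    )
    for m in SENSORY_MODALITIES:
        updated = stm.update_map(
            maps[m], history.stacked_patterns(m), anchors, weights, eta
        )
        changes[m] = float(
            np.linalg.norm(updated.prototypes - maps[m].prototypes)
        )
        new_maps[m] = updated
    ep_anchors = np.stack([e.selected.x_hat_pi for e in history.episodes])
    ep_weights = np.clip(
        np.array([np.mean(e.trace.psi_values) for e in history.episodes])
        * (1.0 - history.competences),
        0.0,
        1.0,
    )
    updated = stm.update_map(
        maps["policy"], history.policies, ep_anchors, ep_weights, eta
    )
    changes["policy"] = float(
        np.linalg.norm(updated.prototypes - maps["policy"].prototypes)
    )
    new_maps["policy"] = updated

    points = np.stack([e.selected.x_hat_pi for e in history.episodes])
    for _ in range(config.predictor_steps):
        predictor = cp.fit_update(predictor, points, history.targets)

    # anneal the neighborhood width for the next epoch
    ordering = max(int(round(config.anneal_fraction * config.epochs)), 1)
    next_sigma = stm.anneal_sigma_r(
        min(epoch + 1, ordering), ordering + 1,
        config.sigma_r_start, config.sigma_r_end,
    )
    new_maps = {m: tm.with_sigma_r(next_sigma) for m, tm in new_maps.items()}

    stats = {
        "epoch": epoch,
        "c_tot": c_tot,
        "eta": eta,
        "mean_psi": float(np.mean(history.stacked_psi())),
        "mean_target": float(np.mean(history.targets)),
        **{f"change_{m}": changes[m] for m in MODALITIES},
    }
    return new_maps, predictor, stats, history


@dataclass
class TrainResult:
    maps: dict
    predictor: cp.CompetencePredictor
    history: pd.DataFrame  # one row per epoch
    episode_log: list  # (epoch, category, x_hat_pi, target, grasped)
    config: TrainConfig
    env: ArmGripperWorld


def train(
    config: TrainConfig,
    *,
    env: Optional[ArmGripperWorld] = None,
    rng: Optional[np.random.Generator] = None,
    progress: bool = False,
    keep_histories: bool = False,
) -> TrainResult:
    """Full training run of the epoch loop.

    A single seeded generator drives environment sampling, map
    initialization and exploration noise, so runs are reproducible from
    ``config.seed``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    env = env or ArmGripperWorld()
    maps, predictor = init_learner(config, rng)
    rows = []
    episode_log = []
    iterator = range(config.epochs)
    if progress:
        from tqdm import tqdm  # local import: optional nicety

        iterator = tqdm(iterator, desc="epochs")
    histories = [] if keep_histories else None
    for epoch in iterator:
        maps, predictor, stats, hist = run_epoch(
            env, maps, predictor, config, rng, epoch=epoch
        )
        rows.append(stats)
        for rec in hist.episodes:
            episode_log.append(
                {
                    "epoch": epoch,
                    "category": rec.category,
                    "x_hat_pi": rec.selected.x_hat_pi,
                    "target": rec.target,
                    "grasped": rec.grasped,
                }
            )
        if keep_histories:
            histories.append(hist)
    result = TrainResult(
        maps=maps,
        predictor=predictor,
        history=pd.DataFrame(rows),
        episode_log=episode_log,
        config=config,
        env=env,
    )
    if keep_histories:
        result.epoch_histories = histories  # type: ignore[attr-defined]
    return result
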