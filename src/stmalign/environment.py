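"""Deterministic 2-D manipulation world: planar arm, coupled gripper,
touch, retinal and saliency vision, and three object categories.

The agent is a 3-joint planar arm anchored at the origin, ending in a
two-fingered gripper whose fingers mirror one shared (opening, curl)
command, so the whole body has 5 controlled degrees of freedom.  One
object is present per episode, drawn from three categories that differ in
what they afford:

* ``fixed``     — small quadrilateral, blue-dominant; can be touched but
  never displaced.
* ``movable``   — big triangle, red-dominant; pushed when contacted,
  never grasped.
* ``graspable`` — small quadrilateral, green-dominant; pushed when
  contacted, and locks to the gripper when both fingers' inner touch
  sensors contact it while the gripper is closing.

Dynamics are kinematic, not force-based: joints servo toward commanded
angles under a per-step rate limit, and contacts resolve by the category
rules above.  Same state + same command always produce the same result.

Sensory channels per timestep: 5 normalized joint angles (proprioception),
40 binary touch sensors (10 inner + 10 outer per finger), a 10x10x3 retina
cropped around the most salient point, and an SxS saliency map whose
argmax is returned in world coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

CATEGORIES = ("fixed", "movable", "graspable")


# ---------------------------------------------------------------------------
# small vectorized geometry (hot path: called every simulation step)

def point_segment_distance(
    points: np.ndarray, a: np.ndarray, b: np.ndarray
) -> np.ndarray:
    """Distances from points (N, 2) to the segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-18:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def points_in_polygon(points: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Even-odd (ray crossing) containment test, vectorized over points."""
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < np.where(crosses, xint, np.inf))
    return inside


def polygon_distance(points: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Distance from points to a polygon; 0 for points inside it."""
    d = np.min(
        np.stack(
            [
                point_segment_distance(points, verts[i], verts[(i + 1) % len(verts)])
                for i in range(len(verts))
            ]
        ),
        axis=0,
    )
    d[points_in_polygon(points, verts)] = 0.0
    return d


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


# ---------------------------------------------------------------------------
# configuration and state containers

@dataclass
class EnvConfig:
    """Geometry and sensing constants, all in world units ([-1, 1]^2)."""

    link_lengths: tuple = (0.4, 0.3, 0.2)
    phalanx_lengths: tuple = (0.08, 0.06)
    finger_base_sep: float = 0.05
    arm_limits_lo: tuple = (0.0, -2.4, -2.4)
    arm_limits_hi: tuple = (np.pi, 2.4, 2.4)
    gripper_limits_lo: tuple = (0.05, 0.0)
    gripper_limits_hi: tuple = (1.2, 1.2)
    rest_posture: tuple = (np.pi / 2, 0.0, 0.0, 0.6, 0.2)
    max_step: float = 0.2  # rad per joint per timestep
    contact_tol: float = 0.01
    push_step: float = 0.02  # object displacement per contacted step
    sensors_per_side: int = 5  # per phalanx side; 2 phal x 2 sides x 5 x 2 fingers = 40
    retina_size: int = 10
    crop_side: float = 0.3
    saliency_size: int = 20
    saliency_sigma: float = 0.1
    workspace: tuple = (-1.0, 1.0)
    object_radius_range: tuple = (0.4, 0.75)
    object_angle_range: tuple = (np.pi / 3, 2 * np.pi / 3)

    @property
    def joint_lo(self) -> np.ndarray:
        return np.array(self.arm_limits_lo + self.gripper_limits_lo)

    @property
    def joint_hi(self) -> np.ndarray:
        return np.array(self.arm_limits_hi + self.gripper_limits_hi)


@dataclass
class ObjectSpec:
    """One scene object: category, body-frame polygon, color, world pose."""

    category: str
    vertices: np.ndarray  # (V, 2) in body frame, centred on the centroid
    color: np.ndarray  # (3,) RGB in [0, 1]
    pose: np.ndarray  # (3,) x, y, theta

    def world_vertices(self) -> np.ndarray:
        return self.vertices @ _rot(self.pose[2]).T + self.pose[:2]

    def centroid(self) -> np.ndarray:
        return self.pose[:2].copy()


@dataclass
class WorldState:
    joint_angles: np.ndarray  # (5,) = 3 arm + (opening, curl)
    object: Optional[ObjectSpec]
    grasped: bool = False
    grasp_offset: Optional[np.ndarray] = None  # object pose in gripper frame


@dataclass
class SensoryFrame:
    """One timestep's multimodal observation."""

    proprio: np.ndarray  # (5,) joint angles normalized to [0, 1]
    touch: np.ndarray  # (40,) binary contact
    retina: np.ndarray  # (10, 10, 3) in [0, 1]
    saliency: np.ndarray  # (S, S) in [0, 1], max 1
    salient_point: np.ndarray  # (2,) world coordinates of the argmax


@dataclass
class GripperGeometry:
    """World-space body points derived from the joint angles."""

    arm_joints: np.ndarray  # (4, 2) base..tip
    tip: np.ndarray  # (2,) wrist point
    tip_angle: float
    finger_segments: list  # 4 segments [(a, b)] : 2 phalanges x 2 fingers
    sensor_points: np.ndarray  # (40, 2)
    sensor_inner: np.ndarray  # (40,) bool, True for inner-side sensors
    sensor_finger: np.ndarray  # (40,) 0 = left, 1 = right
    finger_tips: np.ndarray  # (2, 2)


class ArmGripperWorld:
    """The simulated manipulation environment.

    Stateless with respect to the world: :meth:`reset` creates a
    :class:`WorldState`, :meth:`step` maps (state, command) to the next
    state plus a fresh :class:`SensoryFrame`.
    """

    def __init__(self, config: Optional[EnvConfig] = None):
        self.cfg = config or EnvConfig()

    # -- kinematics ---------------------------------------------------------

    def fk_arm(self, arm_angles: np.ndarray) -> np.ndarray:
        """Joint positions (4, 2): base, elbow, wrist-1, tip."""
        cfg = self.cfg
        pts = [np.zeros(2)]
        angle = 0.0
        for L, a in zip(cfg.link_lengths, arm_angles):
            angle += a
            pts.append(pts[-1] + L * np.array([np.cos(angle), np.sin(angle)]))
        return np.array(pts)

    def gripper_geometry(self, joint_angles: np.ndarray) -> GripperGeometry:
        cfg = self.cfg
        arm = np.asarray(joint_angles[:3], dtype=float)
        opening, curl = float(joint_angles[3]), float(joint_angles[4])
        joints = self.fk_arm(arm)
        tip = joints[-1]
        phi = float(np.sum(arm))
        normal = np.array([-np.sin(phi), np.cos(phi)])
        segments = []
        sensor_pts, sensor_inner, sensor_finger = [], [], []
        for side, sign in (("left", +1.0), ("right", -1.0)):
            base = tip + sign * (cfg.finger_base_sep / 2.0) * normal
            a1 = phi + sign * opening
            a2 = a1 - sign * curl
            p1 = base + cfg.phalanx_lengths[0] * np.array([np.cos(a1), np.sin(a1)])
            p2 = p1 + cfg.phalanx_lengths[1] * np.array([np.cos(a2), np.sin(a2)])
            segments.append((base, p1))
            segments.append((p1, p2))
            for (sa, sb, ang) in ((base, p1, a1), (p1, p2, a2)):
                # inner side faces the other finger: -sign of the lateral normal
                seg_normal = np.array([-np.sin(ang), np.cos(ang)])
                for inner in (True, False):
                    offset = (-sign if inner else sign) * 0.006 * seg_normal
                    fr = (np.arange(cfg.sensors_per_side) + 0.5) / cfg.sensors_per_side
                    pts = sa + fr[:, None] * (sb - sa) + offset
                    sensor_pts.append(pts)
                    sensor_inner.extend([inner] * cfg.sensors_per_side)
                    sensor_finger.extend(
                        [0 if side == "left" else 1] * cfg.sensors_per_side
                    )
        return GripperGeometry(
            arm_joints=joints,
            tip=tip,
            tip_angle=phi,
            finger_segments=segments,
            sensor_points=np.concatenate(sensor_pts, axis=0),
            sensor_inner=np.array(sensor_inner),
            sensor_finger=np.array(sensor_finger),
            finger_tips=np.array([segments[1][1], segments[3][1]]),
        )

    # -- episode setup ------------------------------------------------------

    def _sample_object(
        self, rng: np.random.Generator, category: Optional[str]
    ) -> ObjectSpec:
        cfg = self.cfg
        if category is None:
            category = CATEGORIES[rng.integers(len(CATEGORIES))]
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        if category == "movable":
            # big triangle, red-dominant
            r = 0.12
            angles = np.array([0.0, 2 * np.pi / 3, 4 * np.pi / 3])
            verts = r * np.stack([np.cos(angles), np.sin(angles)], axis=1)
            dominant = 0
        else:
            # small quadrilateral; blue for fixed, green for graspable
            half = 0.04 if category == "fixed" else 0.035
            verts = np.array(
                [[-half, -half], [half, -half], [half, half], [-half, half]]
            )
            verts = verts + rng.uniform(-0.25 * half, 0.25 * half, size=verts.shape)
            dominant = 2 if category == "fixed" else 1
        color = rng.uniform(0.0, 0.4, size=3)
        color[dominant] = rng.uniform(0.6, 1.0)
        ang = rng.uniform(*cfg.object_angle_range)
        rad = rng.uniform(*cfg.object_radius_range)
        pose = np.array(
            [rad * np.cos(ang), rad * np.sin(ang), rng.uniform(0, 2 * np.pi)]
        )
        verts = verts - verts.mean(axis=0)
        return ObjectSpec(category=category, vertices=verts, color=color, pose=pose)

    def reset(
        self, rng: np.random.Generator, category: Optional[str] = None
    ) -> tuple[WorldState, SensoryFrame]:
        """Arm at the rest posture, one freshly sampled object in the scene."""
        state = WorldState(
            joint_angles=np.array(self.cfg.rest_posture, dtype=float),
            object=self._sample_object(rng, category),
            grasped=False,
            grasp_offset=None,
        )
        return state, self.observe(state)

    # -- dynamics -----------------------------------------------------------

    def step(
        self, state: WorldState, command: np.ndarray
    ) -> tuple[WorldState, SensoryFrame]:
        """Rate-limited servo toward the commanded joint angles, followed by
        category-dependent contact resolution."""
        cfg = self.cfg
        command = np.asarray(command, dtype=float).ravel()
        if command.shape != (5,) or not np.all(np.isfinite(command)):
            raise ValueError("command must be a finite 5-vector of joint targets")
        command = np.clip(command, cfg.joint_lo, cfg.joint_hi)
        old = state.joint_angles
        delta = np.clip(command - old, -cfg.max_step, cfg.max_step)
        new_angles = np.clip(old + delta, cfg.joint_lo, cfg.joint_hi)
        closing = (new_angles[3] < old[3] - 1e-9) or (new_angles[4] > old[4] + 1e-9)

        geom = self.gripper_geometry(new_angles)
        obj = state.object
        grasped = state.grasped
        grasp_offset = state.grasp_offset

        if obj is not None:
            if grasped:
                obj = self._follow_gripper(obj, geom, grasp_offset)
            else:
                verts = obj.world_vertices()
                body_pts = np.vstack(
                    [geom.sensor_points, geom.arm_joints[2:], geom.finger_tips]
                )
                d = polygon_distance(body_pts, verts)
                contact = d <= cfg.contact_tol
                if obj.category in ("movable", "graspable") and np.any(contact):
                    push_dir = obj.centroid() - body_pts[contact].mean(axis=0)
                    norm = np.linalg.norm(push_dir)
                    if norm > 1e-12:
                        new_pose = obj.pose.copy()
                        new_pose[:2] += cfg.push_step * push_dir / norm
                        obj = replace(obj, pose=new_pose)
                if obj.category == "graspable" and closing:
                    sd = polygon_distance(geom.sensor_points, obj.world_vertices())
                    touching = sd <= cfg.contact_tol
                    inner_l = np.any(
                        touching & geom.sensor_inner & (geom.sensor_finger == 0)
                    )
                    inner_r = np.any(
                        touching & geom.sensor_inner & (geom.sensor_finger == 1)
                    )
                    if inner_l and inner_r:
                        grasped = True
                        grasp_offset = self._relative_pose(obj, geom)

        new_state = WorldState(
            joint_angles=new_angles,
            object=obj,
            grasped=grasped,
            grasp_offset=grasp_offset,
        )
        return new_state, self.observe(new_state)

    @staticmethod
    def _relative_pose(obj: ObjectSpec, geom: GripperGeometry) -> np.ndarray:
        rel_xy = _rot(-geom.tip_angle) @ (obj.pose[:2] - geom.tip)
        return np.array([rel_xy[0], rel_xy[1], obj.pose[2] - geom.tip_angle])

    @staticmethod
    def _follow_gripper(
        obj: ObjectSpec, geom: GripperGeometry, offset: np.ndarray
    ) -> ObjectSpec:
        xy = geom.tip + _rot(geom.tip_angle) @ offset[:2]
        return replace(
            obj, pose=np.array([xy[0], xy[1], offset[2] + geom.tip_angle])
        )

    # -- sensing ------------------------------------------------------------

    def touch_readout(self, state: WorldState) -> np.ndarray:
        """40 binary contact sensors; 1 where the sensor anchor is within
        the contact tolerance of the object (boundary or interior)."""
        geom = self.gripper_geometry(state.joint_angles)
        touch = np.zeros(40)
        if state.object is not None:
            d = polygon_distance(geom.sensor_points, state.object.world_vertices())
            touch[d <= self.cfg.contact_tol] = 1.0
        return touch

    def render_saliency(self, state: WorldState) -> tuple[np.ndarray, np.ndarray]:
        """Gaussian blob at the object centroid (or the gripper tip when no
        object is present), normalized to max 1; plus the argmax in world
        coordinates."""
        cfg = self.cfg
        lo, hi = cfg.workspace
        centers = (np.arange(cfg.saliency_size) + 0.5) / cfg.saliency_size
        centers = lo + centers * (hi - lo)
        gx, gy = np.meshgrid(centers, centers, indexing="xy")
        if state.object is not None:
            target = state.object.centroid()
        else:
            geom = self.gripper_geometry(state.joint_angles)
            target = geom.finger_tips.mean(axis=0)
        d2 = (gx - target[0]) ** 2 + (gy - target[1]) ** 2
        sal = np.exp(-d2 / (2.0 * cfg.saliency_sigma**2))
        sal = sal / sal.max()
        idx = np.unravel_index(np.argmax(sal), sal.shape)
        point = np.array([gx[idx], gy[idx]])
        return sal, point

    def render_retina(
        self, state: WorldState, salient_point: Optional[np.ndarray] = None
    ) -> np.ndarray:
        """10x10x3 crop around the salient point: object pixels take the
        object color, gripper pixels mid-gray, background zero."""
        cfg = self.cfg
        if salient_point is None:
            _, salient_point = self.render_saliency(state)
        n = cfg.retina_size
        half = cfg.crop_side / 2.0
        centers = (np.arange(n) + 0.5) / n * cfg.crop_side - half
        gx, gy = np.meshgrid(centers, centers, indexing="xy")
        pts = np.stack([gx.ravel(), gy.ravel()], axis=1) + salient_point
        img = np.zeros((n * n, 3))
        geom = self.gripper_geometry(state.joint_angles)
        seg_d = np.full(n * n, np.inf)
        for a, b in geom.finger_segments:
            seg_d = np.minimum(seg_d, point_segment_distance(pts, a, b))
        seg_d = np.minimum(
            seg_d,
            point_segment_distance(pts, geom.arm_joints[2], geom.arm_joints[3]),
        )
        img[seg_d <= 0.012] = 0.5
        if state.object is not None:
            inside = points_in_polygon(pts, state.object.world_vertices())
            img[inside] = state.object.color
        return img.reshape(n, n, 3)

    def observe(self, state: WorldState) -> SensoryFrame:
        cfg = self.cfg
        sal, point = self.render_saliency(state)
        proprio = (state.joint_angles - cfg.joint_lo) / (cfg.joint_hi - cfg.joint_lo)
        return SensoryFrame(
            proprio=proprio,
            touch=self.touch_readout(state),
            retina=self.render_retina(state, point),
            saliency=sal,
            salient_point=point,
        )
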