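"""The distance-based intrinsic learning signal.

At every timestep of an episode the agent summarizes each sensory modality
and the executed policy as points in the shared 2-D internal space.  The
mean Euclidean distance of those points from the point encoding the policy
*selected* at the start of the episode (``xi_hat``) is squashed through a
radial function (``xi``, in (0, 1], maximal when all representations
coincide).  The intrinsic signal ``psi`` fires only when ``xi`` has just
increased by more than a threshold: representations are *converging*, which
the architecture reads as evidence of a motor-sensory contingency — the
current policy is probably causing the observed sensory change.  ``psi``
then gates which timesteps participate in the topological-map update.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: default increment threshold th_delta for the contingency filter
DEFAULT_TH_DELTA = 0.01
#: default radial width sigma_xi (internal distances are in grid units)
DEFAULT_SIGMA_XI = 0.5


def xi_hat(
    sensory_points: Sequence[np.ndarray],
    policy_point: np.ndarray,
    selected_policy_point: np.ndarray,
) -> float:
    """Mean internal distance of sensory and executed-policy points from
    the selected policy's point.

    ``(sum_i ||x_si - x_hat_pi|| + ||x_pi - x_hat_pi||) / (N_s + 1)``.
    """
    pts = [np.asarray(p, dtype=float).ravel() for p in sensory_points]
    if len(pts) == 0:
        raise ValueError("at least one sensory point is required")
    anchor = np.asarray(selected_policy_point, dtype=float).ravel()
    exec_pt = np.asarray(policy_point, dtype=float).ravel()
    total = sum(float(np.linalg.norm(p - anchor)) for p in pts)
    total += float(np.linalg.norm(exec_pt - anchor))
    return total / (len(pts) + 1)


def xi(xi_hat_value: float, sigma_xi: float = DEFAULT_SIGMA_XI) -> float:
    """Radial transform ``exp(-xi_hat^2 / (2 sigma_xi))`` in (0, 1].

    Equal to 1 exactly when the mean distance is 0.  Note the width
    parameter enters unsquared.
    """
    if sigma_xi <= 0:
        raise ValueError("sigma_xi must be positive")
    if xi_hat_value < 0:
        raise ValueError("xi_hat is a mean of norms and cannot be negative")
    return float(np.exp(-(xi_hat_value**2) / (2.0 * sigma_xi)))


def psi(xi_t: float, xi_prev: float, th_delta: float = DEFAULT_TH_DELTA) -> float:
    """Contingency-gated signal: ``xi_t`` if its increment over the previous
    timestep exceeds ``th_delta``, else 0."""
    delta = xi_t - xi_prev
    return float(xi_t) if delta > th_delta else 0.0


@dataclass
class SignalTrace:
    """Per-episode trace of the intrinsic signal and its ingredients.

    Append one timestep at a time with :meth:`step`; the first timestep has
    no predecessor, so its increment is defined as 0 and hence psi_0 = 0.
    """

    sigma_xi: float = DEFAULT_SIGMA_XI
    th_delta: float = DEFAULT_TH_DELTA
    xi_hat_values: list = field(default_factory=list)
    xi_values: list = field(default_factory=list)
    delta_values: list = field(default_factory=list)
    psi_values: list = field(default_factory=list)

    def step(
        self,
        sensory_points: Sequence[np.ndarray],
        policy_point: np.ndarray,
        selected_policy_point: np.ndarray,
    ) -> float:
        """Ingest one timestep's internal points; returns psi_t."""
        xh = xi_hat(sensory_points, policy_point, selected_policy_point)
        x = xi(xh, self.sigma_xi)
        x_prev = self.xi_values[-1] if self.xi_values else x
        d = x - x_prev
        p = psi(x, x_prev, self.th_delta)
        self.xi_hat_values.append(xh)
        self.xi_values.append(x)
        self.delta_values.append(d)
        self.psi_values.append(p)
        return p

    def __len__(self) -> int:
        return len(self.xi_values)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view (timestep, xi_hat, xi, delta, psi) for CSV logging."""
        return pd.DataFrame(
            {
                "timestep": np.arange(len(self)),
                "xi_hat": self.xi_hat_values,
                "xi": self.xi_values,
                "delta": self.delta_values,
                "psi": self.psi_values,
            }
        )
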