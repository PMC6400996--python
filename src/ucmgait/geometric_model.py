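"""Frontal-plane geometric model of the lower-limb kinematic chain.

The performance variable is the mediolateral (ML) position of the swing-foot
endpoint relative to the stance-foot contact.  It is expressed as a function
of seven segment angles — stance foot, stance shank, stance thigh, pelvis,
swing thigh, swing shank, swing foot — each parameterized by the angle of the
link's traversal vector (the direction in which the chain is walked from the
stance foot to the swing foot) measured from the lab vertical in the frontal
(ML–vertical) plane:

    x(phi) = sum_i  l_i * sin(phi_i)

so the Jacobian row is J_i = l_i * cos(phi_i).  A single sign convention for
every link (pelvis included) keeps the model and its derivatives uniform;
segment-specific signs are absorbed into the angles themselves.  With seven
elemental angles and a scalar performance variable, the null space ("the
uncontrolled manifold") has dimension 6 and its orthogonal complement
dimension 1 at every non-degenerate configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space as _null_space

__all__ = [
    "LINK_NAMES",
    "N_ANGLES",
    "DIM_UCM",
    "DIM_ORT",
    "SegmentChain",
    "DegenerateJacobianError",
    "default_chain",
    "forward_ml_position",
    "jacobian",
    "null_space_basis",
    "joint_positions",
]

LINK_NAMES: tuple[str, ...] = (
    "stance_foot",
    "stance_shank",
    "stance_thigh",
    "pelvis",
    "swing_thigh",
    "swing_shank",
    "swing_foot",
)
N_ANGLES = 7
DIM_UCM = 6  # null-space ("good" variance) dimension
DIM_ORT = 1  # orthogonal-complement ("bad" variance) dimension


class DegenerateJacobianError(ValueError):
    """The Jacobian row vanished, so the 6/1 subspace split is undefined."""


@dataclass(frozen=True)
class SegmentChain:
    """Ordered 7-link chain with link lengths in meters.

    Order is fixed: stance foot, stance shank, stance thigh, pelvis,
    swing thigh, swing shank, swing foot.
    """

    lengths: np.ndarray = field(
        default_factory=lambda: np.array([0.12, 0.40, 0.42, 0.28, 0.42, 0.40, 0.12])
    )

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float)
        if lengths.shape != (N_ANGLES,):
            raise ValueError(f"chain needs exactly {N_ANGLES} link lengths, got shape {lengths.shape}")
        if not np.all(lengths > 0):
            raise ValueError("all link lengths must be positive")
        object.__setattr__(self, "lengths", lengths)


def default_chain() -> SegmentChain:
    """Anthropometric default chain (meters) for an adult of ~1.7 m stature."""
    return SegmentChain()


def forward_ml_position(config: np.ndarray, chain: SegmentChain) -> float | np.ndarray:
    """ML position (m) of the swing-foot endpoint relative to the stance foot.

    ``config`` is the 7-vector of traversal angles (rad); an arbitrary number
    of leading dimensions is broadcast over.
    """
    config = np.asarray(config, dtype=float)
    if config.shape[-1] != N_ANGLES:
        raise ValueError(f"configuration must have {N_ANGLES} angles in its last axis")
    if not np.all(np.isfinite(config)):
        raise ValueError("configuration contains non-finite angles")
    x = np.sin(config) @ chain.lengths
    return float(x) if x.ndim == 0 else x


def jacobian(config: np.ndarray, chain: SegmentChain) -> np.ndarray:
    """Row of partials d x / d phi_i = l_i cos(phi_i), shape (..., 7), m/rad."""
    config = np.asarray(config, dtype=float)
    if config.shape[-1] != N_ANGLES:
        raise ValueError(f"configuration must have {N_ANGLES} angles in its last axis")
    if not np.all(np.isfinite(config)):
        raise ValueError("configuration contains non-finite angles")
    return chain.lengths * np.cos(config)


def null_space_basis(J: np.ndarray, *, tol: float = 1e-12) -> np.ndarray:
    """Orthonormal 7x6 basis E of {v : J v = 0}.

    The basis is computed by SVD, which is deterministic for a given J; the
    mathematically meaningful object is the projector E E^T = I - jhat jhat^T,
    which is unique.
    """
    J = np.asarray(J, dtype=float).reshape(-1)
    if J.shape != (N_ANGLES,):
        raise ValueError(f"Jacobian row must have {N_ANGLES} entries")
    if np.linalg.norm(J) <= tol:
        raise DegenerateJacobianError("zero Jacobian row: degenerate configuration")
    E = _null_space(J[None, :])
    if E.shape != (N_ANGLES, DIM_UCM):  # pragma: no cover - guaranteed for nonzero J
        raise DegenerateJacobianError(f"unexpected null-space dimension {E.shape[1]}")
    return E


def joint_positions(config: np.ndarray, chain: SegmentChain) -> np.ndarray:
    """Tip-to-tail frontal-plane joint positions, shape (..., 8, 2) as (ML, UP).

    Index 0 is the stance-foot contact at the origin; index 7 is the
    swing-foot endpoint.  Used by the synthetic marker generator and as an
    explicit vector-chain oracle for :func:`forward_ml_position`.
    """
    config = np.asarray(config, dtype=float)
    steps = np.stack(
        [chain.lengths * np.sin(config), chain.lengths * np.cos(config)], axis=-1
    )  # (..., 7, 2)
    pts = np.concatenate(
        [np.zeros(steps.shape[:-2] + (1, 2)), np.cumsum(steps, axis=-2)], axis=-2
    )
    return pts
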