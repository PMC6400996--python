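"""Uncontrolled-manifold (UCM) variance decomposition across steps.

At each percent of swing the step-to-step deviations of the 7 segment angles
from their across-step mean are split into a component inside the Jacobian's
null space (combinations that leave the mediolateral swing-foot position
unchanged — "good" variance, V_UCM) and a component along the Jacobian
direction ("bad" variance, V_ORT).  Each is normalized per degree of freedom
(6 and 1 respectively), total variance per all 7 DOF is V_TOT, and the
synergy index is

    dV = (V_UCM - V_ORT) / V_TOT,           dV in (-7, 7/6]

which is z-transformed with a Fisher-type log whose singularities sit at the
attainable bounds:

    dV_Z = 0.5 * ln( (7 + dV) / (7/6 - dV) ).

Profiles are averaged over the 101 swing samples (0..100%) for statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

from .geometric_model import (
    DIM_ORT,
    DIM_UCM,
    N_ANGLES,
    SegmentChain,
    jacobian,
    null_space_basis,
)

if TYPE_CHECKING:  # pragma: no cover
    from .io_gait import TrialMeta

__all__ = [
    "N_POINTS",
    "DV_LOWER",
    "DV_UPPER",
    "AngleEnsemble",
    "VarianceProfile",
    "UCMSummary",
    "DegenerateVarianceError",
    "SynergyBoundError",
    "decompose",
    "synergy_index",
    "z_transform",
    "inverse_z_transform",
    "average_swing",
]

N_POINTS = 101
DV_LOWER = -float(N_ANGLES)  # all variance orthogonal
DV_UPPER = N_ANGLES / DIM_UCM  # all variance inside the manifold: 7/6


class DegenerateVarianceError(ValueError):
    """Zero total variance at some percent of swing: the index is undefined."""


class SynergyBoundError(ValueError):
    """Synergy index at or beyond an attainable bound: z-transform undefined."""


@dataclass
class AngleEnsemble:
    """Per-step, time-normalized segment-angle trajectories for one trial.

    ``steps`` has shape (n_steps, 101, 7) in radians; at least two steps are
    required because the decomposition is an across-step variance.
    """

    steps: np.ndarray
    chain: SegmentChain
    meta: "TrialMeta | None" = None

    def __post_init__(self) -> None:
        steps = np.asarray(self.steps, dtype=float)
        if steps.ndim != 3 or steps.shape[1] != N_POINTS or steps.shape[2] != N_ANGLES:
            raise ValueError(
                f"steps must have shape (N, {N_POINTS}, {N_ANGLES}); got {steps.shape}"
            )
        if steps.shape[0] < 2:
            raise ValueError("need at least 2 steps to estimate across-step variance")
        if not np.all(np.isfinite(steps)):
            raise ValueError("angle ensemble contains non-finite values")
        self.steps = steps

    @property
    def n_steps(self) -> int:
        return int(self.steps.shape[0])


@dataclass
class VarianceProfile:
    """Per-percent variance components and synergy index for one trial.

    ``dvz`` is computed lazily so that degenerate-but-valid profiles (e.g. a
    constructed ensemble with V_ORT exactly 0, where dV sits at its bound)
    can still be inspected; accessing ``dvz`` then raises
    :class:`SynergyBoundError`.
    """

    v_ucm: np.ndarray
    v_ort: np.ndarray
    v_tot: np.ndarray
    dv: np.ndarray
    n_steps: int
    meta: "TrialMeta | None" = None
    d_ucm: int = DIM_UCM
    d_ort: int = DIM_ORT
    d_tot: int = N_ANGLES
    _dvz: np.ndarray | None = field(default=None, repr=False)

    @property
    def dvz(self) -> np.ndarray:
        if self._dvz is None:
            self._dvz = z_transform(self.dv)
        return self._dvz


@dataclass
class UCMSummary:
    """Swing-averaged outcomes for one subject x session x condition."""

    dvz: float
    v_ucm: float
    v_ort: float
    v_tot: float
    n_steps: int
    meta: "TrialMeta | None" = None


def decompose(
    ensemble: AngleEnsemble,
    *,
    divisor: str = "n",
) -> VarianceProfile:
    """Decompose across-step angle variance at each percent of swing.

    At each t the Jacobian is evaluated at the across-step mean configuration
    (the standard linearization point); deviations are projected onto the
    orthonormal null-space basis E, with the parallel (within-manifold) and
    perpendicular components normalized per DOF and per step:

        V_UCM(t) = sum_k ||E^T d_k||^2 / (6 N),
        V_ORT(t) = sum_k ||d_k - E E^T d_k||^2 / (1 N),
        V_TOT(t) = sum_k ||d_k||^2 / (7 N).

    ``divisor`` selects the step-count normalization: ``"n"`` (default,
    common UCM practice; the sample mean is estimated, so expectations carry
    an (N-1)/N factor) or ``"n-1"`` for the unbiased convention.
    """
    if divisor not in ("n", "n-1"):
        raise ValueError(f"divisor must be 'n' or 'n-1', got {divisor!r}")
    steps = ensemble.steps
    n = ensemble.n_steps
    denom = n if divisor == "n" else n - 1

    mean_cfg = steps.mean(axis=0)  # (101, 7)
    dev = steps - mean_cfg[None]  # (N, 101, 7)

    v_ucm = np.empty(N_POINTS)
    v_ort = np.empty(N_POINTS)
    v_tot = np.empty(N_POINTS)
    for t in range(N_POINTS):
        J = jacobian(mean_cfg[t], ensemble.chain)
        E = null_space_basis(J)  # may raise DegenerateJacobianError
        d = dev[:, t, :]  # (N, 7)
        par = d @ E  # (N, 6) coordinates inside the manifold
        ort = d - par @ E.T  # residual outside; vector form avoids cancellation
        ssq_tot = float(np.sum(d * d))
        ssq_par = float(np.sum(par * par))
        ssq_ort = float(np.sum(ort * ort))
        v_ucm[t] = ssq_par / (DIM_UCM * denom)
        v_ort[t] = ssq_ort / (DIM_ORT * denom)
        v_tot[t] = ssq_tot / (N_ANGLES * denom)

    profile = VarianceProfile(
        v_ucm=v_ucm, v_ort=v_ort, v_tot=v_tot, dv=np.empty(0), n_steps=n, meta=ensemble.meta
    )
    profile.dv = synergy_index(profile)
    return profile


def synergy_index(profile: VarianceProfile) -> np.ndarray:
    """Per-percent synergy index dV = (V_UCM - V_ORT) / V_TOT."""
    v_tot = np.asarray(profile.v_tot, dtype=float)
    if np.any(v_tot <= 0):
        bad = np.flatnonzero(v_tot <= 0)
        raise DegenerateVarianceError(
            f"V_TOT is zero at percent(s) {bad.tolist()}: no step-to-step variability"
        )
    return (np.asarray(profile.v_ucm) - np.asarray(profile.v_ort)) / v_tot


def z_transform(dv: np.ndarray | float) -> np.ndarray | float:
    """Fisher-type z-transform of the synergy index.

    dV_Z = 0.5 * ln((7 + dV) / (7/6 - dV)); strictly increasing on the open
    interval (-7, 7/6) with singularities exactly at the attainable bounds.
    """
    dv_arr = np.asarray(dv, dtype=float)
    if np.any(dv_arr <= DV_LOWER) or np.any(dv_arr >= DV_UPPER):
        raise SynergyBoundError(
            "synergy index at or beyond its attainable bounds (-7, 7/6); "
            "this indicates a degenerate variance decomposition"
        )
    out = 0.5 * np.log((N_ANGLES + dv_arr) / (DV_UPPER - dv_arr))
    return float(out) if out.ndim == 0 else out


def inverse_z_transform(dvz: np.ndarray | float) -> np.ndarray | float:
    """Inverse of :func:`z_transform` (used for round-trip checks)."""
    z = np.asarray(dvz, dtype=float)
    e = np.exp(2.0 * z)
    out = (DV_UPPER * e - N_ANGLES) / (1.0 + e)
    return float(out) if out.ndim == 0 else out


def average_swing(
    profile: VarianceProfile,
    *,
    transform_order: str = "transform-then-average",
) -> UCMSummary:
    """Arithmetic mean of each outcome over the 101 swing samples.

    ``transform_order`` controls the z-transform convention:
    ``"transform-then-average"`` (default: z per percent, then mean — the
    dominant convention in the UCM gait literature) or
    ``"average-then-transform"`` (mean dV, then one z).
    """
    if transform_order not in ("transform-then-average", "average-then-transform"):
        raise ValueError(f"unknown transform_order {transform_order!r}")
    if transform_order == "transform-then-average":
        dvz = float(np.mean(profile.dvz))
    else:
        dvz = float(z_transform(float(np.mean(profile.dv))))
    return UCMSummary(
        dvz=dvz,
        v_ucm=float(np.mean(profile.v_ucm)),
        v_ort=float(np.mean(profile.v_ort)),
        v_tot=float(np.mean(profile.v_tot)),
        n_steps=profile.n_steps,
        meta=profile.meta,
    )
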