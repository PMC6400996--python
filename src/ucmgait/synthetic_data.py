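"""Synthetic cohorts, trials and angle ensembles with known ground truth.

The generator emulates the statistical structure the analysis assumes: smooth
per-step frontal-plane segment-angle trajectories whose step-to-step
deviations are injected directly into the null space of the geometric model
(pointwise variance sigma2_ucm per dimension) and along the Jacobian
direction (sigma2_ort); walking trials with marker positions, gait events and
gait speeds synthesized from those angles; and full three-group pre/post
cohorts whose group x session x condition effects mirror the study design
(e.g. "bad" variance reduced to 0.75x after instability free-weight training
in the uneven-surface conditions, unchanged on the even surface).

Smoothness comes from low-order (4) random Fourier series scaled so the
pointwise variance is exact.  Deviations are injected in the null/orthogonal
frame of the *template* mean while the decomposition linearizes at the
*sample* mean; the mismatch is second order in the deviations and covered by
the recovery tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometric_model import (
    DIM_UCM,
    N_ANGLES,
    SegmentChain,
    default_chain,
    jacobian,
    joint_positions,
    null_space_basis,
)
from .io_gait import (
    CONDITIONS,
    GROUPS,
    OUTCOME_COLUMNS,
    SESSIONS,
    MarkerFrameSeries,
    OutcomeTable,
    TrialMeta,
)
from .preprocess import CHAIN_MARKERS, GaitEventTable
from .ucm_core import N_POINTS, AngleEnsemble, average_swing, decompose

__all__ = [
    "SimulationSpec",
    "EFFECT_MAP_STUDY",
    "null_effect_map",
    "ifrt_only_effect_map",
    "template_angles",
    "generate_ensemble",
    "generate_markers",
    "generate_cohort",
]

#: Pre -> post multiplicative factors on (sigma2_ucm, sigma2_ort) per
#: group x condition, mirroring the study's reported percent changes: no
#: change on the even surface; "good" variance up 21/28/50% (US) and
#: 19/28/43% (US_ISB); "bad" variance down 25%/24% after instability
#: free-weight training but up >35% after both machine-based modalities.
EFFECT_MAP_STUDY: dict[tuple[str, str], tuple[float, float]] = {
    ("S-MRT", "ES"): (1.00, 1.00),
    ("I-FRT", "ES"): (1.00, 1.00),
    ("S-MRT_HIP", "ES"): (1.00, 1.00),
    ("S-MRT", "US"): (1.21, 1.37),
    ("I-FRT", "US"): (1.28, 0.75),
    ("S-MRT_HIP", "US"): (1.50, 1.37),
    ("S-MRT", "US_ISB"): (1.19, 1.35),
    ("I-FRT", "US_ISB"): (1.28, 0.76),
    ("S-MRT_HIP", "US_ISB"): (1.43, 1.41),
}


def null_effect_map() -> dict[tuple[str, str], tuple[float, float]]:
    """No pre -> post change anywhere (type-I calibration cohorts)."""
    return {(g, c): (1.0, 1.0) for g in GROUPS for c in CONDITIONS}


def ifrt_only_effect_map(f_ort: float = 0.75) -> dict[tuple[str, str], tuple[float, float]]:
    """Orthogonal variance scaled only for I-FRT in the uneven conditions."""
    out = null_effect_map()
    out[("I-FRT", "US")] = (1.0, f_ort)
    out[("I-FRT", "US_ISB")] = (1.0, f_ort)
    return out


# Secondary measures: (pre means per group, pre SD per group, pre->post mean
# change per group, SD of change).  Units: s (tug, sts), cm (mdrt_*),
# N (imtp, strengths), points (fes_i).  FES-I values follow the reported
# descriptives (19.3+-2.6 -> 18.0 etc.); the rest are physiologic magnitudes
# for healthy 65-80 year olds with change directions matching the study.
_G3 = tuple[float, float, float]
SECONDARY_DEFAULTS: dict[str, tuple[_G3, _G3, _G3, float]] = {
    "tug": ((9.2, 9.4, 9.1), (1.4, 1.4, 1.4), (-0.2, -0.2, -0.2), 0.6),
    "mdrt_forward": ((27.0, 27.0, 27.0), (5.0, 5.0, 5.0), (2.2, 2.2, 2.2), 2.0),
    "mdrt_backward": ((18.0, 18.0, 18.0), (4.0, 4.0, 4.0), (0.3, 0.3, 0.3), 2.0),
    "mdrt_ml": ((22.0, 22.0, 22.0), (4.0, 4.0, 4.0), (0.9, 3.1, -2.6), 3.0),
    "sts": ((12.5, 12.5, 12.5), (2.5, 2.5, 2.5), (-1.25, -1.25, -1.25), 1.2),
    "imtp": ((1150.0, 1150.0, 1150.0), (280.0, 280.0, 280.0), (120.0, 260.0, 30.0), 150.0),
    "hip_adduction": ((210.0, 210.0, 210.0), (50.0, 50.0, 50.0), (8.0, 8.0, 8.0), 25.0),
    "hip_abduction": ((200.0, 200.0, 200.0), (50.0, 50.0, 50.0), (2.0, 2.0, 2.0), 25.0),
    "knee_extension": ((320.0, 320.0, 320.0), (80.0, 80.0, 80.0), (28.0, 28.0, 28.0), 40.0),
    "fes_i": ((19.3, 20.0, 18.9), (2.6, 3.7, 3.2), (-1.3, -1.6, -0.6), 1.5),
}

#: Total lifted load over the program, post-test only (kg): machine-based
#: whole-limb training accumulates far more load than free-weight or
#: adductor/abductor work, giving the very large pairwise effects reported.
TRAINING_LOAD_DEFAULTS: tuple[_G3, _G3] = ((4200.0, 1900.0, 1150.0), (650.0, 480.0, 380.0))


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the synthetic cohort.

    Defaults mirror the trial: 24/21/23 subjects in S-MRT/I-FRT/S-MRT_HIP,
    20 analyzed steps per subject x condition, baseline variance magnitudes
    of order 1e-4 rad^2 (SD ~0.01 rad, physiologic for frontal-plane segment
    angles; the study reports no absolute variance values), higher on the
    uneven surfaces, with the effect map above.  Between-subject and
    session-to-session variability are multiplicative log-normal factors on
    the variance components; gait-speed pre -> post paired effects are the
    reported standardized magnitudes (0.45 ES, 0.41 US, 0.29 US_ISB).
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {"S-MRT": 24, "I-FRT": 21, "S-MRT_HIP": 23}
    )
    n_steps: int = 20
    chain: SegmentChain = field(default_factory=default_chain)
    base_variance: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ES": (1.0e-4, 4.0e-5),
            "US": (1.3e-4, 6.0e-5),
            "US_ISB": (1.4e-4, 6.5e-5),
        }
    )
    effect_map: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(EFFECT_MAP_STUDY)
    )
    subject_sigma: float = 0.35  # log-SD of between-subject variance factors
    session_sigma: float = 0.20  # log-SD of session-to-session variance factors
    fourier_order: int = 4
    speed_mean: dict[str, float] = field(
        default_factory=lambda: {"ES": 1.25, "US": 1.10, "US_ISB": 1.05}
    )
    speed_between_sd: float = 0.18  # m/s, between subjects
    speed_diff_sd: float = 0.06  # m/s, SD of paired pre->post change
    speed_effect_d: dict[str, float] = field(
        default_factory=lambda: {"ES": 0.45, "US": 0.41, "US_ISB": 0.29}
    )
    secondary: dict[str, tuple[_G3, _G3, _G3, float]] = field(
        default_factory=lambda: dict(SECONDARY_DEFAULTS)
    )
    training_load: tuple[_G3, _G3] = TRAINING_LOAD_DEFAULTS
    seed: int = 0

    def __post_init__(self) -> None:
        for cond, (s2u, s2o) in self.base_variance.items():
            if s2u <= 0 or s2o < 0:
                raise ValueError(f"non-positive base variance for {cond}")
        for key, (fu, fo) in self.effect_map.items():
            if fu <= 0 or fo <= 0:
                raise ValueError(f"non-positive effect factor for {key}")

    def null(self) -> "SimulationSpec":
        """A copy with every pre -> post effect switched off."""
        return replace(
            self,
            effect_map=null_effect_map(),
            speed_effect_d={c: 0.0 for c in CONDITIONS},
            secondary={
                k: (pre, sd, (0.0, 0.0, 0.0), dsd)
                for k, (pre, sd, _, dsd) in self.secondary.items()
            },
        )


# ---------------------------------------------------------------------------
# Angle templates and ensembles
# ---------------------------------------------------------------------------

# (offset, sine amplitude, sine phase) per segment; swing-limb traversal
# vectors point downward, so their angles sit near -pi + delta with delta
# kept well away from the branch cut.
_TEMPLATE = np.array(
    [
        (0.05, 0.030, 0.0),
        (0.03, 0.020, 0.5),
        (0.06, 0.030, 1.0),
        (np.pi / 2 - 0.12, 0.050, 0.2),
        (-np.pi + 0.28, 0.060, 0.0),
        (-np.pi + 0.22, -0.050, 0.3),
        (-np.pi + 0.18, 0.040, 0.1),
    ]
)

_CONDITION_SCALE = {"ES": 1.0, "US": 1.15, "US_ISB": 1.2}


def template_angles(condition: str = "ES", n_points: int = N_POINTS) -> np.ndarray:
    """Smooth mean swing trajectory theta_bar(t), shape (n_points, 7), rad."""
    tau = np.linspace(0.0, 1.0, n_points)
    scale = _CONDITION_SCALE.get(condition, 1.0)
    off, amp, phase = _TEMPLATE[:, 0], _TEMPLATE[:, 1] * scale, _TEMPLATE[:, 2]
    return off[None, :] + amp[None, :] * np.sin(np.pi * tau[:, None] + phase[None, :])


def _unit_fourier(rng: np.random.Generator, shape: tuple[int, ...], order: int,
                  n_points: int = N_POINTS) -> np.ndarray:
    """Random Fourier series with exactly unit pointwise variance.

    Coefficients alpha_m, beta_m ~ N(0, 1/order) give pointwise variance
    sum_m (cos^2 + sin^2)/order = 1 at every t.
    """
    tau = np.linspace(0.0, 1.0, n_points)
    m = np.arange(1, order + 1)
    cos = np.cos(2 * np.pi * np.outer(m, tau))  # (order, T)
    sin = np.sin(2 * np.pi * np.outer(m, tau))
    alpha = rng.normal(0.0, np.sqrt(1.0 / order), size=shape + (order,))
    beta = rng.normal(0.0, np.sqrt(1.0 / order), size=shape + (order,))
    return alpha @ cos + beta @ sin  # (..., T)


def generate_ensemble(
    spec: SimulationSpec,
    meta: TrialMeta,
    rng: np.random.Generator,
    sigma2: tuple[float, float] | None = None,
    n_steps: int | None = None,
) -> AngleEnsemble:
    """Generate one trial's angle ensemble with prescribed variance split.

    Each step is theta_k(t) = theta_bar(t) + E(t) a_k(t) + jhat(t) b_k(t)
    with E, jhat from the chain model at the template and a_k, b_k smooth
    random Fourier curves of pointwise variance sigma2_ucm (per null-space
    dimension) and sigma2_ort.
    """
    n = n_steps or spec.n_steps
    s2u, s2o = sigma2 if sigma2 is not None else spec.base_variance[meta.condition]
    template = template_angles(meta.condition)
    E = np.empty((N_POINTS, N_ANGLES, DIM_UCM))
    jhat = np.empty((N_POINTS, N_ANGLES))
    for t in range(N_POINTS):
        J = jacobian(template[t], spec.chain)
        E[t] = null_space_basis(J)
        jhat[t] = J / np.linalg.norm(J)
    a = np.sqrt(s2u) * _unit_fourier(rng, (n, DIM_UCM), spec.fourier_order)  # (n, 6, T)
    b = np.sqrt(s2o) * _unit_fourier(rng, (n,), spec.fourier_order)  # (n, T)
    steps = (
        template[None]
        + np.einsum("tij,kjt->kti", E, a)
        + jhat[None] * b[:, :, None]
    )
    return AngleEnsemble(steps, spec.chain, meta)


# ---------------------------------------------------------------------------
# Marker synthesis
# ---------------------------------------------------------------------------


def generate_markers(
    ensemble: AngleEnsemble,
    rate_hz: float = 120.0,
    noise_sd: float = 0.0,
    speed: float = 1.2,
    swing_duration_s: float = 0.4,
    stance_duration_s: float = 0.7,
    lead_in_s: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[MarkerFrameSeries, GaitEventTable]:
    """Synthesize a walking trial's marker series from an angle ensemble.

    Frontal-plane (ML, UP) joint positions come tip-to-tail from the chain;
    fore-aft (AP) progression is a straight pass at ``speed`` for the pelvis
    and hips, with each foot planted during stance and advancing linearly
    during its swing, which puts the extrema of foot-relative-to-pelvis AP
    exactly at the true toe-off/heel-strike frames.  Isotropic Gaussian
    measurement noise is added to every coordinate.  Returns the series and
    the ground-truth event table (left = swing/analysis limb).
    """
    rng = rng or np.random.default_rng()
    chain = ensemble.chain
    n = ensemble.n_steps
    period = swing_duration_s + stance_duration_s
    swing_frames = int(round(swing_duration_s * rate_hz))
    to_frames = np.array(
        [int(round((lead_in_s + k * period) * rate_hz)) for k in range(n)]
    )
    hs_frames = to_frames + swing_frames
    n_total = hs_frames[-1] + int(lead_in_s * rate_hz)

    # per-frame 7-angle configuration: each swing follows its step, stance
    # phases blend linearly between neighboring swing endpoints
    config = np.empty((n_total, N_ANGLES))
    config[: to_frames[0]] = ensemble.steps[0, 0]
    pct_grid = np.arange(N_POINTS, dtype=float)
    for k in range(n):
        to, hs = to_frames[k], hs_frames[k]
        pct = 100.0 * (np.arange(to, hs + 1) - to) / (hs - to)
        for j in range(N_ANGLES):
            config[to : hs + 1, j] = np.interp(pct, pct_grid, ensemble.steps[k, :, j])
        nxt = to_frames[k + 1] if k + 1 < n else n_total
        if hs + 1 < nxt:
            tail = ensemble.steps[k + 1, 0] if k + 1 < n else ensemble.steps[k, -1]
            frac = (np.arange(hs + 1, nxt) - hs) / (nxt - hs)
            config[hs + 1 : nxt] = ensemble.steps[k, -1][None] + np.outer(
                frac, tail - ensemble.steps[k, -1]
            )

    pts = joint_positions(config, chain)  # (T, 8, 2) as (ML, UP)
    tvec = np.arange(n_total) / rate_hz
    pelvis_ap = -1.0 + speed * tvec
    stride = speed * period

    def foot_ap(windows: np.ndarray, first_plant: float) -> np.ndarray:
        ap = np.empty(n_total)
        plant = first_plant
        ap[: windows[0, 0]] = plant
        for w, (to, hs) in enumerate(windows):
            s = (np.arange(to, hs + 1) - to) / (hs - to)
            ap[to : hs + 1] = plant + stride * s
            plant += stride
            nxt = windows[w + 1, 0] if w + 1 < len(windows) else n_total
            ap[hs + 1 : nxt] = plant
        return ap

    left_windows = np.stack([to_frames, hs_frames], axis=1)
    half = int(round(period / 2 * rate_hz))
    right_windows = left_windows - half
    right_windows = right_windows[right_windows[:, 0] > 0]
    l_ap = foot_ap(left_windows, pelvis_ap[to_frames[0]] - stride / 2)
    r_ap = (
        foot_ap(right_windows, pelvis_ap[right_windows[0, 0]] - stride / 2)
        if len(right_windows)
        else np.full(n_total, pelvis_ap[0])
    )

    hip_ap = pelvis_ap
    markers: dict[str, np.ndarray] = {}
    ap_for_joint = {
        "r_foot": r_ap, "r_ankle": r_ap, "r_knee": (r_ap + hip_ap) / 2,
        "r_hip": hip_ap, "l_hip": hip_ap, "l_knee": (l_ap + hip_ap) / 2,
        "l_ankle": l_ap, "l_foot": l_ap,
    }
    for i, name in enumerate(CHAIN_MARKERS):
        markers[name] = np.stack(
            [pts[:, i, 0], ap_for_joint[name], pts[:, i, 1]], axis=1
        )
    markers["pelvis"] = np.stack(
        [(pts[:, 3, 0] + pts[:, 4, 0]) / 2, pelvis_ap, (pts[:, 3, 1] + pts[:, 4, 1]) / 2],
        axis=1,
    )
    if noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(0.0, noise_sd, markers[name].shape)

    events = GaitEventTable(
        {
            "left": {"TO": to_frames, "HS": hs_frames},
            "right": {"TO": right_windows[:, 0], "HS": right_windows[:, 1]}
            if len(right_windows)
            else {"TO": [], "HS": []},
        }
    )
    return MarkerFrameSeries(rate_hz, markers), events


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


def _chi2_factor(rng: np.random.Generator, df: float, size: int) -> np.ndarray:
    """chi^2_df / df multiplicative sampling noise (mean 1)."""
    return rng.gamma(shape=df / 2.0, scale=2.0 / df, size=size)


def generate_cohort(
    spec: SimulationSpec,
    seed: int | None = None,
    path: str = "fast",
    return_ensembles: bool = False,
) -> OutcomeTable | tuple[OutcomeTable, dict[TrialMeta, AngleEnsemble]]:
    """Generate a full pre/post cohort as an outcomes table.

    ``path="fast"`` draws the swing-averaged UCM outcomes directly from the
    distributions the ensemble process implies: the per-subject variance
    components are the prescribed sigma^2 times log-normal subject and
    session factors, the (N-1)/N divisor-N bias, and a chi^2 sampling factor
    whose degrees of freedom (2 * order * d * (N-1)) count the independent
    Fourier coefficients that survive mean subtraction.  ``path="full"``
    generates every angle ensemble and runs it through the decomposition;
    both paths agree in distribution.
    """
    if path not in ("fast", "full"):
        raise ValueError("path must be 'fast' or 'full'")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_steps
    bias = (n - 1) / n
    df_u = 2 * spec.fourier_order * DIM_UCM * (n - 1)
    df_o = 2 * spec.fourier_order * 1 * (n - 1)

    rows: list[dict] = []
    ensembles: dict[TrialMeta, AngleEnsemble] = {}
    for gi, group in enumerate(GROUPS):
        for i in range(spec.n_per_group[group]):
            sid = f"{group}-{i:02d}"
            subj_u = rng.lognormal(0.0, spec.subject_sigma)
            subj_o = rng.lognormal(0.0, spec.subject_sigma)
            subj_speed = rng.normal(0.0, spec.speed_between_sd)
            sec_pre = {
                name: rng.normal(pre[gi], sd[gi])
                for name, (pre, sd, _, _) in spec.secondary.items()
            }
            sec_post = {
                name: sec_pre[name] + rng.normal(delta[gi], dsd)
                for name, (_, _, delta, dsd) in spec.secondary.items()
            }
            load = rng.normal(spec.training_load[0][gi], spec.training_load[1][gi])
            for condition in CONDITIONS:
                s2u_base, s2o_base = spec.base_variance[condition]
                speed_pre = spec.speed_mean[condition] + subj_speed + rng.normal(0.0, 0.03)
                d_speed = spec.speed_effect_d[condition]
                speed_post = speed_pre + rng.normal(
                    d_speed * spec.speed_diff_sd, spec.speed_diff_sd
                )
                for session in SESSIONS:
                    fu, fo = (
                        spec.effect_map[(group, condition)] if session == "post" else (1.0, 1.0)
                    )
                    s2u = s2u_base * subj_u * fu * rng.lognormal(0.0, spec.session_sigma)
                    s2o = s2o_base * subj_o * fo * rng.lognormal(0.0, spec.session_sigma)
                    meta = TrialMeta(sid, group, session, condition)
                    if path == "fast":
                        v_ucm = s2u * bias * _chi2_factor(rng, df_u, 1)[0]
                        v_ort = s2o * bias * _chi2_factor(rng, df_o, 1)[0]
                        v_tot = (DIM_UCM * v_ucm + v_ort) / N_ANGLES
                        dv = (v_ucm - v_ort) / v_tot
                        dvz = 0.5 * np.log((N_ANGLES + dv) / (N_ANGLES / DIM_UCM - dv))
                    else:
                        ens = generate_ensemble(spec, meta, rng, sigma2=(s2u, s2o))
                        if return_ensembles:
                            ensembles[meta] = ens
                        summ = average_swing(decompose(ens))
                        v_ucm, v_ort, v_tot, dvz = summ.v_ucm, summ.v_ort, summ.v_tot, summ.dvz
                    rows.append(
                        {
                            "subject_id": sid,
                            "group": group,
                            "session": session,
                            "condition": condition,
                            "dvz": float(dvz),
                            "v_ucm": float(v_ucm),
                            "v_ort": float(v_ort),
                            "v_tot": float(v_tot),
                            "gait_speed": float(speed_pre if session == "pre" else speed_post),
                            "training_load": float(load) if session == "post" else np.nan,
                            **{k: float(sec_pre[k] if session == "pre" else sec_post[k])
                               for k in spec.secondary},
                        }
                    )
    df = pd.DataFrame(rows)
    for col in OUTCOME_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    table = OutcomeTable(df)
    return (table, ensembles) if return_ensembles else table
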