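"""Readers and writers for every external representation the pipeline touches.

CSV is the canonical interchange format throughout; the motion-capture C3D
standard is accepted read-only behind an optional dependency.  Angles are
stored in radians, lengths in meters, speeds in m/s.  No reader invents
values: missing marker samples stay flagged as gaps (NaN + mask).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometric_model import N_ANGLES, SegmentChain
from .ucm_core import N_POINTS, AngleEnsemble

__all__ = [
    "AXES",
    "GROUPS",
    "SESSIONS",
    "CONDITIONS",
    "OUTCOME_COLUMNS",
    "GaitIOError",
    "UnknownDialectError",
    "C3DSupportError",
    "MissingRateError",
    "MissingAxisMappingError",
    "EnsembleFormatError",
    "TrialMeta",
    "MarkerFrameSeries",
    "OutcomeTable",
    "read_markers",
    "write_markers",
    "read_angle_ensemble",
    "write_angle_ensemble",
    "read_outcomes",
    "write_outcomes",
]

AXES: tuple[str, str, str] = ("ML", "AP", "UP")
GROUPS: tuple[str, ...] = ("S-MRT", "I-FRT", "S-MRT_HIP")
SESSIONS: tuple[str, ...] = ("pre", "post")
CONDITIONS: tuple[str, ...] = ("ES", "US", "US_ISB")

#: Public, documented column order of the outcomes CSV.  The first nine are
#: per subject x session x condition; the remainder are per subject x session
#: and are repeated verbatim on each condition row (missing values allowed).
OUTCOME_COLUMNS: tuple[str, ...] = (
    "subject_id",
    "group",
    "session",
    "condition",
    "dvz",
    "v_ucm",
    "v_ort",
    "v_tot",
    "gait_speed",
    "tug",
    "mdrt_forward",
    "mdrt_backward",
    "mdrt_ml",
    "sts",
    "imtp",
    "hip_adduction",
    "hip_abduction",
    "knee_extension",
    "fes_i",
    "training_load",
)


class GaitIOError(ValueError):
    """Base class for file-format failures."""


class UnknownDialectError(GaitIOError):
    """Marker file dialect is not one of {'csv', 'c3d'}."""


class C3DSupportError(GaitIOError):
    """C3D requested but the optional ezc3d dependency is not installed."""


class MissingRateError(GaitIOError):
    """Marker file does not declare its sampling rate."""


class MissingAxisMappingError(GaitIOError):
    """Marker file does not declare the ML/AP/UP axis mapping."""


class EnsembleFormatError(GaitIOError):
    """Angle-ensemble CSV violates its contract (step length, duplicates...)."""


@dataclass(frozen=True)
class TrialMeta:
    """Identity of one trial: subject, training group, session, condition."""

    subject_id: str
    group: str
    session: str
    condition: str

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}, got {self.session!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")


class MarkerFrameSeries:
    """Raw 3D marker positions over time for one walking trial.

    ``markers`` maps marker name -> (n_frames, 3) float array in (ML, AP, UP)
    lab axes, meters, with NaN at gaps; ``gaps`` maps name -> boolean mask.
    """

    def __init__(self, rate_hz: float, markers: dict[str, np.ndarray]):
        if not rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if not markers:
            raise ValueError("at least one marker is required")
        lengths = {name: np.asarray(a).shape[0] for name, a in markers.items()}
        if len(set(lengths.values())) != 1:
            raise ValueError(f"markers have inconsistent frame counts: {lengths}")
        self.rate_hz = float(rate_hz)
        self.markers = {
            name: np.asarray(a, dtype=float).reshape(-1, 3) for name, a in markers.items()
        }

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.n_frames)

    @property
    def gaps(self) -> dict[str, np.ndarray]:
        return {name: np.isnan(a).any(axis=1) for name, a in self.markers.items()}

    def copy(self) -> "MarkerFrameSeries":
        return MarkerFrameSeries(self.rate_hz, {k: v.copy() for k, v in self.markers.items()})


def read_markers(path: str | Path, dialect: str = "csv") -> MarkerFrameSeries:
    """Read marker trajectories from CSV (canonical) or C3D (optional)."""
    if dialect == "csv":
        return _read_markers_csv(Path(path))
    if dialect == "c3d":
        return _read_markers_c3d(Path(path))
    raise UnknownDialectError(f"unknown marker dialect {dialect!r}; expected 'csv' or 'c3d'")


def _read_markers_csv(path: Path) -> MarkerFrameSeries:
    rate_hz = None
    axes = None
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].strip().partition("=")
            if key.strip() == "rate_hz":
                rate_hz = float(value)
            elif key.strip() == "axes":
                axes = tuple(v.strip() for v in value.split(","))
    if rate_hz is None:
        raise MissingRateError(f"{path}: no '# rate_hz=' header line")
    if axes is None:
        raise MissingAxisMappingError(f"{path}: no '# axes=' header line")
    if set(axes) != set(AXES) or len(axes) != 3:
        raise MissingAxisMappingError(f"{path}: axes must cover exactly {set(AXES)}, got {axes}")
    df = pd.read_csv(path, skiprows=header_lines)
    names: list[str] = []
    for col in df.columns:
        if col == "frame":
            continue
        base, _, axis = col.rpartition("_")
        if axis not in AXES or not base:
            raise MissingAxisMappingError(f"{path}: column {col!r} lacks an _ML/_AP/_UP suffix")
        if base not in names:
            names.append(base)
    markers = {}
    for name in names:
        cols = [f"{name}_{ax}" for ax in AXES]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise MissingAxisMappingError(f"{path}: marker {name!r} missing columns {missing}")
        markers[name] = df[cols].to_numpy(dtype=float)
    return MarkerFrameSeries(rate_hz, markers)


def _read_markers_c3d(path: Path) -> MarkerFrameSeries:
    try:
        import ezc3d  # type: ignore
    except ImportError as exc:  # pragma: no cover - exercised only without ezc3d
        raise C3DSupportError(
            "C3D input requires the optional 'ezc3d' dependency (pip install ucmgait[c3d])"
        ) from exc
    c3d = ezc3d.c3d(str(path))  # pragma: no cover
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])  # pragma: no cover
    labels = list(c3d["parameters"]["POINT"]["LABELS"]["value"])  # pragma: no cover
    pts = np.asarray(c3d["data"]["points"])[:3]  # pragma: no cover
    markers = {  # pragma: no cover
        name: pts[:, i, :].T / 1000.0 for i, name in enumerate(labels)
    }
    return MarkerFrameSeries(rate, markers)  # pragma: no cover


def write_markers(series: MarkerFrameSeries, path: str | Path) -> Path:
    """Write a marker series to the canonical CSV dialect."""
    path = Path(path)
    data = {"frame": series.frames}
    for name, arr in series.markers.items():
        for j, ax in enumerate(AXES):
            data[f"{name}_{ax}"] = arr[:, j]
    buf = io.StringIO()
    buf.write(f"# rate_hz={series.rate_hz!r}\n")
    buf.write(f"# axes={','.join(AXES)}\n")
    pd.DataFrame(data).to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    return path


# ---------------------------------------------------------------------------
# Angle ensembles
# ---------------------------------------------------------------------------

_THETA_COLUMNS = tuple(f"theta{i}" for i in range(1, N_ANGLES + 1))
_ENSEMBLE_KEY = ("subject_id", "group", "session", "condition")


def write_angle_ensemble(
    ensembles: list[AngleEnsemble] | AngleEnsemble, path: str | Path
) -> Path:
    """Write one or more ensembles to a tidy CSV (101 rows of pct per step)."""
    if isinstance(ensembles, AngleEnsemble):
        ensembles = [ensembles]
    frames = []
    for ens in ensembles:
        if ens.meta is None:
            raise GaitIOError("cannot write an ensemble without TrialMeta")
        n, p, _ = ens.steps.shape
        df = pd.DataFrame(ens.steps.reshape(n * p, N_ANGLES), columns=list(_THETA_COLUMNS))
        df.insert(0, "pct", np.tile(np.arange(p), n))
        df.insert(0, "step_id", np.repeat(np.arange(n), p))
        for col, val in zip(
            _ENSEMBLE_KEY,
            (ens.meta.subject_id, ens.meta.group, ens.meta.session, ens.meta.condition),
        ):
            df.insert(list(_ENSEMBLE_KEY).index(col), col, val)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def read_angle_ensemble(
    path: str | Path, chain: SegmentChain | None = None
) -> list[AngleEnsemble]:
    """Read a tidy angle-ensemble CSV, grouped by subject x session x condition.

    Contract: per step exactly 101 rows with pct 0..100, finite angles, no
    duplicate (step_id, pct) pairs.  Violations raise
    :class:`EnsembleFormatError` naming the offending step.
    """
    chain = chain or SegmentChain()
    df = pd.read_csv(path)
    required = set(_ENSEMBLE_KEY) | {"step_id", "pct"} | set(_THETA_COLUMNS)
    missing = required - set(df.columns)
    if missing:
        raise EnsembleFormatError(f"{path}: missing columns {sorted(missing)}")
    theta = df[list(_THETA_COLUMNS)].to_numpy(dtype=float)
    if not np.all(np.isfinite(theta)):
        raise EnsembleFormatError(f"{path}: non-finite angle values")
    ensembles = []
    for key, grp in df.groupby(list(_ENSEMBLE_KEY), sort=True):
        meta = TrialMeta(str(key[0]), key[1], key[2], key[3])
        steps = []
        for step_id, step in grp.groupby("step_id", sort=True):
            if step.duplicated(subset="pct").any():
                raise EnsembleFormatError(
                    f"{path}: duplicate (step_id, pct) rows in step {step_id} of {key}"
                )
            if len(step) != N_POINTS or not np.array_equal(
                np.sort(step["pct"].to_numpy()), np.arange(N_POINTS)
            ):
                raise EnsembleFormatError(
                    f"{path}: step {step_id} of {key} has {len(step)} samples; "
                    f"expected pct 0..100 in {N_POINTS} rows"
                )
            step = step.sort_values("pct")
            steps.append(step[list(_THETA_COLUMNS)].to_numpy(dtype=float))
        ensembles.append(AngleEnsemble(np.stack(steps), chain, meta))
    return ensembles


# ---------------------------------------------------------------------------
# Outcome tables
# ---------------------------------------------------------------------------


class OutcomeTable:
    """Tidy per-subject outcomes: one row per subject x session x condition.

    Wraps a pandas DataFrame; unknown extra columns are preserved, never
    dropped.  Secondary (per subject x session) measures repeat across the
    three condition rows and may be missing (NaN).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in OUTCOME_COLUMNS if c not in df.columns]
        if missing:
            raise GaitIOError(f"outcome table missing columns {missing}")
        extra = [c for c in df.columns if c not in OUTCOME_COLUMNS]
        self.df = df[list(OUTCOME_COLUMNS) + extra].reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        for col, allowed in (("group", GROUPS), ("session", SESSIONS), ("condition", CONDITIONS)):
            bad = set(df[col].unique()) - set(allowed)
            if bad:
                raise GaitIOError(f"invalid {col} value(s) {sorted(bad)}")
        if df.duplicated(subset=["subject_id", "session", "condition"]).any():
            raise GaitIOError("duplicate subject x session x condition rows")
        for col in ("v_ucm", "v_ort", "v_tot", "gait_speed"):
            vals = df[col].dropna()
            if (vals <= 0).any():
                raise GaitIOError(f"{col} must be positive where present")

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, OutcomeTable) and self.df.equals(other.df)


def write_outcomes(table: OutcomeTable, path: str | Path) -> Path:
    """Write the outcomes CSV in the fixed documented column order."""
    path = Path(path)
    table.df.to_csv(path, index=False, float_format="%.12g")
    return path


def read_outcomes(path: str | Path) -> OutcomeTable:
    df = pd.read_csv(
        path, dtype={"subject_id": str, "group": str, "session": str, "condition": str}
    )
    return OutcomeTable(df)
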