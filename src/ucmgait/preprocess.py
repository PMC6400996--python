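"""From raw marker trajectories to per-step, time-normalized angle ensembles.

Processing order mirrors standard gait practice: interpolate short marker
gaps (cubic spline), low-pass filter (6 Hz zero-lag Butterworth), detect
gait events from foot-relative-to-pelvis fore-aft excursions, compute
frontal-plane segment angles, cut left-limb swing phases (toe-off to
heel-strike), and time-normalize each to 0..100% in 101 samples.  Gait speed
is the mean speed over complete passes through the capture volume; swings
that leave the volume (turns) are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import butter, find_peaks, sosfiltfilt

from .geometric_model import N_ANGLES, SegmentChain
from .io_gait import MarkerFrameSeries

__all__ = [
    "CHAIN_MARKERS",
    "FilterSpec",
    "GaitEventTable",
    "FilterError",
    "EventDetectionError",
    "SwingExtractionError",
    "DegenerateSegmentError",
    "NoPassError",
    "interpolate_gaps",
    "lowpass_filter",
    "filter_series",
    "detect_gait_events",
    "compute_segment_angles",
    "chain_from_markers",
    "extract_swing_cycles",
    "time_normalize",
    "compute_gait_speed",
]

#: Chain joint markers in traversal order, stance (right) foot to swing
#: (left) foot; consecutive pairs define the 7 segments of the model.
CHAIN_MARKERS: tuple[str, ...] = (
    "r_foot",
    "r_ankle",
    "r_knee",
    "r_hip",
    "l_hip",
    "l_knee",
    "l_ankle",
    "l_foot",
)

_AX = {"ML": 0, "AP": 1, "UP": 2}


class FilterError(ValueError):
    pass


class EventDetectionError(ValueError):
    pass


class SwingExtractionError(ValueError):
    pass


class DegenerateSegmentError(ValueError):
    pass


class NoPassError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Zero-lag Butterworth low-pass specification.

    The conventional reading of "fourth-order zero-lag" is a forward and a
    backward pass of a 2nd-order filter (``mode="split"``, default, 4th-order
    effective response).  ``mode="cascade"`` instead runs both passes at the
    stated order (8th-order effective) for labs that report it that way.
    """

    cutoff_hz: float = 6.0
    order: int = 4
    zero_lag: bool = True
    mode: str = "split"

    def __post_init__(self) -> None:
        if self.cutoff_hz <= 0:
            raise ValueError("cutoff_hz must be positive")
        if self.order <= 0 or self.order % 2:
            raise ValueError("order must be an even positive integer")
        if self.mode not in ("split", "cascade"):
            raise ValueError("mode must be 'split' or 'cascade'")


@dataclass
class GaitEventTable:
    """Per-limb toe-off (TO) and heel-strike (HS) frame indices.

    Within each limb the analyzed events alternate TO, HS, TO, HS, ... with
    strictly increasing frames, so every swing has toe-off < heel-strike.
    """

    events: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for limb, table in self.events.items():
            to = np.asarray(table.get("TO", []), dtype=int)
            hs = np.asarray(table.get("HS", []), dtype=int)
            self.events[limb] = {"TO": to, "HS": hs}
            merged = sorted([(f, "TO") for f in to] + [(f, "HS") for f in hs])
            frames = [f for f, _ in merged]
            if len(frames) != len(set(frames)):
                raise ValueError(f"{limb}: duplicate event frames")
            labels = [lab for _, lab in merged]
            for a, b in zip(labels, labels[1:]):
                if a == b:
                    raise ValueError(f"{limb}: events do not alternate TO/HS")

    def swing_pairs(self, limb: str) -> list[tuple[int, int]]:
        """(toe_off, heel_strike) frame pairs for the limb, in order."""
        table = self.events[limb]
        pairs = []
        hs = table["HS"]
        for to in table["TO"]:
            later = hs[hs > to]
            if later.size:
                pairs.append((int(to), int(later[0])))
        return pairs


# ---------------------------------------------------------------------------
# Gap interpolation and filtering
# ---------------------------------------------------------------------------


def _gap_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    in_run = False
    for i, m in enumerate(mask):
        if m and not in_run:
            start, in_run = i, True
        elif not m and in_run:
            runs.append((start, i))
            in_run = False
    if in_run:
        runs.append((start, len(mask)))
    return runs


def interpolate_gaps(series: MarkerFrameSeries, max_gap: int = 12) -> MarkerFrameSeries:
    """Fill marker gaps of length <= ``max_gap`` by cubic spline.

    The spline is fit through all valid samples of the affected coordinate,
    so polynomial trajectories up to cubic are reproduced exactly.  Longer
    gaps and gaps touching the series boundary (no anchor on one side)
    remain flagged, with a warning for the latter.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = series.copy()
    for name, arr in out.markers.items():
        mask = np.isnan(arr).any(axis=1)
        if not mask.any():
            continue
        valid = ~mask
        if valid.sum() < 4:
            warnings.warn(f"marker {name!r}: too few valid samples to interpolate")
            continue
        spline = CubicSpline(np.flatnonzero(valid), arr[valid], axis=0)
        for start, stop in _gap_runs(mask):
            if stop - start > max_gap:
                continue
            if start == 0 or stop == len(mask):
                warnings.warn(f"marker {name!r}: gap at series boundary left unfilled")
                continue
            idx = np.arange(start, stop)
            arr[idx] = spline(idx)
    return out


def lowpass_filter(signal: np.ndarray, rate_hz: float, spec: FilterSpec | None = None) -> np.ndarray:
    """Zero-lag Butterworth low-pass of a uniformly sampled signal.

    Works along axis 0; forward-backward application gives zero phase shift
    and unit DC gain.
    """
    spec = spec or FilterSpec()
    signal = np.asarray(signal, dtype=float)
    if np.isnan(signal).any():
        raise FilterError("signal contains NaN; fill gaps before filtering")
    if rate_hz <= 2 * spec.cutoff_hz:
        raise FilterError(f"rate {rate_hz} Hz too low for cutoff {spec.cutoff_hz} Hz")
    design_order = spec.order // 2 if spec.mode == "split" else spec.order
    sos = butter(design_order, spec.cutoff_hz, btype="low", fs=rate_hz, output="sos")
    try:
        return sosfiltfilt(sos, signal, axis=0)
    except ValueError as exc:
        raise FilterError(f"signal too short for filter warm-up: {exc}") from exc


def filter_series(series: MarkerFrameSeries, spec: FilterSpec | None = None) -> MarkerFrameSeries:
    """Apply :func:`lowpass_filter` to every gap-free marker coordinate."""
    out = series.copy()
    for name, arr in out.markers.items():
        if np.isnan(arr).any():
            raise FilterError(f"marker {name!r} still has unfilled gaps")
        out.markers[name] = lowpass_filter(arr, series.rate_hz, spec)
    return out


# ---------------------------------------------------------------------------
# Gait events
# ---------------------------------------------------------------------------


def detect_gait_events(
    series: MarkerFrameSeries,
    foot_markers: dict[str, str] | None = None,
    pelvis_marker: str = "pelvis",
    min_step_interval_s: float = 0.35,
    min_prominence_m: float = 0.05,
) -> GaitEventTable:
    """Coordinate-based gait event detection from marker data alone.

    Heel-strikes are maxima and toe-offs minima of the foot marker's fore-aft
    (AP) position relative to the pelvis, signed by the instantaneous walking
    direction so back-and-forth trials are handled uniformly.
    """
    foot_markers = foot_markers or {"left": "l_foot", "right": "r_foot"}
    if pelvis_marker not in series.markers:
        raise EventDetectionError(f"pelvis marker {pelvis_marker!r} not present")
    pelvis_ap = series.markers[pelvis_marker][:, _AX["AP"]]
    # walking direction from a heavily smoothed pelvis AP velocity
    vel = np.gradient(pelvis_ap) * series.rate_hz
    win = max(int(series.rate_hz), 1)
    kernel = np.ones(win) / win
    vel_smooth = np.convolve(vel, kernel, mode="same")
    direction = np.sign(vel_smooth)
    direction[direction == 0] = 1.0
    if np.max(np.abs(vel_smooth)) < 0.05:  # stationary subject: < 5 cm/s everywhere
        return GaitEventTable({limb: {"TO": [], "HS": []} for limb in foot_markers})

    distance = max(int(min_step_interval_s * series.rate_hz), 1)
    events: dict[str, dict[str, np.ndarray]] = {}
    for limb, marker in foot_markers.items():
        if marker not in series.markers:
            raise EventDetectionError(f"foot marker {marker!r} not present")
        rel = (series.markers[marker][:, _AX["AP"]] - pelvis_ap) * direction
        hs, _ = find_peaks(rel, distance=distance, prominence=min_prominence_m)
        to, _ = find_peaks(-rel, distance=distance, prominence=min_prominence_m)
        merged = sorted([(int(f), "HS") for f in hs] + [(int(f), "TO") for f in to])
        # enforce alternation: of two consecutive same-label events keep the
        # more extreme one
        kept: list[tuple[int, str]] = []
        for frame, label in merged:
            if kept and kept[-1][1] == label:
                prev = kept[-1][0]
                better = rel[frame] > rel[prev] if label == "HS" else rel[frame] < rel[prev]
                if better:
                    kept[-1] = (frame, label)
            else:
                kept.append((frame, label))
        events[limb] = {
            "TO": np.array([f for f, lab in kept if lab == "TO"], dtype=int),
            "HS": np.array([f for f, lab in kept if lab == "HS"], dtype=int),
        }
    if all(e["TO"].size == 0 and e["HS"].size == 0 for e in events.values()):
        raise EventDetectionError("no gait events detectable in trial")
    return GaitEventTable(events)


# ---------------------------------------------------------------------------
# Segment angles
# ---------------------------------------------------------------------------


def compute_segment_angles(
    series: MarkerFrameSeries, chain_markers: tuple[str, ...] = CHAIN_MARKERS
) -> np.ndarray:
    """Frontal-plane traversal angles of the 7 chain segments, shape (T, 7).

    For each segment the endpoint-to-endpoint traversal vector (stance foot
    toward swing foot) is projected onto the ML-vertical plane and its angle
    from the lab vertical taken as atan2(ML, UP); positive rotation tips the
    vector toward +ML.  Series are unwrapped over time and re-anchored so the
    starting value lies in (-pi, pi].
    """
    if len(chain_markers) != N_ANGLES + 1:
        raise ValueError(f"need {N_ANGLES + 1} chain markers, got {len(chain_markers)}")
    missing = [m for m in chain_markers if m not in series.markers]
    if missing:
        raise ValueError(f"chain markers missing from series: {missing}")
    pts = np.stack([series.markers[m] for m in chain_markers], axis=1)  # (T, 8, 3)
    vec = np.diff(pts, axis=1)  # (T, 7, 3)
    ml, up = vec[:, :, _AX["ML"]], vec[:, :, _AX["UP"]]
    norm = np.hypot(ml, up)
    if np.any(norm < 1e-9):
        t, i = np.argwhere(norm < 1e-9)[0]
        raise DegenerateSegmentError(
            f"segment {i} has coincident endpoints in the frontal plane at frame {t}"
        )
    phi = np.unwrap(np.arctan2(ml, up), axis=0)
    # offset removal: put the starting value of each series in (-pi, pi]
    shift = 2 * np.pi * np.ceil((phi[0] - np.pi) / (2 * np.pi))
    return phi - shift[None, :]


def chain_from_markers(
    series: MarkerFrameSeries, chain_markers: tuple[str, ...] = CHAIN_MARKERS
) -> SegmentChain:
    """Per-subject segment lengths: mean frontal-plane endpoint distances."""
    pts = np.stack([series.markers[m] for m in chain_markers], axis=1)
    vec = np.diff(pts, axis=1)
    lengths = np.hypot(vec[:, :, _AX["ML"]], vec[:, :, _AX["UP"]])
    return SegmentChain(np.nanmean(lengths, axis=0))


# ---------------------------------------------------------------------------
# Swing extraction and time normalization
# ---------------------------------------------------------------------------


def extract_swing_cycles(
    angles: np.ndarray, events: GaitEventTable, limb: str = "left"
) -> list[np.ndarray]:
    """Cut the per-frame angle series into toe-off..heel-strike segments."""
    pairs = events.swing_pairs(limb)
    if not pairs:
        raise SwingExtractionError(f"no toe-off/heel-strike pair for limb {limb!r}")
    for (_, hs0), (to1, _) in zip(pairs, pairs[1:]):
        if to1 < hs0:
            raise SwingExtractionError("overlapping swing pairs")
    return [np.asarray(angles[to : hs + 1]) for to, hs in pairs]


def time_normalize(segment: np.ndarray, n_points: int = 101) -> np.ndarray:
    """Cubic resample of one swing onto equally spaced 0..100% samples.

    Endpoints are preserved exactly; interior samples come from a cubic
    spline over the segment's own frames.
    """
    segment = np.asarray(segment, dtype=float)
    if segment.shape[0] < 4:
        raise SwingExtractionError(
            f"swing segment of {segment.shape[0]} frames is too short to resample (need >= 4)"
        )
    old = np.linspace(0.0, 100.0, segment.shape[0])
    new = np.linspace(0.0, 100.0, n_points)
    out = CubicSpline(old, segment, axis=0)(new)
    out[0], out[-1] = segment[0], segment[-1]
    return out


# ---------------------------------------------------------------------------
# Gait speed
# ---------------------------------------------------------------------------


def compute_gait_speed(
    series: MarkerFrameSeries,
    volume_length: float = 5.0,
    pelvis_marker: str = "pelvis",
    volume_start: float = 0.0,
) -> float:
    """Mean speed (m/s) over complete passes through the capture volume.

    A pass is a traversal of the pelvis marker's AP coordinate from one
    volume boundary to the other (either direction); crossing times are
    linearly interpolated between frames.
    """
    if pelvis_marker not in series.markers:
        raise NoPassError(f"pelvis marker {pelvis_marker!r} not present")
    ap = series.markers[pelvis_marker][:, _AX["AP"]]
    lo, hi = volume_start, volume_start + volume_length
    crossings: list[tuple[float, str]] = []
    for bound, label in ((lo, "lo"), (hi, "hi")):
        s = ap - bound
        idx = np.flatnonzero(((s[:-1] <= 0) & (s[1:] > 0)) | ((s[:-1] >= 0) & (s[1:] < 0)))
        for i in idx:
            frac = s[i] / (s[i] - s[i + 1])
            crossings.append((i + frac, label))
    crossings.sort()
    speeds = []
    for (t0, b0), (t1, b1) in zip(crossings, crossings[1:]):
        if b0 != b1:
            speeds.append(volume_length / ((t1 - t0) / series.rate_hz))
    if not speeds:
        raise NoPassError("no complete pass through the capture volume")
    return float(np.mean(speeds))


def swing_inside_volume(
    series: MarkerFrameSeries,
    pair: tuple[int, int],
    foot_marker: str = "l_foot",
    volume_length: float = 5.0,
    volume_start: float = 0.0,
) -> bool:
    """True if the whole swing lies inside the capture volume (turn exclusion)."""
    ap = series.markers[foot_marker][pair[0] : pair[1] + 1, _AX["AP"]]
    return bool(np.all((ap >= volume_start) & (ap <= volume_start + volume_length)))
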