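"""Synthetic gaze recordings with the statistical structure the analysis assumes.

The generator reproduces the fixation-grid protocol (a 4 x 8 outer grid plus
a 3 x 7 inner grid of targets shown 1500 ms each), human-like gaze signals
(white measurement noise + random-walk drift + microsaccadic steps), static
artificial-eye signals (pure noise), optional recording-side low-pass
filtering, and Gaussian software-timestamp jitter.  Every stochastic
component draws from an independent stream spawned from one root seed, so a
given (config, seed) pair yields bit-identical recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np

from .config import FilterSpec, SimulationConfig
from .errors import DomainError, InvalidConfigError
from .geometry import cm_to_deg, fick_from_vector, vector_from_fick

__all__ = [
    "TargetPoint",
    "Presentation",
    "SessionProtocol",
    "GazeRecording",
    "build_target_grid",
    "build_presentation_sequence",
    "simulate_human_recording",
    "simulate_artificial_eye",
    "simulate_gaze_vectors",
    "apply_recording_filter",
]

GRID_SPAN_W_CM = 45.5
GRID_SPAN_H_CM = 26.8
VIEWING_DISTANCE_CM = 65.0
DURATION_PER_POINT_MS = 1500.0


@dataclass(frozen=True)
class TargetPoint:
    """One fixation target, in cm on screen and degrees of visual angle."""

    grid_id: int
    x_cm: float
    y_cm: float
    x_deg: float
    y_deg: float


@dataclass(frozen=True)
class Presentation:
    """One timed showing of a target."""

    target: TargetPoint
    onset_ms: float
    offset_ms: float


@dataclass(frozen=True)
class SessionProtocol:
    """Ordered target presentations for one recording session."""

    presentations: tuple
    duration_per_point_ms: float = DURATION_PER_POINT_MS
    includes_initial_center: bool = True

    def __len__(self) -> int:
        return len(self.presentations)

    @property
    def total_duration_ms(self) -> float:
        return self.presentations[-1].offset_ms if self.presentations else 0.0


@dataclass
class GazeRecording:
    """A timestamped single-eye gaze trace.

    ``timestamps_ms`` are the *reported* times (possibly jittered); sample
    values always sit on the nominal sampling comb of ``fs_hz``.
    """

    timestamps_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    fs_hz: float
    gaze_vector: Optional[np.ndarray] = None  # (n, 3) unit directions
    pupil: Optional[np.ndarray] = None
    valid: Optional[np.ndarray] = None
    eye: str = "synthetic"
    source: str = "synthetic"  # human | artificial | synthetic

    def __post_init__(self):
        self.timestamps_ms = np.asarray(self.timestamps_ms, dtype=float)
        self.x_deg = np.asarray(self.x_deg, dtype=float)
        self.y_deg = np.asarray(self.y_deg, dtype=float)
        n = len(self.timestamps_ms)
        if self.valid is None:
            self.valid = np.ones(n, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        for name in ("x_deg", "y_deg", "valid"):
            if len(getattr(self, name)) != n:
                raise DomainError(f"channel {name} length differs from timestamps")
        if self.gaze_vector is not None:
            self.gaze_vector = np.asarray(self.gaze_vector, dtype=float)
            if self.gaze_vector.shape != (n, 3):
                raise DomainError("gaze_vector must have shape (n, 3)")
        if self.pupil is not None and len(self.pupil) != n:
            raise DomainError("pupil channel length differs from timestamps")
        if n > 1 and not np.all(np.diff(self.timestamps_ms) > 0):
            raise DomainError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.timestamps_ms)

    @property
    def duration_ms(self) -> float:
        return len(self) / self.fs_hz * 1000.0


# ---------------------------------------------------------------------------
# Stimulus protocol
# ---------------------------------------------------------------------------

def build_target_grid(
    span_w_cm: float = GRID_SPAN_W_CM,
    span_h_cm: float = GRID_SPAN_H_CM,
    viewing_distance_cm: float = VIEWING_DISTANCE_CM,
) -> List[TargetPoint]:
    """The 53-point fixation grid: a 4 x 8 outer grid spanning the given
    width/height, plus a 3 x 7 inner grid at the centers of the outer cells.

    Ordering is deterministic: outer grid first, row-major from top-left,
    then the inner grid in the same order.  Coordinates are relative to the
    screen center, x rightward and y upward.
    """
    if span_w_cm <= 0 or span_h_cm <= 0:
        raise InvalidConfigError("grid spans must be positive")
    if viewing_distance_cm <= 0:
        raise InvalidConfigError("viewing_distance_cm must be positive")

    xs_outer = np.linspace(-span_w_cm / 2, span_w_cm / 2, 8)
    ys_outer = np.linspace(span_h_cm / 2, -span_h_cm / 2, 4)
    xs_inner = (xs_outer[:-1] + xs_outer[1:]) / 2
    ys_inner = (ys_outer[:-1] + ys_outer[1:]) / 2

    points: List[TargetPoint] = []

    def add(x_cm: float, y_cm: float) -> None:
        points.append(
            TargetPoint(
                grid_id=len(points),
                x_cm=float(x_cm),
                y_cm=float(y_cm),
                x_deg=float(cm_to_deg(x_cm, viewing_distance_cm)),
                y_deg=float(cm_to_deg(y_cm, viewing_distance_cm)),
            )
        )

    for y in ys_outer:
        for x in xs_outer:
            add(x, y)
    for y in ys_inner:
        for x in xs_inner:
            add(x, y)
    return points


def center_target(targets: Sequence[TargetPoint]) -> TargetPoint:
    """The target closest to the screen center (exactly central for the
    default grid, where the middle inner point sits at (0, 0))."""
    return min(targets, key=lambda t: (t.x_cm ** 2 + t.y_cm ** 2, t.grid_id))


def build_presentation_sequence(
    targets: Sequence[TargetPoint],
    repeats: int = 4,
    seed: Optional[int] = None,
    duration_per_point_ms: float = DURATION_PER_POINT_MS,
    include_initial_center: bool = True,
) -> SessionProtocol:
    """Randomized presentation order: an initial central fixation followed by
    a seeded permutation containing each target ``repeats`` times (213
    presentations in total for the default 53-target grid)."""
    if repeats < 1:
        raise InvalidConfigError("repeats must be >= 1")
    rng = np.random.default_rng(seed)
    order = np.repeat(np.arange(len(targets)), repeats)
    order = rng.permutation(order)
    sequence: List[TargetPoint] = []
    if include_initial_center:
        sequence.append(center_target(targets))
    sequence.extend(targets[i] for i in order)

    presentations = tuple(
        Presentation(
            target=t,
            onset_ms=i * duration_per_point_ms,
            offset_ms=(i + 1) * duration_per_point_ms,
        )
        for i, t in enumerate(sequence)
    )
    return SessionProtocol(
        presentations=presentations,
        duration_per_point_ms=duration_per_point_ms,
        includes_initial_center=include_initial_center,
    )


# ---------------------------------------------------------------------------
# Signal generation
# ---------------------------------------------------------------------------

def apply_recording_filter(series, filter_spec: Optional[FilterSpec]):
    """Apply the configured causal unit-DC-gain low-pass filter.

    Output length equals input length; moving-average startup is handled by
    holding the first sample.  ``kind='none'`` (or None) is the identity.
    """
    x = np.asarray(series, dtype=float)
    if filter_spec is None or filter_spec.kind == "none":
        return x.copy()
    filter_spec.validate()
    if filter_spec.kind == "moving_average":
        m = filter_spec.order
        if len(x) == 0:
            return x.copy()
        padded = np.concatenate([np.full(m - 1, x[0]), x])
        kernel = np.full(m, 1.0 / m)
        return np.convolve(padded, kernel, mode="valid")
    if filter_spec.kind == "exponential":
        from scipy.signal import lfilter, lfiltic

        a = filter_spec.smoothing
        if len(x) == 0:
            return x.copy()
        # y[n] = a x[n] + (1-a) y[n-1], initialized at y[-1] = x[0]
        zi = lfiltic([a], [1.0, -(1.0 - a)], y=[x[0]])
        y, _ = lfilter([a], [1.0, -(1.0 - a)], x, zi=zi)
        return y
    raise InvalidConfigError(f"unknown filter kind {filter_spec.kind!r}")


def _spawn_streams(seed: int, n: int = 5):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _jittered_timestamps(n: int, fs_hz: float, jitter_pct: float, rng) -> np.ndarray:
    """Nominal sampling comb with Gaussian timestamp noise.

    ``jitter_pct`` parameterizes the resulting inter-sample-interval
    variability, SD(ISI) as % of the nominal ISI — the statistic trackers
    report.  Independent per-timestamp noise doubles in variance when
    differenced, hence the sqrt(2) factor.
    """
    nominal_isi = 1000.0 / fs_hz
    t = np.arange(n) * nominal_isi
    if jitter_pct > 0:
        sd = jitter_pct / 100.0 * nominal_isi / np.sqrt(2.0)
        t = np.sort(t + rng.normal(0.0, sd, n))
    return t


def _drift_and_saccades(n: int, fs_hz: float, config: SimulationConfig,
                        drift_rng, sacc_rng):
    """Random-walk drift plus Poisson-timed persistent step displacements for
    one fixation epoch of n samples (both channels)."""
    dx = np.zeros(n)
    dy = np.zeros(n)
    if config.drift_step_sd_deg > 0:
        dx += np.cumsum(drift_rng.normal(0.0, config.drift_step_sd_deg, n))
        dy += np.cumsum(drift_rng.normal(0.0, config.drift_step_sd_deg, n))
    if config.microsaccade_rate_hz > 0 and config.microsaccade_amp_deg > 0:
        n_sacc = sacc_rng.poisson(config.microsaccade_rate_hz * n / fs_hz)
        for _ in range(n_sacc):
            idx = int(sacc_rng.integers(0, n))
            angle = sacc_rng.uniform(0.0, 2.0 * np.pi)
            dx[idx:] += config.microsaccade_amp_deg * np.cos(angle)
            dy[idx:] += config.microsaccade_amp_deg * np.sin(angle)
    return dx, dy


def simulate_human_recording(
    protocol: SessionProtocol, config: SimulationConfig, eye: str = "synthetic"
) -> GazeRecording:
    """Simulate one eye following the fixation protocol.

    Per presentation the gaze signal is target position + random-walk drift
    (restarted at each target jump) + microsaccadic steps; i.i.d. noise and
    the optional pupil-driven slow deviation are added over the whole trace,
    the recording filter is applied last, and timestamps get Gaussian jitter.
    """
    config.validate()
    if len(protocol) == 0:
        raise InvalidConfigError("protocol has no presentations")
    noise_rng, drift_rng, sacc_rng, jitter_rng, pupil_rng = _spawn_streams(config.seed)

    xs, ys = [], []
    for pres in protocol.presentations:
        n = int(round((pres.offset_ms - pres.onset_ms) * config.fs_hz / 1000.0))
        dx, dy = _drift_and_saccades(n, config.fs_hz, config, drift_rng, sacc_rng)
        xs.append(pres.target.x_deg + dx)
        ys.append(pres.target.y_deg + dy)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    n_total = len(x)

    if config.noise_sd_deg > 0:
        x = x + noise_rng.normal(0.0, config.noise_sd_deg, n_total)
        y = y + noise_rng.normal(0.0, config.noise_sd_deg, n_total)

    pupil = None
    if config.pupil_artifact is not None:
        t_s = np.arange(n_total) / config.fs_hz
        pa = config.pupil_artifact
        phx = pupil_rng.uniform(0.0, 2.0 * np.pi)
        phy = pupil_rng.uniform(0.0, 2.0 * np.pi)
        x = x + pa.amplitude_deg * np.sin(2 * np.pi * pa.freq_hz * t_s + phx)
        y = y + pa.amplitude_deg * np.sin(2 * np.pi * pa.freq_hz * t_s + phy)
        pupil = 3.0 + np.sin(2 * np.pi * pa.freq_hz * t_s + phx)

    x = apply_recording_filter(x, config.filter_spec)
    y = apply_recording_filter(y, config.filter_spec)
    t = _jittered_timestamps(n_total, config.fs_hz, config.isi_jitter_pct, jitter_rng)

    return GazeRecording(
        timestamps_ms=t, x_deg=x, y_deg=y, fs_hz=config.fs_hz,
        pupil=pupil, eye=eye, source="human",
    )


def simulate_artificial_eye(
    config: SimulationConfig, duration_ms: float = 19000.0, eye: str = "synthetic"
) -> GazeRecording:
    """Simulate a static artificial-eye recording: pure i.i.d. measurement
    noise about a fixed position, optionally filtered.

    A static eye cannot rotate, so any nonzero drift or microsaccade
    parameter is a configuration error.
    """
    config.validate()
    for name in ("drift_step_sd_deg", "microsaccade_rate_hz", "microsaccade_amp_deg"):
        if getattr(config, name) != 0:
            raise InvalidConfigError(
                f"artificial-eye simulation requires {name} == 0 (got {getattr(config, name)})"
            )
    noise_rng, _, _, jitter_rng, _ = _spawn_streams(config.seed)
    n = int(round(duration_ms * config.fs_hz / 1000.0))
    x = noise_rng.normal(0.0, config.noise_sd_deg, n)
    y = noise_rng.normal(0.0, config.noise_sd_deg, n)
    x = apply_recording_filter(x, config.filter_spec)
    y = apply_recording_filter(y, config.filter_spec)
    t = _jittered_timestamps(n, config.fs_hz, config.isi_jitter_pct, jitter_rng)
    return GazeRecording(
        timestamps_ms=t, x_deg=x, y_deg=y, fs_hz=config.fs_hz,
        eye=eye, source="artificial",
    )


def simulate_gaze_vectors(recording: GazeRecording, viewing_distance_cm: float = VIEWING_DISTANCE_CM) -> GazeRecording:
    """Fill in unit gaze-direction vectors consistent with the angular trace.

    The Fick decomposition of the returned vectors reproduces x_deg / y_deg,
    providing the unfiltered-pathway input used to test the geometry route.
    """
    vec = vector_from_fick(recording.x_deg, recording.y_deg)
    return replace(recording, gaze_vector=vec)
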