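"""Analysis-window selection.

For human data, one 200-ms window is picked per fixation-point presentation:
candidate windows slide (one sample at a time) over the segment from 200 ms
after target onset to target offset, the half with the largest dispersion

    sqrt((max x - min x)^2 + (max y - min y)^2)

is discarded (these likely contain a microsaccade), and of the survivors the
window whose mean gaze position lies closest to the target is selected.  The
procedure deliberately uses no fixation classifier and no stability measure
beyond the dispersion screen, so it does not bias the spectrum of the
selected samples.

Artificial-eye recordings contain no eye movement to avoid, so fixed 200-ms
windows at 50-ms steps across the whole recording are used instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DomainError
from .synthetic import GazeRecording, SessionProtocol, TargetPoint

__all__ = [
    "TrialSegment",
    "CandidateWindow",
    "SelectedWindow",
    "window_length_samples",
    "segment_trials",
    "dispersion",
    "slide_candidates",
    "filter_by_dispersion",
    "select_window",
    "select_trial_window",
    "artificial_eye_windows",
]

WINDOW_MS = 200.0
START_OFFSET_MS = 200.0
ARTIFICIAL_STEP_MS = 50.0


def window_length_samples(fs_hz: float, window_ms: float = WINDOW_MS) -> int:
    """Closest realizable window length in samples (12 at 60 Hz for 200 ms)."""
    return int(round(window_ms * fs_hz / 1000.0))


@dataclass(frozen=True)
class TrialSegment:
    """Samples of one eye during one fixation-point presentation."""

    trial_id: int
    target: TargetPoint
    onset_ms: float
    offset_ms: float
    timestamps_ms: np.ndarray
    x_deg: np.ndarray
    y_deg: np.ndarray
    valid: np.ndarray
    fs_hz: float

    def __len__(self) -> int:
        return len(self.timestamps_ms)


@dataclass(frozen=True)
class CandidateWindow:
    """A 200-ms candidate window with its dispersion and mean position."""

    start_index: int
    n_samples: int
    x: np.ndarray
    y: np.ndarray
    dispersion_deg: float
    mean_x_deg: float
    mean_y_deg: float
    distance_to_target_deg: Optional[float] = None
    start_ms: float = 0.0


@dataclass(frozen=True)
class SelectedWindow:
    """The single window retained for one trial."""

    window: CandidateWindow
    trial_id: int
    eye: str = "unknown"


def segment_trials(recording: GazeRecording, protocol: SessionProtocol) -> List[TrialSegment]:
    """Split a recording into per-presentation segments.

    Samples are assigned by nominal sample index (timestamp jitter never
    moves a sample across a trial boundary in the tracker's own bookkeeping).
    """
    segments = []
    for i, pres in enumerate(protocol.presentations):
        lo = int(round(pres.onset_ms * recording.fs_hz / 1000.0))
        hi = int(round(pres.offset_ms * recording.fs_hz / 1000.0))
        hi = min(hi, len(recording))
        if hi <= lo:
            continue
        sl = slice(lo, hi)
        segments.append(
            TrialSegment(
                trial_id=i,
                target=pres.target,
                onset_ms=pres.onset_ms,
                offset_ms=pres.offset_ms,
                timestamps_ms=recording.timestamps_ms[sl],
                x_deg=recording.x_deg[sl],
                y_deg=recording.y_deg[sl],
                valid=recording.valid[sl],
                fs_hz=recording.fs_hz,
            )
        )
    return segments


def dispersion(x, y) -> float:
    """Window spread: sqrt((max x - min x)^2 + (max y - min y)^2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DomainError("dispersion of an empty window is undefined")
    return float(np.hypot(np.max(x) - np.min(x), np.max(y) - np.min(y)))


def slide_candidates(
    segment: TrialSegment,
    window_ms: float = WINDOW_MS,
    start_offset_ms: float = START_OFFSET_MS,
    step_samples: int = 1,
) -> List[CandidateWindow]:
    """All candidate windows of one trial.

    Windows start no earlier than ``start_offset_ms`` after target onset and
    lie fully inside the segment.  Windows touching any invalid sample are
    disqualified (the dispersion measure is undefined on gaps).  Returns an
    empty list when the segment cannot hold a single window.
    """
    win = window_length_samples(segment.fs_hz, window_ms)
    skip = int(round(start_offset_ms * segment.fs_hz / 1000.0))
    n = len(segment)
    if n - skip < win or win < 1:
        return []

    x = segment.x_deg[skip:]
    y = segment.y_deg[skip:]
    v = segment.valid[skip:]
    xv = sliding_window_view(x, win)[::step_samples]
    yv = sliding_window_view(y, win)[::step_samples]
    vv = sliding_window_view(v, win)[::step_samples]

    disp = np.hypot(xv.max(axis=1) - xv.min(axis=1), yv.max(axis=1) - yv.min(axis=1))
    mx = xv.mean(axis=1)
    my = yv.mean(axis=1)
    ok = vv.all(axis=1)
    tx, ty = segment.target.x_deg, segment.target.y_deg
    dist = np.hypot(mx - tx, my - ty)

    out: List[CandidateWindow] = []
    for j in np.nonzero(ok)[0]:
        start = skip + j * step_samples
        out.append(
            CandidateWindow(
                start_index=int(start),
                n_samples=win,
                x=segment.x_deg[start:start + win],
                y=segment.y_deg[start:start + win],
                dispersion_deg=float(disp[j]),
                mean_x_deg=float(mx[j]),
                mean_y_deg=float(my[j]),
                distance_to_target_deg=float(dist[j]),
                start_ms=segment.onset_ms + start * 1000.0 / segment.fs_hz,
            )
        )
    return out


def filter_by_dispersion(candidates: Sequence[CandidateWindow]) -> List[CandidateWindow]:
    """Drop the 50% of candidates with the largest dispersion.

    ceil(N/2) windows are retained; ties at the cut keep the earlier start.
    The result is returned in start-index order.
    """
    if len(candidates) == 0:
        raise DomainError("no candidate windows to screen")
    keep = (len(candidates) + 1) // 2
    ranked = sorted(candidates, key=lambda c: (c.dispersion_deg, c.start_index))
    kept = ranked[:keep]
    return sorted(kept, key=lambda c: c.start_index)


def select_window(
    candidates: Sequence[CandidateWindow], target: TargetPoint,
    trial_id: int = -1, eye: str = "unknown",
) -> SelectedWindow:
    """Of the dispersion-screened candidates, pick the one whose mean gaze
    position is closest to the target (ties: earlier start)."""
    if len(candidates) == 0:
        raise DomainError("no surviving candidate windows to select from")
    best = min(
        candidates,
        key=lambda c: (
            np.hypot(c.mean_x_deg - target.x_deg, c.mean_y_deg - target.y_deg),
            c.start_index,
        ),
    )
    return SelectedWindow(window=best, trial_id=trial_id, eye=eye)


def select_trial_window(
    segment: TrialSegment,
    window_ms: float = WINDOW_MS,
    start_offset_ms: float = START_OFFSET_MS,
    step_samples: int = 1,
    eye: str = "unknown",
) -> Optional[SelectedWindow]:
    """Full per-trial procedure: slide, dispersion-screen, select.

    Returns None when the trial holds no admissible window (trial excluded).
    """
    cands = slide_candidates(segment, window_ms, start_offset_ms, step_samples)
    if not cands:
        return None
    survivors = filter_by_dispersion(cands)
    return select_window(survivors, segment.target, trial_id=segment.trial_id, eye=eye)


def artificial_eye_windows(
    recording: GazeRecording,
    window_ms: float = WINDOW_MS,
    step_ms: float = ARTIFICIAL_STEP_MS,
) -> List[CandidateWindow]:
    """Fixed windows at 50-ms steps across the whole recording; no screening
    (a static eye produces nothing that needs avoiding)."""
    win = window_length_samples(recording.fs_hz, window_ms)
    n = len(recording)
    if win < 1 or n < win:
        return []
    step = step_ms * recording.fs_hz / 1000.0
    out: List[CandidateWindow] = []
    k = 0
    while True:
        # fractional steps round up: a window may not start before its slot
        start = int(np.ceil(k * step - 1e-9))
        if start + win > n:
            break
        x = recording.x_deg[start:start + win]
        y = recording.y_deg[start:start + win]
        out.append(
            CandidateWindow(
                start_index=start,
                n_samples=win,
                x=x,
                y=y,
                dispersion_deg=dispersion(x, y),
                mean_x_deg=float(np.mean(x)),
                mean_y_deg=float(np.mean(y)),
                start_ms=start * 1000.0 / recording.fs_hz,
            )
        )
        k += 1
    return out
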