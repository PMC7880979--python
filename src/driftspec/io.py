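"""CSV / YAML dialects for recordings, protocols, windows, spectra and fits.

Gaze CSV (one file per eye per session):
    time_ms, eye, x_deg, y_deg, gvec_x, gvec_y, gvec_z, pupil, valid
Protocol CSV:
    presentation_index, grid_id, x_deg, y_deg, onset_ms, offset_ms
Configs round-trip through YAML via SimulationConfig.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .geometry import deg_to_cm
from .pipeline import EyeResult
from .spectra import SlopeFit, Spectrum, amplitude_from_power
from .synthetic import (
    VIEWING_DISTANCE_CM,
    GazeRecording,
    Presentation,
    SessionProtocol,
    TargetPoint,
)
from .windowing import SelectedWindow

GAZE_COLUMNS = [
    "time_ms", "eye", "x_deg", "y_deg",
    "gvec_x", "gvec_y", "gvec_z", "pupil", "valid",
]


def write_gaze_csv(recording: GazeRecording, path) -> None:
    n = len(recording)
    vec = recording.gaze_vector
    df = pd.DataFrame(
        {
            "time_ms": recording.timestamps_ms,
            "eye": recording.eye,
            "x_deg": recording.x_deg,
            "y_deg": recording.y_deg,
            "gvec_x": vec[:, 0] if vec is not None else np.full(n, np.nan),
            "gvec_y": vec[:, 1] if vec is not None else np.full(n, np.nan),
            "gvec_z": vec[:, 2] if vec is not None else np.full(n, np.nan),
            "pupil": recording.pupil if recording.pupil is not None else np.full(n, np.nan),
            "valid": recording.valid.astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_gaze_csv(path, fs_hz: Optional[float] = None, source: str = "synthetic") -> GazeRecording:
    df = pd.read_csv(path)
    missing = set(GAZE_COLUMNS) - set(df.columns)
    if missing:
        raise DomainError(f"gaze CSV missing columns: {sorted(missing)}")
    if fs_hz is None:
        isi = np.median(np.diff(df["time_ms"].to_numpy()))
        fs_hz = 1000.0 / isi
    vec = df[["gvec_x", "gvec_y", "gvec_z"]].to_numpy()
    if np.all(np.isnan(vec)):
        vec = None
    pupil = df["pupil"].to_numpy()
    if np.all(np.isnan(pupil)):
        pupil = None
    eye = str(df["eye"].iloc[0]) if len(df) else "unknown"
    return GazeRecording(
        timestamps_ms=df["time_ms"].to_numpy(),
        x_deg=df["x_deg"].to_numpy(),
        y_deg=df["y_deg"].to_numpy(),
        fs_hz=float(fs_hz),
        gaze_vector=vec,
        pupil=pupil,
        valid=df["valid"].to_numpy().astype(bool),
        eye=eye,
        source=source,
    )


def write_protocol_csv(protocol: SessionProtocol, path) -> None:
    rows = [
        {
            "presentation_index": i,
            "grid_id": p.target.grid_id,
            "x_deg": p.target.x_deg,
            "y_deg": p.target.y_deg,
            "onset_ms": p.onset_ms,
            "offset_ms": p.offset_ms,
        }
        for i, p in enumerate(protocol.presentations)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_protocol_csv(path, viewing_distance_cm: float = VIEWING_DISTANCE_CM) -> SessionProtocol:
    df = pd.read_csv(path)
    presentations = []
    for _, row in df.iterrows():
        t = TargetPoint(
            grid_id=int(row["grid_id"]),
            x_cm=float(deg_to_cm(row["x_deg"], viewing_distance_cm)),
            y_cm=float(deg_to_cm(row["y_deg"], viewing_distance_cm)),
            x_deg=float(row["x_deg"]),
            y_deg=float(row["y_deg"]),
        )
        presentations.append(
            Presentation(target=t, onset_ms=float(row["onset_ms"]),
                         offset_ms=float(row["offset_ms"]))
        )
    dur = presentations[0].offset_ms - presentations[0].onset_ms if presentations else 0.0
    return SessionProtocol(presentations=tuple(presentations), duration_per_point_ms=dur)


def write_windows_csv(windows: Sequence[SelectedWindow], path) -> None:
    rows = [
        {
            "trial_id": w.trial_id,
            "eye": w.eye,
            "start_ms": w.window.start_ms,
            "n_samples": w.window.n_samples,
            "dispersion_deg": w.window.dispersion_deg,
            "mean_x_deg": w.window.mean_x_deg,
            "mean_y_deg": w.window.mean_y_deg,
            "distance_to_target_deg": w.window.distance_to_target_deg,
        }
        for w in windows
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_spectra_csv(spectra: Sequence[Spectrum], path, eye: str = "unknown") -> None:
    frames = []
    for s in spectra:
        amp = amplitude_from_power(s).power if s.kind == "power" else s.power
        frames.append(
            pd.DataFrame(
                {
                    "freq_hz": s.freqs_hz,
                    "power": s.power if s.kind == "power" else s.power ** 2,
                    "amplitude": amp,
                    "estimator": s.estimator,
                    "channel": s.channel,
                    "eye": eye,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_slopes_csv(fits: Sequence[SlopeFit], path, eye: str = "unknown",
                     n_windows: int = 0) -> None:
    rows = [
        {
            "eye": eye,
            "channel": f.channel,
            "band": f"{f.f_lo_hz:g}-{f.f_hi_hz:g}Hz",
            "alpha": f.alpha,
            "r_squared": f.r_squared,
            "n_windows": n_windows,
        }
        for f in fits
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
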