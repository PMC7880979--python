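"""Simulation configuration: recording-side filters and signal parameters.

The generator models a gaze recording as the sum of three processes expressed
in degrees of visual angle:

* i.i.d. Gaussian measurement noise (``noise_sd_deg``) — the white component
  every video-based tracker produces;
* ocular drift as a random walk, i.e. the cumulative sum of i.i.d. Gaussian
  increments (``drift_step_sd_deg`` per sample), restarting at each fixation
  target;
* microsaccades as Poisson-timed instantaneous step displacements
  (``microsaccade_rate_hz``, ``microsaccade_amp_deg``).

An optional causal low-pass filter stands in for the unpublished vendor
smoothing ("heuristic") filters, and Gaussian timestamp jitter emulates
software-timestamp noise: reported times move, sample values stay on the
nominal sampling comb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import yaml

from .errors import InvalidConfigError

__all__ = ["FilterSpec", "PupilArtifact", "SimulationConfig"]

_FILTER_KINDS = ("none", "moving_average", "exponential")


@dataclass(frozen=True)
class FilterSpec:
    """A causal unit-DC-gain low-pass filter applied to the gaze trace.

    ``moving_average`` uses ``order`` taps (startup handled by holding the
    first sample); ``exponential`` is the first-order recursion
    ``y[n] = smoothing * x[n] + (1 - smoothing) * y[n-1]``.  Both pass a
    constant input through unchanged.
    """

    kind: str = "none"
    order: int = 8
    smoothing: float = 0.25

    def validate(self) -> None:
        if self.kind not in _FILTER_KINDS:
            raise InvalidConfigError(
                f"unknown filter kind {self.kind!r}; expected one of {_FILTER_KINDS}"
            )
        if self.kind == "moving_average" and self.order < 1:
            raise InvalidConfigError("moving_average filter needs order >= 1")
        if self.kind == "exponential" and not 0.0 < self.smoothing <= 1.0:
            raise InvalidConfigError("exponential smoothing constant must be in (0, 1]")


@dataclass(frozen=True)
class PupilArtifact:
    """Slow sinusoidal gaze-position deviation driven by pupil-size change."""

    amplitude_deg: float = 0.1
    freq_hz: float = 0.2

    def validate(self) -> None:
        if self.amplitude_deg < 0 or self.freq_hz <= 0:
            raise InvalidConfigError("pupil artifact needs amplitude >= 0 and freq > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated recording session (one eye).

    Defaults describe a low-noise 1000-Hz research tracker recording a human
    eye: ~0.03 deg RMS white noise, drift covering ~0.1 deg within a 200-ms
    window, 1.5 microsaccades/s of 0.3 deg.
    """

    fs_hz: float = 1000.0
    duration_ms: float = 19000.0
    noise_sd_deg: float = 0.03
    drift_step_sd_deg: float = 0.008
    microsaccade_rate_hz: float = 1.5
    microsaccade_amp_deg: float = 0.3
    filter_spec: Optional[FilterSpec] = None
    isi_jitter_pct: float = 0.0
    pupil_artifact: Optional[PupilArtifact] = None
    seed: int = 0

    def validate(self) -> None:
        if self.fs_hz <= 0:
            raise InvalidConfigError("fs_hz must be positive")
        if self.duration_ms <= 0:
            raise InvalidConfigError("duration_ms must be positive")
        for name in ("noise_sd_deg", "drift_step_sd_deg", "microsaccade_rate_hz",
                     "microsaccade_amp_deg"):
            if getattr(self, name) < 0:
                raise InvalidConfigError(f"{name} must be >= 0")
        if not 0.0 <= self.isi_jitter_pct <= 15.0:
            raise InvalidConfigError("isi_jitter_pct must lie in [0, 15]")
        if self.filter_spec is not None:
            self.filter_spec.validate()
        if self.pupil_artifact is not None:
            self.pupil_artifact.validate()

    @classmethod
    def artificial_default(cls, **overrides) -> "SimulationConfig":
        """Artificial-eye condition: no eye rotation, noise at one third of
        the human level (static eyes image more cleanly than real ones)."""
        base = dict(
            noise_sd_deg=cls.noise_sd_deg / 3.0,
            drift_step_sd_deg=0.0,
            microsaccade_rate_hz=0.0,
            microsaccade_amp_deg=0.0,
            pupil_artifact=None,
        )
        base.update(overrides)
        return cls(**base)

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        if self.filter_spec is None:
            d["filter_spec"] = {"kind": "none"}
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        fspec = d.get("filter_spec")
        if fspec is not None and not isinstance(fspec, FilterSpec):
            fspec = FilterSpec(**fspec)
            if fspec.kind == "none":
                fspec = None
            d["filter_spec"] = fspec
        pup = d.get("pupil_artifact")
        if pup is not None and not isinstance(pup, PupilArtifact):
            d["pupil_artifact"] = PupilArtifact(**pup)
        cfg = cls(**d)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
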