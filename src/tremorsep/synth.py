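"""Synthetic hand-arm orientation recordings with known tremor/voluntary split.

The clinical recordings this package targets are not publicly deposited, so
every downstream stage is exercised on simulated channels that reproduce the
stated statistical structure: a voluntary component with spectral content
below 3 Hz, a tremulous component between 3 and 10 Hz, additive white sensor
noise, a linear drift, and occasional missing samples. Ground-truth
components are retained uncorrupted so decomposition quality is measurable.

Voluntary motion is a random superposition of 3-6 sub-3 Hz sinusoids; the
"drinking" activity additionally carries a slow reach-and-return trajectory
(four cycles per recording). Tremor is an amplitude- and frequency-modulated
tone whose carrier is drawn per subject from 3.5-9 Hz with a slow +/-0.3 Hz
wobble and 10-50% amplitude modulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .signal import OrientationSignal

ACTIVITIES = ("resting", "outstretching", "wing", "drinking")
BODY_PARTS = ("lower_arm", "upper_arm", "palm")
AXES = ("roll", "pitch", "yaw")

#: per-activity default amplitudes (degrees); free parameters of the
#: simulator, not calibrated to any clinic (no amplitude statistics exist
#: for the target recordings).
_ACTIVITY_DEFAULTS = {
    "resting": dict(voluntary_amplitude_deg=1.0, tremor_amplitude_deg=1.5),
    "outstretching": dict(voluntary_amplitude_deg=2.0, tremor_amplitude_deg=1.5),
    "wing": dict(voluntary_amplitude_deg=2.0, tremor_amplitude_deg=1.2),
    "drinking": dict(voluntary_amplitude_deg=15.0, tremor_amplitude_deg=2.0),
}


class ConfigurationError(ValueError):
    """Raised when a profile or generator argument is invalid."""


@dataclass(frozen=True)
class ActivityProfile:
    """Statistical description of one recorded activity.

    The three static postures last 10 s; drinking is configurable (>= 10 s)
    because its duration depends on completing four reach-and-return cycles.
    """

    name: str
    duration_s: float = 10.0
    voluntary_band_hz: tuple[float, float] = (0.0, 3.0)
    tremor_band_hz: tuple[float, float] = (3.0, 10.0)
    voluntary_amplitude_deg: float = 1.0
    tremor_amplitude_deg: float = 1.5
    noise_std_deg: float = 0.05
    drift_slope_deg_per_s: float = 0.1
    missing_fraction: float = 0.01
    fs: float = 100.0

    def __post_init__(self):
        if self.name not in ACTIVITIES:
            raise ConfigurationError(
                f"unknown activity {self.name!r}; expected one of {ACTIVITIES}"
            )
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.name == "drinking" and self.duration_s < 10.0:
            raise ConfigurationError("drinking duration must be >= 10 s")
        if not (0.0 <= self.missing_fraction < 0.2):
            raise ConfigurationError("missing_fraction must be in [0, 0.2)")
        for attr in ("voluntary_amplitude_deg", "tremor_amplitude_deg",
                     "noise_std_deg"):
            if getattr(self, attr) < 0:
                raise ConfigurationError(f"{attr} must be >= 0")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @classmethod
    def default(cls, name: str, **overrides) -> "ActivityProfile":
        """Default profile for a named activity (drinking lasts 12 s)."""
        kwargs = dict(_ACTIVITY_DEFAULTS.get(name, {}))
        if name == "drinking":
            kwargs["duration_s"] = 12.0
        kwargs.update(overrides)
        return cls(name=name, **kwargs)


@dataclass(frozen=True)
class SyntheticRecording:
    """A mixed channel plus its uncorrupted ground-truth components.

    Invariant: before missing-sample corruption,
    mixed = voluntary_truth + tremor_truth + noise + drift, sample by sample.
    """

    mixed: OrientationSignal
    voluntary_truth: OrientationSignal
    tremor_truth: OrientationSignal
    profile: ActivityProfile
    seed: int

    def __post_init__(self):
        n = len(self.mixed)
        if len(self.voluntary_truth) != n or len(self.tremor_truth) != n:
            raise ValueError("component signals must share length")


def _scale_to_amplitude(x: np.ndarray, amplitude: float) -> np.ndarray:
    peak = np.max(np.abs(x))
    if peak == 0 or amplitude == 0:
        return np.zeros_like(x)
    return x * (amplitude / peak)


def _reach_and_return(t: np.ndarray, duration: float, n_cycles: int = 4) -> np.ndarray:
    """Slow piecewise-smooth drinking trajectory: n_cycles raised-cosine
    reach-and-return bumps, unit peak."""
    cycle = duration / n_cycles
    phase = (t % cycle) / cycle  # in [0, 1)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))


def generate_voluntary(profile: ActivityProfile, seed: int) -> OrientationSignal:
    """Voluntary motion: random superposition of 3-6 sub-3 Hz sinusoids.

    Frequencies are drawn uniformly in [0.2, 2.5] Hz (strictly inside the
    voluntary band) with random phases; the sum is peak-scaled to
    ``voluntary_amplitude_deg``. For drinking a slow reach-and-return
    trajectory is superposed. >= 95% of periodogram power lies below 3 Hz.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))
    n = profile.n_samples
    t = np.arange(n) / profile.fs
    k = int(rng.integers(3, 7))
    freqs = rng.uniform(0.2, 2.5, size=k)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
    amps = rng.uniform(0.3, 1.0, size=k)
    x = np.sum(amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t
                                      + phases[:, None]), axis=0)
    if profile.name == "drinking":
        # reach-and-return dominates; the sinusoids ride on top of it
        x = 0.3 * x / max(np.max(np.abs(x)), 1e-12) + _reach_and_return(
            t, profile.duration_s)
    x = _scale_to_amplitude(x, profile.voluntary_amplitude_deg)
    return OrientationSignal(x, fs=profile.fs,
                             meta={"component": "voluntary",
                                   "activity": profile.name, "seed": seed})


def generate_tremor(profile: ActivityProfile, seed: int,
                    carrier_hz: float | None = None,
                    am_depth: float | None = None,
                    fm_depth_hz: float = 0.3) -> OrientationSignal:
    """Tremulous motion: AM/FM tone with instantaneous frequency in 3-10 Hz.

    The carrier defaults to a uniform draw in [3.5, 9] Hz; a slow sinusoidal
    wobble of +/- ``fm_depth_hz`` modulates the instantaneous frequency and a
    10-50% amplitude modulation emulates waxing-and-waning tremor. Setting
    ``carrier_hz`` with ``am_depth=0, fm_depth_hz=0`` yields a pure tone.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    n = profile.n_samples
    t = np.arange(n) / profile.fs
    f0 = float(rng.uniform(3.5, 9.0)) if carrier_hz is None else float(carrier_hz)
    depth = float(rng.uniform(0.1, 0.5)) if am_depth is None else float(am_depth)
    lo, hi = profile.tremor_band_hz
    if not (lo < f0 < hi):
        raise ConfigurationError(f"tremor carrier {f0} Hz outside band {profile.tremor_band_hz}")
    fm_rate = rng.uniform(0.1, 0.3)     # Hz, slow wobble
    am_rate = rng.uniform(0.2, 0.5)     # Hz
    fm_phase = rng.uniform(0, 2 * np.pi)
    am_phase = rng.uniform(0, 2 * np.pi)
    f_inst = f0 + fm_depth_hz * np.sin(2 * np.pi * fm_rate * t + fm_phase)
    phase = 2.0 * np.pi * np.cumsum(f_inst) / profile.fs
    env = 1.0 - depth * 0.5 * (1.0 + np.sin(2 * np.pi * am_rate * t + am_phase))
    x = env * np.sin(phase)
    x = _scale_to_amplitude(x, profile.tremor_amplitude_deg)
    return OrientationSignal(x, fs=profile.fs,
                             meta={"component": "tremor", "carrier_hz": f0,
                                   "activity": profile.name, "seed": seed})


def generate_recording(profile: ActivityProfile, seed: int,
                       carrier_hz: float | None = None) -> SyntheticRecording:
    """Mixed = voluntary + tremor + white Gaussian noise + linear drift;
    then ``missing_fraction`` of interior samples are replaced by NaN.
    Ground-truth components are returned uncorrupted."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    vol = generate_voluntary(profile, seed)
    tre = generate_tremor(profile, seed, carrier_hz=carrier_hz)
    n = profile.n_samples
    t = np.arange(n) / profile.fs
    noise = (rng.standard_normal(n) * profile.noise_std_deg
             if profile.noise_std_deg > 0 else np.zeros(n))
    drift = profile.drift_slope_deg_per_s * t
    mixed = vol.values + tre.values + noise + drift
    n_missing = int(round(profile.missing_fraction * n))
    if n_missing > 0:
        # endpoints are never dropped so interpolation stays bounded
        idx = rng.choice(np.arange(1, n - 1), size=n_missing, replace=False)
        mixed = mixed.copy()
        mixed[idx] = np.nan
    meta = {"activity": profile.name, "seed": seed,
            "carrier_hz": tre.meta["carrier_hz"]}
    return SyntheticRecording(
        mixed=OrientationSignal(mixed, fs=profile.fs, meta=meta),
        voluntary_truth=vol, tremor_truth=tre, profile=profile, seed=seed,
    )


def generate_cohort(n_subjects: int,
                    profiles: Sequence[ActivityProfile],
                    seed: int,
                    body_parts: Sequence[str] = ("lower_arm",),
                    axes: Sequence[str] = ("roll",),
                    ) -> tuple[list[SyntheticRecording], list[dict]]:
    """Simulate a cohort: every subject performs every profile on every
    body-part/axis channel.

    Inter-subject variability: each subject gets one tremor carrier frequency
    (uniform in 3.5-9 Hz) and an amplitude factor shared across that
    subject's channels. Returns (recordings, manifest); the manifest records
    every per-recording seed so the cohort is exactly reproducible.
    """
    if n_subjects < 1:
        raise ConfigurationError("n_subjects must be >= 1")
    if len(profiles) == 0:
        raise ConfigurationError("profiles list must not be empty")
    recordings: list[SyntheticRecording] = []
    manifest: list[dict] = []
    for s in range(n_subjects):
        subj_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(s,)))
        carrier = float(subj_rng.uniform(3.5, 9.0))
        amp_factor = float(subj_rng.uniform(0.6, 1.4))
        for p_i, prof in enumerate(profiles):
            prof_s = ActivityProfile(
                **{**asdict(prof),
                   "tremor_amplitude_deg": prof.tremor_amplitude_deg * amp_factor})
            for b_i, part in enumerate(body_parts):
                for a_i, axis in enumerate(axes):
                    rec_seed = int(np.random.SeedSequence(
                        seed, spawn_key=(s, p_i, b_i, a_i)
                    ).generate_state(1)[0] % (2 ** 31))
                    rec = generate_recording(prof_s, rec_seed, carrier_hz=carrier)
                    rec.mixed.meta.update(subject=s, body_part=part, axis=axis)
                    recordings.append(rec)
                    manifest.append({
                        "subject": s, "activity": prof.name, "body_part": part,
                        "axis": axis, "seed": rec_seed, "carrier_hz": carrier,
                        "profile": asdict(prof_s),
                    })
    return recordings, manifest
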