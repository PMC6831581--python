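"""EMG/kinematic preprocessing into the nonnegative envelope matrix ``X``.

The chain mirrors a standard reaching-task EMG protocol: band-pass (10–450 Hz)
then high-pass (50 Hz) Butterworth filtering, movement segmentation from a
kinematic speed proxy (rest mean + 1.05 × rest SD threshold), full-wave
rectification and 5 Hz low-pass enveloping, linear tonic/gravity baseline
subtraction from two 300 ms flanking windows, resampling of each movement to
exactly 200 samples, per-muscle normalization by the average of the two trial
maxima, trial averaging, and horizontal concatenation over targets.

All filtering is zero-phase (forward–backward), so envelopes carry no group
delay relative to the kinematics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal
from scipy.integrate import cumulative_trapezoid

from synreach.muscles import (
    KINEMATIC_VARIABLES,
    MOVEMENT_SAMPLES,
    SENSOR_POSITIONS,
)

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    """Raised on contract violations in the preprocessing chain."""


class SegmentationError(PreprocessError):
    """Raised when no movement can be segmented from a kinematic trace."""


class DeadChannelError(PreprocessError):
    """Raised when a muscle channel has zero amplitude and cannot be normalized."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class EMGRecording:
    """Raw multi-channel surface EMG for one subject/target/trial.

    ``data`` is samples × channels in arbitrary units.
    """

    data: np.ndarray
    sampling_rate: float
    muscle_labels: tuple[str, ...]
    subject: str = ""
    target: int = 0
    trial: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise PreprocessError("EMG data must be samples x channels")
        if self.data.shape[1] != len(self.muscle_labels):
            raise PreprocessError(
                f"channel count {self.data.shape[1]} != label count "
                f"{len(self.muscle_labels)}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class KinematicTrace:
    """Inertial-sensor traces: x/y/z acceleration and roll/pitch/yaw angles.

    ``data`` is samples × (sensors × variables); ``columns`` names each channel
    as ``"<sensor>:<variable>"`` using the fixed sensor/variable sets.
    """

    data: np.ndarray
    sampling_rate: float
    columns: tuple[str, ...]
    subject: str = ""
    target: int = 0
    trial: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.columns):
            raise PreprocessError("kinematic data/columns mismatch")
        if not np.all(np.isfinite(self.data)):
            raise PreprocessError("kinematic trace contains non-finite values")
        for col in self.columns:
            sensor, _, var = col.partition(":")
            if sensor not in SENSOR_POSITIONS or var not in KINEMATIC_VARIABLES:
                raise PreprocessError(f"unknown kinematic channel {col!r}")

    def channel(self, sensor: str, variable: str) -> np.ndarray:
        name = f"{sensor}:{variable}"
        try:
            idx = self.columns.index(name)
        except ValueError:
            raise PreprocessError(f"missing kinematic channel {name!r}") from None
        return self.data[:, idx]

    def acceleration(self, sensor: str) -> np.ndarray:
        """samples × 3 array of the x/y/z accelerations of one sensor."""
        return np.column_stack(
            [self.channel(sensor, f"acc_{ax}") for ax in "xyz"]
        )


@dataclass(frozen=True)
class MovementSegment:
    """Half-open ``[start_sample, end_sample)`` window in EMG samples."""

    start_sample: int
    end_sample: int
    target: int = 0
    trial: int = 0
    phase: str = "out"

    def __post_init__(self) -> None:
        if not self.start_sample < self.end_sample:
            raise PreprocessError(
                f"empty movement segment [{self.start_sample}, {self.end_sample})"
            )

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass
class EnvelopeMatrix:
    """Nonnegative muscles × (n_targets · 200) matrix fed to the factorization.

    ``block_boundaries`` holds the half-open column range of each target
    block; ``norm_constants`` the per-target, per-muscle normalization
    divisors; ``provenance`` a free-form record of the processing applied.
    """

    X: np.ndarray
    muscle_labels: tuple[str, ...]
    block_boundaries: tuple[tuple[int, int], ...]
    norm_constants: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if np.any(self.X < 0):
            raise PreprocessError("envelope matrix must be nonnegative")

    def block(self, i: int) -> np.ndarray:
        lo, hi = self.block_boundaries[i]
        return self.X[:, lo:hi]


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _butter_sos(order: int, cutoff, btype: str, rate: float) -> np.ndarray:
    nyq = rate / 2.0
    cutoffs = np.atleast_1d(cutoff)
    if np.any(cutoffs >= nyq):
        raise PreprocessError(
            f"filter cutoff {cutoff} Hz >= Nyquist {nyq} Hz at rate {rate} Hz"
        )
    return signal.butter(order, cutoff, btype=btype, fs=rate, output="sos")


def bandpass_then_highpass(
    rec: EMGRecording,
    band: tuple[float, float] = (10.0, 450.0),
    highpass: float = 50.0,
    order: int = 2,
) -> EMGRecording:
    """Zero-phase 2nd-order Butterworth band-pass, then high-pass.

    The high-pass after the band-pass attenuates residual movement artifact.
    Both stages run forward–backward (``sosfiltfilt``), doubling the effective
    magnitude order while keeping zero phase.
    """
    if rec.sampling_rate <= 2 * band[1]:
        raise PreprocessError(
            f"sampling rate {rec.sampling_rate} Hz too low for band {band}"
        )
    sos_bp = _butter_sos(order, band, "bandpass", rec.sampling_rate)
    sos_hp = _butter_sos(order, highpass, "highpass", rec.sampling_rate)
    out = signal.sosfiltfilt(sos_bp, rec.data, axis=0)
    out = signal.sosfiltfilt(sos_hp, out, axis=0)
    return EMGRecording(
        data=out,
        sampling_rate=rec.sampling_rate,
        muscle_labels=rec.muscle_labels,
        subject=rec.subject,
        target=rec.target,
        trial=rec.trial,
    )


def combined_filter_response(freqs_hz, rate: float = 2048.0) -> np.ndarray:
    """|H(f)| of the zero-phase band-pass + high-pass cascade.

    Forward–backward filtering squares each stage's magnitude response; this
    helper exposes the analytic response for tests and documentation.
    """
    sos_bp = _butter_sos(2, (10.0, 450.0), "bandpass", rate)
    sos_hp = _butter_sos(2, 50.0, "highpass", rate)
    w = 2 * np.pi * np.asarray(freqs_hz, dtype=float) / rate
    _, h_bp = signal.sosfreqz(sos_bp, worN=w)
    _, h_hp = signal.sosfreqz(sos_hp, worN=w)
    return (np.abs(h_bp) * np.abs(h_hp)) ** 2


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def speed_proxy(
    kin: KinematicTrace,
    rest_window: tuple[int, int],
    sensor: str = "forearm",
    drift_cutoff_hz: float = 0.0,
    acc_highpass_hz: float = 0.0,
) -> np.ndarray:
    """Speed estimate from single integration of the 3-axis acceleration.

    Each axis is integrated once (trapezoid rule), drift-corrected by
    subtracting the straight line fitted to the rest window and then
    optionally high-passed (zero-phase, 2nd-order Butterworth at
    ``drift_cutoff_hz``; off by default — on records only a few times longer
    than the filter period the edge transients dominate) and the Euclidean
    norm is taken last.  Residual integration drift is tolerated because the
    movement is identified as the longest sustained suprathreshold run.  The task never
    defines speed operationally from accelerations, so this proxy is a
    deliberate, configurable choice.
    """
    acc = kin.acceleration(sensor)
    dt = 1.0 / kin.sampling_rate
    if acc_highpass_hz and acc_highpass_hz > 0:
        # High-passing the acceleration before integrating keeps the
        # velocity noise stationary: raw integration turns broadband sensor
        # noise into a random walk that dwarfs the 1.05-SD threshold.
        sos = _butter_sos(2, acc_highpass_hz, "highpass", kin.sampling_rate)
        acc = signal.sosfiltfilt(sos, acc, axis=0)
    vel = cumulative_trapezoid(acc, dx=dt, axis=0, initial=0.0)
    lo, hi = rest_window
    t = np.arange(vel.shape[0], dtype=float)
    for ax in range(vel.shape[1]):
        coeffs = np.polyfit(t[lo:hi], vel[lo:hi, ax], 1)
        vel[:, ax] -= np.polyval(coeffs, t)
    if drift_cutoff_hz and drift_cutoff_hz > 0:
        sos = _butter_sos(2, drift_cutoff_hz, "highpass", kin.sampling_rate)
        vel = signal.sosfiltfilt(sos, vel, axis=0)
    return np.linalg.norm(vel, axis=1)


def segment_movement(
    kin: KinematicTrace,
    rest_window: tuple[int, int],
    emg_rate: float,
    search_window: tuple[int, int] | None = None,
    phase: str = "out",
    sensor: str = "forearm",
    criterion: str = "mean_plus_sd",
    speed: np.ndarray | None = None,
    min_run_s: float = 0.1,
) -> MovementSegment:
    """Detect movement on/offset where speed exceeds the rest statistics.

    The movement is the longest run of suprathreshold speed inside
    ``search_window`` (kinematic samples; defaults to the whole trace); runs
    shorter than ``min_run_s`` are discarded.  With a threshold only
    1.05 rest-SD above the rest mean, isolated noise samples exceed it by
    chance, so first-to-last crossing would be fragile; the longest
    sustained excursion is the movement.
    ``criterion`` selects the reading of the 5 % rule:

    * ``"mean_plus_sd"`` (default): rest mean + 1.05 × rest SD;
    * ``"sd_only"``: 1.05 × rest SD as an absolute threshold.

    The returned segment is expressed in EMG samples via the rate ratio.
    """
    lo, hi = rest_window
    n = kin.data.shape[0]
    if not (0 <= lo < hi <= n) or hi - lo < 10:
        raise PreprocessError(f"rest window {rest_window} invalid for {n} samples")
    if speed is None:
        speed = speed_proxy(kin, rest_window, sensor=sensor)
    rest_mean = float(np.mean(speed[lo:hi]))
    rest_sd = float(np.std(speed[lo:hi], ddof=1))
    if criterion == "mean_plus_sd":
        threshold = rest_mean + 1.05 * rest_sd
    elif criterion == "sd_only":
        threshold = 1.05 * rest_sd
    else:
        raise PreprocessError(f"unknown segmentation criterion {criterion!r}")

    s_lo, s_hi = search_window if search_window is not None else (0, n)
    s_lo, s_hi = max(0, s_lo), min(n, s_hi)
    above = speed[s_lo:s_hi] > threshold
    min_run = max(1, int(round(min_run_s * kin.sampling_rate)))

    edges = np.diff(np.concatenate([[0], above.astype(int), [0]]))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    lengths = ends - starts
    valid = lengths >= min_run
    if not valid.any():
        raise SegmentationError(
            f"speed never crossed the threshold for subject={kin.subject!r} "
            f"target={kin.target} trial={kin.trial} phase={phase!r}"
        )
    best = int(np.flatnonzero(valid)[np.argmax(lengths[valid])])
    start_kin = s_lo + int(starts[best])
    end_kin = s_lo + int(ends[best])
    ratio = emg_rate / kin.sampling_rate
    return MovementSegment(
        start_sample=int(round(start_kin * ratio)),
        end_sample=int(round(end_kin * ratio)),
        target=kin.target,
        trial=kin.trial,
        phase=phase,
    )


# ---------------------------------------------------------------------------
# Enveloping, tonic subtraction, resampling
# ---------------------------------------------------------------------------

def envelope(
    data: np.ndarray,
    rate: float,
    cutoff: float = 5.0,
    order: int = 4,
) -> np.ndarray:
    """Full-wave rectification followed by a zero-phase low-pass."""
    sos = _butter_sos(order, cutoff, "lowpass", rate)
    return signal.sosfiltfilt(sos, np.abs(np.asarray(data, dtype=float)), axis=0)


def tonic_subtract(
    env: np.ndarray,
    seg: MovementSegment,
    rate: float,
    win_ms: float = 300.0,
) -> np.ndarray:
    """Subtract the linearly interpolated tonic baseline across a movement.

    Per muscle, the mean rectified value is computed in a ``win_ms`` window
    immediately before the segment and one immediately after it; the straight
    line between the two means is subtracted sample-wise inside the segment
    and negative residuals are padded to zero.  Samples outside the segment
    are left untouched.
    """
    env = np.asarray(env, dtype=float)
    w = int(round(win_ms / 1000.0 * rate))
    if w < 1:
        raise PreprocessError("tonic window shorter than one sample")
    if seg.start_sample - w < 0 or seg.end_sample + w > env.shape[0]:
        raise PreprocessError(
            f"insufficient flanking samples for a {win_ms} ms tonic window "
            f"around [{seg.start_sample}, {seg.end_sample})"
        )
    pre = env[seg.start_sample - w : seg.start_sample].mean(axis=0)
    post = env[seg.end_sample : seg.end_sample + w].mean(axis=0)
    n = seg.n_samples
    ramp = np.linspace(0.0, 1.0, n)[:, None] * (post - pre)[None, :] + pre[None, :]
    out = env.copy()
    moved = out[seg.start_sample : seg.end_sample] - ramp
    out[seg.start_sample : seg.end_sample] = np.maximum(moved, 0.0)
    return out


def resample_movement(
    env: np.ndarray,
    seg: MovementSegment,
    n_out: int = MOVEMENT_SAMPLES,
    method: str = "linear",
) -> np.ndarray:
    """Crop an envelope to a movement and resample it to ``n_out`` samples.

    ``method="linear"`` interpolates onto ``n_out`` equispaced points (the
    default; preserves nonnegativity exactly); ``method="poly"`` uses
    polyphase resampling.
    """
    env = np.asarray(env, dtype=float)
    crop = env[seg.start_sample : seg.end_sample]
    if crop.shape[0] < 20:
        raise PreprocessError(
            f"movement segment of {crop.shape[0]} samples too short to resample"
        )
    if method == "linear":
        xp = np.linspace(0.0, 1.0, crop.shape[0])
        xq = np.linspace(0.0, 1.0, n_out)
        return np.column_stack(
            [np.interp(xq, xp, crop[:, j]) for j in range(crop.shape[1])]
        )
    if method == "poly":
        return signal.resample_poly(crop, n_out, crop.shape[0], axis=0)
    raise PreprocessError(f"unknown resampling method {method!r}")


def envelope_and_resample(
    data: np.ndarray,
    seg: MovementSegment,
    rate: float,
    n_out: int = MOVEMENT_SAMPLES,
    cutoff: float = 5.0,
    method: str = "linear",
) -> np.ndarray:
    """Rectify, 5 Hz low-pass, crop to the segment and resample to ``n_out``."""
    return resample_movement(envelope(data, rate, cutoff=cutoff), seg, n_out, method)


def process_trial(
    rec: EMGRecording,
    seg: MovementSegment,
    win_ms: float = 300.0,
    n_out: int = MOVEMENT_SAMPLES,
    resample_method: str = "linear",
) -> np.ndarray:
    """Filtered EMG → movement envelope (``n_out`` × muscles), tonic-corrected.

    Order of operations: rectify and low-pass the already band-/high-passed
    signal, estimate and subtract the tonic baseline from the two flanking
    windows (clamping at zero), then crop and resample the movement.
    """
    env = envelope(rec.data, rec.sampling_rate)
    env = tonic_subtract(env, seg, rec.sampling_rate, win_ms=win_ms)
    return resample_movement(env, seg, n_out, resample_method)


# ---------------------------------------------------------------------------
# Normalization, assembly, summary measures
# ---------------------------------------------------------------------------

def normalize_and_average(
    trial_a: np.ndarray,
    trial_b: np.ndarray,
    muscle_labels: Sequence[str] | None = None,
    mode: str = "per_muscle",
) -> tuple[np.ndarray, np.ndarray]:
    """Normalize two same-target movement envelopes and average them.

    The divisor is the average of the two per-trial global maxima — per
    muscle by default, or a single global scalar with ``mode="global"`` —
    after gravity compensation.  Returns ``(averaged, divisor)`` where
    ``divisor`` has one entry per muscle.
    """
    a = np.asarray(trial_a, dtype=float)
    b = np.asarray(trial_b, dtype=float)
    if a.shape != b.shape:
        raise PreprocessError(f"trial shapes differ: {a.shape} vs {b.shape}")
    if mode == "per_muscle":
        divisor = (a.max(axis=0) + b.max(axis=0)) / 2.0
    elif mode == "global":
        divisor = np.full(a.shape[1], (a.max() + b.max()) / 2.0)
    else:
        raise PreprocessError(f"unknown normalization mode {mode!r}")
    dead = np.flatnonzero(divisor == 0.0)
    if dead.size:
        labels = muscle_labels or [str(i) for i in range(a.shape[1])]
        names = ", ".join(labels[i] for i in dead)
        raise DeadChannelError(f"zero-amplitude channel(s): {names}")
    avg = (a / divisor + b / divisor) / 2.0
    return avg, divisor


def assemble_X(
    per_target_envelopes: Sequence[np.ndarray],
    muscle_labels: Sequence[str],
    norm_constants: np.ndarray | None = None,
    provenance: dict | None = None,
) -> EnvelopeMatrix:
    """Concatenate per-target 200 × muscles envelopes into muscles × time."""
    m = len(muscle_labels)
    blocks, bounds, col = [], [], 0
    for i, env in enumerate(per_target_envelopes):
        env = np.asarray(env, dtype=float)
        if env.ndim != 2 or env.shape[1] != m:
            raise PreprocessError(
                f"target {i}: envelope shape {env.shape} inconsistent with "
                f"{m} muscles"
            )
        blocks.append(env.T)
        bounds.append((col, col + env.shape[0]))
        col += env.shape[0]
    X = np.concatenate(blocks, axis=1)
    return EnvelopeMatrix(
        X=X,
        muscle_labels=tuple(muscle_labels),
        block_boundaries=tuple(bounds),
        norm_constants=(
            np.asarray(norm_constants, dtype=float)
            if norm_constants is not None
            else np.ones((len(blocks), m))
        ),
        provenance=dict(provenance or {}),
    )


def rms_activity(env: np.ndarray) -> np.ndarray:
    """Per-muscle root mean square of a normalized movement envelope."""
    env = np.asarray(env, dtype=float)
    return np.sqrt(np.mean(env**2, axis=0))


def kinematic_cov(
    kin: KinematicTrace,
    window: tuple[int, int],
    ddof: int = 1,
    eps: float = 1e-12,
) -> dict[tuple[str, str], float]:
    """COV = SD / |mean| per (sensor, variable) over a movement window.

    COV is taken across the time samples of the movement (cross-repetition
    COV is ill-conditioned with two trials).  Cells with |mean| ~ 0 are
    returned as NaN and logged; callers exclude them downstream.
    """
    lo, hi = window
    out: dict[tuple[str, str], float] = {}
    for sensor in SENSOR_POSITIONS:
        for var in KINEMATIC_VARIABLES:
            x = kin.channel(sensor, var)[lo:hi]
            mean = float(np.mean(x))
            sd = float(np.std(x, ddof=ddof)) if x.size > 1 else 0.0
            if abs(mean) < eps:
                logger.warning(
                    "COV undefined (zero mean) for %s:%s, subject=%s target=%d",
                    sensor, var, kin.subject, kin.target,
                )
                out[(sensor, var)] = float("nan")
            else:
                out[(sensor, var)] = sd / abs(mean)
    return out
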