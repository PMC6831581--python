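"""Synthetic reaching-study generator with known modular ground truth.

Emulates the study design the analysis assumes: 15 subjects × 13 shoulder/arm
muscles × 8 radial targets × 2 trials of surface EMG during point-to-point
reaching, paced in four periods (hold-center ~4 s, transition-out ~2 s,
hold-target ~4 s, transition-back ~2 s).  Muscle activity is driven by a
three-module generative structure ``S_true · P_true`` with cosine directional
tuning of the activation amplitudes, an additive tonic (gravity) baseline, and
broadband noise at a configurable SNR.  EMG is simulated as amplitude-
modulated Gaussian noise — all downstream computation uses envelopes, so a
motor-unit-level model would add nothing the pipeline can see.

Each (subject, muscle) carries a trigger-point label in {ACT, LAT, NO}; when
``tp_effect_delta > 0``, the weighting of every muscle that hosts an ACT TP
*and* is dominant in a module is inflated by ``delta`` before EMG synthesis,
so parameter-recovery tests can probe detection of exactly that effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from synreach.muscles import MUSCLES
from synreach.preprocess import EMGRecording, KinematicTrace
from synreach.muscles import KINEMATIC_VARIABLES, SENSOR_POSITIONS


class ConfigError(ValueError):
    """Raised for invalid generative configurations."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenerativeConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the study design: 15 subjects, the 13 named muscles,
    8 targets at 45° spacing, 2 trials per target, 3 true modules, EMG at
    2048 Hz and kinematics at 100 Hz.  ``tp_prevalence`` defaults to the
    observed palpation rates (13/195 active, 50/195 latent).
    """

    n_subjects: int = 15
    muscle_names: tuple[str, ...] = MUSCLES
    n_targets: int = 8
    n_trials_per_target: int = 2
    n_true_modules: int = 3
    sampling_rate_emg: float = 2048.0
    sampling_rate_kin: float = 100.0
    snr_db: float = 20.0
    tp_prevalence: tuple[float, float] = (13.0 / 195.0, 50.0 / 195.0)
    tp_effect_delta: float = 0.0
    seed: int = 0
    # Task rhythm (nominal four-period pacing plus a short relaxation tail).
    hold_center_s: float = 4.0
    transition_s: float = 2.0
    hold_target_s: float = 4.0
    tail_s: float = 0.5
    # Generative details.
    tuning_floor: float = 0.15
    subject_weight_jitter: float = 0.12
    tonic_level: float = 0.06
    acc_jitter_sd: float = 0.01
    dominance_fraction: float = 0.3

    def __post_init__(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_targets": self.n_targets,
            "n_trials_per_target": self.n_trials_per_target,
            "n_true_modules": self.n_true_modules,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigError(f"{name} must be a positive integer, got {value}")
        if self.n_true_modules > len(self.muscle_names):
            raise ConfigError("n_true_modules exceeds the number of muscles")
        p_act, p_lat = self.tp_prevalence
        if not (0 <= p_act <= 1 and 0 <= p_lat <= 1 and p_act + p_lat <= 1):
            raise ConfigError(f"invalid tp_prevalence {self.tp_prevalence}")
        if not np.isfinite(self.snr_db):
            raise ConfigError("snr_db must be finite")
        if self.sampling_rate_emg <= 0 or self.sampling_rate_kin <= 0:
            raise ConfigError("sampling rates must be positive")

    @property
    def target_angles(self) -> np.ndarray:
        return np.arange(self.n_targets) * (360.0 / self.n_targets)

    @property
    def total_duration_s(self) -> float:
        return (
            self.hold_center_s
            + 2 * self.transition_s
            + self.hold_target_s
            + self.tail_s
        )

    @property
    def period_boundaries_s(self) -> tuple[float, float, float, float]:
        """End times (s) of hold-center, transition-out, hold-target,
        transition-back."""
        b1 = self.hold_center_s
        b2 = b1 + self.transition_s
        b3 = b2 + self.hold_target_s
        b4 = b3 + self.transition_s
        return (b1, b2, b3, b4)

    def subject_id(self, i: int) -> str:
        return f"S{i + 1:02d}"


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

#: Canonical weightings for the default 13-muscle, three-module structure:
#: A — reach initiation (anterior deltoid dominant); B — arm elevation and
#: extension (posterior/middle deltoid, triceps, biceps long head); C —
#: scapular/neck stabilisation (upper and middle trapezius).
_CANONICAL_S: dict[str, tuple[float, float, float]] = {
    "TU":   (0.05, 0.08, 1.00),
    "TM":   (0.05, 0.06, 0.65),
    "TL":   (0.04, 0.06, 0.55),
    "DA":   (1.00, 0.35, 0.05),
    "DM":   (0.08, 0.70, 0.06),
    "DP":   (0.06, 1.00, 0.08),
    "PM":   (0.55, 0.06, 0.04),
    "BS":   (0.10, 0.40, 0.04),
    "BL":   (0.06, 0.45, 0.04),
    "TLA":  (0.05, 0.55, 0.05),
    "TLO":  (0.06, 0.60, 0.07),
    "BR":   (0.45, 0.12, 0.04),
    "SCOM": (0.04, 0.04, 0.45),
}


@dataclass
class GroundTruth:
    """Generative structure shared by all trials of one synthetic study."""

    config: GenerativeConfig
    S_true: np.ndarray                      # muscles × modules, column max 1
    P_true: np.ndarray                      # targets × modules × 200 templates
    tp_table: "TPTable"                     # noqa: F821 - see synreach.tpstats
    dominance_true: np.ndarray              # muscles × modules boolean
    subject_weightings: np.ndarray          # subjects × muscles × modules
    activation_params: dict = field(default_factory=dict)
    module_names: tuple[str, ...] = ()

    def dominant_sets(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for j, name in enumerate(self.module_names):
            out[name] = {
                self.config.muscle_names[i]
                for i in np.flatnonzero(self.dominance_true[:, j])
            }
        return out


@dataclass
class TrialBundle:
    """One trial's EMG, kinematics and task-phase boundaries (seconds)."""

    emg: EMGRecording
    kinematics: KinematicTrace
    period_boundaries: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        b = self.period_boundaries
        if not all(b[i] < b[i + 1] for i in range(len(b) - 1)):
            raise ConfigError(f"period boundaries not increasing: {b}")
        if b[-1] > self.emg.duration + 1.0 / self.emg.sampling_rate:
            raise ConfigError("period boundaries exceed record length")
        if abs(
            self.emg.duration
            - self.kinematics.data.shape[0] / self.kinematics.sampling_rate
        ) > 1.0 / min(self.emg.sampling_rate, self.kinematics.sampling_rate):
            raise ConfigError("EMG and kinematic durations disagree")


def _base_weightings(config: GenerativeConfig) -> np.ndarray:
    m, k = len(config.muscle_names), config.n_true_modules
    if tuple(config.muscle_names) == MUSCLES and k == 3:
        S = np.array([_CANONICAL_S[name] for name in config.muscle_names])
    else:
        # Generic structured fallback: spaced dominant muscles, one
        # co-dominant each, low background weights.
        rng = np.random.default_rng([config.seed, 7000])
        S = rng.uniform(0.05, 0.25, size=(m, k))
        for j in range(k):
            d = (j * m) // k
            S[d, j] = 1.0
            S[(d + 1) % m, j] = rng.uniform(0.45, 0.8)
    S = S / S.max(axis=0, keepdims=True)
    return S


def _activation_params(config: GenerativeConfig, S: np.ndarray) -> dict:
    k = config.n_true_modules
    # Burst timing: staggered, largely non-overlapping unimodal bursts across
    # the movement, so the module terms are close to mutually orthogonal and
    # the VAF curve's change of slope sits at the true rank.
    centers = np.linspace(0.2, 0.8, k) if k > 1 else np.array([0.5])
    widths = np.full(k, 0.11)
    pref_dirs = 90.0 + np.arange(k) * (360.0 / k)
    params = {
        "centers": centers,
        "widths": widths,
        "pref_dirs_deg": pref_dirs,
        "gains": np.ones(k),
        "floor": config.tuning_floor,
    }
    params["gains"] = _equalize_module_energy(config, S, params)
    return params


def _equalize_module_energy(
    config: GenerativeConfig, S: np.ndarray, params: dict, n_iter: int = 6
) -> np.ndarray:
    """Calibrate module gains so each module contributes equal variance.

    The normalized envelope matrix divides each movement by its global
    maximum, which couples the effective module energies to the gains; a
    short deterministic fixed point balances the realized (post-
    normalization) energies across modules, summed over all targets.
    """
    k = config.n_true_modules
    tau = np.linspace(0.0, 1.0, 200)
    gains = np.ones(k)
    for _ in range(n_iter):
        p = {**params, "gains": gains}
        energies = np.zeros(k)
        for angle in config.target_angles:
            act = activation_templates(p, tau, float(angle))  # 200 x k
            env = act @ S.T                                   # 200 x m
            peak = env.max()
            if peak <= 0:
                continue
            contrib = np.einsum("tj,mj->jtm", act, S)         # k x 200 x m
            energies += (contrib**2).sum(axis=(1, 2)) / peak**2
        if np.any(energies <= 0):
            break
        gains = gains / np.sqrt(energies / energies.mean())
        gains = gains / gains.max()
    return gains


def _bump(tau: np.ndarray, center: float, width: float) -> np.ndarray:
    """Smooth unimodal burst on [0, 1], tapered to zero at both ends."""
    taper = np.sin(np.pi * np.clip(tau, 0.0, 1.0)) ** 0.5
    return np.exp(-0.5 * ((tau - center) / width) ** 2) * taper


def activation_templates(
    params: Mapping, tau: np.ndarray, angle_deg: float
) -> np.ndarray:
    """Module activations (len(tau) × k) for one movement toward ``angle_deg``.

    Amplitude follows cosine directional tuning around each module's
    preferred direction, with a floor so every module participates in every
    direction.
    """
    centers = params["centers"]
    widths = params["widths"]
    pref = params["pref_dirs_deg"]
    gains = params["gains"]
    floor = params["floor"]
    k = len(centers)
    out = np.empty((tau.size, k))
    for j in range(k):
        tuning = floor + (1.0 - floor) * 0.5 * (
            1.0 + np.cos(np.deg2rad(angle_deg - pref[j]))
        )
        out[:, j] = gains[j] * tuning * _bump(tau, centers[j], widths[j])
    return out


def make_ground_truth(
    config: GenerativeConfig, tp_table: "TPTable | None" = None  # noqa: F821
) -> GroundTruth:
    """Build the study-level generative structure, deterministically.

    The TP table and the per-subject weighting jitter are drawn from streams
    that do not depend on ``tp_effect_delta``, so paired runs differing only
    in ``delta`` share labels and jitter exactly — the injected effect is the
    *only* difference between them.

    ``tp_table`` optionally fixes the TP labels instead of drawing them —
    e.g. to anchor a synthetic study on an observed palpation grid.  The
    table must have ``n_subjects`` rows over the configured muscles; its
    cells are assigned to the generated subjects by position.
    """
    from synreach.tpstats import TPTable  # deferred: tpstats imports synergy

    S = _base_weightings(config)
    frac = config.dominance_fraction
    dominance = S >= frac * S.max(axis=0, keepdims=True)
    if not dominance.any(axis=0).all():
        bad = int(np.flatnonzero(~dominance.any(axis=0))[0])
        raise ConfigError(f"module {bad} has no dominant muscle")

    params = _activation_params(config, S)
    tau = np.linspace(0.0, 1.0, 200)
    P = np.stack(
        [
            activation_templates(params, tau, angle).T
            for angle in config.target_angles
        ]
    )

    subjects = [config.subject_id(i) for i in range(config.n_subjects)]
    if tp_table is not None:
        if tp_table.grid.shape != (config.n_subjects, len(config.muscle_names)):
            raise ConfigError(
                f"fixed TP table shape {tp_table.grid.shape} does not match "
                f"({config.n_subjects}, {len(config.muscle_names)})"
            )
        status = (
            tp_table.grid[list(config.muscle_names)].to_numpy(dtype=object)
        )
        tp_table = TPTable.from_grid(subjects, config.muscle_names, status)
    else:
        p_act, p_lat = config.tp_prevalence
        rng_tp = np.random.default_rng([config.seed, 7001])
        u = rng_tp.random((config.n_subjects, len(config.muscle_names)))
        status = np.where(
            u < p_act, "ACT", np.where(u < p_act + p_lat, "LAT", "NO")
        )
        tp_table = TPTable.from_grid(subjects, config.muscle_names, status)

    rng_jitter = np.random.default_rng([config.seed, 7002])
    jitter = np.exp(
        rng_jitter.normal(
            0.0,
            config.subject_weight_jitter,
            size=(config.n_subjects, *S.shape),
        )
    )
    subject_S = S[None, :, :] * jitter
    if config.tp_effect_delta != 0.0:
        act = status == "ACT"                        # subjects × muscles
        inject = act[:, :, None] & dominance[None, :, :]
        subject_S = subject_S + config.tp_effect_delta * inject

    module_names = tuple(chr(ord("A") + j) for j in range(config.n_true_modules))
    return GroundTruth(
        config=config,
        S_true=S,
        P_true=P,
        tp_table=tp_table,
        dominance_true=dominance,
        subject_weightings=subject_S,
        activation_params=params,
        module_names=module_names,
    )


# ---------------------------------------------------------------------------
# Trial synthesis
# ---------------------------------------------------------------------------

def _minimum_jerk_speed(tau: np.ndarray) -> np.ndarray:
    """Bell-shaped speed profile on [0, 1], peak 1 at tau = 0.5."""
    v = tau**2 * (1.0 - tau) ** 2
    return v / 0.0625


_SENSOR_SCALE = {"sternum": 0.1, "shoulder": 0.4, "arm": 0.8, "forearm": 1.0}


def synthesize_trial(
    gt: GroundTruth,
    subject: int,
    target: int,
    trial: int,
    config: GenerativeConfig | None = None,
) -> TrialBundle:
    """Forward-simulate one trial of EMG and kinematics.

    EMG per muscle is a zero-mean Gaussian carrier amplitude-modulated by the
    noiseless envelope ``S_subject · P(target)`` plus a slowly drifting tonic
    baseline, with additive white noise at ``snr_db``.  Rest and hold phases
    carry tonic activity only.  Kinematic speed is near zero at rest (small
    jitter keeps the rest SD strictly positive, so the 5 % segmentation
    criterion is always well defined) and bell-shaped in the two transitions.
    Deterministic given (seed, subject, target, trial).
    """
    cfg = config or gt.config
    if not (0 <= target < cfg.n_targets):
        raise ConfigError(f"target index {target} out of range")
    if not (0 <= subject < cfg.n_subjects):
        raise ConfigError(f"subject index {subject} out of range")
    if not (0 <= trial < cfg.n_trials_per_target):
        raise ConfigError(f"trial index {trial} out of range")

    rng = np.random.default_rng([cfg.seed, 7100, subject, target, trial])
    fs = cfg.sampling_rate_emg
    n = int(round(cfg.total_duration_s * fs))
    m = len(cfg.muscle_names)
    b1, b2, b3, b4 = cfg.period_boundaries_s
    angle = float(cfg.target_angles[target])
    S_subj = gt.subject_weightings[subject]

    amp = np.zeros((n, m))
    out_sl = slice(int(round(b1 * fs)), int(round(b2 * fs)))
    back_sl = slice(int(round(b3 * fs)), int(round(b4 * fs)))
    tau_out = np.linspace(0.0, 1.0, out_sl.stop - out_sl.start)
    tau_back = np.linspace(0.0, 1.0, back_sl.stop - back_sl.start)
    act_out = activation_templates(gt.activation_params, tau_out, angle)
    act_back = activation_templates(
        gt.activation_params, 1.0 - tau_back, (angle + 180.0) % 360.0
    )
    amp[out_sl] = act_out @ S_subj.T
    amp[back_sl] = act_back @ S_subj.T

    t_rel = np.arange(n) / n
    tonic0 = cfg.tonic_level * (0.5 + rng.random(m))
    slope = cfg.tonic_level * 0.2 * (rng.random(m) - 0.5)
    tonic = tonic0[None, :] + slope[None, :] * t_rel[:, None]
    amp = amp + tonic

    carrier = rng.standard_normal((n, m))
    sig = amp * carrier
    rms = np.sqrt(np.mean(sig**2, axis=0))
    noise_sd = rms * 10.0 ** (-cfg.snr_db / 20.0)
    emg_data = sig + noise_sd[None, :] * rng.standard_normal((n, m))

    kin = _synthesize_kinematics(cfg, angle, rng)
    sid = cfg.subject_id(subject)
    emg = EMGRecording(
        data=emg_data,
        sampling_rate=fs,
        muscle_labels=tuple(cfg.muscle_names),
        subject=sid,
        target=target,
        trial=trial,
    )
    kin.subject, kin.target, kin.trial = sid, target, trial
    return TrialBundle(
        emg=emg, kinematics=kin, period_boundaries=cfg.period_boundaries_s
    )


def _synthesize_kinematics(
    cfg: GenerativeConfig, angle: float, rng: np.random.Generator
) -> KinematicTrace:
    fs = cfg.sampling_rate_kin
    n = int(round(cfg.total_duration_s * fs))
    t = np.arange(n) / fs
    b1, b2, b3, b4 = cfg.period_boundaries_s

    speed = np.zeros(n)
    out_mask = (t >= b1) & (t < b2)
    back_mask = (t >= b3) & (t < b4)
    speed[out_mask] = _minimum_jerk_speed((t[out_mask] - b1) / (b2 - b1))
    speed[back_mask] = _minimum_jerk_speed((t[back_mask] - b3) / (b4 - b3))

    theta = np.deg2rad(angle)
    direction = np.array([np.cos(theta), np.sin(theta), 0.3])
    direction /= np.linalg.norm(direction)
    sign = np.where(back_mask, -1.0, 1.0)
    vel = (speed * sign)[:, None] * direction[None, :]
    acc = np.gradient(vel, 1.0 / fs, axis=0)
    # Constant per-axis offsets emulate imperfect gravity removal; the speed
    # proxy's rest-window drift correction must cope with them.
    acc = acc + np.array([0.02, 0.015, 0.025])[None, :]

    # Net displacement-like excursion: rises during "out", returns in "back".
    excursion = np.cumsum(speed * sign) / fs

    columns, data = [], []
    for sensor in SENSOR_POSITIONS:
        scale = _SENSOR_SCALE[sensor]
        sensor_acc = scale * acc + cfg.acc_jitter_sd * rng.standard_normal((n, 3))
        angles = {
            "roll": 5.0 + scale * 20.0 * excursion,
            "pitch": -3.0 + scale * 12.0 * excursion,
            "yaw": 1.0 + scale * 6.0 * excursion,
        }
        for i, var in enumerate(KINEMATIC_VARIABLES):
            if var.startswith("acc_"):
                data.append(sensor_acc[:, i])
            else:
                data.append(
                    angles[var] + 0.05 * rng.standard_normal(n)
                )
            columns.append(f"{sensor}:{var}")
    return KinematicTrace(
        data=np.column_stack(data),
        sampling_rate=fs,
        columns=tuple(columns),
    )


def rest_window_kin(cfg: GenerativeConfig) -> tuple[int, int]:
    """Kinematic-sample window inside the hold-center phase used as rest."""
    fs = cfg.sampling_rate_kin
    return (int(round(0.5 * fs)), int(round((cfg.hold_center_s - 0.5) * fs)))


def search_window_kin(cfg: GenerativeConfig, phase: str = "out") -> tuple[int, int]:
    """Kinematic-sample window bracketing one transition (± 0.3 s margin)."""
    fs = cfg.sampling_rate_kin
    b1, b2, b3, b4 = cfg.period_boundaries_s
    lo, hi = (b1, b2) if phase == "out" else (b3, b4)
    return (int(round((lo - 0.3) * fs)), int(round((hi + 0.3) * fs)))


# ---------------------------------------------------------------------------
# Fixture-study writer
# ---------------------------------------------------------------------------

def write_fixture_study(config: GenerativeConfig, out_dir) -> dict:
    """Write a full synthetic study as delimited text plus a JSON manifest.

    One EMG and one kinematic file per trial, the TP table, the ground-truth
    weightings/templates, and a manifest listing every path together with the
    configuration.  Everything round-trips through :mod:`synreach.cli_io`
    readers at 1e-9 relative precision.
    """
    import json

    from synreach import cli_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gt = make_ground_truth(config)

    trial_files = []
    for s in range(config.n_subjects):
        for tgt in range(config.n_targets):
            for tr in range(config.n_trials_per_target):
                bundle = synthesize_trial(gt, s, tgt, tr, config)
                sid = config.subject_id(s)
                emg_path = out / f"emg_{sid}_t{tgt}_r{tr}.tsv"
                kin_path = out / f"kin_{sid}_t{tgt}_r{tr}.tsv"
                cli_io.write_matrix(
                    emg_path, bundle.emg.data, bundle.emg.muscle_labels
                )
                cli_io.write_matrix(
                    kin_path, bundle.kinematics.data, bundle.kinematics.columns
                )
                trial_files.append(
                    {
                        "subject": sid,
                        "target": tgt,
                        "trial": tr,
                        "emg": emg_path.name,
                        "kinematics": kin_path.name,
                    }
                )

    tp_path = out / "tp_table.tsv"
    gt.tp_table.to_file(tp_path)
    s_path = out / "S_true.tsv"
    cli_io.write_matrix(s_path, gt.S_true, gt.module_names)
    p_path = out / "P_true.tsv"
    n_t, k, n_s = gt.P_true.shape
    p_long = np.column_stack(
        [
            np.repeat(np.arange(n_t), k * n_s),
            np.tile(np.repeat(np.arange(k), n_s), n_t),
            np.tile(np.arange(n_s), n_t * k),
            gt.P_true.ravel(),
        ]
    )
    cli_io.write_matrix(p_path, p_long, ("target", "module", "sample", "value"))
    dom_path = out / "dominance_true.tsv"
    cli_io.write_matrix(
        dom_path, gt.dominance_true.astype(float), gt.module_names
    )

    manifest = {
        "config": _config_to_dict(config),
        "muscles": list(config.muscle_names),
        "trials": trial_files,
        "tp_table": tp_path.name,
        "S_true": s_path.name,
        "P_true": p_path.name,
        "dominance_true": dom_path.name,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _config_to_dict(config: GenerativeConfig) -> dict:
    from dataclasses import asdict

    d = asdict(config)
    d["muscle_names"] = list(d["muscle_names"])
    d["tp_prevalence"] = list(d["tp_prevalence"])
    return d


def config_from_dict(d: Mapping) -> GenerativeConfig:
    d = dict(d)
    if "muscle_names" in d:
        d["muscle_names"] = tuple(d["muscle_names"])
    if "tp_prevalence" in d:
        d["tp_prevalence"] = tuple(d["tp_prevalence"])
    return GenerativeConfig(**d)
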