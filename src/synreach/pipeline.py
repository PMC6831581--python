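"""End-to-end orchestration: simulate → preprocess → extract → associate.

Glue used by the command-line interface and the acceptance checks.  Each
stage delegates to the public operations of :mod:`synreach.synthgen`,
:mod:`synreach.preprocess`, :mod:`synreach.synergy` and
:mod:`synreach.tpstats`; this module only wires them together and carries
intermediate results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from synreach import preprocess as pp
from synreach import synergy, synthgen, tpstats


@dataclass
class PreprocessedStudy:
    """Per-subject envelope matrices plus RMS and kinematic-COV tables."""

    config: synthgen.GenerativeConfig
    ground_truth: synthgen.GroundTruth
    X_by_subject: dict[str, pp.EnvelopeMatrix]
    rms_table: pd.DataFrame   # subject, muscle, target, rms
    cov_table: pd.DataFrame   # subject, sensor, variable, target, cov


@dataclass
class ExtractionResult:
    """NMF sweep/selection/matching outputs for one study."""

    curves: dict[str, synergy.VAFCurve]
    k_selected: int
    k_per_subject: dict[str, int]
    decomps: dict[str, synergy.SynergyDecomposition]
    match: synergy.ModuleMatch
    weightings: dict[str, np.ndarray]          # matched muscles x k
    dominance: dict[str, synergy.DominanceLabeling]
    module_names: tuple[str, ...]


@dataclass
class StudyResult:
    preprocessed: PreprocessedStudy
    extraction: ExtractionResult
    observations: pd.DataFrame
    contrast: tpstats.ContrastResult
    dim_regression: tpstats.DimRegressionResult | None = None
    grid_null: tpstats.GridNullResult | None = None
    extra: dict = field(default_factory=dict)


def _normalize_average(trials: list[np.ndarray], labels, mode: str):
    if len(trials) == 2:
        return pp.normalize_and_average(trials[0], trials[1], labels, mode)
    stacked_max = np.stack([t.max(axis=0) for t in trials])
    if mode == "global":
        divisor = np.full(trials[0].shape[1], stacked_max.max(axis=1).mean())
    else:
        divisor = stacked_max.mean(axis=0)
    if np.any(divisor == 0):
        raise pp.DeadChannelError("zero-amplitude channel in trial set")
    avg = np.mean([t / divisor for t in trials], axis=0)
    return avg, divisor


def preprocess_study(
    config: synthgen.GenerativeConfig,
    gt: synthgen.GroundTruth | None = None,
    norm_mode: str = "global",
    segmentation_criterion: str = "mean_plus_sd",
    band: tuple[float, float] = (10.0, 450.0),
    highpass: float = 50.0,
    envelope_cutoff: float = 5.0,
    tonic_window_ms: float = 300.0,
) -> PreprocessedStudy:
    """Simulate every trial and reduce it to per-subject envelope matrices.

    For each subject and target: filter, envelope, segment the outward
    movement from the forearm speed proxy, subtract the tonic baseline,
    resample to 200 samples, normalize by the average trial maxima and
    average the trials; concatenate the 8 targets into ``X``.  Also collects
    per-target RMS activity and kinematic COV tables.
    """
    if gt is None:
        gt = synthgen.make_ground_truth(config)
    rest_win = synthgen.rest_window_kin(config)
    search_win = synthgen.search_window_kin(config, "out")
    fs = config.sampling_rate_emg
    fs_kin = config.sampling_rate_kin

    X_by_subject: dict[str, pp.EnvelopeMatrix] = {}
    rms_rows, cov_rows = [], []
    b1, b2, _, _ = config.period_boundaries_s
    cov_window = (int(round(b1 * fs_kin)), int(round(b2 * fs_kin)))

    for s in range(config.n_subjects):
        sid = config.subject_id(s)
        per_target, divisors = [], []
        for tgt in range(config.n_targets):
            trial_envs = []
            for tr in range(config.n_trials_per_target):
                bundle = synthgen.synthesize_trial(gt, s, tgt, tr, config)
                filtered = pp.bandpass_then_highpass(
                    bundle.emg, band=band, highpass=highpass
                )
                seg = pp.segment_movement(
                    bundle.kinematics,
                    rest_win,
                    emg_rate=fs,
                    search_window=search_win,
                    phase="out",
                    criterion=segmentation_criterion,
                )
                env = pp.envelope(
                    filtered.data, fs, cutoff=envelope_cutoff
                )
                env = pp.tonic_subtract(env, seg, fs, win_ms=tonic_window_ms)
                trial_envs.append(pp.resample_movement(env, seg))
                if tr == 0:
                    covs = pp.kinematic_cov(bundle.kinematics, cov_window)
                    for (sensor, var), val in covs.items():
                        cov_rows.append((sid, sensor, var, tgt, val))
            avg, divisor = _normalize_average(
                trial_envs, config.muscle_names, norm_mode
            )
            per_target.append(avg)
            divisors.append(divisor)
            for mi, muscle in enumerate(config.muscle_names):
                rms_rows.append(
                    (sid, muscle, tgt, float(pp.rms_activity(avg)[mi]))
                )
        X_by_subject[sid] = pp.assemble_X(
            per_target,
            config.muscle_names,
            norm_constants=np.stack(divisors),
            provenance={
                "filters": "BP 10-450 Hz (2nd) + HP 50 Hz (2nd) + LP 5 Hz "
                           "(4th), zero-phase",
                "normalization": norm_mode,
                "trials_averaged": config.n_trials_per_target,
            },
        )
    rms_table = pd.DataFrame(
        rms_rows, columns=["subject", "muscle", "target", "rms"]
    )
    cov_table = pd.DataFrame(
        cov_rows, columns=["subject", "sensor", "variable", "target", "cov"]
    )
    return PreprocessedStudy(
        config=config,
        ground_truth=gt,
        X_by_subject=X_by_subject,
        rms_table=rms_table,
        cov_table=cov_table,
    )


def _subject_seed(seed: int, tag: int, index: int) -> int:
    return int(
        np.random.SeedSequence([seed, tag, index]).generate_state(1)[0] % (2**31)
    )


def extract_study(
    X_by_subject: dict[str, pp.EnvelopeMatrix],
    k_range=tuple(range(1, 13)),
    n_restarts: int = 10,
    seed: int = 0,
    force_k: int | None = None,
    sweep: bool = True,
    dominance_fraction: float = 0.3,
) -> ExtractionResult:
    """VAF sweep, dimensionality selection, shared-k extraction and matching.

    When ``sweep`` is false the per-subject VAF curves are skipped and
    ``force_k`` (required) is extracted directly — the mode used when a
    common dimensionality is imposed on all subjects.
    """
    subjects = list(X_by_subject)
    curves: dict[str, synergy.VAFCurve] = {}
    k_per_subject: dict[str, int] = {}
    if sweep:
        for i, sid in enumerate(subjects):
            curves[sid] = synergy.vaf_curve(
                X_by_subject[sid],
                k_range=k_range,
                n_restarts=n_restarts,
                seed=_subject_seed(seed, 310, i),
            )
        k_selected = synergy.select_dim_inflexion(
            list(curves.values()), mode="averaged"
        )
        per_subject = synergy.select_dim_inflexion(
            list(curves.values()), mode="per_subject"
        )
        k_per_subject = dict(zip(subjects, per_subject))
    else:
        if force_k is None:
            raise ValueError("force_k required when sweep is disabled")
        k_selected = force_k
    k_shared = force_k if force_k is not None else k_selected

    decomps = {
        sid: synergy.nmf_factorize(
            X_by_subject[sid],
            k_shared,
            n_restarts=n_restarts,
            seed=_subject_seed(seed, 311, i),
        )
        for i, sid in enumerate(subjects)
    }
    match = synergy.match_modules(decomps)
    weightings: dict[str, np.ndarray] = {}
    dominance: dict[str, synergy.DominanceLabeling] = {}
    for sid in subjects:
        matched = synergy.reorder_to_reference(decomps[sid], match.mapping[sid])
        weightings[sid] = matched.S
        muscle_labels = X_by_subject[sid].muscle_labels
        dominance[sid] = synergy.label_dominant(
            matched.S, dominance_fraction, muscle_labels
        )
    module_names = tuple(chr(ord("A") + j) for j in range(k_shared))
    return ExtractionResult(
        curves=curves,
        k_selected=k_selected,
        k_per_subject=k_per_subject,
        decomps=decomps,
        match=match,
        weightings=weightings,
        dominance=dominance,
        module_names=module_names,
    )


def run_study(
    config: synthgen.GenerativeConfig,
    engine: str = "perm",
    n_perm: int = 1000,
    n_grids: int | None = None,
    seed: int | None = None,
    sweep: bool = True,
    force_k: int | None = None,
    k_range=tuple(range(1, 13)),
    n_restarts: int = 10,
    tp_table: tpstats.TPTable | None = None,
) -> StudyResult:
    """Full pipeline on one synthetic study.

    ``sweep=False`` with ``force_k`` skips the dimensionality sweep (used for
    replicate studies where the shared k is imposed).  ``n_grids`` enables
    the random-grid robustness test.  ``tp_table`` anchors the study on a
    fixed TP grid instead of drawing labels.
    """
    seed = config.seed if seed is None else seed
    gt = synthgen.make_ground_truth(config, tp_table=tp_table)
    pre = preprocess_study(config, gt)
    extraction = extract_study(
        pre.X_by_subject,
        k_range=k_range,
        n_restarts=n_restarts,
        seed=seed,
        force_k=force_k,
        sweep=sweep,
    )
    table = pre.ground_truth.tp_table
    obs = tpstats.assemble_observations(
        extraction.weightings, extraction.dominance, table,
        extraction.module_names,
    )
    contrast = tpstats.weighting_contrast(
        obs, engine=engine, n_perm=n_perm, seed=seed, table=table
    )
    dim_res = None
    if sweep and extraction.k_per_subject:
        dim_res = tpstats.dim_regression(extraction.k_per_subject, table)
    grid_res = None
    if n_grids:
        grid_res = tpstats.random_grid_null(
            obs, table, contrast, n_grids=n_grids, seed=seed
        )
    return StudyResult(
        preprocessed=pre,
        extraction=extraction,
        observations=obs,
        contrast=contrast,
        dim_regression=dim_res,
        grid_null=grid_res,
    )


def matched_ndp_to_truth(
    extraction: ExtractionResult, gt: synthgen.GroundTruth
) -> float:
    """Mean NDP between recovered and generative modules, after optimally
    assigning recovered modules to true modules per subject."""
    from scipy.optimize import linear_sum_assignment

    vals = []
    for sid, S in extraction.weightings.items():
        k = min(S.shape[1], gt.S_true.shape[1])
        M = np.array(
            [
                [synergy.ndp(gt.S_true[:, i], S[:, j]) for j in range(S.shape[1])]
                for i in range(gt.S_true.shape[1])
            ]
        )
        rows, cols = linear_sum_assignment(-M)
        vals.extend(M[rows[:k], cols[:k]].tolist())
    return float(np.mean(vals))
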