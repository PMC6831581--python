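"""Trigger-point tables and all TP-association statistics.

Houses the subject × muscle trigger-point grid (ACT / LAT / NO), assembles
the long-format observation table coupling each muscle's weighting
coefficient with its TP status and its dominance condition within each
module, and runs the association statistics:

* mixed-effects contrast of weighting coefficients (TP presence × muscle
  condition fixed effects, subject and muscle random effects), with a
  permutation engine as the assumption-free reference;
* RMS "muscle activity" model (TP × muscle × target interaction test);
* kinematic COV model (active-TP group effect per kinematic variable);
* dimensionality regressions (per-subject module count vs TP burden);
* the random-TP-grid robustness test: regenerate the TP grid many times
  with the observed ACT/LAT totals preserved and count how often the key
  contrast lands inside the original 95 % CI.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from synreach.muscles import MUSCLES, TP_LEVELS
from synreach.synergy import DominanceLabeling

logger = logging.getLogger(__name__)

OBS_COLUMNS = (
    "subject", "muscle", "module", "weighting", "tp_status", "condition",
)


class TPStatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# TP table
# ---------------------------------------------------------------------------

@dataclass
class TPTable:
    """Subject × muscle grid of trigger-point statuses."""

    grid: pd.DataFrame  # index: subject ids, columns: muscles, values in TP_LEVELS

    def __post_init__(self) -> None:
        bad = set(np.unique(self.grid.to_numpy())) - set(TP_LEVELS)
        if bad:
            raise TPStatsError(f"invalid TP status value(s): {sorted(bad)}")

    @classmethod
    def from_grid(
        cls, subjects: Sequence[str], muscles: Sequence[str], status
    ) -> "TPTable":
        return cls(
            pd.DataFrame(
                np.asarray(status, dtype=object),
                index=list(subjects),
                columns=list(muscles),
            )
        )

    @property
    def subjects(self) -> list[str]:
        return list(self.grid.index)

    @property
    def muscles(self) -> list[str]:
        return list(self.grid.columns)

    @property
    def n_cells(self) -> int:
        return int(self.grid.size)

    def status(self, subject: str, muscle: str) -> str:
        return str(self.grid.loc[subject, muscle])

    def to_long(self) -> pd.DataFrame:
        long = self.grid.stack().rename("status").reset_index()
        long.columns = ["subject", "muscle", "status"]
        return long

    def to_file(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    def with_labels(self, labels: Sequence[str]) -> "TPTable":
        """Copy of the table with cell statuses replaced row-major by
        ``labels`` (used by the random-grid generator)."""
        arr = np.asarray(labels, dtype=object).reshape(self.grid.shape)
        return TPTable.from_grid(self.subjects, self.muscles, arr)


def load_tp_table(
    path,
    muscles: Sequence[str] = MUSCLES,
    subjects: Sequence[str] | None = None,
) -> TPTable:
    """Read a delimited TP listing (columns subject, muscle, status).

    Each row assigns one muscle's status for one subject; any (subject,
    muscle) cell not listed defaults to NO, so files may list only the ACT
    and LAT findings.  Unknown muscle names and conflicting duplicate
    listings (the same muscle both ACT and LAT for one subject) are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject", "muscle", "status"}
    if not required.issubset(df.columns):
        raise TPStatsError(
            f"TP file {path} must have columns {sorted(required)}"
        )
    muscles = list(muscles)
    unknown = set(df["muscle"]) - set(muscles)
    if unknown:
        raise TPStatsError(f"unknown muscle label(s): {sorted(unknown)}")
    bad_status = set(df["status"]) - set(TP_LEVELS)
    if bad_status:
        raise TPStatsError(f"unknown status value(s): {sorted(bad_status)}")
    dup = df.groupby(["subject", "muscle"])["status"].nunique()
    conflicts = dup[dup > 1]
    if len(conflicts):
        key = conflicts.index[0]
        raise TPStatsError(
            f"subject {key[0]} lists muscle {key[1]} with conflicting statuses"
        )
    subj = list(subjects) if subjects is not None else sorted(df["subject"].unique())
    grid = pd.DataFrame("NO", index=subj, columns=muscles, dtype=object)
    for _, row in df.drop_duplicates(["subject", "muscle"]).iterrows():
        if row["subject"] not in grid.index:
            raise TPStatsError(f"subject {row['subject']} not in subject set")
        grid.loc[row["subject"], row["muscle"]] = row["status"]
    return TPTable(grid)


def bundled_palpation_path() -> Path:
    """Path of the shipped palpation-table fixture."""
    return Path(__file__).parent / "data" / "palpation_tp.tsv"


@dataclass
class TPCounts:
    """Summary counts of a TP table."""

    n_cells: int
    n_act: int
    n_lat: int
    per_muscle: pd.DataFrame   # index muscle, columns ACT, LAT
    per_subject: pd.DataFrame  # index subject, columns n_act, n_lat, profile


def count_tp(table: TPTable) -> TPCounts:
    """Totals by status, per-muscle counts and per-subject TP profile."""
    arr = table.grid.to_numpy()
    per_muscle = pd.DataFrame(
        {
            "ACT": (arr == "ACT").sum(axis=0),
            "LAT": (arr == "LAT").sum(axis=0),
        },
        index=table.muscles,
    )
    n_act_s = (arr == "ACT").sum(axis=1)
    n_lat_s = (arr == "LAT").sum(axis=1)
    profile = np.where(
        (n_act_s > 0) & (n_lat_s > 0),
        "both",
        np.where(
            n_act_s > 0,
            "active-only",
            np.where(n_lat_s > 0, "latent-only", "none"),
        ),
    )
    per_subject = pd.DataFrame(
        {"n_act": n_act_s, "n_lat": n_lat_s, "profile": profile},
        index=table.subjects,
    )
    return TPCounts(
        n_cells=table.n_cells,
        n_act=int(per_muscle["ACT"].sum()),
        n_lat=int(per_muscle["LAT"].sum()),
        per_muscle=per_muscle,
        per_subject=per_subject,
    )


# ---------------------------------------------------------------------------
# Observation assembly
# ---------------------------------------------------------------------------

def assemble_observations(
    weightings: Mapping[str, np.ndarray],
    dominance: Mapping[str, DominanceLabeling],
    table: TPTable,
    module_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Long observation table: one row per subject × muscle × module.

    ``weightings[s]`` is subject ``s``'s matched muscles × k weighting matrix
    (module order aligned across subjects); ``dominance[s]`` the matching
    dominance grid.  TP status is constant across a subject-muscle's rows.
    """
    muscles = table.muscles
    rows = []
    for s in table.subjects:
        if s not in weightings or s not in dominance:
            raise TPStatsError(f"missing weightings/dominance for subject {s}")
        S = np.asarray(weightings[s], dtype=float)
        dom = dominance[s].dominant
        if S.shape[0] != len(muscles) or dom.shape != S.shape:
            raise TPStatsError(f"shape mismatch for subject {s}")
        k = S.shape[1]
        names = (
            list(module_names)
            if module_names is not None
            else [chr(ord("A") + j) for j in range(k)]
        )
        for mi, muscle in enumerate(muscles):
            status = table.status(s, muscle)
            for j in range(k):
                rows.append(
                    (
                        s, muscle, names[j], float(S[mi, j]), status,
                        "DOMINANT" if dom[mi, j] else "NON-DOMINANT",
                    )
                )
    obs = pd.DataFrame(rows, columns=OBS_COLUMNS)
    if (obs["weighting"] < 0).any():
        raise TPStatsError("negative weighting coefficient in observations")
    return obs


# ---------------------------------------------------------------------------
# Contrast machinery
# ---------------------------------------------------------------------------

CONDITIONS = ("DOMINANT", "NON-DOMINANT")
_PAIRS = (("ACT", "LAT"), ("ACT", "NO"), ("LAT", "NO"))


@dataclass
class ContrastResult:
    """Pairwise TP-status contrasts plus model-fit metadata."""

    contrasts: pd.DataFrame
    model_info: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)
    engine: str = ""
    alpha: float = 0.05

    def contrast(self, level_1: str, level_2: str, condition: str) -> pd.Series:
        c = self.contrasts
        row = c[
            (c["level_1"] == level_1)
            & (c["level_2"] == level_2)
            & (c["condition"] == condition)
        ]
        if len(row) != 1:
            raise TPStatsError(
                f"no unique contrast {level_1}-{level_2} in {condition}"
            )
        return row.iloc[0]


class _ObsIndex:
    """Vectorized cell-mean machinery over the observation table.

    Rows are indexed by (condition, status-of-unit); units are the
    subject-muscle pairs whose TP label is the exchangeable quantity.
    """

    def __init__(self, obs: pd.DataFrame, table: TPTable):
        self.w = obs["weighting"].to_numpy(dtype=float)
        self.cond_idx = (obs["condition"] == "NON-DOMINANT").to_numpy(int)
        units = [(s, m) for s in table.subjects for m in table.muscles]
        unit_pos = {u: i for i, u in enumerate(units)}
        self.unit_idx = np.array(
            [unit_pos[(s, m)] for s, m in zip(obs["subject"], obs["muscle"])]
        )
        flat = table.grid.to_numpy().ravel()
        self.labels = np.array([TP_LEVELS.index(x) for x in flat])
        self.n_units = len(units)

    def cell_means(self, labels: np.ndarray) -> np.ndarray:
        """2 × 3 matrix of mean weighting by (condition, status); NaN for
        empty cells."""
        status_rows = labels[self.unit_idx]
        code = self.cond_idx * 3 + status_rows
        sums = np.bincount(code, weights=self.w, minlength=6)
        counts = np.bincount(code, minlength=6)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = sums / counts
        means[counts == 0] = np.nan
        return means.reshape(2, 3)

    def contrast_estimates(self, labels: np.ndarray) -> np.ndarray:
        """6-vector of pairwise status mean differences per condition, in the
        order (cond × pair) of ``CONDITIONS`` × ``_PAIRS``."""
        m = self.cell_means(labels)
        out = np.empty(6)
        for ci in range(2):
            for pi, (a, b) in enumerate(_PAIRS):
                out[ci * 3 + pi] = (
                    m[ci, TP_LEVELS.index(a)] - m[ci, TP_LEVELS.index(b)]
                )
        return out


def _check_design(obs: pd.DataFrame) -> None:
    ok = False
    for cond in CONDITIONS:
        sub = obs[obs["condition"] == cond]
        counts = sub["tp_status"].value_counts()
        if (counts >= 2).sum() >= 2:
            ok = True
    if not ok:
        raise TPStatsError(
            "degenerate design: need >= 2 TP levels with >= 2 observations "
            "each in some condition"
        )


def _table_from_obs(obs: pd.DataFrame) -> TPTable:
    cells = obs.drop_duplicates(["subject", "muscle"])
    conflicting = obs.groupby(["subject", "muscle"])["tp_status"].nunique()
    if (conflicting > 1).any():
        raise TPStatsError("inconsistent TP status within a subject-muscle")
    subjects = sorted(obs["subject"].unique())
    muscles = list(dict.fromkeys(obs["muscle"]))
    grid = pd.DataFrame("NO", index=subjects, columns=muscles, dtype=object)
    for _, row in cells.iterrows():
        grid.loc[row["subject"], row["muscle"]] = row["tp_status"]
    return TPTable(grid)


def weighting_contrast(
    obs: pd.DataFrame,
    engine: str = "mixed",
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    include_module: bool = True,
    table: TPTable | None = None,
) -> ContrastResult:
    """Pairwise TP-status contrasts of weighting coefficients per condition.

    ``engine="mixed"`` fits a linear mixed model (ML) with TP presence ×
    muscle condition (and optionally module) as fixed effects and crossed
    subject and muscle variance components, screens fixed effects for
    collinearity (VIF >= 2 drops the module predictor, as in the published
    protocol), compares the models with/without module by likelihood ratio
    and AIC, and reports Wald least-squares-mean contrasts with 95 % CIs
    (normal approximation in place of Kenward–Roger degrees of freedom).

    ``engine="perm"`` reports the same cell-mean contrasts with p-values and
    CIs from shuffling TP status across subject-muscle units.
    """
    _check_design(obs)
    if table is None:
        table = _table_from_obs(obs)
    if engine == "perm":
        return _perm_contrast(obs, table, n_perm=n_perm, seed=seed, alpha=alpha)
    if engine == "mixed":
        return _mixed_contrast(obs, alpha=alpha, include_module=include_module)
    raise TPStatsError(f"unknown engine {engine!r}")


def _perm_contrast(
    obs: pd.DataFrame,
    table: TPTable,
    n_perm: int,
    seed: int,
    alpha: float,
) -> ContrastResult:
    idx = _ObsIndex(obs, table)
    observed = idx.contrast_estimates(idx.labels)
    rng = np.random.default_rng([seed, 880])
    perms = np.empty((n_perm, 6))
    for b in range(n_perm):
        perms[b] = idx.contrast_estimates(rng.permutation(idx.labels))

    notes: list[str] = []
    rows = []
    for ci, cond in enumerate(CONDITIONS):
        for pi, (a, b) in enumerate(_PAIRS):
            j = ci * 3 + pi
            est = observed[j]
            col = perms[:, j]
            valid = col[np.isfinite(col)]
            if not np.isfinite(est) or valid.size == 0:
                rows.append((cond, a, b, np.nan, np.nan, np.nan, np.nan))
                notes.append(f"contrast {a}-{b} in {cond} undefined (empty cell)")
                continue
            n_invalid = n_perm - valid.size
            if n_invalid:
                notes.append(
                    f"{n_invalid} permutations degenerate for {a}-{b} in {cond}"
                )
            p = (1.0 + np.sum(np.abs(valid) >= abs(est))) / (valid.size + 1.0)
            centered = valid - valid.mean()
            lo, hi = np.quantile(centered, [alpha / 2, 1 - alpha / 2])
            rows.append((cond, a, b, est, est + lo, est + hi, p))
    contrasts = pd.DataFrame(
        rows,
        columns=["condition", "level_1", "level_2", "estimate",
                 "ci_low", "ci_high", "p"],
    )
    return ContrastResult(
        contrasts=contrasts,
        model_info={"n_perm": n_perm, "n_units": idx.n_units},
        notes=notes,
        engine="perm",
        alpha=alpha,
    )


def _fixed_design(formula: str, df: pd.DataFrame):
    import patsy

    return patsy.dmatrices(formula, df, return_type="dataframe")


def _term_vifs(X: pd.DataFrame) -> dict[str, float]:
    """Max column-wise VIF per patsy term (intercept excluded)."""
    di = X.design_info
    A = X.to_numpy()
    n, p = A.shape
    vifs_col = np.full(p, np.nan)
    for j in range(p):
        if di.column_names[j] == "Intercept":
            continue
        others = np.delete(A, j, axis=1)
        beta, *_ = np.linalg.lstsq(others, A[:, j], rcond=None)
        resid = A[:, j] - others @ beta
        tss = np.sum((A[:, j] - A[:, j].mean()) ** 2)
        rss = np.sum(resid**2)
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        vifs_col[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    out = {}
    for term, sl in di.term_name_slices.items():
        if term == "Intercept":
            continue
        cols = vifs_col[sl]
        out[term] = float(np.nanmax(cols)) if cols.size else np.nan
    return out


def _fit_mixedlm(formula: str, df: pd.DataFrame, vc: dict[str, str]):
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula,
            df,
            groups=np.ones(len(df)),
            vc_formula=vc,
            re_formula="0",
        )
        return model, model.fit(reml=False, maxiter=200)


def _mixed_contrast(
    obs: pd.DataFrame, alpha: float, include_module: bool
) -> ContrastResult:
    import patsy
    from scipy.stats import norm

    df = obs.rename(columns={"weighting": "y"}).copy()
    base = "y ~ C(tp_status) * C(condition)"
    full_formula = base + " + C(module)" if include_module else base
    notes: list[str] = []

    vc = {"subject": "0 + C(subject)", "muscle": "0 + C(muscle)"}
    model_full, fit_full = _fit_mixedlm(full_formula, df, vc)
    model_red, fit_red = _fit_mixedlm(base, df, vc)

    _, X_full = _fixed_design(full_formula, df)
    vifs = _term_vifs(X_full)
    dropped = []
    retained_formula, retained_fit, retained_model = full_formula, fit_full, model_full
    if include_module and vifs.get("C(module)", 0.0) >= 2.0:
        dropped.append("C(module)")
        retained_formula, retained_fit, retained_model = base, fit_red, model_red
        notes.append(
            f"C(module) dropped: VIF {vifs['C(module)']:.2f} >= 2"
        )

    # Zero-variance random effects are dropped and the model refit.
    vcomp = dict(zip(retained_model.exog_vc.names, retained_fit.vcomp))
    dead = [k for k, v in vcomp.items() if v < 1e-8]
    if dead:
        vc_kept = {k: v for k, v in vc.items() if k not in dead}
        notes.append(
            f"random effect variance ~0 for {dead}; component(s) dropped"
        )
        if vc_kept:
            retained_model, retained_fit = _fit_mixedlm(
                retained_formula, df, vc_kept
            )
            vcomp = dict(
                zip(retained_model.exog_vc.names, retained_fit.vcomp)
            )
        else:
            vcomp = {}

    lr = 2.0 * (fit_full.llf - fit_red.llf)
    lr_df = fit_full.df_modelwc - fit_red.df_modelwc
    lr_p = float(stats.chi2.sf(max(lr, 0.0), lr_df)) if lr_df > 0 else np.nan

    # Least-squares-mean contrasts from the retained model.
    di = patsy.dmatrices(retained_formula, df, return_type="dataframe")[1].design_info
    k_fe = len(di.column_names)
    fe = np.asarray(retained_fit.params)[:k_fe]
    cov = np.asarray(retained_fit.cov_params())[:k_fe, :k_fe]
    module0 = sorted(df["module"].unique())[0]

    def cell_row(status: str, condition: str) -> np.ndarray:
        new = pd.DataFrame(
            {"tp_status": [status], "condition": [condition],
             "module": [module0]}
        )
        return np.asarray(patsy.build_design_matrices([di], new)[0])[0]

    present = {
        (s, c): ((df["tp_status"] == s) & (df["condition"] == c)).any()
        for s in TP_LEVELS
        for c in CONDITIONS
    }
    z = norm.ppf(1 - alpha / 2)
    rows = []
    for cond in CONDITIONS:
        for a, b in _PAIRS:
            if not (present[(a, cond)] and present[(b, cond)]):
                rows.append((cond, a, b, np.nan, np.nan, np.nan, np.nan))
                notes.append(f"contrast {a}-{b} in {cond} undefined (empty cell)")
                continue
            d = cell_row(a, cond) - cell_row(b, cond)
            est = float(d @ fe)
            se = float(np.sqrt(d @ cov @ d))
            p = float(2 * norm.sf(abs(est) / se)) if se > 0 else np.nan
            rows.append((cond, a, b, est, est - z * se, est + z * se, p))
    contrasts = pd.DataFrame(
        rows,
        columns=["condition", "level_1", "level_2", "estimate",
                 "ci_low", "ci_high", "p"],
    )

    # Variance partition (marginal/conditional R^2, Nakagawa-style).
    X_ret = patsy.build_design_matrices([di], df)[0]
    var_f = float(np.var(np.asarray(X_ret) @ fe))
    var_re = float(sum(vcomp.values()))
    var_res = float(retained_fit.scale)
    total = var_f + var_re + var_res
    key = contrasts[
        (contrasts["level_1"] == "ACT")
        & (contrasts["level_2"] == "NO")
        & (contrasts["condition"] == "DOMINANT")
    ]["estimate"]
    es = (
        float(key.iloc[0]) / np.sqrt(total)
        if len(key) and np.isfinite(key.iloc[0]) and total > 0
        else np.nan
    )

    model_info = {
        "aic_full": float(fit_full.aic),
        "aic_reduced": float(fit_red.aic),
        "lr_stat": float(lr),
        "lr_df": int(lr_df),
        "lr_p": lr_p,
        "vif": vifs,
        "dropped_terms": dropped,
        "vcomp": {k: float(v) for k, v in vcomp.items()},
        "resid_var": var_res,
        "marginal_r2": var_f / total if total > 0 else np.nan,
        "conditional_r2": (var_f + var_re) / total if total > 0 else np.nan,
        "effect_size": es,
        "converged": bool(getattr(retained_fit, "converged", True)),
    }
    return ContrastResult(
        contrasts=contrasts,
        model_info=model_info,
        notes=notes,
        engine="mixed",
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# RMS model
# ---------------------------------------------------------------------------

def _pruned_dmatrix(formula: str, df: pd.DataFrame) -> tuple[np.ndarray, int]:
    """Patsy design with empty/collinear columns removed; returns (X, rank)."""
    import patsy

    X = np.asarray(patsy.dmatrix(formula, df))
    keep = ~np.all(X == 0, axis=0)
    X = X[:, keep]
    q, r, piv = _qr_pivot(X)
    tol = np.abs(r).max() * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(np.abs(np.diag(r)) > tol))
    cols = np.sort(piv[:rank])
    return X[:, cols], rank


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def rms_model(
    rms_df: pd.DataFrame,
    table: TPTable,
    engine: str = "mixed",
    n_perm: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
) -> ContrastResult:
    """Does TP status interact with muscle and target in shaping RMS activity?

    ``rms_df`` has one row per subject × muscle × target with column ``rms``.
    The mixed engine fits TP × muscle × target fixed effects with a random
    subject intercept (ML) and reports the likelihood-ratio test of the
    interaction structure against the additive model, plus pairwise marginal
    TP contrasts from the additive fit.  The permutation engine permutes TP
    labels over subject-muscle units and uses the OLS sum-of-squares
    reduction as the test statistic.
    """
    df = rms_df.copy()
    df["tp_status"] = [
        table.status(s, m) for s, m in zip(df["subject"], df["muscle"])
    ]
    y = df["rms"].to_numpy(dtype=float)

    full_f = "0 + C(tp_status):C(muscle):C(target)"
    red_f = "C(tp_status) + C(muscle) + C(target)"

    if engine == "perm":
        return _rms_perm(df, y, table, full_f, red_f, n_perm, seed, alpha)
    if engine != "mixed":
        raise TPStatsError(f"unknown engine {engine!r}")

    import statsmodels.api as sm

    X_full, rank_full = _pruned_dmatrix(full_f, df)
    X_red, rank_red = _pruned_dmatrix(red_f, df)
    groups = df["subject"].to_numpy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit_full = sm.MixedLM(y, X_full, groups=groups).fit(
            reml=False, maxiter=200
        )
        fit_red = sm.MixedLM(y, X_red, groups=groups).fit(
            reml=False, maxiter=200
        )
    lr = 2.0 * (fit_full.llf - fit_red.llf)
    lr_df = rank_full - rank_red
    lr_p = float(stats.chi2.sf(max(lr, 0.0), lr_df)) if lr_df > 0 else np.nan

    rows = []
    means = df.groupby("tp_status")["rms"].mean()
    for a, b in _PAIRS:
        if a in means.index and b in means.index:
            est = float(means[a] - means[b])
        else:
            est = np.nan
        rows.append(("ALL", a, b, est, np.nan, np.nan, np.nan))
    contrasts = pd.DataFrame(
        rows,
        columns=["condition", "level_1", "level_2", "estimate",
                 "ci_low", "ci_high", "p"],
    )
    return ContrastResult(
        contrasts=contrasts,
        model_info={
            "aic_full": float(fit_full.aic),
            "aic_reduced": float(fit_red.aic),
            "lr_stat": float(lr),
            "lr_df": int(lr_df),
            "lr_p": lr_p,
            "n_rows": int(len(df)),
        },
        engine="mixed",
        alpha=alpha,
    )


def _rms_perm(df, y, table, full_f, red_f, n_perm, seed, alpha):
    def stat(frame: pd.DataFrame) -> float:
        # Full model = observed-cell means; reduced = additive OLS.
        cells = frame.groupby(["tp_status", "muscle", "target"])["rms"]
        rss_full = float(((frame["rms"] - cells.transform("mean")) ** 2).sum())
        X_red, _ = _pruned_dmatrix(red_f, frame)
        beta, *_ = np.linalg.lstsq(X_red, y, rcond=None)
        rss_red = float(np.sum((y - X_red @ beta) ** 2))
        return (rss_red - rss_full) / max(rss_full, 1e-300)

    observed = stat(df)
    units = df.drop_duplicates(["subject", "muscle"])[["subject", "muscle"]]
    unit_status = np.array(
        [table.status(s, m) for s, m in zip(units["subject"], units["muscle"])],
        dtype=object,
    )
    key = list(zip(units["subject"], units["muscle"]))
    pos = {u: i for i, u in enumerate(key)}
    row_unit = np.array([pos[(s, m)] for s, m in zip(df["subject"], df["muscle"])])
    rng = np.random.default_rng([seed, 881])
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(unit_status)
        frame = df.copy()
        frame["tp_status"] = perm[row_unit]
        if stat(frame) >= observed:
            count += 1
    p = (1.0 + count) / (n_perm + 1.0)
    contrasts = pd.DataFrame(
        [("ALL", "interaction", "additive", observed, np.nan, np.nan, p)],
        columns=["condition", "level_1", "level_2", "estimate",
                 "ci_low", "ci_high", "p"],
    )
    return ContrastResult(
        contrasts=contrasts,
        model_info={"n_perm": n_perm, "statistic": observed, "p": p},
        engine="perm",
        alpha=alpha,
    )


# ---------------------------------------------------------------------------
# Kinematic COV model
# ---------------------------------------------------------------------------

@dataclass
class KinematicModelResult:
    """Per-variable group tests and a per-(variable, sensor) breakdown."""

    tests: pd.DataFrame      # variable, chi2, df, p
    by_sensor: pd.DataFrame  # variable, sensor, mean_act, mean_no, diff, p
    notes: list[str] = field(default_factory=list)


def dichotomize_act(table: TPTable) -> pd.Series:
    """ACT/NO group per subject: ACT if the subject hosts any active TP."""
    arr = table.grid.to_numpy()
    has_act = (arr == "ACT").any(axis=1)
    return pd.Series(
        np.where(has_act, "ACT", "NO"), index=table.subjects, name="group"
    )


def kinematic_model(
    cov_df: pd.DataFrame,
    table: TPTable,
    alpha: float = 0.05,
) -> KinematicModelResult:
    """Test whether active-TP subjects moved differently, per kinematic
    variable.

    ``cov_df`` has one row per subject × sensor × variable × target with
    column ``cov``.  For each variable a mixed model with the ACT/NO group as
    the fixed effect and subject, target and sensor variance components is
    compared to its null by likelihood ratio (χ², 1 df); a non-significant
    test indicates no kinematic alteration.  Undefined COV cells are excluded
    with a log entry.  ``by_sensor`` breaks the group difference down per
    sensor (Welch t).
    """
    notes: list[str] = []
    df = cov_df.copy()
    n_bad = int(df["cov"].isna().sum())
    if n_bad:
        notes.append(f"{n_bad} undefined COV cells excluded")
        logger.info("kinematic_model: %d undefined COV cells excluded", n_bad)
        df = df.dropna(subset=["cov"])
    groups = dichotomize_act(table)
    df["group"] = df["subject"].map(groups)

    test_rows = []
    for var, sub in df.groupby("variable", sort=True):
        chi2, p = _group_lr(sub, notes, var)
        test_rows.append((var, chi2, 1, p))
    tests = pd.DataFrame(test_rows, columns=["variable", "chi2", "df", "p"])

    sens_rows = []
    for (var, sensor), sub in df.groupby(["variable", "sensor"], sort=True):
        a = sub.loc[sub["group"] == "ACT", "cov"].to_numpy()
        b = sub.loc[sub["group"] == "NO", "cov"].to_numpy()
        if a.size >= 2 and b.size >= 2:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            sens_rows.append(
                (var, sensor, a.mean(), b.mean(), a.mean() - b.mean(), float(p))
            )
        else:
            sens_rows.append((var, sensor, np.nan, np.nan, np.nan, np.nan))
    by_sensor = pd.DataFrame(
        sens_rows,
        columns=["variable", "sensor", "mean_act", "mean_no", "diff", "p"],
    )
    return KinematicModelResult(tests=tests, by_sensor=by_sensor, notes=notes)


def _group_lr(sub: pd.DataFrame, notes: list[str], var: str) -> tuple[float, float]:
    vc = {
        "subject": "0 + C(subject)",
        "target": "0 + C(target)",
        "sensor": "0 + C(sensor)",
    }
    frame = sub.rename(columns={"cov": "y"})
    try:
        _, fit1 = _fit_mixedlm("y ~ C(group)", frame, vc)
        _, fit0 = _fit_mixedlm("y ~ 1", frame, vc)
        chi2 = 2.0 * (fit1.llf - fit0.llf)
    except Exception as exc:  # pragma: no cover - fit pathologies
        notes.append(f"{var}: mixed fit failed ({exc}); OLS fallback")
        a = frame.loc[frame["group"] == "ACT", "y"]
        b = frame.loc[frame["group"] == "NO", "y"]
        if len(a) < 2 or len(b) < 2:
            return np.nan, np.nan
        t, p = stats.ttest_ind(a, b, equal_var=False)
        return float(t**2), float(p)
    return float(chi2), float(stats.chi2.sf(max(chi2, 0.0), 1))


# ---------------------------------------------------------------------------
# Dimensionality regressions
# ---------------------------------------------------------------------------

@dataclass
class DimRegressionResult:
    """Pearson correlations of per-subject dimensionality with TP burden."""

    r_total: float
    p_total: float
    r_active: float
    p_active: float
    n: int
    undefined: list[str] = field(default_factory=list)


def dim_regression(
    k_by_subject: Mapping[str, int], table: TPTable
) -> DimRegressionResult:
    """Correlate per-subject module count with total TPs and ACT presence."""
    subjects = [s for s in table.subjects if s in k_by_subject]
    if len(subjects) < 3:
        raise TPStatsError("need at least 3 subjects for the regression")
    counts = count_tp(table).per_subject.loc[subjects]
    ks = np.array([float(k_by_subject[s]) for s in subjects])
    total = (counts["n_act"] + counts["n_lat"]).to_numpy(dtype=float)
    act = (counts["n_act"] > 0).to_numpy(dtype=float)

    undefined: list[str] = []

    def corr(x, y, name):
        if np.std(x) == 0 or np.std(y) == 0:
            undefined.append(name)
            return np.nan, np.nan
        r, p = stats.pearsonr(x, y)
        return float(r), float(p)

    r_t, p_t = corr(ks, total, "total")
    r_a, p_a = corr(ks, act, "active")
    return DimRegressionResult(
        r_total=r_t, p_total=p_t, r_active=r_a, p_active=p_a,
        n=len(subjects), undefined=undefined,
    )


# ---------------------------------------------------------------------------
# Random-grid robustness test
# ---------------------------------------------------------------------------

@dataclass
class GridNullResult:
    """Outcome of the random-TP-grid robustness test."""

    n_grids: int
    estimates: np.ndarray
    n_within: int
    fraction: float
    passed: bool
    ci: tuple[float, float]
    n_resampled: int = 0

    def __post_init__(self) -> None:
        assert self.n_within <= self.n_grids


def random_grid_null(
    obs: pd.DataFrame,
    table: TPTable,
    reference: ContrastResult,
    n_grids: int = 2000,
    seed: int = 0,
    mode: str = "uniform",
    level_1: str = "ACT",
    level_2: str = "NO",
    condition: str = "DOMINANT",
    max_resample: int = 100,
) -> GridNullResult:
    """Re-run the key contrast under randomly regenerated TP grids.

    Each grid redistributes the observed ACT and LAT cells over the subject ×
    muscle grid — uniformly over all cells by default (``mode="uniform"``),
    or within each muscle column (``mode="per_muscle"``), preserving the
    observed totals exactly in both cases.  A grid counts as "similar" when
    its ``level_1 - level_2`` mean difference in ``condition`` lies inside
    the original contrast's 95 % CI; the association is considered robust
    when fewer than 5 % of grids are similar.  Grids yielding a degenerate
    (empty-cell) design are resampled, with the count reported.
    """
    ref = reference.contrast(level_1, level_2, condition)
    ci = (float(ref["ci_low"]), float(ref["ci_high"]))
    if not np.all(np.isfinite(ci)):
        raise TPStatsError("reference contrast has no finite 95% CI")
    idx = _ObsIndex(obs, table)
    slot = (
        CONDITIONS.index(condition) * 3
        + _PAIRS.index((level_1, level_2))
    )
    labels = idx.labels
    n_subj = len(table.subjects)
    n_musc = len(table.muscles)
    rng = np.random.default_rng([seed, 882])

    def draw() -> np.ndarray:
        if mode == "identity":  # degenerate control: grids equal the original
            return labels.copy()
        if mode == "uniform":
            return rng.permutation(labels)
        if mode == "per_muscle":
            grid = labels.reshape(n_subj, n_musc).copy()
            for j in range(n_musc):
                grid[:, j] = rng.permutation(grid[:, j])
            return grid.ravel()
        raise TPStatsError(f"unknown grid mode {mode!r}")

    estimates = np.empty(n_grids)
    n_resampled = 0
    for g in range(n_grids):
        md = idx.contrast_estimates(draw())[slot]
        tries = 0
        while not np.isfinite(md):
            tries += 1
            n_resampled += 1
            if tries > max_resample:
                raise TPStatsError("random grids persistently degenerate")
            md = idx.contrast_estimates(draw())[slot]
        estimates[g] = md
    if n_resampled:
        logger.info("random_grid_null: %d degenerate grids resampled", n_resampled)
    within = (estimates >= ci[0]) & (estimates <= ci[1])
    n_within = int(within.sum())
    fraction = n_within / n_grids
    return GridNullResult(
        n_grids=n_grids,
        estimates=estimates,
        n_within=n_within,
        fraction=fraction,
        passed=fraction < 0.05,
        ci=ci,
        n_resampled=n_resampled,
    )
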