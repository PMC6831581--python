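"""Motor-module extraction: NMF, VAF, dimensionality, matching, dominance.

The envelope matrix is factorized as ``X ≈ S · P`` with nonnegative muscle
weightings ``S`` (muscles × k) and activation signals ``P`` (k × time) using
multiplicative updates on the Frobenius objective, started from random
nonnegative matrices and restarted several times; the restart with the best
reconstruction (highest VAF) is kept.  Dimensionality is chosen at the
inflexion point of the VAF-versus-k curve; modules are matched across
subjects by maximizing the total normalized dot product under a one-to-one
assignment; a muscle is *dominant* in a module when its weighting reaches a
fraction (default 0.3) of the module's maximum weighting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

logger = logging.getLogger(__name__)

_EPS = 1e-12


class SynergyError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class SynergyDecomposition:
    """One NMF solution: ``S`` (muscles × k), ``P`` (k × time), and metadata.

    ``S`` columns are normalized to unit maximum (the scale is pushed into
    ``P``), so weighting coefficients are comparable across subjects.
    """

    S: np.ndarray
    P: np.ndarray
    k: int
    vaf: float
    n_restarts: int
    seed: int
    n_iterations: int

    def reconstruct(self) -> np.ndarray:
        return self.S @ self.P


@dataclass
class VAFCurve:
    """Per-k VAF for a sweep, plus the selected dimensionality (if any)."""

    ks: tuple[int, ...]
    vaf: np.ndarray
    selected_k: int | None = None
    method: str = ""

    def __post_init__(self) -> None:
        self.vaf = np.asarray(self.vaf, dtype=float)
        if len(self.ks) != self.vaf.size:
            raise SynergyError("ks and vaf length mismatch")


@dataclass
class ModuleMatch:
    """Cross-subject module correspondence against the best reference subject.

    ``mapping[s]`` is a permutation ``p`` such that subject ``s``'s module
    ``p[i]`` corresponds to reference module ``i``; ``pair_ndp[s]`` holds the
    matched per-module NDP values.
    """

    reference: str
    mapping: dict[str, tuple[int, ...]]
    pair_ndp: dict[str, np.ndarray]
    average_ndp: float


@dataclass
class DominanceLabeling:
    """Boolean muscles × k dominance grid for one subject's weightings."""

    dominant: np.ndarray
    threshold_fraction: float
    muscle_labels: tuple[str, ...] = ()

    def dominant_muscles(self, module: int) -> set[str]:
        labels = self.muscle_labels or tuple(
            str(i) for i in range(self.dominant.shape[0])
        )
        return {labels[i] for i in np.flatnonzero(self.dominant[:, module])}


# ---------------------------------------------------------------------------
# Core NMF
# ---------------------------------------------------------------------------

def compute_vaf(X: np.ndarray, Xr: np.ndarray) -> float:
    """Variance accounted for: ``1 - SSE/SST``.

    SSE is the sum of squared reconstruction errors; SST the total sum of
    squares about the grand mean of ``X``.
    """
    X = np.asarray(X, dtype=float)
    Xr = np.asarray(Xr, dtype=float)
    if X.shape != Xr.shape:
        raise SynergyError(f"shape mismatch {X.shape} vs {Xr.shape}")
    sst = float(np.sum((X - X.mean()) ** 2))
    if sst == 0.0:
        raise SynergyError("VAF undefined for a constant matrix (SST = 0)")
    sse = float(np.sum((X - Xr) ** 2))
    return 1.0 - sse / sst


def _as_array(X) -> np.ndarray:
    # Accept the EnvelopeMatrix container or a bare array.
    arr = getattr(X, "X", X)
    arr = np.asarray(arr, dtype=float)
    if arr.ndim != 2:
        raise SynergyError("X must be a 2-D matrix")
    if np.any(arr < 0):
        raise SynergyError("X must be nonnegative")
    return arr


def _mu_nmf_batch(
    X: np.ndarray,
    k: int,
    rngs: Sequence[np.random.Generator],
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Lee–Seung multiplicative updates, all restarts advanced in lockstep.

    Each restart draws its own random nonnegative initialization; updates are
    batched over the restart axis for speed.  A restart is considered
    converged when its Frobenius objective changes by less than ``tol``
    (relative) between successive checks (every 10 iterations); iteration
    stops when every restart has converged or at ``max_iter``.
    """
    m, n = X.shape
    B = len(rngs)
    scale = np.sqrt(X.mean() / k)
    W = np.stack([scale * r.random((m, k)) + _EPS for r in rngs])
    H = np.stack([scale * r.random((k, n)) + _EPS for r in rngs])
    Xb = X[None, :, :]
    prev_obj = np.full(B, np.inf)
    converged = np.zeros(B, dtype=bool)
    it = 0
    for it in range(1, max_iter + 1):
        Wt = W.transpose(0, 2, 1)
        H *= (Wt @ X) / (Wt @ W @ H + _EPS)
        Ht = H.transpose(0, 2, 1)
        W *= (Xb @ Ht) / (W @ (H @ Ht) + _EPS)
        if it % 10 == 0 or it == max_iter:
            obj = np.linalg.norm(Xb - W @ H, axis=(1, 2))
            with np.errstate(invalid="ignore"):
                rel = np.abs(prev_obj - obj) / np.where(prev_obj > 0, prev_obj, 1.0)
            converged |= np.isfinite(prev_obj) & (rel < tol)
            if converged.all():
                break
            prev_obj = obj
    return W, H, it


def nmf_factorize(
    X,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> SynergyDecomposition:
    """Best-of-restarts multiplicative-update NMF at a fixed rank ``k``.

    Each restart draws a fresh random nonnegative initialization from a
    substream of ``seed``; the restart with the highest VAF is returned.
    Deterministic given ``seed``.
    """
    A = _as_array(X)
    if k < 1:
        raise SynergyError(f"k must be >= 1, got {k}")
    if not np.any(A > 0):
        raise SynergyError("cannot factorize an all-zero matrix")
    streams = np.random.SeedSequence([seed, k]).spawn(n_restarts)
    rngs = [np.random.default_rng(ss) for ss in streams]
    Wb, Hb, its = _mu_nmf_batch(A, k, rngs, tol, max_iter)
    vafs = [compute_vaf(A, Wb[b] @ Hb[b]) for b in range(len(rngs))]
    b_best = int(np.argmax(vafs))
    vaf, W, H = vafs[b_best], Wb[b_best], Hb[b_best]
    # Normalize: unit-maximum weighting columns, scale absorbed by P.
    colmax = W.max(axis=0)
    colmax[colmax == 0] = 1.0
    W = W / colmax[None, :]
    H = H * colmax[:, None]
    return SynergyDecomposition(
        S=W, P=H, k=k, vaf=vaf, n_restarts=n_restarts, seed=seed,
        n_iterations=its,
    )


def vaf_curve(
    X,
    k_range: Sequence[int] = tuple(range(1, 13)),
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> VAFCurve:
    """Best-of-restarts VAF for each candidate dimensionality."""
    vals = [
        nmf_factorize(X, k, n_restarts=n_restarts, seed=seed, tol=tol,
                      max_iter=max_iter).vaf
        for k in k_range
    ]
    return VAFCurve(ks=tuple(int(k) for k in k_range), vaf=np.array(vals))


# ---------------------------------------------------------------------------
# Dimensionality selection
# ---------------------------------------------------------------------------

def _inflexion_point(
    ks: Sequence[int], vaf: np.ndarray, method: str, gain_threshold: float
) -> int:
    """Operationalize the "change in slope" of a VAF curve.

    ``method="second_difference"``: the selected k maximizes the drop in
    marginal VAF gain, i.e. argmax over k of (gain at k) − (gain at k+1),
    with the gain at the first k measured from VAF = 0.  Ties break toward
    the smallest k (parsimony) and are logged.

    ``method="gain_threshold"``: the first k whose *next* marginal gain falls
    below ``gain_threshold``.
    """
    v = np.concatenate([[0.0], np.asarray(vaf, dtype=float)])
    gains = np.diff(v)
    if method == "second_difference":
        drops = gains[:-1] - gains[1:]
        best = float(drops.max())
        ties = np.flatnonzero(np.isclose(drops, best, rtol=0, atol=1e-12))
        if ties.size > 1:
            logger.info(
                "inflexion tie among k=%s; choosing smallest",
                [int(ks[i]) for i in ties],
            )
        return int(ks[int(ties[0])])
    if method == "gain_threshold":
        for i in range(len(gains) - 1):
            if gains[i + 1] < gain_threshold:
                return int(ks[i])
        return int(ks[-1])
    raise SynergyError(f"unknown inflexion method {method!r}")


def select_dim_inflexion(
    curves: Sequence[VAFCurve] | VAFCurve,
    mode: str = "averaged",
    method: str = "second_difference",
    gain_threshold: float = 0.05,
):
    """Select the number of modules from one or more VAF curves.

    ``mode="averaged"`` averages the curves across subjects and returns a
    single k; ``mode="per_subject"`` applies the same rule to each curve and
    returns a list of k values.
    """
    if isinstance(curves, VAFCurve):
        curves = [curves]
    if len(curves) == 0:
        raise SynergyError("need at least one VAF curve")
    ks = curves[0].ks
    for c in curves:
        if c.ks != ks:
            raise SynergyError("VAF curves have inconsistent k grids")
    if mode == "averaged":
        mean_vaf = np.mean([c.vaf for c in curves], axis=0)
        return _inflexion_point(ks, mean_vaf, method, gain_threshold)
    if mode == "per_subject":
        return [_inflexion_point(ks, c.vaf, method, gain_threshold) for c in curves]
    raise SynergyError(f"unknown selection mode {mode!r}")


# ---------------------------------------------------------------------------
# Cross-subject matching and dominance
# ---------------------------------------------------------------------------

def ndp(u: np.ndarray, v: np.ndarray) -> float:
    """Normalized dot product (cosine similarity) of two weighting vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise SynergyError("NDP requires equal-length vectors")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise SynergyError("NDP undefined for a zero vector")
    return float(u @ v / (nu * nv))


def _ndp_matrix(S_ref: np.ndarray, S_other: np.ndarray) -> np.ndarray:
    k = S_ref.shape[1]
    M = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            M[i, j] = ndp(S_ref[:, i], S_other[:, j])
    return M


def match_modules(
    decomps: Mapping[str, SynergyDecomposition],
) -> ModuleMatch:
    """Match modules across subjects against the best reference subject.

    Every subject is iteratively used as the reference: each other subject's
    modules are assigned one-to-one to the reference modules by maximizing
    the total NDP (Hungarian algorithm), and the reference achieving the
    highest average matched NDP is retained.
    """
    subjects = list(decomps)
    if len(subjects) == 0:
        raise SynergyError("no decompositions to match")
    k = decomps[subjects[0]].k
    for s in subjects:
        if decomps[s].k != k:
            raise SynergyError(
                f"subject {s} has k={decomps[s].k}, expected {k}"
            )
    best: ModuleMatch | None = None
    for ref in subjects:
        S_ref = decomps[ref].S
        mapping: dict[str, tuple[int, ...]] = {ref: tuple(range(k))}
        pair_ndp: dict[str, np.ndarray] = {
            ref: np.ones(k)
        }
        totals = []
        for s in subjects:
            if s == ref:
                continue
            M = _ndp_matrix(S_ref, decomps[s].S)
            rows, cols = linear_sum_assignment(-M)
            perm = tuple(int(cols[np.argwhere(rows == i)[0, 0]]) for i in range(k))
            matched = M[rows, cols]
            order = np.argsort(rows)
            mapping[s] = perm
            pair_ndp[s] = matched[order]
            totals.append(float(matched.mean()))
        avg = float(np.mean(totals)) if totals else 1.0
        if best is None or avg > best.average_ndp:
            best = ModuleMatch(
                reference=ref, mapping=mapping, pair_ndp=pair_ndp,
                average_ndp=avg,
            )
    return best


def reorder_to_reference(
    dec: SynergyDecomposition, perm: Sequence[int]
) -> SynergyDecomposition:
    """Return a copy with columns of S (rows of P) reordered by ``perm``."""
    perm = list(perm)
    return SynergyDecomposition(
        S=dec.S[:, perm],
        P=dec.P[perm, :],
        k=dec.k,
        vaf=dec.vaf,
        n_restarts=dec.n_restarts,
        seed=dec.seed,
        n_iterations=dec.n_iterations,
    )


def label_dominant(
    S: np.ndarray,
    threshold_fraction: float = 0.3,
    muscle_labels: Sequence[str] = (),
) -> DominanceLabeling:
    """Label each muscle dominant where its weighting reaches the fraction-of-
    maximum threshold within a module (boundary inclusive)."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise SynergyError("weightings must be nonnegative")
    colmax = S.max(axis=0)
    zero_cols = np.flatnonzero(colmax == 0)
    if zero_cols.size:
        logger.warning(
            "all-zero module column(s) %s: no dominant muscles",
            zero_cols.tolist(),
        )
    with np.errstate(invalid="ignore"):
        dominant = S >= threshold_fraction * colmax[None, :]
    dominant[:, zero_cols] = False
    return DominanceLabeling(
        dominant=dominant,
        threshold_fraction=threshold_fraction,
        muscle_labels=tuple(muscle_labels),
    )
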