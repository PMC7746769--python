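"""Model-based clustering with eigen-decomposed covariance families.

Gaussian mixtures are fitted by EM under the fourteen covariance
parameterizations Σ_k = λ_k D_k A_k D_kᵀ, where λ (volume, a positive
scalar), A (shape, a diagonal matrix with unit determinant) and D
(orientation, orthonormal) may each be Equal across components, Variable,
or — for shape/orientation — the Identity. The three-letter codes follow
the established naming (EII, VII, EEI, VEI, EVI, VVI, EEE, EVE, VEE, VVE,
EEV, VEV, EVV, VVV). Closed-form M-steps exist for most families; VEI,
VEE, VEV alternate between volume and shape updates, and the shared-
orientation families EVE/VVE update D by a majorize–minimize step on the
orthogonal group. All iterative M-step updates are warm-started from the
previous EM iteration, so the observed-data log-likelihood is monotone
non-decreasing.

Model selection sweeps families × component counts and ranks converged fits
by BIC under the *maximize* convention, BIC = 2·loglik − n_params·log(n),
so the best model is the one with the largest BIC. Fits whose covariances
degenerate (collapsed component, numerically singular Σ) are reported as
non-converged and excluded from selection rather than raising.

EM is initialized from seeded k-means++ hard assignments; several restarts
are fitted per (family, k) and the best final log-likelihood kept. The
whole sweep is deterministic given (data, seed, restart count).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

FAMILY_CODES = (
    "EII", "VII", "EEI", "VEI", "EVI", "VVI", "EEE",
    "EVE", "VEE", "VVE", "EEV", "VEV", "EVV", "VVV",
)

_LOG_2PI = math.log(2.0 * math.pi)
_INNER_TOL = 1e-10
_INNER_MAX = 50
#: Components whose covariance condition number falls below this are degenerate.
_COND_FLOOR = 1e-14


class DegenerateFitError(Exception):
    """Raised internally when a covariance update collapses; caught by fit_mixture."""


class ModelSelectionError(RuntimeError):
    """All fits in a sweep degenerated; carries the sweep table."""

    def __init__(self, message: str, table: pd.DataFrame):
        super().__init__(message)
        self.table = table


# ---------------------------------------------------------------------------
# Feature matrix


@dataclass
class FeatureMatrix:
    """Sources × named features, replicate-averaged, optionally z-standardized."""

    frame: pd.DataFrame
    standardized: bool = False

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    @property
    def sources(self) -> list:
        return list(self.frame.index)

    @property
    def features(self) -> list:
        return list(self.frame.columns)


def build_feature_matrix(records: pd.DataFrame, feature_list) -> FeatureMatrix:
    """Replicate-average long-format feature records into a FeatureMatrix.

    ``records`` has columns (source_id, replicate_id, feature, value); the
    mean over replicates is taken per (source, feature). A missing cell is
    an error naming the (source, feature) pair.
    """
    feature_list = list(feature_list)
    sources = list(dict.fromkeys(records["source_id"]))
    means = records.pivot_table(
        index="source_id", columns="feature", values="value", aggfunc="mean", sort=False
    )
    for src in sources:
        for feat in feature_list:
            if feat not in means.columns or pd.isna(means.at[src, feat]):
                raise ValueError(f"missing feature value for (source {src!r}, feature {feat!r})")
    frame = means.reindex(index=sources, columns=feature_list)
    return FeatureMatrix(frame=frame, standardized=False)


def standardize(m: FeatureMatrix) -> FeatureMatrix:
    """Column-wise z-scores (sample SD, ddof=1): mean 0, SD 1 per column."""
    values = m.values
    sd = values.std(axis=0, ddof=1)
    for j, col in enumerate(m.features):
        if not sd[j] > 0:
            raise ValueError(f"column {col!r} has zero variance; cannot standardize")
    z = (values - values.mean(axis=0)) / sd
    frame = pd.DataFrame(z, index=m.frame.index, columns=m.frame.columns)
    return FeatureMatrix(frame=frame, standardized=True)


# ---------------------------------------------------------------------------
# Mixture model types


@dataclass(frozen=True)
class MixtureSpec:
    """A covariance family code and a number of mixture components."""

    family: str
    k: int

    def __post_init__(self):
        if self.family not in FAMILY_CODES:
            raise ValueError(f"unknown covariance family {self.family!r}")
        if self.k < 1:
            raise ValueError("k must be >= 1")


def covariance_param_count(family: str, d: int, k: int) -> int:
    """Free covariance parameters for a family at dimension d, k components."""
    orient = d * (d - 1) // 2
    table = {
        "EII": 1,
        "VII": k,
        "EEI": d,
        "VEI": k + (d - 1),
        "EVI": 1 + k * (d - 1),
        "VVI": k * d,
        "EEE": d * (d + 1) // 2,
        "EVE": 1 + k * (d - 1) + orient,
        "VEE": k + (d - 1) + orient,
        "VVE": k + k * (d - 1) + orient,
        "EEV": d + k * orient,
        "VEV": k + (d - 1) + k * orient,
        "EVV": 1 + k * (d - 1) + k * orient,
        "VVV": k * d * (d + 1) // 2,
    }
    return table[family]


def n_mixture_params(family: str, d: int, k: int) -> int:
    """Total free parameters: weights (k−1) + means (k·d) + covariance."""
    return (k - 1) + k * d + covariance_param_count(family, d, k)


@dataclass
class FittedMixture:
    """One constrained Gaussian-mixture fit.

    ``covariances`` are the realized per-component matrices built from the
    shared/varying (volume, shape, orientation) factors in ``detail``, so
    the family's equality constraints hold exactly by construction.
    """

    spec: MixtureSpec
    weights: np.ndarray | None = None
    means: np.ndarray | None = None
    covariances: np.ndarray | None = None
    detail: dict = field(default_factory=dict)
    responsibilities: np.ndarray | None = None
    loglik: float = float("nan")
    loglik_trace: list = field(default_factory=list)
    n_params: int = 0
    bic: float = float("nan")
    assignments: np.ndarray | None = None
    converged: bool = False
    n_iter: int = 0
    n_obs: int = 0
    message: str = ""

    def to_dict(self) -> dict:
        out = {
            "family": self.spec.family,
            "k": self.spec.k,
            "loglik": self.loglik,
            "n_params": self.n_params,
            "bic": self.bic,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "n_obs": self.n_obs,
            "message": self.message,
        }
        if self.weights is not None:
            out["weights"] = self.weights.tolist()
            out["means"] = self.means.tolist()
            out["covariances"] = self.covariances.tolist()
            out["assignments"] = self.assignments.tolist()
        return out


@dataclass
class ModelSelection:
    """BIC-ranked sweep over (family, k) with the best converged fit."""

    table: pd.DataFrame
    best: FittedMixture

    def to_dict(self) -> dict:
        return {
            "sweep": self.table.to_dict(orient="records"),
            "best": self.best.to_dict(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def bic(fit: FittedMixture) -> float:
    """BIC under the maximize convention: 2·loglik − n_params·log(n)."""
    return 2.0 * fit.loglik - fit.n_params * math.log(fit.n_obs)


# ---------------------------------------------------------------------------
# Covariance M-steps.  W: (k,d,d) scatter matrices, nk: (k,), n: total weight.
# Each returns (sigmas (k,d,d), detail, state); state carries warm starts for
# the iterative families so each M-step ascends from the previous parameters.


def _det1_diag(v: np.ndarray) -> tuple[float, np.ndarray]:
    """Split a positive vector into (volume, unit-determinant shape)."""
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise DegenerateFitError("non-positive diagonal in shape update")
    loglam = float(np.mean(np.log(v)))
    return math.exp(loglam), v * math.exp(-loglam)


def _det1_full(M: np.ndarray) -> tuple[float, np.ndarray]:
    sign, logdet = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(logdet):
        raise DegenerateFitError("non-positive-definite matrix in covariance update")
    d = M.shape[0]
    scale = math.exp(logdet / d)
    return scale, M / scale


def _eigh_desc(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    vals, vecs = np.linalg.eigh(M)
    return vals[::-1], vecs[:, ::-1]


def _mstep_EII(W, nk, n, d, state):
    lam = float(np.trace(W.sum(axis=0))) / (n * d)
    if lam <= 0:
        raise DegenerateFitError("zero volume")
    eye = np.eye(d)
    return np.broadcast_to(lam * eye, W.shape).copy(), {"volume": lam}, state


def _mstep_VII(W, nk, n, d, state):
    lam = np.einsum("kii->k", W) / (nk * d)
    if np.any(lam <= 0):
        raise DegenerateFitError("zero component volume")
    sig = lam[:, None, None] * np.eye(d)
    return sig, {"volume": lam}, state


def _mstep_EEI(W, nk, n, d, state):
    diag = np.einsum("kii->i", W) / n
    lam, A = _det1_diag(diag)
    sig = np.broadcast_to(np.diag(diag), W.shape).copy()
    return sig, {"volume": lam, "shape": A}, state


def _mstep_VEI(W, nk, n, d, state):
    Wdiag = np.einsum("kii->ki", W)  # (k,d)
    _, A = _det1_diag(state.get("A", Wdiag.sum(axis=0)))
    prev_f = np.inf
    for _ in range(_INNER_MAX):
        lam = (Wdiag / A).sum(axis=1) / (nk * d)
        if np.any(lam <= 0):
            raise DegenerateFitError("zero component volume")
        _, A = _det1_diag((Wdiag / lam[:, None]).sum(axis=0))
        f = float(((Wdiag / A).sum(axis=1) / lam).sum() + (nk * d * np.log(lam)).sum())
        if abs(prev_f - f) <= _INNER_TOL * (1 + abs(f)):
            break
        prev_f = f
    state["A"] = A
    sig = lam[:, None, None] * np.diag(A)
    return sig, {"volume": lam, "shape": A}, state


def _mstep_EVI(W, nk, n, d, state):
    Wdiag = np.einsum("kii->ki", W)
    if np.any(Wdiag <= 0):
        raise DegenerateFitError("zero diagonal scatter")
    logdets = np.log(Wdiag).sum(axis=1)
    A = Wdiag * np.exp(-logdets / d)[:, None]
    lam = float(np.exp(logdets / d).sum()) / n
    sig = lam * np.einsum("ki,ij->kij", A, np.eye(d))
    return sig, {"volume": lam, "shape": A}, state


def _mstep_VVI(W, nk, n, d, state):
    Wdiag = np.einsum("kii->ki", W) / nk[:, None]
    if np.any(Wdiag <= 0):
        raise DegenerateFitError("zero diagonal scatter")
    sig = np.einsum("ki,ij->kij", Wdiag, np.eye(d))
    vols = np.exp(np.log(Wdiag).sum(axis=1) / d)
    return sig, {"volume": vols, "shape": Wdiag / vols[:, None]}, state


def _mstep_EEE(W, nk, n, d, state):
    S = W.sum(axis=0) / n
    lam, C = _det1_full(S)
    return np.broadcast_to(S, W.shape).copy(), {"volume": lam, "shared_covariance": S}, state


def _mstep_VVV(W, nk, n, d, state):
    sig = W / nk[:, None, None]
    for j in range(len(nk)):
        sign, logdet = np.linalg.slogdet(sig[j])
        if sign <= 0 or not np.isfinite(logdet):
            raise DegenerateFitError("singular component covariance")
    return sig, {}, state


def _mstep_EVV(W, nk, n, d, state):
    k = len(nk)
    C = np.empty_like(W)
    roots = np.empty(k)
    for j in range(k):
        sign, logdet = np.linalg.slogdet(W[j])
        if sign <= 0 or not np.isfinite(logdet):
            raise DegenerateFitError("singular component scatter")
        roots[j] = math.exp(logdet / d)
        C[j] = W[j] / roots[j]
    lam = float(roots.sum()) / n
    if lam <= 0:
        raise DegenerateFitError("zero volume")
    return lam * C, {"volume": lam}, state


def _mstep_VEE(W, nk, n, d, state):
    _, C = _det1_full(state.get("C", W.sum(axis=0)))
    k = len(nk)
    prev_f = np.inf
    for _ in range(_INNER_MAX):
        Cinv_W = np.linalg.solve(C[None, :, :].repeat(k, axis=0), W)
        lam = np.einsum("kii->k", Cinv_W) / (nk * d)
        if np.any(lam <= 0):
            raise DegenerateFitError("zero component volume")
        _, C = _det1_full((W / lam[:, None, None]).sum(axis=0))
        f = float(
            (np.einsum("kii->k", np.linalg.solve(C[None, :, :].repeat(k, axis=0), W)) / lam).sum()
            + (nk * d * np.log(lam)).sum()
        )
        if abs(prev_f - f) <= _INNER_TOL * (1 + abs(f)):
            break
        prev_f = f
    state["C"] = C
    sig = lam[:, None, None] * C
    return sig, {"volume": lam, "shared_shape_orientation": C}, state


def _mstep_EEV(W, nk, n, d, state):
    k = len(nk)
    D = np.empty_like(W)
    omega = np.empty((k, d))
    for j in range(k):
        omega[j], D[j] = _eigh_desc(W[j])
    if np.any(omega <= 0):
        raise DegenerateFitError("singular component scatter")
    S = omega.sum(axis=0) / n  # shared λ·A eigenvalue vector, descending
    lam, A = _det1_diag(S)
    sig = np.einsum("kij,j,klj->kil", D, S, D)
    return sig, {"volume": lam, "shape": A, "orientation": D}, state


def _mstep_VEV(W, nk, n, d, state):
    k = len(nk)
    D = np.empty_like(W)
    omega = np.empty((k, d))
    for j in range(k):
        omega[j], D[j] = _eigh_desc(W[j])
    if np.any(omega <= 0):
        raise DegenerateFitError("singular component scatter")
    _, A = _det1_diag(state.get("A", omega.sum(axis=0)))
    prev_f = np.inf
    for _ in range(_INNER_MAX):
        lam = (omega / A).sum(axis=1) / (nk * d)
        if np.any(lam <= 0):
            raise DegenerateFitError("zero component volume")
        _, A = _det1_diag((omega / lam[:, None]).sum(axis=0))
        f = float(((omega / A).sum(axis=1) / lam).sum() + (nk * d * np.log(lam)).sum())
        if abs(prev_f - f) <= _INNER_TOL * (1 + abs(f)):
            break
        prev_f = f
    state["A"] = A
    scaled = lam[:, None] * A[None, :]
    sig = np.einsum("kij,kj,klj->kil", D, scaled, D)
    return sig, {"volume": lam, "shape": A, "orientation": D}, state


def _orientation_mm(W_scaled, invA, D, n_iter=_INNER_MAX):
    """Minimize Σ_k tr(diag(invA_k) Dᵀ W_k D) over orthonormal D (MM descent).

    Each W_k is majorized by its largest eigenvalue times the identity,
    which linearizes the objective; the linear problem is solved by an SVD.
    Descent from the supplied D is guaranteed.
    """
    omega = np.array([np.linalg.eigvalsh(Wj)[-1] for Wj in W_scaled])
    for _ in range(n_iter):
        G = np.einsum("kij,jl,kl->il", W_scaled, D, invA)
        G -= np.einsum("k,jl,kl->jl", omega, D, invA)
        U, _, Vt = np.linalg.svd(G)
        D_new = -(U @ Vt)
        if np.abs(D_new - D).max() < 1e-12:
            D = D_new
            break
        D = D_new
    return D


def _shared_orientation_family(W, nk, n, d, state, per_component_volume):
    """M-step for EVE (shared volume) and VVE (per-component volume)."""
    k = len(nk)
    if "D" in state:
        D = state["D"]
    else:
        _, D = _eigh_desc(W.sum(axis=0))
    Wdiag_rot = lambda D_: np.einsum("ji,kjl,li->ki", D_, W, D_)  # diag(DᵀW_kD)
    lam = state.get("lam", np.ones(k))
    prev_f = np.inf
    A = None
    for _ in range(_INNER_MAX):
        diag = Wdiag_rot(D)
        if np.any(diag <= 0):
            raise DegenerateFitError("degenerate rotated scatter")
        logdets = np.log(diag).sum(axis=1)
        A = diag * np.exp(-logdets / d)[:, None]
        if per_component_volume:
            lam = (diag / A).sum(axis=1) / (nk * d)
            if np.any(lam <= 0):
                raise DegenerateFitError("zero component volume")
            W_scaled = W / lam[:, None, None]
        else:
            W_scaled = W
        D = _orientation_mm(W_scaled, 1.0 / A, D)
        diag = Wdiag_rot(D)
        if np.any(diag <= 0):
            raise DegenerateFitError("degenerate rotated scatter")
        if per_component_volume:
            f = float(((diag / A).sum(axis=1) / lam).sum() + (nk * d * np.log(lam)).sum())
        else:
            lam_s = float((diag / A).sum()) / (n * d)
            f = float((diag / A).sum() / lam_s + n * d * math.log(lam_s))
        if abs(prev_f - f) <= _INNER_TOL * (1 + abs(f)):
            break
        prev_f = f
    diag = Wdiag_rot(D)
    logdets = np.log(diag).sum(axis=1)
    A = diag * np.exp(-logdets / d)[:, None]
    if per_component_volume:
        lam = (diag / A).sum(axis=1) / (nk * d)
        scaled = lam[:, None] * A
    else:
        lam = float((diag / A).sum()) / (n * d)
        scaled = lam * A
    if np.any(np.asarray(lam) <= 0):
        raise DegenerateFitError("zero volume")
    state["D"] = D
    if per_component_volume:
        state["lam"] = lam
    sig = np.einsum("ij,kj,lj->kil", D, scaled, D)
    return sig, {"volume": lam, "shape": A, "orientation": D}, state


def _mstep_EVE(W, nk, n, d, state):
    return _shared_orientation_family(W, nk, n, d, state, per_component_volume=False)


def _mstep_VVE(W, nk, n, d, state):
    return _shared_orientation_family(W, nk, n, d, state, per_component_volume=True)


_MSTEPS = {
    "EII": _mstep_EII, "VII": _mstep_VII, "EEI": _mstep_EEI, "VEI": _mstep_VEI,
    "EVI": _mstep_EVI, "VVI": _mstep_VVI, "EEE": _mstep_EEE, "EVE": _mstep_EVE,
    "VEE": _mstep_VEE, "VVE": _mstep_VVE, "EEV": _mstep_EEV, "VEV": _mstep_VEV,
    "EVV": _mstep_EVV, "VVV": _mstep_VVV,
}


# ---------------------------------------------------------------------------
# EM


def _kmeanspp_assignments(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Near-hard responsibilities from k-means++ seeded centers."""
    n = len(X)
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min([((X - c) ** 2).sum(axis=1) for c in centers], axis=0)
        total = d2.sum()
        if total > 0:
            centers.append(X[rng.choice(n, p=d2 / total)])
        else:
            centers.append(X[rng.integers(n)])
    dists = np.stack([((X - c) ** 2).sum(axis=1) for c in centers], axis=1)
    resp = np.full((n, k), 0.1 / k)  # softened so every component sees all points
    resp[np.arange(n), dists.argmin(axis=1)] += 0.9
    return resp


def _component_log_density(X, mean, sigma):
    d = X.shape[1]
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError(f"covariance not positive definite: {exc}") from exc
    diag = np.diag(chol)
    if (diag.min() / diag.max()) ** 2 < _COND_FLOOR:
        raise DegenerateFitError("covariance numerically singular")
    sol = solve_triangular(chol, (X - mean).T, lower=True)
    logdet = np.log(diag).sum()
    return -0.5 * (d * _LOG_2PI + (sol ** 2).sum(axis=0)) - logdet


def fit_mixture(
    x,
    spec: MixtureSpec,
    seed: int = 0,
    init_resp: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> FittedMixture:
    """Fit one constrained Gaussian mixture by EM.

    ``x`` is a :class:`FeatureMatrix` or array of shape (n, d) with n > k.
    EM runs until the relative log-likelihood change falls below ``tol`` or
    ``max_iter`` iterations; degenerate covariance updates end the fit with
    ``converged=False`` and a diagnostic message instead of raising.
    """
    X = np.asarray(x.values if isinstance(x, FeatureMatrix) else x, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be 2-dimensional (n observations × d features)")
    n, d = X.shape
    k = spec.k
    if n <= k:
        raise ValueError(f"need more observations ({n}) than components ({k})")

    if init_resp is not None:
        resp = np.asarray(init_resp, dtype=float)
    elif k == 1:
        resp = np.ones((n, 1))
    else:
        resp = _kmeanspp_assignments(X, k, np.random.default_rng(seed))

    fit = FittedMixture(spec=spec, n_obs=n, n_params=n_mixture_params(spec.family, d, k))
    mstep = _MSTEPS[spec.family]
    state: dict = {}
    ll_prev = -np.inf
    trace: list[float] = []
    # fp overflow/underflow in a collapsing fit surfaces as a non-finite
    # log-likelihood or a failed Cholesky; both are handled as degeneracy
    try:
        with np.errstate(over="ignore", under="ignore", invalid="ignore", divide="ignore"):
            for it in range(1, max_iter + 1):
                nk = resp.sum(axis=0)
                if np.any(nk < 1e-10):
                    raise DegenerateFitError("component collapsed to zero weight")
                weights = nk / n
                means = (resp.T @ X) / nk[:, None]
                W = np.empty((k, d, d))
                for j in range(k):
                    Xc = X - means[j]
                    Wj = (resp[:, j, None] * Xc).T @ Xc
                    W[j] = (Wj + Wj.T) / 2.0
                sigmas, detail, state = mstep(W, nk, float(n), d, state)

                log_dens = np.empty((n, k))
                for j in range(k):
                    log_dens[:, j] = _component_log_density(X, means[j], sigmas[j])
                log_joint = log_dens + np.log(weights)
                log_norm = logsumexp(log_joint, axis=1)
                ll = float(log_norm.sum())
                if not np.isfinite(ll):
                    raise DegenerateFitError("non-finite log-likelihood")
                trace.append(ll)
                resp = np.exp(log_joint - log_norm[:, None])

                fit.weights, fit.means, fit.covariances, fit.detail = weights, means, sigmas, detail
                fit.responsibilities = resp
                fit.loglik, fit.n_iter = ll, it
                if it > 1 and ll - ll_prev <= tol * max(1.0, abs(ll)):
                    fit.converged = True
                    break
                ll_prev = ll
            else:
                fit.message = f"maximum iterations ({max_iter}) reached"
    except (DegenerateFitError, np.linalg.LinAlgError) as exc:
        fit.converged = False
        fit.message = str(exc) or exc.__class__.__name__
        fit.loglik_trace = trace
        return fit

    fit.loglik_trace = trace
    fit.assignments = fit.responsibilities.argmax(axis=1)  # ties -> lower index
    fit.bic = bic(fit)
    return fit


def select_model(
    x,
    families=FAMILY_CODES,
    k_range=range(1, 10),
    n_restarts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> ModelSelection:
    """Sweep (family, k) fits with restarts; return the BIC table and best model.

    For each (family, k), ``n_restarts`` seeded initializations are fitted
    and the best final log-likelihood kept (k=1 needs no restarts). The best
    model maximizes BIC among converged fits. Deterministic given
    (data, seed, restart count).
    """
    X = x.values if isinstance(x, FeatureMatrix) else np.asarray(x, dtype=float)
    n = len(X)
    k_range = list(k_range)
    if not k_range or min(k_range) < 1 or max(k_range) > n - 1:
        raise ValueError(f"k_range must lie within [1, n-1] = [1, {n - 1}]")

    rng = np.random.default_rng(seed)
    rows = []
    best: FittedMixture | None = None
    for family in families:
        for k in k_range:
            restarts = 1 if k == 1 else n_restarts
            best_fk: FittedMixture | None = None
            for _ in range(restarts):
                sub_seed = int(rng.integers(2 ** 31))
                fit = fit_mixture(x, MixtureSpec(family, k), seed=sub_seed,
                                  tol=tol, max_iter=max_iter)
                if fit.converged and (best_fk is None or fit.loglik > best_fk.loglik):
                    best_fk = fit
            rows.append({
                "family": family,
                "k": k,
                "bic": best_fk.bic if best_fk else float("nan"),
                "loglik": best_fk.loglik if best_fk else float("nan"),
                "converged": best_fk is not None,
                "n_iter": best_fk.n_iter if best_fk else 0,
            })
            if best_fk is not None and (best is None or best_fk.bic > best.bic):
                best = best_fk
    table = pd.DataFrame(rows)
    if best is None:
        raise ModelSelectionError("every fit in the sweep was degenerate", table)
    return ModelSelection(table=table, best=best)


def two_component_plot_data(x: FeatureMatrix, selection: ModelSelection) -> dict:
    """Per feature-pair scatter tables with cluster labels from the best fit.

    Returns {(feature_i, feature_j): DataFrame(source_id, f_i, f_j, cluster)}
    for every unordered pair; labels come from the full d-dimensional fit and
    are therefore identical across pair tables.
    """
    labels = selection.best.assignments
    if labels is None or len(labels) != len(x.frame):
        raise ValueError("selection was not computed on this feature matrix")
    out = {}
    for fi, fj in combinations(x.features, 2):
        out[(fi, fj)] = pd.DataFrame({
            "source_id": x.sources,
            fi: x.frame[fi].to_numpy(),
            fj: x.frame[fj].to_numpy(),
            "cluster": labels + 1,
        })
    return out
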