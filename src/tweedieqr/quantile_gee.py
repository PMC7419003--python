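"""Induced-smoothed quantile estimating equations with plugged-in BLUPs.

The conditional tau-quantile is modelled multiplicatively,
Q_tau(Y_ij | U) = U_ij mu_ij(tau) with mu_ij(tau) = exp(x_ij' beta_tau); the
random effects are replaced by the orthodox BLUPs of the fitted mean model
and are NOT updated during quantile estimation.  The estimating function
weights check-score residuals psi_tau by a working covariance
Sigma_i = tau(1-tau) C_i(rho) whose correlation C_i is a general stationary
(Toeplitz) matrix with lag parameters rho_l estimated from standardized
residual signs.  The indicator inside psi_tau is smoothed with a normal CDF
whose bandwidth is tied to Omega, the current covariance estimate of
beta_tau (induced smoothing), giving a differentiable score that a
Newton-Raphson solver can handle and yielding the sandwich covariance as a
by-product.  A second covariance term propagates the BLUP prediction error
through a first-order expansion in the random effects.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import toeplitz
from scipy.special import ndtr

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _phi(x):
    # standard normal pdf without distribution-object overhead
    return np.exp(-0.5 * x * x) / _SQRT2PI

from .panel_io import PanelData
from .tweedie_mean import MeanFit, TweedieSpec, _EXP_CLIP, fit_mean_model

logger = logging.getLogger("tweedieqr")

RHO_CLAMP = 0.95
_PD_EPS = 1e-8


# ---------------------------------------------------------------------------
# check-loss primitives


def psi_tau(s, tau: float):
    """Check-loss subgradient tau - I(s < 0); ties at 0 count as tau."""
    s = np.asarray(s, dtype=float)
    out = np.where(s < 0, tau - 1.0, tau)
    return out if out.ndim else float(out)


def check_loss(s, tau: float):
    """Asymmetric absolute loss rho_tau(s) = s (tau - I(s <= 0)) >= 0."""
    s = np.asarray(s, dtype=float)
    out = s * (tau - (s <= 0))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# working correlation


@dataclass
class CorrelationModel:
    """Per-size working matrices for the stationary Toeplitz structure.

    All subjects share the lag parameters, so matrices depend only on the
    block size n; they are built once per iteration for each distinct size.
    """

    tau: float
    rho: np.ndarray  # possibly shrunk for positive definiteness
    C: dict[int, np.ndarray] = field(default_factory=dict)
    Sigma: dict[int, np.ndarray] = field(default_factory=dict)
    Sigma_inv: dict[int, np.ndarray] = field(default_factory=dict)


def build_sigma(rho: np.ndarray, tau: float, n_sizes) -> CorrelationModel:
    """Build C_i(rho) (unit-diagonal Toeplitz) and Sigma_i = tau(1-tau) C_i.

    If the Toeplitz matrix at the largest size is not positive definite the
    lag vector is shrunk geometrically (rho <- 0.9 rho) until its smallest
    eigenvalue exceeds 1e-8; shrinkage terminates at rho = 0 (identity).
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float)).copy()
    sizes = sorted({int(n) for n in np.atleast_1d(n_sizes)})
    n_max = sizes[-1]

    def first_row(r):
        row = np.ones(n_max)
        k = min(len(r), n_max - 1)
        row[1 : 1 + k] = r[:k]
        row[1 + k :] = 0.0
        return row

    for _ in range(200):
        C_big = toeplitz(first_row(rho))
        if np.all(np.abs(rho) < 1e-12):
            break
        if np.linalg.eigvalsh(C_big)[0] > _PD_EPS:
            break
        rho *= 0.9
    else:  # pragma: no cover - geometric shrinkage always exits above
        rho[:] = 0.0
    C_big = toeplitz(first_row(rho))

    model = CorrelationModel(tau=tau, rho=rho)
    v = tau * (1.0 - tau)
    for n in sizes:
        C = C_big[:n, :n]
        model.C[n] = C
        model.Sigma[n] = v * C
        model.Sigma_inv[n] = np.linalg.inv(v * C)
    return model


def estimate_autocorr(ytilde: np.ndarray, n_i: np.ndarray, max_lag: int) -> np.ndarray:
    """Moment estimates of the stationary lag correlations rho_l.

    ``ytilde`` holds the standardized residual signs psi_tau(eps)/(tau(1-tau))
    record by record; lags are formed within subjects only.  For unbalanced
    panels the lag-l numerator averages over sum_i max(n_i - l, 0) available
    pairs.  The series is centered at its overall mean before forming lag
    products: at the solution E psi_tau = 0 and centering is immaterial, but
    during iteration a displaced beta_tau shifts the sign mean, and the raw
    (uncentered) moment then reads that squared mean as correlation —
    feeding a near-equicorrelation working matrix whose inverse supports a
    spurious root of the weighted score far above the data.  Estimates are
    clamped to [-0.95, 0.95]; if the centered series has no variation the
    lag correlations are undefined and an all-zero vector (independence) is
    returned with a warning.
    """
    n_i = np.asarray(n_i, dtype=int)
    ytilde = np.asarray(ytilde, dtype=float)
    ytilde = ytilde - np.mean(ytilde) if len(ytilde) else ytilde
    starts = np.concatenate(([0], np.cumsum(n_i)[:-1]))
    denom = float(np.sum(ytilde**2)) / max(len(ytilde), 1)
    if denom <= 0:
        warnings.warn(
            "residual signs have no variation; using independence", stacklevel=2
        )
        return np.zeros(max_lag)
    rho = np.zeros(max_lag)
    for lag in range(1, max_lag + 1):
        num = 0.0
        npairs = 0
        for s, n in zip(starts, n_i):
            if n > lag:
                block = ytilde[s : s + n]
                num += float(np.dot(block[:-lag], block[lag:]))
                npairs += n - lag
        if npairs > 0:
            rho[lag - 1] = (num / npairs) / denom
    return np.clip(rho, -RHO_CLAMP, RHO_CLAMP)


# ---------------------------------------------------------------------------
# smoothed score ingredients


def _smoothing_args(
    y: np.ndarray,
    U_hat_ij: np.ndarray,
    mu_tau: np.ndarray,
    Omega: np.ndarray,
    X: np.ndarray,
    sqrt_bandwidth: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized log-residuals b_ij and bandwidths r_ij.

    b_ij = log(y / (U_hat_ij mu_tau)) with y = 0 mapped to -inf;
    r_ij = sqrt(x' Omega x) by default (``sqrt_bandwidth=False`` uses the
    raw quadratic form x' Omega x).
    """
    with np.errstate(divide="ignore"):
        b = np.where(y > 0, np.log(np.maximum(y, 1e-300) / (U_hat_ij * mu_tau)), -np.inf)
    quad = np.einsum("ij,jk,ik->i", X, Omega, X)
    quad = np.maximum(quad, 0.0)
    r = np.sqrt(quad) if sqrt_bandwidth else quad
    return b, r


def smoothed_psi(
    y: np.ndarray,
    U_hat_ij: np.ndarray,
    mu_tau: np.ndarray,
    tau: float,
    Omega: np.ndarray,
    X: np.ndarray,
    sqrt_bandwidth: bool = True,
) -> np.ndarray:
    """Induced-smoothed score components tau - 1 + Phi(b_ij / r_ij).

    Each component lies in (tau-1, tau); y = 0 is the b -> -inf limit giving
    exactly tau - 1.  Records with r = 0 fall back to the unsmoothed psi_tau.
    """
    b, r = _smoothing_args(y, U_hat_ij, mu_tau, Omega, X, sqrt_bandwidth)
    out = np.empty_like(b)
    pos = r > 0
    out[pos] = tau - 1.0 + ndtr(b[pos] / r[pos])
    if np.any(~pos):
        out[~pos] = psi_tau(y[~pos] - U_hat_ij[~pos] * mu_tau[~pos], tau)
    return out


def _lambda_diag(b: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Diagonal of Lambda_i: phi(b/r)/r, with the b = -inf and r = 0 limits 0."""
    lam = np.zeros_like(b)
    ok = (r > 0) & np.isfinite(b)
    lam[ok] = _phi(b[ok] / r[ok]) / r[ok]
    return lam


def estimate_gamma(
    mode: str,
    X: np.ndarray,
    beta_tau_plus: np.ndarray | None = None,
    beta_tau_minus: np.ndarray | None = None,
    h_n: float | None = None,
    floor: float = 1e-8,
) -> np.ndarray:
    """Per-record density-at-zero values for the Gamma_i matrices.

    ``"identity"`` treats Gamma as a scalar matrix (all ones).  The
    ``"difference-quotient"`` mode estimates f_ij(0) as
    2 h_n / (exp(x' beta_{tau+h}) - exp(x' beta_{tau-h})), the reciprocal of
    a symmetric difference quotient of the conditional quantile function in
    tau, floored at ``floor`` when the quotient degenerates.
    """
    N = X.shape[0]
    if mode == "identity":
        return np.ones(N)
    if mode != "difference-quotient":
        raise ValueError(f"unknown gamma mode: {mode!r}")
    if beta_tau_plus is None or beta_tau_minus is None or h_n is None:
        raise ValueError("difference-quotient mode needs beta at tau +/- h_n")
    qp = np.exp(np.clip(X @ beta_tau_plus, -_EXP_CLIP, _EXP_CLIP))
    qm = np.exp(np.clip(X @ beta_tau_minus, -_EXP_CLIP, _EXP_CLIP))
    diff = qp - qm
    out = np.full(N, floor)
    good = diff > 0
    out[good] = np.maximum(2.0 * h_n / diff[good], floor)
    return out


# ---------------------------------------------------------------------------
# score, Jacobian and covariance (summed over subjects)


def _size_groups(panel: PanelData) -> dict[int, np.ndarray]:
    """Map block size -> (k, n) record-row index array for those subjects."""
    cached = getattr(panel, "_size_groups_cache", None)
    if cached is not None:
        return cached
    groups: dict[int, np.ndarray] = {}
    for n in np.unique(panel.n_i):
        idx = np.flatnonzero(panel.n_i == n)
        rows = panel.starts[idx][:, None] + np.arange(int(n))[None, :]
        groups[int(n)] = rows
    panel._size_groups_cache = groups
    return groups


def quantile_score(
    panel: PanelData,
    U_hat_ij: np.ndarray,
    mu_tau: np.ndarray,
    tau: float,
    corr: CorrelationModel,
    Omega: np.ndarray,
    gamma_diag: np.ndarray,
    sqrt_bandwidth: bool = True,
) -> np.ndarray:
    """Smoothed weighted score sum_i X_i' Delta_i Gamma_i Sigma_i^{-1} psi~_i."""
    psi = smoothed_psi(panel.y, U_hat_ij, mu_tau, tau, Omega, panel.X, sqrt_bandwidth)
    d = U_hat_ij * mu_tau * gamma_diag  # diagonal of Delta Gamma
    score = np.zeros(panel.p)
    for n, rows in _size_groups(panel).items():
        Si = corr.Sigma_inv[n]
        t = psi[rows] @ Si  # (k, n), Sigma symmetric
        score += np.einsum("knp,kn->p", panel.X[rows] * d[rows][..., None], t)
    return score


def quantile_jacobian(
    panel: PanelData,
    U_hat_ij: np.ndarray,
    mu_tau: np.ndarray,
    tau: float,
    corr: CorrelationModel,
    Omega: np.ndarray,
    gamma_diag: np.ndarray,
    sqrt_bandwidth: bool = True,
) -> np.ndarray:
    """d score / d beta_tau = -sum_i X_i' Delta_i Gamma_i Sigma_i^{-1} Lambda_i X_i."""
    b, r = _smoothing_args(panel.y, U_hat_ij, mu_tau, Omega, panel.X, sqrt_bandwidth)
    lam = _lambda_diag(b, r)
    d = U_hat_ij * mu_tau * gamma_diag
    J = np.zeros((panel.p, panel.p))
    for n, rows in _size_groups(panel).items():
        Si = corr.Sigma_inv[n]
        Xg = panel.X[rows]
        L = Xg * lam[rows][..., None]
        M = np.einsum("nm,kmp->knp", Si, L)
        J -= np.einsum("knp,knq->pq", Xg * d[rows][..., None], M)
    return J


def score_covariance(
    panel: PanelData,
    mean_fit: MeanFit,
    U_hat_ij: np.ndarray,
    mu_tau: np.ndarray,
    tau: float,
    corr: CorrelationModel,
    Omega: np.ndarray,
    gamma_diag: np.ndarray,
    sqrt_bandwidth: bool = True,
) -> np.ndarray:
    """cov of the smoothed score: empirical term plus BLUP-uncertainty term.

    The first term is the sum of per-subject outer products of the weighted
    score contributions; the second propagates the prediction error of the
    plugged-in random effects.  When nu^2 = 0 the prediction error is the
    shared subject-level error, with within-subject covariance c_i in every
    entry (C_i = c_i 11'); when nu^2 != 0 the observation-level errors are
    taken with C_i = diag(c_ij).  The result is symmetrized against rounding
    and is positive semi-definite.
    """
    psi = smoothed_psi(panel.y, U_hat_ij, mu_tau, tau, Omega, panel.X, sqrt_bandwidth)
    b, r = _smoothing_args(panel.y, U_hat_ij, mu_tau, Omega, panel.X, sqrt_bandwidth)
    lam = _lambda_diag(b, r)
    d = U_hat_ij * mu_tau * gamma_diag
    o = mu_tau * gamma_diag  # diagonal of O Gamma
    one_level = not (mean_fit.two_level and mean_fit.nu2 > 0)
    cvec = np.repeat(mean_fit.c_i, panel.n_i) if one_level else mean_fit.c_ij
    V = np.zeros((panel.p, panel.p))
    for n, rows in _size_groups(panel).items():
        Si = corr.Sigma_inv[n]
        Xg = panel.X[rows]
        t = psi[rows] @ Si
        u = np.einsum("knp,kn->kp", Xg * d[rows][..., None], t)  # per-subject scores
        V += u.T @ u
        # BLUP term: A' Si (Lambda C Lambda) Si A with A = O Gamma X
        A = Xg * o[rows][..., None]
        SA = np.einsum("nm,kmp->knp", Si, A)
        if one_level:
            # C = c_i 11': rank-one per subject
            g = np.einsum("knp,kn->kp", SA, lam[rows])
            ci = cvec[rows[:, 0]]
            V += (g * ci[:, None]).T @ g
        else:
            k = (lam[rows] ** 2) * cvec[rows]
            V += np.einsum("knp,kn,knq->pq", SA, k, SA)
    return 0.5 * (V + V.T)


# ---------------------------------------------------------------------------
# solver


@dataclass
class QuantileFit:
    """State of a fitted quantile model at level tau."""

    tau: float
    beta_tau: np.ndarray
    mu_tau: np.ndarray
    Omega: np.ndarray
    rho: np.ndarray
    gamma_mode: str
    converged: bool
    n_iter: int
    se: np.ndarray | None = None
    boot_se: np.ndarray | None = None
    columns: list[str] = field(default_factory=list)


def fit_quantile(
    panel: PanelData,
    mean_fit: MeanFit,
    tau: float,
    gamma_mode: str = "identity",
    tol: float = 1e-8,
    max_iter: int = 100,
    h_n: float | None = None,
    sqrt_bandwidth: bool = True,
    beta_init: np.ndarray | None = None,
) -> QuantileFit:
    """Solve the smoothed quantile estimating equation by Newton-Raphson.

    Each outer iteration (1) re-estimates the lag correlations and rebuilds
    Sigma_i at the current residuals, (2) takes a Newton step
    beta* = beta + (-J)^{-1} Psi~, and (3) refreshes the induced-smoothing /
    covariance matrix Omega via the sandwich (-J)^{-1} cov(Psi~) (-J)^{-1}.
    The BLUPs, their mean squared distances and the dispersion parameters are
    taken from ``mean_fit`` and held fixed throughout.  Asymptotic standard
    errors are sqrt(diag Omega).

    If the score norm grows for five consecutive iterations the Newton steps
    are halved; persistent failure returns the last iterate flagged
    unconverged.
    """
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must lie strictly between 0 and 1")
    X, y = panel.X, panel.y
    U_hat = mean_fit.U_hat_ij
    beta_t = (
        np.asarray(beta_init, dtype=float).copy()
        if beta_init is not None
        else mean_fit.beta.copy()
    )
    Omega = (
        mean_fit.cov_beta.copy()
        if mean_fit.cov_beta is not None
        else 0.01 * np.eye(panel.p)
    )
    if not np.all(np.isfinite(Omega)) or np.trace(Omega) <= 0:
        Omega = 0.01 * np.eye(panel.p)

    if gamma_mode == "difference-quotient":
        if h_n is None:
            h_n = panel.m ** (-1.0 / 3.0)
        h_n = min(h_n, 0.9 * min(tau, 1.0 - tau))
        try:
            fp = fit_quantile(panel, mean_fit, tau + h_n, "identity", tol, max_iter)
            fm = fit_quantile(panel, mean_fit, tau - h_n, "identity", tol, max_iter)
            gamma_diag = estimate_gamma(
                "difference-quotient", X, fp.beta_tau, fm.beta_tau, h_n
            )
        except Exception:  # auxiliary fit failure -> scalar Gamma
            warnings.warn(
                "auxiliary quantile fits failed; using identity Gamma", stacklevel=2
            )
            gamma_mode = "identity"
            gamma_diag = np.ones(panel.n_records)
    else:
        gamma_diag = estimate_gamma(gamma_mode, X)

    max_lag = int(np.max(panel.n_i)) - 1
    v = tau * (1.0 - tau)
    converged = False
    corr = build_sigma(np.zeros(max(max_lag, 1))[:max_lag] if max_lag else [0.0],
                       tau, panel.n_i)

    def _score_and_norm(beta, corr_, Omega_):
        # the norm is standardized by the Delta scale so that driving
        # mu_tau -> 0 (which kills the score trivially) is not rewarded
        mt = np.exp(np.clip(X @ beta, -_EXP_CLIP, _EXP_CLIP))
        s = quantile_score(
            panel, U_hat, mt, tau, corr_, Omega_, gamma_diag, sqrt_bandwidth
        )
        scale = float(np.mean(U_hat * mt * gamma_diag)) + 1e-12
        return s, float(np.linalg.norm(s)) / scale

    def _scaled_norm(beta, corr_, Omega_):
        return _score_and_norm(beta, corr_, Omega_)[1]

    def _solve_beta(beta, corr_, Omega_, inner_max=60):
        """Damped Newton solve of the score at fixed (rho, Omega)."""
        score, norm = _score_and_norm(beta, corr_, Omega_)
        for _ in range(inner_max):
            mt = np.exp(np.clip(X @ beta, -_EXP_CLIP, _EXP_CLIP))
            J = quantile_jacobian(
                panel, U_hat, mt, tau, corr_, Omega_, gamma_diag, sqrt_bandwidth
            )
            # ridge-regularize -J so a rank-deficient density matrix Lambda
            # (few records near their quantile) cannot yield unbounded steps
            nJ = 0.5 * ((-J) + (-J).T)
            eig = np.linalg.eigvalsh(nJ)
            floor = 1e-6 * max(eig[-1], 1.0)
            if eig[0] < floor:
                nJ = nJ + (floor - eig[0]) * np.eye(panel.p)
            step = np.linalg.solve(nJ, score)
            cap = np.max(np.abs(step))
            if cap > 2.0:  # huge moves are meaningless on the log scale
                step *= 2.0 / cap
            alpha = 1.0
            new_score = new_norm = None
            for _h in range(15):
                cand_score, cand = _score_and_norm(beta + alpha * step, corr_, Omega_)
                if cand < norm or np.max(np.abs(alpha * step)) < 1e-13:
                    new_score, new_norm = cand_score, cand
                    break
                alpha *= 0.5
            if new_norm is None:  # no descent available: local stationary point
                break
            beta = beta + alpha * step
            score = new_score
            if np.max(np.abs(alpha * step)) < 0.1 * tol * (np.max(np.abs(beta)) + 1e-4):
                norm = new_norm
                break
            norm = new_norm
        return beta

    # The smoothing bandwidth matrix is held at its initial consistent
    # O(1/m) value (the mean-fit sandwich) while beta_tau is solved; the
    # covariance Omega~ is then formed once from the sandwich at the
    # solution.  Iterating Omega jointly with beta to a fixed point is
    # unstable for tau != 0.5: the map has a blow-up attractor (as the
    # bandwidth grows the Jacobian vanishes like 1/r while the score
    # covariance does not) and a collapse attractor on the other side.
    Omega0 = Omega.copy()
    it = 0
    rho = np.zeros(max(max_lag, 1))
    beta_hist: list[np.ndarray] = []
    # the discrete residual signs make the rho-hat <-> beta alternation
    # prone to tight limit cycles (each iterate is an exact root at its own
    # rho-hat); a drift-free cycle whose amplitude is far below the
    # estimator's sampling noise is accepted at its mean
    cycle_tol = max(1e3 * tol, 0.03)
    for it in range(1, max_iter + 1):
        # (1) working correlation at current residuals
        mu_tau = np.exp(np.clip(X @ beta_t, -_EXP_CLIP, _EXP_CLIP))
        if max_lag >= 1:
            ytilde = psi_tau(y - U_hat * mu_tau, tau) / v
            rho = estimate_autocorr(ytilde, panel.n_i, max_lag)
            corr = build_sigma(rho, tau, panel.n_i)

        # (2) Newton solve for beta_tau at fixed (rho, Omega)
        beta_new = _solve_beta(beta_t, corr, Omega0)

        rel = np.max(np.abs(beta_new - beta_t) / (np.abs(beta_t) + 1e-4))
        beta_t = beta_new
        if rel < tol:
            converged = True
            break
        beta_hist.append(beta_t.copy())
        # only consider cycle acceptance once an honest Newton/rho
        # alternation has had ample time to converge on its own
        if it >= max(50, max_iter // 2):
            recent = np.asarray(beta_hist[-8:])
            older = np.asarray(beta_hist[-16:-8])
            center = recent.mean(axis=0)
            spread = np.max(np.abs(recent - center) / (np.abs(center) + 1e-4))
            drift = np.max(
                np.abs(older.mean(axis=0) - center) / (np.abs(center) + 1e-4)
            )
            if spread < cycle_tol and drift < 1e-3:
                beta_t = center
                converged = True
                break

    if not converged:
        logger.warning("quantile fit at tau=%.3g did not converge", tau)

    # sandwich covariance at the solution
    mu_tau = np.exp(np.clip(X @ beta_t, -_EXP_CLIP, _EXP_CLIP))
    J = quantile_jacobian(
        panel, U_hat, mu_tau, tau, corr, Omega0, gamma_diag, sqrt_bandwidth
    )
    V = score_covariance(
        panel, mean_fit, U_hat, mu_tau, tau, corr, Omega0, gamma_diag, sqrt_bandwidth
    )
    try:
        negJinv = np.linalg.inv(-J)
    except np.linalg.LinAlgError:
        negJinv = np.linalg.pinv(-J)
    Omega_new = negJinv @ V @ negJinv.T
    Omega_new = 0.5 * (Omega_new + Omega_new.T)
    if np.all(np.isfinite(Omega_new)) and np.trace(Omega_new) > 0:
        Omega = Omega_new
    se = np.sqrt(np.maximum(np.diag(Omega), 0.0))
    return QuantileFit(
        tau=tau,
        beta_tau=beta_t,
        mu_tau=mu_tau,
        Omega=Omega,
        rho=corr.rho if max_lag else np.zeros(0),
        gamma_mode=gamma_mode,
        converged=converged,
        n_iter=it,
        se=se,
        columns=list(panel.columns),
    )


def bootstrap_se(
    panel: PanelData,
    tau: float,
    B: int = 200,
    seed: int = 0,
    spec: TweedieSpec = TweedieSpec(),
    two_level: bool = True,
    gamma_mode: str = "identity",
    gamma2_mode: str = "unbiased",
    tol: float = 1e-5,
    max_iter: int = 100,
    mean_max_iter: int = 400,
    parent: "tuple[MeanFit, QuantileFit] | None" = None,
) -> np.ndarray:
    """Cluster-bootstrap standard deviations of beta_tau.

    Subjects are resampled with replacement B times; each replicate reruns
    the full mean-model + quantile pipeline.  These are the unconditional
    standard deviations of beta_tau: unlike the sandwich Omega, they carry
    the sampling variability of the mean-model parameters and BLUPs, not
    just the plug-in quantile step.  The SD is taken over converged
    replicates only; a warning is attached when more than 20% fail.
    Deterministic given ``seed`` (independent per-replicate substreams).
    ``parent`` optionally supplies the original-data fits as warm starts.
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    if parent is None:
        mf0 = fit_mean_model(panel, spec, two_level, tol=tol, gamma2_mode=gamma2_mode)
        qf0 = fit_quantile(panel, mf0, tau, gamma_mode, tol=tol, max_iter=max_iter)
    else:
        mf0, qf0 = parent
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=B)  # reserved for stochastic fits
    estimates = []
    n_fail = 0
    for b in range(B):
        sub_rng = np.random.default_rng(rep_seeds[b])
        idx = sub_rng.integers(0, panel.m, size=panel.m)
        boot = panel.subset(idx)
        try:
            mf = fit_mean_model(
                boot,
                spec,
                two_level,
                tol=tol,
                max_iter=mean_max_iter,
                gamma2_mode=gamma2_mode,
                warm_start=mf0,
            )
            qf = fit_quantile(
                boot,
                mf,
                tau,
                gamma_mode,
                tol=tol,
                max_iter=max_iter,
                beta_init=qf0.beta_tau,
            )
        except Exception:
            n_fail += 1
            continue
        if qf.converged:
            estimates.append(qf.beta_tau)
        else:
            n_fail += 1
    if n_fail > 0.2 * B:
        warnings.warn(
            f"{n_fail}/{B} bootstrap replicates failed to converge", stacklevel=2
        )
    if len(estimates) < 2:
        return np.full(panel.p, np.nan)
    return np.std(np.asarray(estimates), axis=0, ddof=1)
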