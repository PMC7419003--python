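"""Tweedie mixed mean model: orthodox BLUPs and a Newton–Raphson GEE fit.

Model
-----
Subjects i = 1..m carry positive random effects U_i with E(U_i) = 1,
var(U_i) = sigma^2 (Tweedie Tw_r(1, sigma^2), r >= 2); given U_i = u_i each
observation carries U_ij | U_i ~ Tw_t(u_i, nu^2 u_i^{1-t}), t >= 2, so that
E(U_ij) = 1 and var(U_ij | U_i) = nu^2 u_i at t = 2.  Conditionally the
response follows Y_ij | U ~ Tw_q(u_ij mu_ij, gamma^2 u_ij^{1-q}) with
mu_ij = exp(x_ij' beta); q = 1 is the Poisson case for counts.

The random effects are never integrated out: they are predicted by orthodox
best linear unbiased predictors (exact Tweedie moment formulas), the
regression parameter solves a GEE whose Newton step uses the model-based
sensitivity matrix, and the dispersion parameters (sigma^2, nu^2, gamma^2)
are updated by bias-adjusted Pearson estimators.  Setting ``two_level=False``
forces nu^2 = 0, collapsing the observation-level effects onto U_i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel_io import PanelData

logger = logging.getLogger("tweedieqr")

_EXP_CLIP = 30.0  # bound on linear predictors before exponentiation


class DegenerateModelError(ValueError):
    """All response-level dispersion is zero: weights are undefined."""


class FittingError(RuntimeError):
    """Singular sensitivity matrix or otherwise unusable Newton step."""


@dataclass(frozen=True)
class TweedieSpec:
    """Shape parameters of the three Tweedie layers.

    q is the conditional-response shape (0 normal, 1 Poisson, 2 gamma,
    3 inverse-Gaussian); r and t are the subject- and observation-level
    random-effect shapes, both >= 2 (gamma at 2).
    """

    q: int = 1
    r: int = 2
    t: int = 2

    def __post_init__(self) -> None:
        if self.q not in (0, 1, 2, 3):
            raise ValueError("q must be one of {0, 1, 2, 3}")
        if self.r < 2 or self.t < 2:
            raise ValueError("random-effect shapes require r >= 2 and t >= 2")


@dataclass
class MeanFit:
    """State of a converged (or last-iterate) mean-model fit."""

    beta: np.ndarray
    mu: np.ndarray
    sigma2: float
    nu2: float
    gamma2: float
    w: np.ndarray
    U_hat_i: np.ndarray
    U_hat_ij: np.ndarray
    c_i: np.ndarray
    c_ij: np.ndarray
    two_level: bool
    converged: bool
    n_iter: int
    cov_beta: np.ndarray | None = None
    se: np.ndarray | None = None
    columns: list[str] = field(default_factory=list)

    @property
    def dispersions(self) -> dict[str, float]:
        return {
            "sigma2": float(self.sigma2),
            "nu2": float(self.nu2),
            "gamma2": float(self.gamma2),
        }


# ---------------------------------------------------------------------------
# moment primitives


def compute_weights(
    mu: np.ndarray, gamma2: float, nu2: float, q: int
) -> np.ndarray:
    """Per-record weights w_ij = 1 / (gamma^2 + nu^2 mu_ij^{2-q}).

    These are the BLUP weights combining the response dispersion and the
    observation-level random-effect dispersion on the variance scale of Y.
    """
    if gamma2 <= 0 and nu2 <= 0:
        raise DegenerateModelError("gamma2 = nu2 = 0 leaves no response variance")
    mu = np.asarray(mu, dtype=float)
    return 1.0 / (gamma2 + nu2 * mu ** (2 - q))


def predict_subject_blup(
    y: np.ndarray, mu: np.ndarray, w: np.ndarray, sigma2: float, q: int
) -> tuple[float, float]:
    """Orthodox BLUP of a single subject effect and its mean squared distance.

    Returns (U_hat_i, c_i) with
    U_hat_i = (1 + sigma^2 sum_j w mu^{1-q} y) / (1 + sigma^2 sum_j w mu^{2-q})
    and c_i = sigma^2 / (1 + sigma^2 sum_j w mu^{2-q}), so c_i in [0, sigma^2].
    """
    y, mu, w = (np.asarray(a, dtype=float) for a in (y, mu, w))
    num = 1.0 + sigma2 * np.sum(w * mu ** (1 - q) * y)
    den = 1.0 + sigma2 * np.sum(w * mu ** (2 - q))
    return float(num / den), float(sigma2 / den)


def predict_observation_blup(
    U_hat_i: float,
    c_i: float,
    y: np.ndarray,
    mu: np.ndarray,
    w: np.ndarray,
    gamma2: float,
    nu2: float,
    q: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Observation-level BLUPs U_hat_ij and their mean squared distances c_ij.

    U_hat_ij = gamma^2 w U_hat_i + nu^2 w mu^{1-q} y;
    c_ij = gamma^2 w (nu^2 + gamma^2 c_i w).  With nu^2 = 0 the weights are
    1/gamma^2 and both reduce to the subject-level quantities.
    """
    y, mu, w = (np.asarray(a, dtype=float) for a in (y, mu, w))
    U_hat_ij = gamma2 * w * U_hat_i + nu2 * w * mu ** (1 - q) * y
    c_ij = gamma2 * w * (nu2 + gamma2 * c_i * w)
    return U_hat_ij, c_ij


def _blups_all(
    panel: PanelData,
    mu: np.ndarray,
    w: np.ndarray,
    sigma2: float,
    nu2: float,
    gamma2: float,
    q: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized BLUPs for every subject at once (reduceat over blocks)."""
    starts = panel.starts
    a = np.add.reduceat(w * mu ** (1 - q) * panel.y, starts)
    b = np.add.reduceat(w * mu ** (2 - q), starts)
    den = 1.0 + sigma2 * b
    U_i = (1.0 + sigma2 * a) / den
    c_i = sigma2 / den
    rep = np.repeat(np.arange(panel.m), panel.n_i)
    U_ij = gamma2 * w * U_i[rep] + nu2 * w * mu ** (1 - q) * panel.y
    c_ij = gamma2 * w * (nu2 + gamma2 * c_i[rep] * w)
    return U_i, c_i, U_ij, c_ij


def estimate_dispersions(
    panel: PanelData,
    mu: np.ndarray,
    w: np.ndarray,
    U_hat_i: np.ndarray,
    U_hat_ij: np.ndarray,
    c_i: np.ndarray,
    c_ij: np.ndarray,
    gamma2: float,
    q: int,
    two_level: bool = True,
    gamma2_mode: str = "unbiased",
) -> tuple[float, float, float]:
    """Bias-adjusted Pearson estimators of (sigma^2, nu^2, gamma^2).

    sigma^2: mean over subjects of (U_hat_i - 1)^2 + c_i.
    nu^2:    mean over records of (U_hat_ij - U_hat_i)^2 + c_ij + c_i
             - 2 gamma^2 c_i w_ij (forced to 0 when ``two_level`` is False).
    gamma^2: mean over records of (y - U_hat mu)^2 / mu^q + c mu^{2-q}.  In
             the default ``"unbiased"`` mode the residual uses the
             observation-level predictor (U_hat_ij, c_ij), which makes the
             estimator exactly unbiased under the model; ``"subject"`` uses
             (U_hat_i, c_i), which absorbs the observation-level variance
             nu^2 mu^{2-q} into gamma^2 (the two coincide when nu^2 = 0).

    Moment estimators can go negative in finite samples; all three are
    floored at 0.
    """
    m = panel.m
    N = panel.n_records
    rep = np.repeat(np.arange(m), panel.n_i)
    sigma2 = float(np.sum((U_hat_i - 1.0) ** 2) / m + np.sum(c_i) / m)

    if two_level:
        summand = (
            (U_hat_ij - U_hat_i[rep]) ** 2
            + c_ij
            + c_i[rep]
            - 2.0 * gamma2 * c_i[rep] * w
        )
        nu2 = float(np.sum(summand) / N)
    else:
        nu2 = 0.0

    if gamma2_mode == "unbiased":
        resid = panel.y - U_hat_ij * mu
        corr = c_ij * mu ** (2 - q)
    elif gamma2_mode == "subject":
        resid = panel.y - U_hat_i[rep] * mu
        corr = c_i[rep] * mu ** (2 - q)
    else:
        raise ValueError(f"unknown gamma2_mode: {gamma2_mode!r}")
    gamma2_new = float(np.sum(resid**2 / mu**q + corr) / N)
    return max(sigma2, 0.0), max(nu2, 0.0), max(gamma2_new, 0.0)


# ---------------------------------------------------------------------------
# estimating equation for beta


def mean_score(
    panel: PanelData,
    mu: np.ndarray,
    U_hat_ij: np.ndarray,
    gamma2: float,
    q: int,
) -> np.ndarray:
    """GEE score sum_ij x_ij mu^{1-q} (y_ij - U_hat_ij mu_ij) / gamma^2."""
    if gamma2 <= 0:
        raise DegenerateModelError("gamma2 must be positive in the mean score")
    r = mu ** (1 - q) * (panel.y - U_hat_ij * mu) / gamma2
    return panel.X.T @ r


def _score_by_subject(
    panel: PanelData,
    mu: np.ndarray,
    U_hat_ij: np.ndarray,
    gamma2: float,
    q: int,
) -> np.ndarray:
    """(m, p) matrix of per-subject score contributions."""
    r = mu ** (1 - q) * (panel.y - U_hat_ij * mu) / gamma2
    return np.add.reduceat(panel.X * r[:, None], panel.starts, axis=0)


def sensitivity_matrix(
    panel: PanelData,
    mu: np.ndarray,
    w: np.ndarray,
    c_i: np.ndarray,
    gamma2: float,
    nu2: float,
    q: int,
) -> np.ndarray:
    """Model-based derivative S(beta) of the mean score.

    S = -sum_ij mu^{2-q} x x' / gamma^2
        + sum_i c_i (sum_j w mu^{2-q} x)(sum_j w mu^{2-q} x)'
        + sum_ij nu^2 w / gamma^2 (mu^{2-q} x)(mu^{2-q} x)'

    The second and third terms account for the feedback of y on the plugged-in
    BLUPs; with sigma^2 = nu^2 = 0 the matrix reduces to minus the quasi-GLM
    information scaled by gamma^2.
    """
    X = panel.X
    v = mu ** (2 - q)
    S = -(X * (v / gamma2)[:, None]).T @ X
    B = np.add.reduceat(X * (w * v)[:, None], panel.starts, axis=0)  # (m, p)
    S += (B * c_i[:, None]).T @ B
    Z = X * v[:, None]
    S += (Z * (nu2 * w / gamma2)[:, None]).T @ Z
    return S


def _quasi_glm_init(panel: PanelData, q: int, max_iter: int = 50) -> tuple[np.ndarray, float]:
    """Independence working-model fit (log link, variance mu^q) via IRLS.

    Supplies the starting beta and a Pearson dispersion for gamma^2; this is
    the standard quasi-likelihood fit ignoring all random effects.
    """
    X, y = panel.X, panel.y
    beta = np.zeros(panel.p)
    beta[0] = np.log(max(np.mean(y), 1e-8))
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -_EXP_CLIP, _EXP_CLIP)
        mu = np.exp(eta)
        # working response and weights for log link, var = mu^q
        z = eta + (y - mu) / mu
        wts = mu**2 / mu**q
        WX = X * wts[:, None]
        try:
            beta_new = np.linalg.solve(WX.T @ X, WX.T @ z)
        except np.linalg.LinAlgError as err:
            raise FittingError("singular information in the initial fit") from err
        if np.max(np.abs(beta_new - beta)) < 1e-10:
            beta = beta_new
            break
        beta = beta_new
    mu = np.exp(np.clip(X @ beta, -_EXP_CLIP, _EXP_CLIP))
    df = max(panel.n_records - panel.p, 1)
    gamma2 = float(np.sum((y - mu) ** 2 / mu**q) / df)
    return beta, max(gamma2, 1e-8)


def fit_mean_model(
    panel: PanelData,
    spec: TweedieSpec = TweedieSpec(),
    two_level: bool = True,
    tol: float = 1e-8,
    max_iter: int = 1000,
    gamma2_mode: str = "unbiased",
    init_dispersion: float = 0.1,
    ci_level: float = 0.95,
    warm_start: "MeanFit | None" = None,
    fix_sigma2: float | None = None,
    fix_nu2: float | None = None,
    fix_gamma2: float | None = None,
) -> MeanFit:
    """Fit the Tweedie mixed mean model by alternating Newton/BLUP/Pearson steps.

    Each outer iteration takes one Newton–Raphson step
    beta* = beta - S^{-1}(beta) Psi'(beta), refreshes mu, the weights and the
    BLUPs at beta*, then refreshes the dispersion parameters; iteration stops
    when the maximum relative change across (beta, sigma^2, nu^2, gamma^2)
    falls below ``tol``.  Standard errors come from the sandwich
    S^{-1} V S^{-1} with V the empirical covariance of per-subject scores.
    """
    q = spec.q
    if warm_start is not None:
        beta = warm_start.beta.copy()
        gamma2 = max(warm_start.gamma2, 1e-8)
        sigma2 = warm_start.sigma2
        nu2 = warm_start.nu2 if two_level else 0.0
    else:
        beta, gamma2 = _quasi_glm_init(panel, q)
        sigma2 = init_dispersion
        nu2 = init_dispersion if two_level else 0.0

    def _apply_fixed(s2, n2, g2):
        # pinning a dispersion turns its Pearson update into a no-op
        if fix_sigma2 is not None:
            s2 = fix_sigma2
        if fix_nu2 is not None:
            n2 = fix_nu2
        if fix_gamma2 is not None:
            g2 = fix_gamma2
        return s2, n2, g2

    sigma2, nu2, gamma2 = _apply_fixed(sigma2, nu2, gamma2)

    converged = False
    it = 0
    mu = np.exp(np.clip(panel.X @ beta, -_EXP_CLIP, _EXP_CLIP))
    w = compute_weights(mu, gamma2, nu2, q)
    U_i, c_i, U_ij, c_ij = _blups_all(panel, mu, w, sigma2, nu2, gamma2, q)

    for it in range(1, max_iter + 1):
        old = np.concatenate((beta, [sigma2, nu2, gamma2]))

        score = mean_score(panel, mu, U_ij, gamma2, q)
        S = sensitivity_matrix(panel, mu, w, c_i, gamma2, nu2, q)
        try:
            step = np.linalg.solve(S, score)
        except np.linalg.LinAlgError as err:
            raise FittingError("singular sensitivity matrix") from err
        beta = beta - step

        mu = np.exp(np.clip(panel.X @ beta, -_EXP_CLIP, _EXP_CLIP))
        w = compute_weights(mu, gamma2, nu2, q)
        U_i, c_i, U_ij, c_ij = _blups_all(panel, mu, w, sigma2, nu2, gamma2, q)
        sigma2, nu2, gamma2 = estimate_dispersions(
            panel, mu, w, U_i, U_ij, c_i, c_ij, gamma2, q, two_level, gamma2_mode
        )
        sigma2, nu2, gamma2 = _apply_fixed(sigma2, nu2, gamma2)
        gamma2 = max(gamma2, 1e-10)
        w = compute_weights(mu, gamma2, nu2, q)
        U_i, c_i, U_ij, c_ij = _blups_all(panel, mu, w, sigma2, nu2, gamma2, q)

        new = np.concatenate((beta, [sigma2, nu2, gamma2]))
        rel = np.max(np.abs(new - old) / (np.abs(old) + 1e-4))
        if rel < tol:
            converged = True
            break

    if not converged:
        logger.warning("mean model did not converge in %d iterations", max_iter)

    S = sensitivity_matrix(panel, mu, w, c_i, gamma2, nu2, q)
    G = _score_by_subject(panel, mu, U_ij, gamma2, q)
    # m/(m-p) is the usual small-sample inflation of the empirical
    # score covariance in GEE sandwiches
    V = G.T @ G * (panel.m / max(panel.m - panel.p, 1))
    Sinv = np.linalg.inv(S)
    cov_beta = Sinv @ V @ Sinv.T
    cov_beta = 0.5 * (cov_beta + cov_beta.T)
    se = np.sqrt(np.maximum(np.diag(cov_beta), 0.0))

    fit = MeanFit(
        beta=beta,
        mu=mu,
        sigma2=sigma2,
        nu2=nu2,
        gamma2=gamma2,
        w=w,
        U_hat_i=U_i,
        U_hat_ij=U_ij,
        c_i=c_i,
        c_ij=c_ij,
        two_level=two_level,
        converged=converged,
        n_iter=it,
        cov_beta=cov_beta,
        se=se,
        columns=list(panel.columns),
    )
    return fit


def mean_fit_confint(fit: MeanFit, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Normal-theory confidence intervals for the mean coefficients."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    return fit.beta - z * fit.se, fit.beta + z * fit.se
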