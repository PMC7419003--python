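"""Synthetic panels from the generative model and the pseudo-population study.

The generator draws seizure-like covariates, two levels of gamma random
effects and a conditionally Poisson response:

    U_i   ~ Gamma(mean 1, var sigma^2)          (subject level)
    U_ij  | U_i ~ Gamma(mean u_i, var nu^2 u_i) (observation level)
    Y_ij  | U ~ Poisson(u_ij exp(x_ij' beta))

The study treats one large generated cohort (default 10000 subjects, 4
visits) as a pseudo-population, fits the model once on the full cohort to
obtain reference parameter values, then repeatedly samples small cohorts
(default 59 subjects, matching the epilepsy panel) without replacement and
summarizes bias, average standard errors and 95% interval coverage per
parameter, per quantile level and per dispersion structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .panel_io import PanelData, VISIT_CODES
from .tweedie_mean import TweedieSpec, fit_mean_model, mean_fit_confint
from .quantile_gee import bootstrap_se, fit_quantile

logger = logging.getLogger("tweedieqr")

#: Generating mean-model coefficients of the seizure-like study design
#: (Intercept, Base, Trt, Age, Visit, Base.Trt).
DEFAULT_BETA = (-1.30, 0.88, -0.88, 0.50, -0.23, 0.34)
COLUMNS = ["Intercept", "Base", "Trt", "Age", "Visit", "Base.Trt"]

# Negative-binomial baseline counts matched to the epilepsy panel moments
# (mean ~31, variance ~720).
_BASE_MEAN = 31.0
_BASE_VAR = 720.0


@dataclass
class SimulationConfig:
    """Parameters, shapes and sizes of the pseudo-population study."""

    beta_true: tuple = DEFAULT_BETA
    sigma2: float = 0.24
    nu2: float = 0.44
    gamma2: float = 1.0  # Poisson response: natural dispersion 1 in generation
    q: int = 1
    r: int = 2
    t: int = 2
    m_pop: int = 10000
    m_sample: int = 59
    n_visits: int = 4
    n_reps: int = 500
    n_boot: int = 0  # 0 disables bootstrap; ESD then uses asymptotic SEs
    taus: tuple = (0.25, 0.5, 0.85)
    seed: int = 0
    covariate_scheme: str = "seizure-like"
    fit_tol: float = 1e-6
    fit_max_iter: int = 1000
    #: restrict bootstrap SEs to these quantile levels / structures
    #: (None means all); keeps the study affordable at small n_boot
    boot_taus: tuple | None = None
    boot_structures: tuple = ("two_level", "one_level")

    def __post_init__(self) -> None:
        if self.m_sample > self.m_pop:
            raise ValueError("m_sample cannot exceed m_pop")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if min(self.sigma2, self.nu2, self.gamma2) < 0:
            raise ValueError("dispersions must be nonnegative")


def generate_covariates(
    m: int, n: int, scheme: str = "seizure-like", seed: int = 0
) -> tuple[np.ndarray, list[str]]:
    """Covariate rows for m subjects with n visits each.

    The seizure-like scheme mimics the epilepsy panel: per-subject Base =
    log(quarter of a negative-binomial baseline count), Trt ~ Bernoulli(0.5),
    Age = log of an integer uniform on [18, 42]; Visit cycles the centred
    linear codes; the interaction column is Base*Trt.
    """
    if scheme != "seizure-like":
        raise NotImplementedError(f"covariate scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    size = _BASE_MEAN**2 / (_BASE_VAR - _BASE_MEAN)
    p_nb = size / (size + _BASE_MEAN)
    b_counts = np.maximum(rng.negative_binomial(size, p_nb, size=m), 1)
    base = np.log(b_counts / 4.0)
    trt = rng.integers(0, 2, size=m).astype(float)
    age = np.log(rng.integers(18, 43, size=m).astype(float))
    visit = np.resize(np.asarray(VISIT_CODES), n)
    X = np.empty((m * n, 6))
    X[:, 0] = 1.0
    X[:, 1] = np.repeat(base, n)
    X[:, 2] = np.repeat(trt, n)
    X[:, 3] = np.repeat(age, n)
    X[:, 4] = np.tile(visit, m)
    X[:, 5] = X[:, 1] * X[:, 2]
    return X, list(COLUMNS)


def generate_random_effects(
    m: int,
    n_i: np.ndarray | int,
    sigma2: float,
    nu2: float,
    r: int = 2,
    t: int = 2,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the two levels of gamma random effects.

    U_i has mean 1 and variance sigma^2 (Gamma shape 1/sigma^2); given u_i,
    U_ij has mean u_i and variance nu^2 u_i (Gamma shape u_i/nu^2, scale
    nu^2).  sigma^2 = 0 degenerates U_i to 1 and nu^2 = 0 sets U_ij = U_i.
    Only the gamma shapes (r = t = 2) are implemented.
    """
    if r != 2 or t != 2:
        raise NotImplementedError("only gamma random effects (r = t = 2)")
    rng = np.random.default_rng(seed)
    n_i = np.full(m, n_i, dtype=int) if np.isscalar(n_i) else np.asarray(n_i, int)
    if sigma2 > 0:
        U_i = rng.gamma(shape=1.0 / sigma2, scale=sigma2, size=m)
    else:
        U_i = np.ones(m)
    u_rep = np.repeat(U_i, n_i)
    if nu2 > 0:
        U_ij = rng.gamma(shape=u_rep / nu2, scale=nu2)
    else:
        U_ij = u_rep.copy()
    return U_i, U_ij


def generate_panel(
    config: SimulationConfig, m: int | None = None, seed: int | None = None
) -> tuple[PanelData, np.ndarray, np.ndarray]:
    """Generate a panel plus the true random effects used (for diagnostics)."""
    m = config.m_pop if m is None else m
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    s_cov, s_u, s_y = rng.integers(0, 2**31 - 1, size=3)
    X, cols = generate_covariates(m, config.n_visits, config.covariate_scheme, s_cov)
    U_i, U_ij = generate_random_effects(
        m, config.n_visits, config.sigma2, config.nu2, config.r, config.t, s_u
    )
    mu = np.exp(X @ np.asarray(config.beta_true))
    y_rng = np.random.default_rng(s_y)
    if config.q == 1:
        y = y_rng.poisson(U_ij * mu).astype(float)
    elif config.q == 0:
        sd = np.sqrt(config.gamma2 * U_ij)
        y = np.maximum(y_rng.normal(U_ij * mu, sd), 0.0)
    else:
        raise NotImplementedError("response generation supports q in {0, 1}")
    subject_ids = np.repeat(np.arange(m), config.n_visits)
    panel = PanelData(subject_ids=subject_ids, y=y, X=X, columns=cols)
    return panel, U_i, U_ij


# ---------------------------------------------------------------------------
# pseudo-population study


def _param_names(columns: list[str]) -> list[str]:
    return [f"beta{k}" for k in range(len(columns))]


def _fit_both(
    panel,
    config,
    two_level,
    tol,
    max_iter,
    taus,
    gamma_mode="identity",
    warm=None,
):
    """Mean fit plus quantile fits at each tau for one dispersion structure."""
    spec = TweedieSpec(q=config.q, r=config.r, t=config.t)
    ws_mean = warm[0] if warm is not None else None
    mf = fit_mean_model(
        panel, spec, two_level=two_level, tol=tol, max_iter=max_iter,
        warm_start=ws_mean,
    )
    qfs = {
        tau: fit_quantile(
            panel, mf, tau, gamma_mode, tol=tol, max_iter=100,
            beta_init=None if warm is None else warm[1].get(tau),
        )
        for tau in taus
    }
    return mf, qfs


def run_simulation_study(config: SimulationConfig) -> dict:
    """Run the full pseudo-population simulation and summarize it.

    Returns a dict with keys ``summary`` (tidy DataFrame: block, parameter,
    structure, Bias, ESD, CP), ``reference`` (pseudo-population fits used as
    the bias reference), ``truth`` (generating parameters), ``n_converged``,
    ``esd_source`` and ``config``.  Fully reproducible given the config seed.
    """
    pop, U_i_true, U_ij_true = generate_panel(config)
    p = pop.p
    structures = [("two_level", True), ("one_level", False)]

    reference: dict[str, dict] = {}
    warm: dict[str, tuple] = {}
    for name, two in structures:
        mf, qfs = _fit_both(pop, config, two, 1e-8, 5000, config.taus)
        reference[name] = {
            "beta": mf.beta.copy(),
            "sigma2": mf.sigma2,
            "nu2": mf.nu2,
            "beta_tau": {tau: qfs[tau].beta_tau.copy() for tau in config.taus},
        }
        warm[name] = (mf, {tau: qfs[tau].beta_tau for tau in config.taus})

    rng = np.random.default_rng(config.seed + 1)
    rows = []  # replicate-level records
    n_conv = {name: 0 for name, _ in structures}
    for rep in range(config.n_reps):
        idx = rng.choice(config.m_pop, size=config.m_sample, replace=False)
        sub = pop.subset(idx)
        first = int(idx[0])
        u1_true = U_i_true[first]
        u11_true = U_ij_true[first * config.n_visits]
        for name, two in structures:
            try:
                # replicates re-run the estimator from its own initial values
                # (quasi-GLM beta, default dispersions); warm-starting at the
                # population solution can pin fits to a different branch of
                # the estimating equations and bias the replicate estimates
                mf, qfs = _fit_both(
                    sub, config, two, config.fit_tol, config.fit_max_iter,
                    config.taus,
                )
            except Exception:
                logger.warning("replicate %d (%s) failed", rep, name)
                continue
            if not mf.converged:
                continue
            n_conv[name] += 1
            lo, hi = mean_fit_confint(mf)
            ref = reference[name]
            rec = {
                "rep": rep,
                "structure": name,
                "sigma2": mf.sigma2,
                "nu2": mf.nu2,
                "U1_cover": float(
                    abs(mf.U_hat_i[0] - u1_true) <= 1.96 * np.sqrt(max(mf.c_i[0], 0))
                ),
            }
            if two:
                rec["U11_cover"] = float(
                    abs(mf.U_hat_ij[0] - u11_true) <= 1.96 * np.sqrt(max(mf.c_ij[0], 0))
                )
            for k in range(p):
                rec[f"mean_beta{k}"] = mf.beta[k]
                rec[f"mean_se{k}"] = mf.se[k]
                rec[f"mean_cover{k}"] = float(lo[k] <= ref["beta"][k] <= hi[k])
            for tau in config.taus:
                qf = qfs[tau]
                if not qf.converged:
                    continue
                do_boot = (
                    config.n_boot > 1
                    and name in config.boot_structures
                    and (config.boot_taus is None or tau in config.boot_taus)
                )
                if do_boot:
                    # bootstrap gives the unconditional SD; use it for the CI
                    se_ci = bootstrap_se(
                        sub,
                        tau,
                        B=config.n_boot,
                        seed=int(rng.integers(0, 2**31 - 1)),
                        two_level=two,
                        tol=max(config.fit_tol, 1e-5),
                        parent=(mf, qf),
                    )
                    se_ci = np.where(np.isfinite(se_ci), se_ci, qf.se)
                else:
                    se_ci = qf.se
                for k in range(p):
                    est = qf.beta_tau[k]
                    rtau = ref["beta_tau"][tau][k]
                    rec[f"q{tau}_beta{k}"] = est
                    rec[f"q{tau}_se{k}"] = se_ci[k]
                    rec[f"q{tau}_cover{k}"] = float(
                        est - 1.96 * se_ci[k] <= rtau <= est + 1.96 * se_ci[k]
                    )
            rows.append(rec)

    reps = pd.DataFrame(rows)
    summary_rows = []
    for name, two in structures:
        d = reps[reps["structure"] == name]
        ref = reference[name]
        for k in range(p):
            summary_rows.append(
                {
                    "block": "mean",
                    "parameter": f"beta{k}",
                    "structure": name,
                    "Bias": d[f"mean_beta{k}"].mean() - ref["beta"][k],
                    "ESD": d[f"mean_se{k}"].mean(),
                    "MC_SD": d[f"mean_beta{k}"].std(ddof=1),
                    "CP": d[f"mean_cover{k}"].mean(),
                    "SE_source": "sandwich",
                }
            )
        summary_rows.append(
            {
                "block": "mean",
                "parameter": "sigma2",
                "structure": name,
                "Bias": d["sigma2"].mean() - ref["sigma2"],
                "ESD": np.nan,
                "CP": np.nan,
            }
        )
        if two:
            summary_rows.append(
                {
                    "block": "mean",
                    "parameter": "nu2",
                    "structure": name,
                    "Bias": d["nu2"].mean() - ref["nu2"],
                    "ESD": np.nan,
                    "CP": np.nan,
                }
            )
        summary_rows.append(
            {
                "block": "mean",
                "parameter": "U1",
                "structure": name,
                "Bias": np.nan,
                "ESD": np.nan,
                "CP": d["U1_cover"].mean(),
            }
        )
        if two:
            summary_rows.append(
                {
                    "block": "mean",
                    "parameter": "U11",
                    "structure": name,
                    "Bias": np.nan,
                    "ESD": np.nan,
                    "CP": d["U11_cover"].mean(),
                }
            )
        for tau in config.taus:
            boot_here = (
                config.n_boot > 1
                and name in config.boot_structures
                and (config.boot_taus is None or tau in config.boot_taus)
            )
            for k in range(p):
                col = f"q{tau}_beta{k}"
                if col not in d:
                    continue
                ok = d[col].notna()
                summary_rows.append(
                    {
                        "block": f"tau={tau}",
                        "parameter": f"beta{k}",
                        "structure": name,
                        "Bias": d.loc[ok, col].mean() - ref["beta_tau"][tau][k],
                        "ESD": d.loc[ok, f"q{tau}_se{k}"].mean(),
                        "MC_SD": d.loc[ok, col].std(ddof=1),
                        "CP": d.loc[ok, f"q{tau}_cover{k}"].mean(),
                        "SE_source": "bootstrap" if boot_here else "asymptotic",
                    }
                )
    summary = pd.DataFrame(summary_rows)
    return {
        "summary": summary,
        "replicates": reps,
        "reference": reference,
        "truth": {
            "beta": np.asarray(config.beta_true),
            "sigma2": config.sigma2,
            "nu2": config.nu2,
        },
        "n_converged": n_conv,
        "esd_source": "bootstrap" if config.n_boot > 1 else "asymptotic",
        "config": asdict(config),
    }
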