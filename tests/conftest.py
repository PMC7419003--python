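"""Shared fixtures: the seizure panel, small synthetic panels, stub fits."""

from pathlib import Path

import numpy as np
import pytest

import tweedieqr as tq
from tweedieqr.panel_io import PanelData
from tweedieqr.tweedie_mean import MeanFit

DATA_DIR = Path(__file__).resolve().parent.parent / "data"


@pytest.fixture(scope="session")
def epilepsy_path() -> Path:
    return DATA_DIR / "epilepsy.csv"


@pytest.fixture(scope="session")
def epilepsy(epilepsy_path) -> PanelData:
    return tq.load_epilepsy(epilepsy_path)


@pytest.fixture()
def tiny_panel() -> PanelData:
    """3 subjects x 2-3 records, intercept + one covariate."""
    rng = np.random.default_rng(42)
    n_i = [2, 3, 2]
    subj = np.repeat(["a", "b", "c"], n_i)
    x = rng.normal(size=7)
    X = np.column_stack([np.ones(7), x])
    y = rng.poisson(np.exp(0.5 + 0.3 * x)).astype(float)
    return PanelData(subject_ids=subj, y=y, X=X, columns=["Intercept", "x"])


def make_unit_mean_fit(panel: PanelData, beta=None, omega_scale=0.01) -> MeanFit:
    """MeanFit stub with U == 1, no random-effect uncertainty, gamma^2 = 1.

    Used to exercise the quantile machinery in the pure fixed-effects case;
    ``omega_scale`` sets the induced-smoothing bandwidth matrix to
    omega_scale * I (0.01 is the package's own fallback value).
    """
    N = panel.n_records
    beta = np.zeros(panel.p) if beta is None else np.asarray(beta, float)
    mu = np.exp(panel.X @ beta)
    return MeanFit(
        beta=beta,
        mu=mu,
        sigma2=0.0,
        nu2=0.0,
        gamma2=1.0,
        w=np.ones(N),
        U_hat_i=np.ones(panel.m),
        U_hat_ij=np.ones(N),
        c_i=np.zeros(panel.m),
        c_ij=np.zeros(N),
        two_level=False,
        converged=True,
        n_iter=1,
        cov_beta=omega_scale * np.eye(panel.p),
        se=np.full(panel.p, 1e-3),
        columns=list(panel.columns),
    )


@pytest.fixture()
def unit_mean_fit_factory():
    return make_unit_mean_fit
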