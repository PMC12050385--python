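"""Probability-of-normothermy model.

Hibernating heterotherms alternate between two physiological states:
energetically cheap torpor and expensive normothermy. This module fits the
probability that an individual is normothermic as a function of ambient
temperature from binary state records (normothermy = 1, torpor = 0), using a
binomial GLMM with a per-individual Gaussian random intercept on the link
scale, and converts the fitted probability into daily minutes per state.

Because captive experiments cannot safely expose animals to temperatures far
below the torpor minimum, predictions below the mirror temperature are
extrapolated by reflecting the fitted curve: the effective temperature is
``mirror_temp + |ta - mirror_temp|``, so the probability of normothermy rises
symmetrically on both sides of the mirror point. No ceiling is applied on the
warm side; with the heavy-tailed cauchit link the probability tends to 1 only
at extreme temperatures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess

from ._links import LINKS, inverse_link, statsmodels_link

__all__ = [
    "StateModel",
    "fit_state_model",
    "select_link",
    "predict_p_normothermy",
    "state_minutes",
    "read_state_records",
]

MINUTES_PER_DAY = 1440

#: Required columns of a state-record table.
STATE_COLUMNS = ["individual_id", "timestamp", "chamber_temp", "state"]


@dataclass
class StateModel:
    """Fitted state-probability model (population level).

    ``beta0`` and ``beta1`` are link-scale intercept and slope per °C of
    effective temperature; ``re_sd`` is the estimated standard deviation of
    the individual random intercept. Predictions marginalise the random
    effect by evaluating at its mean (zero).
    """

    link: str
    beta0: float
    beta1: float
    mirror_temp: float = 2.0
    re_sd: float = 0.0
    fit_diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.link not in LINKS:
            raise ValueError(f"unknown link {self.link!r}")

    def to_json(self, path=None) -> str:
        payload = {
            "link": self.link,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "mirror_temp": self.mirror_temp,
            "re_sd": self.re_sd,
            "fit_diagnostics": self.fit_diagnostics,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "StateModel":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            source = Path(source).read_text()
        return cls(**json.loads(source))


def read_state_records(path) -> pd.DataFrame:
    """Read a state-record CSV (individual_id, timestamp, chamber_temp, state)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in STATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"state records missing columns: {missing}")
    return df


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    if not {"individual_id", "chamber_temp", "state"} <= set(records.columns):
        raise ValueError("records need individual_id, chamber_temp and state columns")
    states = set(pd.unique(records["state"]))
    if not states <= {0, 1}:
        raise ValueError(f"state must be binary 0/1, found {states}")
    if len(states) < 2:
        raise ValueError("degenerate fit: records contain a single state")
    if records["chamber_temp"].nunique() < 2:
        raise ValueError("rank deficiency: records contain a single temperature")
    return records


def _mixed_nll_factory(y_by_ind, ta_by_ind, inv, n_quad=25):
    # Marginal likelihood integrates the Gaussian random intercept with
    # Gauss-Hermite quadrature (probabilists' weights sum to sqrt(2*pi)).
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    weights = weights / np.sqrt(2.0 * np.pi)

    def nll(theta):
        beta0, beta1, log_sd = theta
        sd = np.exp(log_sd)
        total = 0.0
        for y, ta in zip(y_by_ind, ta_by_ind):
            eta = beta0 + beta1 * ta
            p = inv(eta[:, None] + sd * nodes[None, :])
            p = np.clip(p, 1e-12, 1.0 - 1e-12)
            logp = np.where(y[:, None] == 1, np.log(p), np.log1p(-p)).sum(axis=0)
            mx = logp.max()
            total += np.log(np.exp(logp - mx) @ weights) + mx
        return -total

    return nll


def fit_state_model(
    records: pd.DataFrame,
    link: str = "cauchit",
    mirror_temp: float = 2.0,
    n_quad: int = 25,
) -> StateModel:
    """Fit the binomial GLMM by Gauss–Hermite maximum likelihood.

    The optimiser is warm-started from a population-average GLM with the same
    link. Standard errors come from the inverse numerical Hessian of the
    marginal negative log-likelihood; the reported AIC is marginal
    (3 parameters: intercept, slope, random-intercept SD).

    Raises ``ValueError`` for single-state (degenerate) or
    single-temperature (rank-deficient) data.
    """
    records = _validate_records(records)
    inv = inverse_link(link)

    y_all = records["state"].to_numpy(dtype=float)
    ta_all = records["chamber_temp"].to_numpy(dtype=float)
    X = sm.add_constant(ta_all)
    glm = sm.GLM(
        y_all, X, family=sm.families.Binomial(statsmodels_link(link))
    ).fit(maxiter=200)

    groups = [g for _, g in records.groupby("individual_id", sort=True)]
    y_by_ind = [g["state"].to_numpy(dtype=float) for g in groups]
    ta_by_ind = [g["chamber_temp"].to_numpy(dtype=float) for g in groups]
    nll = _mixed_nll_factory(y_by_ind, ta_by_ind, inv, n_quad=n_quad)

    start = np.array([glm.params[0], glm.params[1], np.log(0.3)])
    res = optimize.minimize(
        nll, start, method="Nelder-Mead",
        options=dict(maxiter=4000, xatol=1e-6, fatol=1e-9),
    )
    beta0, beta1, log_sd = res.x
    loglik = -res.fun
    k = 3
    try:
        hess = approx_hess(res.x, nll)
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:  # flat direction: fall back on GLM SEs
        se = np.array([glm.bse[0], glm.bse[1], np.nan])
    diagnostics = {
        "loglik": float(loglik),
        "aic": float(2 * k - 2 * loglik),
        "n_obs": int(len(records)),
        "n_individuals": int(records["individual_id"].nunique()),
        "se_beta0": float(se[0]),
        "se_beta1": float(se[1]),
        "se_log_re_sd": float(se[2]),
        "converged": bool(res.success),
    }
    return StateModel(
        link=link,
        beta0=float(beta0),
        beta1=float(beta1),
        mirror_temp=float(mirror_temp),
        re_sd=float(np.exp(log_sd)),
        fit_diagnostics=diagnostics,
    )


def select_link(
    records: pd.DataFrame,
    candidates: list[str],
    mirror_temp: float = 2.0,
) -> str:
    """Pick the candidate link with the lowest marginal AIC (ties: first)."""
    if len(candidates) < 1:
        raise ValueError("need at least one candidate link")
    best_name, best_aic = None, np.inf
    for name in candidates:
        model = fit_state_model(records, link=name, mirror_temp=mirror_temp)
        aic = model.fit_diagnostics["aic"]
        if aic < best_aic:  # strict: earlier candidate wins ties
            best_name, best_aic = name, aic
    return best_name


def effective_temperature(model: StateModel, ta):
    """Mirror rule: reflect temperatures below the mirror point upward."""
    ta = np.asarray(ta, dtype=float)
    return model.mirror_temp + np.abs(ta - model.mirror_temp)


def predict_p_normothermy(model: StateModel, ta):
    """Probability of normothermy at ambient temperature ``ta`` (°C).

    Applies the mirror rule, then the inverse link at the population-level
    linear predictor. Returns values strictly inside (0, 1).
    """
    inv = inverse_link(model.link)
    eta = model.beta0 + model.beta1 * effective_temperature(model, ta)
    p = inv(eta)
    return np.clip(p, np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))


def state_minutes(model: StateModel, ta):
    """Daily minutes in (normothermy, torpor); the two always sum to 1440."""
    minutes_n = MINUTES_PER_DAY * predict_p_normothermy(model, ta)
    return minutes_n, MINUTES_PER_DAY - minutes_n
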