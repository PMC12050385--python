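"""Thermoregulatory curves from steady-state respirometry.

Metabolic rate as a function of ambient temperature differs sharply between
the two physiological states:

* **normothermy** follows a Scholander–Irving line — a plateau ``mtnz`` above
  the lower critical temperature ``t_lc`` and a linear rise with slope
  ``c_n`` per °C of cooling below it;
* **torpor** is minimal (``m_tmin``) at the thermoconforming minimum
  ``t_min``; above it the torpid rate rises exponentially with temperature
  (Q10-type coefficient ``k``), below it the animal defends its body
  temperature and the rate rises linearly with slope ``c_r`` per °C of
  cooling (regulated torpor).

The fit is a two-component latent-state mixture with lognormal residuals:
each steady-state mean is classified as normothermic or torpid as part of
the likelihood, with no reliance on skin temperature.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools.numdiff import approx_hess

__all__ = [
    "RESP_COLUMNS",
    "ThermoCurves",
    "steady_state_means",
    "vco2_to_power",
    "fit_thermo_curves",
    "predict_mr",
    "thermoconforming_minimum",
    "read_respirometry_records",
    "read_steady_state_means",
]

#: kJ released per litre of CO2 at a respiratory quotient of 0.7 (fat catabolism).
KJ_PER_L_CO2 = 27.8

RESP_COLUMNS = ["individual_id", "timestamp", "chamber_temp", "skin_temp", "vco2"]
MEAN_COLUMNS = ["individual_id", "chamber_temp", "mean_rate", "n_points"]


@dataclass
class ThermoCurves:
    """Fitted two-state thermoregulatory model (rates in kJ/h, temps in °C)."""

    mtnz: float          # plateau rate above the lower critical temperature
    t_lc: float          # lower critical temperature
    c_n: float           # normothermic slope (kJ/h per °C below t_lc)
    t_min: float         # thermoconforming minimum
    m_tmin: float        # minimal torpid rate, at t_min
    c_r: float           # regulated-torpor slope (kJ/h per °C below t_min)
    k: float             # exponential coefficient of thermoconforming torpor (per °C)
    sigma: float = 0.10  # lognormal residual SD (log scale)
    uncertainty: dict = field(default_factory=dict)  # param -> (lo, hi)
    state_assignments: list = field(default_factory=list, repr=False)

    def to_json(self, path=None) -> str:
        payload = {
            f: getattr(self, f)
            for f in ("mtnz", "t_lc", "c_n", "t_min", "m_tmin", "c_r", "k", "sigma")
        }
        payload["uncertainty"] = {k: list(v) for k, v in self.uncertainty.items()}
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ThermoCurves":
        if isinstance(source, (str, Path)) and Path(str(source)).exists():
            source = Path(source).read_text()
        data = json.loads(source)
        data["uncertainty"] = {k: tuple(v) for k, v in data.get("uncertainty", {}).items()}
        return cls(**data)


def read_respirometry_records(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in RESP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"respirometry records missing columns: {missing}")
    return df


def read_steady_state_means(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MEAN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"steady-state means missing columns: {missing}")
    return df


def vco2_to_power(vco2):
    """Convert CO2 production (L/h) to power (kJ/h) at RQ 0.7 (27.8 kJ/L)."""
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vco2 < 0):
        raise ValueError("vco2 must be non-negative")
    out = vco2 * KJ_PER_L_CO2
    return float(out) if out.ndim == 0 else out


def steady_state_means(
    records: pd.DataFrame,
    min_window_minutes: float = 3.0,
    sd_rate_max: float = 0.2,
    sd_skin_max: float = 0.5,
    rate_column: str = "vco2",
    chamber_tol: float = 1.0,
    max_gap_minutes: float = 30.0,
) -> pd.DataFrame:
    """Screen measurement windows for stability and average the stable ones.

    Records are grouped per individual into contiguous windows: a new window
    starts when the time gap exceeds ``max_gap_minutes`` or the chamber
    temperature departs by more than ``chamber_tol`` °C from the window's
    start. A window contributes one mean iff it spans at least
    ``min_window_minutes`` and both stability criteria hold (SD of the rate
    < ``sd_rate_max`` and SD of skin temperature < ``sd_skin_max``).
    Unstable or too-short windows are silently discarded; empty input yields
    an empty table.
    """
    out = []
    if len(records) == 0:
        return pd.DataFrame(columns=MEAN_COLUMNS)
    for ind, g in records.groupby("individual_id", sort=True):
        g = g.sort_values("timestamp")
        t = pd.to_datetime(g["timestamp"]).to_numpy()
        temp = g["chamber_temp"].to_numpy(dtype=float)
        gaps = np.diff(t) / np.timedelta64(1, "m")
        window_id = np.zeros(len(g), dtype=int)
        start_temp = temp[0]
        for i in range(1, len(g)):
            if gaps[i - 1] > max_gap_minutes or abs(temp[i] - start_temp) > chamber_tol:
                window_id[i] = window_id[i - 1] + 1
                start_temp = temp[i]
            else:
                window_id[i] = window_id[i - 1]
        for _, w in g.groupby(window_id):
            span = (w["timestamp"].iloc[-1] - w["timestamp"].iloc[0]) / pd.Timedelta(minutes=1)
            if span < min_window_minutes:
                continue
            sd_rate = w[rate_column].std(ddof=1) if len(w) > 1 else 0.0
            sd_skin = w["skin_temp"].std(ddof=1) if len(w) > 1 else 0.0
            if sd_rate < sd_rate_max and sd_skin < sd_skin_max:
                out.append(
                    {
                        "individual_id": ind,
                        "chamber_temp": float(w["chamber_temp"].mean()),
                        "mean_rate": float(w[rate_column].mean()),
                        "n_points": int(len(w)),
                    }
                )
    return pd.DataFrame(out, columns=MEAN_COLUMNS)


def _rate_normothermy(ta, mtnz, t_lc, c_n):
    ta = np.asarray(ta, dtype=float)
    return np.where(ta >= t_lc, mtnz, mtnz + c_n * (t_lc - ta))


def _rate_torpor(ta, t_min, m_tmin, c_r, k):
    ta = np.asarray(ta, dtype=float)
    return np.where(
        ta < t_min,
        m_tmin + c_r * (t_min - ta),
        m_tmin * np.exp(k * (ta - t_min)),
    )


_PARAM_NAMES = ["mtnz", "t_lc", "c_n", "t_min", "m_tmin", "c_r", "k", "log_sigma", "logit_w"]
_BOUNDS = [
    (0.05, 3.0),            # mtnz
    (15.0, 35.0),           # t_lc
    (0.01, 0.5),            # c_n
    (0.0, 15.0),            # t_min (weakly informative range)
    (1e-3, 0.5),            # m_tmin
    (0.01, 0.5),            # c_r
    (0.01, 0.3),            # k
    (np.log(0.01), np.log(1.0)),  # log sigma
    (-5.0, 5.0),            # logit mixture weight
]


def _mixture_nll(theta, ta, log_rate):
    mtnz, t_lc, c_n, t_min, m_tmin, c_r, k, log_sigma, logit_w = theta
    sigma = np.exp(log_sigma)
    w = 1.0 / (1.0 + np.exp(-logit_w))
    # lognormal with mean equal to the curve value (mu = log m - sigma^2/2)
    mu_n = np.log(_rate_normothermy(ta, mtnz, t_lc, c_n)) - sigma**2 / 2
    mu_t = np.log(_rate_torpor(ta, t_min, m_tmin, c_r, k)) - sigma**2 / 2
    lp_n = stats.norm.logpdf(log_rate, mu_n, sigma) + np.log(w)
    lp_t = stats.norm.logpdf(log_rate, mu_t, sigma) + np.log1p(-w)
    mx = np.maximum(lp_n, lp_t)
    return -np.sum(mx + np.log(np.exp(lp_n - mx) + np.exp(lp_t - mx)))


def fit_thermo_curves(
    means: pd.DataFrame,
    rate_column: str = "mean_rate",
    ci_level: float = 0.95,
) -> ThermoCurves:
    """Fit the two-state mixture by constrained maximum likelihood.

    Deterministic multi-start L-BFGS-B (a small grid of starting values for
    the plateau and the thermoconforming minimum) guards against local
    optima. Intervals are Wald intervals from the numerical Hessian of the
    profile in the natural parametrisation. Each observation is assigned the
    state with the higher posterior component probability.

    Raises ``ValueError`` if every observation lands in one component
    (degenerate mixture) and ``RuntimeError`` if no start converges.
    """
    if len(means) < 10:
        raise ValueError("too few steady-state means to fit the mixture")
    ta = means["chamber_temp"].to_numpy(dtype=float)
    rate = means[rate_column].to_numpy(dtype=float)
    if np.any(rate <= 0):
        raise ValueError("metabolic rates must be positive")
    log_rate = np.log(rate)

    best = None
    for mtnz0, tmin0 in itertools.product((0.4, 0.7, 1.0), (3.0, 5.0, 7.0)):
        x0 = np.array([mtnz0, 30.0, 0.14, tmin0, 0.03, 0.14, 0.09, np.log(0.15), 0.0])
        res = optimize.minimize(
            _mixture_nll, x0, args=(ta, log_rate), method="L-BFGS-B", bounds=_BOUNDS
        )
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError("thermoregulatory mixture fit failed to converge from any start")

    theta = best.x
    mtnz, t_lc, c_n, t_min, m_tmin, c_r, k, log_sigma, logit_w = theta
    sigma = float(np.exp(log_sigma))
    w = 1.0 / (1.0 + np.exp(-logit_w))

    mu_n = np.log(_rate_normothermy(ta, mtnz, t_lc, c_n)) - sigma**2 / 2
    mu_t = np.log(_rate_torpor(ta, t_min, m_tmin, c_r, k)) - sigma**2 / 2
    lp_n = stats.norm.logpdf(log_rate, mu_n, sigma) + np.log(w)
    lp_t = stats.norm.logpdf(log_rate, mu_t, sigma) + np.log1p(-w)
    assignments = np.where(lp_n > lp_t, "normothermy", "torpor")
    if len(set(assignments)) < 2:
        raise ValueError("degenerate mixture: all observations assigned one state")

    z = stats.norm.ppf(0.5 + ci_level / 2)
    uncertainty = {}
    try:
        hess = approx_hess(theta, _mixture_nll, args=(ta, log_rate))
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        for name, value, s in zip(_PARAM_NAMES[:7], theta[:7], se[:7]):
            uncertainty[name] = (float(value - z * s), float(value + z * s))
    except np.linalg.LinAlgError:
        pass

    return ThermoCurves(
        mtnz=float(mtnz),
        t_lc=float(t_lc),
        c_n=float(c_n),
        t_min=float(t_min),
        m_tmin=float(m_tmin),
        c_r=float(c_r),
        k=float(k),
        sigma=sigma,
        uncertainty=uncertainty,
        state_assignments=list(assignments),
    )


def predict_mr(curves: ThermoCurves, ta, state: str):
    """Metabolic rate (kJ/h) at ``ta`` in the requested state.

    Extrapolation below the measured range follows the fitted lines.
    """
    if state in ("normothermy", "n"):
        out = _rate_normothermy(ta, curves.mtnz, curves.t_lc, curves.c_n)
    elif state in ("torpor", "t"):
        out = _rate_torpor(ta, curves.t_min, curves.m_tmin, curves.c_r, curves.k)
    else:
        raise ValueError(f"state must be 'normothermy' or 'torpor', got {state!r}")
    return float(out) if np.ndim(out) == 0 else out


def thermoconforming_minimum(curves: ThermoCurves):
    """Return (t_min, (lo, hi)) — the temperature of minimal torpid rate."""
    interval = curves.uncertainty.get("t_min", (np.nan, np.nan))
    return curves.t_min, interval
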