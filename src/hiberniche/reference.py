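"""Reference parameter set for the common noctule (*Nyctalus noctula*).

These are the published physiological estimates used throughout the
examples, tests and acceptance runs as the ground truth behind the
synthetic-data generators:

* state model (cauchit link, mirrored at 2 °C) anchored so that a bat at
  -5 °C spends 0.86 h/day in normothermy and one at 20 °C is normothermic
  99% of the time;
* thermoregulatory curves with thermoconforming minimum 4.5 °C, regulated-
  torpor slope 0.14 kJ/h per °C, torpid rate 1.35 kJ/h and normothermic
  rate 5.71 kJ/h at -5 °C (giving a minimal torpid rate of 0.02 kJ/h), a
  lower critical temperature of 30 °C with a 0.71 kJ/h plateau, and a
  Q10 of 2.5 for thermoconforming torpor;
* energy/season constants: huddling 0.5, insulation +5 °C, 27.8 kJ/L CO2,
  37.7 kJ/g fat, a 27 g fat budget (46 g pre-hibernation minus 19 g minimum
  mass), and the 7 °C / 14-day season rule.
"""

from __future__ import annotations

import numpy as np

from ._links import link_fun
from .budget import EnergyParams, SeasonParams
from .respirometry import ThermoCurves
from .state import StateModel

__all__ = [
    "reference_state_model",
    "reference_thermo_curves",
    "reference_energy_params",
    "reference_season_params",
]

# Anchors of the state model: (ambient temperature °C, probability of normothermy)
_ANCHOR_COLD = (-5.0, 0.86 / 24.0)   # 0.86 h/day normothermic at -5 °C
_ANCHOR_WARM = (20.0, 0.99)          # essentially always normothermic at 20 °C
_MIRROR = 2.0


def reference_state_model(re_sd: float = 0.5) -> StateModel:
    """Cauchit state model through the two reference anchors (mirror 2 °C)."""
    g = link_fun("cauchit")
    t_cold = _MIRROR + abs(_ANCHOR_COLD[0] - _MIRROR)
    t_warm = _MIRROR + abs(_ANCHOR_WARM[0] - _MIRROR)
    eta_cold, eta_warm = g(_ANCHOR_COLD[1]), g(_ANCHOR_WARM[1])
    beta1 = (eta_warm - eta_cold) / (t_warm - t_cold)
    beta0 = eta_cold - beta1 * t_cold
    return StateModel(
        link="cauchit", beta0=float(beta0), beta1=float(beta1),
        mirror_temp=_MIRROR, re_sd=re_sd,
        fit_diagnostics={"source": "reference anchors"},
    )


def reference_thermo_curves() -> ThermoCurves:
    """Two-state thermoregulatory curves anchored at the published estimates."""
    t_min, c_r = 4.5, 0.14
    m_at_minus5_torpor = 1.35
    m_tmin = m_at_minus5_torpor - c_r * (t_min - (-5.0))  # = 0.02 kJ/h
    t_lc, mtnz = 30.0, 0.71
    c_n = (5.71 - mtnz) / (t_lc - (-5.0))  # anchors Mn(-5 °C) = 5.71 kJ/h
    return ThermoCurves(
        mtnz=mtnz, t_lc=t_lc, c_n=c_n,
        t_min=t_min, m_tmin=m_tmin, c_r=c_r,
        k=float(np.log(2.5) / 10.0),  # Q10 = 2.5
        sigma=0.10,
    )


def reference_energy_params(**overrides) -> EnergyParams:
    return EnergyParams.from_masses(46.0, 19.0, **overrides)


def reference_season_params() -> SeasonParams:
    return SeasonParams()
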