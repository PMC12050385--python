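"""Binomial link functions shared by the state-probability model.

Each link maps a probability in (0, 1) to the real line; the inverse maps
back. The cauchit link (Cauchy CDF) has heavy tails, which lets the
probability of normothermy approach but never reach 0/1 even far from the
observed temperature range — the property that motivates its use here.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri
from statsmodels.genmod.families import links as _sm_links

__all__ = ["LINKS", "inverse_link", "link_fun", "statsmodels_link"]


def _cauchit_inv(eta):
    return 0.5 + np.arctan(eta) / np.pi


def _cauchit(p):
    return np.tan(np.pi * (np.asarray(p, dtype=float) - 0.5))


def _logit_inv(eta):
    return 1.0 / (1.0 + np.exp(-np.asarray(eta, dtype=float)))


def _logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p / (1.0 - p))


def _cloglog_inv(eta):
    return 1.0 - np.exp(-np.exp(np.asarray(eta, dtype=float)))


def _cloglog(p):
    return np.log(-np.log1p(-np.asarray(p, dtype=float)))


LINKS = {
    "cauchit": (_cauchit, _cauchit_inv),
    "logit": (_logit, _logit_inv),
    "probit": (ndtri, ndtr),
    "cloglog": (_cloglog, _cloglog_inv),
}

_SM = {
    "cauchit": _sm_links.Cauchy,
    "logit": _sm_links.Logit,
    "probit": _sm_links.Probit,
    "cloglog": _sm_links.CLogLog,
}


def _check(link: str) -> str:
    if link not in LINKS:
        raise ValueError(f"unknown link {link!r}; choose from {sorted(LINKS)}")
    return link


def inverse_link(link: str):
    """Return eta -> p for the named link."""
    return LINKS[_check(link)][1]


def link_fun(link: str):
    """Return p -> eta for the named link."""
    return LINKS[_check(link)][0]


def statsmodels_link(link: str):
    """Instantiate the matching statsmodels link (used for warm starts)."""
    return _SM[_check(link)]()
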