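import numpy as np
import pandas as pd
import pytest

import hiberniche as hn


@pytest.fixture(scope="session")
def ref_state_model():
    return hn.reference_state_model()


@pytest.fixture(scope="session")
def ref_curves():
    return hn.reference_thermo_curves()


@pytest.fixture(scope="session")
def ep_solitary_uninsulated():
    return hn.reference_energy_params(solitary=True, uninsulated=True)


@pytest.fixture(scope="session")
def ep_default():
    return hn.reference_energy_params()


def constant_winter(ta: float, winter_year: int = 2015,
                    location_id: str = "const") -> hn.TemperatureSeries:
    """Full winter window at a constant temperature."""
    dates = pd.date_range(f"{winter_year}-07-01", f"{winter_year + 1}-06-30", freq="D")
    dates = dates[~((dates.month == 2) & (dates.day == 29))]
    return hn.TemperatureSeries(
        location_id=location_id, winter_year=winter_year,
        dates=dates, ta=np.full(len(dates), float(ta)),
    )


def block_winter(cold_ta: float, warm_ta: float, cold_start: str, cold_end: str,
                 winter_year: int = 2015) -> hn.TemperatureSeries:
    """Winter that is ``warm_ta`` except for a cold block [cold_start, cold_end]."""
    series = constant_winter(warm_ta, winter_year)
    mask = (series.dates >= pd.Timestamp(cold_start)) & (
        series.dates <= pd.Timestamp(cold_end)
    )
    ta = series.ta.copy()
    ta[mask] = cold_ta
    return hn.TemperatureSeries(
        location_id="block", winter_year=winter_year, dates=series.dates, ta=ta
    )


@pytest.fixture(scope="session")
def ten_replicate_curve_fits(ref_curves):
    """Fit the thermoregulatory mixture to ten independently seeded synthetic
    respirometry experiments generated from the reference curves.

    Shared across the recovery-property and acceptance tests because the fits
    are the expensive part; the seeds are fixed and the fits deterministic.
    """
    fits = []
    for seed in range(1, 11):
        records = hn.simulate_respirometry(
            hn.RespSimConfig(true_curves=ref_curves, seed=seed)
        )
        means = hn.steady_state_means(records, rate_column="rate_kj_h")
        fits.append(hn.fit_thermo_curves(means))
    return fits
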