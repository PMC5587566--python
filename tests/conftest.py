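"""Shared fixtures: the reference synthetic city run (session-scoped, heavy)."""

import numpy as np
import pytest

from circarest.cli_io import RunConfig, analyze_city, default_city, extract_city
from circarest.solar import night_length_series
from circarest.synthgen import generate_calls, generate_temperatures, generate_users


@pytest.fixture(scope="session")
def city():
    return default_city()


@pytest.fixture(scope="session")
def nights(city):
    return night_length_series(city, 2007)


@pytest.fixture(scope="session")
def city_40n0e():
    from circarest.solar import CityConfig

    return CityConfig(name="test-40N", latitude=40.0, longitude=0.0, utc_offset=0.0, population=100000)


@pytest.fixture(scope="session")
def reference_run(city, nights):
    """Full simulate -> extract -> analyze at the reference conditions.

    2000 users (10% planted filter violations), 365 days, seed 1; the seed
    layout matches ``cmd_simulate`` (temperatures seed, users seed+1,
    calls seed+2).
    """
    cfg = RunConfig(seed=1)
    temps = generate_temperatures(
        city, cfg.year, cfg.temp_mean, cfg.temp_amplitude, cfg.temp_noise_sd, seed=cfg.seed
    )
    users, user_truth = generate_users(city, cfg.n_users, cfg.frac_invalid, seed=cfg.seed + 1)
    calls, truth = generate_calls(city, users, cfg.year, nights, temps, cfg.gen, seed=cfg.seed + 2)
    extract = extract_city(calls, users, cfg)
    summary = analyze_city(extract.resting, nights, temps, cfg)
    summary.pop("_crosscorr")
    return {
        "cfg": cfg,
        "temps": temps,
        "users": users,
        "user_truth": user_truth,
        "calls": calls,
        "truth": truth,
        "extract": extract,
        "summary": summary,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
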