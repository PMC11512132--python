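import datetime as dt

import numpy as np
import pytest

import searchtrend as st


def make_raw(values, start=dt.date(2016, 1, 1), label="13-18"):
    return st.RawDailySeries(group_label=label, start_date=start, values=np.asarray(values, float))


def year_series(year, values, label="g"):
    """Repeat/trim `values` to exactly fill calendar year `year`."""
    n = (dt.date(year + 1, 1, 1) - dt.date(year, 1, 1)).days
    v = np.resize(np.asarray(values, float), n)
    return make_raw(v, start=dt.date(year, 1, 1), label=label)


@pytest.fixture(scope="session")
def clean_config():
    """Zero-noise two-group panel with the published-shape multipliers."""
    return st.SyntheticConfig(
        groups=(
            st.adolescent_group(noise_sigma=0.0),
            st.adult_group(noise_sigma=0.0),
        ),
        seed=0,
    )


@pytest.fixture(scope="session")
def clean_panel(clean_config):
    return st.generate_panel(clean_config)


@pytest.fixture(scope="session")
def noisy_config():
    return st.default_config(seed=11)


@pytest.fixture(scope="session")
def noisy_panel(noisy_config):
    return st.generate_panel(noisy_config)


@pytest.fixture(scope="session")
def noisy_decomposed(noisy_panel):
    return {
        label: st.fft_bandsplit(st.annual_median_normalize(s))
        for label, s in noisy_panel.series_by_group.items()
    }
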