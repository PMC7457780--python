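import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from noctura import ActivitySeries, LightRegime, annotate_light

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

T0 = pd.Timestamp("2017-08-08 08:00:00")  # lights-on (ZT0) at 08:00
LD = LightRegime(lights_on_hour=8.0, photoperiod_hours=12.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20170808)


def make_series(counts, bin_minutes=60, t0=T0, fly_id="fly", flags=None):
    return ActivitySeries(
        fly_id=fly_id,
        t0=t0,
        bin_minutes=bin_minutes,
        counts=np.asarray(counts, dtype=np.int64),
        light_flags=None if flags is None else np.asarray(flags, dtype=object),
    )


def make_ld_series(counts, bin_minutes=60, t0=T0, fly_id="fly"):
    """Series starting at lights-on, annotated under LD 12:12."""
    return annotate_light(make_series(counts, bin_minutes, t0, fly_id), LD)


def dam_row(idx, time, status, ch1, date="8 Aug 17"):
    channels = [str(ch1)] + ["0"] * 31
    fields = [str(idx), date, time, str(status)] + ["0"] * 6 + channels
    return "\t".join(fields)


@pytest.fixture
def dam_writer(tmp_path):
    def _write(lines, name="Monitor1.txt"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write
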