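import numpy as np
import pandas as pd
import pytest

from geodetect import AccidentTable, FactorCoding


@pytest.fixture
def simple_coding():
    return {
        "x1": FactorCoding("x1", tuple((c, f"cat {c}") for c in range(1, 6))),
        "x2": FactorCoding("x2", ((1, "low"), (2, "high"))),
    }


def build_table(coding, fatalities, injuries, x1, x2, lon=None, lat=None):
    n = len(fatalities)
    frame = pd.DataFrame(
        {
            "record_id": [f"r{i}" for i in range(n)],
            "lon": lon if lon is not None else np.linspace(113.9, 114.4, n),
            "lat": lat if lat is not None else np.linspace(22.5, 22.8, n),
            "year": [2014 + i % 3 for i in range(n)],
            "fatalities": fatalities,
            "injuries": injuries,
            "x1": x1,
            "x2": x2,
        }
    )
    return AccidentTable(frame, coding)


@pytest.fixture
def small_table(simple_coding):
    return build_table(
        simple_coding,
        fatalities=[1, 0, 0, 2],
        injuries=[0, 2, 0, 1],
        x1=[1, 1, 2, 3],
        x2=[1, 2, 1, 2],
    )


@pytest.fixture(scope="session")
def shenzhen_table():
    from geodetect import generate, make_preset

    return generate(make_preset("shenzhen_like"), seed=11)
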