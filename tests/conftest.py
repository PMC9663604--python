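import numpy as np
import pytest

from photoresponse.curve_core import MRHParameters, ResponseCurve, ResponsePoint
from photoresponse.fitting import FitConfig
from photoresponse.io_cli import load_fixture, response_curves


@pytest.fixture(scope="session")
def table3():
    return load_fixture("table3_reference")


@pytest.fixture(scope="session")
def table6():
    return load_fixture("table6_reference")


@pytest.fixture(scope="session")
def light_curves():
    return response_curves(load_fixture("table2_light_response"))


@pytest.fixture(scope="session")
def co2_curves():
    return response_curves(load_fixture("table4_co2_response"))


@pytest.fixture(scope="session")
def rlc_table():
    return load_fixture("table5_rlc").table


@pytest.fixture(scope="session")
def light_r1_params(table3):
    r = table3["light"][0]
    return MRHParameters(e=r["e"], m=r["m"], n=r["n"], cp=r["cp"])


@pytest.fixture(scope="session")
def co2_r1_params(table3):
    r = table3["co2"][0]
    return MRHParameters(e=r["e"], m=r["m"], n=r["n"], cp=r["cp"])


@pytest.fixture
def fit_config():
    return FitConfig()


def make_curve(drivers, rates, axis_kind="light", repeat_id="t"):
    points = [ResponsePoint(driver=d, rate=r) for d, r in zip(drivers, rates)]
    return ResponseCurve(axis_kind=axis_kind, points=points, repeat_id=repeat_id)


@pytest.fixture
def simple_curve():
    params = MRHParameters(e=0.05, m=2e-4, n=0.01, cp=15.0)
    x = np.array([20.0, 50.0, 100.0, 200.0, 400.0, 800.0, 1200.0, 2000.0])
    from photoresponse.curve_core import mrh_predict

    return make_curve(x, mrh_predict(params, x)), params
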