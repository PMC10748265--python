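import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from chromval.calibration import CalibrationCurve
from chromval.synthetic import ResponseModel

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_curve(
    slope: float,
    intercept: float,
    slope_sd: float = 0.0,
    intercept_sd: float = 0.0,
    r: float = 1.0,
    range_low: float = 0.14,
    range_high: float = 245.0,
    n_points: int = 27,
    n_levels: int = 9,
    residual_sd: float = 0.0,
) -> CalibrationCurve:
    """Construct a curve directly from summary statistics (no raw data)."""
    return CalibrationCurve(
        slope=slope,
        intercept=intercept,
        slope_sd=slope_sd,
        intercept_sd=intercept_sd,
        r=r,
        r2=r * r,
        range_low=range_low,
        range_high=range_high,
        n_points=n_points,
        n_levels=n_levels,
        residual_sd=residual_sd,
    )


@pytest.fixture
def noiseless_response() -> ResponseModel:
    """The reference full-range response line with all noise switched off."""
    return ResponseModel(slope=15485.0, intercept=11659.0,
                         sigma_additive=0.0, cv_proportional=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230917)
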