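import numpy as np
import pytest

from tufkit import (
    GrowthSimParams,
    LabeledAlignment,
    PlateReaderSeries,
    ProteinSequence,
    simulate_growth_curve,
)


@pytest.fixture
def toy_alignment() -> LabeledAlignment:
    """Four-row alignment with one planted discriminating column (col 3).

    Viable rows agree everywhere; nonviable rows differ at column 3 and also
    vary at column 5 (where viables disagree too, so col 5 must not qualify).
    """
    rows = [
        ("ref", "ACDEF", "reference"),
        ("v1", "ACDEF", "viable"),
        ("v2", "ACDEG", "viable"),
        ("n1", "ACSEF", "nonviable"),
        ("n2", "ACDEF", "nonviable"),
    ]
    return LabeledAlignment(
        sequences=[ProteinSequence(i, s) for i, s, _ in rows],
        labels=[lab for _, _, lab in rows],
    )


@pytest.fixture
def noiseless_curve() -> tuple[PlateReaderSeries, PlateReaderSeries]:
    params = GrowthSimParams(
        doubling_time=25.0, lag_time=6.8, max_od=1.39, noise_sd=0.0, seed=0
    )
    ((sample, blank),) = simulate_growth_curve(params)
    return sample, blank


def ols_r_squared(x, y) -> float:
    """Independent R² oracle: 1 − SSres/SStot from a polyfit line."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return 1.0 - float((resid**2).sum()) / float(((y - y.mean()) ** 2).sum())
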