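"""Linear-dependency analysis of hotspot reliability.

Simple ordinary least squares of reliability on a hotspot summary statistic,
reported as the coefficient of determination R^2 = 1 - SSE/SST.  In the
published Naples case study, reliability shows a strong linear dependence on
the membership standard deviation (R^2 about 0.86) but essentially none on
the hotspot area (R^2 about 0.13): compact hotspots are not automatically
the reliable ones, while low membership fluctuation is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


class RegressionInputError(ValueError):
    """Mismatched or insufficient regression inputs."""


class DegenerateFitError(ValueError):
    """The predictor is constant; the slope is unidentifiable."""


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit summary for y ~ slope * x + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_observations: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise RegressionInputError("r_squared must lie in [0, 1]")
        if self.n_observations < 3:
            raise RegressionInputError("need at least 3 observations")


def linear_fit(x, y) -> RegressionResult:
    """Ordinary least squares of y on x with R^2.

    Constant x raises (the fit is unidentifiable); constant y returns
    R^2 = 0 with a warning (there is no variance to explain).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise RegressionInputError("x and y must have equal length")
    if x.size < 3:
        raise RegressionInputError("need at least 3 observations")
    if np.ptp(x) == 0.0:
        raise DegenerateFitError("x is constant; slope unidentifiable")
    if np.ptp(y) == 0.0:
        warnings.warn("y is constant; reporting r_squared = 0", stacklevel=2)
        return RegressionResult(slope=0.0, intercept=float(y[0]),
                                r_squared=0.0, n_observations=x.size)
    fit = stats.linregress(x, y)
    r2 = float(fit.rvalue) ** 2
    return RegressionResult(slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r_squared=min(r2, 1.0),
                            n_observations=x.size)
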