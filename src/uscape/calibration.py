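"""Extinction-coefficient calibration and dye-concentration selection.

The Beer-Lambert law makes absorbance bilinear in concentration and optical
path: ``A = eps * c * d``.  Calibrating against a depth series (several
known depths at one concentration) or a concentration series (several known
concentrations at one depth) therefore reduces to an ordinary least-squares
line of absorbance on the independent variable; the extinction coefficient
is the slope divided by the fixed quantity.  For Allura Red in the blue
channel the expected value is about 0.00052 / mM / um.

Quantification stays linear only while absorbance is modest; the working
rule is to pick a dye concentration keeping the deepest feature below
``A = 0.6``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "CalibrationSeries",
    "CalibrationFit",
    "ExtinctionCalibrator",
    "fit_series",
    "combine_fits",
    "recommend_concentration",
    "beer_lambert_absorbance",
]

MODES = ("depth_series", "concentration_series")
DEFAULT_A_MAX = 0.6


def beer_lambert_absorbance(epsilon: float, concentration_mm: float,
                            depth_um: float) -> float:
    """Predicted absorbance ``A = eps * c * d`` (dimensionless, log10)."""
    return epsilon * concentration_mm * depth_um


@dataclass
class CalibrationSeries:
    """A measured calibration standard series.

    ``independent`` holds depths (um) for a depth series at fixed
    concentration, or concentrations (mM) for a concentration series at
    fixed depth; ``fixed_value`` is the held-constant quantity.  Absorbance
    means/sds are per-point replicate statistics.
    """

    mode: str
    fixed_value: float
    independent: np.ndarray
    a_mean: np.ndarray
    a_sd: np.ndarray | None = None
    n_replicates: int = 3
    channel: str = "B"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        self.independent = np.asarray(self.independent, dtype=np.float64)
        self.a_mean = np.asarray(self.a_mean, dtype=np.float64)
        if self.a_sd is not None:
            self.a_sd = np.asarray(self.a_sd, dtype=np.float64)
        if self.independent.shape != self.a_mean.shape:
            raise ValueError("independent values and absorbances differ in length")
        if self.independent.size < 3:
            raise ValueError("a calibration series needs at least 3 points")
        if np.any(self.independent <= 0):
            raise ValueError("independent values must be strictly positive")
        if np.unique(self.independent).size != self.independent.size:
            raise ValueError("independent values must be distinct")
        if self.fixed_value <= 0:
            raise ValueError("fixed value must be positive")


@dataclass
class CalibrationFit:
    """OLS line of absorbance on depth or concentration, and derived eps."""

    slope: float
    intercept: float
    r_squared: float
    epsilon: float
    epsilon_sd: float
    channel: str
    mode: str
    valid: bool
    n_points: int
    diagnostics: dict = field(default_factory=dict)


class ExtinctionCalibrator(BaseEstimator):
    """Estimate the dye extinction coefficient from a standard series.

    sklearn-style estimator: ``fit(x, A)`` regresses absorbance on the
    independent variable (depth in um, or concentration in mM) with a free
    intercept; the intercept magnitude is reported as a quality diagnostic
    rather than forced to zero.

    Parameters
    ----------
    mode : {"depth_series", "concentration_series"}
        Which quantity varies along ``x``.
    fixed_value : float
        The held-constant concentration (mM) or depth (um).
    channel : {"R", "G", "B"}
        Color channel of the absorbances.  Blue is the standard choice for
        Allura Red (largest extinction coefficient, best linearity); fitting
        another channel emits a warning.
    weighted : bool
        If True, weight points by inverse replicate variance when sds are
        supplied to :meth:`fit`.

    Attributes
    ----------
    slope_, intercept_, r_squared_ : float
        OLS line diagnostics.
    epsilon_ : float
        Extinction coefficient in / mM / um (slope divided by fixed_value).
    epsilon_sd_ : float
        Standard error of ``epsilon_`` from the slope standard error.
    valid_ : bool
        False when the slope is non-positive (no usable signal).
    """

    def __init__(self, mode: str = "depth_series", fixed_value: float = 6.0,
                 channel: str = "B", weighted: bool = False):
        self.mode = mode
        self.fixed_value = fixed_value
        self.channel = channel
        self.weighted = weighted

    def fit(self, x, a_mean, a_sd=None):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.channel != "B":
            warnings.warn(
                f"calibrating in channel {self.channel!r}; blue is the "
                "standard choice (largest extinction coefficient)",
                stacklevel=2,
            )
        x = np.asarray(x, dtype=np.float64).ravel()
        a = np.asarray(a_mean, dtype=np.float64).ravel()
        if x.size < 3:
            raise ValueError("need at least 3 calibration points")
        if x.size != a.size:
            raise ValueError("x and absorbance lengths differ")

        if self.weighted and a_sd is not None:
            sd = np.asarray(a_sd, dtype=np.float64).ravel()
            w = 1.0 / np.maximum(sd, 1e-12) ** 2
            wm = np.polynomial.polynomial.polyfit(x, a, 1, w=np.sqrt(w))
            intercept, slope = wm
            pred = intercept + slope * x
            ss_res = float(np.sum(w * (a - pred) ** 2))
            ss_tot = float(np.sum(w * (a - np.average(a, weights=w)) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            stderr = float("nan")
        else:
            res = stats.linregress(x, a)
            slope, intercept = res.slope, res.intercept
            r2 = res.rvalue**2
            stderr = res.stderr

        self.slope_ = float(slope)
        self.intercept_ = float(intercept)
        self.r_squared_ = float(r2)
        self.epsilon_ = float(slope / self.fixed_value)
        self.epsilon_sd_ = float(stderr / self.fixed_value) if np.isfinite(
            stderr) else float("nan")
        self.valid_ = self.slope_ > 0
        if not self.valid_:
            warnings.warn("non-positive calibration slope; epsilon flagged "
                          "invalid", stacklevel=2)
        self.n_points_ = int(x.size)
        return self

    def predict(self, x):
        """Absorbance predicted by the fitted line at ``x``."""
        x = np.asarray(x, dtype=np.float64)
        return self.intercept_ + self.slope_ * x

    def to_fit(self) -> CalibrationFit:
        return CalibrationFit(
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            epsilon=self.epsilon_,
            epsilon_sd=self.epsilon_sd_,
            channel=self.channel,
            mode=self.mode,
            valid=self.valid_,
            n_points=self.n_points_,
        )


def fit_series(series: CalibrationSeries, weighted: bool = False) -> CalibrationFit:
    """Fit one calibration series; see :class:`ExtinctionCalibrator`."""
    cal = ExtinctionCalibrator(
        mode=series.mode,
        fixed_value=series.fixed_value,
        channel=series.channel,
        weighted=weighted,
    ).fit(series.independent, series.a_mean, series.a_sd)
    return cal.to_fit()


def combine_fits(fits: Sequence[CalibrationFit]) -> CalibrationFit:
    """Pool several calibration fits into one extinction coefficient.

    Valid fits are combined by inverse-variance weighting of their epsilon
    estimates; fits without a finite epsilon standard error get equal
    weight.  Invalid fits (non-positive slope) are excluded with a warning.
    """
    if len(fits) == 0:
        raise ValueError("need at least one fit")
    channels = {f.channel for f in fits}
    if len(channels) > 1:
        raise ValueError(f"cannot combine fits from mixed channels {channels}")
    usable = [f for f in fits if f.valid]
    if len(usable) < len(fits):
        warnings.warn(
            f"excluding {len(fits) - len(usable)} invalid fit(s) from pooling",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("no valid fits to combine")
    eps = np.array([f.epsilon for f in usable])
    sds = np.array([f.epsilon_sd for f in usable])
    if np.all(np.isfinite(sds)) and np.all(sds > 0):
        w = 1.0 / sds**2
    else:
        w = np.ones_like(eps)
    pooled = float(np.average(eps, weights=w))
    pooled_sd = float(1.0 / np.sqrt(w.sum())) if np.all(np.isfinite(sds)) and np.all(
        sds > 0) else float("nan")
    return CalibrationFit(
        slope=float("nan"),
        intercept=float("nan"),
        r_squared=float(min(f.r_squared for f in usable)),
        epsilon=pooled,
        epsilon_sd=pooled_sd,
        channel=usable[0].channel,
        mode="pooled",
        valid=True,
        n_points=int(sum(f.n_points for f in usable)),
        diagnostics={"per_fit_epsilon": [f.epsilon for f in usable]},
    )


def recommend_concentration(d_max_um: float, epsilon: float,
                            a_max: float = DEFAULT_A_MAX) -> float:
    """Dye concentration (mM) putting the deepest feature at ``a_max``.

    ``c = a_max / (eps * d_max)``: deeper structures call for more dilute
    dye so the darkest pixel stays in the linear regime (default bound 0.6).
    """
    if d_max_um <= 0 or epsilon <= 0:
        raise ValueError("depth and extinction coefficient must be positive")
    if a_max < 0:
        raise ValueError("absorbance bound must be non-negative")
    if a_max == 0:
        warnings.warn("a_max = 0 gives the degenerate recommendation c = 0",
                      stacklevel=2)
    return a_max / (epsilon * d_max_um)
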