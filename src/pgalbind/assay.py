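"""Assay arithmetic: probit IC50, linear calibration, ROS inhibition.

Dose-response curves (DPPH/ORAC-style fraction-inhibited data) are fitted
with a probit model, response = Phi(b0 + b1 * log10 c), by maximum likelihood
when replicate counts are available (binomial GLM with probit link) or by
least squares on the fractions otherwise; IC50 = 10^(-b0/b1) with a
delta-method standard error.  Linear calibration (Trolox equivalents,
TNBSA amino-acid quantification) is ordinary least squares with inverse
prediction.  ROS inhibition is the percent reduction of positive cells
relative to the control, 100 * (control - treated) / control.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib.resources import files

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "DoseResponse",
    "CalibrationCurve",
    "ProbitIC50Model",
    "ProbitIC50Results",
    "probit_ic50",
    "simulate_dose_response",
    "linear_calibration",
    "quantify",
    "inhibition_percent",
    "inhibition_table",
    "load_ros_table",
]


@dataclass
class DoseResponse:
    """Concentration/response table (responses are inhibition fractions)."""

    concentrations: np.ndarray
    responses: np.ndarray
    replicates: np.ndarray | None = None  # trials per dose (binomial n)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, float)
        self.responses = np.asarray(self.responses, float)
        if self.concentrations.ndim != 1 or self.concentrations.shape != self.responses.shape:
            raise ValueError("concentrations and responses must be matching 1-D arrays")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any((self.responses < 0) | (self.responses > 1)):
            raise ValueError("responses must be fractions in [0, 1]")
        if self.replicates is not None:
            self.replicates = np.asarray(self.replicates)
            if self.replicates.shape != self.concentrations.shape:
                raise ValueError("replicates must match concentrations")


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS calibration line y = slope * x + intercept."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass
class ProbitIC50Results:
    """Fitted probit dose-response: IC50, its SE, and the link coefficients."""

    ic50: float
    ic50_se: float
    beta0: float
    beta1: float
    cov: np.ndarray
    extrapolated: bool
    n_obs: int

    def summary(self) -> str:
        lines = [
            "Probit dose-response fit",
            f"  observations        {self.n_obs}",
            f"  intercept (b0)      {self.beta0:12.5f}",
            f"  slope on log10 c    {self.beta1:12.5f}",
            f"  IC50                {self.ic50:12.6g}",
            f"  IC50 std. error     {self.ic50_se:12.6g}",
        ]
        if self.extrapolated:
            lines.append("  warning: 50% response outside the dosed range "
                         "(IC50 is an extrapolation)")
        return "\n".join(lines) + "\n"


class ProbitIC50Model:
    """Probit dose-response model, response = Phi(b0 + b1 * log10 c)."""

    def __init__(self, data: DoseResponse, link: str = "probit") -> None:
        if link not in ("probit", "logit"):
            raise ValueError("link must be 'probit' or 'logit'")
        if len(data.concentrations) < 3:
            raise ValueError("need at least 3 doses")
        if np.allclose(data.responses, data.responses[0]):
            raise ValueError("flat response data: probit fit is degenerate")
        self.data = data
        self.link = link
        self._cdf = stats.norm.cdf if link == "probit" else stats.logistic.cdf

    def fit(self) -> ProbitIC50Results:
        d = self.data
        x = np.log10(d.concentrations)
        if d.replicates is not None:
            # binomial maximum likelihood (GLM with probit/logit link)
            link = (sm.families.links.Probit() if self.link == "probit"
                    else sm.families.links.Logit())
            X = sm.add_constant(x)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.GLM(d.responses, X, family=sm.families.Binomial(link=link),
                             var_weights=np.asarray(d.replicates, float)).fit()
            beta0, beta1 = res.params
            cov = np.asarray(res.cov_params())
        else:
            # least squares on the fractions
            p0 = self._start(x, d.responses)
            with warnings.catch_warnings():
                # a perfect (noiseless) fit has singular covariance; the SE
                # is then reported as nan rather than warned about
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                popt, pcov = optimize.curve_fit(
                    lambda xx, b0, b1: self._cdf(b0 + b1 * xx),
                    x, d.responses, p0=p0, maxfev=10_000,
                )
            beta0, beta1 = popt
            cov = pcov
        if beta1 == 0 or not np.isfinite(beta1):
            raise RuntimeError("degenerate probit fit: zero slope")
        log_ic50 = -beta0 / beta1
        ic50 = 10.0 ** log_ic50
        # delta method on IC50 = 10^(-b0/b1)
        ln10 = math.log(10.0)
        grad = np.array([
            -ln10 * ic50 / beta1,
            ln10 * ic50 * beta0 / beta1**2,
        ])
        var = float(grad @ cov @ grad)
        se = math.sqrt(var) if var > 0 and np.isfinite(var) else float("nan")
        extrapolated = not (x.min() <= log_ic50 <= x.max())
        if extrapolated:
            warnings.warn("50% response not crossed within the dosed range; "
                          "IC50 is an extrapolation", stacklevel=2)
        return ProbitIC50Results(float(ic50), se, float(beta0), float(beta1),
                                 cov, extrapolated, len(x))

    @staticmethod
    def _start(x: np.ndarray, p: np.ndarray) -> tuple[float, float]:
        z = stats.norm.ppf(np.clip(p, 1e-4, 1 - 1e-4))
        slope, intercept, *_ = stats.linregress(x, z)
        if slope == 0 or not np.isfinite(slope):
            slope, intercept = 1.0, 0.0
        return intercept, slope


def probit_ic50(data: DoseResponse, link: str = "probit") -> ProbitIC50Results:
    """Fit the probit dose-response model and return the IC50 estimate."""
    return ProbitIC50Model(data, link=link).fit()


def simulate_dose_response(
    true_ic50: float,
    slope: float,
    doses: np.ndarray,
    n_replicates: int | None = None,
    rng: np.random.Generator | None = None,
) -> DoseResponse:
    """Synthetic dose-response from a true probit curve.

    Noiseless fractions when ``n_replicates`` is None; otherwise binomial
    counts out of ``n_replicates`` trials per dose (seeded via *rng*).
    """
    doses = np.asarray(doses, float)
    p = stats.norm.cdf(slope * (np.log10(doses) - math.log10(true_ic50)))
    if n_replicates is None:
        return DoseResponse(doses, p)
    if rng is None:
        rng = np.random.default_rng()
    k = rng.binomial(n_replicates, p)
    return DoseResponse(doses, k / n_replicates,
                        np.full(doses.shape, n_replicates))


# ---------------------------------------------------------------------------
# linear calibration
# ---------------------------------------------------------------------------

def linear_calibration(x: np.ndarray, y: np.ndarray) -> CalibrationCurve:
    """OLS fit of standards (>= 2 distinct x values)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(np.unique(x)) < 2:
        raise ValueError("need >= 2 standards with distinct x values")
    res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    return CalibrationCurve(float(res.slope), float(res.intercept), r2)


def quantify(curve: CalibrationCurve, y_obs: float | np.ndarray):
    """Invert the calibration line: x = (y - intercept) / slope."""
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; cannot quantify")
    return (np.asarray(y_obs, float) - curve.intercept) / curve.slope


# ---------------------------------------------------------------------------
# ROS inhibition
# ---------------------------------------------------------------------------

def inhibition_percent(control: float, treated: float) -> float:
    """Percent reduction relative to control: 100 (control - treated)/control."""
    if not (0.0 <= control <= 100.0 and 0.0 <= treated <= 100.0):
        raise ValueError("percent-positive values must lie in [0, 100]")
    if control == 0:
        raise ZeroDivisionError("inhibition undefined for zero control")
    return 100.0 * (control - treated) / control


def inhibition_table(table: pd.DataFrame, control_label: str = "Control",
                     flag_threshold: float = 70.0) -> pd.DataFrame:
    """Per-treatment, per-timepoint inhibition relative to the control row.

    *table* columns: ``treatment``, ``timepoint_h``, ``percent_positive``.
    Adds ``inhibition_percent`` (full precision), ``inhibition_rounded``
    (nearest integer) and ``exceeds_threshold``.
    """
    required = {"treatment", "timepoint_h", "percent_positive"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    out_rows = []
    for t, grp in table.groupby("timepoint_h", sort=True):
        ctrl = grp.loc[grp["treatment"] == control_label, "percent_positive"]
        if ctrl.empty:
            raise ValueError(f"no control row {control_label!r} at {t} h")
        c = float(ctrl.iloc[0])
        for _, row in grp.iterrows():
            if row["treatment"] == control_label:
                continue
            inh = inhibition_percent(c, float(row["percent_positive"]))
            out_rows.append({
                "treatment": row["treatment"],
                "timepoint_h": t,
                "percent_positive": row["percent_positive"],
                "inhibition_percent": inh,
                "inhibition_rounded": int(round(inh)),
                "exceeds_threshold": inh > flag_threshold,
            })
    return pd.DataFrame(out_rows)


def load_ros_table() -> pd.DataFrame:
    """The bundled ROS positive-cell table (THP-1 macrophages, flow cytometry)."""
    path = files("pgalbind.data").joinpath("ros_thp1.csv")
    return pd.read_csv(str(path))
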