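"""Single-hit multitarget survival model and dose-equivalence ratios.

Survival after dose ``D`` is ``1 - (1 - exp(-D/D0))**m`` with ``D0``
the 37%-survival dose of the exponential tail and ``m`` the
extrapolation number.  The shoulder dose ``Dq = D0 * ln(m)`` is the
x-intercept of the log-linear asymptote and serves as the equivalence
scale between treatments.  Fitting minimizes unweighted squared error
on the survival-fraction scale across replicates; initial values come
from the classical graphical construction (terminal log-slope for D0,
zero-dose intercept of the asymptote for m).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from ._report import report_round
from .errors import DataError, DegenerateFitError

__all__ = [
    "SurvivalCurve",
    "survival",
    "shoulder_dose",
    "fit_survival",
    "FitResult",
    "sensitivity_ratio",
    "dose_fraction",
    "read_dose_response",
]


@dataclass(frozen=True)
class SurvivalCurve:
    """Fitted dose-response parameters."""

    d0: float
    m: float

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise DataError(f"D0 must be > 0, got {self.d0}")
        if self.m < 1:
            raise DataError(f"m must be >= 1, got {self.m}")

    @property
    def dq(self) -> float:
        return shoulder_dose(self.d0, self.m)


def survival(dose, curve: SurvivalCurve):
    """Survival fraction at ``dose`` (scalar or array) under the model."""
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise DataError("dose must be >= 0")
    s = 1.0 - (1.0 - np.exp(-d / curve.d0)) ** curve.m
    return float(s) if np.isscalar(dose) else s


def shoulder_dose(d0: float, m: float) -> float:
    """Shoulder dose ``Dq = D0 * ln(m)``."""
    if d0 <= 0:
        raise DataError(f"D0 must be > 0, got {d0}")
    if m < 1:
        raise DataError(f"m must be >= 1, got {m}")
    return d0 * float(np.log(m))


@dataclass
class FitResult:
    curve: SurvivalCurve
    residual_ss: float
    n_points: int
    converged: bool

    def to_json(self) -> str:
        d = asdict(self)
        d["dq"] = self.curve.dq
        return json.dumps(d, indent=2)


REQUIRED_COLUMNS = ("dose", "survivors", "total", "replicate")


def read_dose_response(path: str) -> pd.DataFrame:
    """Read a dose-response CSV (dose, survivors, total, replicate)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"dose-response CSV missing columns: {missing}")
    return validate_dose_response(df)


def validate_dose_response(df: pd.DataFrame) -> pd.DataFrame:
    if (df["dose"] < 0).any():
        raise DataError("doses must be >= 0")
    if ((df["survivors"] < 0) | (df["survivors"] > df["total"])).any():
        raise DataError("require 0 <= survivors <= total")
    return df


def _initial_guess(df: pd.DataFrame) -> tuple[float, float]:
    """Graphical-method initialization from the terminal log-slope."""
    mean = (
        df.assign(s=df["survivors"] / df["total"])
        .groupby("dose")["s"]
        .mean()
        .sort_index()
    )
    pos = mean[mean > 0]
    tail = pos.iloc[-max(2, len(pos) // 2) :]
    if len(tail) >= 2 and tail.index.max() > tail.index.min():
        slope, intercept = np.polyfit(tail.index.values, np.log(tail.values), 1)
        d0 = -1.0 / slope if slope < 0 else float(mean.index.max())
        m = float(np.exp(intercept))
    else:
        d0 = float(mean.index.max() or 1.0)
        m = 2.0
    return max(d0, 1e-6), max(m, 1.0)


def fit_survival(data: pd.DataFrame) -> FitResult:
    """Least-squares fit of (D0, m) to per-replicate survival fractions.

    Requires at least three distinct doses including a low-dose anchor;
    all-survival or all-death data are degenerate and rejected.
    """
    df = validate_dose_response(data)
    if df["dose"].nunique() < 3:
        raise DegenerateFitError("need >= 3 distinct doses")
    frac = df["survivors"] / df["total"]
    if (frac == 1.0).all() or (frac == 0.0).all():
        raise DegenerateFitError("all-survival or all-death data cannot be fitted")
    doses = df["dose"].to_numpy(float)
    obs = frac.to_numpy(float)

    def residuals(params: np.ndarray) -> np.ndarray:
        d0, m = params
        model = 1.0 - (1.0 - np.exp(-doses / d0)) ** m
        return model - obs

    x0 = np.array(_initial_guess(df))
    result = least_squares(
        residuals,
        x0,
        bounds=([1e-9, 1.0], [np.inf, np.inf]),
        method="trf",
    )
    if not result.success:
        raise DegenerateFitError(
            f"fit did not converge (last iterate D0={result.x[0]:.4g}, "
            f"m={result.x[1]:.4g}, residual={2 * result.cost:.4g})"
        )
    curve = SurvivalCurve(d0=float(result.x[0]), m=float(result.x[1]))
    return FitResult(
        curve=curve,
        residual_ss=float(2 * result.cost),
        n_points=len(df),
        converged=True,
    )


def sensitivity_ratio(dq_reference: float, dq_test: float) -> float:
    """Fold-difference in sensitivity from two shoulder doses (one decimal)."""
    if dq_reference <= 0 or dq_test <= 0:
        raise DataError("shoulder doses must be > 0")
    return report_round(dq_reference / dq_test, 1)


def dose_fraction(dose: float, dq: float) -> int:
    """A dose expressed as a whole percentage of the shoulder dose."""
    if dq <= 0:
        raise DataError("Dq must be > 0")
    if dose < 0:
        raise DataError("dose must be >= 0")
    return int(report_round(100.0 * dose / dq, 0))
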