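"""Per-reaction amplification efficiency from raw fluorescence curves.

The pipeline mirrors how single-tube qPCR kinetics are analysed: remove
background fluorescence (three baseline conventions), fit a four-parameter
logistic to the corrected trace, locate the cycle of the second-derivative
maximum (cpD2, the standard take-off landmark), and read the efficiency as
the per-cycle fluorescence ratio E = F(n)/F(n-1) at the quantification
point n where the fitted curve reaches 20% of its fluorescence at cpD2.
E = 1 means no amplification, E = 2 perfect doubling every cycle.

All landmark quantities have closed forms for the logistic
F(c) = F0 + a / (1 + exp(-(c - m)/b)):
cpD2 = m - b*ln(2 + sqrt(3)), and the rising limb inverts analytically, so
n and E come from the fitted parameters, not from noisy raw cycles.  n is
kept real-valued: E is evaluated on the fitted curve, where rounding to an
integer cycle would only add a phase-dependent bias.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (
    ConfigurationError,
    EstimationError,
    FitError,
    NoAmplificationError,
)

__all__ = [
    "AmplificationCurve",
    "EfficiencyEstimate",
    "SigmoidFit",
    "baseline_correct",
    "estimate_efficiency",
    "estimate_plate",
    "fit_sigmoid",
    "logistic",
    "read_curves_csv",
    "second_derivative_max",
    "write_estimates_csv",
]

BASELINE_METHODS = ("standard", "dynamic_tube", "adaptive")

#: ln(2 + sqrt(3)): cycles between the logistic midpoint and cpD2, in units of b.
LN_2_PLUS_SQRT3 = math.log(2.0 + math.sqrt(3.0))
#: Sigmoid fraction of the amplitude at cpD2: 1 / (3 + sqrt(3)).
SIGMOID_FRACTION_AT_CPD2 = 1.0 / (3.0 + math.sqrt(3.0))
#: Fraction of the amplitude at the quantification point (20% of F(cpD2)).
QUANT_FRACTION = 0.2 * SIGMOID_FRACTION_AT_CPD2
#: exp((n - m)/b) at the quantification point, a shape constant of the logistic.
QUANT_U = QUANT_FRACTION / (1.0 - QUANT_FRACTION)

MIN_CYCLES = 10
_B_STARTS = (1.0, 2.0, 4.0, 8.0, 16.0)  # deterministic restart ladder for the slope


@dataclass(frozen=True)
class AmplificationCurve:
    """One reaction's cycle/fluorescence trace plus its baseline state."""

    cycles: np.ndarray
    fluorescence: np.ndarray
    baseline_state: str = "raw"
    baseline_level: float | None = None  # what was subtracted, if corrected here

    def __post_init__(self):
        cyc = np.asarray(self.cycles, dtype=float)
        flu = np.asarray(self.fluorescence, dtype=float)
        if cyc.ndim != 1 or flu.ndim != 1 or len(cyc) != len(flu):
            raise ConfigurationError("cycles and fluorescence must be 1-D and equal length")
        if len(cyc) and np.any(np.diff(cyc) <= 0):
            raise ConfigurationError("cycles must be strictly increasing")
        if not np.all(np.isfinite(flu)):
            raise ConfigurationError("fluorescence values must be finite")
        object.__setattr__(self, "cycles", cyc)
        object.__setattr__(self, "fluorescence", flu)

    def __len__(self) -> int:
        return len(self.cycles)


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted 4-parameter logistic: F(c) = f0 + amplitude/(1+exp(-(c-midpoint)/slope))."""

    f0: float
    amplitude: float
    midpoint: float
    slope: float
    sse: float

    def __call__(self, c):
        return logistic(c, self.f0, self.amplitude, self.midpoint, self.slope)


@dataclass(frozen=True)
class EfficiencyEstimate:
    """Efficiency E with the landmarks it was read from.

    For a no-amplification curve E = 1 and the landmarks are NaN.
    """

    efficiency: float
    n: float
    cpd2: float
    f_at_cpd2: float
    fit: SigmoidFit | None

    @property
    def amplified(self) -> bool:
        return self.fit is not None


def logistic(c, f0, amplitude, midpoint, slope):
    """4-parameter logistic evaluated at cycle(s) *c*."""
    z = np.clip((np.asarray(c, dtype=float) - midpoint) / slope, -700, 700)
    return f0 + amplitude / (1.0 + np.exp(-z))


def baseline_correct(curve: AmplificationCurve, method: str = "standard") -> AmplificationCurve:
    """Subtract background fluorescence; returns a new curve.

    standard
        subtract the mean fluorescence of the first five cycles.
    dynamic_tube
        locate the take-off as the maximum of the smoothed finite-difference
        second derivative and subtract the mean fluorescence of all cycles
        before it (falls back to standard, with a warning, when the trace is
        flat or the take-off leaves no baseline cycles).
    adaptive
        subtract the median of the lowest quartile of fluorescence values.

    Corrected values may be negative.  Re-correcting an already corrected
    curve is an error.
    """
    if method not in BASELINE_METHODS:
        raise ConfigurationError(
            f"unknown baseline method {method!r}; choose from {BASELINE_METHODS}"
        )
    if curve.baseline_state != "raw":
        raise ConfigurationError(
            f"curve is already baseline-corrected ({curve.baseline_state!r})"
        )
    if len(curve) < MIN_CYCLES:
        raise ConfigurationError(f"need at least {MIN_CYCLES} cycles, got {len(curve)}")
    flu = curve.fluorescence
    if method == "standard":
        level = float(np.mean(flu[:5]))
    elif method == "adaptive":
        q = np.quantile(flu, 0.25)
        level = float(np.median(flu[flu <= q]))
    else:  # dynamic_tube
        if np.ptp(flu) == 0.0:
            warnings.warn(
                "constant trace: dynamic_tube take-off undefined, using standard"
            )
            return replace(
                baseline_correct(curve, "standard"), baseline_state="dynamic_tube"
            )
        smooth = np.convolve(flu, np.ones(3) / 3.0, mode="same")
        d2 = np.diff(smooth, 2)
        takeoff = int(np.argmax(d2)) + 1  # index of the centre point of the 2nd diff
        if takeoff < 2:
            warnings.warn("take-off at the curve start, falling back to standard")
            return replace(
                baseline_correct(curve, "standard"), baseline_state="dynamic_tube"
            )
        level = float(np.mean(flu[:takeoff]))
    return AmplificationCurve(
        curve.cycles, flu - level, baseline_state=method, baseline_level=level
    )


def _no_amplification(curve: AmplificationCurve, min_ratio: float) -> bool:
    """Flat-curve detector: raw-scale max/median fluorescence ratio below
    *min_ratio* (the baseline subtracted here is added back when known)."""
    flu = curve.fluorescence
    base = curve.baseline_level
    if base is not None and base > 0:
        denom = base + float(np.median(flu))
        if denom <= 0:
            return float(np.ptp(flu)) == 0.0
        return (base + float(np.max(flu))) / denom < min_ratio
    # baseline unknown (externally corrected curve): only a truly flat
    # trace can be called non-amplified reliably
    return float(np.ptp(flu)) <= 1e-12 * max(1.0, float(np.abs(flu).max()))


def fit_sigmoid(curve: AmplificationCurve, min_fluorescence_ratio: float = 1.2) -> SigmoidFit:
    """Least-squares 4-parameter logistic fit of a baseline-corrected curve.

    Raises :class:`NoAmplificationError` when the raw-scale max/median
    fluorescence ratio falls below *min_fluorescence_ratio* (the flat-curve
    case, which callers map to E = 1), and :class:`FitError` when the
    optimizer cannot produce a finite fit with positive amplitude and slope.
    """
    if curve.baseline_state == "raw":
        raise ConfigurationError("baseline-correct the curve before fitting")
    if len(curve) < MIN_CYCLES:
        raise ConfigurationError(f"need at least {MIN_CYCLES} cycles, got {len(curve)}")
    cyc, flu = curve.cycles, curve.fluorescence
    amplitude = float(np.ptp(flu))
    if _no_amplification(curve, min_fluorescence_ratio):
        raise NoAmplificationError(
            f"max/median fluorescence ratio below {min_fluorescence_ratio:g}"
        )
    f0_init = float(np.min(flu))
    mid_init = float(cyc[int(np.argmax(np.diff(flu))) + 1])
    best: SigmoidFit | None = None
    for b0 in _B_STARTS:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                params, _ = curve_fit(
                    logistic, cyc, flu,
                    p0=[f0_init, amplitude, mid_init, b0],
                    maxfev=50000, xtol=1e-12, ftol=1e-12, gtol=1e-12,
                )
        except RuntimeError:
            continue
        f0, a, m, b = (float(v) for v in params)
        if not all(map(math.isfinite, (f0, a, m, b))) or a <= 0 or b <= 0:
            continue
        resid = flu - logistic(cyc, f0, a, m, b)
        sse = float(resid @ resid)
        if best is None or sse < best.sse:
            best = SigmoidFit(f0, a, m, b, sse)
    if best is None:
        raise FitError("logistic fit did not converge from any restart")
    return best


def second_derivative_max(fit: SigmoidFit) -> float:
    """Analytic cycle of the second-derivative maximum: midpoint - slope*ln(2+sqrt(3))."""
    if fit.slope <= 0:
        raise FitError(f"invalid fit: slope {fit.slope:.4g} must be positive")
    return fit.midpoint - fit.slope * LN_2_PLUS_SQRT3


def estimate_efficiency(
    curve: AmplificationCurve, min_fluorescence_ratio: float = 1.2
) -> EfficiencyEstimate:
    """Estimate E = F(n)/F(n-1) at the 20%-of-cpD2 quantification point.

    A flat (no-amplification) curve yields E = 1.  Raises
    :class:`EstimationError` when the 20% target falls at or below the
    fitted baseline, i.e. the exponential phase was never observed.
    """
    try:
        fit = fit_sigmoid(curve, min_fluorescence_ratio=min_fluorescence_ratio)
    except NoAmplificationError:
        return EfficiencyEstimate(1.0, math.nan, math.nan, math.nan, None)
    cpd2 = second_derivative_max(fit)
    f_cpd2 = float(fit(cpd2))
    if 0.2 * f_cpd2 <= fit.f0:
        raise EstimationError(
            "20% of the cpD2 fluorescence is below the fitted baseline; "
            "exponential phase not observed"
        )
    # E is the ratio of amplified product, i.e. of fitted fluorescence net of
    # the residual baseline f0 (zero for a perfectly corrected curve); the 20%
    # target on that scale is a fixed fraction of the amplitude, so the rising
    # limb inverts to n = midpoint + slope * ln(u*)
    n = fit.midpoint + fit.slope * math.log(QUANT_U)
    sig = lambda c: fit(c) - fit.f0  # noqa: E731 - amplified component
    eff = float(sig(n) / sig(n - 1.0))
    return EfficiencyEstimate(eff, n, cpd2, f_cpd2, fit)


# ---------------------------------------------------------------------------
# plate-level I/O helpers

def read_curves_csv(path, layout: str = "long") -> dict[str, AmplificationCurve]:
    """Read per-well curves from CSV.

    ``long`` expects columns well, cycle, fluorescence (one row per
    measurement); ``wide`` expects a cycle column followed by one column per
    well.
    """
    df = pd.read_csv(path)
    curves: dict[str, AmplificationCurve] = {}
    if layout == "long":
        required = {"well", "cycle", "fluorescence"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"long curve CSV is missing columns {sorted(missing)}")
        for well, grp in df.groupby("well", sort=False):
            grp = grp.sort_values("cycle")
            curves[str(well)] = AmplificationCurve(
                grp["cycle"].to_numpy(), grp["fluorescence"].to_numpy()
            )
    elif layout == "wide":
        if "cycle" not in df.columns:
            raise ConfigurationError("wide curve CSV needs a 'cycle' column")
        cyc = df["cycle"].to_numpy()
        for col in df.columns:
            if col != "cycle":
                curves[str(col)] = AmplificationCurve(cyc, df[col].to_numpy())
    else:
        raise ConfigurationError(f"unknown curve layout {layout!r}")
    return curves


def estimate_plate(
    curves: dict[str, AmplificationCurve], baseline: str = "standard"
) -> pd.DataFrame:
    """Baseline-correct and estimate every well; one row per well."""
    rows = []
    for well, curve in curves.items():
        if curve.baseline_state == "raw":
            curve = baseline_correct(curve, baseline)
        est = estimate_efficiency(curve)
        rows.append(
            {
                "well": well,
                "efficiency": est.efficiency,
                "n": est.n,
                "cpD2": est.cpd2,
                "f_at_cpD2": est.f_at_cpd2,
                "amplified": est.amplified,
                "sse": est.fit.sse if est.fit else math.nan,
            }
        )
    return pd.DataFrame(rows)


def write_estimates_csv(estimates: pd.DataFrame, path) -> None:
    estimates.to_csv(path, index=False)
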